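"""Binned CNV profiles: readers, SKY/WGS comparison, L1 trees, events."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from karyoevo import (
    CNVProfile,
    SegmentDirection,
    build_manual_tree,
    classify_segment_events,
    cnv_l1_distance,
    cnv_nj_tree,
    compare_sky_wgs,
    detect_segment_events,
    karyotype_to_bins,
    read_bin_table,
    sky_chrom_log2,
    wgs_chrom_log2,
    write_bin_table,
)
from karyoevo.simulate import toy_chrom_sizes

from conftest import make_cell


def profile(sample_id, values_by_chrom, bin_size=10_000):
    frames = []
    for chrom, vals in values_by_chrom.items():
        starts = np.arange(len(vals)) * bin_size
        frames.append(pd.DataFrame({
            "chrom": chrom, "start": starts, "end": starts + bin_size,
            "log2_ratio": vals}))
    return CNVProfile(sample_id, pd.concat(frames, ignore_index=True),
                      bin_size)


class TestReader:
    def test_minimal_three_bin_file(self, tmp_path):
        p = tmp_path / "b.tsv"
        p.write_text("chrom\tstart\tend\tlog2_ratio\n"
                     "1\t0\t10000\t0.1\n1\t10000\t20000\t-0.2\n"
                     "2\t0\t10000\t0.0\n")
        prof = read_bin_table(p, sample_id="s")
        assert len(prof.bins) == 3
        assert prof.chromosomes() == ["1", "2"]

    def test_linear_ratio_one_becomes_log2_zero(self, tmp_path):
        p = tmp_path / "b.tsv"
        p.write_text("chromosome\tstart\tratio\n1\t0\t1.0\n1\t10000\t2.0\n")
        prof = read_bin_table(p, sample_id="s")
        assert prof.bins["log2_ratio"].tolist() == pytest.approx([0.0, 1.0])

    def test_nonpositive_ratio_rejected(self, tmp_path):
        p = tmp_path / "b.tsv"
        p.write_text("chrom\tstart\tratio\n1\t0\t0.0\n")
        with pytest.raises(ValueError, match="ratio"):
            read_bin_table(p)

    def test_off_grid_bin_rejected_naming_position(self, tmp_path):
        p = tmp_path / "b.tsv"
        p.write_text("chrom\tstart\tend\tlog2_ratio\n1\t5000\t15000\t0.0\n")
        with pytest.raises(ValueError, match="1:5000"):
            read_bin_table(p)

    def test_round_trip(self, tmp_path, type2_cnv_case):
        prof = next(iter(type2_cnv_case.cnv_profiles.values()))
        p = tmp_path / "b.tsv"
        write_bin_table(prof, p)
        back = read_bin_table(p, sample_id=prof.sample_id)
        pd.testing.assert_frame_equal(back.bins, prof.bins)


BALANCED = {"X": 1, "Y": 1}  # raise sex chromosomes to the autosomal level


class TestSkyLog2:
    def test_equal_counts_give_all_zero(self):
        cell = make_cell(delta=BALANCED)  # every chromosome at 2 copies
        assert all(v == 0 for v in sky_chrom_log2([cell]).values())

    def test_half_median_count_gives_minus_one(self):
        vals = sky_chrom_log2([make_cell(delta=BALANCED | {"19": -1})])
        assert vals["19"] == pytest.approx(-1.0)
        assert vals["1"] == pytest.approx(0.0)

    def test_y_chromosome_excluded(self):
        assert "Y" not in sky_chrom_log2([make_cell()])

    def test_pure_wgd_population_equals_diploid_ancestor(self):
        # median normalization cancels ploidy exactly
        diploid = sky_chrom_log2([make_cell("a")])
        doubled = sky_chrom_log2([make_cell("b", wgd=True)])
        assert doubled == diploid

    def test_simulated_wgd_chr19_loss_population(self):
        cells = [make_cell(f"c{i}", wgd=True,
                           delta={"19": -2, "X": 2, "Y": 2})
                 for i in range(10)]
        vals = sky_chrom_log2(cells)
        assert vals["19"] == pytest.approx(-1.0)
        assert all(abs(vals[c]) < 1e-12 for c in vals if c != "19")


class TestWgsLog2:
    def test_flat_profile_returns_its_level(self):
        prof = profile("s", {"1": [0.585] * 10})
        assert wgs_chrom_log2(prof)["1"] == pytest.approx(0.585)

    def test_median_robust_to_outlier_bin(self):
        vals = [0.0] * 9 + [3.0]
        prof = profile("s", {"1": vals})
        assert wgs_chrom_log2(prof)["1"] == pytest.approx(0.0)


class TestCompare:
    def test_identical_maps_give_r_one(self):
        sky = {"1": 0.0, "2": 0.5, "3": -1.0, "4": 0.2}
        cmp = compare_sky_wgs(sky, dict(sky))
        assert cmp.pearson_r == pytest.approx(1.0)

    def test_negated_maps_give_r_minus_one(self):
        sky = {"1": 0.0, "2": 0.5, "3": -1.0}
        cmp = compare_sky_wgs(sky, {k: -v for k, v in sky.items()})
        assert cmp.pearson_r == pytest.approx(-1.0)

    def test_zero_variance_flagged_undefined(self):
        cmp = compare_sky_wgs({"1": 0.0, "2": 0.0, "3": 0.0},
                              {"1": 0.1, "2": 0.2, "3": 0.3})
        assert not cmp.defined

    def test_noiseless_matched_synthetic_r_is_one(self, toy_sizes):
        # bins generated from the same sex-balanced karyotype as the SKY
        # counts; under a uniform baseline the two log2 maps are identical
        cells = [make_cell(f"c{i}", wgd=True,
                           delta={"19": -2, "6": 1, "X": 2, "Y": 2})
                 for i in range(5)]
        sky = sky_chrom_log2(cells)
        wgs = wgs_chrom_log2(karyotype_to_bins(
            cells[0], toy_sizes, noise_sd_log2=0.0,
            baseline={c: 2 for c in toy_sizes}))
        cmp = compare_sky_wgs(sky, wgs)
        assert cmp.pearson_r == pytest.approx(1.0, abs=1e-12)


class TestL1Distance:
    def test_identical_profiles_distance_zero(self):
        a = profile("a", {"1": [0.1, -0.2, 0.3]})
        assert cnv_l1_distance(a, a) == 0.0

    def test_single_bin_difference(self):
        a = profile("a", {"1": [0.0, 0.0]})
        b = profile("b", {"1": [0.0, 0.5]})
        assert cnv_l1_distance(a, b) == pytest.approx(0.5)

    def test_three_bin_hand_sum(self):
        a = profile("a", {"1": [0.2, -0.1, 0.0]})
        b = profile("b", {"1": [0.0, 0.2, -0.1]})
        assert cnv_l1_distance(a, b) == pytest.approx(0.2 + 0.3 + 0.1)

    def test_disjoint_grids_rejected(self):
        a = profile("a", {"1": [0.0]})
        b = profile("b", {"2": [0.0]})
        with pytest.raises(ValueError, match="share no bins"):
            cnv_l1_distance(a, b)

    @given(st.lists(st.tuples(
        st.floats(-2, 2, allow_nan=False),
        st.floats(-2, 2, allow_nan=False),
        st.floats(-2, 2, allow_nan=False)), min_size=1, max_size=12))
    @settings(max_examples=100, deadline=None)
    def test_metric_properties(self, triples):
        xs = [t[0] for t in triples]
        ys = [t[1] for t in triples]
        zs = [t[2] for t in triples]
        a, b, c = (profile(n, {"1": v})
                   for n, v in (("a", xs), ("b", ys), ("c", zs)))
        dab, dbc, dac = (cnv_l1_distance(a, b), cnv_l1_distance(b, c),
                         cnv_l1_distance(a, c))
        assert dab >= 0
        assert dab == pytest.approx(cnv_l1_distance(b, a))
        assert dac <= dab + dbc + 1e-9
        assert cnv_l1_distance(a, a) == 0.0


class TestCnvTree:
    def test_divergent_profile_on_long_branch(self):
        base = {"1": [0.0] * 10}
        profs = [profile(f"s{i}", base) for i in range(3)]
        profs.append(profile("far", {"1": [1.0] * 10}))
        tree = cnv_nj_tree(profs, include_control=False)
        assert tree.path_length("far", "s0") == pytest.approx(10.0)
        assert tree.path_length("s0", "s1") == pytest.approx(0.0)

    def test_near_2n_clones_closer_to_outgroup_than_sub_4n(self,
                                                           type2_cnv_case,
                                                           toy_sizes):
        """Seven single-cell-derived clones: near-2N clones with and without
        the founding NRT sit closer to the normal outgroup than their
        sub-4N counterparts on the L1 tree."""
        case = type2_cnv_case
        near = [c for s in case.samples for c in s.cells
                if case.clone_of_cell[c.cell_id] == "FC_NRT"][:4]
        sub = [c for s in case.samples for c in s.cells
               if case.clone_of_cell[c.cell_id] == "FC_WGD"][:3]
        assert len(near) == 4 and len(sub) == 3
        profs = [karyotype_to_bins(c, toy_sizes, noise_sd_log2=0.0,
                                   sample_id=f"near{i}")
                 for i, c in enumerate(near)]
        profs += [karyotype_to_bins(c, toy_sizes, noise_sd_log2=0.0,
                                    sample_id=f"sub{i}")
                  for i, c in enumerate(sub)]
        tree = cnv_nj_tree(profs, include_control=True)
        lengths = tree.root_to_leaf_lengths()
        assert max(lengths[f"near{i}"] for i in range(4)) < \
            min(lengths[f"sub{i}"] for i in range(3))

    def test_identical_profiles_give_zero_star(self):
        profs = [profile(f"s{i}", {"1": [0.3] * 5}) for i in range(4)]
        tree = cnv_nj_tree(profs, include_control=False)
        for a in ("s0", "s1", "s2", "s3"):
            for b in ("s0", "s1", "s2", "s3"):
                if a != b:
                    assert tree.path_length(a, b) == pytest.approx(0.0)


class TestSegmentEvents:
    def test_identical_deletion_in_two_samples_is_shared(self):
        vals = [0.0] * 3 + [-1.0] * 4 + [0.0] * 13
        profs = {"s1": profile("s1", {"1": vals}),
                 "s2": profile("s2", {"1": vals})}
        part = classify_segment_events(profs)
        assert len(part.shared["s1"]) == 1
        assert part.shared["s1"][0].key == part.shared["s2"][0].key
        assert not part.private["s1"]

    def test_boundary_off_by_one_bin_is_private(self):
        v1 = [0.0] * 3 + [-1.0] * 4 + [0.0] * 13
        v2 = [0.0] * 4 + [-1.0] * 3 + [0.0] * 13
        part = classify_segment_events({
            "s1": profile("s1", {"1": v1}),
            "s2": profile("s2", {"1": v2})})
        assert not part.shared["s1"] and not part.shared["s2"]
        assert len(part.private["s1"]) == 1

    def test_whole_chromosome_loss_excluded(self):
        whole = [-1.0] * 20
        focal = [0.0] * 18 + [-1.0] * 2
        part = classify_segment_events({
            "s1": profile("s1", {"19": whole, "1": focal}),
            "s2": profile("s2", {"19": whole, "1": focal})})
        assert all(e.chrom != "19"
                   for e in part.shared["s1"] + part.private["s1"])
        assert part.excluded_whole_chromosome["s1"][0].chrom == "19"
        assert len(part.shared["s1"]) == 1  # the focal event still shared

    def test_direction_detected(self):
        prof = profile("s", {"1": [0.0, 0.7, 0.7, 0.0, -0.8, 0.0]})
        evts = detect_segment_events(prof)
        dirs = sorted(e.direction for e in evts)
        assert dirs == [SegmentDirection.GAIN, SegmentDirection.LOSS]


class TestManualTree:
    def test_trunk_and_branch_lengths_proportional_to_event_counts(self):
        # 20 bins; four events shared by both samples (losses at bins 2-4
        # and 15-16, gains at 6-7 and 12-13), plus isolated private bins
        shared = [0.0, 0.0, -1.0, -1.0, -1.0, 0.0, 0.8, 0.8, 0.0, 0.0,
                  0.0, 0.0, 0.9, 0.9, 0.0, -0.9, -0.9, 0.0, 0.0, 0.0]
        p1 = list(shared)
        p1[0] = 1.2                      # private gain
        p1[9] = -1.2                     # private loss
        p2 = list(shared)
        p2[1] = 1.4                      # private gain (next to a loss run)
        p2[10] = -1.3                    # private loss
        p2[18] = -1.5                    # private loss
        part = classify_segment_events({
            "s1": profile("s1", {"1": p1}, bin_size=10_000),
            "s2": profile("s2", {"1": p2}, bin_size=10_000)})
        assert len(part.shared["s1"]) == 4
        assert len(part.private["s1"]) == 2
        assert len(part.private["s2"]) == 3
        tree = build_manual_tree(part)
        lengths = tree.root_to_leaf_lengths()
        assert lengths["s1"] == pytest.approx(4 + 2)
        assert lengths["s2"] == pytest.approx(4 + 3)
        assert tree.path_length("s1", "s2") == pytest.approx(2 + 3)

    def test_no_shared_events_gives_zero_trunk(self):
        p1 = [0.0] * 5 + [-1.0] * 2 + [0.0] * 13
        p2 = [0.0] * 10 + [1.0] * 2 + [0.0] * 8
        part = classify_segment_events({
            "s1": profile("s1", {"1": p1}),
            "s2": profile("s2", {"1": p2})})
        tree = build_manual_tree(part)
        assert tree.root_to_leaf_lengths()["s1"] == pytest.approx(1.0)
        assert tree.path_length("s1", "s2") == pytest.approx(2.0)

    def test_simulated_trunk_contains_planted_early_driver(self,
                                                           type2_cnv_case):
        case = type2_cnv_case
        part = classify_segment_events(case.cnv_profiles)
        chrom, start, end = case.config.focal_deletion
        sid = case.samples[0].sample_id
        trunk_keys = {e.key for e in part.shared[sid]}
        assert any(k[0] == chrom and k[1] == start and k[2] == end
                   and k[3] == SegmentDirection.LOSS for k in trunk_keys)
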