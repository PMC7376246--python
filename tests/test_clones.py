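"""Founder clones: identification, genotype containment, ordering, seeding."""

from __future__ import annotations

import pytest

from karyoevo import (
    FounderClone,
    Scenario,
    SimulationConfig,
    build_distance_matrix,
    canonicalize,
    genotype_contains,
    identify_founder_clones,
    infer_seeding_pattern,
    neighbor_joining,
    order_founder_clones,
    root_with_outgroup,
    simulate_case,
)
from karyoevo.clones import FCGenotype

from conftest import make_cell


def fcs_from_cells(cells):
    tree = root_with_outgroup(
        neighbor_joining(build_distance_matrix(cells, include_control=True)))
    return identify_founder_clones(tree, cells), tree


class TestIdentify:
    def test_identical_cells_form_one_clone(self):
        cells = [make_cell(f"c{i}", events=["t(2;4)"]) for i in range(5)]
        fcs, _ = fcs_from_cells(cells)
        assert len(fcs) == 1
        assert set(fcs[0].member_cells) == {c.cell_id for c in cells}

    def test_nested_event_sets_give_two_clones(self):
        # {chr16 loss} and {chr16 loss, t(2;4)}: two clones whose genotypes
        # nest on the shared chr16 loss
        early = [make_cell(f"e{i}", delta={"16": -1}) for i in range(3)]
        late = [make_cell(f"l{i}", delta={"16": -1}, events=["t(2;4)"])
                for i in range(3)]
        fcs, _ = fcs_from_cells(early + late)
        assert len(fcs) == 2
        by_members = {fc.member_cells: fc for fc in fcs}
        genos = sorted(fcs, key=lambda fc: fc.genotype.n_events)
        assert genotype_contains(genos[0].genotype, genos[1].genotype)
        assert ("16", -1.0) in genos[0].genotype.deviations
        assert ("16", -1.0) in genos[1].genotype.deviations

    def test_singletons_flagged_low_confidence(self):
        cells = [make_cell(f"c{i}", events=["t(2;4)"]) for i in range(4)]
        cells.append(make_cell("odd", events=["t(6;9)"]))
        fcs, _ = fcs_from_cells(cells)
        singles = [fc for fc in fcs if len(fc.member_cells) == 1]
        assert singles and all(fc.low_confidence for fc in singles)

    def test_genotype_is_intersection_of_member_events(self, type2_case):
        for sample in type2_case.samples:
            cells = list(sample.cells)
            fcs, _ = fcs_from_cells(cells)
            by_id = {c.cell_id: c for c in cells}
            for fc in fcs:
                profiles = [canonicalize(by_id[m]) for m in fc.member_cells]
                shared = set(profiles[0].events)
                for p in profiles[1:]:
                    shared &= set(p.events)
                assert set(fc.genotype.event_dict) == shared


class TestContainment:
    def g(self, wgd=False, events=(), devs=()):
        return FCGenotype(wgd=wgd, events=tuple(events),
                          deviations=tuple(devs))

    def test_wgd_is_irreversible(self):
        assert not genotype_contains(self.g(wgd=True), self.g(wgd=False))
        assert genotype_contains(self.g(wgd=False), self.g(wgd=True))

    def test_event_subset_required(self):
        key = ("NRT", ("2", "4"), "b1")
        assert genotype_contains(self.g(), self.g(events=[(key, 1)]))
        assert not genotype_contains(self.g(events=[(key, 1)]), self.g())

    def test_losses_may_deepen_but_not_revert(self):
        lost = self.g(devs=[("16", -1.0)])
        deeper = self.g(devs=[("16", -2.0)])
        assert genotype_contains(lost, deeper)
        assert not genotype_contains(deeper, lost)

    def test_wgd_rescaling_doubles_deviations(self):
        near = self.g(devs=[("16", -1.0)])
        post = self.g(wgd=True, devs=[("16", -2.0)])
        assert genotype_contains(near, post)


class TestOrdering:
    def test_linear_chain_recovered(self):
        key = ("NRT", ("2", "4"), "b1")
        fc1 = FounderClone("FC1", FCGenotype(False, (), (("16", -1.0),)),
                           ("a",), "S")
        fc2 = FounderClone("FC2", FCGenotype(False, ((key, 1),),
                                             (("16", -1.0),)), ("b",), "S")
        fc3 = FounderClone("FC3", FCGenotype(
            False, ((key, 1),), (("16", -1.0), ("18", -1.0))), ("c",), "S")
        fc4 = FounderClone("FC4", FCGenotype(
            True, ((key, 2),), (("16", -2.0), ("18", -2.0))), ("d",), "S")
        lineage = order_founder_clones([fc4, fc2, fc1, fc3])
        assert set(lineage.edges) == {("FC1", "FC2"), ("FC2", "FC3"),
                                      ("FC3", "FC4")}
        assert lineage.roots == ["FC1"]

    def test_wgd_edge_only_from_2n_to_4n(self):
        near = FounderClone("N", FCGenotype(False, (), ()), ("a",), "S")
        post = FounderClone("W", FCGenotype(True, (), ()), ("b",), "S")
        lineage = order_founder_clones([near, post])
        assert lineage.edges == [("N", "W")]

    def test_disjoint_private_events_stay_siblings(self):
        k1 = ("NRT", ("2", "4"), "b1")
        k2 = ("NRT", ("6", "9"), "b2")
        fc1 = FounderClone("A", FCGenotype(False, ((k1, 1),), ()), ("a",), "S")
        fc2 = FounderClone("B", FCGenotype(False, ((k2, 1),), ()), ("b",), "S")
        lineage = order_founder_clones([fc1, fc2])
        assert lineage.edges == []
        assert set(lineage.roots) == {"A", "B"}

    def test_ambiguous_parentage_left_unresolved(self):
        k1 = ("NRT", ("2", "4"), "b1")
        k2 = ("NRT", ("6", "9"), "b2")
        p1 = FounderClone("P1", FCGenotype(False, ((k1, 1),), ()), ("a",), "S")
        p2 = FounderClone("P2", FCGenotype(False, ((k2, 1),), ()), ("b",), "S")
        child = FounderClone("C", FCGenotype(
            False, ((k1, 1), (k2, 1)), ()), ("c",), "S")
        lineage = order_founder_clones([p1, p2, child])
        assert lineage.ambiguous_parents == {"C": ("P1", "P2")}
        assert all(e[1] != "C" for e in lineage.edges)

    def test_lineage_is_acyclic_forest(self, type2_case):
        for sample in type2_case.samples:
            fcs, _ = fcs_from_cells(list(sample.cells))
            lineage = order_founder_clones(fcs)
            children = {c for _, c in lineage.edges}
            assert len(children) == len(lineage.edges)  # one parent each
            # walk up from every node; must terminate (acyclic)
            parent = dict((c, p) for p, c in lineage.edges)
            for fc in lineage.fcs:
                seen, cur = set(), fc.fc_id
                while cur in parent:
                    assert cur not in seen
                    seen.add(cur)
                    cur = parent[cur]

    def test_wgd_monotone_along_paths(self, type2_case):
        for sample in type2_case.samples:
            fcs, _ = fcs_from_cells(list(sample.cells))
            lineage = order_founder_clones(fcs)
            by_id = {fc.fc_id: fc for fc in lineage.fcs}
            for p, c in lineage.edges:
                assert not (by_id[p].genotype.wgd
                            and not by_id[c].genotype.wgd)


class TestPredictedIntermediates:
    def test_intersection_of_two_children_proposed(self):
        from karyoevo import predict_intermediate_fcs
        kA = ("NRT", ("2", "4"), "b1")
        parent = FounderClone("P", FCGenotype(False, (), (("16", -1.0),)),
                              ("a",), "S")
        c1 = FounderClone("C1", FCGenotype(
            False, ((kA, 1),), (("16", -1.0), ("18", -1.0))), ("b",), "S")
        c2 = FounderClone("C2", FCGenotype(
            False, ((kA, 1),), (("16", -1.0), ("18", -1.0), ("5", 1.0))),
            ("c",), "S")
        preds = predict_intermediate_fcs([parent, c1, c2])
        # the c1/c2 intersection equals c1's genotype -> nothing to predict
        assert preds == []
        c3 = FounderClone("C3", FCGenotype(
            False, ((kA, 1),), (("16", -1.0), ("18", -1.0), ("9", -1.0))),
            ("d",), "S")
        preds = predict_intermediate_fcs([parent, c2, c3])
        assert len(preds) == 1
        assert preds[0].predicted and not preds[0].member_cells
        assert preds[0].genotype.deviations == (("16", -1.0), ("18", -1.0))
        assert dict(preds[0].genotype.events) == {kA: 1}


TRUE_RANK = {"NORMAL": 0, "FC_NRT": 1, "FC_WGD": 2, "FC_SUB": 3}
TRUE_RANK_T1 = {"NORMAL": 0, "FC_WGD": 1, "FC_NRT": 2, "FC_SUB": 3}


def ordering_agreement(case, scenario):
    """Fraction of resolved parent->child FC edges whose mapped true clones
    are in the true acquisition order."""
    rank = TRUE_RANK if scenario is Scenario.TYPE2 else TRUE_RANK_T1
    good = total = 0
    for sample in case.samples:
        cells = list(sample.cells)
        fcs, _ = fcs_from_cells(cells)
        lineage = order_founder_clones(fcs)
        by_id = {fc.fc_id: fc for fc in lineage.fcs}

        def true_clone(fc):
            labels = [case.clone_of_cell[m] for m in fc.member_cells]
            return max(set(labels), key=labels.count)

        for p, c in lineage.edges:
            tp, tc = true_clone(by_id[p]), true_clone(by_id[c])
            if tp == tc:
                continue
            total += 1
            if rank[tp] < rank[tc]:
                good += 1
    return good, total


def test_ordering_matches_true_acquisition_order_across_seeds():
    """Inferred FC parent/child order agrees with the planted acquisition
    order in >= 90% of nested FC pairs over 50 simulated cases."""
    good = total = 0
    for seed in range(50):
        scen = Scenario.TYPE2 if seed % 2 == 0 else Scenario.TYPE1
        case = simulate_case(SimulationConfig(seed=seed, scenario=scen,
                                              generate_cnv=False))
        g, t = ordering_agreement(case, scen)
        good += g
        total += t
    assert total >= 50
    assert good / total >= 0.90


class TestSeeding:
    def fc(self, fc_id, members):
        return FounderClone(fc_id, FCGenotype(False, (), ()),
                            tuple(members), "S")

    def test_one_clone_in_three_sites_is_parallel(self):
        fcs = [self.fc("FC1", ["a", "b", "c"])]
        sites = {"a": "T1", "b": "T2", "c": "T3"}
        rep = infer_seeding_pattern(fcs, sites)
        assert rep.parallel_seeding == ("FC1",)
        assert not rep.has_polyclonal_seeding

    def test_many_clones_in_one_site_is_polyclonal(self):
        fcs = [self.fc(f"FC{i}", [f"c{i}"]) for i in range(7)]
        sites = {f"c{i}": "T1" for i in range(7)}
        rep = infer_seeding_pattern(fcs, sites)
        assert rep.polyclonal_seeding == ("T1",)
        assert not rep.has_parallel_seeding

    def test_single_site_single_clone_has_no_flags(self):
        rep = infer_seeding_pattern([self.fc("FC1", ["a", "b"])],
                                    {"a": "T1", "b": "T1"})
        assert not rep.has_parallel_seeding
        assert not rep.has_polyclonal_seeding

    def test_simulated_parallel_seeding_detected(self):
        case = simulate_case(SimulationConfig(
            seed=21, n_sites=3, generate_cnv=False))
        fcs = []
        for sample in case.samples:
            got, _ = fcs_from_cells(list(sample.cells))
            # tag clone ids by sample to keep member sets disjoint
            fcs += [FounderClone(f"{sample.sample_id}:{fc.fc_id}",
                                 fc.genotype, fc.member_cells,
                                 fc.sample_id) for fc in got]
        # merge clones sharing the same genotype across samples: the
        # parallel-seeded WGD clone spans both parenchymal sites
        by_geno = {}
        for fc in fcs:
            key = (fc.genotype.wgd, fc.genotype.events)
            if key in by_geno:
                old = by_geno[key]
                by_geno[key] = FounderClone(
                    old.fc_id, old.genotype,
                    old.member_cells + fc.member_cells, old.sample_id)
            else:
                by_geno[key] = fc
        rep = infer_seeding_pattern(list(by_geno.values()),
                                    case.site_of_cell)
        assert rep.has_parallel_seeding
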