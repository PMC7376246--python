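"""Shared fixtures: small hand-built karyotypes and simulated cases."""

from __future__ import annotations

import pytest

from karyoevo import (
    MetaphaseKaryotype,
    NORMAL_MALE_COUNTS,
    SampleKaryotypeSet,
    Scenario,
    SimulationConfig,
    Site,
    StructuralEvent,
    parse_event_notation,
    simulate_case,
)
from karyoevo.simulate import toy_chrom_sizes


def make_cell(cell_id="c1", sample_id="S1", delta=None, events=(),
              wgd=False):
    """A male mouse cell: normal counts +- delta, optionally genome-doubled.

    ``delta`` maps chromosome -> count change applied after doubling;
    ``events`` participants are debited one intact copy each (the
    derivative carries the material).
    """
    counts = dict(NORMAL_MALE_COUNTS)
    if wgd:
        counts = {k: 2 * v for k, v in counts.items()}
    for chrom, d in (delta or {}).items():
        counts[chrom] += d
    evs = []
    for e in events:
        if isinstance(e, str):
            e = parse_event_notation(e)
        if wgd and e.copies == 1:
            e = e.with_copies(2)
        for p in e.participants:
            counts[p] = max(0, counts[p] - e.copies)
        evs.append(e)
    return MetaphaseKaryotype(cell_id=cell_id, sample_id=sample_id,
                              counts=counts, events=tuple(evs))


def make_sample(cells, sample_id="S1", animal_id="A1", site=Site.PARENCHYMA):
    return SampleKaryotypeSet(sample_id=sample_id, animal_id=animal_id,
                              site=site, cells=tuple(cells))


@pytest.fixture(scope="session")
def type2_case():
    return simulate_case(SimulationConfig(seed=11, scenario=Scenario.TYPE2,
                                          generate_cnv=False))


@pytest.fixture(scope="session")
def type1_case():
    return simulate_case(SimulationConfig(seed=12, scenario=Scenario.TYPE1,
                                          generate_cnv=False))


@pytest.fixture(scope="session")
def toy_sizes():
    return toy_chrom_sizes(20)


@pytest.fixture(scope="session")
def type2_cnv_case(toy_sizes):
    return simulate_case(SimulationConfig(
        seed=13, scenario=Scenario.TYPE2, chrom_sizes=toy_sizes,
        noise_sd_log2=0.0, focal_deletion=("11", 50_000, 120_000)))
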