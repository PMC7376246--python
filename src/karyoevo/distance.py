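"""Event-weighted pairwise distance between metaphase karyotypes.

Every chromosomal event counts 1 distance unit, with two exceptions: the
de novo acquisition of a nonreciprocal translocation counts 5 (its
breakpoint makes it a unique lineage identifier), and whole-genome
duplication counts 1 regardless of doubling all 40 chromosomes (one
genetic event).  A cell that acquired an NRT at the 2N stage and then
underwent WGD is therefore at distance 6 (5 + 1) from a normal cell, not
10.

The distance operates on *canonical profiles*: the WGD flag, per-chromosome
material copy-number deviations from the ploidy-scaled baseline, and the
structural-event set with ploidy-normalized copy numbers.  Material copy
number credits each derivative chromosome to its participants, so a
copy-neutral translocation changes only the event set, never the
copy-number term.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .model import (
    AUTOSOMES,
    CHROMOSOMES,
    EventKind,
    MetaphaseKaryotype,
    NORMAL_MALE_COUNTS,
    WGD_COUNT_THRESHOLD,
    classify_ploidy,
)

#: Baseline copy number per chromosome in a euploid 2N cell (male mouse).
DEFAULT_BASELINE: dict[str, int] = dict(NORMAL_MALE_COUNTS)

CONTROL_LABEL = "CONTROL"


@dataclass(frozen=True)
class DistanceConfig:
    """Weights of the event-weighted distance.

    w_copy: per unit chromosome copy-number difference (gain/loss = 1).
    w_nrt: de novo NRT acquisition (5; unique breakpoint identifier).
    w_other_event: fusion/ring/RT presence difference (1).
    w_wgd: whole-genome duplication (1; a single genetic event).
    """

    w_copy: float = 1.0
    w_nrt: float = 5.0
    w_other_event: float = 1.0
    w_wgd: float = 1.0

    def __post_init__(self) -> None:
        if min(self.w_copy, self.w_nrt, self.w_other_event, self.w_wgd) <= 0:
            raise ValueError("all distance weights must be > 0")

    def event_weight(self, kind: EventKind) -> float:
        return self.w_nrt if kind is EventKind.NRT else self.w_other_event


@dataclass(frozen=True)
class CanonicalProfile:
    """What the distance sees of one cell.

    deviations: material copies minus the (WGD-doubled) baseline.
    events: identity key -> (copies, pre_wgd).  In a WGD cell an event
    present in >= 2 copies is taken to predate the WGD (its copies were
    doubled with the genome); single-copy events are post-WGD.
    """

    label: str
    wgd: bool
    deviations: Mapping[str, float]
    events: Mapping[tuple, tuple[int, bool]]

    def ploidy_multiplier(self, key: tuple) -> int:
        copies, pre_wgd = self.events[key]
        return 2 if (self.wgd and pre_wgd) else 1


def canonicalize(
    cell: MetaphaseKaryotype,
    baseline: Optional[Mapping[str, int]] = None,
    wgd_threshold: int = WGD_COUNT_THRESHOLD,
) -> CanonicalProfile:
    """Reduce a metaphase to the canonical profile the distance is defined on."""
    base = dict(DEFAULT_BASELINE if baseline is None else baseline)
    wgd = classify_ploidy(cell, wgd_threshold).wgd
    mult = 2 if wgd else 1
    material = cell.material_counts()
    deviations = {c: material.get(c, 0) - mult * base.get(c, 0)
                  for c in CHROMOSOMES}
    events: dict[tuple, tuple[int, bool]] = {}
    for e in cell.events:
        key = e.identity
        copies = events.get(key, (0, False))[0] + e.copies
        events[key] = (copies, wgd and copies >= 2)
    return CanonicalProfile(label=cell.cell_id, wgd=wgd,
                            deviations=deviations, events=events)


def control_profile(baseline: Optional[Mapping[str, int]] = None,
                    label: str = CONTROL_LABEL) -> CanonicalProfile:
    """The normal euploid outgroup cell: no deviations, no events, no WGD."""
    return CanonicalProfile(label=label, wgd=False,
                            deviations={c: 0.0 for c in CHROMOSOMES}, events={})


def pair_distance(a: CanonicalProfile, b: CanonicalProfile,
                  cfg: DistanceConfig = DistanceConfig()) -> float:
    """Weighted event distance between two canonical profiles.

    d = w_wgd * |wgd_a - wgd_b|
      + w_copy * sum_chr |dev_a - dev_b|
      + per event identity: the acquisition weight if present in exactly
        one profile, else w_copy * |copies_a/m_a - copies_b/m_b| where the
        ploidy multiplier m is 2 for a pre-WGD event in a WGD cell.
    """
    d = cfg.w_wgd * abs(int(a.wgd) - int(b.wgd))
    d += cfg.w_copy * sum(
        abs(a.deviations.get(c, 0.0) - b.deviations.get(c, 0.0))
        for c in CHROMOSOMES)
    for key in set(a.events) | set(b.events):
        in_a, in_b = key in a.events, key in b.events
        if in_a and in_b:
            ca = a.events[key][0] / a.ploidy_multiplier(key)
            cb = b.events[key][0] / b.ploidy_multiplier(key)
            d += cfg.w_copy * abs(ca - cb)
        else:
            kind = key[0]
            d += cfg.event_weight(kind)
    return float(d)


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric non-negative dissimilarity matrix with zero diagonal."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "labels", tuple(self.labels))
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(v, v.T):
            raise ValueError("matrix must be symmetric")
        if np.any(v < 0):
            raise ValueError("matrix entries must be non-negative")
        if not np.allclose(np.diag(v), 0):
            raise ValueError("diagonal must be zero")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.values[i, j])

    def to_tsv(self, path) -> None:
        import pandas as pd
        pd.DataFrame(self.values, index=list(self.labels),
                     columns=list(self.labels)).to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "DistanceMatrix":
        import pandas as pd
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(tuple(str(c) for c in df.columns), df.to_numpy(dtype=float))


def build_distance_matrix(
    cells: Sequence[MetaphaseKaryotype],
    cfg: DistanceConfig = DistanceConfig(),
    include_control: bool = True,
    baseline: Optional[Mapping[str, int]] = None,
    wgd_threshold: int = WGD_COUNT_THRESHOLD,
) -> DistanceMatrix:
    """Pairwise distances over all cells, optionally appending the normal
    euploid CONTROL outgroup as the last label."""
    ids = [c.cell_id for c in cells]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate cell_id(s): {', '.join(dupes)}")
    profiles = [canonicalize(c, baseline, wgd_threshold) for c in cells]
    if include_control:
        profiles.append(control_profile(baseline))
    n = len(profiles)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = pair_distance(
                profiles[i], profiles[j], cfg)
    return DistanceMatrix(tuple(p.label for p in profiles), values)
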