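"""Binned copy-ratio profiles: SKY/WGS comparison, L1 trees, segment events.

Profiles live on a fixed 10-kb grid of 0-based half-open bins carrying
log2 copy ratios (0 = balanced against the matched normal).  Three
analyses are built on them:

* per-chromosome log2 comparison between SKY counts and WGS bins
  (SKY side: log2(ci / median(c)) over chromosomes 1-19 and X);
* L1 distance between profiles (sum over bins of |r_a - r_b|) feeding
  neighbor-joining trees for single-cell-derived clones;
* shared/private segment-event partitions for bulk samples ("manual"
  trees whose trunk/branch lengths are proportional to the number of
  shared/private events; whole-chromosome gains and losses are excluded
  as nonspecific).
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .distance import CONTROL_LABEL, DistanceMatrix
from .model import AUTOSOMES, MetaphaseKaryotype
from .njtree import PhyloTree, neighbor_joining, root_with_outgroup

logger = logging.getLogger(__name__)

DEFAULT_BIN_SIZE = 10_000

#: Chromosomes entering the SKY-side log2 ratio (1-19 and X; Y excluded).
SKY_LOG2_CHROMS: tuple[str, ...] = AUTOSOMES + ("X",)


@dataclass(frozen=True)
class CNVProfile:
    """Per-bin log2 copy ratios for one sample on a fixed bin grid."""

    sample_id: str
    bins: pd.DataFrame  # columns: chrom, start, end, log2_ratio
    bin_size: int = DEFAULT_BIN_SIZE

    def __post_init__(self) -> None:
        df = self.bins.reset_index(drop=True)
        required = ["chrom", "start", "end", "log2_ratio"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"bins missing column(s): {', '.join(missing)}")
        df = df[required].copy()
        df["chrom"] = df["chrom"].astype(str)
        df["start"] = df["start"].astype(int)
        df["end"] = df["end"].astype(int)
        df["log2_ratio"] = df["log2_ratio"].astype(float)
        bad = df[(df["start"] % self.bin_size != 0) | (df["end"] <= df["start"])]
        if len(bad):
            row = bad.iloc[0]
            raise ValueError(
                f"off-grid bin at {row['chrom']}:{row['start']}-{row['end']} "
                f"(bin size {self.bin_size})")
        df = df.sort_values(["chrom", "start"], kind="mergesort",
                            ignore_index=True)
        overlap = (df["chrom"] == df["chrom"].shift()) & (
            df["start"] < df["end"].shift())
        if overlap.any():
            row = df[overlap].iloc[0]
            raise ValueError(
                f"overlapping bins at {row['chrom']}:{row['start']}")
        object.__setattr__(self, "bins", df)

    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.bins["chrom"]))

    def grid_index(self) -> pd.MultiIndex:
        return pd.MultiIndex.from_frame(self.bins[["chrom", "start"]])


def read_bin_table(path, sample_id: Optional[str] = None,
                   bin_size: int = DEFAULT_BIN_SIZE) -> CNVProfile:
    """Read a binned copy-ratio table.

    Accepts either the native dialect (chrom, start, end, log2_ratio) or a
    Control-FREEC-style ratio file (chrom, start, ratio) whose linear
    ratios are converted to log2; ratios must be positive.
    """
    df = pd.read_csv(path, sep="\t")
    df.columns = [str(c).strip().lower() for c in df.columns]
    if "chromosome" in df.columns:
        df = df.rename(columns={"chromosome": "chrom"})
    if "chrom" not in df.columns or "start" not in df.columns:
        raise ValueError("bin table needs 'chrom' and 'start' columns")
    if "log2_ratio" in df.columns:
        log2 = df["log2_ratio"].astype(float)
    elif "log2" in df.columns:
        log2 = df["log2"].astype(float)
    elif "ratio" in df.columns:
        ratio = df["ratio"].astype(float)
        if (ratio <= 0).any():
            pos = df[ratio <= 0].iloc[0]
            raise ValueError(
                f"non-positive ratio at {pos['chrom']}:{pos['start']}")
        log2 = np.log2(ratio)
    else:
        raise ValueError("bin table needs a log2_ratio, log2, or ratio column")
    end = (df["end"].astype(int) if "end" in df.columns
           else df["start"].astype(int) + bin_size)
    bins = pd.DataFrame({
        "chrom": df["chrom"].astype(str),
        "start": df["start"].astype(int),
        "end": end,
        "log2_ratio": log2,
    })
    sid = sample_id if sample_id is not None else str(path)
    return CNVProfile(sample_id=sid, bins=bins, bin_size=bin_size)


def write_bin_table(profile: CNVProfile, path) -> None:
    profile.bins.to_csv(path, sep="\t", index=False)


def sky_chrom_log2(cells: Sequence[MetaphaseKaryotype],
                   material: bool = True) -> dict[str, float]:
    """Per-chromosome log2 ratio from SKY counts: log2(ci / median(c)).

    ci is the average copy number of chromosome i over the cells (with
    derivative contributions credited to their participants when
    ``material``), c the median of the ci over chromosomes 1-19 and X.
    """
    if not cells:
        raise ValueError("need at least one cell")
    ci: dict[str, float] = {}
    for chrom in SKY_LOG2_CHROMS:
        if material:
            vals = [c.material_counts().get(chrom, 0) for c in cells]
        else:
            vals = [c.counts[chrom] for c in cells]
        ci[chrom] = float(np.mean(vals))
    med = float(np.median(list(ci.values())))
    if med == 0:
        raise ValueError("median chromosome count is zero")
    return {chrom: math.log2(v / med) if v > 0 else -math.inf
            for chrom, v in ci.items()}


def wgs_chrom_log2(profile: CNVProfile) -> dict[str, float]:
    """Per-chromosome median of the binned WGS log2 ratios."""
    out: dict[str, float] = {}
    for chrom, grp in profile.bins.groupby("chrom", sort=False):
        if grp.empty:
            logger.warning("chromosome %s has no bins; omitted", chrom)
            continue
        out[str(chrom)] = float(grp["log2_ratio"].median())
    return out


@dataclass(frozen=True)
class SkyWgsComparison:
    pearson_r: float
    defined: bool
    table: pd.DataFrame  # columns: chrom, sky_log2, wgs_log2


def compare_sky_wgs(sky: Mapping[str, float],
                    wgs: Mapping[str, float]) -> SkyWgsComparison:
    """Pearson correlation of per-chromosome log2 ratios, SKY vs WGS."""
    shared = [c for c in SKY_LOG2_CHROMS if c in sky and c in wgs]
    shared += [c for c in sky if c in wgs and c not in shared]
    if len(shared) < 3:
        raise ValueError("need >= 3 shared chromosomes")
    x = np.array([sky[c] for c in shared], dtype=float)
    y = np.array([wgs[c] for c in shared], dtype=float)
    table = pd.DataFrame({"chrom": shared, "sky_log2": x, "wgs_log2": y})
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return SkyWgsComparison(pearson_r=float("nan"), defined=False,
                                table=table)
    r, _ = sps.pearsonr(x, y)
    return SkyWgsComparison(pearson_r=float(r), defined=True, table=table)


def _common_grid(a: CNVProfile, b: CNVProfile) -> tuple[np.ndarray, np.ndarray]:
    ga, gb = a.grid_index(), b.grid_index()
    if ga.equals(gb):
        return (a.bins["log2_ratio"].to_numpy(),
                b.bins["log2_ratio"].to_numpy())
    logger.warning("bin grids differ between %s and %s; intersecting",
                   a.sample_id, b.sample_id)
    merged = pd.merge(a.bins, b.bins, on=["chrom", "start", "end"],
                      suffixes=("_a", "_b"))
    if merged.empty:
        raise ValueError(
            f"profiles {a.sample_id} and {b.sample_id} share no bins")
    return (merged["log2_ratio_a"].to_numpy(),
            merged["log2_ratio_b"].to_numpy())


def cnv_l1_distance(a: CNVProfile, b: CNVProfile) -> float:
    """L1 distance: sum over shared bins of |log2_a - log2_b|."""
    ra, rb = _common_grid(a, b)
    return float(np.abs(ra - rb).sum())


def cnv_nj_tree(profiles: Sequence[CNVProfile],
                include_control: bool = True) -> PhyloTree:
    """Neighbor-joining tree on the pairwise L1 CNV distance matrix.

    When ``include_control`` a flat (all-zero log2) normal profile is
    appended as outgroup and the tree is rooted on it.
    """
    if len(profiles) < (2 if include_control else 3):
        raise ValueError("need at least 3 leaves for a tree")
    profiles = list(profiles)
    labels = [p.sample_id for p in profiles]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate sample_id among profiles")
    if include_control:
        ref = profiles[0].bins.copy()
        ref["log2_ratio"] = 0.0
        profiles.append(CNVProfile(sample_id=CONTROL_LABEL, bins=ref,
                                   bin_size=profiles[0].bin_size))
        labels.append(CONTROL_LABEL)
    n = len(profiles)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = cnv_l1_distance(
                profiles[i], profiles[j])
    tree = neighbor_joining(DistanceMatrix(tuple(labels), values))
    if include_control:
        tree = root_with_outgroup(tree, CONTROL_LABEL)
    return tree


class SegmentDirection(str, enum.Enum):
    GAIN = "GAIN"
    LOSS = "LOSS"


@dataclass(frozen=True)
class SegmentEvent:
    """A contiguous gain or loss with grid-resolution boundaries."""

    chrom: str
    start: int
    end: int
    direction: SegmentDirection
    whole_chromosome: bool = False
    genes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("start must be < end")

    @property
    def key(self) -> tuple:
        return (self.chrom, self.start, self.end, self.direction)


def detect_segment_events(
    profile: CNVProfile,
    log2_gain_thr: float = 0.3,
    log2_loss_thr: float = -0.3,
    whole_chromosome_fraction: float = 0.95,
) -> list[SegmentEvent]:
    """Contiguous runs of bins beyond the thresholds, one event per run."""
    events: list[SegmentEvent] = []
    for chrom, grp in profile.bins.groupby("chrom", sort=False):
        grp = grp.reset_index(drop=True)
        span = int(grp["end"].max() - grp["start"].min())
        direction = np.where(grp["log2_ratio"] >= log2_gain_thr, 1,
                             np.where(grp["log2_ratio"] <= log2_loss_thr, -1, 0))
        i = 0
        while i < len(grp):
            d = direction[i]
            if d == 0:
                i += 1
                continue
            j = i
            while (j + 1 < len(grp) and direction[j + 1] == d
                   and grp["start"].iloc[j + 1] == grp["end"].iloc[j]):
                j += 1
            start = int(grp["start"].iloc[i])
            end = int(grp["end"].iloc[j])
            events.append(SegmentEvent(
                chrom=str(chrom), start=start, end=end,
                direction=(SegmentDirection.GAIN if d > 0
                           else SegmentDirection.LOSS),
                whole_chromosome=(end - start)
                >= whole_chromosome_fraction * span,
            ))
            i = j + 1
    return events


@dataclass(frozen=True)
class SharedPrivatePartition:
    """Per-sample shared/private segment events (whole-chromosome excluded)."""

    shared: dict[str, tuple[SegmentEvent, ...]]
    private: dict[str, tuple[SegmentEvent, ...]]
    excluded_whole_chromosome: dict[str, tuple[SegmentEvent, ...]]

    @property
    def samples(self) -> list[str]:
        return list(self.shared)


def classify_segment_events(
    profiles_by_sample: Mapping[str, CNVProfile],
    log2_gain_thr: float = 0.3,
    log2_loss_thr: float = -0.3,
    whole_chromosome_fraction: float = 0.95,
) -> SharedPrivatePartition:
    """Partition each sample's events into shared (identical boundaries and
    direction in >= 2 samples) and private; whole-chromosome gains/losses
    are excluded as nonspecific."""
    if len(profiles_by_sample) < 2:
        raise ValueError("need >= 2 samples")
    per_sample: dict[str, list[SegmentEvent]] = {}
    excluded: dict[str, tuple[SegmentEvent, ...]] = {}
    for sid, profile in profiles_by_sample.items():
        evts = detect_segment_events(profile, log2_gain_thr, log2_loss_thr,
                                     whole_chromosome_fraction)
        excluded[sid] = tuple(e for e in evts if e.whole_chromosome)
        per_sample[sid] = [e for e in evts if not e.whole_chromosome]
    carrier_count: dict[tuple, int] = {}
    for evts in per_sample.values():
        for e in evts:
            carrier_count[e.key] = carrier_count.get(e.key, 0) + 1
    shared = {sid: tuple(e for e in evts if carrier_count[e.key] >= 2)
              for sid, evts in per_sample.items()}
    private = {sid: tuple(e for e in evts if carrier_count[e.key] < 2)
               for sid, evts in per_sample.items()}
    return SharedPrivatePartition(shared=shared, private=private,
                                  excluded_whole_chromosome=excluded)


def build_manual_tree(partition: SharedPrivatePartition) -> PhyloTree:
    """Tree whose edge lengths are proportional to event counts.

    Every event defines the set of samples carrying it; carrier sets are
    nested by containment under a virtual root above the all-sample node.
    The trunk length is the number of events shared by all samples, each
    internal edge the number of events carried by exactly that sample
    subset, and each leaf branch the sample's private event count.
    """
    samples = partition.samples
    if len(samples) < 2:
        raise ValueError("need >= 2 samples")
    events_by_set: dict[frozenset, int] = {}
    seen: set[tuple] = set()
    for sid in samples:
        for e in partition.shared[sid]:
            if e.key in seen:
                continue
            seen.add(e.key)
            carriers = frozenset(s for s in samples
                                 if any(x.key == e.key
                                        for x in partition.shared[s]))
            events_by_set[carriers] = events_by_set.get(carriers, 0) + 1

    all_set = frozenset(samples)
    node_sets: list[frozenset] = [all_set]
    for s in events_by_set:
        if s != all_set and s not in node_sets:
            node_sets.append(s)
    for sid in samples:
        single = frozenset({sid})
        if single not in node_sets:
            node_sets.append(single)
    # order by decreasing size so parents are placed before children
    node_sets.sort(key=lambda s: (-len(s), sorted(s)))

    adjacency: dict[int, dict[int, float]] = {}
    names: dict[int, str] = {}
    ids = {None: 0}  # virtual root
    adjacency[0] = {}

    def add_edge(u: int, v: int, w: float) -> None:
        adjacency.setdefault(u, {})[v] = w
        adjacency.setdefault(v, {})[u] = w

    placed: dict[frozenset, int] = {}
    for s in node_sets:
        nid = len(ids)
        ids[s] = nid
        if len(s) == 1:
            (sid,) = s
            names[nid] = sid
            length = float(len(partition.private[sid])
                           + events_by_set.get(s, 0))
        else:
            length = float(events_by_set.get(s, 0))
        parents = [t for t in placed if s < t]
        if parents:
            parent = min(parents, key=len)
            add_edge(ids[parent], nid, length)
        else:
            add_edge(0, nid, length)
        placed[s] = nid
    return PhyloTree(adjacency, names, root=0)
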