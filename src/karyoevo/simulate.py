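"""Forward simulator of single-cell karyotype evolution with ground truth.

The generator emulates the generative structure the analysis assumes: a
normal diploid founder divides synchronously (every cell divides once per
generation); daughters independently acquire whole-chromosome gains and
losses, nonreciprocal translocations (each with a globally unique
breakpoint id, consuming one intact copy of each participant and creating
a derivative), fusions and rings; at most one whole-genome duplication per
lineage doubles every chromosome and derivative and is immediately followed
by random chromosome losses down to a target total count (60-80 bodies,
the sub-4N range); and sampled cells are assigned to anatomical sites under
parallel and/or polyclonal seeding.

Two scenarios fix the timing of the founding clonal NRT relative to WGD:

* TYPE2 — the founding NRT is acquired at the 2N stage (generation 1); a
  near-2N subpopulation carrying one NRT copy persists at an SVZ site
  while a sub-4N descendant clone (two NRT copies) populates the
  parenchymal site(s).
* TYPE1 — WGD happens first (generation 1, no prior NRT) and the founding
  NRT is acquired in a 4N cell (one copy, three intact participant
  copies); the SVZ site stays normal.

Every sampled cell carries a replayable event ledger; the true genealogy,
the planted clones with their acquisition order, and per-event pre/post-WGD
flags are returned alongside the karyotypes and matched binned CNV
profiles.
"""

from __future__ import annotations

import enum
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .cnv import CNVProfile, DEFAULT_BIN_SIZE, write_bin_table
from .distance import DistanceConfig
from .io import write_karyotype_table
from .model import (
    AUTOSOMES,
    CHROMOSOMES,
    EventKind,
    MetaphaseKaryotype,
    NORMAL_MALE_COUNTS,
    SampleKaryotypeSet,
    Site,
    StructuralEvent,
)
from .njtree import PhyloTree, write_newick

#: mm9 chromosome sizes (bp); the default genome for binned CNV output.
MM9_CHROM_SIZES: dict[str, int] = {
    "1": 197_195_432, "2": 181_748_087, "3": 159_599_783, "4": 155_630_120,
    "5": 152_537_259, "6": 149_517_037, "7": 152_524_553, "8": 131_738_871,
    "9": 124_076_172, "10": 129_993_255, "11": 121_843_856, "12": 121_257_530,
    "13": 120_284_312, "14": 125_194_864, "15": 103_494_974, "16": 98_319_150,
    "17": 95_272_651, "18": 90_772_031, "19": 61_342_430,
    "X": 166_650_296, "Y": 15_902_555,
}

#: An early focal driver deletion (homozygous Nf1-like locus on chr11),
#: planted in the tumor trunk so every tumor-site profile shares it with
#: identical boundaries.
DEFAULT_FOCAL_DELETION: tuple[str, int, int] = ("11", 79_340_000, 79_600_000)


def toy_chrom_sizes(n_bins_per_chrom: int = 20,
                    bin_size: int = DEFAULT_BIN_SIZE) -> dict[str, int]:
    """A scaled-down genome (same 21 chromosomes) for fast CNV tests."""
    return {c: n_bins_per_chrom * bin_size for c in CHROMOSOMES}


class Scenario(str, enum.Enum):
    TYPE1 = "TYPE1"
    TYPE2 = "TYPE2"


class Seeding(str, enum.Enum):
    PARALLEL = "PARALLEL"
    POLYCLONAL = "POLYCLONAL"
    MIXED = "MIXED"


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of one simulated case.

    Rates are per daughter cell per division; the paper-style quantities
    (sub-4N totals in 60-80, clonal founding NRT, 2N-vs-4N acquisition
    timing) are fixed by the scenario, not by the rates.
    """

    seed: int = 0
    scenario: Scenario = Scenario.TYPE2
    n_generations: int = 8
    rate_gain: float = 0.003      # per chromosome per division
    rate_loss: float = 0.003      # per chromosome per division
    rate_nrt: float = 0.02        # per division
    rate_fusion: float = 0.004    # per division
    rate_ring: float = 0.002      # per division
    p_wgd_per_generation: float = 0.0   # extra stochastic WGD (off: planted)
    wgd_generation: int = 3
    founding_nrt_generation: int = 1
    post_wgd_loss_target: tuple[int, int] = (60, 80)
    n_sites: int = 2
    cells_per_site: int = 20
    seeding: Seeding = Seeding.PARALLEL
    dominant_clone_fraction: float = 0.9
    noise_sd_log2: float = 0.1
    bin_size: int = DEFAULT_BIN_SIZE
    chrom_sizes: Optional[Mapping[str, int]] = None
    generate_cnv: bool = True
    #: plant the scenario's founding NRT / WGD events (off: pure
    #: background evolution, useful as a null condition)
    plant_clonal_structure: bool = True
    plant_focal_deletion: bool = True
    focal_deletion: tuple[str, int, int] = DEFAULT_FOCAL_DELETION

    def __post_init__(self) -> None:
        for name in ("rate_gain", "rate_loss", "rate_nrt", "rate_fusion",
                     "rate_ring", "p_wgd_per_generation"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        lo, hi = self.post_wgd_loss_target
        if not (0 < lo <= hi):
            raise ValueError("invalid post_wgd_loss_target interval")
        if self.scenario is Scenario.TYPE2 and self.rate_nrt == 0 \
                and self.founding_nrt_generation is None:
            raise ValueError("TYPE2 needs an NRT source")
        if not 1 <= self.wgd_generation <= self.n_generations:
            raise ValueError("wgd_generation out of range")
        if self.n_sites < 1 or self.cells_per_site < 1:
            raise ValueError("need at least one site and one cell per site")


# ---------------------------------------------------------------------------
# cell state and event application

@dataclass
class _SimCell:
    counts: dict[str, int]
    events: dict[tuple, StructuralEvent]   # identity -> event with copies
    wgd: bool
    ledger: list[dict]
    node_id: int
    parent_id: Optional[int]
    generation: int
    branch_weight: float = 0.0  # weighted events since parent (tree lengths)
    loss_target: Optional[int] = None  # post-WGD shedding target count

    def clone_as_child(self, node_id: int, generation: int) -> "_SimCell":
        return _SimCell(
            counts=dict(self.counts),
            events={k: e for k, e in self.events.items()},
            wgd=self.wgd,
            ledger=list(self.ledger),
            node_id=node_id,
            parent_id=self.node_id,
            generation=generation,
            branch_weight=0.0,
            loss_target=self.loss_target,
        )

    def total(self) -> int:
        return sum(self.counts.values()) + sum(e.copies
                                               for e in self.events.values())


def _apply_op(cell: _SimCell, op: dict, weights: DistanceConfig) -> None:
    """Apply one ledger operation in place and charge its weight."""
    kind = op["op"]
    if kind == "gain":
        cell.counts[op["chrom"]] += 1
        cell.branch_weight += weights.w_copy
    elif kind == "loss":
        target = op["target"]
        if target[0] == "chrom":
            chrom = target[1]
            if cell.counts[chrom] > 0:
                cell.counts[chrom] -= 1
        else:
            key = _key_from_jsonable(target[1])
            if key in cell.events:
                e = cell.events[key]
                if e.copies > 1:
                    cell.events[key] = e.with_copies(e.copies - 1)
                else:
                    del cell.events[key]
        cell.branch_weight += weights.w_copy
    elif kind in ("nrt", "fusion", "ring"):
        ev_kind = {"nrt": EventKind.NRT, "fusion": EventKind.FUSION,
                   "ring": EventKind.RING}[kind]
        participants = tuple(op["participants"])
        event = StructuralEvent(kind=ev_kind, participants=participants,
                                copies=1, breakpoint_id=op["breakpoint_id"])
        for p in participants:
            if cell.counts[p] > 0:
                cell.counts[p] -= 1
        cell.events[event.identity] = event
        cell.branch_weight += weights.event_weight(ev_kind)
    elif kind == "wgd":
        for c in cell.counts:
            cell.counts[c] *= 2
        for key, e in list(cell.events.items()):
            cell.events[key] = e.with_copies(e.copies * 2)
        cell.wgd = True
        cell.branch_weight += weights.w_wgd
    else:  # pragma: no cover - ledger corruption
        raise ValueError(f"unknown ledger op {kind!r}")
    cell.ledger.append(op)


def _key_to_jsonable(key: tuple) -> list:
    kind, participants, bp = key
    return [kind.value if isinstance(kind, EventKind) else kind,
            list(participants), bp]


def _key_from_jsonable(raw) -> tuple:
    kind, participants, bp = raw
    return (EventKind(kind), tuple(participants), bp)


def replay_ledger(ledger: Sequence[dict],
                  weights: DistanceConfig = DistanceConfig()) -> _SimCell:
    """Re-derive a cell's final state from its event ledger (conservation
    check: the replayed counts and events must equal the recorded state)."""
    cell = _SimCell(counts=dict(NORMAL_MALE_COUNTS), events={}, wgd=False,
                    ledger=[], node_id=-1, parent_id=None, generation=0)
    for op in ledger:
        _apply_op(cell, op, weights)
    return cell


# ---------------------------------------------------------------------------
# ground-truth containers

@dataclass(frozen=True)
class PlantedEvent:
    """Ledger entry for one structural event, with ground truth."""

    identity_key: tuple
    notation_kind: str
    participants: tuple[str, ...]
    breakpoint_id: str
    generation: int
    acquired_in_wgd_cell: bool   # True -> a 4N-stage acquisition
    founding: bool               # the scenario's planted clonal NRT


@dataclass(frozen=True)
class TrueClone:
    clone_id: str
    parent: Optional[str]
    wgd: bool
    events: tuple[tuple, ...]   # identity keys present in the clone founder
    founder_node: int


@dataclass
class SimulatedCase:
    config: SimulationConfig
    samples: list[SampleKaryotypeSet]
    true_tree: PhyloTree
    true_clones: list[TrueClone]
    planted_events: list[PlantedEvent]
    cell_ledgers: dict[str, list[dict]]
    cell_states: dict[str, MetaphaseKaryotype]
    clone_of_cell: dict[str, str]
    site_of_cell: dict[str, str]
    true_root_weights: dict[str, float]
    cnv_profiles: dict[str, CNVProfile] = field(default_factory=dict)

    @property
    def animal_id(self) -> str:
        return self.samples[0].animal_id if self.samples else "M1"


# ---------------------------------------------------------------------------
# simulation

def _random_mutations(cell: _SimCell, cfg: SimulationConfig,
                      rng: np.random.Generator, gen: int,
                      weights: DistanceConfig,
                      planted: list[PlantedEvent],
                      bp_counter: list[int]) -> None:
    for chrom in CHROMOSOMES:
        if cell.counts[chrom] > 0 and rng.random() < cfg.rate_gain:
            _apply_op(cell, {"op": "gain", "chrom": chrom}, weights)
        if cell.counts[chrom] > 1 and rng.random() < cfg.rate_loss:
            _apply_op(cell, {"op": "loss", "target": ["chrom", chrom]},
                      weights)
    for op_name, rate in (("nrt", cfg.rate_nrt),
                          ("fusion", cfg.rate_fusion),
                          ("ring", cfg.rate_ring)):
        if rng.random() >= rate:
            continue
        # Type 1 evolution acquires NRTs only in cells that already
        # underwent WGD (the 4N-acquisition scenario)
        if (op_name == "nrt" and cfg.scenario is Scenario.TYPE1
                and not cell.wgd):
            continue
        present = [c for c in CHROMOSOMES if cell.counts[c] > 0]
        if len(present) < 2:
            continue
        if op_name == "ring":
            chrom = str(rng.choice(present))
            participants = (chrom, chrom)
            if cell.counts[chrom] < 2:
                continue
        else:
            participants = tuple(
                str(c) for c in rng.choice(present, size=2, replace=False))
        bp_counter[0] += 1
        bp = f"s{cfg.seed}bp{bp_counter[0]:05d}"
        op = {"op": op_name, "participants": list(participants),
              "breakpoint_id": bp}
        _apply_op(cell, op, weights)
        if op_name == "nrt":
            planted.append(PlantedEvent(
                identity_key=(EventKind.NRT, participants, bp),
                notation_kind="t", participants=participants,
                breakpoint_id=bp, generation=gen,
                acquired_in_wgd_cell=cell.wgd, founding=False))


#: Fraction of the remaining post-WGD excess shed per generation.
POST_WGD_SHED_RATE = 0.4


def _shed_post_wgd_losses(cell: _SimCell, rng: np.random.Generator,
                          weights: DistanceConfig) -> None:
    """Random chromosome losses toward the cell's post-WGD target count.

    Losses are spread over the generations after WGD (each division sheds
    a binomial fraction of the remaining excess), so they are mosaic
    across the clone and the modal copy pattern of the founder survives.
    A loss removes one copy of a body present in >= 2 copies: no
    chromosome or derivative is lost outright, but a 2-copy pre-WGD NRT
    may drop to one copy — the honestly-undetermined acquisition cases.
    """
    if cell.loss_target is None:
        return
    excess = cell.total() - cell.loss_target
    if excess <= 0:
        return
    n_lose = int(rng.binomial(excess, POST_WGD_SHED_RATE))
    for _ in range(n_lose):
        bodies: list[list] = []
        for chrom, n in cell.counts.items():
            if n > 1:
                bodies.extend([["chrom", chrom]] * (n - 1))
        for key, e in cell.events.items():
            if e.copies > 1:
                bodies.extend([["event", _key_to_jsonable(key)]]
                              * (e.copies - 1))
        if not bodies:
            break
        pick = bodies[int(rng.integers(0, len(bodies)))]
        _apply_op(cell, {"op": "loss", "target": pick}, weights)


def _apply_wgd(cell: _SimCell, cfg: SimulationConfig,
               rng: np.random.Generator, weights: DistanceConfig) -> None:
    _apply_op(cell, {"op": "wgd"}, weights)
    lo, hi = cfg.post_wgd_loss_target
    cell.loss_target = int(rng.integers(lo, hi + 1))


def simulate_case(cfg: SimulationConfig) -> SimulatedCase:
    """Run one forward simulation and package karyotypes + ground truth."""
    rng = np.random.default_rng(cfg.seed)
    weights = DistanceConfig()
    bp_counter = [0]
    planted: list[PlantedEvent] = []
    next_node = [0]

    def new_node() -> int:
        next_node[0] += 1
        return next_node[0]

    founder = _SimCell(counts=dict(NORMAL_MALE_COUNTS), events={}, wgd=False,
                       ledger=[], node_id=new_node(), parent_id=None,
                       generation=0)
    population = [founder]
    parent_of: dict[int, Optional[int]] = {founder.node_id: None}
    weight_of: dict[int, float] = {founder.node_id: 0.0}

    founding_key: Optional[tuple] = None
    wgd_done = False
    clone_founders: dict[str, int] = {"NORMAL": founder.node_id}
    subclone_key: Optional[tuple] = None

    for gen in range(1, cfg.n_generations + 1):
        children: list[_SimCell] = []
        for cell in population:
            for _ in range(2):
                child = cell.clone_as_child(new_node(), gen)
                _random_mutations(child, cfg, rng, gen, weights, planted,
                                  bp_counter)
                if (cfg.p_wgd_per_generation > 0 and not child.wgd
                        and rng.random() < cfg.p_wgd_per_generation):
                    _apply_wgd(child, cfg, rng, weights)
                _shed_post_wgd_losses(child, rng, weights)
                children.append(child)
                parent_of[child.node_id] = cell.node_id

        # scenario plantings act on the first eligible child, deterministically
        if gen == cfg.founding_nrt_generation and founding_key is None \
                and cfg.plant_clonal_structure \
                and cfg.scenario is Scenario.TYPE2:
            target = children[0]
            bp_counter[0] += 1
            bp = f"s{cfg.seed}bp{bp_counter[0]:05d}"
            op = {"op": "nrt", "participants": ["2", "4"],
                  "breakpoint_id": bp}
            _apply_op(target, op, weights)
            founding_key = (EventKind.NRT, ("2", "4"), bp)
            planted.append(PlantedEvent(
                identity_key=founding_key, notation_kind="t",
                participants=("2", "4"), breakpoint_id=bp, generation=gen,
                acquired_in_wgd_cell=False, founding=True))
            clone_founders["FC_NRT"] = target.node_id
        if cfg.scenario is Scenario.TYPE1 and gen == 1 and not wgd_done \
                and cfg.plant_clonal_structure:
            # WGD first; the founding NRT is acquired in the 4N cell
            # (participants at 4 copies -> 3 intact + 1 derivative),
            # then random losses shave the genome into the sub-4N range
            target = children[0]
            _apply_wgd(target, cfg, rng, weights)
            wgd_done = True
            clone_founders["FC_WGD"] = target.node_id
            bp_counter[0] += 1
            bp = f"s{cfg.seed}bp{bp_counter[0]:05d}"
            _apply_op(target, {"op": "nrt", "participants": ["11", "7"],
                               "breakpoint_id": bp}, weights)
            founding_key = (EventKind.NRT, ("11", "7"), bp)
            planted.append(PlantedEvent(
                identity_key=founding_key, notation_kind="t",
                participants=("11", "7"), breakpoint_id=bp,
                generation=gen, acquired_in_wgd_cell=True, founding=True))
            clone_founders["FC_NRT"] = target.node_id
        if cfg.scenario is Scenario.TYPE2 and gen == cfg.wgd_generation \
                and not wgd_done and cfg.plant_clonal_structure:
            target = next(
                (c for c in children
                 if founding_key is not None and founding_key in c.events
                 and not c.wgd), None)
            if target is not None:
                _apply_wgd(target, cfg, rng, weights)
                wgd_done = True
                clone_founders["FC_WGD"] = target.node_id
        # a marked subclone inside the WGD clone distinguishes polyclonal sites
        if cfg.seeding in (Seeding.POLYCLONAL, Seeding.MIXED) \
                and wgd_done and subclone_key is None \
                and gen == cfg.wgd_generation + 1:
            target = next((c for c in children if c.wgd), None)
            if target is not None:
                bp_counter[0] += 1
                bp = f"s{cfg.seed}bp{bp_counter[0]:05d}"
                op = {"op": "nrt", "participants": ["9", "15"],
                      "breakpoint_id": bp}
                _apply_op(target, op, weights)
                subclone_key = (EventKind.NRT, ("9", "15"), bp)
                planted.append(PlantedEvent(
                    identity_key=subclone_key, notation_kind="t",
                    participants=("9", "15"), breakpoint_id=bp,
                    generation=gen, acquired_in_wgd_cell=True,
                    founding=False))
                clone_founders["FC_SUB"] = target.node_id

        for child in children:
            weight_of[child.node_id] = child.branch_weight
        population = children

    # -- partition the final population into planted clones -----------------
    def clone_label(cell: _SimCell) -> str:
        has_founding = founding_key is not None and founding_key in cell.events
        if subclone_key is not None and subclone_key in cell.events:
            return "FC_SUB"
        if cell.wgd and has_founding:
            return ("FC_WGD" if cfg.scenario is Scenario.TYPE2 else "FC_NRT")
        if cell.wgd:
            return "FC_WGD"
        if has_founding:
            return "FC_NRT"
        return "NORMAL"

    pools: dict[str, list[_SimCell]] = {}
    for cell in population:
        pools.setdefault(clone_label(cell), []).append(cell)

    # -- site composition ----------------------------------------------------
    animal = "M1"
    site_specs: list[tuple[str, Site, str, str]] = []  # sample, site, major, minor
    if cfg.scenario is Scenario.TYPE2:
        site_specs.append((f"{animal}_SVZ_L", Site.SVZ_L, "FC_NRT", "NORMAL"))
        tumor_major = "FC_WGD" if "FC_WGD" in pools else "FC_NRT"
        for k in range(max(1, cfg.n_sites - 1)):
            major = tumor_major
            if cfg.seeding in (Seeding.POLYCLONAL, Seeding.MIXED) \
                    and "FC_SUB" in pools and k == 0:
                minor = "FC_SUB"
            else:
                minor = "FC_NRT"
            site_specs.append((f"{animal}_T{k + 1}", Site.PARENCHYMA,
                               major, minor))
    else:
        site_specs.append((f"{animal}_SVZ_L", Site.SVZ_L, "NORMAL", "NORMAL"))
        tumor_major = "FC_NRT" if "FC_NRT" in pools else "FC_WGD"
        for k in range(max(1, cfg.n_sites - 1)):
            site_specs.append((f"{animal}_T{k + 1}", Site.PARENCHYMA,
                               tumor_major, "FC_WGD"))

    def draw(pool_name: str, k: int, used: set[int]) -> list[_SimCell]:
        pool = [c for c in pools.get(pool_name, [])
                if c.node_id not in used]
        if not pool:
            return []
        k = min(k, len(pool))
        idx = rng.choice(len(pool), size=k, replace=False)
        return [pool[int(i)] for i in sorted(idx)]

    samples: list[SampleKaryotypeSet] = []
    used: set[int] = set()
    cell_states: dict[str, MetaphaseKaryotype] = {}
    cell_ledgers: dict[str, list[dict]] = {}
    clone_of_cell: dict[str, str] = {}
    site_of_cell: dict[str, str] = {}
    sampled_nodes: dict[int, str] = {}

    for sample_id, site, major, minor in site_specs:
        n_major = int(round(cfg.dominant_clone_fraction * cfg.cells_per_site))
        chosen = draw(major, n_major, used)
        for c in chosen:
            used.add(c.node_id)
        filler = draw(minor if minor != major else "NORMAL",
                      cfg.cells_per_site - len(chosen), used)
        for c in filler:
            used.add(c.node_id)
        picked = chosen + filler
        if not picked:
            continue
        cells = []
        for i, sim in enumerate(picked, start=1):
            cid = f"{sample_id}_c{i:03d}"
            cell = MetaphaseKaryotype(
                cell_id=cid, sample_id=sample_id,
                counts=dict(sim.counts),
                events=tuple(sorted(sim.events.values(),
                                    key=lambda e: repr(e.identity))))
            cells.append(cell)
            cell_states[cid] = cell
            cell_ledgers[cid] = list(sim.ledger)
            clone_of_cell[cid] = clone_label(sim)
            site_of_cell[cid] = site.value
            sampled_nodes[sim.node_id] = cid
        samples.append(SampleKaryotypeSet(
            sample_id=sample_id, animal_id=animal, site=site,
            passage=1, cells=tuple(cells)))

    if not samples:
        raise RuntimeError("simulation produced no sampled cells")

    true_tree, root_weights = _build_true_tree(
        parent_of, weight_of, sampled_nodes, founder.node_id)

    # -- planted clone chain -------------------------------------------------
    true_clones: list[TrueClone] = []
    chain = ["NORMAL"]
    if cfg.scenario is Scenario.TYPE2:
        chain += [c for c in ("FC_NRT", "FC_WGD", "FC_SUB")
                  if c in clone_founders]
    else:
        chain += [c for c in ("FC_WGD", "FC_NRT", "FC_SUB")
                  if c in clone_founders]
    for i, cid in enumerate(chain):
        wgd_flag = cid in ("FC_WGD", "FC_SUB") or (
            cfg.scenario is Scenario.TYPE1 and cid == "FC_NRT")
        keys: list[tuple] = []
        if cid in ("FC_NRT", "FC_WGD", "FC_SUB") and founding_key is not None:
            if cfg.scenario is Scenario.TYPE2 or cid in ("FC_NRT", "FC_SUB"):
                keys.append(founding_key)
        if cid == "FC_SUB" and subclone_key is not None:
            keys.append(subclone_key)
        true_clones.append(TrueClone(
            clone_id=cid, parent=chain[i - 1] if i else None,
            wgd=wgd_flag, events=tuple(keys),
            founder_node=clone_founders[cid]))

    case = SimulatedCase(
        config=cfg, samples=samples, true_tree=true_tree,
        true_clones=true_clones, planted_events=planted,
        cell_ledgers=cell_ledgers, cell_states=cell_states,
        clone_of_cell=clone_of_cell, site_of_cell=site_of_cell,
        true_root_weights=root_weights)

    if cfg.generate_cnv:
        sizes = dict(cfg.chrom_sizes) if cfg.chrom_sizes else MM9_CHROM_SIZES
        focal = []
        if cfg.plant_focal_deletion:
            chrom, start, end = cfg.focal_deletion
            if end <= sizes.get(chrom, 0):
                focal = [(chrom, start, end, -2)]
        for s in samples:
            # profile of the site's dominant planted clone founder
            major = next(
                (clone_of_cell[c.cell_id] for c in s.cells), "NORMAL")
            founder_node = clone_founders.get(major, founder.node_id)
            exemplar = next(
                (c for c in s.cells if clone_of_cell[c.cell_id] == major),
                s.cells[0])
            tumor = major != "NORMAL"
            case.cnv_profiles[s.sample_id] = karyotype_to_bins(
                exemplar, sizes,
                noise_sd_log2=cfg.noise_sd_log2,
                seed=int(rng.integers(0, 2**31 - 1)),
                bin_size=cfg.bin_size,
                focal_events=focal if tumor else (),
                sample_id=s.sample_id)
    return case


def _build_true_tree(parent_of: Mapping[int, Optional[int]],
                     weight_of: Mapping[int, float],
                     sampled_nodes: Mapping[int, str],
                     root_node: int) -> tuple[PhyloTree, dict[str, float]]:
    """Prune the genealogy to the sampled leaves, collapsing unary nodes and
    summing branch weights; returns the tree plus true root-to-leaf weights."""
    keep: set[int] = {root_node}
    for node in sampled_nodes:
        cur: Optional[int] = node
        while cur is not None and cur not in keep:
            keep.add(cur)
            cur = parent_of[cur]
    children: dict[int, list[int]] = {}
    for node in keep:
        p = parent_of[node]
        if p is not None:
            children.setdefault(p, []).append(node)

    adjacency: dict[int, dict[int, float]] = {}
    names: dict[int, str] = {}

    def add_edge(u: int, v: int, w: float) -> None:
        adjacency.setdefault(u, {})[v] = w
        adjacency.setdefault(v, {})[u] = w

    def collapse(node: int) -> tuple[int, float]:
        """Return (representative node, accumulated weight above it)."""
        acc = weight_of.get(node, 0.0)
        while node not in sampled_nodes and len(children.get(node, [])) == 1:
            node = children[node][0]
            acc += weight_of.get(node, 0.0)
        return node, acc

    def build(node: int) -> None:
        for child in children.get(node, []):
            rep, w = collapse(child)
            add_edge(node, rep, w)
            build(rep)

    adjacency.setdefault(root_node, {})
    build(root_node)
    for node, cid in sampled_nodes.items():
        if node in adjacency:
            names[node] = cid
    names[root_node] = "CONTROL"
    tree = PhyloTree(adjacency, names, root=root_node)
    root_weights = {}
    lengths = tree.root_to_leaf_lengths()
    for node, cid in sampled_nodes.items():
        if cid in lengths:
            root_weights[cid] = lengths[cid]
    return tree, root_weights


def karyotype_to_bins(
    cell: MetaphaseKaryotype,
    chrom_sizes: Mapping[str, int],
    noise_sd_log2: float = 0.0,
    seed: Optional[int] = None,
    bin_size: int = DEFAULT_BIN_SIZE,
    focal_events: Sequence[tuple[str, int, int, int]] = (),
    sample_id: Optional[str] = None,
    baseline: Optional[Mapping[str, int]] = None,
) -> CNVProfile:
    """Binned log2 copy-ratio profile matched to a karyotype.

    Emulates a ratio-vs-matched-normal pipeline: each chromosome's material
    copy number is first divided by its baseline copy number in the normal
    genome (2 per autosome, 1 per sex chromosome in a male mouse), then by
    the median of those relative values over chromosomes 1-19 and X, so a
    normal cell is flat zero and pure WGD cancels.  ``focal_events`` are
    (chrom, start, end, delta_copies) overlays emulating focal drivers;
    zero-copy bins are floored at log2 ratio -5.  Gaussian noise is added
    per bin.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    material = cell.material_counts()
    base = dict(NORMAL_MALE_COUNTS if baseline is None else baseline)
    relative = {c: material.get(c, 0) / base[c] for c in base}
    ref_chroms = [c for c in AUTOSOMES + ("X",) if c in chrom_sizes]
    med = float(np.median([relative.get(c, 0.0) for c in ref_chroms]))
    if med <= 0:
        raise ValueError("median relative copy number is zero")
    frames = []
    for chrom, size in chrom_sizes.items():
        n_bins = math.ceil(size / bin_size)
        starts = np.arange(n_bins, dtype=int) * bin_size
        ends = np.minimum(starts + bin_size, size)
        copies = np.full(n_bins, float(material.get(chrom, 0)))
        for f_chrom, f_start, f_end, delta in focal_events:
            if f_chrom != chrom:
                continue
            sel = (starts >= f_start) & (starts < f_end)
            copies[sel] = np.maximum(copies[sel] + delta, 0.0)
        ratio = copies / base.get(chrom, 2) / med
        log2 = np.where(ratio > 0, np.log2(np.maximum(ratio, 2.0**-5)), -5.0)
        if noise_sd_log2 > 0:
            log2 = log2 + rng.normal(0.0, noise_sd_log2, size=n_bins)
        frames.append(pd.DataFrame({
            "chrom": chrom, "start": starts, "end": ends,
            "log2_ratio": log2}))
    bins = pd.concat(frames, ignore_index=True)
    return CNVProfile(sample_id=sample_id or cell.cell_id, bins=bins,
                      bin_size=bin_size)


# ---------------------------------------------------------------------------
# fixture export

def export_fixtures(case: SimulatedCase, out_dir) -> dict[str, str]:
    """Write the case as plain-text fixtures; returns path -> sha256."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_karyotype_table(case.samples, out / "karyotypes.tsv")
    write_newick(case.true_tree, out / "true_tree.nwk")
    for sid, profile in sorted(case.cnv_profiles.items()):
        write_bin_table(profile, out / f"cnv_{sid}.tsv")
    ledger = {
        "config": {
            **{k: (v.value if isinstance(v, enum.Enum) else
                   list(v) if isinstance(v, tuple) else
                   dict(v) if isinstance(v, Mapping) else v)
               for k, v in vars(case.config).items()},
        },
        "planted_events": [
            {
                "identity": _key_to_jsonable(p.identity_key),
                "participants": list(p.participants),
                "breakpoint_id": p.breakpoint_id,
                "generation": p.generation,
                "acquired_in_wgd_cell": p.acquired_in_wgd_cell,
                "founding": p.founding,
            }
            for p in case.planted_events
        ],
        "true_clones": [
            {
                "clone_id": c.clone_id, "parent": c.parent, "wgd": c.wgd,
                "events": [_key_to_jsonable(k) for k in c.events],
            }
            for c in case.true_clones
        ],
        "clone_of_cell": case.clone_of_cell,
        "site_of_cell": case.site_of_cell,
        "true_root_weights": case.true_root_weights,
        "cell_ledgers": case.cell_ledgers,
    }
    with open(out / "ledger.json", "w", encoding="utf-8") as fh:
        json.dump(ledger, fh, indent=1, sort_keys=True)
        fh.write("\n")
    checksums = {}
    for p in sorted(out.iterdir()):
        if p.is_file():
            checksums[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    return checksums
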