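"""Founder-clone identification and evolutionary ordering on rooted trees.

A founder clone (FC) is the inferred ancestor of a maximal clade of
metaphases sharing an identical structural-event set and WGD state; its
genotype is the intersection of its members' canonical profiles.  FCs are
ordered by genotype containment under two rules: the WGD transition is
irreversible (near-2N parents only ever precede sub-4N children), and
evolution runs from simple to more complex genomes.  When a 2N genotype is
tested against a 4N one, the 2N events and deviations are doubled first and
subsequent random chromosome losses are allowed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .distance import CanonicalProfile, canonicalize
from .model import MetaphaseKaryotype, WGD_COUNT_THRESHOLD
from .njtree import PhyloTree

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FCGenotype:
    """Shared genetic features of a founder clone.

    events: identity key -> copies (minimum over members).
    deviations: chromosome -> material copy deviation, kept only where all
    members agree and the deviation is non-zero.
    """

    wgd: bool
    events: tuple[tuple[tuple, int], ...]
    deviations: tuple[tuple[str, float], ...]

    @property
    def event_dict(self) -> dict[tuple, int]:
        return dict(self.events)

    @property
    def deviation_dict(self) -> dict[str, float]:
        return dict(self.deviations)

    @property
    def n_events(self) -> int:
        return len(self.events) + len(self.deviations) + int(self.wgd)

    @classmethod
    def from_profiles(cls, profiles: Sequence[CanonicalProfile]) -> "FCGenotype":
        wgd = profiles[0].wgd
        shared_keys = set(profiles[0].events)
        for p in profiles[1:]:
            shared_keys &= set(p.events)
        events = tuple(sorted(
            ((k, min(p.events[k][0] for p in profiles)) for k in shared_keys),
            key=repr))
        devs = []
        for chrom in profiles[0].deviations:
            vals = {p.deviations[chrom] for p in profiles}
            if len(vals) == 1 and next(iter(vals)) != 0:
                devs.append((chrom, float(next(iter(vals)))))
        return cls(wgd=wgd, events=events, deviations=tuple(sorted(devs)))


@dataclass(frozen=True)
class FounderClone:
    fc_id: str
    genotype: FCGenotype
    member_cells: tuple[str, ...]
    sample_id: str
    parent_fc: Optional[str] = None
    low_confidence: bool = False
    predicted: bool = False


def genotype_contains(parent: FCGenotype, child: FCGenotype) -> bool:
    """True when ``parent`` could be an ancestor genotype of ``child``.

    WGD is irreversible; crossing it doubles the parent's event copies and
    deviations and allows subsequent chromosome losses.
    """
    if parent.wgd and not child.wgd:
        return False
    crossing = child.wgd and not parent.wgd
    child_events = child.event_dict
    for key, copies in parent.events:
        if key not in child_events:
            return False
    child_devs = child.deviation_dict
    for chrom, g in parent.deviations:
        g_scaled = 2 * g if crossing else g
        h = child_devs.get(chrom, 0.0)
        if crossing:
            # after doubling, losses can only deepen; a doubled gain may be
            # eroded by random post-WGD losses but must remain a gain
            if g_scaled < 0 and h > g_scaled:
                return False
            if g_scaled > 0 and h < 1:
                return False
        else:
            if g_scaled < 0 and h > g_scaled:
                return False
            if g_scaled > 0 and h < g_scaled:
                return False
    return True


def _genotype_equal(a: FCGenotype, b: FCGenotype) -> bool:
    return (a.wgd == b.wgd and a.events == b.events
            and a.deviations == b.deviations)


def _signature(profile: CanonicalProfile) -> tuple:
    return (profile.wgd, frozenset(profile.events))


def identify_founder_clones(
    tree: PhyloTree,
    cells: Sequence[MetaphaseKaryotype],
    min_cells: int = 2,
    wgd_threshold: int = WGD_COUNT_THRESHOLD,
) -> list[FounderClone]:
    """Maximal clades of the rooted tree whose members share an identical
    structural-event set and WGD flag.

    The FC genotype is the intersection of the member cells' canonical
    profiles.  Singleton clades are reported but flagged low-confidence
    when smaller than ``min_cells``.
    """
    if not tree.is_rooted:
        raise ValueError("founder clones are read off a rooted tree")
    by_id = {c.cell_id: c for c in cells}
    profiles = {c.cell_id: canonicalize(c, wgd_threshold=wgd_threshold)
                for c in cells}
    sample_id = cells[0].sample_id if cells else ""

    clones: list[FounderClone] = []

    def clade_cells(node: int, parent: Optional[int]) -> list[str]:
        return [tree.names[u] for u in tree.clade_leaves(node, parent)
                if tree.names.get(u) in by_id]

    def uniform(members: list[str]) -> bool:
        sigs = {_signature(profiles[m]) for m in members}
        return len(sigs) == 1

    def visit(node: int, parent: Optional[int]) -> None:
        members = clade_cells(node, parent)
        if not members:
            return
        if uniform(members):
            genotype = FCGenotype.from_profiles(
                [profiles[m] for m in members])
            clones.append(FounderClone(
                fc_id="",
                genotype=genotype,
                member_cells=tuple(sorted(members)),
                sample_id=sample_id,
            ))
            return
        for child in tree.adjacency[node]:
            if child != parent:
                visit(child, node)

    visit(tree.root, None)

    # clades with identical genotypes are fragments of one clone (zero-length
    # edges resolve arbitrarily in NJ); merge them, preserving traversal order
    merged: list[FounderClone] = []
    index: dict[FCGenotype, int] = {}
    for fc in clones:
        if fc.genotype in index:
            old = merged[index[fc.genotype]]
            merged[index[fc.genotype]] = FounderClone(
                fc_id=old.fc_id, genotype=old.genotype,
                member_cells=tuple(sorted(old.member_cells
                                          + fc.member_cells)),
                sample_id=old.sample_id)
        else:
            index[fc.genotype] = len(merged)
            merged.append(fc)
    return [
        FounderClone(
            fc_id=f"FC{i + 1}", genotype=fc.genotype,
            member_cells=fc.member_cells, sample_id=fc.sample_id,
            low_confidence=len(fc.member_cells) < min_cells)
        for i, fc in enumerate(merged)
    ]


@dataclass
class CloneLineage:
    """Forest of founder clones ordered by genotype containment."""

    fcs: list[FounderClone]
    edges: list[tuple[str, str]]
    roots: list[str]
    ambiguous_parents: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "fcs": [
                {
                    "fc_id": fc.fc_id,
                    "sample_id": fc.sample_id,
                    "members": list(fc.member_cells),
                    "wgd": fc.genotype.wgd,
                    "n_events": fc.genotype.n_events,
                    "parent": fc.parent_fc,
                    "low_confidence": fc.low_confidence,
                    "predicted": fc.predicted,
                }
                for fc in self.fcs
            ],
            "edges": [list(e) for e in self.edges],
            "roots": list(self.roots),
            "ambiguous_parents": {k: list(v)
                                  for k, v in self.ambiguous_parents.items()},
        }

    def to_dot(self) -> str:
        lines = ["digraph lineage {"]
        for fc in self.fcs:
            shape = "box" if fc.genotype.wgd else "ellipse"
            lines.append(
                f'  "{fc.fc_id}" [shape={shape}, '
                f'label="{fc.fc_id}\\n{len(fc.member_cells)} cells"];')
        for parent, child in self.edges:
            lines.append(f'  "{parent}" -> "{child}";')
        lines.append("}")
        return "\n".join(lines)


def order_founder_clones(fcs: Sequence[FounderClone]) -> CloneLineage:
    """Order FCs by genotype containment into a lineage forest.

    The parent of an FC is the containing FC with the most events (the
    closest ancestor); when two incomparable candidates tie, both are
    recorded and the edge is left unresolved.
    """
    by_id = {fc.fc_id: fc for fc in fcs}
    edges: list[tuple[str, str]] = []
    roots: list[str] = []
    ambiguous: dict[str, tuple[str, ...]] = {}
    resolved: dict[str, Optional[str]] = {}

    for fc in fcs:
        candidates = [
            other for other in fcs
            if other.fc_id != fc.fc_id
            and genotype_contains(other.genotype, fc.genotype)
            and not _genotype_equal(other.genotype, fc.genotype)
        ]
        if not candidates:
            roots.append(fc.fc_id)
            resolved[fc.fc_id] = None
            continue
        # keep only the closest ancestors (not contained in another candidate)
        maximal = [
            g for g in candidates
            if not any(
                h.fc_id != g.fc_id
                and genotype_contains(g.genotype, h.genotype)
                and not _genotype_equal(g.genotype, h.genotype)
                for h in candidates)
        ]
        best_n = max(g.genotype.n_events for g in maximal)
        best = [g for g in maximal if g.genotype.n_events == best_n]
        if len(best) == 1:
            edges.append((best[0].fc_id, fc.fc_id))
            resolved[fc.fc_id] = best[0].fc_id
        else:
            ambiguous[fc.fc_id] = tuple(sorted(g.fc_id for g in best))
            roots.append(fc.fc_id)
            resolved[fc.fc_id] = None
            logger.info("ambiguous parentage for %s: %s", fc.fc_id,
                        ambiguous[fc.fc_id])

    ordered = [
        FounderClone(fc.fc_id, fc.genotype, fc.member_cells, fc.sample_id,
                     parent_fc=resolved[fc.fc_id],
                     low_confidence=fc.low_confidence, predicted=fc.predicted)
        for fc in fcs
    ]
    return CloneLineage(fcs=ordered, edges=edges, roots=roots,
                        ambiguous_parents=ambiguous)


def predict_intermediate_fcs(fcs: Sequence[FounderClone]
                             ) -> list[FounderClone]:
    """Unobserved intermediate founder clones.

    A predicted FC is the genotype intersection of two observed same-ploidy
    FCs when that intersection is a strict superset of every observed
    genotype contained in both — evidence that an unsampled ancestor
    carried the common features.  Predicted FCs have no member cells and
    are flagged ``predicted``.
    """
    predicted: list[FounderClone] = []
    existing = [fc.genotype for fc in fcs]

    def intersect(a: FCGenotype, b: FCGenotype) -> FCGenotype:
        a_ev, b_ev = a.event_dict, b.event_dict
        events = tuple(sorted(
            ((k, min(a_ev[k], b_ev[k])) for k in set(a_ev) & set(b_ev)),
            key=repr))
        a_dev, b_dev = a.deviation_dict, b.deviation_dict
        devs = tuple(sorted(
            (c, a_dev[c]) for c in set(a_dev) & set(b_dev)
            if a_dev[c] == b_dev[c]))
        return FCGenotype(wgd=a.wgd, events=events, deviations=devs)

    seen: set[FCGenotype] = set(existing)
    for i, fc_a in enumerate(fcs):
        for fc_b in fcs[i + 1:]:
            if fc_a.genotype.wgd != fc_b.genotype.wgd:
                continue
            g = intersect(fc_a.genotype, fc_b.genotype)
            if g in seen or g.n_events == 0:
                continue
            if _genotype_equal(g, fc_a.genotype) \
                    or _genotype_equal(g, fc_b.genotype):
                continue
            # must be strictly above every observed genotype below both
            below = [h for h in existing
                     if genotype_contains(h, fc_a.genotype)
                     and genotype_contains(h, fc_b.genotype)]
            if any(not (genotype_contains(h, g)
                        and not _genotype_equal(h, g)) for h in below):
                continue
            seen.add(g)
            predicted.append(FounderClone(
                fc_id=f"pFC{len(predicted) + 1}", genotype=g,
                member_cells=(), sample_id=fc_a.sample_id,
                low_confidence=True, predicted=True))
    return predicted


@dataclass(frozen=True)
class SeedingReport:
    """Which founder clones seeded which sites."""

    sites_by_fc: Mapping[str, tuple[str, ...]]
    fcs_by_site: Mapping[str, tuple[str, ...]]
    parallel_seeding: tuple[str, ...]   # FCs whose members span >1 site
    polyclonal_seeding: tuple[str, ...]  # sites holding members of >1 FC

    @property
    def has_parallel_seeding(self) -> bool:
        return bool(self.parallel_seeding)

    @property
    def has_polyclonal_seeding(self) -> bool:
        return bool(self.polyclonal_seeding)


def infer_seeding_pattern(
    fcs: Sequence[FounderClone],
    site_of_cell: Mapping[str, str],
) -> SeedingReport:
    """Cross founder clones with the sampling site of their member cells."""
    sites_by_fc: dict[str, tuple[str, ...]] = {}
    fcs_by_site: dict[str, list[str]] = {}
    for fc in fcs:
        sites = tuple(sorted({str(site_of_cell[c]) for c in fc.member_cells}))
        sites_by_fc[fc.fc_id] = sites
        for s in sites:
            fcs_by_site.setdefault(s, []).append(fc.fc_id)
    return SeedingReport(
        sites_by_fc=sites_by_fc,
        fcs_by_site={s: tuple(v) for s, v in sorted(fcs_by_site.items())},
        parallel_seeding=tuple(f for f, s in sorted(sites_by_fc.items())
                               if len(s) > 1),
        polyclonal_seeding=tuple(s for s, f in sorted(fcs_by_site.items())
                                 if len(f) > 1),
    )
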