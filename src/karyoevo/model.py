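"""Core data model for per-metaphase SKY karyotypes.

A *metaphase* is a single mitotic cell whose chromosomes were individually
counted and painted.  Each cell is described by the copy number of every
mouse chromosome (chr1..chr19, X, Y) plus a list of structural events —
nonreciprocal translocations t(a;b), reciprocal translocations
t(a;b)&t(b;a), fusions f(a;b) and ring chromosomes ring(a;a) — written in
an ISCN-like notation.

This module also implements the per-cell and per-sample classifications
built directly on that model:

* whole-genome duplication (WGD) calling by total chromosome count
  (mouse cutoff: 50 bodies, i.e. ploidy 2.5);
* clonality of structural events (>50% of a sample's metaphases);
* the 2N-vs-4N acquisition class of a clonal NRT, read off the modal copy
  pattern in sub-4N carriers (2 NRT copies + 2 intact partner copies means
  the NRT predates WGD; 1 copy + 3 partner copies means it was acquired in
  a 4N cell);
* the karyotype-based Type 1 / Type 2 case classification.
"""

from __future__ import annotations

import enum
import re
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

AUTOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 20))
SEX_CHROMOSOMES: tuple[str, ...] = ("X", "Y")
CHROMOSOMES: tuple[str, ...] = AUTOSOMES + SEX_CHROMOSOMES

#: Copy number of each chromosome in a normal male mouse cell.
NORMAL_MALE_COUNTS: dict[str, int] = {c: 2 for c in AUTOSOMES} | {"X": 1, "Y": 1}

#: Total chromosome count at or above which a mouse cell is called WGD
#: (ploidy 2.5 == 50 bodies; boundary falls on the WGD side).
WGD_COUNT_THRESHOLD = 50


class NotationError(ValueError):
    """Raised when an event string does not match the t/f/ring grammar."""


class ValidationError(ValueError):
    """Raised when a structurally valid object violates a domain invariant."""


class EventKind(str, enum.Enum):
    NRT = "NRT"        # nonreciprocal translocation t(a;b)
    RT = "RT"          # reciprocal translocation t(a;b)&t(b;a)
    FUSION = "FUSION"  # f(a;b)
    RING = "RING"      # ring(a;a)


class Site(str, enum.Enum):
    SVZ_L = "SVZ_L"
    SVZ_R = "SVZ_R"
    PARENCHYMA = "PARENCHYMA"
    OTHER = "OTHER"


class PloidyClass(str, enum.Enum):
    NEAR_2N = "NEAR_2N"
    SUB_4N = "SUB_4N"


class Acquisition(str, enum.Enum):
    CNRT_2N = "CNRT_2N"
    CNRT_4N = "CNRT_4N"
    UNDETERMINED = "UNDETERMINED"
    NOT_APPLICABLE = "NOT_APPLICABLE"


class CaseType(str, enum.Enum):
    TYPE_1 = "TYPE_1"
    TYPE_2 = "TYPE_2"
    UNDETERMINED = "UNDETERMINED"


def _check_label(label: str) -> str:
    if label not in CHROMOSOMES:
        raise ValidationError(f"unknown chromosome label {label!r}")
    return label


@dataclass(frozen=True)
class StructuralEvent:
    """A typed chromosomal aberration carried by a cell.

    ``participants`` is the ordered tuple of chromosome labels written in
    the notation; order is preserved ((2,4) != (4,2)).  ``copies`` is the
    number of copies of this derivative in the cell.  ``breakpoint_id`` is
    an opaque tag: two events sharing it carry the same breakpoint; when
    both events carry a tag, identity requires the tags to match.
    """

    kind: EventKind
    participants: tuple[str, ...]
    copies: int = 1
    breakpoint_id: Optional[str] = None
    uncertain: bool = False

    def __post_init__(self) -> None:
        if len(self.participants) < 2:
            raise ValidationError("an event needs at least 2 participants")
        for p in self.participants:
            _check_label(p)
        if self.copies < 1:
            raise ValidationError("copies must be >= 1")

    @property
    def identity(self) -> tuple:
        """Hashable identity key: (kind, participants, breakpoint_id)."""
        return (self.kind, self.participants, self.breakpoint_id)

    def matches(self, other: "StructuralEvent") -> bool:
        """Same-event predicate: kind, ordered participants, and (when both
        present) breakpoint_id must agree."""
        if self.kind != other.kind or self.participants != other.participants:
            return False
        if self.breakpoint_id is not None and other.breakpoint_id is not None:
            return self.breakpoint_id == other.breakpoint_id
        return True

    def with_copies(self, copies: int) -> "StructuralEvent":
        return StructuralEvent(self.kind, self.participants, copies,
                               self.breakpoint_id, self.uncertain)


_KIND_TOKENS = {"t": EventKind.NRT, "f": EventKind.FUSION, "ring": EventKind.RING}
_EVENT_RE = re.compile(
    r"^(?P<kind>[A-Za-z]+)\((?P<labels>[^()]+)\)"
    r"(?P<unc>\?)?(?:x(?P<copies>\d+))?(?:@(?P<bp>[^\s;&]+))?$"
)


def _parse_single(text: str) -> StructuralEvent:
    m = _EVENT_RE.match(text.strip())
    if m is None:
        raise NotationError(f"malformed event notation {text!r}")
    kind_tok = m.group("kind")
    if kind_tok not in _KIND_TOKENS:
        raise NotationError(f"unknown event kind token {kind_tok!r} in {text!r}")
    labels = tuple(s.strip() for s in m.group("labels").split(";"))
    if len(labels) < 2:
        raise NotationError(f"event {text!r} needs at least two participants")
    for lab in labels:
        _check_label(lab)
    return StructuralEvent(
        kind=_KIND_TOKENS[kind_tok],
        participants=labels,
        copies=int(m.group("copies") or 1),
        breakpoint_id=m.group("bp"),
        uncertain=m.group("unc") is not None,
    )


def parse_event_notation(text: str) -> StructuralEvent:
    """Parse one ISCN-like event string.

    Grammar: ``kind "(" label (";" label)+ ")" ["?"] ["x"copies] ["@"bp]``
    with kind in {t, f, ring}.  A pair of ``&``-joined t(...) forms with
    reversed participants (``t(2;7)&t(7;2)``) parses as one reciprocal
    translocation (kind RT, participants taken from the first form).
    """
    s = text.strip()
    if "&" in s:
        parts = [p.strip() for p in s.split("&")]
        if len(parts) != 2:
            raise NotationError(f"'&' joins exactly two t(...) forms: {text!r}")
        first, second = (_parse_single(p) for p in parts)
        if first.kind is not EventKind.NRT or second.kind is not EventKind.NRT:
            raise NotationError(f"'&' is only valid between t(...) forms: {text!r}")
        if second.participants != tuple(reversed(first.participants)):
            raise NotationError(
                f"reciprocal pair must reverse participants: {text!r}")
        return StructuralEvent(
            kind=EventKind.RT,
            participants=first.participants,
            copies=second.copies if second.copies != 1 else first.copies,
            breakpoint_id=first.breakpoint_id or second.breakpoint_id,
            uncertain=first.uncertain or second.uncertain,
        )
    return _parse_single(s)


def format_event(event: StructuralEvent) -> str:
    """Inverse of :func:`parse_event_notation` (canonical spelling)."""
    kind_tok = {EventKind.NRT: "t", EventKind.RT: "t",
                EventKind.FUSION: "f", EventKind.RING: "ring"}[event.kind]

    def suffix() -> str:
        s = ""
        if event.uncertain:
            s += "?"
        if event.copies != 1:
            s += f"x{event.copies}"
        if event.breakpoint_id is not None:
            s += f"@{event.breakpoint_id}"
        return s

    if event.kind is EventKind.RT:
        fwd = f"t({';'.join(event.participants)})"
        rev = f"t({';'.join(reversed(event.participants))})"
        return fwd + "&" + rev + suffix()
    return f"{kind_tok}({';'.join(event.participants)})" + suffix()


@dataclass(frozen=True)
class MetaphaseKaryotype:
    """One cell: per-chromosome copy counts plus structural events.

    ``total_count`` counts every chromosomal body in the spread: intact
    chromosomes plus each copy of each derivative.
    """

    cell_id: str
    sample_id: str
    counts: Mapping[str, int]
    events: tuple[StructuralEvent, ...] = ()

    def __post_init__(self) -> None:
        counts = {c: 0 for c in CHROMOSOMES}
        for label, n in dict(self.counts).items():
            _check_label(label)
            n = int(n)
            if n < 0:
                raise ValidationError(
                    f"negative count {n} for chr{label} in cell {self.cell_id}")
            counts[label] = n
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "events", tuple(self.events))
        if self.total_count < 1:
            raise ValidationError(f"cell {self.cell_id} has no chromosomes")

    @property
    def total_count(self) -> int:
        return sum(self.counts.values()) + sum(e.copies for e in self.events)

    def material_counts(self) -> dict[str, int]:
        """Copy number of each chromosome's material, counting derivative
        contributions: each copy of a derivative adds 1 per participant
        occurrence.  A translocation is copy-neutral on this scale."""
        mat = dict(self.counts)
        for e in self.events:
            for p in e.participants:
                mat[p] = mat.get(p, 0) + e.copies
        return mat

    def carries(self, event: StructuralEvent) -> bool:
        return any(e.matches(event) for e in self.events)

    def event_copies(self, event: StructuralEvent) -> int:
        return sum(e.copies for e in self.events if e.matches(event))


@dataclass(frozen=True)
class SampleKaryotypeSet:
    """All metaphases karyotyped from one sample (one site of one animal)."""

    sample_id: str
    animal_id: str
    site: Site
    cells: tuple[MetaphaseKaryotype, ...]
    passage: Optional[int] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "cells", tuple(self.cells))
        object.__setattr__(self, "site", Site(self.site))
        if not self.cells:
            raise ValidationError(f"sample {self.sample_id} has no cells")
        for c in self.cells:
            if c.sample_id != self.sample_id:
                raise ValidationError(
                    f"cell {c.cell_id} has sample_id {c.sample_id!r}, "
                    f"expected {self.sample_id!r}")


@dataclass(frozen=True)
class PloidyCall:
    cell_id: str
    total_count: int
    wgd: bool
    ploidy_class: PloidyClass

    def __post_init__(self) -> None:
        if self.wgd != (self.ploidy_class is PloidyClass.SUB_4N):
            raise ValidationError("ploidy_class must be SUB_4N iff wgd")


def classify_ploidy(cell: MetaphaseKaryotype,
                    threshold_count: int = WGD_COUNT_THRESHOLD) -> PloidyCall:
    """Call WGD from the total chromosome count.

    Mouse cells at or above 50 bodies (ploidy 2.5) are called whole-genome
    duplicated (SUB_4N); below, NEAR_2N.
    """
    wgd = cell.total_count >= threshold_count
    return PloidyCall(
        cell_id=cell.cell_id,
        total_count=cell.total_count,
        wgd=wgd,
        ploidy_class=PloidyClass.SUB_4N if wgd else PloidyClass.NEAR_2N,
    )


@dataclass(frozen=True)
class ClonalityCall:
    event: StructuralEvent
    sample_id: str
    n_carrying: int
    n_total: int
    frequency: float
    clonal: bool
    acquisition: Acquisition

    def __post_init__(self) -> None:
        if abs(self.frequency - self.n_carrying / self.n_total) > 1e-12:
            raise ValidationError("frequency must equal n_carrying/n_total")
        if self.clonal != (self.frequency > 0.5):
            raise ValidationError("clonal iff frequency > 0.5 (strict)")
        if (self.acquisition is Acquisition.NOT_APPLICABLE
                and self.event.kind is EventKind.NRT):
            raise ValidationError("NOT_APPLICABLE is reserved for non-NRT events")


def _mode(values: Sequence[int]) -> Optional[int]:
    """Modal value; ties break to None (toward UNDETERMINED)."""
    if not values:
        return None
    counts = Counter(values).most_common()
    if len(counts) > 1 and counts[0][1] == counts[1][1]:
        return None
    return counts[0][0]


def classify_cnrt_acquisition(
    event: StructuralEvent,
    carrying_cells: Sequence[MetaphaseKaryotype],
    wgd_threshold: int = WGD_COUNT_THRESHOLD,
) -> Acquisition:
    """Classify whether a clonal NRT was acquired at the 2N or 4N stage.

    Among sub-4N carriers, take the modal NRT copy number m and the modal
    intact-participant copy number k: m == 2 means the NRT predated WGD
    (CNRT_2N, "2 copies of the NRT with 2 copies of the translocated
    chromosomes"); m == 1 with k >= 3 means acquisition in a 4N cell
    (CNRT_4N).  If the sample only has near-2N carriers with one copy, the
    NRT is a cNRT2N in its single-copy state.  Modal ties and any other
    pattern give UNDETERMINED.
    """
    if not carrying_cells:
        raise ValidationError("empty carrier set")
    for c in carrying_cells:
        if not c.carries(event):
            raise ValidationError(f"cell {c.cell_id} does not carry the event")
    sub4n = [c for c in carrying_cells
             if classify_ploidy(c, wgd_threshold).wgd]
    if sub4n:
        m = _mode([c.event_copies(event) for c in sub4n])
        k = _mode([c.counts[p] for c in sub4n for p in set(event.participants)])
        if m == 2:
            return Acquisition.CNRT_2N
        if m == 1 and k is not None and k >= 3:
            return Acquisition.CNRT_4N
        return Acquisition.UNDETERMINED
    m = _mode([c.event_copies(event) for c in carrying_cells])
    if m == 1:
        return Acquisition.CNRT_2N
    return Acquisition.UNDETERMINED


def call_clonal_events(
    sample: SampleKaryotypeSet,
    include_uncertain: bool = True,
    wgd_threshold: int = WGD_COUNT_THRESHOLD,
) -> list[ClonalityCall]:
    """One clonality call per distinct event identity observed in the sample.

    An event is clonal iff carried by strictly more than 50% of the
    sample's metaphases.  Clonal NRTs get an acquisition class; non-clonal
    NRTs are UNDETERMINED; non-NRT kinds are NOT_APPLICABLE.
    """
    n_total = len(sample.cells)
    by_identity: dict[tuple, StructuralEvent] = {}
    carriers: dict[tuple, list[MetaphaseKaryotype]] = {}
    for cell in sample.cells:
        seen: set[tuple] = set()
        for e in cell.events:
            if e.uncertain and not include_uncertain:
                continue
            key = e.identity
            by_identity.setdefault(key, e)
            if key not in seen:
                carriers.setdefault(key, []).append(cell)
                seen.add(key)
    calls = []
    for key in sorted(by_identity, key=repr):
        event = by_identity[key]
        n_car = len(carriers[key])
        freq = n_car / n_total
        clonal = freq > 0.5
        if event.kind is not EventKind.NRT:
            acq = Acquisition.NOT_APPLICABLE
        elif clonal:
            acq = classify_cnrt_acquisition(event, carriers[key], wgd_threshold)
        else:
            acq = Acquisition.UNDETERMINED
        calls.append(ClonalityCall(
            event=event, sample_id=sample.sample_id,
            n_carrying=n_car, n_total=n_total,
            frequency=freq, clonal=clonal, acquisition=acq,
        ))
    return calls


def classify_case_type(
    samples_of_animal: Sequence[SampleKaryotypeSet],
    include_uncertain: bool = True,
    wgd_threshold: int = WGD_COUNT_THRESHOLD,
) -> CaseType:
    """Karyotype-based Type 1 / Type 2 call for one animal.

    Any clonal NRT acquired at the 2N stage makes the case Type 2
    (multifocal pattern); otherwise at least one 4N-stage clonal NRT makes
    it Type 1 (single-mass pattern); otherwise undetermined.
    """
    if not samples_of_animal:
        raise ValidationError("need at least one sample")
    acquisitions = [
        call.acquisition
        for sample in samples_of_animal
        for call in call_clonal_events(sample, include_uncertain, wgd_threshold)
        if call.clonal and call.event.kind is EventKind.NRT
    ]
    if Acquisition.CNRT_2N in acquisitions:
        return CaseType.TYPE_2
    if Acquisition.CNRT_4N in acquisitions:
        return CaseType.TYPE_1
    return CaseType.UNDETERMINED
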