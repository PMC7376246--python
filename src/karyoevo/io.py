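"""Readers and writers for per-metaphase karyotype tables.

TSV dialect (UTF-8, tab-separated)::

    cell_id  sample_id  animal_id  site  passage  chr1 .. chr19  chrX  chrY  events

``events`` is a semicolon-joined list of notation strings (``t(2;4)``,
``f(3;3)``, ``ring(11;11)``, ``t(2;7)&t(7;2)``); "" means no events.
Optional suffixes ``xN`` (copies > 1) and ``@id`` (breakpoint tag) make the
round-trip through the in-memory model lossless.  A JSON mirror of the same
schema is provided for programmatic use.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence, Union

import pandas as pd

from .model import (
    CHROMOSOMES,
    MetaphaseKaryotype,
    SampleKaryotypeSet,
    Site,
    StructuralEvent,
    ValidationError,
    format_event,
    parse_event_notation,
)

KARYOTYPE_COLUMNS: tuple[str, ...] = (
    ("cell_id", "sample_id", "animal_id", "site", "passage")
    + tuple(f"chr{c}" for c in CHROMOSOMES)
    + ("events",)
)

PathLike = Union[str, Path]


def _events_to_str(events: Sequence[StructuralEvent]) -> str:
    return ";".join(format_event(e) for e in events)


def _split_events(text: str) -> list[str]:
    """Split on semicolons that sit outside parentheses."""
    tokens, depth, cur = [], 0, []
    for ch in text:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
        if ch == ";" and depth == 0:
            tokens.append("".join(cur))
            cur = []
        else:
            cur.append(ch)
    tokens.append("".join(cur))
    return [t.strip() for t in tokens if t.strip()]


def _events_from_str(text: str) -> tuple[StructuralEvent, ...]:
    text = text.strip()
    if not text:
        return ()
    return tuple(parse_event_notation(tok) for tok in _split_events(text))


def _sets_to_rows(samples: Iterable[SampleKaryotypeSet]) -> list[dict]:
    rows = []
    for s in samples:
        for cell in s.cells:
            row = {
                "cell_id": cell.cell_id,
                "sample_id": s.sample_id,
                "animal_id": s.animal_id,
                "site": s.site.value,
                "passage": "" if s.passage is None else str(s.passage),
                "events": _events_to_str(cell.events),
            }
            for c in CHROMOSOMES:
                row[f"chr{c}"] = str(cell.counts[c])
            rows.append(row)
    return rows


def _rows_to_sets(rows: list[dict]) -> list[SampleKaryotypeSet]:
    order: list[str] = []
    grouped: dict[str, dict] = {}
    for i, row in enumerate(rows, start=1):
        try:
            counts = {}
            for c in CHROMOSOMES:
                raw = str(row[f"chr{c}"]).strip()
                try:
                    counts[c] = int(raw)
                except ValueError:
                    raise ValidationError(f"non-integer count {raw!r} for chr{c}")
            cell = MetaphaseKaryotype(
                cell_id=str(row["cell_id"]),
                sample_id=str(row["sample_id"]),
                counts=counts,
                events=_events_from_str(str(row["events"])),
            )
            site = Site(str(row["site"]))
            passage_raw = str(row.get("passage", "")).strip()
            passage = int(passage_raw) if passage_raw else None
        except (ValueError, KeyError) as exc:
            raise ValidationError(f"row {i}: {exc}") from exc
        sid = cell.sample_id
        if sid not in grouped:
            order.append(sid)
            grouped[sid] = {
                "animal_id": str(row["animal_id"]),
                "site": site,
                "passage": passage,
                "cells": [],
            }
        else:
            g = grouped[sid]
            if (g["animal_id"], g["site"], g["passage"]) != (
                    str(row["animal_id"]), site, passage):
                raise ValidationError(
                    f"row {i}: inconsistent metadata for sample {sid!r}")
        grouped[sid]["cells"].append(cell)
    return [
        SampleKaryotypeSet(
            sample_id=sid,
            animal_id=grouped[sid]["animal_id"],
            site=grouped[sid]["site"],
            passage=grouped[sid]["passage"],
            cells=tuple(grouped[sid]["cells"]),
        )
        for sid in order
    ]


def _infer_format(path: PathLike, fmt: str | None) -> str:
    if fmt is not None:
        return fmt.lower()
    suffix = Path(path).suffix.lower()
    return "json" if suffix == ".json" else "tsv"


def read_karyotype_table(path: PathLike, fmt: str | None = None
                         ) -> list[SampleKaryotypeSet]:
    """Read a karyotype table (TSV or JSON) into validated sample sets."""
    fmt = _infer_format(path, fmt)
    if fmt == "json":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        samples = []
        for s in payload["samples"]:
            cells = tuple(
                MetaphaseKaryotype(
                    cell_id=c["cell_id"],
                    sample_id=s["sample_id"],
                    counts={k: int(v) for k, v in c["counts"].items()},
                    events=tuple(
                        StructuralEvent(
                            kind=e["kind"],
                            participants=tuple(e["participants"]),
                            copies=int(e.get("copies", 1)),
                            breakpoint_id=e.get("breakpoint_id"),
                            uncertain=bool(e.get("uncertain", False)),
                        )
                        for e in c.get("events", [])
                    ),
                )
                for c in s["cells"]
            )
            samples.append(SampleKaryotypeSet(
                sample_id=s["sample_id"], animal_id=s["animal_id"],
                site=Site(s["site"]), passage=s.get("passage"), cells=cells))
        return samples
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in KARYOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"missing column(s): {', '.join(missing)}")
    return _rows_to_sets(df.to_dict(orient="records"))


def write_karyotype_table(samples: Sequence[SampleKaryotypeSet],
                          path: PathLike, fmt: str | None = None) -> None:
    """Write sample sets in canonical field order; read-back is identity."""
    fmt = _infer_format(path, fmt)
    if fmt == "json":
        payload = {"samples": [
            {
                "sample_id": s.sample_id,
                "animal_id": s.animal_id,
                "site": s.site.value,
                "passage": s.passage,
                "cells": [
                    {
                        "cell_id": c.cell_id,
                        "counts": {k: c.counts[k] for k in CHROMOSOMES},
                        "events": [
                            {
                                "kind": e.kind.value,
                                "participants": list(e.participants),
                                "copies": e.copies,
                                "breakpoint_id": e.breakpoint_id,
                                "uncertain": e.uncertain,
                            }
                            for e in c.events
                        ],
                    }
                    for c in s.cells
                ],
            }
            for s in samples
        ]}
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")
        return
    df = pd.DataFrame(_sets_to_rows(samples), columns=list(KARYOTYPE_COLUMNS))
    df.to_csv(path, sep="\t", index=False)
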