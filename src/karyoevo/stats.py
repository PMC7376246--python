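"""Exact small-sample statistics for derived count tables.

The Fisher exact test is computed by explicit hypergeometric enumeration:
with the table's margins fixed, every table at least as improbable as the
observed one (probability mass rule, with the customary 1 + 1e-7 relative
slack against floating-point ties) contributes to the two-sided p-value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence, Tuple

import numpy as np
from scipy.stats import hypergeom


@dataclass(frozen=True)
class CountTable2x2:
    """Counts (a, b / c, d): rows are groups, columns outcome yes/no."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.total < 1:
            raise ValueError("table must contain at least one observation")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


def fisher_exact_2x2(table: CountTable2x2,
                     alternative: str = "two_sided") -> float:
    """Two-sided Fisher exact p-value by hypergeometric enumeration.

    Margins are held fixed; all tables whose hypergeometric probability is
    at most that of the observed table are summed.  Degenerate margins
    (an all-zero row or column) give p = 1 with a warning.
    """
    if alternative != "two_sided":
        raise ValueError("only the two-sided alternative is supported")
    a, b, c, d = table.a, table.b, table.c, table.d
    r1, r2 = a + b, c + d
    c1 = a + c
    n = table.total
    if r1 == 0 or r2 == 0 or c1 == 0 or (b + d) == 0:
        warnings.warn("degenerate margins: p = 1", stacklevel=2)
        return 1.0
    support = np.arange(max(0, c1 - r2), min(r1, c1) + 1)
    pmf = hypergeom.pmf(support, n, r1, c1)
    p_obs = hypergeom.pmf(a, n, r1, c1)
    p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    return min(p, 1.0)


@dataclass(frozen=True)
class ProportionReport:
    fractions: dict[str, float]
    counts: dict[str, Tuple[int, int]]
    pairwise_p: dict[Tuple[str, str], float]
    adjusted: bool


def _holm(pvals: Sequence[float]) -> list[float]:
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adjusted = [0.0] * m
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * pvals[idx])
        adjusted[idx] = min(1.0, running)
    return adjusted


def proportion_report(groups: Mapping[str, Tuple[int, int]],
                      holm: bool = False) -> ProportionReport:
    """Fractions per group plus all pairwise two-sided Fisher p-values.

    ``groups`` maps a label to (successes, total).  Raw p-values by
    default; Holm step-down adjustment behind the ``holm`` flag.
    """
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    counts: dict[str, Tuple[int, int]] = {}
    fractions: dict[str, float] = {}
    for label, (k, n) in groups.items():
        if n < 1:
            raise ValueError(f"group {label!r} is empty")
        if not 0 <= k <= n:
            raise ValueError(f"group {label!r}: successes out of range")
        counts[label] = (int(k), int(n))
        fractions[label] = k / n
    labels = list(groups)
    pairs = [(labels[i], labels[j])
             for i in range(len(labels)) for j in range(i + 1, len(labels))]
    raw = []
    for g1, g2 in pairs:
        k1, n1 = counts[g1]
        k2, n2 = counts[g2]
        raw.append(fisher_exact_2x2(
            CountTable2x2(k1, n1 - k1, k2, n2 - k2)))
    if holm:
        raw = _holm(raw)
    return ProportionReport(
        fractions=fractions, counts=counts,
        pairwise_p=dict(zip(pairs, raw)), adjusted=holm)
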