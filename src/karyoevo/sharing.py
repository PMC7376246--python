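"""NRT sharing matrix and the inter-lineage sharing Monte-Carlo null.

Because an NRT's breakpoint is essentially unique at the single-nucleotide
level, two metaphases sharing an NRT identity are almost certainly clonally
related.  The sharing matrix counts shared NRT identities per metaphase
pair; the inter-lineage probability

    p = (n_d / n_r) / (n_a - 1)

is estimated by sampling metaphase pairs uniformly at random (n_r = pairs
sharing at least one NRT, n_d = those pairs from different animals, n_a =
number of animals; the 1/(n_a - 1) factor normalizes for an inter-lineage
pair being (n_a - 1) times as likely as an intra-lineage one under uniform
pairing).  An exhaustive enumeration over all pairs is provided as the
exact reference for small cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .model import EventKind, MetaphaseKaryotype


def _nrt_identity_set(cell: MetaphaseKaryotype) -> frozenset:
    return frozenset(e.identity for e in cell.events
                     if e.kind is EventKind.NRT)


@dataclass(frozen=True)
class SharingMatrix:
    """Symmetric integer matrix of shared NRT identities per cell pair."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=int)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "labels", tuple(self.labels))
        if v.shape != (len(self.labels),) * 2:
            raise ValueError("matrix shape does not match labels")
        if (v != v.T).any() or (v < 0).any() or np.diag(v).any():
            raise ValueError("sharing matrix must be symmetric, non-negative, "
                             "zero-diagonal")

    def to_tsv(self, path) -> None:
        import pandas as pd
        pd.DataFrame(self.values, index=list(self.labels),
                     columns=list(self.labels)).to_csv(path, sep="\t")


def build_sharing_matrix(metaphases: Sequence[MetaphaseKaryotype]
                         ) -> SharingMatrix:
    """Number of shared NRT identities for every metaphase pair (diagonal 0)."""
    if len(metaphases) < 2:
        raise ValueError("need at least 2 metaphases")
    sets = [_nrt_identity_set(c) for c in metaphases]
    n = len(sets)
    values = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            k = len(sets[i] & sets[j])
            values[i, j] = values[j, i] = k
    return SharingMatrix(tuple(c.cell_id for c in metaphases), values)


@dataclass(frozen=True)
class SharingEstimate:
    n_pairs_sampled: int
    n_r: int           # pairs sharing >= 1 NRT
    n_d: int           # sharing pairs from different animals
    n_a: int           # number of animals (lineages)
    p: float
    seed: Optional[int]
    defined: bool      # False when no sharing pair was observed

    def __post_init__(self) -> None:
        if not (0 <= self.n_d <= self.n_r <= self.n_pairs_sampled):
            raise ValueError("need 0 <= n_d <= n_r <= n_pairs_sampled")


def _estimate_from_counts(n_r: int, n_d: int, n_a: int, n_pairs: int,
                          seed: Optional[int]) -> SharingEstimate:
    if n_r > 0:
        p = n_d / n_r / (n_a - 1)
        defined = True
    else:
        p, defined = 0.0, False
    return SharingEstimate(n_pairs_sampled=n_pairs, n_r=n_r, n_d=n_d,
                           n_a=n_a, p=p, seed=seed, defined=defined)


def estimate_interlineage_p(
    metaphases: Sequence[MetaphaseKaryotype],
    animal_labels: Sequence[str],
    n_pairs: int = 100_000,
    seed: Optional[int] = None,
) -> SharingEstimate:
    """Monte-Carlo estimate of the inter-lineage NRT sharing probability.

    Unordered metaphase pairs are sampled uniformly with replacement
    (self-pairs excluded); reproducible for a fixed seed.
    """
    n = len(metaphases)
    if n < 2 or len(animal_labels) != n:
        raise ValueError("need >= 2 metaphases with one animal label each")
    animals = [str(a) for a in animal_labels]
    n_a = len(set(animals))
    if n_a < 2:
        raise ValueError("need metaphases from >= 2 animals")
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    sets = [_nrt_identity_set(c) for c in metaphases]
    rng = np.random.default_rng(seed)
    n_r = n_d = 0
    remaining = n_pairs
    while remaining > 0:
        chunk = max(remaining, 1024)
        ii = rng.integers(0, n, size=chunk)
        jj = rng.integers(0, n, size=chunk)
        keep = ii != jj
        ii, jj = ii[keep][:remaining], jj[keep][:remaining]
        for i, j in zip(ii, jj):
            if sets[i] & sets[j]:
                n_r += 1
                if animals[i] != animals[j]:
                    n_d += 1
        remaining -= len(ii)
    return _estimate_from_counts(n_r, n_d, n_a, n_pairs, seed)


def exact_interlineage_p(
    metaphases: Sequence[MetaphaseKaryotype],
    animal_labels: Sequence[str],
) -> SharingEstimate:
    """Exhaustive enumeration over all unordered metaphase pairs."""
    n = len(metaphases)
    if n < 2 or len(animal_labels) != n:
        raise ValueError("need >= 2 metaphases with one animal label each")
    animals = [str(a) for a in animal_labels]
    n_a = len(set(animals))
    if n_a < 2:
        raise ValueError("need metaphases from >= 2 animals")
    sets = [_nrt_identity_set(c) for c in metaphases]
    n_r = n_d = 0
    total = 0
    for i in range(n):
        for j in range(i + 1, n):
            total += 1
            if sets[i] & sets[j]:
                n_r += 1
                if animals[i] != animals[j]:
                    n_d += 1
    return _estimate_from_counts(n_r, n_d, n_a, total, None)


def plot_sharing_heatmap(matrix: SharingMatrix, path) -> None:
    """Save the sharing matrix as a heatmap PNG."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(matrix.values, cmap="Reds", interpolation="nearest")
    ax.set_xticks(range(len(matrix.labels)))
    ax.set_yticks(range(len(matrix.labels)))
    ax.set_xticklabels(matrix.labels, rotation=90, fontsize=5)
    ax.set_yticklabels(matrix.labels, fontsize=5)
    fig.colorbar(im, ax=ax, label="shared NRTs")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
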