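"""Pattern similarity score (PaSS) and genomic distance between profiles.

Two profiles are compared by superimposing their spiddo sets.  Spiddo
correspondence is computed as the minimum-total-Euclidean-displacement
one-to-one assignment (the automated analogue of visually superimposing
dot patterns), and then

    PaSS = 1 - (1/n) * sum_i |p_i - p'_i| / (|p_i| + |p'_i|)
    dG   = 1 - PaSS

with Euclidean vector norms over the matched pairs.  PaSS is 1 when the
two dot sets coincide; dG is symmetric, zero on the diagonal and bounded
in [0, 1], but makes no triangle-inequality claim.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .spiddos import GenomeProfile

__all__ = [
    "SpiddoPairing",
    "DistanceMatrix",
    "match_spiddos",
    "pass_score",
    "genomic_distance",
    "distance_matrix",
    "average_profiles",
]


@dataclass(frozen=True)
class SpiddoPairing:
    """One-to-one spiddo correspondence; ``pairs`` holds (index in A,
    index in B) tuples and n = min(|A|, |B|)."""

    pairs: tuple[tuple[int, int], ...]
    unmatched_a: int
    unmatched_b: int

    @property
    def n(self) -> int:
        return len(self.pairs)


def match_spiddos(a: GenomeProfile, b: GenomeProfile) -> SpiddoPairing:
    """Optimal bipartite assignment between two spiddo sets, minimizing
    the total Euclidean displacement of matched pairs; with unequal sizes
    the extras stay unmatched (recorded, not scored)."""
    if a.n == 0 or b.n == 0:
        raise ValueError("cannot match an empty profile")
    cost = cdist(a.spiddos, b.spiddos)
    rows, cols = linear_sum_assignment(cost)
    pairs = tuple(sorted(zip(map(int, rows), map(int, cols))))
    return SpiddoPairing(pairs, a.n - len(pairs), b.n - len(pairs))


def pass_score(a: GenomeProfile, b: GenomeProfile, pairing: SpiddoPairing) -> float:
    """PaSS over the matched pairs; a pair with both points at the origin
    is a perfect match and contributes zero displacement."""
    if pairing.n == 0:
        raise ValueError("pairing has no matched spiddos")
    ia = np.array([p[0] for p in pairing.pairs])
    ib = np.array([p[1] for p in pairing.pairs])
    if ia.max() >= a.n or ib.max() >= b.n:
        raise ValueError("pairing indices out of range for the given profiles")
    pa = a.spiddos[ia]
    pb = b.spiddos[ib]
    disp = np.linalg.norm(pa - pb, axis=1)
    denom = np.linalg.norm(pa, axis=1) + np.linalg.norm(pb, axis=1)
    terms = np.divide(disp, denom, out=np.zeros_like(disp), where=denom > 0)
    return float(1.0 - terms.mean())


def genomic_distance(a: GenomeProfile, b: GenomeProfile) -> float:
    """dG = 1 - PaSS under the optimal spiddo assignment."""
    return 1.0 - pass_score(a, b, match_spiddos(a, b))


@dataclass
class DistanceMatrix:
    """Symmetric matrix of genomic distances with sample labels."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise ValueError("sample labels must be unique")
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match label count")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any((self.values < 0) | (self.values > 1)):
            raise ValueError("dG values must lie in [0, 1]")

    @property
    def n(self) -> int:
        return len(self.labels)


def average_profiles(replicates: list[GenomeProfile]) -> GenomeProfile:
    """Mean-spiddos mode for replicate gels of the same sample: match
    every replicate to the first one and average matched coordinates,
    mirroring the averaged-spiddos analysis of repeated GP trials."""
    if not replicates:
        raise ValueError("no replicate profiles given")
    first = replicates[0]
    acc = first.spiddos.copy()
    counts = np.ones(first.n)
    for rep in replicates[1:]:
        pairing = match_spiddos(first, rep)
        for i, j in pairing.pairs:
            acc[i] += rep.spiddos[j]
            counts[i] += 1
    return GenomeProfile(
        first.sample_label,
        acc / counts[:, None],
        {**first.metadata, "n_replicates": len(replicates)},
    )


def distance_matrix(profiles: list[GenomeProfile]) -> DistanceMatrix:
    """All pairwise genomic distances; labels must be unique."""
    if len(profiles) < 2:
        raise ValueError("need at least two profiles")
    labels = [p.sample_label for p in profiles]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate sample labels")
    n = len(profiles)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = genomic_distance(profiles[i], profiles[j])
    return DistanceMatrix(labels, d)
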