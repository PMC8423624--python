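"""Normalized breakpoint distances between genomes.

The dissimilarity between two genomes G1 and G2 is the number of gene
adjacencies that exist in G1 but not in G2, normalized to the number of
adjacencies in G1, where G1 is the genome with the smaller adjacency set.
Normalising by the smaller set corrects for assembly fragmentation and
WGD-induced differences in adjacency counts.  Adjacencies flagged missing
(unscorable) in either genome are excluded from numerator and denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from .markers import ABSENT, MISSING, PRESENT, AdjacencySet, CharacterMatrix

__all__ = [
    "DistanceMatrix",
    "normalized_breakpoint_distance",
    "distance_matrix",
    "distances_from_matrix",
]


class EmptyAdjacencyError(ValueError):
    """A genome has no scorable adjacency; the distance is undefined."""


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with taxon labels."""

    taxa: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.taxa)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match taxa")
        if np.max(np.abs(self.values - self.values.T)) > 1e-12:
            raise ValueError("matrix is not symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("diagonal must be zero")
        if self.values.min() < 0:
            raise ValueError("distances must be non-negative")

    def __getitem__(self, pair) -> float:
        i, j = pair
        if isinstance(i, str):
            i = self.taxa.index(i)
        if isinstance(j, str):
            j = self.taxa.index(j)
        return float(self.values[i, j])

    def __len__(self) -> int:
        return len(self.taxa)


def normalized_breakpoint_distance(
    adj_a: AdjacencySet,
    adj_b: AdjacencySet,
    missing: Optional[set] = None,
) -> float:
    """Pairwise normalized breakpoint distance between two adjacency sets.

    ``missing`` is a set of adjacencies to exclude entirely (unscorable in
    either genome, e.g. because of WGD subgenome masking).  When the two sets
    are equal in size the two possible normalisations are averaged.
    """
    a = adj_a.adjacencies
    b = adj_b.adjacencies
    if missing:
        a = a - missing
        b = b - missing
    if not a or not b:
        raise EmptyAdjacencyError(
            f"empty adjacency set for {adj_a.genome if not a else adj_b.genome}"
        )
    if len(a) < len(b):
        return len(a - b) / len(a)
    if len(b) < len(a):
        return len(b - a) / len(b)
    return 0.5 * (len(a - b) / len(a) + len(b - a) / len(b))


def distances_from_matrix(
    matrix: CharacterMatrix, weights: Optional[np.ndarray] = None
) -> np.ndarray:
    """Vectorised all-pairs normalized breakpoint distance over a character
    matrix, with optional per-column multiplicity weights (the bootstrap
    resampling counts).

    For a pair (i, j) the scorable columns are those not missing in either
    species; the smaller genome is the one with fewer (weighted) present
    columns among these.
    """
    present = matrix.states == PRESENT
    usable = matrix.states != MISSING
    w = np.ones(matrix.n_adjacencies) if weights is None else np.asarray(weights, float)
    pw = present * w
    # n_own[i, j]: weighted adjacencies of i scorable in the (i, j) comparison
    n_own = pw @ usable.T
    # diff[i, j]: weighted adjacencies present in i, scorable-and-absent in j
    diff = pw @ (usable & ~present).T
    if np.any(n_own <= 0):
        raise EmptyAdjacencyError(
            "a species has no scorable present adjacency in some pairwise comparison"
        )
    d_fwd = diff / n_own
    dist = np.where(
        n_own < n_own.T,
        d_fwd,
        np.where(n_own > n_own.T, d_fwd.T, 0.5 * (d_fwd + d_fwd.T)),
    )
    np.fill_diagonal(dist, 0.0)
    return dist


def distance_matrix(
    data: Union[CharacterMatrix, Sequence[AdjacencySet]],
) -> DistanceMatrix:
    """All-pairs distance matrix from a character matrix (missing-aware) or a
    list of per-genome adjacency sets."""
    if isinstance(data, CharacterMatrix):
        if len(data.species) < 3:
            raise ValueError("need at least three taxa")
        return DistanceMatrix(taxa=list(data.species), values=distances_from_matrix(data))
    sets = list(data)
    if len(sets) < 3:
        raise ValueError("need at least three taxa")
    n = len(sets)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = normalized_breakpoint_distance(sets[i], sets[j])
    return DistanceMatrix(taxa=[s.genome for s in sets], values=values)
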