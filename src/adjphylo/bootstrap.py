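"""Adjacency bootstrap for distance trees and branch-length contrasts.

The resampling unit is the adjacency column of the character matrix: each
replicate draws the original number of columns with replacement, recomputes
the pairwise normalized breakpoint distances with the multiplicities as
weights, and rebuilds the tree.  Bipartition supports are mapped onto the
full-data reference tree.

A single integer seed controls the whole run; replicate r draws from a
substream keyed on (seed, r), so results do not depend on execution order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .distances import DistanceMatrix, EmptyAdjacencyError, distances_from_matrix
from .markers import CharacterMatrix
from .tree import PhyloTree
from .treebuild import me_tree, nj_tree, upgma_tree

logger = logging.getLogger(__name__)

__all__ = ["BootstrapResult", "BranchContrast", "bootstrap_trees", "branch_contrast", "BUILDERS"]

BUILDERS: dict[str, Callable[[DistanceMatrix], PhyloTree]] = {
    "nj": nj_tree,
    "upgma": upgma_tree,
    "me": me_tree,
}


@dataclass
class BootstrapResult:
    reference_tree: PhyloTree
    replicate_trees: list[PhyloTree]
    supports: dict[frozenset, float]  # split -> percent of replicates
    terminal_lengths: pd.DataFrame    # replicates x leaves
    seed: int
    n_redrawn: int = 0

    @property
    def n_replicates(self) -> int:
        return len(self.replicate_trees)

    def support_of(self, clade: Iterable[str]) -> float:
        """Support of the split putting exactly these taxa on one side."""
        all_leaves = frozenset(self.reference_tree.leaf_names)
        side = frozenset(clade)
        anchor = min(all_leaves)
        if anchor in side:
            side = all_leaves - side
        count = 0
        for rep in self.replicate_trees:
            if side in rep.bipartitions():
                count += 1
        return 100.0 * count / self.n_replicates


@dataclass
class BranchContrast:
    name: str
    estimate: float
    ci_low: float
    ci_high: float
    replicates: np.ndarray = field(repr=False, default=None)


def bootstrap_trees(
    matrix: CharacterMatrix,
    builder: str = "nj",
    n_rep: int = 100,
    seed: int = 0,
    max_redraws: int = 100,
) -> BootstrapResult:
    """Adjacency-column bootstrap.  Replicates whose resample leaves some
    genome without any scorable adjacency are rejected and redrawn (logged).
    """
    if matrix.n_adjacencies < 1:
        raise ValueError("character matrix has no adjacency columns")
    build = BUILDERS[builder]
    reference = build(DistanceMatrix(matrix.species, distances_from_matrix(matrix)))

    n_col = matrix.n_adjacencies
    replicate_trees = []
    lengths = np.zeros((n_rep, len(matrix.species)))
    leaf_order = list(matrix.species)
    n_redrawn = 0
    for r in range(n_rep):
        for attempt in range(max_redraws):
            rng = np.random.default_rng([seed, r, attempt])
            weights = np.bincount(rng.integers(0, n_col, size=n_col), minlength=n_col)
            try:
                dist = distances_from_matrix(matrix, weights=weights.astype(float))
            except EmptyAdjacencyError:
                n_redrawn += 1
                logger.info("replicate %d redrawn (empty adjacency set)", r)
                continue
            break
        else:
            raise EmptyAdjacencyError(
                f"replicate {r}: no valid resample after {max_redraws} attempts"
            )
        tree = build(DistanceMatrix(leaf_order, dist))
        replicate_trees.append(tree)
        for k, name in enumerate(leaf_order):
            lengths[r, k] = tree.terminal_branch_length(name)

    ref_splits = reference.bipartitions()
    counts = {split: 0 for split in ref_splits}
    for tree in replicate_trees:
        for split in tree.bipartitions() & ref_splits:
            counts[split] += 1
    supports = {s: 100.0 * c / n_rep for s, c in counts.items()}
    _annotate_supports(reference, supports)
    return BootstrapResult(
        reference_tree=reference,
        replicate_trees=replicate_trees,
        supports=supports,
        terminal_lengths=pd.DataFrame(lengths, columns=leaf_order),
        seed=seed,
        n_redrawn=n_redrawn,
    )


def _annotate_supports(tree: PhyloTree, supports: dict[frozenset, float]) -> None:
    all_leaves = frozenset(tree.leaf_names)
    anchor = min(all_leaves)
    for node in tree.postorder():
        if node.is_leaf or node is tree.root:
            continue
        side = frozenset(l.name for l in node.leaves())
        if anchor in side:
            side = all_leaves - side
        if side in supports:
            node.support = supports[side]


def branch_contrast(
    bootstrap: BootstrapResult, focal: str, others: Sequence[str], name: str = ""
) -> BranchContrast:
    """Terminal-branch-length contrast: focal minus the mean of the others,
    with a percentile 95% CI over the bootstrap replicates."""
    cols = bootstrap.terminal_lengths.columns
    for leaf in [focal, *others]:
        if leaf not in cols:
            raise ValueError(f"leaf {leaf!r} missing from replicate trees")
    point = bootstrap.reference_tree.terminal_branch_length(focal) - np.mean(
        [bootstrap.reference_tree.terminal_branch_length(o) for o in others]
    )
    reps = (
        bootstrap.terminal_lengths[focal].to_numpy()
        - bootstrap.terminal_lengths[list(others)].to_numpy().mean(axis=1)
    )
    lo, hi = np.percentile(reps, [2.5, 97.5])
    return BranchContrast(
        name=name or f"{focal} vs {'+'.join(others)}",
        estimate=float(point),
        ci_low=float(lo),
        ci_high=float(hi),
        replicates=reps,
    )
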