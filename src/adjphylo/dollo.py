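"""Dollo small parsimony on adjacency characters and the Kishino–Hasegawa
paired-sites test between two fixed topologies.

Under Dollo's assumption a gene adjacency is gained exactly once (distinct
rearrangements essentially never re-create the same adjacency) but can be
lost independently any number of times.  On a rooted tree the minimal
scenario places the single gain at the most recent common ancestor of the
leaves carrying the adjacency, and one loss on each maximal subtree inside
that clade containing observed absences but no presence.  Missing
(unscorable) states never force or block a loss.
"""

from __future__ import annotations

import logging

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
from scipy import stats

from .markers import ABSENT, MISSING, PRESENT, CharacterMatrix
from .tree import Node, PhyloTree

logger = logging.getLogger(__name__)

__all__ = ["DolloResult", "KHResult", "dollo_steps", "compare_scenarios", "kh_test"]

_STATE_OF = {"present": PRESENT, "absent": ABSENT, "missing": MISSING}


def _branch_id(node: Node) -> Union[str, tuple]:
    if node.is_leaf:
        return node.name
    return tuple(sorted(l.name for l in node.leaves()))


def dollo_steps(
    tree: PhyloTree, states: Mapping[str, Union[int, str]]
) -> tuple[int, dict]:
    """Minimal Dollo step count (1 gain + losses) for one character.

    ``states`` maps each leaf name to PRESENT/ABSENT/MISSING (ints or the
    strings "present"/"absent"/"missing").  Returns ``(steps, events)`` where
    events records the gain node and the loss branches (each identified by
    the clade below it).
    """
    coded = {
        leaf: (_STATE_OF[s] if isinstance(s, str) else int(s))
        for leaf, s in states.items()
    }
    present_leaves = [l for l, s in coded.items() if s == PRESENT]
    if not present_leaves:
        raise ValueError("character has no present leaf; filter such characters upstream")
    missing = set(coded) - set(tree.leaf_names)
    if missing:
        raise ValueError(f"states name leaves not in tree: {sorted(missing)}")

    gain = tree.mrca(present_leaves)

    # per-subtree summary below the gain node
    has_present: dict[int, bool] = {}
    has_absent: dict[int, bool] = {}
    for node in gain.postorder():
        if node.is_leaf:
            s = coded.get(node.name, MISSING)
            has_present[id(node)] = s == PRESENT
            has_absent[id(node)] = s == ABSENT
        else:
            has_present[id(node)] = any(has_present[id(c)] for c in node.children)
            has_absent[id(node)] = any(has_absent[id(c)] for c in node.children)

    losses: list = []

    def walk(node: Node) -> None:
        for child in node.children:
            if has_present[id(child)]:
                walk(child)
            elif has_absent[id(child)]:
                losses.append(child)
            # all-missing subtrees are retained at zero cost

    walk(gain)
    events = {
        "gain": _branch_id(gain),
        "losses": [_branch_id(n) for n in losses],
    }
    return 1 + len(losses), events


def dollo_steps_matrix(
    tree: PhyloTree, states: np.ndarray, leaf_rows: Mapping[str, int]
) -> np.ndarray:
    """Vectorised Dollo step counts for many characters at once.

    ``states`` is a (n_species, n_characters) array over
    {ABSENT, PRESENT, MISSING}; ``leaf_rows`` maps each leaf name to its row.
    Columns with no present leaf get step count 0 (callers filter them).

    A branch is a loss branch when its subtree holds no present leaf but at
    least one observed absence, and its parent lies inside the gain clade
    (the parent either is the gain node — the deepest node containing every
    present leaf — or holds some but not all present leaves).
    """
    states = np.asarray(states)
    n_char = states.shape[1]
    nodes = list(tree.postorder())
    index = {id(n): k for k, n in enumerate(nodes)}

    npres = np.zeros((len(nodes), n_char), dtype=np.int32)
    hasabs = np.zeros((len(nodes), n_char), dtype=bool)
    for k, node in enumerate(nodes):
        if node.is_leaf:
            row = states[leaf_rows[node.name]]
            npres[k] = row == PRESENT
            hasabs[k] = row == ABSENT
        else:
            for c in node.children:
                npres[k] += npres[index[id(c)]]
                hasabs[k] |= hasabs[index[id(c)]]

    total = npres[index[id(tree.root)]]
    is_gain = np.zeros((len(nodes), n_char), dtype=bool)
    for k, node in enumerate(nodes):
        g = (npres[k] == total) & (total > 0)
        for c in node.children:
            g &= npres[index[id(c)]] < total
        is_gain[k] = g

    losses = np.zeros(n_char, dtype=np.int64)
    for k, node in enumerate(nodes):
        if node.parent is None:
            continue
        p = index[id(node.parent)]
        parent_in_clade = (npres[p] > 0) & ((npres[p] < total) | is_gain[p])
        losses += (npres[k] == 0) & hasabs[k] & parent_in_clade
    return np.where(total > 0, 1 + losses, 0)


@dataclass
class DolloResult:
    """Per-character Dollo step counts for one candidate topology."""

    tree_id: str
    characters: list
    steps: np.ndarray
    events: list[dict] = field(repr=False, default=None)

    @property
    def total(self) -> int:
        return int(self.steps.sum())


def compare_scenarios(
    matrix: CharacterMatrix,
    tree_a: PhyloTree,
    tree_b: PhyloTree,
    characters: Optional[np.ndarray] = None,
    ids: tuple[str, str] = ("A", "B"),
) -> tuple[DolloResult, DolloResult]:
    """Score the lineage-specific characters on two rooted topologies with
    identical character ordering, enabling a paired test.

    ``characters`` optionally overrides the column selection (boolean mask);
    by default the matrix's lineage-specific flags are used.  Characters with
    no present state among the tree's leaves are dropped (they carry no
    signal for either topology).
    """
    if set(tree_a.leaf_names) != set(tree_b.leaf_names):
        raise ValueError("the two trees have different leaf sets")
    if not set(matrix.species) >= set(tree_a.leaf_names):
        raise ValueError("tree leaves missing from the character matrix")

    mask = matrix.lineage_specific if characters is None else np.asarray(characters)
    sub = matrix.restrict(mask)
    sp_index = {s: i for i, s in enumerate(sub.species)}
    leaf_rows = {leaf: sp_index[leaf] for leaf in tree_a.leaf_names}

    # drop characters with no present state among the tree's leaves
    rows = [leaf_rows[l] for l in tree_a.leaf_names]
    scorable = (sub.states[rows] == PRESENT).any(axis=0)
    n_dropped = int((~scorable).sum())
    if n_dropped:
        logger.info("dropped %d characters absent in all scenario species", n_dropped)
    sub = sub.restrict(scorable)

    results = []
    for tree, tree_id in ((tree_a, ids[0]), (tree_b, ids[1])):
        steps = dollo_steps_matrix(tree, sub.states, leaf_rows)
        results.append(
            DolloResult(
                tree_id=tree_id,
                characters=list(sub.adjacencies),
                steps=steps.astype(int),
            )
        )
    return results[0], results[1]


@dataclass
class KHResult:
    """Paired-sites comparison of two topologies' parsimony scores."""

    n: int
    statistic: float     # T = total(A) - total(B)
    se: float
    z: float
    p_normal: float      # two-sided normal approximation
    p_permutation: float # seeded sign-permutation p
    n_permutations: int
    seed: int

    def summary(self) -> str:
        return (
            f"KH test: T = {self.statistic:+.0f} over {self.n} characters, "
            f"z = {self.z:.3f}, p = {self.p_normal:.4g} "
            f"(sign-permutation p = {self.p_permutation:.4g})"
        )


def kh_test(
    result_a: DolloResult,
    result_b: DolloResult,
    n_perm: int = 10_000,
    seed: int = 0,
) -> KHResult:
    """Kishino–Hasegawa test on paired per-character step differences.

    T = sum(d_i) with d_i = stepsA_i - stepsB_i, SE computed from the
    per-character variance scaled to the sum, z = T/SE, two-sided normal p.
    A nonparametric sign-permutation p (random sign flips of the d_i) is
    reported alongside, as the normal approximation can be liberal when few
    characters discriminate.
    """
    a, b = result_a.steps, result_b.steps
    if len(a) != len(b):
        raise ValueError("step vectors differ in length")
    n = len(a)
    if n < 2:
        raise ValueError("need at least two paired characters")
    d = a.astype(float) - b.astype(float)
    t = float(d.sum())
    se = float(np.sqrt(n / (n - 1) * np.sum((d - d.mean()) ** 2)))
    if se == 0:
        z, p_normal = 0.0, 1.0
    else:
        z = t / se
        p_normal = float(2 * stats.norm.sf(abs(z)))

    nz = d[d != 0]
    if nz.size == 0:
        p_perm = 1.0
    else:
        rng = np.random.default_rng([seed, n_perm])
        signs = rng.integers(0, 2, size=(n_perm, nz.size)) * 2 - 1
        t_perm = signs @ nz
        p_perm = float((1 + np.sum(np.abs(t_perm) >= abs(t))) / (1 + n_perm))

    return KHResult(
        n=n,
        statistic=t,
        se=se,
        z=z,
        p_normal=p_normal,
        p_permutation=p_perm,
        n_permutations=n_perm,
        seed=seed,
    )
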