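"""Chromosome-level orthology enrichment and micro-chromosome fusion calls.

For two genomes, each one-to-one ortholog pair assigns a gene to a
(chromosome-in-A, chromosome-in-B) cell.  A chromosome pair shares
"significantly more orthologs than expected" when the Yates-corrected chi2
test (or an explicit gene-shuffling permutation test) on its 2x2 contingency
table is significant after Bonferroni correction AND the observed shared
count exceeds the independence expectation.  Derived chromosomes
significantly linked to two or more ancestral reference chromosomes are
candidate fusion products; whether the fused ancestors were
micro-chromosomes decides the classification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .io_formats import GeneOrder

logger = logging.getLogger(__name__)

__all__ = [
    "SharingCounts",
    "FusionTest",
    "FusionCall",
    "ortholog_sharing_counts",
    "enrichment_test",
    "call_fusions",
    "one_to_one_pairs",
    "yates_chi2",
]

NO_FUSION = "no_fusion"
MICRO_FUSION = "micro_fusion"
MACRO_MICRO_FUSION = "macro_micro_fusion"


@dataclass
class SharingCounts:
    """Chromosome assignments of the usable ortholog pairs between two genomes
    and the per-chromosome-pair 2x2 contingency tables."""

    species_a: str
    species_b: str
    assignments: list[tuple[str, str]]  # (chromosome in A, chromosome in B) per ortholog
    tables: dict[tuple[str, str], tuple[int, int, int, int]]
    n_excluded_multicopy: int = 0

    @property
    def n_orthologs(self) -> int:
        return len(self.assignments)


@dataclass
class FusionTest:
    species_a: str
    species_b: str
    chrom_a: str
    chrom_b: str
    a: int
    b: int
    c: int
    d: int
    expected: float
    chi2: Optional[float]
    p_raw: float
    p_adj: float
    significant: bool
    mode: str = "chi2_yates"


@dataclass
class FusionCall:
    derived_chromosome: str
    linked_ancestral: list[str]
    classification: str
    n_micro: int = 0
    n_macro: int = 0


def yates_chi2(a: int, b: int, c: int, d: int) -> float:
    """Yates-corrected chi-square statistic of a 2x2 table (1 df)."""
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        raise ZeroDivisionError("zero marginal: test undefined")
    num = max(abs(a * d - b * c) - n / 2.0, 0.0)
    return n * num * num / denom


def ortholog_sharing_counts(
    order_a: GeneOrder,
    order_b: GeneOrder,
    collapse_duplicates: bool = False,
) -> SharingCounts:
    """Per-chromosome-pair ortholog sharing between two genomes.

    Only families with exactly one copy in each genome are used; multi-copy
    families are excluded and counted.  With ``collapse_duplicates``,
    families with up to two copies in genome A (the post-WGD side) and one in
    genome B also contribute, counted once per distinct chromosome pair.
    """
    chroms_a: dict[str, list[str]] = {}
    chroms_b: dict[str, str] = {}
    for chrom, genes in order_a.chromosomes.items():
        for _, fam, _ in genes:
            chroms_a.setdefault(fam, []).append(chrom)
    for chrom, genes in order_b.chromosomes.items():
        for _, fam, _ in genes:
            chroms_b.setdefault(fam, []).append(chrom)

    assignments: list[tuple[str, str]] = []
    excluded = 0
    for fam in sorted(set(chroms_a) & set(chroms_b)):
        ca, cb = chroms_a[fam], chroms_b[fam]
        if len(cb) != 1:
            excluded += 1
            continue
        if len(ca) == 1:
            assignments.append((ca[0], cb[0]))
        elif collapse_duplicates and len(ca) == 2:
            for chrom in sorted(set(ca)):
                assignments.append((chrom, cb[0]))
        else:
            excluded += 1
    if not assignments:
        raise ValueError(
            f"no usable one-to-one ortholog pairs between "
            f"{order_a.genome} and {order_b.genome}"
        )
    if excluded:
        logger.info(
            "%s vs %s: excluded %d multi-copy families",
            order_a.genome, order_b.genome, excluded,
        )

    n = len(assignments)
    count_a: dict[str, int] = {}
    count_b: dict[str, int] = {}
    joint: dict[tuple[str, str], int] = {}
    for ca, cb in assignments:
        count_a[ca] = count_a.get(ca, 0) + 1
        count_b[cb] = count_b.get(cb, 0) + 1
        joint[(ca, cb)] = joint.get((ca, cb), 0) + 1

    tables = {}
    for (ca, cb), a in sorted(joint.items()):
        b = count_a[ca] - a
        c = count_b[cb] - a
        d = n - a - b - c
        tables[(ca, cb)] = (a, b, c, d)
    return SharingCounts(
        species_a=order_a.genome,
        species_b=order_b.genome,
        assignments=assignments,
        tables=tables,
        n_excluded_multicopy=excluded,
    )


def enrichment_test(
    counts: SharingCounts,
    mode: str = "chi2_yates",
    n_perm: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
) -> list[FusionTest]:
    """Test every populated chromosome pair for ortholog-sharing enrichment.

    ``chi2_yates``: Yates-corrected chi-square on the 2x2 table.
    ``permutation``: shuffle the chromosome assignments of genome B's genes
    ``n_perm`` times; empirical p = (1 + #{shared_perm >= shared_obs}) /
    (1 + n_perm).  Both modes Bonferroni-adjust over the pairs actually
    tested, and significance additionally requires observed > expected.
    """
    if mode not in ("chi2_yates", "permutation"):
        raise ValueError(f"unknown mode {mode!r}")
    pairs = sorted(counts.tables)
    n = counts.n_orthologs

    perm_exceed: Optional[dict] = None
    if mode == "permutation":
        perm_exceed = _permutation_exceedances(counts, pairs, n_perm, seed)

    tested: list[FusionTest] = []
    skipped = 0
    for pair in pairs:
        a, b, c, d = counts.tables[pair]
        expected = (a + b) * (a + c) / n
        chi2_val: Optional[float] = None
        if mode == "chi2_yates":
            try:
                chi2_val = yates_chi2(a, b, c, d)
            except ZeroDivisionError:
                skipped += 1
                logger.info("pair %s skipped: zero marginal", pair)
                continue
            p_raw = float(stats.chi2.sf(chi2_val, df=1))
        else:
            p_raw = (1 + perm_exceed[pair]) / (1 + n_perm)
        tested.append(
            FusionTest(
                species_a=counts.species_a,
                species_b=counts.species_b,
                chrom_a=pair[0],
                chrom_b=pair[1],
                a=a, b=b, c=c, d=d,
                expected=expected,
                chi2=chi2_val,
                p_raw=p_raw,
                p_adj=1.0,  # filled below
                significant=False,
                mode=mode,
            )
        )
    m = len(tested)
    logger.info("Bonferroni over %d populated chromosome pairs (%d skipped)", m, skipped)
    for t in tested:
        t.p_adj = min(1.0, t.p_raw * m)
        t.significant = bool(t.p_adj < alpha and t.a > t.expected)
    return tested


def _permutation_exceedances(counts, pairs, n_perm, seed):
    """#{permuted shared count >= observed} per chromosome pair, shuffling
    genome B's chromosome assignments."""
    cats_a = sorted({ca for ca, _ in counts.assignments})
    cats_b = sorted({cb for _, cb in counts.assignments})
    ia = {c: i for i, c in enumerate(cats_a)}
    ib = {c: i for i, c in enumerate(cats_b)}
    xa = np.array([ia[ca] for ca, _ in counts.assignments])
    xb = np.array([ib[cb] for _, cb in counts.assignments])
    n_a, n_b = len(cats_a), len(cats_b)
    obs = np.zeros((n_a, n_b), dtype=int)
    np.add.at(obs, (xa, xb), 1)
    exceed = np.zeros((n_a, n_b), dtype=int)
    rng = np.random.default_rng([seed, len(xa)])
    for _ in range(n_perm):
        perm = rng.permutation(xb)
        cnt = np.zeros((n_a, n_b), dtype=int)
        np.add.at(cnt, (xa, perm), 1)
        exceed += cnt >= obs
    return {(ca, cb): int(exceed[ia[ca], ib[cb]]) for ca, cb in pairs}


def call_fusions(
    tests: Sequence[FusionTest],
    micro_chromosomes: Sequence[str],
    known_reference_chromosomes: Optional[Sequence[str]] = None,
) -> list[FusionCall]:
    """Classify each derived (genome A) chromosome by its significantly
    linked ancestral (genome B) chromosomes.

    A chromosome linked to >=2 ancestors, >=2 of them micro-chromosomes, is a
    micro-chromosome fusion; >=2 ancestors with at least one micro and one
    macro is a macro+micro fusion; anything else is not a fusion call.
    """
    ref_chroms = {t.chrom_b for t in tests}
    if known_reference_chromosomes is not None:
        ref_chroms |= set(known_reference_chromosomes)
    unknown = set(micro_chromosomes) - ref_chroms
    if unknown:
        raise ValueError(f"micro-chromosome list names unknown chromosomes: {sorted(unknown)}")
    micro = set(micro_chromosomes)

    linked: dict[str, set[str]] = {}
    for t in tests:
        linked.setdefault(t.chrom_a, set())
        if t.significant:
            linked[t.chrom_a].add(t.chrom_b)

    calls = []
    for chrom in sorted(linked):
        anc = sorted(linked[chrom])
        n_micro = sum(1 for c in anc if c in micro)
        n_macro = len(anc) - n_micro
        if len(anc) >= 2 and n_micro >= 2:
            cls = MICRO_FUSION
        elif len(anc) >= 2 and n_micro >= 1 and n_macro >= 1:
            cls = MACRO_MICRO_FUSION
        else:
            cls = NO_FUSION
        calls.append(
            FusionCall(
                derived_chromosome=chrom,
                linked_ancestral=anc,
                classification=cls,
                n_micro=n_micro,
                n_macro=n_macro,
            )
        )
    return calls


def one_to_one_pairs(tests: Sequence[FusionTest]) -> list[tuple[str, str]]:
    """Chromosome pairs that are each other's unique significant partner."""
    partners_a: dict[str, set[str]] = {}
    partners_b: dict[str, set[str]] = {}
    for t in tests:
        if t.significant:
            partners_a.setdefault(t.chrom_a, set()).add(t.chrom_b)
            partners_b.setdefault(t.chrom_b, set()).add(t.chrom_a)
    pairs = []
    for ca, bs in sorted(partners_a.items()):
        if len(bs) == 1:
            cb = next(iter(bs))
            if partners_b.get(cb) == {ca}:
                pairs.append((ca, cb))
    return pairs
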