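"""Marker-gene selection, genome reduction, adjacency extraction and the
species x adjacency character matrix.

Marker families are ortholog families usable as gene-order markers across a
set of genomes straddling a whole-genome duplication (WGD): present in every
species, single copy in every unduplicated species, and one or two copies in
every post-WGD species.  A gene adjacency is an unordered pair of distinct
marker families occupying consecutive positions on one chromosome after all
non-marker genes are removed.  Adjacencies are unoriented by default: strand
is ignored in the pair identity (``signed=True`` appends the relative
orientation of the two markers to the pair).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .io_formats import GeneOrder, SpeciesConfig

logger = logging.getLogger(__name__)

__all__ = [
    "ABSENT",
    "PRESENT",
    "MISSING",
    "MarkerSet",
    "AdjacencySet",
    "CharacterMatrix",
    "TgdMask",
    "select_markers",
    "reduce_to_markers",
    "extract_adjacencies",
    "build_character_matrix",
    "marker_coverage",
]

ABSENT, PRESENT, MISSING = 0, 1, 2
_STATE_CHAR = {ABSENT: "A", PRESENT: "P", MISSING: "?"}

# marker classes
ALL_SINGLE = "ALL_SINGLE"  # single copy in every species
DUP_2 = "DUP_2"            # two copies in every duplicated species
DUP_1OR2 = "DUP_1OR2"      # mixed 1/2 copies across duplicated species


@dataclass
class MarkerSet:
    """Selected marker families with their copy-number class."""

    families: list[str]
    classes: dict[str, str]
    copy_counts: pd.DataFrame  # families x species

    def __len__(self) -> int:
        return len(self.families)

    def class_counts(self) -> dict[str, int]:
        counts = {ALL_SINGLE: 0, DUP_1OR2: 0, DUP_2: 0}
        for fam in self.families:
            counts[self.classes[fam]] += 1
        return counts

    def __contains__(self, family: str) -> bool:
        return family in self.classes


@dataclass
class AdjacencySet:
    """The set A(G) of unordered marker-family pairs adjacent in genome G."""

    genome: str
    adjacencies: set[tuple[str, str]]

    def __len__(self) -> int:
        return len(self.adjacencies)


@dataclass
class TgdMask:
    """Subgenome (duplication copy) labels for chromosomes of post-WGD species.

    ``labels[species][chromosome]`` is "copyA", "copyB" or "unassigned".  Used
    to distinguish adjacency loss by rearrangement from apparent loss caused
    by reciprocal deletion of WGD duplicates onto alternative subgenomes.
    """

    labels: dict[str, dict[str, str]]

    def label(self, species: str, chromosome: str) -> str:
        return self.labels.get(species, {}).get(chromosome, "unassigned")


@dataclass
class CharacterMatrix:
    """Adjacency presence/absence/missing states across species.

    ``states`` is an int8 array (n_species, n_adjacencies) over
    {ABSENT, PRESENT, MISSING}.  ``lineage_specific`` flags adjacencies present
    in at least one ingroup species and absent (observed, not missing) in every
    outgroup — the characters informative about post-divergence gains.
    """

    species: list[str]
    adjacencies: list[tuple[str, str]]
    states: np.ndarray
    lineage_specific: np.ndarray = field(default=None)

    def __post_init__(self):
        self.states = np.asarray(self.states, dtype=np.int8)
        if self.states.shape != (len(self.species), len(self.adjacencies)):
            raise ValueError("state matrix shape mismatch")
        if self.lineage_specific is None:
            self.lineage_specific = np.zeros(len(self.adjacencies), dtype=bool)

    @property
    def n_adjacencies(self) -> int:
        return len(self.adjacencies)

    def species_index(self, name: str) -> int:
        return self.species.index(name)

    def presence_set(self, species: str) -> set[tuple[str, str]]:
        idx = self.species_index(species)
        mask = self.states[idx] == PRESENT
        return {adj for adj, m in zip(self.adjacencies, mask) if m}

    def restrict(self, columns: np.ndarray) -> "CharacterMatrix":
        """Sub-matrix over a boolean column mask or index array."""
        cols = np.asarray(columns)
        if cols.dtype == bool:
            cols = np.flatnonzero(cols)
        return CharacterMatrix(
            species=list(self.species),
            adjacencies=[self.adjacencies[i] for i in cols],
            states=self.states[:, cols].copy(),
            lineage_specific=self.lineage_specific[cols].copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        chars = np.vectorize(_STATE_CHAR.get)(self.states)
        df = pd.DataFrame(
            chars.T,
            index=[f"{a}|{b}" for a, b in self.adjacencies],
            columns=self.species,
        )
        df["lineage_specific"] = self.lineage_specific.astype(int)
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="adjacency")

    @classmethod
    def from_tsv(cls, path) -> "CharacterMatrix":
        df = pd.read_csv(path, sep="\t", index_col="adjacency")
        flags = df.pop("lineage_specific").to_numpy(dtype=bool)
        rev = {v: k for k, v in _STATE_CHAR.items()}
        states = np.vectorize(rev.get)(df.to_numpy()).T.astype(np.int8)
        adjacencies = [tuple(name.split("|")) for name in df.index]
        return cls(
            species=list(df.columns),
            adjacencies=adjacencies,
            states=states,
            lineage_specific=flags,
        )


# --------------------------------------------------------------------------


def select_markers(
    gene_orders: Sequence[GeneOrder],
    config: SpeciesConfig,
    min_species_presence: Optional[int] = None,
) -> MarkerSet:
    """Select ortholog families usable as gene-order markers.

    A family qualifies when it is present in all species (or at least
    ``min_species_presence`` of them, if relaxed), has exactly one copy in
    every unduplicated species where present, and one or two copies in every
    duplicated species where present.
    """
    if not config.species:
        raise ValueError("species list is empty")
    by_name = {g.genome: g for g in gene_orders}
    missing = [s for s in config.species if s not in by_name]
    if missing:
        raise ValueError(f"species in config absent from data: {missing}")
    need = min_species_presence if min_species_presence is not None else len(config.species)

    counts = pd.DataFrame(
        {s: pd.Series(by_name[s].family_counts(), dtype="Int64") for s in config.species}
    ).fillna(0).astype(int)

    dup = [s for s in config.species if s in config.duplicated_species]
    undup = [s for s in config.species if s not in config.duplicated_species]

    present = counts > 0
    if min_species_presence is None:
        keep = (
            present.all(axis=1)
            & (counts[undup] == 1).all(axis=1)
            & ((counts[dup] >= 1) & (counts[dup] <= 2)).all(axis=1)
        )
    else:
        # relaxed mode: absences tolerated, but copy numbers must still be
        # legal wherever the family occurs
        keep = (
            (present.sum(axis=1) >= need)
            & (counts[undup] <= 1).all(axis=1)
            & (counts[dup] <= 2).all(axis=1)
        )

    families = sorted(counts.index[keep])
    classes = {}
    for fam in families:
        row = counts.loc[fam]
        if all(row[s] <= 1 for s in config.species):
            classes[fam] = ALL_SINGLE
        elif dup and all(row[s] == 2 for s in dup):
            classes[fam] = DUP_2
        else:
            classes[fam] = DUP_1OR2
    logger.info(
        "selected %d marker families from %d (classes: %s)",
        len(families), len(counts),
        MarkerSet(families, classes, counts.loc[families]).class_counts(),
    )
    return MarkerSet(families=families, classes=classes, copy_counts=counts.loc[families])


def reduce_to_markers(order: GeneOrder, markers: MarkerSet) -> GeneOrder:
    """Drop non-marker genes, preserving relative order and strand; drop
    chromosomes left empty.  Idempotent."""
    chroms = {}
    for chrom, genes in order.chromosomes.items():
        kept = [g for g in genes if g[1] in markers]
        if kept:
            chroms[chrom] = kept
    return GeneOrder(genome=order.genome, chromosomes=chroms)


def extract_adjacencies(order: GeneOrder, signed: bool = False) -> AdjacencySet:
    """Consecutive marker-family pairs per chromosome, as unordered pairs.

    Tandem pairs of the same family (adjacent WGD copies) carry no
    between-family order information and are skipped (counted in the log).
    In a duplicated genome the result is automatically the union over copies:
    an adjacency exists if any copy pair realises it.
    """
    adjacencies: set = set()
    tandem_skipped = 0
    for genes in order.chromosomes.values():
        for (g1, f1, s1), (g2, f2, s2) in zip(genes, genes[1:]):
            if f1 == f2:
                tandem_skipped += 1
                continue
            if signed:
                # orientation is "head-to-tail" relative to the sorted pair
                if f1 < f2:
                    pair = (f1, f2, "same" if s1 == s2 else "opposite")
                else:
                    pair = (f2, f1, "same" if s1 == s2 else "opposite")
            else:
                pair = (f1, f2) if f1 < f2 else (f2, f1)
            adjacencies.add(pair)
    if tandem_skipped:
        logger.info(
            "%s: skipped %d tandem same-family pairs", order.genome, tandem_skipped
        )
    return AdjacencySet(genome=order.genome, adjacencies=adjacencies)


def build_character_matrix(
    adjacency_sets: Sequence[AdjacencySet],
    config: SpeciesConfig,
    tgd_mask: Optional[TgdMask] = None,
    reduced_orders: Optional[Mapping[str, GeneOrder]] = None,
) -> CharacterMatrix:
    """Assemble the species x adjacency state matrix.

    The adjacency universe is the union over species.  With a ``tgd_mask``,
    an absence in a duplicated species is recoded to MISSING when the two
    families have their retained copies exclusively on chromosomes of
    different subgenome labels — their failure to be adjacent can then be
    explained by reciprocal duplicate loss rather than rearrangement, so the
    apparent loss is ignored.  Recoding requires ``reduced_orders`` (marker-
    reduced genomes) to locate each family's retained copies.
    """
    if len(adjacency_sets) < 2:
        raise ValueError("need at least two species")
    by_species = {a.genome: a for a in adjacency_sets}
    species = [s for s in config.species if s in by_species]
    universe = sorted(set().union(*(by_species[s].adjacencies for s in species)))
    index = {adj: i for i, adj in enumerate(universe)}

    states = np.full((len(species), len(universe)), ABSENT, dtype=np.int8)
    for i, sp in enumerate(species):
        for adj in by_species[sp].adjacencies:
            states[i, index[adj]] = PRESENT

    if tgd_mask is not None:
        if reduced_orders is None:
            raise ValueError("TGD masking requires the marker-reduced gene orders")
        for i, sp in enumerate(species):
            if sp not in config.duplicated_species:
                continue
            fam_chroms = reduced_orders[sp].family_chromosomes()
            labels_of = {
                fam: {tgd_mask.label(sp, c) for c in chroms}
                for fam, chroms in fam_chroms.items()
            }
            recoded = 0
            for j, (f1, f2) in enumerate(universe):
                if states[i, j] != ABSENT:
                    continue
                l1 = labels_of.get(f1)
                l2 = labels_of.get(f2)
                if (
                    l1 in ({"copyA"}, {"copyB"})
                    and l2 in ({"copyA"}, {"copyB"})
                    and l1 != l2
                ):
                    states[i, j] = MISSING
                    recoded += 1
            if recoded:
                logger.info("%s: %d absences recoded to missing by TGD mask", sp, recoded)

    ingroup = [s for s in species if s not in config.outgroup_species]
    outgroup = [s for s in species if s in config.outgroup_species]
    ing_idx = [species.index(s) for s in ingroup]
    out_idx = [species.index(s) for s in outgroup]
    present_in_ingroup = (states[ing_idx] == PRESENT).any(axis=0) if ing_idx else np.zeros(len(universe), bool)
    absent_in_outgroups = (states[out_idx] == ABSENT).all(axis=0) if out_idx else np.zeros(len(universe), bool)
    flags = present_in_ingroup & absent_in_outgroups

    return CharacterMatrix(
        species=species, adjacencies=universe, states=states, lineage_specific=flags
    )


def marker_coverage(order: GeneOrder, markers: MarkerSet) -> float:
    """Fraction of the genome spanned by intervals between marker genes.

    Per chromosome, the span from the first to the last marker gene, summed
    and divided by total chromosome length (max end coordinate).  Requires
    coordinate records; returns 0.0 for marker-free genomes.
    """
    if not order.positions:
        raise ValueError(f"{order.genome}: no coordinate records available")
    total_len = 0
    covered = 0
    for chrom, pos_list in order.positions.items():
        total_len += max(p.end for p in pos_list)
        marker_pos = [p for p in pos_list if p.family_id in markers]
        if marker_pos:
            covered += max(p.end for p in marker_pos) - min(p.start for p in marker_pos) + 1
    return covered / total_len if total_len else 0.0
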