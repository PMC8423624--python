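"""Readers and writers for gene coordinate tables, Newick trees and PHYLIP
distance matrices, plus the core in-memory genome representations.

Coordinates are 1-based inclusive, matching common gene-annotation tables.
Only the ordering of start coordinates is used downstream, so the off-by-one
convention cannot affect any result; it is fixed here for round-trip fidelity.
Scaffolds are treated exactly like chromosomes: gene adjacency is never
inferred across sequence boundaries, since assembly fragmentation must break
adjacencies rather than invent them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .tree import PhyloTree, TreeError

__all__ = [
    "GenePosition",
    "GeneOrder",
    "SpeciesConfig",
    "FormatError",
    "GENE_TABLE_COLUMNS",
    "read_gene_positions",
    "write_gene_positions",
    "read_newick",
    "write_newick",
    "read_phylip_distmat",
    "write_phylip_distmat",
    "read_species_config",
    "write_species_config",
]

GENE_TABLE_COLUMNS = (
    "genome",
    "chromosome",
    "start",
    "end",
    "strand",
    "gene_id",
    "family_id",
)


class FormatError(ValueError):
    """Raised for malformed input files; never silently drops rows."""


@dataclass(frozen=True)
class GenePosition:
    """One gene: its location, strand and ortholog-family assignment."""

    genome: str
    chromosome: str
    start: int
    end: int
    strand: str
    gene_id: str
    family_id: str

    def __post_init__(self):
        if self.start > self.end:
            raise FormatError(
                f"gene {self.gene_id!r}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise FormatError(
                f"gene {self.gene_id!r}: unknown strand {self.strand!r}"
            )


@dataclass
class GeneOrder:
    """Ordered, stranded gene list per chromosome for one genome.

    ``chromosomes`` maps chromosome name to a list of
    ``(gene_id, family_id, strand)`` triples ordered by start coordinate.
    ``positions`` optionally retains the full coordinate records.
    """

    genome: str
    chromosomes: dict[str, list[tuple[str, str, str]]]
    positions: dict[str, list[GenePosition]] = field(default_factory=dict)

    def gene_count(self) -> int:
        return sum(len(genes) for genes in self.chromosomes.values())

    def family_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for genes in self.chromosomes.values():
            for _, fam, _ in genes:
                counts[fam] = counts.get(fam, 0) + 1
        return counts

    def family_chromosomes(self) -> dict[str, set[str]]:
        """Chromosomes on which each family has at least one copy."""
        out: dict[str, set[str]] = {}
        for chrom, genes in self.chromosomes.items():
            for _, fam, _ in genes:
                out.setdefault(fam, set()).add(chrom)
        return out


@dataclass
class SpeciesConfig:
    """Which lineages are post-WGD, which are outgroups, and which reference
    chromosomes are ancestral micro-chromosomes."""

    species: list[str]
    duplicated_species: set[str] = field(default_factory=set)
    outgroup_species: set[str] = field(default_factory=set)
    micro_chromosomes: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self):
        unknown = (set(self.duplicated_species) | set(self.outgroup_species)) - set(
            self.species
        )
        if unknown:
            raise FormatError(f"config names unknown species: {sorted(unknown)}")

    @property
    def ingroup_species(self) -> list[str]:
        return [s for s in self.species if s not in self.outgroup_species]

    @property
    def unduplicated_species(self) -> list[str]:
        return [s for s in self.species if s not in self.duplicated_species]


# --------------------------------------------------------------------------
# gene coordinate tables


def read_gene_positions(
    path: Union[str, Path],
    column_map: Optional[Mapping[str, str]] = None,
) -> list[GeneOrder]:
    """Read a 7-column tab-separated gene coordinate table into one GeneOrder
    per genome, genes sorted by (chromosome, start).

    ``column_map`` maps the canonical column names to the names actually used
    in the file, for adapting externally deposited tables.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    missing = [c for c in GENE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    df = df[list(GENE_TABLE_COLUMNS)].copy()
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)

    orders = []
    for genome, sub in df.groupby("genome", sort=True):
        dup = sub["gene_id"][sub["gene_id"].duplicated()]
        if len(dup):
            raise FormatError(
                f"duplicate gene_id {dup.iloc[0]!r} in genome {genome!r}"
            )
        sub = sub.sort_values(["chromosome", "start"], kind="mergesort")
        chroms: dict[str, list[tuple[str, str, str]]] = {}
        positions: dict[str, list[GenePosition]] = {}
        for row in sub.itertuples(index=False):
            pos = GenePosition(*row)  # validates start/end and strand
            chroms.setdefault(pos.chromosome, []).append(
                (pos.gene_id, pos.family_id, pos.strand)
            )
            positions.setdefault(pos.chromosome, []).append(pos)
        orders.append(GeneOrder(genome=str(genome), chromosomes=chroms, positions=positions))
    return orders


def write_gene_positions(orders: Sequence[GeneOrder], path: Union[str, Path]) -> None:
    rows = []
    for order in orders:
        for chrom, genes in order.chromosomes.items():
            stored = order.positions.get(chrom)
            for i, (gene_id, family_id, strand) in enumerate(genes):
                if stored is not None:
                    p = stored[i]
                    start, end = p.start, p.end
                else:
                    # synthesise well-ordered coordinates: 1 kb genes, 100 bp gaps
                    start = 1 + i * 1100
                    end = start + 999
                rows.append(
                    (order.genome, chrom, start, end, strand, gene_id, family_id)
                )
    pd.DataFrame(rows, columns=list(GENE_TABLE_COLUMNS)).to_csv(
        path, sep="\t", index=False
    )


# --------------------------------------------------------------------------
# Newick


def read_newick(path: Union[str, Path]) -> PhyloTree:
    text = Path(path).read_text()
    return PhyloTree.from_newick(text)


def write_newick(tree: PhyloTree, path: Union[str, Path], include_supports: bool = False) -> None:
    Path(path).write_text(tree.to_newick(include_supports=include_supports) + "\n")


# --------------------------------------------------------------------------
# PHYLIP distance matrices
#
# Relaxed dialect: full-length whitespace-free taxon names, whitespace
# separated values, square matrix.  `strict=True` truncates names to the
# traditional 10 characters for interoperability with classic programs.


def write_phylip_distmat(
    matrix: np.ndarray,
    taxa: Sequence[str],
    path: Union[str, Path],
    strict: bool = False,
) -> None:
    matrix = np.asarray(matrix, dtype=float)
    n = len(taxa)
    if matrix.shape != (n, n):
        raise FormatError(f"matrix shape {matrix.shape} does not match {n} taxa")
    if np.max(np.abs(matrix - matrix.T)) > 1e-9:
        raise FormatError("distance matrix is not symmetric")
    with open(path, "w") as fh:
        fh.write(f"{n}\n")
        for i, name in enumerate(taxa):
            label = f"{name[:10]:<10}" if strict else name
            vals = " ".join(f"{matrix[i, j]:.6f}" for j in range(n))
            fh.write(f"{label}  {vals}\n")


def read_phylip_distmat(path: Union[str, Path]) -> tuple[np.ndarray, list[str]]:
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not lines:
        raise FormatError("empty distance matrix file")
    try:
        n = int(lines[0].split()[0])
    except ValueError as exc:
        raise FormatError("first line must be the taxon count") from exc
    if len(lines) - 1 != n:
        raise FormatError(f"expected {n} matrix rows, found {len(lines) - 1}")
    taxa, rows = [], []
    for ln in lines[1:]:
        parts = ln.split()
        if len(parts) != n + 1:
            raise FormatError(f"row {parts[0]!r}: expected {n} values")
        taxa.append(parts[0])
        rows.append([float(x) for x in parts[1:]])
    matrix = np.array(rows)
    if np.max(np.abs(matrix - matrix.T)) > 1e-9:
        raise FormatError("distance matrix is not symmetric")
    return matrix, taxa


# --------------------------------------------------------------------------
# species configuration (YAML)


def read_species_config(path: Union[str, Path]) -> SpeciesConfig:
    data = yaml.safe_load(Path(path).read_text())
    return SpeciesConfig(
        species=list(data["species"]),
        duplicated_species=set(data.get("duplicated_species", [])),
        outgroup_species=set(data.get("outgroup_species", [])),
        micro_chromosomes={
            k: list(v) for k, v in (data.get("micro_chromosomes") or {}).items()
        },
    )


def write_species_config(config: SpeciesConfig, path: Union[str, Path]) -> None:
    data = {
        "species": list(config.species),
        "duplicated_species": sorted(config.duplicated_species),
        "outgroup_species": sorted(config.outgroup_species),
        "micro_chromosomes": {
            k: list(v) for k, v in config.micro_chromosomes.items()
        },
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
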