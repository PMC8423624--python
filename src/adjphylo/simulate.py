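"""Genome rearrangement simulator: evolves gene orders along a known tree.

The ancestor is a set of chromosomes of sequential genes (family = ancestral
gene identity, so the emitted ortholog table is exact).  Along each branch,
event counts per type are Poisson in (rate x branch length) and applied in
random order:

* inversion        — reverse a uniformly chosen segment, flipping strands
* translocation    — reciprocal exchange of terminal segments of two chromosomes
* fusion           — concatenate two chromosomes in a random relative orientation
* fission          — split a chromosome at a uniform internal breakpoint
* transposition    — excise a segment and reinsert it elsewhere, random orientation

An optional whole-genome duplication (WGD) at a named internal node
duplicates every chromosome; each gene then independently retains both
copies with probability ``p_retain``, otherwise one uniformly chosen copy is
deleted.  Those reciprocal deletions are what create WGD-specific apparent
adjacency losses in the descendants.

Every event is recorded with its concrete operands, so replaying the log
from the ancestor reproduces each tip genome exactly.
"""

from __future__ import annotations

import copy as _copy
import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .io_formats import GeneOrder, GenePosition, SpeciesConfig
from .tree import PhyloTree

__all__ = [
    "Gene",
    "SimParams",
    "EventLog",
    "SimResult",
    "simulate_evolution",
    "replay",
    "make_fixture",
    "apply_inversion",
    "apply_fusion",
    "FIXTURE_NAMES",
]

GENE_LENGTH = 1000  # bp per gene in synthesised coordinates
GENE_GAP = 100


@dataclass(frozen=True)
class Gene:
    uid: str      # unique within the genome
    family: str   # ancestral gene identity = ortholog family
    strand: int   # +1 / -1


Genome = dict  # chromosome name -> list[Gene]


@dataclass
class SimParams:
    """Rearrangement rates (events per unit branch length) and ancestor spec."""

    chromosome_sizes: dict[str, int]
    inversion: float = 0.0
    translocation: float = 0.0
    fusion: float = 0.0
    fission: float = 0.0
    transposition: float = 0.0
    wgd_node: Optional[str] = None
    p_retain: float = 0.0
    micro_chromosomes: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self):
        for rate in (self.inversion, self.translocation, self.fusion,
                     self.fission, self.transposition):
            if rate < 0:
                raise ValueError("rates must be non-negative")
        if not 0.0 <= self.p_retain <= 1.0:
            raise ValueError("p_retain must lie in [0, 1]")
        if any(n < 1 for n in self.chromosome_sizes.values()):
            raise ValueError("every ancestral chromosome needs at least one gene")


@dataclass
class EventLog:
    events: list[dict] = field(default_factory=list)

    def add(self, branch: str, etype: str, **operands) -> None:
        self.events.append({"branch": branch, "type": etype, **operands})

    def on_branch(self, branch: str) -> list[dict]:
        return [e for e in self.events if e["branch"] == branch]

    def count(self, etype: Optional[str] = None) -> int:
        return sum(1 for e in self.events if etype is None or e["type"] == etype)

    def to_json(self) -> str:
        return json.dumps(self.events, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "EventLog":
        return cls(events=json.loads(text))


# --------------------------------------------------------------------------
# event primitives (pure genome -> genome operations, also used by replay)


def apply_inversion(genome: Genome, chrom: str, i: int, j: int) -> None:
    genes = genome[chrom]
    genome[chrom] = (
        genes[:i]
        + [Gene(g.uid, g.family, -g.strand) for g in reversed(genes[i : j + 1])]
        + genes[j + 1 :]
    )


def apply_translocation(genome: Genome, chrom1: str, k1: int, chrom2: str, k2: int) -> None:
    g1, g2 = genome[chrom1], genome[chrom2]
    genome[chrom1] = g1[:k1] + g2[k2:]
    genome[chrom2] = g2[:k2] + g1[k1:]


def apply_fusion(genome: Genome, chrom1: str, chrom2: str, orient2: int, new_name: str) -> None:
    g2 = genome.pop(chrom2)
    if orient2 < 0:
        g2 = [Gene(g.uid, g.family, -g.strand) for g in reversed(g2)]
    genome[new_name] = genome.pop(chrom1) + g2


def apply_fission(genome: Genome, chrom: str, k: int, name1: str, name2: str) -> None:
    genes = genome.pop(chrom)
    genome[name1] = genes[:k]
    genome[name2] = genes[k:]


def apply_transposition(
    genome: Genome, src: str, i: int, j: int, dst: str, k: int, orient: int
) -> None:
    segment = genome[src][i : j + 1]
    genome[src] = genome[src][:i] + genome[src][j + 1 :]
    if orient < 0:
        segment = [Gene(g.uid, g.family, -g.strand) for g in reversed(segment)]
    genome[dst] = genome[dst][:k] + segment + genome[dst][k:]


def apply_wgd(genome: Genome, losses: dict[str, str]) -> None:
    """Duplicate every chromosome into _A/_B copies, then delete the copies
    listed in ``losses`` (uid -> copy suffix kept)."""
    doubled: Genome = {}
    for chrom, genes in genome.items():
        for suffix in ("_A", "_B"):
            doubled[chrom + suffix] = [
                Gene(g.uid + suffix, g.family, g.strand) for g in genes
            ]
    for chrom in doubled:
        suffix = chrom[-2:]
        doubled[chrom] = [
            g
            for g in doubled[chrom]
            if g.uid[:-2] not in losses or losses[g.uid[:-2]] == suffix
        ]
    genome.clear()
    genome.update({c: g for c, g in doubled.items() if g})


_APPLIERS = {
    "inversion": lambda g, e: apply_inversion(g, e["chrom"], e["i"], e["j"]),
    "translocation": lambda g, e: apply_translocation(g, e["chrom1"], e["k1"], e["chrom2"], e["k2"]),
    "fusion": lambda g, e: apply_fusion(g, e["chrom1"], e["chrom2"], e["orient2"], e["new_name"]),
    "fission": lambda g, e: apply_fission(g, e["chrom"], e["k"], e["name1"], e["name2"]),
    "transposition": lambda g, e: apply_transposition(g, e["src"], e["i"], e["j"], e["dst"], e["k"], e["orient"]),
    "wgd": lambda g, e: apply_wgd(g, e["losses"]),
}


def _prune_empty(genome: Genome) -> None:
    for chrom in [c for c, genes in genome.items() if not genes]:
        del genome[chrom]


# --------------------------------------------------------------------------


def make_ancestor(chromosome_sizes: dict[str, int]) -> Genome:
    genome: Genome = {}
    counter = 0
    for chrom, size in chromosome_sizes.items():
        genome[chrom] = [
            Gene(uid=f"g{counter + k}", family=f"g{counter + k}", strand=1)
            for k in range(size)
        ]
        counter += size
    return genome


def genome_to_order(name: str, genome: Genome) -> GeneOrder:
    """Emit a GeneOrder with synthesised coordinates: 1 kb genes, 100 bp gaps."""
    chromosomes = {}
    positions = {}
    for chrom in sorted(genome):
        triples, pos_list = [], []
        for k, gene in enumerate(genome[chrom]):
            strand = "+" if gene.strand > 0 else "-"
            start = 1 + k * (GENE_LENGTH + GENE_GAP)
            triples.append((gene.uid, gene.family, strand))
            pos_list.append(
                GenePosition(
                    genome=name, chromosome=chrom, start=start,
                    end=start + GENE_LENGTH - 1, strand=strand,
                    gene_id=gene.uid, family_id=gene.family,
                )
            )
        chromosomes[chrom] = triples
        positions[chrom] = pos_list
    return GeneOrder(genome=name, chromosomes=chromosomes, positions=positions)


@dataclass
class SimResult:
    gene_orders: list[GeneOrder]
    tree: PhyloTree
    event_log: EventLog
    ancestor: Genome
    params: SimParams
    node_genomes: dict[str, Genome] = field(default_factory=dict, repr=False)


def _internal_node_names(tree: PhyloTree) -> dict[int, str]:
    """Stable names for every node: leaves keep their labels, unnamed internal
    nodes get preorder indices."""
    names = {}
    counter = 0
    for node in tree.preorder():
        if node.is_leaf:
            names[id(node)] = node.name
        elif node.name:
            names[id(node)] = node.name
        else:
            names[id(node)] = f"node{counter}"
        counter += 1
    return names


def simulate_evolution(tree: PhyloTree, params: SimParams) -> SimResult:
    """Evolve the ancestral genome along the tree; returns tip gene orders
    (with synthesised coordinates), the event log and per-node genomes."""
    rng = np.random.default_rng(params.seed)
    names = _internal_node_names(tree)
    if params.wgd_node is not None and params.wgd_node not in names.values():
        raise ValueError(f"wgd_node {params.wgd_node!r} not a node of the tree")

    log = EventLog()
    ancestor = make_ancestor(params.chromosome_sizes)
    node_genomes: dict[str, Genome] = {}
    fresh_names = iter(f"der{k}" for k in range(10_000_000))

    def evolve(node, genome: Genome) -> None:
        label = names[id(node)]
        if node.parent is not None:
            length = node.length if node.length is not None else 0.0
            if length < 0:
                raise ValueError("branch lengths must be positive")
            _evolve_branch(genome, label, length, params, rng, log, fresh_names)
        if params.wgd_node == label:
            _do_wgd(genome, label, params, rng, log)
        node_genomes[label] = genome
        for child in node.children:
            # genes are immutable and event primitives rebuild the per-
            # chromosome lists, so a shallow copy isolates each lineage
            evolve(child, {c: list(g) for c, g in genome.items()})

    evolve(tree.root, {c: list(g) for c, g in ancestor.items()})
    tips = [genome_to_order(leaf, node_genomes[leaf]) for leaf in tree.leaf_names]
    return SimResult(
        gene_orders=tips,
        tree=tree,
        event_log=log,
        ancestor=ancestor,
        params=params,
        node_genomes=node_genomes,
    )


def _evolve_branch(genome, label, length, params, rng, log, fresh_names) -> None:
    kinds = []
    for etype, rate in (
        ("inversion", params.inversion),
        ("translocation", params.translocation),
        ("fusion", params.fusion),
        ("fission", params.fission),
        ("transposition", params.transposition),
    ):
        kinds.extend([etype] * rng.poisson(rate * length))
    rng.shuffle(kinds)
    for etype in kinds:
        _apply_random_event(genome, etype, label, rng, log, fresh_names)
        _prune_empty(genome)


def _pick_chromosome(genome, rng, min_genes=1, exclude=()):
    eligible = sorted(
        c for c, genes in genome.items() if len(genes) >= min_genes and c not in exclude
    )
    if not eligible:
        return None
    weights = np.array([len(genome[c]) for c in eligible], dtype=float)
    return eligible[rng.choice(len(eligible), p=weights / weights.sum())]


def _apply_random_event(genome, etype, label, rng, log, fresh_names) -> None:
    if etype == "inversion":
        chrom = _pick_chromosome(genome, rng, min_genes=2)
        if chrom is None:
            log.add(label, "skipped", reason="no chromosome with >=2 genes for inversion")
            return
        n = len(genome[chrom])
        i, j = sorted(rng.choice(n, size=2, replace=False))
        apply_inversion(genome, chrom, int(i), int(j))
        log.add(label, "inversion", chrom=chrom, i=int(i), j=int(j))
    elif etype == "translocation":
        if len(genome) < 2:
            log.add(label, "skipped", reason="translocation needs two chromosomes")
            return
        c1, c2 = rng.choice(sorted(genome), size=2, replace=False)
        k1 = int(rng.integers(1, len(genome[c1]) + 1))
        k2 = int(rng.integers(0, len(genome[c2])))
        apply_translocation(genome, str(c1), k1, str(c2), k2)
        log.add(label, "translocation", chrom1=str(c1), k1=k1, chrom2=str(c2), k2=k2)
    elif etype == "fusion":
        if len(genome) < 2:
            log.add(label, "skipped", reason="fusion needs two chromosomes")
            return
        c1, c2 = rng.choice(sorted(genome), size=2, replace=False)
        orient = int(rng.choice([1, -1]))
        new_name = next(fresh_names)
        apply_fusion(genome, str(c1), str(c2), orient, new_name)
        log.add(label, "fusion", chrom1=str(c1), chrom2=str(c2), orient2=orient, new_name=new_name)
    elif etype == "fission":
        chrom = _pick_chromosome(genome, rng, min_genes=2)
        if chrom is None:
            log.add(label, "skipped", reason="no chromosome with >=2 genes for fission")
            return
        k = int(rng.integers(1, len(genome[chrom])))
        n1, n2 = next(fresh_names), next(fresh_names)
        apply_fission(genome, chrom, k, n1, n2)
        log.add(label, "fission", chrom=chrom, k=k, name1=n1, name2=n2)
    elif etype == "transposition":
        src = _pick_chromosome(genome, rng, min_genes=2)
        if src is None:
            log.add(label, "skipped", reason="no chromosome with >=2 genes for transposition")
            return
        n = len(genome[src])
        i, j = sorted(rng.choice(n, size=2, replace=False))
        if j - i + 1 == n and len(genome) == 1:
            j = i  # keep at least one gene outside the moved segment
        dst_options = sorted(c for c in genome if c != src or j - i + 1 < len(genome[c]))
        dst = str(rng.choice(dst_options))
        if dst == src:
            remaining = n - (j - i + 1)
            k = int(rng.integers(0, remaining + 1))
        else:
            k = int(rng.integers(0, len(genome[dst]) + 1))
        orient = int(rng.choice([1, -1]))
        apply_transposition(genome, src, int(i), int(j), dst, k, orient)
        log.add(label, "transposition", src=src, i=int(i), j=int(j), dst=dst, k=k, orient=orient)
    else:  # pragma: no cover
        raise ValueError(f"unknown event type {etype!r}")


def _do_wgd(genome, label, params, rng, log) -> None:
    losses: dict[str, str] = {}
    for chrom in sorted(genome):
        for gene in genome[chrom]:
            if rng.random() >= params.p_retain:
                losses[gene.uid] = "_A" if rng.random() < 0.5 else "_B"
    apply_wgd(genome, losses)
    log.add(label, "wgd", losses=losses)


def replay(ancestor: Genome, log: EventLog, branches: Sequence[str]) -> Genome:
    """Re-apply the logged events of a root-to-tip branch sequence to the
    ancestor; reproduces the tip genome exactly."""
    genome = {c: list(g) for c, g in ancestor.items()}
    for branch in branches:
        for event in log.on_branch(branch):
            if event["type"] == "skipped":
                continue
            _APPLIERS[event["type"]](genome, event)
            _prune_empty(genome)
    return genome


# --------------------------------------------------------------------------
# bundled fixtures

FIXTURE_NAMES = ("mini4", "holostei14", "fusion_karyotype")

# sha256 over the tip gene tables at each fixture's default seed; regenerating
# a fixture must reproduce these bit-for-bit
FIXTURE_DIGESTS = {
    "mini4": "9fb4ef524aa3a374ac89448ce2475317d1d38b7fdd9a5f946b2ea05801aa2a60",
    "holostei14": "08aac7c1d1e68c226663710a075354aae14e6e564160bb540783bcf34f0cd869",
    "fusion_karyotype": "033097fc27b01315bdbce021a4ea05e8871977fb35832063e6a3806c74955ad5",
}


def fixture_digest(fixture: "Fixture") -> str:
    """Deterministic digest of a fixture's tip gene orders."""
    import hashlib

    h = hashlib.sha256()
    for order in fixture.gene_orders:
        h.update(order.genome.encode())
        for chrom in sorted(order.chromosomes):
            h.update(chrom.encode())
            for gene in order.chromosomes[chrom]:
                h.update("|".join(gene).encode())
    return h.hexdigest()


@dataclass
class Fixture:
    name: str
    gene_orders: list[GeneOrder]
    species_config: SpeciesConfig
    true_tree: PhyloTree
    event_log: EventLog
    params: SimParams
    ancestor: Genome
    alternative_tree: Optional[PhyloTree] = None
    scripted_fusions: list[dict] = field(default_factory=list)


# Unrooted-equivalent truth and its nearest-neighbour alternative around the
# neopterygian-analog node: the alternative breaks the (HolA, HolB) sister
# pair by swapping HolB with the teleost clade.
HOLOSTEI14_NEWICK = (
    "((Out1:0.25,Out2:0.25)OutAnc:0.2,"
    "((HolA:0.08,HolB:0.08)HolAnc:0.12,"
    "(((Tel1:0.10,Tel2:0.10):0.04,(Tel3:0.10,Tel4:0.10):0.04):0.06,"
    "((Tel5:0.10,Tel6:0.10):0.04,((Tel7:0.10,Tel8:0.10):0.04,"
    "(Tel9:0.10,Tel10:0.10):0.04):0.03):0.06)TelAnc:0.18)NeoAnc:0.2)root;"
)
HOLOSTEI14_ALT_NEWICK = (
    "((Out1:0.25,Out2:0.25)OutAnc:0.2,"
    "((HolA:0.08,(((Tel1:0.10,Tel2:0.10):0.04,(Tel3:0.10,Tel4:0.10):0.04):0.06,"
    "((Tel5:0.10,Tel6:0.10):0.04,((Tel7:0.10,Tel8:0.10):0.04,"
    "(Tel9:0.10,Tel10:0.10):0.04):0.03):0.06)TelAnc:0.12)HalAnc:0.12,"
    "HolB:0.18)NeoAnc:0.2)root;"
)

MINI4_NEWICK = (
    "(Out:0.3,((A:0.1,B:0.1)ab:0.1,(C:0.1,D:0.1)cd:0.1)ingroup:0.2)root;"
)


def _holostei14_params(seed: int) -> SimParams:
    sizes = {f"mac{i}": 740 for i in range(1, 7)}
    sizes.update({f"mic{i}": 70 for i in range(1, 9)})
    return SimParams(
        chromosome_sizes=sizes,
        inversion=1400.0,
        translocation=45.0,
        fusion=1.5,
        fission=1.5,
        transposition=140.0,
        wgd_node="TelAnc",
        p_retain=0.2,
        micro_chromosomes=tuple(f"mic{i}" for i in range(1, 9)),
        seed=seed,
    )


def make_fixture(name: str, seed: Optional[int] = None) -> Fixture:
    """Deterministic bundled datasets exercising the whole pipeline.

    * ``mini4``            — 4 ingroup taxa + 1 outgroup, 200 genes: fast smoke data
    * ``holostei14``       — 14 taxa emulating the study design: 2 outgroups,
      2 slow 'holostean' sisters, 10 post-WGD taxa, ancestor of 6 macro- and
      8 micro-chromosomes, ~5,000 genes
    * ``fusion_karyotype`` — two-species pair in which the derived genome
      carries 3 scripted micro-chromosome fusions
    """
    if name == "mini4":
        seed = 20_260_101 if seed is None else seed
        tree = PhyloTree.from_newick(MINI4_NEWICK)
        params = SimParams(
            chromosome_sizes={"chr1": 100, "chr2": 100},
            inversion=250.0, translocation=10.0, transposition=25.0,
            seed=seed,
        )
        sim = simulate_evolution(tree, params)
        config = SpeciesConfig(
            species=["Out", "A", "B", "C", "D"], outgroup_species={"Out"}
        )
        return Fixture(
            name=name, gene_orders=sim.gene_orders, species_config=config,
            true_tree=tree, event_log=sim.event_log, params=params,
            ancestor=sim.ancestor,
        )

    if name == "holostei14":
        seed = 20_260_102 if seed is None else seed
        tree = PhyloTree.from_newick(HOLOSTEI14_NEWICK)
        params = _holostei14_params(seed)
        sim = simulate_evolution(tree, params)
        config = SpeciesConfig(
            species=[
                "Out1", "Out2", "HolA", "HolB",
                *[f"Tel{i}" for i in range(1, 11)],
            ],
            outgroup_species={"Out1", "Out2"},
            duplicated_species={f"Tel{i}" for i in range(1, 11)},
            micro_chromosomes={"HolA": [f"mic{i}" for i in range(1, 9)]},
        )
        return Fixture(
            name=name, gene_orders=sim.gene_orders, species_config=config,
            true_tree=tree, event_log=sim.event_log, params=params,
            ancestor=sim.ancestor,
            alternative_tree=PhyloTree.from_newick(HOLOSTEI14_ALT_NEWICK),
        )

    if name == "fusion_karyotype":
        seed = 20_260_103 if seed is None else seed
        return _fusion_karyotype(seed)

    raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")


def _fusion_karyotype(seed: int) -> Fixture:
    """Reference genome close to the ancestor; derived genome with exactly
    three scripted micro-chromosome fusions, plus intra-chromosomal
    inversions on both lineages."""
    rng = np.random.default_rng(seed)
    sizes = {f"mac{i}": 120 for i in range(1, 5)}
    sizes.update({f"mic{i}": 55 for i in range(1, 7)})
    micro = tuple(f"mic{i}" for i in range(1, 7))
    params = SimParams(chromosome_sizes=sizes, inversion=0.0, seed=seed,
                       micro_chromosomes=micro)
    ancestor = make_ancestor(sizes)
    log = EventLog()

    def inversions(genome, branch, count):
        for _ in range(count):
            chrom = _pick_chromosome(genome, rng, min_genes=2)
            n = len(genome[chrom])
            i, j = sorted(rng.choice(n, size=2, replace=False))
            apply_inversion(genome, chrom, int(i), int(j))
            log.add(branch, "inversion", chrom=chrom, i=int(i), j=int(j))

    reference = _copy.deepcopy(ancestor)
    inversions(reference, "RefSp", 10)

    derived = _copy.deepcopy(ancestor)
    scripted = []
    for idx, (m1, m2) in enumerate((("mic1", "mic2"), ("mic3", "mic4"), ("mic5", "mic6"))):
        orient = int(rng.choice([1, -1]))
        new_name = f"fus{idx + 1}"
        apply_fusion(derived, m1, m2, orient, new_name)
        log.add("DerSp", "fusion", chrom1=m1, chrom2=m2, orient2=orient, new_name=new_name)
        scripted.append({"derived": new_name, "ancestral": [m1, m2]})
    inversions(derived, "DerSp", 10)

    tree = PhyloTree.from_newick("(RefSp:0.1,DerSp:0.1)root;")
    config = SpeciesConfig(
        species=["RefSp", "DerSp"],
        micro_chromosomes={"RefSp": list(micro)},
    )
    return Fixture(
        name="fusion_karyotype",
        gene_orders=[genome_to_order("RefSp", reference), genome_to_order("DerSp", derived)],
        species_config=config,
        true_tree=tree,
        event_log=log,
        params=params,
        ancestor=ancestor,
        scripted_fusions=scripted,
    )
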