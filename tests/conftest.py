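"""Shared fixtures: simulated datasets and pipeline helpers.

The 20-seed 14-taxon simulations are expensive, so they are built once per
session and shared between the topology-recovery and scenario-discrimination
tests and anything else that needs realistic data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

import adjphylo as ap
from adjphylo.simulate import Fixture, make_fixture
from adjphylo.tree import Node, PhyloTree

N_SEEDS = 20


@dataclass
class PipelineRun:
    fixture: Fixture
    markers: ap.MarkerSet
    matrix: ap.CharacterMatrix
    distances: ap.DistanceMatrix


def run_pipeline(fixture: Fixture) -> PipelineRun:
    cfg = fixture.species_config
    markers = ap.select_markers(fixture.gene_orders, cfg)
    reduced = {o.genome: ap.reduce_to_markers(o, markers) for o in fixture.gene_orders}
    sets = [ap.extract_adjacencies(reduced[s]) for s in cfg.species]
    matrix = ap.build_character_matrix(sets, cfg)
    return PipelineRun(
        fixture=fixture,
        markers=markers,
        matrix=matrix,
        distances=ap.distance_matrix(matrix),
    )


@pytest.fixture(scope="session")
def mini4_run() -> PipelineRun:
    return run_pipeline(make_fixture("mini4"))


@pytest.fixture(scope="session")
def holostei_runs() -> list[PipelineRun]:
    """One pipeline run of the 14-taxon fixture per seed."""
    return [run_pipeline(make_fixture("holostei14", seed=seed)) for seed in range(N_SEEDS)]


@pytest.fixture(scope="session")
def holostei_first(holostei_runs) -> PipelineRun:
    return holostei_runs[0]


def random_binary_tree(rng: np.random.Generator, n_taxa: int) -> PhyloTree:
    """Random unrooted binary topology (trifurcating root) with branch
    lengths bounded away from zero, so it is uniquely recoverable from its
    additive distances."""
    nodes = [Node(name=f"T{i}") for i in range(n_taxa)]
    for node in nodes:
        node.length = rng.uniform(0.02, 0.1)
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = Node(length=rng.uniform(0.02, 0.1))
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [parent]
    root = Node()
    for node in nodes:
        root.add_child(node)
    return PhyloTree(root)
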