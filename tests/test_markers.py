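import numpy as np
import pytest

from adjphylo.io_formats import GeneOrder, SpeciesConfig
from adjphylo.markers import (
    ABSENT,
    MISSING,
    PRESENT,
    CharacterMatrix,
    TgdMask,
    build_character_matrix,
    extract_adjacencies,
    marker_coverage,
    reduce_to_markers,
    select_markers,
)


def order_from(genome, chroms):
    """chroms: {chrom: [(family, strand), ...]}; gene ids generated."""
    return GeneOrder(
        genome=genome,
        chromosomes={
            c: [(f"{genome}.{c}.{i}", fam, strand) for i, (fam, strand) in enumerate(genes)]
            for c, genes in chroms.items()
        },
    )


class TestSelectMarkers:
    def test_copy_number_filter_three_species(self):
        # species s3 is post-WGD; family copy counts per species:
        # F1 (1,1,1) usable single; F2 (1,1,2) usable duplicated;
        # F3 (1,1,3) too many copies; F4 (1,0,1) absent from s2
        s1 = order_from("s1", {"c": [("F1", "+"), ("F2", "+"), ("F3", "+"), ("F4", "+")]})
        s2 = order_from("s2", {"c": [("F1", "+"), ("F2", "+"), ("F3", "+")]})
        s3 = order_from(
            "s3",
            {"c": [("F1", "+"), ("F2", "+"), ("F2", "+"),
                   ("F3", "+"), ("F3", "+"), ("F3", "+"), ("F4", "+")]},
        )
        cfg = SpeciesConfig(species=["s1", "s2", "s3"], duplicated_species={"s3"})
        markers = select_markers([s1, s2, s3], cfg)
        assert markers.families == ["F1", "F2"]
        assert markers.classes == {"F1": "ALL_SINGLE", "F2": "DUP_2"}

    def test_two_copies_in_unduplicated_species_excluded(self):
        s1 = order_from("s1", {"c": [("F1", "+"), ("F1", "+")]})
        s2 = order_from("s2", {"c": [("F1", "+")]})
        cfg = SpeciesConfig(species=["s1", "s2"])
        assert len(select_markers([s1, s2], cfg)) == 0

    def test_mixed_copy_counts_in_duplicated_species_class(self):
        s1 = order_from("s1", {"c": [("F1", "+")]})
        d1 = order_from("d1", {"c": [("F1", "+"), ("F1", "+")]})
        d2 = order_from("d2", {"c": [("F1", "+")]})
        cfg = SpeciesConfig(species=["s1", "d1", "d2"], duplicated_species={"d1", "d2"})
        markers = select_markers([s1, d1, d2], cfg)
        assert markers.classes == {"F1": "DUP_1OR2"}

    def test_missing_species_in_data_is_an_error(self):
        s1 = order_from("s1", {"c": [("F1", "+")]})
        cfg = SpeciesConfig(species=["s1", "ghost"])
        with pytest.raises(ValueError, match="ghost"):
            select_markers([s1], cfg)


class TestReduceAndExtract:
    def test_reduction_drops_non_markers_and_empty_chromosomes(self):
        g = order_from("s1", {"c1": [("a", "+"), ("x", "+"), ("b", "-")], "c2": [("x", "+")]})
        s2 = order_from("s2", {"c": [("a", "+"), ("b", "+")]})
        cfg = SpeciesConfig(species=["s1", "s2"])
        markers = select_markers([g, s2], cfg)
        red = reduce_to_markers(g, markers)
        assert [f for _, f, _ in red.chromosomes["c1"]] == ["a", "b"]
        assert "c2" not in red.chromosomes
        # idempotent
        assert reduce_to_markers(red, markers).chromosomes == red.chromosomes

    def test_linear_chromosome_adjacencies(self):
        g = order_from("s", {"c": [(f, "+") for f in "abcde"]})
        adj = extract_adjacencies(g)
        assert adj.adjacencies == {("a", "b"), ("b", "c"), ("c", "d"), ("d", "e")}

    def test_union_over_wgd_copies(self):
        g = order_from("s", {"chr1": [("a", "+"), ("b", "+")], "chr2": [("a", "+"), ("c", "+")]})
        assert extract_adjacencies(g).adjacencies == {("a", "b"), ("a", "c")}

    def test_single_gene_chromosome_contributes_nothing(self):
        g = order_from("s", {"c1": [("a", "+")], "c2": [("b", "+"), ("c", "+")]})
        assert extract_adjacencies(g).adjacencies == {("b", "c")}

    def test_tandem_same_family_pairs_skipped(self):
        g = order_from("s", {"c": [("a", "+"), ("a", "-"), ("b", "+")]})
        assert extract_adjacencies(g).adjacencies == {("a", "b")}

    def test_strand_flip_and_chromosome_relabel_invariance(self):
        rng = np.random.default_rng(5)
        fams = [f"f{i}" for i in range(30)]
        rng.shuffle(fams)
        genes = [(f, "+" if rng.random() < 0.5 else "-") for f in fams]
        g = order_from("s", {"c1": genes[:15], "c2": genes[15:]})
        flipped = GeneOrder(
            genome="s",
            chromosomes={
                f"renamed_{c}": [
                    (gid, fam, "+" if strand == "-" else "-")
                    for gid, fam, strand in reversed(genes)
                ]
                for c, genes in g.chromosomes.items()
            },
        )
        assert extract_adjacencies(g).adjacencies == extract_adjacencies(flipped).adjacencies

    def test_signed_adjacencies_record_relative_orientation(self):
        same = order_from("s", {"c": [("a", "+"), ("b", "+")]})
        opp = order_from("s", {"c": [("a", "+"), ("b", "-")]})
        assert extract_adjacencies(same, signed=True).adjacencies == {("a", "b", "same")}
        assert extract_adjacencies(opp, signed=True).adjacencies == {("a", "b", "opposite")}

    def test_adjacency_count_equals_copies_minus_chromosomes(self):
        # no tandem repeats: |A| = total marker copies - number of chromosomes
        rng = np.random.default_rng(11)
        fams = [f"f{i}" for i in range(40)]
        rng.shuffle(fams)
        g = order_from("s", {"c1": [(f, "+") for f in fams[:25]],
                             "c2": [(f, "+") for f in fams[25:]]})
        assert len(extract_adjacencies(g)) == 40 - 2


class TestCharacterMatrix:
    def _two_species_matrix(self):
        from adjphylo.markers import AdjacencySet

        cfg = SpeciesConfig(species=["s1", "s2"])
        sets = [
            AdjacencySet("s1", {("a", "b"), ("b", "c")}),
            AdjacencySet("s2", {("a", "b"), ("c", "d")}),
        ]
        return build_character_matrix(sets, cfg)

    def test_universe_is_union_and_states_match(self):
        cm = self._two_species_matrix()
        assert cm.adjacencies == [("a", "b"), ("b", "c"), ("c", "d")]
        i1, i2 = cm.species_index("s1"), cm.species_index("s2")
        assert list(cm.states[i1]) == [PRESENT, PRESENT, ABSENT]
        assert list(cm.states[i2]) == [PRESENT, ABSENT, PRESENT]

    def test_lineage_specific_flags(self):
        from adjphylo.markers import AdjacencySet

        cfg = SpeciesConfig(species=["out", "in1", "in2"], outgroup_species={"out"})
        sets = [
            AdjacencySet("out", {("a", "b")}),
            AdjacencySet("in1", {("a", "b"), ("b", "c")}),
            AdjacencySet("in2", {("b", "c"), ("c", "d")}),
        ]
        cm = build_character_matrix(sets, cfg)
        flagged = {adj for adj, f in zip(cm.adjacencies, cm.lineage_specific) if f}
        assert flagged == {("b", "c"), ("c", "d")}

    def test_tgd_mask_recodes_reciprocal_loss_to_missing(self):
        from adjphylo.markers import AdjacencySet

        cfg = SpeciesConfig(species=["s1", "dup"], duplicated_species={"dup"})
        # in "dup", family a retained only on a copyA chromosome, b only on copyB
        dup = order_from("dup", {"c1A": [("a", "+"), ("x", "+")], "c1B": [("x", "+"), ("b", "+")]})
        s1 = order_from("s1", {"c": [("a", "+"), ("b", "+"), ("x", "+")]})
        sets = [
            AdjacencySet("s1", {("a", "b"), ("a", "x")}),
            AdjacencySet("dup", {("a", "x"), ("b", "x")}),
        ]
        mask = TgdMask(labels={"dup": {"c1A": "copyA", "c1B": "copyB"}})
        unmasked = build_character_matrix(sets, cfg)
        masked = build_character_matrix(
            sets, cfg, tgd_mask=mask, reduced_orders={"dup": dup, "s1": s1}
        )
        j = unmasked.adjacencies.index(("a", "b"))
        d = unmasked.species_index("dup")
        assert unmasked.states[d, j] == ABSENT
        assert masked.states[d, j] == MISSING

    def test_recoding_never_changes_present_states(self):
        cm = self._two_species_matrix()
        assert np.all((cm.states == PRESENT) | (cm.states == ABSENT))

    def test_tsv_round_trip(self, tmp_path):
        cm = self._two_species_matrix()
        cm.to_tsv(tmp_path / "cm.tsv")
        again = CharacterMatrix.from_tsv(tmp_path / "cm.tsv")
        assert again.adjacencies == cm.adjacencies
        assert np.array_equal(again.states, cm.states)
        assert np.array_equal(again.lineage_specific, cm.lineage_specific)


class TestMarkerCoverage:
    def test_span_fraction(self):
        from adjphylo.io_formats import GenePosition

        positions = [
            GenePosition("s", "c", 100, 199, "+", "g1", "m1"),
            GenePosition("s", "c", 500, 599, "+", "g2", "x"),
            GenePosition("s", "c", 801, 900, "+", "g3", "m2"),
            GenePosition("s", "c", 901, 1000, "+", "g4", "x2"),
        ]
        order = GeneOrder(
            genome="s",
            chromosomes={"c": [(p.gene_id, p.family_id, p.strand) for p in positions]},
            positions={"c": positions},
        )
        other = order_from("o", {"c": [("m1", "+"), ("m2", "+"), ("x", "+"), ("x2", "+")]})
        cfg = SpeciesConfig(species=["s", "o"])
        markers = select_markers([order, other], cfg)
        assert set(markers.families) >= {"m1", "m2"}
        # markers m1..m2 span 100..900 of a 1000 bp chromosome

        class OnlyM:
            def __contains__(self, fam):
                return fam in ("m1", "m2")

        assert marker_coverage(order, OnlyM()) == pytest.approx(0.801, abs=1e-9)

    def test_no_markers_gives_zero(self):
        from adjphylo.io_formats import GenePosition

        p = GenePosition("s", "c", 1, 1000, "+", "g1", "fam")
        order = GeneOrder("s", {"c": [("g1", "fam", "+")]}, positions={"c": [p]})

        class NoneSet:
            def __contains__(self, fam):
                return False

        assert marker_coverage(order, NoneSet()) == 0.0


def test_adjacency_universe_matches_independent_union(mini4_run):
    """The character-matrix universe equals a brute-force union of
    consecutive-pair sets recomputed directly from the reduced gene orders."""
    import adjphylo as ap

    fx = mini4_run.fixture
    union = set()
    for order in fx.gene_orders:
        red = ap.reduce_to_markers(order, mini4_run.markers)
        for genes in red.chromosomes.values():
            for (_, f1, _), (_, f2, _) in zip(genes, genes[1:]):
                if f1 != f2:
                    union.add(tuple(sorted((f1, f2))))
    assert set(mini4_run.matrix.adjacencies) == union
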