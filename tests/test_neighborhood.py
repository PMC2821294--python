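import pytest

from efpmod.neighborhood import (
    NeighborhoodConfig,
    are_clustered,
    classify_clustering,
    is_operon,
    neighborhood_context,
)

from conftest import assign, make_genome


def spaced_genome(ids, gap=200, start=100, strand="+", width=150):
    """Genes laid left to right with a fixed intergenic gap."""
    spec = []
    pos = start
    for gid in ids:
        spec.append((gid, pos, pos + width - 1, strand))
        pos += width + gap
    return make_genome(spec)


class TestAreClustered:
    def test_adjacent_genes_cluster(self):
        g = spaced_genome(["a", "b"])
        assert are_clustered(g.gene("a"), g.gene("b"), g)

    def test_symmetric(self):
        g = spaced_genome(["a", "x1", "x2", "b"])
        ab = are_clustered(g.gene("a"), g.gene("b"), g)
        ba = are_clustered(g.gene("b"), g.gene("a"), g)
        assert ab == ba is True

    def test_boundary_at_max_intervening(self):
        ids = ["a"] + [f"x{i}" for i in range(6)] + ["b"]
        g = spaced_genome(ids)
        config = NeighborhoodConfig(max_intervening=5)
        assert not are_clustered(g.gene("a"), g.gene("b"), g, config)
        g5 = spaced_genome(["a"] + [f"x{i}" for i in range(5)] + ["b"])
        assert are_clustered(g5.gene("a"), g5.gene("b"), g5, config)

    def test_different_replicons_never_cluster(self):
        from efpmod.genome_model import GeneFeature, Genome, Replicon

        r1 = Replicon("c1", 5000, genes=[
            GeneFeature("a", "c1", 100, 200, "+", "MKT" * 10)])
        r2 = Replicon("c2", 5000, genes=[
            GeneFeature("b", "c2", 100, 200, "+", "MKT" * 10)])
        g = Genome("G", "G", [r1, r2])
        assert not are_clustered(g.gene("a"), g.gene("b"), g)

    def test_circular_wraps_origin(self):
        ids = ["a"] + [f"x{i}" for i in range(10)] + ["b"]
        linear = spaced_genome(ids)
        assert not are_clustered(linear.gene("a"), linear.gene("b"), linear)
        spec = [(gid, g.start, g.end, g.strand) for gid, g in
                zip(ids, linear.genes)]
        circular = make_genome(spec, circular=True)
        # around the origin a and b are adjacent (0 intervening)
        assert are_clustered(circular.gene("a"), circular.gene("b"), circular)

    def test_foreign_gene_is_error(self):
        g = spaced_genome(["a", "b"])
        other = spaced_genome(["z"]).gene("z")
        with pytest.raises(ValueError):
            are_clustered(g.gene("a"), other, g)


class TestIsOperon:
    def test_consecutive_same_strand_small_gaps(self):
        g = make_genome([
            ("a", 100, 400, "+"), ("b", 421, 700, "+"), ("c", 741, 1000, "+"),
        ])
        assert is_operon([g.gene("a"), g.gene("b"), g.gene("c")], g)

    def test_large_gap_breaks_operon(self):
        g = make_genome([("a", 100, 400, "+"), ("b", 5401, 5700, "+")])
        assert not is_operon([g.gene("a"), g.gene("b")], g)

    def test_opposite_strands_break_operon(self):
        g = make_genome([("a", 100, 400, "+"), ("b", 421, 700, "-")])
        assert not is_operon([g.gene("a"), g.gene("b")], g)

    def test_intervening_gene_breaks_operon(self):
        g = make_genome([
            ("a", 100, 400, "+"), ("x", 421, 700, "+"), ("b", 741, 1000, "+"),
        ])
        assert not is_operon([g.gene("a"), g.gene("b")], g)

    def test_operon_implies_pairwise_clustering(self):
        g = make_genome([
            ("a", 100, 400, "+"), ("b", 421, 700, "+"), ("c", 741, 1000, "+"),
        ])
        genes = [g.gene("a"), g.gene("b"), g.gene("c")]
        assert is_operon(genes, g)
        for i in range(3):
            for j in range(i + 1, 3):
                assert are_clustered(genes[i], genes[j], g)


class TestClassify:
    def test_operon_category(self):
        g = make_genome([
            ("e", 100, 400, "+"), ("a", 421, 700, "+"), ("k", 741, 1000, "+"),
        ])
        fams = assign(g, {"e": "efp", "a": "yjeA", "k": "yjeK"})
        cc = classify_clustering(g, fams)
        assert cc.category == "three_gene_operon"

    def test_pairwise_efp_yjek(self):
        ids = ["e", "k"] + [f"x{i}" for i in range(8)] + ["a"]
        g = spaced_genome(ids)
        fams = assign(g, {"e": "efp", "k": "yjeK", "a": "yjeA"})
        cc = classify_clustering(g, fams)
        assert cc.category == "pairwise_cluster"
        assert cc.pair == "efp_yjeK"

    def test_all_separated_is_no_cluster(self):
        ids = (["e"] + [f"p{i}" for i in range(7)] + ["a"]
               + [f"q{i}" for i in range(7)] + ["k"])
        g = spaced_genome(ids)
        fams = assign(g, {"e": "efp", "a": "yjeA", "k": "yjeK"})
        assert classify_clustering(g, fams).category == "no_cluster"

    def test_missing_family_is_incomplete(self):
        g = spaced_genome(["e", "a"])
        fams = assign(g, {"e": "efp", "a": "yjeA"})
        cc = classify_clustering(g, fams)
        assert cc.category == "incomplete"

    def test_operon_takes_precedence_over_pairwise(self):
        # triple operon plus an extra efp/yjeK pair elsewhere
        ids = ["e", "a", "k"] + [f"x{i}" for i in range(8)] + ["e2", "k2"]
        spec = []
        pos = 100
        for gid in ids:
            spec.append((gid, pos, pos + 149, "+"))
            pos += 150 + (50 if gid in ("e", "a") else 300)
        g = make_genome(spec)
        fams = assign(g, {"e": "efp", "a": "yjeA", "k": "yjeK",
                          "e2": "efp", "k2": "yjeK"})
        assert classify_clustering(g, fams).category == "three_gene_operon"

    def test_paralog_any_combination_counts(self):
        # first efp copy far away, second one adjacent to yjeK
        ids = ["e1"] + [f"x{i}" for i in range(8)] + ["e2", "k", "a2"]
        g = spaced_genome(ids)
        fams = assign(g, {"e1": "efp", "e2": "efp", "k": "yjeK"})
        cc = classify_clustering(g, fams)
        assert cc.category == "incomplete"  # yjeA missing entirely
        fams = assign(g, {"e1": "efp", "e2": "efp", "k": "yjeK", "a2": "yjeA"})
        cc = classify_clustering(g, fams)
        assert cc.category == "pairwise_cluster"
        assert "e2" in cc.supporting_genes

    def test_invariant_under_assignment_order(self):
        ids = ["e", "k"] + [f"x{i}" for i in range(8)] + ["a"]
        g = spaced_genome(ids)
        fams = assign(g, {"e": "efp", "k": "yjeK", "a": "yjeA"})
        assert classify_clustering(g, fams) == classify_clustering(g, fams[::-1])


class TestContext:
    def test_family_within_window(self):
        ids = ["lam", "x0", "e"]
        g = spaced_genome(ids)
        fams = assign(g, {"lam": "yjeK", "e": "efp"})
        ctx = neighborhood_context(g.gene("lam"), g, fams)
        assert ctx == {"efp"}

    def test_isolated_gene_empty_context(self):
        g = spaced_genome(["lam"])
        fams = assign(g, {"lam": "yjeK"})
        assert neighborhood_context(g.gene("lam"), g, fams) == set()

    def test_linear_edge_truncates_window(self):
        ids = ["lam"] + [f"x{i}" for i in range(3)] + ["b"]
        g = spaced_genome(ids)
        fams = assign(g, {"lam": "ablA", "b": "ablB"})
        config = NeighborhoodConfig(context_window=2)
        assert neighborhood_context(g.gene("lam"), g, fams, config) == set()
        config = NeighborhoodConfig(context_window=4)
        assert neighborhood_context(g.gene("lam"), g, fams, config) == {"ablB"}
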