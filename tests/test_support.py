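import itertools
import random

import dendropy
import numpy as np
import pytest

from degenkit.errors import DegenkitError
from degenkit.support import (
    Bipartition,
    SupportedTree,
    UtilityRecord,
    classify_support,
    fit_utility_trend,
    genes_supporting_nodes,
    missing_taxon_count,
    parse_tree,
    score_gene,
    utility,
)

from conftest import make_matrix


def random_supported_newick(leaves, rng):
    """Random binary topology with random integer supports."""
    nodes = [lab for lab in leaves]
    rng.shuffle(nodes)
    while len(nodes) > 1:
        a = nodes.pop(rng.randrange(len(nodes)))
        b = nodes.pop(rng.randrange(len(nodes)))
        nodes.append(f"({a},{b}){rng.randrange(0, 101)}")
    return nodes[0] + ";"


def oracle_bipartitions(newick, leaves):
    """Independent bipartition set: test every leaf subset for monophyly."""
    tree = dendropy.Tree.get(data=newick, schema="newick", rooting="force-rooted")
    tree.encode_bipartitions()
    tns = tree.taxon_namespace
    found = {}
    for r in range(2, len(leaves) - 1):
        for combo in itertools.combinations(sorted(leaves), r):
            taxa = [tns.get_taxon(t) for t in combo]
            mask = tns.taxa_bitmask(taxa=taxa)
            node = tree.mrca(taxa=taxa)
            side = frozenset(frozenset(s) for s in (combo, tuple(set(leaves) - set(combo))))
            if node is not None and node.leafset_bitmask == mask:
                val = float(node.label) if node.label else None
                prev = found.get(side)
                if side not in found or (val is not None and (prev is None or val > prev)):
                    found[side] = val
    return found


class TestParseTree:
    def test_four_leaf_single_informative_bipartition(self):
        t = parse_tree("((A,B)95,(C,D)87);")
        assert len(t.clades) == 1
        (b, s), = t.clades.items()
        assert b == Bipartition({"A", "B"}, {"C", "D"})
        assert s == 95.0

    def test_caterpillar_has_two_informative_bipartitions(self):
        t = parse_tree("((((A,B)90,C)80,D)70,E);")
        assert len(t.clades) == 2

    def test_missing_supports_are_absent_not_zero(self):
        t = parse_tree("((A,B),(C,D));")
        assert list(t.clades.values()) == [None]

    def test_duplicate_leaf_rejected(self):
        with pytest.raises(DegenkitError):
            parse_tree("((A,A),(C,D));")

    def test_malformed_newick_rejected(self):
        with pytest.raises(DegenkitError):
            parse_tree("((A,B(;")


class TestBipartition:
    def test_unordered_equality(self):
        assert Bipartition("AB", "CD") == Bipartition("DC", "BA")

    def test_restriction_drops_emptied_side(self):
        b = Bipartition({"A", "B"}, {"C", "D"})
        assert b.restrict({"A", "B", "C"}) == Bipartition({"A", "B"}, {"C"})
        assert b.restrict({"A", "B"}) is None

    def test_overlapping_sides_rejected(self):
        with pytest.raises(ValueError):
            Bipartition({"A"}, {"A", "B"})


class TestClassifySupport:
    def test_identical_trees_all_strong_no_conflict(self):
        nwk = "(((A,B)100,(C,D)100)100,(E,F)100);"
        res = classify_support(parse_tree(nwk), parse_tree(nwk))
        assert res.n_strong_match == len(parse_tree(nwk).clades)
        assert res.n_conflict == res.n_strong_conflict == 0

    def test_strong_novel_clade_is_strong_conflict(self):
        ref = parse_tree("(((A,B)100,(C,D)100)100,(E,F)100);")
        cand = parse_tree("(((A,C)82,(B,D)55)100,(E,F)100);")
        res = classify_support(ref, cand)
        assert res.n_strong_match == 1  # ABCD|EF
        assert res.n_conflict == 2  # AC at 82, BD at 55
        assert res.n_strong_conflict == 1  # AC only

    def test_restriction_aware_matching_avoids_false_conflict(self):
        ref = parse_tree("(((A,B)100,(C,D)100)100,(E,F)100);")
        cand = parse_tree("(((A,B)99,C)90,(E,F)95);")  # D missing
        res = classify_support(ref, cand)
        assert res.n_conflict == 0
        assert res.n_strong_match == 2

    def test_disjoint_leaf_sets_rejected(self):
        with pytest.raises(DegenkitError):
            classify_support(parse_tree("((A,B),(C,D));"), parse_tree("((W,X),(Y,Z));"))

    @pytest.mark.parametrize("n_leaves", [5, 6, 7])
    def test_counts_match_exhaustive_oracle(self, n_leaves):
        rng = random.Random(n_leaves * 101)
        leaves = [chr(ord("A") + i) for i in range(n_leaves)]
        for _ in range(25):
            ref_nwk = random_supported_newick(leaves, rng)
            cand_nwk = random_supported_newick(leaves, rng)
            res = classify_support(parse_tree(ref_nwk), parse_tree(cand_nwk))
            ref_b = oracle_bipartitions(ref_nwk, leaves)
            cand_b = oracle_bipartitions(cand_nwk, leaves)
            strong_ref = {b for b, s in ref_b.items() if s is not None and s >= 80}
            exp_strong = sum(
                1 for b, s in cand_b.items()
                if s is not None and s >= 80 and b in strong_ref
            )
            exp_conf = sum(
                1 for b, s in cand_b.items()
                if s is not None and s >= 50 and b not in strong_ref
            )
            exp_strong_conf = sum(
                1 for b, s in cand_b.items()
                if s is not None and s >= 80 and b not in strong_ref
            )
            assert (res.n_strong_match, res.n_conflict, res.n_strong_conflict) == (
                exp_strong, exp_conf, exp_strong_conf,
            )


class TestGenesSupportingNodes:
    def test_no_gene_trees_all_zero(self):
        ref = parse_tree("((A,B)90,(C,D)90);")
        counts = genes_supporting_nodes(ref, [])
        assert set(counts.values()) == {0}

    def test_manual_tally(self):
        ref = parse_tree("(((A,B)100,C)100,(D,E)100);")
        ab = Bipartition({"A", "B"}, {"C", "D", "E"})
        genes = [
            parse_tree("(((A,B)80,C)70,(D,E)60);"),
            parse_tree("(((A,B)90,D)70,(C,E)60);"),
            parse_tree("(((A,C)85,B)70,(D,E)90);"),
            parse_tree("(((A,B)40,C)70,(D,E)75);"),
            parse_tree("((A,B)76,(C,(D,E)10)5);"),
        ]
        counts = genes_supporting_nodes(ref, genes, threshold=75)
        assert counts[ab] == 3

    def test_restriction_to_gene_taxa(self):
        ref = parse_tree("(((A,B)100,C)100,(D,E)100);")
        gene = parse_tree("((A,B)80,(D,E)80);")  # C missing
        counts = genes_supporting_nodes(ref, [gene])
        de = Bipartition({"D", "E"}, {"A", "B", "C"})
        assert counts[de] == 1


class TestUtility:
    def test_formula_examples(self):
        assert utility(10, 1000, 0) == pytest.approx(10.0)
        assert utility(10, 1000, 16) == pytest.approx(12.5)  # 10 * 80/64
        assert utility(0, 500, 5) == 0.0

    def test_homogeneity(self):
        base = utility(7, 1200, 10)
        assert utility(14, 1200, 10) == pytest.approx(2 * base)
        assert utility(7, 2400, 10) == pytest.approx(base / 2)

    @pytest.mark.parametrize("G,L,m", [(1, 0, 0), (1, 100, 80), (1, 100, 90)])
    def test_invalid_inputs_rejected(self, G, L, m):
        with pytest.raises(ValueError):
            utility(G, L, m)

    def test_missing_taxon_count(self):
        m = make_matrix(
            ["ACGACG", "??????", "---ACG"],
            charsets={"g": range(6)}, fragments=["g"],
        )
        assert missing_taxon_count(m, "g") == 1

    def test_score_gene_counts_recovered_nodes(self):
        ref = parse_tree("(((A,B)100,C)100,(D,E)100);")
        gene = parse_tree("(((A,B)80,C)70,(D,E)76);")
        rec = score_gene("g1", ref, gene, length=1000, missing=0, total_taxa=5)
        assert rec.G == 2
        assert rec.utility == pytest.approx(2.0)


class TestTrendFit:
    def _records(self, xs, ys):
        return (
            [UtilityRecord(f"g{i}", 0, 1000, 0, y) for i, y in enumerate(ys)],
            {"rates": {f"g{i}": x for i, x in enumerate(xs)}},
        )

    def test_collinear_points_exact(self):
        recs, rates = self._records([0, 1, 2, 3], [1, 3, 5, 7])
        fit = fit_utility_trend(recs, type("R", (), rates))
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.slope_sd == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_noise_slope_within_se(self):
        x = np.arange(10, dtype=float)
        noise = np.array([0.3, -0.3] * 5)
        recs, rates = self._records(x, 2 * x + 1 + noise)
        fit = fit_utility_trend(recs, type("R", (), rates))
        assert abs(fit.slope - 2.0) <= 2 * fit.slope_sd + 1e-9

    def test_order_invariance(self):
        recs, rates = self._records([0, 1, 2, 3, 4], [0.1, 2.2, 3.9, 6.1, 8.0])
        R = type("R", (), rates)
        fwd = fit_utility_trend(recs, R)
        rev = fit_utility_trend(recs[::-1], R)
        assert fwd == pytest.approx(rev)

    def test_degenerate_inputs_rejected(self):
        recs, rates = self._records([1, 1, 1], [1, 2, 3])
        with pytest.raises(ValueError):
            fit_utility_trend(recs, type("R", (), rates))
        with pytest.raises(ValueError):
            fit_utility_trend(recs[:2], type("R", (), rates))
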