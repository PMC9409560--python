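import math

import numpy as np
import pytest
from scipy import stats

from netoverlap import (
    GeneSet,
    adjust_pvalues,
    fisher_overlap,
    gmt_enrichment,
    load_gmt,
    simulate_gene_set_collection,
)
from netoverlap.overlap_stats import write_gmt

import oracles


def _sets_with_overlap(n_a: int, n_b: int, n_shared: int):
    shared = [f"S{i}" for i in range(n_shared)]
    a = GeneSet("A", tuple(shared + [f"A{i}" for i in range(n_a - n_shared)]))
    b = GeneSet("B", tuple(shared + [f"B{i}" for i in range(n_b - n_shared)]))
    return a, b


class TestFisherOverlap:
    def test_independence_table(self):
        a, b = _sets_with_overlap(20, 20, 10)
        res = fisher_overlap(a, b, universe=40)
        assert res.table.as_array().tolist() == [[10, 10], [10, 10]]
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1.0)

    def test_headline_scale_overlap_is_below_reporting_floor(self):
        a, b = _sets_with_overlap(118, 151, 17)
        res = fisher_overlap(a, b, universe=20_000)
        assert res.p_value <= 2.2e-16
        assert res.odds_ratio > 1
        assert len(res.overlap_genes) == 17

    def test_swap_invariance(self):
        a, b = _sets_with_overlap(15, 40, 6)
        assert fisher_overlap(a, b, 500).p_value == pytest.approx(
            fisher_overlap(b, a, 500).p_value
        )

    def test_genes_outside_universe_dropped(self):
        a = GeneSet("A", ("U1", "U2", "X"))
        b = GeneSet("B", ("U2", "U3"))
        uni = GeneSet("U", tuple(f"U{i}" for i in range(10)))
        res = fisher_overlap(a, b, uni)
        assert res.table.a == 1
        assert res.table.universe_size == 10

    def test_infinite_odds_ratio_when_nested(self):
        a = GeneSet("A", ("S0", "S1"))
        b = GeneSet("B", ("S0", "S1", "B0"))
        res = fisher_overlap(a, b, 100)
        assert math.isinf(res.odds_ratio)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 25))
        n_a = int(rng.integers(1, 12))
        n_b = int(rng.integers(1, 12))
        shared = int(rng.integers(0, min(n_a, n_b) + 1))
        if n < n_a + n_b - shared:
            n = n_a + n_b - shared + int(rng.integers(0, 5))
        a, b = _sets_with_overlap(n_a, n_b, shared)
        res = fisher_overlap(a, b, n)
        t = res.table
        expected = oracles.bf_fisher_two_sided(t.a, t.b, t.c, t.d)
        assert res.p_value == pytest.approx(expected, rel=1e-9, abs=1e-12)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            fisher_overlap(GeneSet("A", ("x",)), GeneSet("B", ("y",)), 1)


class TestAdjustPvalues:
    def test_bonferroni_m3(self):
        assert adjust_pvalues([0.01, 0.02, 0.03], "bonferroni") == pytest.approx(
            [0.03, 0.06, 0.09]
        )

    def test_single_p_unchanged(self):
        for method in ("bh", "bonferroni"):
            assert adjust_pvalues([0.5], method) == pytest.approx([0.5])

    @pytest.mark.parametrize("seed", range(10))
    def test_bh_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed + 30)
        p = rng.uniform(size=int(rng.integers(1, 9))).tolist()
        assert adjust_pvalues(p, "bh") == pytest.approx(oracles.bf_bh(p), abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_ordering_invariants(self, seed):
        rng = np.random.default_rng(seed + 60)
        p = rng.uniform(size=8).tolist()
        bh = adjust_pvalues(p, "bh")
        bonf = adjust_pvalues(p, "bonferroni")
        assert all(x <= y + 1e-12 for x, y in zip(bh, bonf))
        assert all(x >= raw - 1e-12 for x, raw in zip(bh, p))
        assert all(x >= raw - 1e-12 for x, raw in zip(bonf, p))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_pvalues([0.5, 1.2], "bh")


class TestGmtEnrichment:
    def test_round_trip_and_parse_errors(self, tmp_path):
        sets = [GeneSet("s1", ("A", "B")), GeneSet("s2", ("C",))]
        f = tmp_path / "c.gmt"
        write_gmt(sets, f)
        loaded = load_gmt(f)
        assert [s.name for s in loaded] == ["s1", "s2"]
        assert loaded[0].genes == ("A", "B")
        bad = tmp_path / "bad.gmt"
        bad.write_text("only_name\tdesc\n")
        with pytest.raises(ValueError):
            load_gmt(bad)

    def test_exact_match_ranks_first_with_minimal_p(self):
        universe = GeneSet("U", tuple(f"G{i}" for i in range(1000)))
        target = GeneSet("target", universe.genes[:20])
        decoy = GeneSet("decoy", universe.genes[500:540])
        records = gmt_enrichment(target, [target, decoy], universe)
        assert records[0].set_name == "target"
        assert records[0].p_value == pytest.approx(
            1 / (stats.hypergeom(1000, 20, 20).pmf(20) ** -1), rel=1e-6
        )

    def test_expected_overlap_not_significant(self):
        universe = GeneSet("U", tuple(f"G{i}" for i in range(1000)))
        # query 100, set 100 -> expected overlap 10
        query = GeneSet("q", universe.genes[:100])
        s = GeneSet("s", universe.genes[90:190])  # overlap exactly 10
        rec = gmt_enrichment(query, [s], universe)[0]
        assert rec.overlap == 10
        assert 0.05 < rec.p_value < 0.95

    def test_planted_collection_recovered(self):
        universe = GeneSet("U", tuple(f"G{i:04d}" for i in range(2000)))
        rng = np.random.default_rng(5)
        query = GeneSet("q", tuple(universe.genes[i] for i in rng.choice(2000, 50, replace=False)))
        sets = simulate_gene_set_collection(query, universe, seed=6, n_sets=50)
        records = gmt_enrichment(query, sets, universe)
        assert records[0].set_name == "planted_set"
        assert records[0].fdr < 0.01

    def test_upper_tail_monotone_in_overlap(self):
        n, K, q = 1000, 50, 60
        ps = [float(stats.hypergeom.sf(k - 1, n, K, q)) for k in range(0, 20)]
        assert all(x >= y for x, y in zip(ps, ps[1:]))

    def test_hypergeom_pmf_sums_to_one(self):
        n, K, q = 400, 30, 25
        total = sum(oracles.hypergeom_pmf(a, q, K, n) for a in range(0, min(K, q) + 1))
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_set_outside_universe_skipped(self):
        universe = GeneSet("U", tuple(f"G{i}" for i in range(50)))
        query = GeneSet("q", universe.genes[:10])
        outside = GeneSet("out", ("X1", "X2"))
        inside = GeneSet("in", universe.genes[:5])
        records = gmt_enrichment(query, [outside, inside], universe)
        assert [r.set_name for r in records] == ["in"]
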