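import numpy as np
import pandas as pd
import pytest

from evintegra import syndata
from evintegra.enrich import (
    celltype_target_enrichment,
    gsea_preranked,
    ora_hypergeom,
    rank_genes,
)


def _ranked(n):
    return pd.Series(np.linspace(2.0, 1.0, n), index=[f"g{i}" for i in range(n)])


class TestRunningSum:
    def test_top_ranked_set_hand_computed_es(self):
        # N=10, |S|=2 occupying ranks 1-2, weight 0: ES = 1 - |S|/N = 0.8
        res = gsea_preranked(_ranked(10), ["g0", "g1"], weight=0.0,
                             permutations="exact")
        assert res.es == pytest.approx(0.8)
        assert sorted(res.leading_edge) == ["g0", "g1"]

    def test_bottom_ranked_set_negative_es_and_trailing_edge(self):
        res = gsea_preranked(_ranked(10), ["g8", "g9"], weight=0.0,
                             permutations="exact")
        assert res.es == pytest.approx(-0.8)
        assert sorted(res.leading_edge) == ["g8", "g9"]

    def test_es_sign_flips_when_metric_negated(self):
        rng = np.random.default_rng(2)
        metric = pd.Series(rng.normal(size=30),
                           index=[f"g{i}" for i in range(30)])
        gene_set = list(metric.nlargest(4).index)
        a = gsea_preranked(metric, gene_set, n_perm=50, seed=1)
        b = gsea_preranked(-metric, gene_set, n_perm=50, seed=1)
        assert a.es == pytest.approx(-b.es)

    def test_empty_intersection_rejected(self):
        with pytest.raises(ValueError, match="intersect"):
            gsea_preranked(_ranked(5), ["absent"])

    def test_set_equal_to_universe_flagged_degenerate(self):
        res = gsea_preranked(_ranked(4), [f"g{i}" for i in range(4)],
                             n_perm=10, seed=0)
        assert res.degenerate

    def test_duplicate_gene_ids_rejected(self):
        metric = pd.Series([1.0, 2.0], index=["a", "a"])
        with pytest.raises(ValueError, match="duplicate"):
            rank_genes(metric)


class TestPermutationP:
    def test_exact_p_matches_independent_enumeration_sweep(self):
        from evintegra.benchmarks import gsea_enumeration_sweep
        res = gsea_enumeration_sweep(max_n=8, max_s=3)
        assert res["max_abs_diff"] == 0.0
        assert res["n"] > 200

    def test_exact_p_for_fifteen_placements(self):
        # N=6, |S|=2: p over all C(6,2)=15 placements
        res = gsea_preranked(_ranked(6), ["g0", "g1"], weight=0.0,
                             permutations="exact")
        assert res.n_perm == 15
        assert res.p * 15 == pytest.approx(round(res.p * 15))

    def test_random_p_respects_add_one_lower_bound(self):
        res = gsea_preranked(_ranked(30), ["g0", "g1", "g2"], n_perm=99, seed=3)
        assert res.p >= 1.0 / 100.0
        assert res.p > 0

    def test_null_mean_es_near_zero(self):
        # the unweighted running sum is a symmetric bridge: random placements
        # have mean ES ~ 0 (weighted increments on a trending metric do not)
        rng = np.random.default_rng(9)
        ranked = _ranked(50)
        es = []
        for _ in range(1000):
            genes = list(ranked.index[rng.choice(50, size=5, replace=False)])
            es.append(gsea_preranked(ranked, genes, n_perm=1, seed=0,
                                     weight=0.0).es)
        assert abs(np.mean(es)) < 0.05


class TestOra:
    def test_closed_form_tail(self):
        universe = [f"u{i}" for i in range(10)]
        p, k = ora_hypergeom(universe[:4], universe[:5], universe)
        assert k == 4
        assert p == pytest.approx(5.0 / 210.0)

    def test_zero_overlap_full_tail_is_one(self):
        universe = [f"u{i}" for i in range(10)]
        p, k = ora_hypergeom(universe[:3], universe[5:], universe)
        assert k == 0 and p == 1.0

    def test_matches_monte_carlo_tail(self):
        rng = np.random.default_rng(12)
        universe = [f"u{i}" for i in range(40)]
        gene_set = universe[:12]
        hits = universe[4:13]
        p, k = ora_hypergeom(hits, gene_set, universe)
        draws = rng.hypergeometric(12, 28, len(hits), size=100_000)
        mc = np.mean(draws >= k)
        se = np.sqrt(mc * (1 - mc) / 100_000)
        assert abs(p - mc) < 3 * max(se, 1e-4)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            ora_hypergeom(["a"], ["a"], [])


class TestCelltypeGrid:
    def test_planted_target_set_peaks_in_its_cell_type(self, planted):
        sig, markers = planted
        target_ct = sig.columns[2]
        grid = celltype_target_enrichment(
            {"mirX_targets": markers[target_ct][:30]}, sig, n_perm=200, seed=5)
        best = grid.loc[grid["nes"].idxmax()]
        assert best["cell_type"] == target_ct
        assert grid.loc[grid["cell_type"] == target_ct, "p_adj"].iloc[0] < 0.05

    def test_uniform_target_sets_rarely_enriched(self):
        # non-specific gene sets drawn at random should almost never be
        # significant in any cell type; markers are kept scarce (100 of 600
        # genes) so non-specific genes scatter through the ranking like the
        # bulk, as in real profiles
        from evintegra import syndata
        from evintegra.signatures import build_signature_matrix

        sig, markers = syndata.gen_cell_signatures(600, 5, 20, 3.0, seed=11)
        cells_ = syndata.gen_single_cell_counts(sig, 40, 20000.0, 0.3, seed=31)
        profiles = build_signature_matrix(cells_)
        all_markers = {g for m in markers.values() for g in m}
        nonmark = [g for g in sig.index if g not in all_markers]
        rng = np.random.default_rng(0)
        significant_pairs, total_pairs = 0, 0
        for seed in range(20):
            uniform = list(rng.choice(nonmark, size=30, replace=False))
            grid = celltype_target_enrichment({"u": uniform}, profiles,
                                              n_perm=200, seed=seed)
            significant_pairs += int((grid["p_adj"] < 0.05).sum())
            total_pairs += len(grid)
        assert significant_pairs / total_pairs <= 0.08

    def test_planted_set_has_max_nes_on_derived_profiles(self, planted, cells):
        from evintegra.signatures import build_signature_matrix

        sig, markers = planted
        profiles = build_signature_matrix(cells)  # noisy, all genes
        target_ct = sig.columns[3]
        grid = celltype_target_enrichment(
            {"t": markers[target_ct][:30]}, profiles, n_perm=200, seed=8)
        assert grid.loc[grid["nes"].idxmax(), "cell_type"] == target_ct

    def test_grid_shape_contract(self, planted):
        sig, markers = planted
        sets = {f"s{i}": list(markers[ct][:10])
                for i, ct in enumerate(sig.columns[:3])}
        grid = celltype_target_enrichment(sets, sig, n_perm=20, seed=7)
        assert len(grid) == 3 * sig.shape[1]
        assert set(grid.columns) >= {"set", "cell_type", "es", "nes", "p", "p_adj"}
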