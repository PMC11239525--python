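import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom
from statsmodels.stats.contingency_tables import Table2x2

from epistate.genomic_io import GeneModel, GenomicInterval
from epistate.scores import (
    bivalency_score,
    cmh_composition,
    de_logistic,
    mantel_haenszel_or,
    module_score,
    motif_enrichment,
    regional_variance,
    select_perturbation_regions,
)
from epistate.synthetic import simulate_composition, simulate_perturbation_expression


class TestModuleScore:
    def test_cell_specific_elevation_scores_near_shift(self, rng):
        # genes elevated by delta in a subset of cells: the score contrast
        # between elevated and baseline cells recovers delta (a uniform shift
        # across all cells is absorbed by the average-matched background)
        n_cells, n_genes, delta = 500, 300, 0.8
        base = rng.uniform(0.5, 2.0, n_genes)
        base[:20] = rng.uniform(0.6, 1.4, 20)  # keep set averages inside the background range
        X = rng.normal(base, 0.2, (n_cells, n_genes))
        gene_set = [f"g{i}" for i in range(20)]
        elevated = np.zeros(n_cells, dtype=bool)
        elevated[:150] = True
        X[np.ix_(elevated, np.arange(20))] += delta
        features = [f"g{i}" for i in range(n_genes)]
        score = module_score(X, features, gene_set, seed=0)
        contrast = score[elevated].mean() - score[~elevated].mean()
        assert abs(contrast - delta) < 0.1

    def test_expectation_zero_for_random_sets(self, rng):
        X = rng.normal(1.0, 0.3, (1000, 200))
        features = [f"g{i}" for i in range(200)]
        means = []
        for k in range(100):
            gene_set = list(rng.choice(features, 15, replace=False))
            means.append(module_score(X, features, gene_set, seed=k).mean())
        assert abs(np.mean(means)) < 0.02

    def test_deterministic_given_seed(self, rng):
        X = rng.normal(size=(50, 40))
        features = [f"g{i}" for i in range(40)]
        s1 = module_score(X, features, ["g0", "g1", "g2"], seed=9)
        s2 = module_score(X, features, ["g0", "g1", "g2"], seed=9)
        np.testing.assert_array_equal(s1, s2)

    def test_small_gene_set_rejected(self, rng):
        with pytest.raises(ValueError):
            module_score(rng.normal(size=(5, 5)), list("abcde"), ["a"])


class TestBivalencyScore:
    def test_equal_ranks_give_zero(self):
        k4 = pd.Series([1.0, 2.0, 3.0], index=["c0", "c1", "c2"])
        me3 = pd.Series([10.0, 20.0, 30.0], index=["c0", "c1", "c2"])
        out = bivalency_score(k4, me3)
        np.testing.assert_allclose(out["bivalency"], 0, atol=1e-12)

    def test_zscore_arithmetic(self, rng):
        k4 = pd.Series(rng.normal(size=10), index=[f"c{i}" for i in range(10)])
        me3 = pd.Series(rng.normal(size=10), index=k4.index)
        out = bivalency_score(k4, me3)
        za = (k4 - k4.mean()) / k4.std(ddof=0)
        zr = (me3 - me3.mean()) / me3.std(ddof=0)
        np.testing.assert_allclose(out["bivalency"], za - zr, atol=1e-12)

    def test_too_few_clusters_rejected(self):
        s = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.raises(ValueError):
            bivalency_score(s, s)


class TestRegionalVariance:
    def test_pure_region_effect(self):
        region = pd.Series({"c0": "tel", "c1": "tel", "c2": "dien", "c3": "dien"})
        pt = pd.Series({"c0": 0.1, "c1": 0.9, "c2": 0.2, "c3": 0.8})
        means = pd.DataFrame([[5.0, 5.0, 1.0, 1.0]], index=["f"], columns=region.index)
        out = regional_variance(means, region, pt)
        assert out.loc["f", "r2_region"] == pytest.approx(1.0)
        assert out.loc["f", "r2_pseudotime"] < 0.05

    def test_constant_feature_all_zero(self):
        region = pd.Series({"c0": "a", "c1": "a", "c2": "b"})
        pt = pd.Series({"c0": 0.1, "c1": 0.5, "c2": 0.9})
        means = pd.DataFrame([[2.0, 2.0, 2.0]], index=["f"], columns=region.index)
        out = regional_variance(means, region, pt)
        assert (out.loc["f"] == 0).all()

    def test_matches_hand_computed_r2(self):
        # 3 clusters, y = (1, 2, 4), pt = (0, 0.5, 1): OLS slope 3, yhat (0.83, 2.33, 3.83)
        region = pd.Series({"c0": "a", "c1": "a", "c2": "b"})
        pt = pd.Series({"c0": 0.0, "c1": 0.5, "c2": 1.0})
        means = pd.DataFrame([[1.0, 2.0, 4.0]], index=["f"], columns=region.index)
        out = regional_variance(means, region, pt)
        ss_tot = ((np.array([1, 2, 4]) - 7 / 3) ** 2).sum()
        ss_res = ((np.array([1, 2, 4]) - np.array([5 / 6, 7 / 3, 23 / 6])) ** 2).sum()
        assert out.loc["f", "r2_pseudotime"] == pytest.approx(1 - ss_res / ss_tot)

    def test_nesting_property(self, rng):
        clusters = [f"c{i}" for i in range(12)]
        region = pd.Series(rng.choice(["a", "b", "c"], 12), index=clusters)
        pt = pd.Series(rng.uniform(0, 1, 12), index=clusters)
        means = pd.DataFrame(rng.normal(size=(30, 12)), columns=clusters)
        out = regional_variance(means, region, pt)
        assert (out["r2_both"] >= out[["r2_region", "r2_pseudotime"]].max(axis=1) - 1e-9).all()


class TestCmh:
    def test_single_stratum_equals_plain_2x2(self):
        df = simulate_composition(n_per_stratum=500, n_strata=1, odds_ratio=3.0, seed=0)
        out = cmh_composition(df["cluster"], df["condition"], df["stratum"])
        row = out.set_index("cluster").loc[0]
        a = len(df.query("cluster == 0 and condition == 'treated'"))
        b = len(df.query("cluster == 0 and condition == 'control'"))
        c = len(df.query("cluster != 0 and condition == 'treated'"))
        d = len(df.query("cluster != 0 and condition == 'control'"))
        t22 = Table2x2(np.array([[a, b], [c, d]]))
        assert row["odds_ratio"] == pytest.approx(t22.oddsratio)

    def test_matches_mantel_haenszel_formula(self):
        df = simulate_composition(n_per_stratum=400, n_strata=3, odds_ratio=3.0, seed=1)
        out = cmh_composition(df["cluster"], df["condition"], df["stratum"])
        tables = []
        for s in sorted(df["stratum"].unique()):
            sub = df[df["stratum"] == s]
            a = len(sub.query("cluster == 0 and condition == 'treated'"))
            b = len(sub.query("cluster == 0 and condition == 'control'"))
            c = len(sub.query("cluster != 0 and condition == 'treated'"))
            d = len(sub.query("cluster != 0 and condition == 'control'"))
            tables.append(np.array([[a, b], [c, d]], dtype=float))
        expected = mantel_haenszel_or(tables)
        assert out.set_index("cluster").loc[0, "odds_ratio"] == pytest.approx(expected)

    def test_planted_enrichment_detected(self):
        df = simulate_composition(n_per_stratum=800, n_strata=3, odds_ratio=3.0, seed=2)
        out = cmh_composition(df["cluster"], df["condition"], df["stratum"]).set_index("cluster")
        assert out.loc[0, "odds_ratio"] > 1.5
        assert out.loc[0, "fdr"] < 1e-4 and out.loc[0, "significant"]

    def test_balanced_table_no_association(self):
        rows = []
        for cond in ("treated", "control"):
            rows += [dict(cluster=0, condition=cond, stratum="s")] * 10
            rows += [dict(cluster=1, condition=cond, stratum="s")] * 10
        df = pd.DataFrame(rows)
        out = cmh_composition(df["cluster"], df["condition"], df["stratum"]).set_index("cluster")
        assert out.loc[0, "odds_ratio"] == pytest.approx(1.0)
        assert out.loc[0, "p"] > 0.9


class TestDeLogistic:
    def test_planted_effect_recovered_and_null_controlled(self):
        sim = simulate_perturbation_expression(n_genes=200, n_de=20, seed=0)
        out = de_logistic(sim["Y"], sim["condition"], sim["covariates"]).set_index("gene_id")
        de = out.loc[sim["de_genes"]]
        null = out.drop(sim["de_genes"])
        assert de["significant"].mean() >= 0.8
        assert (null["fdr"] < 0.01).mean() <= 0.02
        # effect direction agrees with the raw detection-rate difference
        sig = out[out["significant"]]
        agree = (np.sign(sig["coef"]) == np.sign(sig["rate_treated"] - sig["rate_control"]))
        assert agree.mean() >= 0.99

    def test_identical_conditions_not_significant(self, rng):
        n = 200
        Y = pd.DataFrame({"g": rng.integers(0, 2, 2 * n)})
        cond = pd.Series(["control"] * n + ["treated"] * n)
        cov = pd.DataFrame({"n_umi": np.full(2 * n, 1000)})
        out = de_logistic(Y, cond, cov)
        assert out.iloc[0]["fdr"] > 0.05

    def test_separation_fallback_flagged(self):
        n = 50
        Y = pd.DataFrame({"g": [1] * n + [0] * n})
        cond = pd.Series(["treated"] * n + ["control"] * n)
        cov = pd.DataFrame({"n_umi": np.full(2 * n, 1000)})
        out = de_logistic(Y, cond, cov)
        assert out.iloc[0]["separation_fallback"]
        assert out.iloc[0]["p"] < 1e-10


class TestMotifEnrichment:
    def _table(self):
        peaks = [f"p{i}" for i in range(20)]
        occ = pd.DataFrame(0, index=peaks, columns=["m_enriched", "m_flat", "m_absent"])
        occ.loc[[f"p{i}" for i in range(8)], "m_enriched"] = 1  # all in foreground
        occ["m_flat"] = 1
        return occ

    def test_extreme_and_flat_motifs(self):
        occ = self._table()
        fg = {f"p{i}" for i in range(8)}
        bg = set(occ.index)
        out = motif_enrichment(fg, bg, occ).set_index("motif")
        assert "m_absent" not in out.index
        assert out.loc["m_enriched", "p"] < 1e-4
        assert out.loc["m_enriched", "odds_ratio"] > 100
        assert out.loc["m_flat", "p"] == pytest.approx(1.0)

    def test_matches_hypergeometric(self, rng):
        peaks = [f"p{i}" for i in range(20)]
        occ = pd.DataFrame({"m": rng.integers(0, 2, 20)}, index=peaks)
        fg = set(peaks[:7])
        bg = set(peaks)
        out = motif_enrichment(fg, bg, occ)
        a = int(occ.loc[sorted(fg), "m"].sum())
        n_fg, n_bg = 7, 13
        K = int(occ["m"].sum())
        # two-sided Fisher == sum of hypergeometric probabilities <= P(a)
        rv = hypergeom(n_fg + n_bg, K, n_fg)
        p_obs = rv.pmf(a)
        p_two = sum(rv.pmf(k) for k in range(max(0, K - n_bg), min(K, n_fg) + 1)
                    if rv.pmf(k) <= p_obs * (1 + 1e-9))
        assert out.iloc[0]["p"] == pytest.approx(p_two, rel=1e-6)


class TestSelectPerturbationRegions:
    def _fixture(self):
        genes = [
            GeneModel("up", GenomicInterval("chr1", 100_000, 105_000), "+"),
            GeneModel("flat", GenomicInterval("chr1", 500_000, 505_000), "+"),
        ]
        de = pd.DataFrame(
            [
                dict(gene_id="up", det_lfc=2.0, fdr=1e-6),
                dict(gene_id="flat", det_lfc=0.0, fdr=0.9),
            ]
        )
        peaks = [
            GenomicInterval("chr1", 95_100, 95_500),    # 9.5 kb away, depleted
            GenomicInterval("chr1", 80_000, 80_400),    # >10 kb away, depleted
            GenomicInterval("chr1", 96_000, 96_400),    # close, but not depleted
            GenomicInterval("chr1", 499_000, 499_400),  # close to non-DE gene
        ]
        lfc = pd.Series(
            {peaks[0].peak_id: -2.0, peaks[1].peak_id: -2.0,
             peaks[2].peak_id: -0.5, peaks[3].peak_id: -2.0}
        )
        return de, lfc, peaks, genes

    def test_window_and_lfc_rules(self):
        de, lfc, peaks, genes = self._fixture()
        selected = select_perturbation_regions(de, lfc, peaks, genes)
        assert selected == [peaks[0].peak_id]

    def test_survivor_count_matches_brute_force(self, rng):
        genes = [GeneModel(f"g{i}", GenomicInterval("chr1", s, s + 2_000), "+")
                 for i, s in enumerate(range(0, 400_000, 40_000))]
        de = pd.DataFrame(
            dict(gene_id=[g.gene_id for g in genes],
                 det_lfc=rng.uniform(-1, 3, len(genes)),
                 fdr=10.0 ** rng.uniform(-8, 0, len(genes)))
        )
        peaks = [GenomicInterval("chr1", int(s), int(s) + 300)
                 for s in rng.integers(0, 420_000, 80)]
        lfc = pd.Series(rng.uniform(-3, 1, 80), index=[p.peak_id for p in peaks])
        selected = set(select_perturbation_regions(de, lfc, peaks, genes))
        passing = {r.gene_id for r in de.itertuples() if r.fdr < 1e-4 and r.det_lfc > 1}
        expected = set()
        for p in peaks:
            if lfc[p.peak_id] >= -1:
                continue
            for g in genes:
                if g.gene_id in passing:
                    d = max(g.body.start - p.end, p.start - g.body.end, 0)
                    if d < 10_000:
                        expected.add(p.peak_id)
        assert selected == expected
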