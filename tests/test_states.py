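import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from scipy.stats import kstest

from epistate.genomic_io import GeneModel, GenomicInterval
from epistate.states import (
    binarize,
    bulk_peak_lfc,
    call_bivalent,
    call_switching,
    classify_locus,
    detection_rates,
    differential_peaks,
    gene_regulatory_census,
    region_embedding_build,
)
from epistate.synthetic import simulate_null_binary_peaks


class TestBinarize:
    def test_thresholds_at_zero(self):
        X = sp.csr_matrix(np.array([[3, 0], [1, 2]]))
        B = binarize(X).toarray()
        np.testing.assert_array_equal(B, [[1, 0], [1, 1]])

    def test_column_sums_count_detected_cells(self, rng):
        X = sp.csr_matrix(rng.integers(0, 3, (40, 10)))
        B = binarize(X)
        np.testing.assert_array_equal(
            np.asarray(B.sum(axis=0)).ravel(),
            (X.toarray() > 0).sum(axis=0),
        )


class TestDetectionRates:
    def test_quarter_rate(self):
        Y = np.array([[1], [0], [0], [0]])
        rates = detection_rates(Y, pd.Series([0, 0, 0, 0]))
        assert rates.iloc[0, 0] == 0.25

    def test_matches_groupby_oracle(self, rng):
        Y = rng.integers(0, 2, (60, 5))
        labels = pd.Series(rng.integers(0, 4, 60))
        rates = detection_rates(Y, labels)
        oracle = pd.DataFrame(Y).groupby(labels).mean()
        np.testing.assert_allclose(rates.to_numpy(), oracle.to_numpy(), atol=1e-12)
        assert ((rates >= 0) & (rates <= 1)).all().all()


class TestDifferentialPeaks:
    def test_strong_effect_detected_with_positive_sign(self, rng):
        n = 200
        y = np.concatenate([rng.random(n) < 0.9, rng.random(n) < 0.0]).astype(int)
        Y = pd.DataFrame({"pk": y})
        group = np.array(["A"] * n + ["B"] * n)
        frag = np.full(2 * n, 500)
        tab = differential_peaks(Y, group, frag)
        row_a = tab[(tab["peak_id"] == "pk") & (tab["group"] == "A")].iloc[0]
        assert row_a["fdr"] < 1e-6
        assert row_a["det_lfc"] > 0

    def test_null_calibration_and_uniformity(self):
        sim = simulate_null_binary_peaks(n_peaks=1000, n_cells=400, seed=0)
        tab = differential_peaks(sim["Y"], sim["group"], sim["n_fragments"])
        p = tab.drop_duplicates("peak_id")["p"].to_numpy()
        assert 0.03 <= (p < 0.05).mean() <= 0.07
        assert kstest(p, "uniform").pvalue > 0.01
        assert (tab[~tab["degenerate"]]["fdr"] < 0.05).mean() < 0.01

    def test_degenerate_peaks_reported_with_p_one(self):
        Y = pd.DataFrame({"all0": [0, 0, 0, 0], "all1": [1, 1, 1, 1], "ok": [1, 0, 1, 0]})
        tab = differential_peaks(Y, ["A", "A", "B", "B"], np.full(4, 100))
        assert set(tab["peak_id"]) == {"all0", "all1", "ok"}
        deg = tab[tab["peak_id"].isin(["all0", "all1"])]
        assert (deg["p"] == 1).all() and deg["degenerate"].all()

    def test_fdr_at_least_p(self):
        sim = simulate_null_binary_peaks(n_peaks=50, n_cells=100, seed=1)
        tab = differential_peaks(sim["Y"], sim["group"], sim["n_fragments"])
        assert (tab["fdr"] >= tab["p"] - 1e-12).all()
        assert tab["fdr"].between(0, 1).all()


def _interval(start, chrom="chr1", width=500):
    return GenomicInterval(chrom, start, start + width)


def _diff_table(entries, branches=("tel", "dien")):
    """entries: {peak_id: {branch: (lfc, fdr)}}; everything else null."""
    rows = []
    for pid, per_branch in entries.items():
        for b in branches:
            lfc, fdr = per_branch.get(b, (0.0, 1.0))
            rows.append(
                dict(peak_id=pid, group=b, effect=lfc, det_lfc=lfc,
                     p=min(fdr, 1.0), fdr=fdr, degenerate=False)
            )
    return pd.DataFrame(rows)


class TestBivalentCaller:
    def _rates(self, values):
        # single NE cluster "ne0"
        return pd.DataFrame(values, index=["ne0"])

    def test_co_detected_resolving_pair_called(self):
        me3 = [_interval(1000)]
        k4 = [_interval(1200)]
        me3_rates = self._rates({me3[0].peak_id: [0.4]})
        k4_rates = self._rates({k4[0].peak_id: [0.3]})
        me3_diff = _diff_table({me3[0].peak_id: {"tel": (-1.0, 1e-8)}})
        k4_diff = _diff_table({k4[0].peak_id: {"tel": (1.2, 1e-8)}})
        calls = call_bivalent(me3, k4, me3_rates, k4_rates, me3_diff, k4_diff, {"ne0"})
        assert len(calls) == 1
        assert calls.iloc[0]["resolution_tel"] == "activated"
        assert calls.iloc[0]["resolution_dien"] == "stays_bivalent"

    def test_low_ne_detection_excluded(self):
        me3 = [_interval(1000)]
        k4 = [_interval(1200)]
        me3_rates = self._rates({me3[0].peak_id: [0.04]})  # not more than 5%
        k4_rates = self._rates({k4[0].peak_id: [0.3]})
        me3_diff = _diff_table({me3[0].peak_id: {"tel": (-1.0, 1e-8)}})
        k4_diff = _diff_table({k4[0].peak_id: {"tel": (1.2, 1e-8)}})
        calls = call_bivalent(me3, k4, me3_rates, k4_rates, me3_diff, k4_diff, {"ne0"})
        assert len(calls) == 0

    def test_same_sign_differential_excluded(self):
        me3 = [_interval(1000)]
        k4 = [_interval(1200)]
        me3_rates = self._rates({me3[0].peak_id: [0.4]})
        k4_rates = self._rates({k4[0].peak_id: [0.3]})
        me3_diff = _diff_table({me3[0].peak_id: {"tel": (1.0, 1e-8)}})
        k4_diff = _diff_table({k4[0].peak_id: {"tel": (1.2, 1e-8)}})
        calls = call_bivalent(me3, k4, me3_rates, k4_rates, me3_diff, k4_diff, {"ne0"})
        assert len(calls) == 0

    def test_non_overlapping_peaks_never_paired(self):
        me3 = [_interval(1000)]
        k4 = [_interval(10_000)]  # > 2x2kb away
        me3_rates = self._rates({me3[0].peak_id: [0.4]})
        k4_rates = self._rates({k4[0].peak_id: [0.3]})
        me3_diff = _diff_table({me3[0].peak_id: {"tel": (-1.0, 1e-8)}})
        k4_diff = _diff_table({k4[0].peak_id: {"tel": (1.2, 1e-8)}})
        calls = call_bivalent(me3, k4, me3_rates, k4_rates, me3_diff, k4_diff, {"ne0"})
        assert len(calls) == 0


class TestSwitchingCaller:
    def _setup(self, me3_ne, ac_ne, me3_branch=(-1.0, 1e-8), ac_branch=(1.2, 1e-8)):
        me3 = [_interval(1000)]
        ac = [_interval(1200)]
        me3_rates = pd.DataFrame({me3[0].peak_id: [me3_ne]}, index=["ne0"])
        ac_rates = pd.DataFrame({ac[0].peak_id: [ac_ne]}, index=["ne0"])
        me3_diff = _diff_table({me3[0].peak_id: {"tel": me3_branch}})
        ac_diff = _diff_table({ac[0].peak_id: {"tel": ac_branch}})
        return call_switching(me3, ac, me3_rates, ac_rates, me3_diff, ac_diff, {"ne0"})

    def test_me3_to_ac_switch_called_with_branch(self):
        calls = self._setup(me3_ne=0.4, ac_ne=0.01)
        assert len(calls) == 1
        assert calls.iloc[0]["branch"] == "tel"
        assert calls.iloc[0]["direction"] == "me3_to_ac"

    def test_both_marks_at_ne_excluded(self):
        assert len(self._setup(me3_ne=0.4, ac_ne=0.3)) == 0

    def test_no_branch_activation_excluded(self):
        calls = self._setup(me3_ne=0.4, ac_ne=0.01, ac_branch=(0.0, 1.0))
        assert len(calls) == 0


class TestRecoveryFromPlantedTruth:
    def test_bivalent_and_switching_precision_recall(self, domain_results):
        assert domain_results["bivalent_score"]["precision"] >= 0.9
        assert domain_results["bivalent_score"]["recall"] >= 0.9
        assert domain_results["switching_score"]["precision"] >= 0.9
        assert domain_results["switching_score"]["recall"] >= 0.9

    def test_callers_disjoint_on_same_pair(self, domain_results):
        biv = domain_results["bivalent"]
        swi = domain_results["switching"]
        biv_me3 = set(biv["me3_peak"]) if len(biv) else set()
        swi_me3 = set(swi["me3_peak"]) if len(swi) else set()
        assert not (biv_me3 & swi_me3)


class TestClassifyLocus:
    GENES = [GeneModel("g", GenomicInterval("chr1", 10_000, 14_000), "+")]

    @pytest.mark.parametrize(
        "start,expected",
        [
            (9_998, "promoter"),     # 1 bp from the TSS at 10,000
            (19_000, "distal"),      # 5 kb beyond the gene body end
            (16_500, "other"),       # 2.5 kb from the body, > 2 kb from TSS
            (11_000, "promoter"),    # overlapping the TSS region
        ],
    )
    def test_rule(self, start, expected):
        got = classify_locus([_interval(start, width=100)], self.GENES)
        assert got.iloc[0] == expected


class TestRegionEmbedding:
    def _rates(self, rng, peaks, values):
        return pd.DataFrame(values, index=[f"cl{i}" for i in range(60)],
                            columns=[p.peak_id for p in peaks])

    def test_cluster_count_and_rate_filters(self, rng):
        peaks = [_interval(s) for s in (1_000, 20_000, 40_000)]
        vals = np.zeros((60, 3))
        vals[:55, 0] = 0.2     # survives: 55 clusters, max 0.2
        vals[:40, 1] = 0.2     # filtered: only 40 clusters
        vals[:55, 2] = 0.08    # filtered: max rate below 0.10
        rates = {"H3K4me3": self._rates(rng, peaks, vals)}
        emb = region_embedding_build(
            {"H3K4me3": rates["H3K4me3"]}, {"H3K4me3": peaks},
            n_pcs=2, resolution=1.0, seed=0,
        )
        assert emb.regions == [peaks[0].peak_id]
        assert emb.peak_class.iloc[0] == "H3K4me3"

    def test_cross_modality_merge_and_class(self, rng):
        k4 = [_interval(1_000)]
        me3 = [_interval(1_200)]
        vals = np.full((60, 1), 0.3)
        emb = region_embedding_build(
            {"H3K4me3": self._rates(rng, k4, vals), "H3K27me3": self._rates(rng, me3, vals)},
            {"H3K4me3": k4, "H3K27me3": me3},
            n_pcs=2, resolution=1.0, seed=0,
        )
        assert len(emb.regions) == 1
        assert emb.peak_class.iloc[0] == "H3K27me3+H3K4me3"

    def test_no_survivors_errors(self, rng):
        peaks = [_interval(1_000)]
        vals = np.zeros((60, 1))
        with pytest.raises(ValueError):
            region_embedding_build(
                {"H3K4me3": self._rates(rng, peaks, vals)}, {"H3K4me3": peaks}, seed=0
            )


class TestCensus:
    def test_rule_table(self):
        idx = ["gA", "gB", "gC", "gD"]
        zeros = pd.DataFrame(0.0, index=idx, columns=["c0", "c1"])
        k4 = zeros.copy(); k4.loc["gA", "c0"] = 0.3; k4.loc["gB", "c0"] = 0.3
        me3 = zeros.copy(); me3.loc["gA", "c1"] = 0.3; me3.loc["gC", "c1"] = 0.3
        classes, fractions = gene_regulatory_census({"H3K4me3": k4, "H3K27me3": me3})
        assert classes["gA"] == "active_and_repressed"
        assert classes["gB"] == "always_active"
        assert classes["gC"] == "inactive_and_repressed"
        assert classes["gD"] == "inactive_unmarked"
        assert fractions["inactive_unmarked"] == 0.25

    def test_synthetic_census_matches_planted_design(self, dataset):
        # detection-based census over true states recovers the planted classes
        truth = dataset.truth.cells.set_index("cell_id")
        detection = {}
        for modality in ("RNA", "H3K27ac", "H3K4me3", "H3K27me3"):
            cm = dataset.counts[modality]
            states = truth.loc[cm.cell_ids, "state"]
            Y = (cm.values > 0).astype(float)
            rates = pd.DataFrame(
                {s: np.asarray(Y[(states == s).to_numpy()].mean(axis=0)).ravel()
                 for s in states.unique()},
                index=cm.feature_ids,
            )
            if modality != "RNA":
                # aggregate peak detection to genes by promoter proximity
                from epistate.genomic_io import intersect_intervals, parse_peak_id

                peaks = [parse_peak_id(p) for p in cm.feature_ids]
                windows = [g.activity_window(2_000) for g in dataset.genes]
                pairs = intersect_intervals(peaks, windows, slop=0)
                per_gene = {}
                for i, j in pairs:
                    gid = dataset.genes[j].gene_id
                    row = rates.iloc[i]
                    per_gene[gid] = np.maximum(per_gene.get(gid, 0.0), row.to_numpy())
                rates = pd.DataFrame(per_gene, index=rates.columns).T
            else:
                rates.index = [g.gene_id for g in dataset.genes]
            detection[modality] = rates
        classes, fractions = gene_regulatory_census(detection)
        planted = dataset.truth.gene_classes.set_index("gene_id")["census_class"]
        planted_frac = planted.value_counts(normalize=True)
        for cls in planted_frac.index:
            assert abs(fractions.get(cls, 0.0) - planted_frac[cls]) <= 0.02


class TestBulkLfc:
    def _design(self):
        return pd.DataFrame(
            dict(condition=["control", "control", "treated", "treated"],
                 concentration=[0, 0, 1, 1]),
            index=["s1", "s2", "s3", "s4"],
        )

    def test_equal_intensity_gives_zero(self):
        intensity = pd.DataFrame(np.full((5, 4), 7.0), columns=["s1", "s2", "s3", "s4"])
        lfc = bulk_peak_lfc(intensity, self._design())
        np.testing.assert_allclose(lfc.to_numpy(), 0.0, atol=1e-12)

    def test_fourfold_gives_two(self):
        intensity = pd.DataFrame(
            dict(s1=[3.0], s2=[3.0], s3=[15.0], s4=[15.0])
        )
        lfc = bulk_peak_lfc(intensity, self._design())
        assert lfc.iloc[0, 0] == pytest.approx(2.0)

    def test_matches_direct_recomputation(self, rng):
        intensity = pd.DataFrame(rng.uniform(1, 10, (8, 4)), columns=["s1", "s2", "s3", "s4"])
        design = self._design()
        lfc = bulk_peak_lfc(intensity, design)
        ctrl = intensity[["s1", "s2"]].mean(axis=1)
        expected = (np.log2((intensity["s3"] + 1) / (ctrl + 1))
                    + np.log2((intensity["s4"] + 1) / (ctrl + 1))) / 2
        np.testing.assert_allclose(lfc[1].to_numpy(), expected.to_numpy(), atol=1e-12)

    def test_missing_control_errors(self):
        design = pd.DataFrame(dict(condition=["treated"], concentration=[1]), index=["s1"])
        with pytest.raises(ValueError):
            bulk_peak_lfc(pd.DataFrame(dict(s1=[1.0])), design)
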