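"""Nearest-TSS linkage and the coupling statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from enhdyn.core_io import GeneModel, GenomicInterval
from enhdyn.linkage import (
    category_expression_test,
    distance_filter,
    enhancer_burden_fit,
    enhancer_loss_binning,
    gene_centric_acetylation_fc,
    nearest_tss,
    permutation_control_test,
)


def _gene(gid, chrom, tss, strand="+"):
    if strand == "+":
        return GeneModel(gid, GenomicInterval(chrom, tss, tss + 1000, strand="+"))
    return GeneModel(gid, GenomicInterval(chrom, max(0, tss - 999), tss + 1, strand="-"))


class TestNearestTss:
    def test_midpoint_at_tss_distance_zero(self):
        genes = [_gene("g1", "chr1", 5_000)]
        link = nearest_tss([GenomicInterval("chr1", 4_950, 5_050)], genes)
        assert link.iloc[0]["gene_id"] == "g1"
        assert link.iloc[0]["distance"] == 0

    def test_tie_breaks_to_lower_tss(self):
        genes = [_gene("g_high", "chr1", 200), _gene("g_low", "chr1", 100)]
        link = nearest_tss([GenomicInterval("chr1", 100, 200)], genes)  # mid 150
        assert link.iloc[0]["gene_id"] == "g_low"

    def test_equal_tss_tie_breaks_lexicographic(self):
        genes = [_gene("gB", "chr1", 100), _gene("gA", "chr1", 101, strand="-")]
        # midpoint 150: distances 50 and 49 -> gA; make them equal instead
        genes = [_gene("gB", "chr1", 100), _gene("gA", "chr1", 100, strand="-")]
        link = nearest_tss([GenomicInterval("chr1", 100, 200)], genes)
        assert link.iloc[0]["gene_id"] == "gA"

    def test_empty_gene_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            nearest_tss([GenomicInterval("chr1", 0, 10)], [])

    def test_peak_without_same_chrom_gene_dropped_with_warning(self):
        genes = [_gene("g1", "chr1", 100)]
        with pytest.warns(UserWarning, match="dropped"):
            link = nearest_tss([GenomicInterval("chr2", 0, 10)], genes)
        assert len(link) == 0

    def test_matches_brute_force(self, rng):
        genes = [
            _gene(f"g{i}", f"chr{rng.integers(1, 3)}", int(rng.integers(0, 100_000)))
            for i in range(100)
        ]
        peaks = [
            GenomicInterval(
                f"chr{rng.integers(1, 3)}", int(s), int(s) + int(rng.integers(100, 2000))
            )
            for s in rng.integers(0, 100_000, 500)
        ]
        link = nearest_tss(peaks, genes)
        for i, iv in enumerate(peaks):
            mid = iv.midpoint
            cands = [
                (abs(mid - g.tss), g.tss, g.gene_id)
                for g in genes
                if g.chrom == iv.chrom
            ]
            expected = min(cands)[2]
            assert link.loc[i, "gene_id"] == expected

    def test_every_peak_linked_once(self, sim):
        truth, genes = sim["truth"], sim["genes"]
        peaks = [
            GenomicInterval(r["chrom"], r["start"], r["end"], name=eid)
            for eid, r in truth.iterrows()
        ]
        link = nearest_tss(peaks, genes)
        assert len(link) == len(peaks)
        assert link.groupby("gene_id").size().sum() == len(peaks)

    def test_generator_truth_linkage_is_nearest_tss(self, sim):
        truth, genes = sim["truth"], sim["genes"]
        peaks = [
            GenomicInterval(r["chrom"], r["start"], r["end"], name=eid)
            for eid, r in truth.iterrows()
        ]
        link = nearest_tss(peaks, genes)
        assert (link["gene_id"] == truth["gene_id"].reindex(link.index)).all()


class TestDistanceFilter:
    def test_boundary(self):
        link = pd.DataFrame(
            {"gene_id": ["a", "b", "c"], "distance": [0, 10_000, -10_001]},
            index=["p0", "p1", "p2"],
        )
        out = distance_filter(link)
        assert list(out.index) == ["p0", "p1"]

    def test_matches_scan_oracle(self, rng):
        d = rng.integers(-50_000, 50_000, 300)
        link = pd.DataFrame({"gene_id": "g", "distance": d})
        out = distance_filter(link, max_bp=10_000)
        assert len(out) == int(np.sum(np.abs(d) <= 10_000))


class TestCategoryExpressionTest:
    def _setup(self, shift):
        rng = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(40)]
        base = rng.normal(5, 1, 40)
        expr = pd.DataFrame(
            {"WT": base, "KO": base + shift + rng.normal(0, 0.05, 40)}, index=genes
        )
        link = pd.DataFrame(
            {"gene_id": genes, "distance": 0}, index=[f"p{i}" for i in range(40)]
        )
        cats = pd.Series(["catA"] * 40, index=link.index)
        return link, expr, cats

    def test_identical_paired_vectors_p_one(self):
        link, expr, cats = self._setup(0.0)
        expr["KO"] = expr["WT"]
        res = category_expression_test(link, expr, cats, [("WT", "KO")])
        assert res.iloc[0]["pvalue"] == 1.0

    def test_consistent_shift_detected(self):
        link, expr, cats = self._setup(-1.0)
        res = category_expression_test(link, expr, cats, [("WT", "KO")])
        assert res.iloc[0]["pvalue"] < 1e-4
        assert res.iloc[0]["median_diff"] == pytest.approx(-1.0, abs=0.1)

    def test_duplicate_gene_links_count_once(self):
        link, expr, cats = self._setup(-1.0)
        link2 = pd.concat([link, link.set_axis([f"q{i}" for i in range(40)])])
        cats2 = pd.Series(["catA"] * 80, index=link2.index)
        r1 = category_expression_test(link, expr, cats, [("WT", "KO")])
        r2 = category_expression_test(link2, expr, cats2, [("WT", "KO")])
        assert r1.iloc[0]["n_genes"] == r2.iloc[0]["n_genes"] == 40

    def test_small_category_skipped_with_warning(self):
        link, expr, cats = self._setup(0.0)
        cats.iloc[3:] = "catB"
        with pytest.warns(UserWarning, match="skipped"):
            res = category_expression_test(link, expr, cats, [("WT", "KO")])
        assert set(res["category"]) == {"catB"}


class TestPermutationControlTest:
    def test_exhaustive_enumeration_oracle(self):
        # all genes {1,2,3,4}, state {3,4}: independent complete enumeration
        allv = np.array([1.0, 2.0, 3.0, 4.0])
        state = np.array([3.0, 4.0])

        def u_dev(x):
            u = stats.mannwhitneyu(x, allv, alternative="two-sided").statistic
            return abs(u - len(x) * len(allv) / 2)

        obs = u_dev(state)
        devs = [u_dev(allv[list(c)]) for c in itertools.combinations(range(4), 2)]
        expected = np.mean([d >= obs - 1e-12 for d in devs])
        with pytest.warns(UserWarning, match="coarse"):
            p = permutation_control_test(state, allv, n_perm=1000, seed=0)
        assert p == expected == pytest.approx(1 / 3)

    def test_state_equal_to_typical_draw_p_one(self):
        allv = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        state = np.array([1.0, 3.0, 5.0])  # U deviation 1.5; several draws tie
        p = permutation_control_test(state, allv, n_perm=1000, seed=0)
        assert p > 0.5
        # zero-deviation state set gives p = 1 by symmetry of the two-sided rule
        state2 = np.array([2.0, 3.5, 5.0])
        allv2 = np.array([1.0, 2.0, 3.0, 3.5, 5.0, 6.0, 7.0])
        assert (
            permutation_control_test(state2, allv2, n_perm=2000, seed=0) > 0.5
        )

    def test_not_subset_rejected(self):
        with pytest.raises(ValueError, match="subset"):
            permutation_control_test(
                np.array([9.0, 9.0, 9.0]), np.array([1.0, 2.0, 3.0, 4.0])
            )

    def test_minimum_state_size(self):
        with pytest.raises(ValueError):
            permutation_control_test(np.array([1.0]), np.array([1.0, 2.0, 3.0]))

    def test_invariant_to_constant_shift(self, rng):
        allv = rng.normal(0, 1, 60)
        state = allv[:8].copy()
        p1 = permutation_control_test(state, allv, n_perm=300, seed=4)
        p2 = permutation_control_test(state + 100, allv + 100, n_perm=300, seed=4)
        assert p1 == p2

    def test_null_calibration(self, rng):
        # state sets drawn uniformly from the control: p should be ~uniform
        allv = rng.normal(0, 1, 120)
        hits = 0
        n_rep = 200
        for rep in range(n_rep):
            idx = rng.choice(120, size=10, replace=False)
            p = permutation_control_test(allv[idx], allv, n_perm=200, seed=rep)
            hits += p < 0.05
        assert 0.01 <= hits / n_rep <= 0.10


class TestEnhancerBurdenFit:
    def test_two_points_define_the_line(self):
        fit = enhancer_burden_fit(np.array([0, 4]), np.array([0.0, -2.0]))
        assert fit["slope"] == pytest.approx(-0.5)
        assert fit["intercept"] == pytest.approx(0.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            enhancer_burden_fit(np.array([2, 2, 2]), np.array([1.0, 2.0, 3.0]))

    def test_null_slope_ci_contains_zero(self, rng):
        x = rng.integers(0, 5, 300)
        y = rng.normal(0, 1, 300)
        fit = enhancer_burden_fit(x, y)
        assert fit["ci_low"] <= 0 <= fit["ci_high"]

    def test_planted_slope_recovered(self, rng):
        x = rng.integers(0, 5, 400)
        y = -0.5 * x + rng.normal(0, 0.3, 400)
        fit = enhancer_burden_fit(x, y)
        assert fit["ci_low"] <= -0.5 <= fit["ci_high"]


class TestEnhancerLossBinning:
    def test_bin_arithmetic(self):
        pct = np.array([0.0, 50.0, 10.0, 80.0, 100.0])
        lfc = np.zeros(5)
        out = enhancer_loss_binning(pct, lfc)
        assert out.loc["0", "n"] == 1
        assert out.loc["(25,50]", "n"] == 1  # 2 of 4 dependent = 50% -> (25,50]
        assert out.loc["(0,25]", "n"] == 1
        assert out.loc["(75,100]", "n"] == 2

    def test_monotone_medians_under_full_coupling(self, rng):
        pct = rng.choice([0, 20, 40, 60, 90], 500).astype(float)
        lfc = -0.02 * pct + rng.normal(0, 0.3, 500)
        out = enhancer_loss_binning(pct, lfc)
        med = out["median"].to_numpy()
        assert np.all(np.diff(med) < 0)
        assert (out["fdr"].dropna() < 0.05).all()


class TestGeneCentricAcetylationFc:
    def _classes(self):
        return pd.DataFrame(
            {
                "transition": ["formative"] * 4,
                "mll34": ["dependent", "dependent", "independent", "independent"],
            },
            index=["g1", "g2", "g3", "g4"],
        )

    def test_zero_fc_for_equal_densities(self):
        link = pd.DataFrame(
            {"gene_id": ["g1", "g3"], "distance": 0}, index=["p1", "p2"]
        )
        fc = pd.Series([0.0, 0.0], index=["p1", "p2"])
        out = gene_centric_acetylation_fc(self._classes(), link, fc)
        assert out["dependent_median"] == 0.0

    def test_planted_shift_between_classes(self, rng):
        peaks = [f"p{i}" for i in range(200)]
        gene = np.where(np.arange(200) < 100, "g1", "g3")
        link = pd.DataFrame({"gene_id": gene, "distance": 0}, index=peaks)
        fc = pd.Series(
            np.where(np.arange(200) < 100, -2.0, 0.0) + rng.normal(0, 0.1, 200),
            index=peaks,
        )
        out = gene_centric_acetylation_fc(self._classes(), link, fc)
        assert out["dependent_median"] < out["independent_median"] - 1.5
        assert out["pvalue"] < 1e-10

    def test_membership_filter_does_not_change_values(self, rng):
        peaks = [f"p{i}" for i in range(50)]
        link = pd.DataFrame(
            {"gene_id": ["g1"] * 25 + ["g3"] * 25,
             "distance": rng.integers(-20_000, 20_000, 50)},
            index=peaks,
        )
        fc = pd.Series(rng.normal(0, 1, 50), index=peaks)
        full = gene_centric_acetylation_fc(self._classes(), link, fc)
        near = gene_centric_acetylation_fc(
            self._classes(), distance_filter(link, 10_000), fc
        )
        # restricting changes membership only, never any retained value
        assert set(near["distributions"]["dependent"]) <= set(
            full["distributions"]["dependent"]
        )
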