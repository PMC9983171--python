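"""Quantification, TMM, BH and the differential tests against straight-line
oracle implementations."""

import numpy as np
import pandas as pd
import pytest

from enhdyn.core_io import GenomicInterval, SignalTrack
from enhdyn.diffquant import (
    CountMatrix,
    bh_adjust,
    count_in_peaks,
    cpm_filter,
    differential_test,
    log2cpm_density,
    tmm_factors,
    union_peaks,
)


def _cm(counts: np.ndarray, lib=None) -> CountMatrix:
    df = pd.DataFrame(
        counts,
        index=[f"f{i}" for i in range(counts.shape[0])],
        columns=[f"s{j}" for j in range(counts.shape[1])],
    )
    lib_series = None if lib is None else pd.Series(lib, index=df.columns, dtype=float)
    return CountMatrix(df, lib_size=lib_series)


class TestUnionPeaks:
    def test_overlap_merges(self):
        out = union_peaks(
            [[GenomicInterval("chr1", 0, 100)], [GenomicInterval("chr1", 50, 150)]]
        )
        assert [(iv.start, iv.end) for iv in out] == [(0, 150)]

    def test_bookended_merge_and_disjoint_sorted(self):
        out = union_peaks(
            [
                [GenomicInterval("chr1", 100, 200), GenomicInterval("chr1", 400, 500)],
                [GenomicInterval("chr1", 200, 300), GenomicInterval("chr2", 0, 10)],
            ]
        )
        assert [(iv.chrom, iv.start, iv.end) for iv in out] == [
            ("chr1", 100, 300),
            ("chr1", 400, 500),
            ("chr2", 0, 10),
        ]

    def test_matches_boolean_mask_oracle(self, rng):
        ivs = [
            GenomicInterval("chr1", int(s), int(s) + int(w))
            for s, w in zip(rng.integers(0, 9_000, 80), rng.integers(1, 500, 80))
        ]
        mask = np.zeros(10_000, dtype=bool)
        for iv in ivs:
            mask[iv.start : iv.end] = True
        merged = union_peaks([ivs])
        got = np.zeros(10_000, dtype=bool)
        for iv in merged:
            # merged intervals must be disjoint and non-adjacent
            assert not got[max(0, iv.start - 1) : iv.end].any()
            got[iv.start : iv.end] = True
        assert np.array_equal(got, mask)


class TestCountInPeaks:
    def test_zero_track_and_contained_block(self):
        peaks = [GenomicInterval("chr1", 0, 100), GenomicInterval("chr1", 200, 300)]
        assert list(count_in_peaks(SignalTrack.empty(), peaks)) == [0, 0]
        track = SignalTrack.from_records([("chr1", 10, 20, 3.0)])
        assert list(count_in_peaks(track, peaks)) == [30, 0]

    def test_overlapping_peaks_rejected(self):
        track = SignalTrack.from_records([("chr1", 0, 10, 1.0)])
        with pytest.raises(ValueError, match="overlap"):
            count_in_peaks(
                track,
                [GenomicInterval("chr1", 0, 50), GenomicInterval("chr1", 40, 80)],
            )

    def test_matches_per_base_summation_oracle(self, rng):
        base = np.zeros(5_000)
        records = []
        pos = 0
        while pos < 4_900:
            pos += int(rng.integers(1, 40))
            w = int(rng.integers(1, 30))
            v = float(rng.uniform(0.5, 4.0))
            records.append(("chr1", pos, min(pos + w, 5_000), v))
            base[pos : pos + w] = v
            pos += w
        track = SignalTrack.from_records(records)
        peaks, cursor = [], 0
        while cursor < 4_800:
            cursor += int(rng.integers(10, 100))
            end = cursor + int(rng.integers(10, 150))
            peaks.append(GenomicInterval("chr1", cursor, min(end, 5_000)))
            cursor = end + 1
        got = count_in_peaks(track, peaks)
        expected = [round(base[p.start : p.end].sum()) for p in peaks]
        assert list(got) == expected


class TestCpmFilter:
    def test_all_zero_feature_removed(self):
        m = _cm(np.array([[0, 0, 0], [10, 10, 10]]))
        out = cpm_filter(m, min_cpm=1, min_samples=2)
        assert list(out.counts.index) == ["f1"]

    def test_boundary_two_of_six_kept(self):
        # feature with CPM 2.0 in exactly 2 of 6 samples is kept
        lib = [1e6] * 6
        counts = np.zeros((2, 6), dtype=int)
        counts[0] = [2, 2, 0, 0, 0, 0]
        counts[1] = [1, 0, 0, 0, 0, 0]  # CPM 1.0 not > 1, and only 1 sample
        m = _cm(counts, lib=lib)
        out = cpm_filter(m, min_cpm=1, min_samples=2)
        assert list(out.counts.index) == ["f0"]

    def test_library_sizes_fixed_at_load(self):
        m = _cm(np.array([[5, 5], [100, 200]]))
        out = cpm_filter(m, min_cpm=1e6, min_samples=1)  # removes everything
        pd.testing.assert_series_equal(out.lib_size, m.lib_size)

    def test_matches_double_loop_oracle(self, rng):
        counts = rng.integers(0, 50, size=(200, 6))
        lib = counts.sum(axis=0).astype(float)
        m = _cm(counts)
        out = cpm_filter(m, min_cpm=1, min_samples=2)
        survivors = 0
        for i in range(200):
            n_pass = 0
            for j in range(6):
                if counts[i, j] / lib[j] * 1e6 > 1:
                    n_pass += 1
            if n_pass >= 2:
                survivors += 1
        assert len(out.counts) == survivors


def _tmm_pair_oracle(obs, ref, lo, lr):
    """Independent straight-line trimmed weighted mean of M-values."""
    keep = (obs > 0) & (ref > 0)
    o, r = obs[keep] / lo, ref[keep] / lr
    M = np.log2(o / r)
    A = 0.5 * np.log2(o * r)
    w = (lo - obs[keep]) / (lo * obs[keep]) + (lr - ref[keep]) / (lr * ref[keep])
    n = len(M)
    lo_m, hi_m = np.floor(n * 0.3) + 1, n - np.floor(n * 0.3)
    lo_a, hi_a = np.floor(n * 0.05) + 1, n - np.floor(n * 0.05)
    rm = pd.Series(M).rank().to_numpy()
    ra = pd.Series(A).rank().to_numpy()
    sel = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    return 2 ** (np.sum(M[sel] / w[sel]) / np.sum(1.0 / w[sel]))


class TestTmmFactors:
    def test_pure_depth_difference_gives_unit_factors(self, rng):
        c1 = rng.integers(10, 1000, size=500)
        m = _cm(np.column_stack([c1, 2 * c1]))
        f = tmm_factors(m)
        assert np.allclose(f, 1.0, atol=1e-9)

    def test_identical_columns_give_unit_factors(self, rng):
        c = rng.integers(1, 500, size=300)
        m = _cm(np.column_stack([c, c, c]))
        assert np.allclose(tmm_factors(m), 1.0, atol=1e-12)

    def test_matches_hand_rolled_trimmed_mean_oracle(self, rng):
        # 10% of features 4-fold up in sample 2, the rest equal
        base = rng.integers(50, 2000, size=400).astype(float)
        s2 = base.copy()
        s2[:40] *= 4
        counts = np.column_stack([base, s2])
        m = _cm(counts)
        lib = m.lib_size.to_numpy()
        f = tmm_factors(m, ref_sample="s0")
        expected = _tmm_pair_oracle(s2, base, lib[1], lib[0])
        # factors are geometric-mean normalized; compare the ratio
        assert f["s1"] / f["s0"] == pytest.approx(expected, abs=1e-6)

    def test_all_zero_sample_rejected(self):
        m = _cm(np.array([[0, 5], [0, 5]]))
        with pytest.raises(ValueError, match="all-zero"):
            tmm_factors(m)

    def test_invariant_to_scaling_one_sample(self, rng):
        # depth differences are absorbed by the library size; the delta-method
        # precision weights retain a weak depth dependence, so the invariance
        # is approximate rather than exact
        counts = rng.integers(1, 300, size=(200, 3)).astype(float)
        f1 = tmm_factors(_cm(counts))
        counts2 = counts.copy()
        counts2[:, 1] *= 10
        f2 = tmm_factors(_cm(counts2))
        assert np.allclose(f1, f2, atol=0.03)


class TestLog2CpmDensity:
    def test_zero_count_gives_zero(self):
        assert log2cpm_density(0, 1e6, 500) == 0.0

    def test_one_cpm_closed_form(self):
        # count/library = 1e-6 (1 CPM), width 1000 -> log2(2)/1000 = 0.001
        assert log2cpm_density(1.0, 1e6, 1000) == pytest.approx(0.001, abs=1e-15)

    def test_matches_formula_oracle(self, rng):
        for _ in range(200):
            c = float(rng.integers(0, 10_000))
            lib = float(rng.integers(10_000, 10_000_000))
            w = float(rng.integers(1, 5_000))
            expected = np.log2(c / lib * 1e6 + 1.0) / w
            assert log2cpm_density(c, lib, w) == pytest.approx(expected, abs=1e-12)

    def test_nonpositive_width_rejected(self):
        with pytest.raises(ValueError):
            log2cpm_density(1, 1e6, 0)


class TestBhAdjust:
    def test_hand_evaluated_example(self):
        assert np.allclose(bh_adjust(np.array([0.01, 0.02, 0.03])), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust(np.array([0.42]))[0] == 0.42

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust(np.array([0.5, 1.2]))

    def test_matches_step_up_oracle_and_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(100):
            p = rng.random(int(rng.integers(1, 40)))
            q = bh_adjust(p)
            # brute-force step-up oracle
            m = len(p)
            order = np.argsort(p)
            expected = np.empty(m)
            for rank, idx in enumerate(order, start=1):
                expected[idx] = min(
                    min(p[j] * m / (list(order).index(j) + 1) for j in order[rank - 1 :]),
                    1.0,
                )
            assert np.allclose(q, expected)
            assert np.allclose(q, multipletests(p, method="fdr_bh")[1])
            assert (q >= p - 1e-15).all()


class TestDifferentialTest:
    def test_equal_counts_equal_libraries_zero_lfc(self):
        m = _cm(np.array([[10, 10, 10, 10], [50, 50, 50, 50]]), lib=[1e5] * 4)
        res = differential_test(m, ["s0", "s1"], ["s2", "s3"], method="permutation")
        assert np.allclose(res["log2fc"], 0.0)

    def test_group_swap_negates_lfc_keeps_p(self, rng):
        counts = rng.integers(5, 500, size=(100, 4))
        m = _cm(counts)
        a, b = ["s0", "s1"], ["s2", "s3"]
        r1 = differential_test(m, a, b, method="nb_wald")
        r2 = differential_test(m, b, a, method="nb_wald")
        assert np.allclose(r1["log2fc"], -r2["log2fc"], atol=1e-9)
        assert np.allclose(r1["pvalue"], r2["pvalue"], atol=1e-9)

    def test_permutation_symmetry(self, rng):
        counts = rng.integers(5, 500, size=(50, 6))
        m = _cm(counts)
        a, b = ["s0", "s1", "s2"], ["s3", "s4", "s5"]
        r1 = differential_test(m, a, b, method="permutation", seed=3)
        r2 = differential_test(m, b, a, method="permutation", seed=3)
        assert np.allclose(r1["pvalue"], r2["pvalue"])

    def test_fdr_at_least_pvalue(self, rng):
        counts = rng.integers(0, 300, size=(200, 4))
        m = _cm(counts)
        res = differential_test(m, ["s0", "s1"], ["s2", "s3"], method="nb_wald")
        assert (res["fdr"] >= res["pvalue"] - 1e-12).all()

    def test_nb_wald_needs_replicates(self):
        m = _cm(np.array([[1, 2], [3, 4]]))
        with pytest.raises(ValueError, match="permutation"):
            differential_test(m, ["s0"], ["s1"], method="nb_wald")

    def test_planted_fold_change_recovered(self, rng):
        # 4-fold planted change at high depth: lfc = 2 +/- 0.2, FDR < 0.05
        n_feat = 400
        mu = rng.lognormal(np.log(500), 0.5, n_feat)
        planted = np.zeros(n_feat, dtype=bool)
        planted[:40] = True
        r = 1 / 0.02
        mu_b = mu * np.where(planted, 4.0, 1.0)
        counts = np.column_stack(
            [rng.negative_binomial(r, r / (r + mu), size=n_feat) for _ in range(3)]
            + [rng.negative_binomial(r, r / (r + mu_b), size=n_feat) for _ in range(3)]
        )
        m = _cm(counts, lib=[1e6] * 6)
        res = differential_test(
            m, ["s0", "s1", "s2"], ["s3", "s4", "s5"], method="nb_wald"
        )
        lfc = res["log2fc"][planted]
        assert np.median(np.abs(lfc - 2.0)) < 0.2
        assert (res["fdr"][planted] < 0.05).mean() >= 0.95
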