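"""Weir-Cockerham theta, heterozygosity, windowing, and the dual outlier test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from divscan.data import GenotypeMatrix, LineAssignment, SnpMap
from divscan.fst import (FstScanConfig, expected_het, flag_fst_candidates,
                         nei_chesser_gst, snp_fst_table, wc_theta)
from divscan.windows import window_average


def wc_theta_oracle(n_i, p_i):
    """Independently coded Weir-Cockerham variance components for r pops.

    Written from the general r-population formulas (n_i diploids, sample
    frequencies p_i, HWE-expected heterozygosities), looping over pops.
    """
    r = len(n_i)
    nbar = sum(n_i) / r
    pbar = sum(n * p for n, p in zip(n_i, p_i)) / (r * nbar)
    s2 = sum(n * (p - pbar) ** 2 for n, p in zip(n_i, p_i)) / ((r - 1) * nbar)
    nc = (r * nbar - sum(n * n for n in n_i) / (r * nbar)) / (r - 1)
    hbar = sum(n * 2 * p * (1 - p) for n, p in zip(n_i, p_i)) / (r * nbar)
    a = (nbar / nc) * (s2 - 1 / (nbar - 1)
                       * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                               - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return a / (a + b + c)


class TestWcTheta:
    def test_fixed_difference_is_one(self):
        assert wc_theta(50, 100, 50, 0) == pytest.approx(1.0)

    def test_equal_frequencies_nonpositive(self):
        for n1, n2, p in [(10, 10, 0.5), (7, 23, 0.2), (100, 3, 0.9)]:
            t = wc_theta(n1, round(2 * n1 * p), n2, round(2 * n2 * p))
            # identical sample frequencies: no between-population variance
            assert t <= 0

    def test_pooled_monomorphic_undefined(self):
        assert np.isnan(wc_theta(10, 0, 12, 0))
        assert np.isnan(wc_theta(10, 20, 12, 24))

    def test_matches_independent_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(500):
            n1, n2 = rng.integers(2, 200, size=2)
            x1 = rng.integers(0, 2 * n1 + 1)
            x2 = rng.integers(0, 2 * n2 + 1)
            if x1 + x2 == 0 or x1 + x2 == 2 * (n1 + n2):
                continue
            got = wc_theta(n1, x1, n2, x2)
            want = wc_theta_oracle([n1, n2], [x1 / (2 * n1), x2 / (2 * n2)])
            assert got == pytest.approx(want, abs=1e-10)

    @settings(max_examples=50, deadline=None)
    @given(n1=st.integers(2, 80), n2=st.integers(2, 80), seed=st.integers(0, 999))
    def test_label_and_coding_invariance(self, n1, n2, seed):
        rng = np.random.default_rng(seed)
        x1 = int(rng.integers(0, 2 * n1 + 1))
        x2 = int(rng.integers(0, 2 * n2 + 1))
        t = wc_theta(n1, x1, n2, x2)
        swapped = wc_theta(n2, x2, n1, x1)
        recoded = wc_theta(n1, 2 * n1 - x1, n2, 2 * n2 - x2)
        if np.isnan(t):
            assert np.isnan(swapped) and np.isnan(recoded)
        else:
            assert t == pytest.approx(swapped, abs=1e-12)
            assert t == pytest.approx(recoded, abs=1e-12)

    def test_nei_chesser_alternative_behaves(self):
        assert nei_chesser_gst(50, 100, 50, 0) == pytest.approx(1.0, abs=1e-2)
        assert nei_chesser_gst(20, 8, 30, 12) <= 0.05


class TestExpectedHet:
    def test_values(self):
        assert expected_het(0.5, 0.5) == pytest.approx(0.5)
        assert expected_het(0.0, 0.0) == 0.0
        assert expected_het(0.2, 0.6) == pytest.approx(0.48)


class TestWindowAverage:
    def _map(self, pos, chrom=None):
        n = len(pos)
        return SnpMap(np.array([f"s{i}" for i in range(n)], dtype=object),
                      np.asarray(chrom if chrom is not None else [1] * n),
                      np.asarray(pos),
                      np.array(["A"] * n, dtype=object),
                      np.array(["G"] * n, dtype=object))

    def test_interval_arithmetic(self):
        m = self._map([10_000, 110_000])
        w = window_average(np.array([1.0, 3.0]), m)
        w = w.set_index("start")
        # grid runs 0..100k in 25-kb steps; the first SNP only occupies the
        # window starting at 0, the second enters from start 25k onward
        assert w.loc[0, "n_snps"] == 1 and w.loc[0, "mean"] == 1.0
        assert w.loc[25_000, "n_snps"] == 1 and w.loc[25_000, "mean"] == 3.0
        assert w.loc[100_000, "n_snps"] == 1 and w.loc[100_000, "mean"] == 3.0
        assert w.index.max() == 100_000
        # SNPs exactly 100 kb apart can never share a 100-kb half-open window
        assert (w.n_snps <= 1).all()

    def test_snps_within_one_window(self):
        m = self._map([30_000, 90_000])
        w = window_average(np.array([1.0, 3.0]), m).set_index("start")
        assert w.loc[0, "n_snps"] == 2 and w.loc[0, "mean"] == 2.0

    def test_nan_values_do_not_count(self):
        m = self._map([10_000, 20_000, 30_000])
        w = window_average(np.array([1.0, np.nan, 2.0]), m)
        first = w[w.start == 0].iloc[0]
        assert first.n_snps == 2 and first["mean"] == 1.5

    def test_half_open_boundary(self):
        m = self._map([100_000])
        w = window_average(np.array([1.0]), m).set_index("start")
        assert w.loc[0, "n_snps"] == 0          # pos 100000 not in [0, 100000)
        assert w.loc[25_000, "n_snps"] == 1

    def test_multiple_chromosomes_independent(self):
        m = self._map([10_000, 10_000], chrom=[1, 2])
        w = window_average(np.array([1.0, 5.0]), m)
        assert set(w.chrom) == {1, 2}
        assert w[w.chrom == 1]["mean"].iloc[0] == 1.0
        assert w[w.chrom == 2]["mean"].iloc[0] == 5.0


def _window_frame(mean, het, n_snps=10):
    n = len(mean)
    return pd.DataFrame({
        "chrom": np.ones(n, dtype=int),
        "start": np.arange(n) * 25_000,
        "end": np.arange(n) * 25_000 + 100_000,
        "n_snps": np.full(n, n_snps),
        "mean": mean,
        "mean_het": het,
    })


class TestFlagFstCandidates:
    def test_planted_outliers_recovered_exactly(self):
        # independent backgrounds in the two comparisons; the same 10
        # windows planted high in both, with hets spread across bins so the
        # per-bin CIs stay uncontaminated
        rng = np.random.default_rng(23)
        n = 1000
        mean1 = rng.uniform(0.0, 0.2, n)
        mean2 = rng.uniform(0.0, 0.2, n)
        het = rng.uniform(0.1, 0.5, n)
        planted = rng.choice(n, 10, replace=False)
        mean1[planted] = rng.uniform(0.8, 0.9, 10)
        mean2[planted] = rng.uniform(0.8, 0.9, 10)
        out = flag_fst_candidates(_window_frame(mean1, het),
                                  _window_frame(mean2, het), FstScanConfig())
        got = set(out[out.candidate]["start"])
        assert got == set(planted * 25_000)
        # brute-force quantile check: every candidate beats the empirical
        # 99th percentile computed directly
        assert all(mean1[planted] > np.quantile(mean1, 0.99))
        assert all(mean2[planted] > np.quantile(mean2, 0.99))

    def test_single_comparison_not_enough(self):
        rng = np.random.default_rng(3)
        n = 400
        mean1 = rng.uniform(0, 0.2, n)
        mean2 = rng.uniform(0, 0.2, n)
        het = rng.uniform(0.2, 0.5, n)
        top = int(np.argmax(mean1))
        mean1[top] = 0.95          # outlier in comparison 1 only
        mean2[top] = 0.0
        out = flag_fst_candidates(_window_frame(mean1, het),
                                  _window_frame(mean2, het))
        assert not out[out.start == top * 25_000].candidate.iloc[0]

    def test_identical_values_flag_nothing(self):
        n = 200
        w = _window_frame(np.full(n, 0.1), np.full(n, 0.3))
        out = flag_fst_candidates(w, w.copy())
        assert not out.candidate.any()

    def test_min_snps_gate(self):
        rng = np.random.default_rng(9)
        n = 300
        mean = rng.uniform(0, 0.2, n)
        het = rng.uniform(0.2, 0.5, n)
        mean[7] = 0.99
        w1 = _window_frame(mean, het)
        w1.loc[7, "n_snps"] = 5     # "more than five SNPs" fails
        out = flag_fst_candidates(w1, _window_frame(mean, het))
        assert not out[out.start == 7 * 25_000].candidate.iloc[0]


class TestSnpFstTable:
    def test_counts_and_theta(self, toy_lines):
        d = np.array([[0, 2], [0, 2], [2, 0], [2, 0], [1, 1], [1, 1]],
                     dtype=np.int8)
        G = GenotypeMatrix(list(toy_lines.mapping), d)
        m = SnpMap(np.array(["a", "b"], dtype=object), np.array([1, 1]),
                   np.array([100, 200]), np.array(["A", "A"], dtype=object),
                   np.array(["G", "G"], dtype=object))
        t = snp_fst_table(G, m, toy_lines, "CTRL", "SELA")
        # CTRL fixed 0, SELA fixed 2 at SNP a -> theta = 1
        assert t.theta[0] == pytest.approx(1.0)
        assert t.n1[0] == 2 and t.n2[0] == 2
        assert t.het[0] == pytest.approx(0.5)
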