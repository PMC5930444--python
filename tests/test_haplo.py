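"""EHH curves vs brute-force enumeration, iHH integration, iHS/XP-EHH scans."""

import itertools

import numpy as np
import pandas as pd
import pytest

from divscan.data import HaplotypeMatrix, SnpMap
from divscan.haplo import (EhhCurve, HaploScanConfig, ehh_curve, ihh,
                           ihs_scan, window_flag_haplo, xpehh_scan)
from conftest import random_haplotypes


def brute_force_ehh(hap, core, carriers, direction):
    """Pair-enumeration EHH oracle: at flank x, fraction of carrier pairs
    identical over the inclusive slice core..x."""
    n_snps = hap.shape[1]
    idxs = (range(core - 1, -1, -1) if direction == "left"
            else range(core + 1, n_snps))
    vals = []
    pairs = list(itertools.combinations(carriers, 2))
    for x in idxs:
        lo, hi = min(core, x), max(core, x) + 1
        same = sum(
            1 for a, b in pairs if np.array_equal(hap[a, lo:hi], hap[b, lo:hi]))
        vals.append(same / len(pairs))
    return np.array(vals)


def simple_map(n, chrom=1, spacing=1000):
    return SnpMap(np.array([f"s{i}" for i in range(n)], dtype=object),
                  np.full(n, chrom), (np.arange(n) + 1) * spacing,
                  np.array(["A"] * n, dtype=object),
                  np.array(["T"] * n, dtype=object))


class TestEhhCurve:
    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(99)
        for _ in range(30):
            n_h = int(rng.integers(4, 16))
            n_s = int(rng.integers(5, 40))
            H = random_haplotypes(rng, n_h, n_s)
            m = simple_map(n_s)
            core = int(rng.integers(0, n_s))
            carriers = rng.choice(2 * n_h, size=int(rng.integers(2, 2 * n_h)),
                                  replace=False)
            for direction in ("left", "right"):
                got = ehh_curve(H, core, carriers, direction, snp_map=m)
                want = brute_force_ehh(H.haplotypes, core, carriers, direction)
                np.testing.assert_array_equal(got.values, want)

    def test_known_class_partition(self):
        # 4 carriers extending as {ab, ab, ac, ad}: classes {2,1,1} at the
        # second flank -> EHH = C(2,2)/C(4,2) = 1/6
        hap = np.array([[1, 0, 0],
                        [1, 0, 0],
                        [1, 0, 1],
                        [1, 1, 0]], dtype=np.uint8)
        H = HaplotypeMatrix(["x", "y"], hap)
        got = ehh_curve(H, 0, np.arange(4), "right", snp_map=simple_map(3))
        assert got.values[1] == pytest.approx(1 / 6)

    def test_all_distinct_hits_zero(self):
        hap = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=np.uint8)[:, [0, 1]]
        H = HaplotypeMatrix(["x", "y"], np.array(
            [[1, 0], [1, 1], [1, 0], [1, 1]], dtype=np.uint8))
        # carriers split 2/2 at first flank -> EHH = 2*C(2,2)/C(4,2) = 1/3
        got = ehh_curve(H, 0, np.arange(4), "right", snp_map=simple_map(2))
        assert got.values[0] == pytest.approx(1 / 3)

    def test_edge_core_empty_side(self):
        rng = np.random.default_rng(1)
        H = random_haplotypes(rng, 4, 5)
        got = ehh_curve(H, 0, np.arange(8), "left", snp_map=simple_map(5))
        assert len(got.values) == 0

    def test_non_increasing(self):
        rng = np.random.default_rng(12)
        for _ in range(10):
            H = random_haplotypes(rng, 8, 30)
            got = ehh_curve(H, 0, np.arange(16), "right", snp_map=simple_map(30))
            assert np.all(np.diff(got.values) <= 1e-15)


class TestIhh:
    def _curve(self, positions, values, reached_end=True):
        return EhhCurve(core=0, direction="right",
                        positions=np.asarray(positions),
                        values=np.asarray(values), reached_end=reached_end)

    def _empty(self):
        return EhhCurve(core=0, direction="left", positions=np.array([]),
                        values=np.array([]), reached_end=False)

    def test_hand_worked_trapezoid(self):
        # points (0,1.0)-(1000,0.5)-(2000,0.04), cutoff 0.05 -> 1020 exactly
        right = self._curve([1000, 2000], [0.5, 0.04])
        got = ihh(self._empty(), right, core_pos=0, cfg=HaploScanConfig())
        assert got.valid and got.value == pytest.approx(1020.0, abs=1e-12)

    def test_never_decaying_curve_invalid(self):
        right = self._curve([1000, 2000, 3000], [1.0, 1.0, 1.0], reached_end=True)
        got = ihh(self._empty(), right, core_pos=0)
        assert not got.valid and got.reason == "no_decay"

    def test_immediate_truncation_single_trapezoid(self):
        right = self._curve([500, 1500], [0.01, 0.0])
        got = ihh(self._empty(), right, core_pos=0)
        assert got.valid and got.value == pytest.approx((1 + 0.01) / 2 * 500)

    def test_gap_invalidates(self):
        cfg = HaploScanConfig(max_gap_bp=200_000)
        right = self._curve([250_000, 260_000], [0.5, 0.01])
        got = ihh(self._empty(), right, core_pos=0, cfg=cfg)
        assert not got.valid and got.reason == "gap"


def drifted_populations(seed, n_samples=40, n_snps=400):
    """Two populations with block-correlated haplotypes (LD) for scan tests."""
    rng = np.random.default_rng(seed)
    pops = []
    for _ in range(2):
        base = rng.random((12, n_snps)) < rng.uniform(0.2, 0.8, n_snps)
        pick = rng.integers(0, 12, size=2 * n_samples)
        hap = base[pick].astype(np.uint8)
        flip = rng.random((2 * n_samples, n_snps)) < 0.05
        hap = np.where(flip, 1 - hap, hap).astype(np.uint8)
        pops.append(HaplotypeMatrix([f"p{i}" for i in range(n_samples)], hap))
    return pops[0], pops[1], simple_map(n_snps, spacing=5000)


class TestIhsScan:
    def test_bins_standardized(self):
        H, _, m = drifted_populations(4, n_samples=60, n_snps=500)
        cfg = HaploScanConfig(seed=1, n_freq_bins=5)
        out = ihs_scan(H, m, cfg)
        scored = out.dropna(subset=["ihs_std"])
        assert len(scored) > 50
        for _, grp in scored.groupby("freq_bin"):
            if len(grp) >= 10:
                assert abs(grp.ihs_std.mean()) < 1e-9
                assert abs(grp.ihs_std.std(ddof=0) - 1) < 1e-9

    def test_maf_filter_applied(self):
        H, _, m = drifted_populations(4)
        hap = H.haplotypes.copy()
        hap[:, 10] = 0
        hap[0, 10] = 1      # MAF ~ 0.6% < 1%
        out = ihs_scan(HaplotypeMatrix(H.samples, hap), m, HaploScanConfig())
        assert np.isnan(out.raw_ihs[10])

    def test_reference_allele_seed_stability(self):
        H, _, m = drifted_populations(4, n_samples=60, n_snps=500)
        a = ihs_scan(H, m, HaploScanConfig(seed=1))
        b = ihs_scan(H, m, HaploScanConfig(seed=1))
        pd.testing.assert_frame_equal(a, b)
        # different reference seed: |iHS| sets strongly correlated
        c = ihs_scan(H, m, HaploScanConfig(seed=2))
        both = np.isfinite(a.ihs_abs) & np.isfinite(c.ihs_abs)
        assert both.sum() > 50
        r = np.corrcoef(a.ihs_abs[both], c.ihs_abs[both])[0, 1]
        assert r > 0.8


def brute_force_xpehh(hap_sel, hap_con, pos, core, cutoff=0.05):
    """Independent XP-EHH oracle: pair enumeration + hand trapezoids with
    truncation at the combined-population EHH cutoff. EHH over the
    inclusive interval [core..x]; the curve starts at the core-site
    homozygosity of each (sub)population."""
    comb = np.vstack([hap_sel, hap_con])

    def ehh_at(hap, x):
        lo, hi = min(core, x), max(core, x) + 1
        pairs = list(itertools.combinations(range(hap.shape[0]), 2))
        same = sum(1 for a, b in pairs
                   if np.array_equal(hap[a, lo:hi], hap[b, lo:hi]))
        return same / len(pairs)

    if ehh_at(comb, core) < cutoff:
        return None
    total_sel, total_con = 0.0, 0.0
    for step_idxs in (range(core - 1, -1, -1), range(core + 1, hap_sel.shape[1])):
        prev_d = 0.0
        prev_s, prev_c = ehh_at(hap_sel, core), ehh_at(hap_con, core)
        done = False
        for x in step_idxs:
            d = abs(pos[x] - pos[core])
            e_comb = ehh_at(comb, x)
            e_s, e_c = ehh_at(hap_sel, x), ehh_at(hap_con, x)
            total_sel += (prev_s + e_s) / 2 * (d - prev_d)
            total_con += (prev_c + e_c) / 2 * (d - prev_d)
            prev_d, prev_s, prev_c = d, e_s, e_c
            if e_comb < cutoff:
                done = True
                break
        if not done:
            return None
    return np.log(total_sel / total_con)


class TestXpehhScan:
    def test_identical_populations_score_zero(self):
        H, _, m = drifted_populations(8)
        out = xpehh_scan(H, H, m, HaploScanConfig())
        raw = out.raw_xpehh.dropna()
        assert len(raw) > 20
        np.testing.assert_allclose(raw, 0.0, atol=1e-12)

    def test_direction_contract(self):
        # selected dominated by one long haplotype (but not so much that the
        # combined EHH can never decay below the cutoff), control diverse
        rng = np.random.default_rng(5)
        n_snps = 200
        m = simple_map(n_snps, spacing=2000)
        one = (rng.random(n_snps) < 0.5).astype(np.uint8)
        sel_h = (rng.random((40, n_snps)) < 0.5).astype(np.uint8)
        sel_h[:15] = one               # 15 identical copies out of 40
        sel = HaplotypeMatrix([f"s{i}" for i in range(20)], sel_h)
        con_h = (rng.random((40, n_snps)) < 0.5).astype(np.uint8)
        con = HaplotypeMatrix([f"c{i}" for i in range(20)], con_h)
        out = xpehh_scan(sel, con, m, HaploScanConfig())
        raw = out.raw_xpehh.dropna()
        assert len(raw) > 50 and raw.mean() > 0 and (raw > 0).mean() > 0.9

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(31)
        hits = 0
        for _ in range(12):
            n_snps = 25
            base = rng.random((4, n_snps)) < 0.5
            sel = base[rng.integers(0, 2, 4)].astype(np.uint8)
            con = base[rng.integers(0, 4, 4)].astype(np.uint8)
            # per-haplotype noise so shared haplotypes decay along the map
            sel = np.where(rng.random(sel.shape) < 0.15, 1 - sel, sel).astype(np.uint8)
            con = np.where(rng.random(con.shape) < 0.15, 1 - con, con).astype(np.uint8)
            m = simple_map(n_snps, spacing=3000)
            out = xpehh_scan(
                HaplotypeMatrix(["a", "b"], sel),
                HaplotypeMatrix(["c", "d"], con), m, HaploScanConfig())
            for core in range(n_snps):
                want = brute_force_xpehh(sel, con, m.pos_bp, core)
                got = out.raw_xpehh[core]
                if want is None:
                    assert np.isnan(got)
                else:
                    assert got == pytest.approx(want, abs=1e-10)
                    hits += 1
        assert hits > 20


class TestWindowFlagging:
    def _scores(self, m, values, col):
        return pd.DataFrame({"snp_id": m.snp_id, "chrom": m.chrom,
                             "pos_bp": m.pos_bp, col: values})

    def test_ihs_mode_threshold_and_count(self):
        m = simple_map(20, spacing=5000)   # all SNPs within [0, 100k)
        cfg = HaploScanConfig()
        high = self._scores(m, np.full(20, 2.60), "ihs_abs")
        w = window_flag_haplo(high, m, cfg, mode="ihs")
        assert w[w.start == 0].flagged.iloc[0]
        few = self._scores(m, np.r_[np.full(5, 3.0), np.full(15, np.nan)], "ihs_abs")
        w2 = window_flag_haplo(few, m, cfg, mode="ihs")
        assert not w2[w2.start == 0].flagged.iloc[0]   # 5 scored SNPs < 6

    def test_xpehh_needs_both_comparisons(self):
        m = simple_map(20, spacing=5000)
        cfg = HaploScanConfig()
        hi = self._scores(m, np.full(20, 3.0), "xpehh_std")
        lo = self._scores(m, np.full(20, 1.0), "xpehh_std")
        w = window_flag_haplo(hi, m, cfg, mode="xpehh", scores2=lo)
        assert not w.flagged.any()
        w2 = window_flag_haplo(hi, m, cfg, mode="xpehh", scores2=hi.copy())
        assert w2[w2.start == 0].flagged.iloc[0]

    def test_negative_xpehh_never_flagged(self):
        m = simple_map(20, spacing=5000)
        neg = self._scores(m, np.full(20, -5.0), "xpehh_std")
        w = window_flag_haplo(neg, m, HaploScanConfig(), mode="xpehh",
                              scores2=neg.copy())
        assert not w.flagged.any()
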