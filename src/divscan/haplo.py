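"""EHH curves, iHH integration, and the iHS / XP-EHH selection scans.

iHS contrasts the integrated EHH (iHH) of the two alleles at a core SNP
within one population: a recently selected allele sits on unusually long
shared haplotypes, so ln(iHH_ref / iHH_alt) is pushed away from 0. Because
the score's null distribution depends on allele frequency, raw scores are
standardized within equal-count frequency bins and the absolute value is
used (no ancestral-allele information: the reference allele is assigned at
random, seeded).

XP-EHH contrasts iHH between two populations at the same core SNP, with
population-level EHH computed over all haplotypes (no allele
conditioning). Both integrals are truncated where the EHH of the combined
sample decays below the cutoff, so they share limits; the ln ratio is
z-scored genome-wide. Positive values mean longer haplotype homozygosity —
recent selection — in the numerator (selected) population.

Cores whose EHH never decays below the cutoff before the chromosome end,
or that hit an inter-SNP gap larger than ``max_gap_bp``, are dropped
rather than integrated partially, preventing boundary-inflated scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._ehh_kernels import STATUS_OK, ehh_fixed, ehh_pair_decay
from .data import HaplotypeMatrix, SnpMap
from .windows import window_average

__all__ = [
    "HaploScanConfig",
    "EhhCurve",
    "IhhValue",
    "ehh_curve",
    "ihh",
    "ihs_scan",
    "xpehh_scan",
    "window_flag_haplo",
]


@dataclass
class HaploScanConfig:
    maf_min: float = 0.01          # iHS only
    n_freq_bins: int = 20
    ehh_cutoff: float = 0.05
    max_gap_bp: int = 200_000
    window_size: int = 100_000
    overlap: int = 75_000
    min_snps: int = 6
    threshold: float = 2.58        # |z| cut-off, p < 0.005
    seed: int = 0                  # reference-allele assignment

    def __post_init__(self) -> None:
        if not (0 < self.ehh_cutoff < 1):
            raise ValueError("ehh_cutoff must be in (0, 1)")
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")


@dataclass
class EhhCurve:
    """One-sided EHH curve: flanking positions outward from the core."""

    core: int
    direction: str               # "left" or "right"
    positions: np.ndarray        # bp of each flanking SNP, outward order
    values: np.ndarray           # EHH at each flanking SNP
    reached_end: bool            # curve extends to the chromosome edge
    core_ehh: float = 1.0        # EHH at the core: core-site homozygosity of
                                 # the carriers (1 if conditioned on an allele)


@dataclass
class IhhValue:
    value: float
    valid: bool
    reason: str = ""             # "", "no_decay", "gap"


def ehh_curve(H: HaplotypeMatrix, core: int, carriers: np.ndarray,
              direction: str, snp_map: SnpMap | None = None,
              positions: np.ndarray | None = None) -> EhhCurve:
    """Full one-sided EHH curve for the given carrier haplotype rows.

    ``carriers`` are haplotype row indices (>= 2 of them). EHH at the core
    itself is 1 by definition and not included in the returned arrays; a
    core at the chromosome edge yields an empty side curve. Positions come
    from ``snp_map`` (or a raw ``positions`` array); the curve runs to the
    chromosome edge without truncation.
    """
    if positions is None:
        if snp_map is None:
            raise ValueError("need snp_map or positions")
        positions = snp_map.pos_bp
    carriers = np.asarray(carriers, dtype=np.int64)
    if len(carriers) < 2:
        raise ValueError("need at least 2 carrier haplotypes")
    if direction not in ("left", "right"):
        raise ValueError("direction must be 'left' or 'right'")
    step = -1 if direction == "left" else 1
    n_snps = H.n_snps
    n_steps = core if direction == "left" else n_snps - 1 - core
    out = np.empty(max(n_steps, 1), dtype=np.float64)
    hap = np.ascontiguousarray(H.haplotypes)
    m = ehh_fixed(hap, carriers, core, step, n_steps, out)
    idx = core + step * (1 + np.arange(m))
    return EhhCurve(core=core, direction=direction,
                    positions=np.asarray(positions)[idx] if m else np.array([], dtype=np.int64),
                    values=out[:m].copy(), reached_end=True,
                    core_ehh=_core_homozygosity(hap[carriers, core]))


def _core_homozygosity(col: np.ndarray) -> float:
    """Pair fraction identical at the core site (1 if all carriers share it)."""
    n = len(col)
    k1 = int(col.sum())
    k0 = n - k1
    return (k0 * (k0 - 1) / 2 + k1 * (k1 - 1) / 2) / (n * (n - 1) / 2)


def _integrate_points(dists: np.ndarray, vals: np.ndarray, cutoff: float,
                      max_gap: int, reaches_end: bool,
                      core_ehh: float = 1.0) -> IhhValue:
    """Trapezoid integral of one side, truncated at the first sub-cutoff point.

    ``dists``/``vals`` are flanking points only (outward, core excluded);
    the core point (0, ``core_ehh``) is implicit. Invalid if a gap larger
    than ``max_gap`` occurs before truncation, or if the curve never drops
    below the cutoff before running out (``reaches_end``).
    """
    total = 0.0
    prev_d, prev_v = 0.0, float(core_ehh)
    for d, v in zip(dists, vals):
        if d - prev_d > max_gap:
            return IhhValue(0.0, False, "gap")
        total += (prev_v + v) / 2.0 * (d - prev_d)
        if v < cutoff:
            return IhhValue(total, True)
        prev_d, prev_v = float(d), float(v)
    if reaches_end:
        return IhhValue(0.0, False, "no_decay")
    return IhhValue(total, True)


def ihh(left: EhhCurve, right: EhhCurve, core_pos: int,
        cfg: HaploScanConfig = HaploScanConfig()) -> IhhValue:
    """Two-sided integrated EHH (bp * EHH units) from a pair of side curves.

    Each side accumulates consecutive trapezoids until the first point with
    EHH below the cutoff (that trapezoid included); the sides are summed.
    Invalid if either side runs off the chromosome before decaying or
    crosses an over-gap region first.
    """
    total = 0.0
    for side in (left, right):
        dists = np.abs(np.asarray(side.positions, dtype=np.float64) - core_pos)
        part = _integrate_points(dists, np.asarray(side.values, dtype=np.float64),
                                 cfg.ehh_cutoff, cfg.max_gap_bp, side.reached_end,
                                 core_ehh=side.core_ehh)
        if not part.valid:
            return part
        total += part.value
    return IhhValue(total, True)


def _side_integral(d: np.ndarray, vals: np.ndarray, cutoff: float,
                   h0: float, truncate: bool = True) -> float:
    """One-sided trapezoid integral from the implicit (0, h0) core point.

    With ``truncate`` the accumulation stops at the first sub-cutoff point
    (included); the caller guarantees such a point exists.
    """
    if truncate:
        below = np.nonzero(vals < cutoff)[0]
        if len(below):
            stop = below[0] + 1
            d = d[:stop]
            vals = vals[:stop]
    vv = np.concatenate([[h0], vals])
    dd = np.diff(np.concatenate([[0.0], d]))
    return float(np.sum((vv[:-1] + vv[1:]) / 2.0 * dd))


def _equal_count_bins(freq: np.ndarray, n_bins: int) -> np.ndarray:
    n = len(freq)
    order = np.argsort(freq, kind="mergesort")
    ranks = np.empty(n, dtype=np.int64)
    ranks[order] = np.arange(n)
    return (ranks * n_bins) // n


def _standardize_in_bins(raw: np.ndarray, bins: np.ndarray, n_bins: int) -> np.ndarray:
    """Z-score within bins; bins with < 2 scores are merged into a neighbor."""
    bins = bins.copy()
    labels = sorted(set(bins.tolist()))
    counts = {b: int(np.sum(bins == b)) for b in labels}
    merged = True
    while merged and len(labels) > 1:
        merged = False
        for b in list(labels):
            if counts[b] < 2:
                others = [x for x in labels if x != b]
                nb = min(others, key=lambda x: abs(x - b))
                warnings.warn(f"frequency bin {b} has <2 scores; merged into bin {nb}")
                bins[bins == b] = nb
                counts[nb] += counts[b]
                labels.remove(b)
                del counts[b]
                merged = True
                break
    z = np.full(len(raw), np.nan)
    for b in labels:
        inb = bins == b
        mu = raw[inb].mean()
        sd = raw[inb].std()
        if sd > 0:
            z[inb] = (raw[inb] - mu) / sd
        else:
            z[inb] = 0.0
    return z


def ihs_scan(H: HaplotypeMatrix, snp_map: SnpMap,
             cfg: HaploScanConfig = HaploScanConfig()) -> pd.DataFrame:
    """Integrated haplotype score scan within one (pooled) population.

    Returns a DataFrame aligned to ``snp_map`` with columns ref_allele,
    ref_freq, raw_ihs, ihs_std (signed within-bin z), ihs_abs; NaN where
    the SNP was filtered (MAF), had < 2 carriers of an allele, or had an
    invalid iHH on either allele.
    """
    if not snp_map.is_sorted():
        raise ValueError("snp_map must be sorted")
    n = len(snp_map)
    hap_all = H.haplotypes
    freq1 = hap_all.mean(axis=0)
    maf = np.minimum(freq1, 1 - freq1)
    rng = np.random.default_rng(cfg.seed)
    ref = rng.integers(0, 2, size=n)

    raw = np.full(n, np.nan)
    for c in np.unique(snp_map.chrom):
        gidx = np.nonzero(snp_map.chrom == c)[0]
        hap = np.ascontiguousarray(hap_all[:, gidx])
        pos = snp_map.pos_bp[gidx].astype(np.int64)
        m_chrom = len(gidx)
        rows_all = np.arange(hap.shape[0], dtype=np.int64)
        buf_a = np.empty(max(m_chrom, 1), dtype=np.float64)
        buf_b = np.empty(max(m_chrom, 1), dtype=np.float64)
        buf_c = np.empty(max(m_chrom, 1), dtype=np.float64)
        for lj, g in enumerate(gidx):
            if maf[g] < cfg.maf_min:
                continue
            col = hap[:, lj]
            in_ref = col == ref[g]
            n_ref = int(in_ref.sum())
            if n_ref < 2 or hap.shape[0] - n_ref < 2:
                continue
            total_ref = 0.0
            total_alt = 0.0
            ok = True
            for step in (-1, 1):
                m, st_a, st_b, _ = ehh_pair_decay(
                    hap, rows_all, in_ref, lj, step, pos, cfg.ehh_cutoff,
                    cfg.max_gap_bp, False, buf_a, buf_b, buf_c)
                if st_a != STATUS_OK or st_b != STATUS_OK:
                    ok = False
                    break
                idx = lj + step * (1 + np.arange(m))
                d = np.abs(pos[idx] - pos[lj]).astype(np.float64)
                total_ref += _side_integral(d, buf_a[:m], cfg.ehh_cutoff, 1.0)
                total_alt += _side_integral(d, buf_b[:m], cfg.ehh_cutoff, 1.0)
            if ok and total_ref > 0 and total_alt > 0:
                raw[g] = np.log(total_ref / total_alt)

    ref_freq = np.where(ref == 1, freq1, 1 - freq1)
    scored = ~np.isnan(raw)
    z = np.full(n, np.nan)
    if scored.sum() >= 2:
        bins = _equal_count_bins(ref_freq[scored], cfg.n_freq_bins)
        z[scored] = _standardize_in_bins(raw[scored], bins, cfg.n_freq_bins)
    bin_full = np.full(n, -1, dtype=np.int64)
    if scored.sum() >= 2:
        bin_full[scored] = _equal_count_bins(ref_freq[scored], cfg.n_freq_bins)
    return pd.DataFrame(
        {
            "snp_id": snp_map.snp_id,
            "chrom": snp_map.chrom,
            "pos_bp": snp_map.pos_bp,
            "ref_allele": ref,
            "ref_freq": ref_freq,
            "freq_bin": bin_full,
            "raw_ihs": raw,
            "ihs_std": z,
            "ihs_abs": np.abs(z),
        }
    )


def xpehh_scan(H_selected: HaplotypeMatrix, H_control: HaplotypeMatrix,
               snp_map: SnpMap, cfg: HaploScanConfig = HaploScanConfig()) -> pd.DataFrame:
    """Cross-population EHH scan (selected vs control).

    Population-level EHH is computed over all haplotypes of each
    population; integration is truncated where the combined-population EHH
    decays below the cutoff so both integrals share limits. Returns a
    DataFrame aligned to ``snp_map`` with raw and genome-wide-standardized
    scores (NaN where the core was dropped).
    """
    if not snp_map.is_sorted():
        raise ValueError("snp_map must be sorted")
    if H_selected.n_snps != H_control.n_snps:
        raise ValueError("populations must share the SNP map")
    n = len(snp_map)
    n_sel = H_selected.haplotypes.shape[0]
    raw = np.full(n, np.nan)
    for c in np.unique(snp_map.chrom):
        gidx = np.nonzero(snp_map.chrom == c)[0]
        comb = np.ascontiguousarray(
            np.vstack([H_selected.haplotypes[:, gidx], H_control.haplotypes[:, gidx]]))
        pos = snp_map.pos_bp[gidx].astype(np.int64)
        rows_all = np.arange(comb.shape[0], dtype=np.int64)
        in_sel = rows_all < n_sel
        m_chrom = len(gidx)
        buf_a = np.empty(max(m_chrom, 1), dtype=np.float64)
        buf_b = np.empty(max(m_chrom, 1), dtype=np.float64)
        buf_c = np.empty(max(m_chrom, 1), dtype=np.float64)
        for lj in range(m_chrom):
            col = comb[:, lj]
            h0_comb = _core_homozygosity(col)
            if h0_comb < cfg.ehh_cutoff:
                continue        # EHH already below cutoff at the core itself
            h0_sel = _core_homozygosity(col[:n_sel])
            h0_con = _core_homozygosity(col[n_sel:])
            total_sel = 0.0
            total_con = 0.0
            ok = True
            for step in (-1, 1):
                m, _, _, st_c = ehh_pair_decay(
                    comb, rows_all, in_sel, lj, step, pos, cfg.ehh_cutoff,
                    cfg.max_gap_bp, True, buf_a, buf_b, buf_c)
                if st_c != STATUS_OK:
                    ok = False
                    break
                idx = lj + step * (1 + np.arange(m))
                d = np.abs(pos[idx] - pos[lj]).astype(np.float64)
                total_sel += _side_integral(d, buf_a[:m], cfg.ehh_cutoff,
                                            h0_sel, truncate=False)
                total_con += _side_integral(d, buf_b[:m], cfg.ehh_cutoff,
                                            h0_con, truncate=False)
            if ok and total_sel > 0 and total_con > 0:
                raw[gidx[lj]] = np.log(total_sel / total_con)
    scored = ~np.isnan(raw)
    z = np.full(n, np.nan)
    if scored.sum() >= 2:
        mu = raw[scored].mean()
        sd = raw[scored].std()
        z[scored] = (raw[scored] - mu) / sd if sd > 0 else 0.0
    return pd.DataFrame(
        {
            "snp_id": snp_map.snp_id,
            "chrom": snp_map.chrom,
            "pos_bp": snp_map.pos_bp,
            "raw_xpehh": raw,
            "xpehh_std": z,
        }
    )


def window_flag_haplo(scores: pd.DataFrame, snp_map: SnpMap,
                      cfg: HaploScanConfig, mode: str,
                      scores2: pd.DataFrame | None = None) -> pd.DataFrame:
    """Window means of standardized scores with the 2.58 flag rule.

    ``mode='ihs'``: window mean |iHS| > threshold with >= min_snps scored
    SNPs. ``mode='xpehh'``: window mean standardized XP-EHH above the
    threshold in BOTH comparisons (``scores`` and ``scores2``) with >=
    min_snps in each; negative windows are never flagged.
    """
    if mode == "ihs":
        w = window_average(scores["ihs_abs"].to_numpy(), snp_map,
                           cfg.window_size, cfg.overlap)
        w["flagged"] = (w["n_snps"] >= cfg.min_snps) & (w["mean"] > cfg.threshold)
        return w
    if mode == "xpehh":
        if scores2 is None:
            raise ValueError("xpehh mode needs both comparisons")
        w1 = window_average(scores["xpehh_std"].to_numpy(), snp_map,
                            cfg.window_size, cfg.overlap)
        w2 = window_average(scores2["xpehh_std"].to_numpy(), snp_map,
                            cfg.window_size, cfg.overlap)
        w = w1.merge(w2, on=["chrom", "start", "end"], suffixes=("_1", "_2"))
        w["flagged"] = (
            (w["n_snps_1"] >= cfg.min_snps) & (w["mean_1"] > cfg.threshold)
            & (w["n_snps_2"] >= cfg.min_snps) & (w["mean_2"] > cfg.threshold)
        )
        return w
    raise ValueError("mode must be 'ihs' or 'xpehh'")
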