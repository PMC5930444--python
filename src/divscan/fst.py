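"""Per-SNP FST, windowed means, and the dual FST/heterozygosity outlier test.

The fixation index is estimated per SNP with the Weir & Cockerham (1984)
two-population theta-hat, which corrects for unequal sample sizes through
the variance components a (between populations), b (between individuals
within populations) and c (within individuals); here the within-population
heterozygosity term uses HWE-expected frequencies, i.e. only sample allele
frequencies and sizes enter. Nei & Chesser's corrected GST is available as
an alternative estimator.

Candidate windows must simultaneously (a) fall in the empirical top
quantile of windowed FST and (b) exceed the upper tail of the FST
distribution of their heterozygosity bin — in BOTH control-vs-selected
comparisons. The heterozygosity conditioning matters because the null
dispersion of FST depends strongly on allele frequency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import GenotypeMatrix, LineAssignment, SnpMap, allele_frequencies
from .windows import window_average

__all__ = [
    "FstScanConfig",
    "wc_theta",
    "nei_chesser_gst",
    "expected_het",
    "snp_fst_table",
    "window_average",
    "flag_fst_candidates",
    "fst_scan",
]


@dataclass
class FstScanConfig:
    window_size: int = 100_000
    overlap: int = 75_000
    min_snps: int = 6          # "more than five SNPs"
    top_quantile: float = 0.99
    het_bins: int = 20
    ci: float = 0.95
    estimator: str = "wc"      # "wc" (Weir-Cockerham) or "nc" (Nei-Chesser GST)
    het_mode: str = "expected"  # "expected" (HWE from mean freq) or "observed"

    def __post_init__(self) -> None:
        if not (0 < self.top_quantile < 1):
            raise ValueError("top_quantile must be in (0, 1)")
        if self.overlap >= self.window_size:
            raise ValueError("overlap must be smaller than window_size")
        if self.estimator not in ("wc", "nc"):
            raise ValueError("estimator must be 'wc' or 'nc'")


def wc_theta(n1, x1, n2, x2):
    """Weir & Cockerham (1984) two-population theta-hat.

    ``n_i`` = called diploids, ``x_i`` = allele_b count (0..2*n_i). Uses the
    allele-frequency-only variance components with the heterozygosity term
    taken as the HWE expectation 2 p_i (1 - p_i). Vectorized; returns NaN
    where the SNP is monomorphic in the pooled sample.
    """
    n1 = np.asarray(n1, dtype=np.float64)
    n2 = np.asarray(n2, dtype=np.float64)
    x1 = np.asarray(x1, dtype=np.float64)
    x2 = np.asarray(x2, dtype=np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = x1 / (2 * n1)
        p2 = x2 / (2 * n2)
        r = 2.0
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        h1 = 2 * p1 * (1 - p1)
        h2 = 2 * p2 * (1 - p2)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        denom = a + b + c
        theta = np.where(denom != 0, a / np.where(denom != 0, denom, 1.0), np.nan)
    pooled_mono = (x1 + x2 == 0) | (x1 + x2 == 2 * (n1 + n2))
    theta = np.where(pooled_mono, np.nan, theta)
    if np.ndim(theta) == 0:
        return float(theta)
    return theta


def nei_chesser_gst(n1, x1, n2, x2):
    """Nei & Chesser (1983) sample-size-corrected GST (two populations)."""
    n1 = np.asarray(n1, dtype=np.float64)
    n2 = np.asarray(n2, dtype=np.float64)
    x1 = np.asarray(x1, dtype=np.float64)
    x2 = np.asarray(x2, dtype=np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = x1 / (2 * n1)
        p2 = x2 / (2 * n2)
        nh = 2.0 / (1.0 / n1 + 1.0 / n2)  # harmonic mean of sample sizes
        pbar = (p1 + p2) / 2
        hs_hat = (2 * p1 * (1 - p1) + 2 * p2 * (1 - p2)) / 2
        hs = (2 * nh / (2 * nh - 1)) * hs_hat
        ht = 2 * pbar * (1 - pbar) + hs / (4 * nh)
        gst = np.where(ht > 0, (ht - hs) / np.where(ht > 0, ht, 1.0), np.nan)
    pooled_mono = (x1 + x2 == 0) | (x1 + x2 == 2 * (n1 + n2))
    gst = np.where(pooled_mono, np.nan, gst)
    if np.ndim(gst) == 0:
        return float(gst)
    return gst


def expected_het(p1, p2):
    """HWE-expected total heterozygosity 2 pbar (1 - pbar), pbar unweighted."""
    p1 = np.asarray(p1, dtype=np.float64)
    p2 = np.asarray(p2, dtype=np.float64)
    pbar = (p1 + p2) / 2.0
    het = 2.0 * pbar * (1.0 - pbar)
    if np.ndim(het) == 0:
        return float(het)
    return het


def snp_fst_table(G: GenotypeMatrix, snp_map: SnpMap, lines: LineAssignment,
                  pop1: str, pop2: str, cfg: FstScanConfig = FstScanConfig()) -> pd.DataFrame:
    """Per-SNP FST/heterozygosity table for one pair of lines."""
    f1 = allele_frequencies(G, lines.samples_in(pop1))
    f2 = allele_frequencies(G, lines.samples_in(pop2))
    est = wc_theta if cfg.estimator == "wc" else nei_chesser_gst
    x1 = np.round(f1.p_b * 2 * f1.n_called)
    x2 = np.round(f2.p_b * 2 * f2.n_called)
    theta = est(f1.n_called, x1, f2.n_called, x2)
    theta = np.where((f1.n_called < 1) | (f2.n_called < 1), np.nan, theta)
    if cfg.het_mode == "expected":
        het = expected_het(f1.p_b, f2.p_b)
    else:
        obs1 = (G.dosages[G.sample_index(lines.samples_in(pop1))] == 1).mean(axis=0)
        obs2 = (G.dosages[G.sample_index(lines.samples_in(pop2))] == 1).mean(axis=0)
        het = (obs1 + obs2) / 2.0
    return pd.DataFrame(
        {
            "snp_id": snp_map.snp_id,
            "chrom": snp_map.chrom,
            "pos_bp": snp_map.pos_bp,
            "n1": f1.n_called,
            "n2": f2.n_called,
            "p1": f1.p_b,
            "p2": f2.p_b,
            "theta": theta,
            "het": het,
        }
    )


def _het_bin_assign(het: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-count bins by heterozygosity rank (ties broken by order)."""
    n = len(het)
    order = np.argsort(het, kind="mergesort")
    ranks = np.empty(n, dtype=np.int64)
    ranks[order] = np.arange(n)
    return (ranks * n_bins) // n


def flag_fst_candidates(windows_cmp1: pd.DataFrame, windows_cmp2: pd.DataFrame,
                        cfg: FstScanConfig = FstScanConfig()) -> pd.DataFrame:
    """Joint top-quantile + heterozygosity-bin outlier flags.

    Both window tables must be on the same grid and carry columns
    chrom/start/end/n_snps/mean (FST) and mean_het. Returns the merged grid
    with per-comparison flags and a combined ``candidate`` column.
    """
    w = windows_cmp1.merge(windows_cmp2, on=["chrom", "start", "end"],
                           suffixes=("_1", "_2"))
    flags = {}
    for s in ("1", "2"):
        mean = w[f"mean_{s}"].to_numpy()
        het = w[f"mean_het_{s}"].to_numpy()
        n_snps = w[f"n_snps_{s}"].to_numpy()
        eligible = (n_snps >= cfg.min_snps) & ~np.isnan(mean) & ~np.isnan(het)
        top = np.zeros(len(w), dtype=bool)
        binflag = np.zeros(len(w), dtype=bool)
        if eligible.sum() > 0:
            vals = mean[eligible]
            q_top = np.quantile(vals, cfg.top_quantile)
            top[eligible] = mean[eligible] > q_top
            n_bins = cfg.het_bins
            if eligible.sum() < cfg.het_bins:
                n_bins = max(1, int(eligible.sum()) // 50)
                warnings.warn(
                    f"only {int(eligible.sum())} eligible windows; "
                    f"reducing heterozygosity bins to {n_bins}")
            bins = _het_bin_assign(het[eligible], n_bins)
            q_hi = (1 + cfg.ci) / 2
            bf = np.zeros(int(eligible.sum()), dtype=bool)
            for bi in range(n_bins):
                inb = bins == bi
                if inb.sum() == 0:
                    continue
                q = np.quantile(vals[inb], q_hi)
                bf[inb] = vals[inb] > q
            binflag[eligible] = bf
        flags[f"eligible_{s}"] = eligible
        flags[f"top_{s}"] = top
        flags[f"hetbin_{s}"] = binflag
    for k, v in flags.items():
        w[k] = v
    w["candidate"] = (w["top_1"] & w["hetbin_1"] & w["top_2"] & w["hetbin_2"])
    return w


def fst_scan(G: GenotypeMatrix, snp_map: SnpMap, lines: LineAssignment,
             cfg: FstScanConfig = FstScanConfig()):
    """Windowed FST outlier scan across both control-vs-selected comparisons.

    Returns ``(per_snp_tables, window_table)`` where ``per_snp_tables`` maps
    "control_vs_<line>" to the per-SNP table and ``window_table`` is the
    merged grid with the joint candidate flags (first two selected lines).
    """
    if len(lines.selected) < 2:
        raise ValueError("the dual criterion needs two control-vs-selected comparisons")
    sel1, sel2 = lines.selected[0], lines.selected[1]
    tables = {}
    wins = []
    for sel in (sel1, sel2):
        t = snp_fst_table(G, snp_map, lines, lines.control, sel, cfg)
        tables[f"control_vs_{sel}"] = t
        wv = window_average(t["theta"].to_numpy(), snp_map, cfg.window_size,
                            cfg.overlap, extra={"het": t["het"].to_numpy()})
        wins.append(wv)
    flagged = flag_fst_candidates(wins[0], wins[1], cfg)
    return tables, flagged
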