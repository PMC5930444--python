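"""Sliding-window averaging on the shared 100-kb / 25-kb-step grid.

All scans (FST, |iHS|, XP-EHH) summarize per-SNP values over the same
window grid: per chromosome, half-open windows [s, s + window_size) with
s = 0, step, 2*step, ... up to the last SNP, where step = window_size -
overlap. Window means use only SNPs with a defined (non-NaN) value, and
``n_snps`` counts exactly those SNPs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data import SnpMap

__all__ = ["window_average"]


def window_average(values: np.ndarray, snp_map: SnpMap, window_size: int = 100_000,
                   overlap: int = 75_000, extra: dict | None = None) -> pd.DataFrame:
    """Mean of ``values`` per sliding window.

    ``values`` is aligned to ``snp_map`` (NaN = undefined, excluded from
    means and from ``n_snps``). ``extra`` maps column name -> aligned value
    array to average alongside (e.g. heterozygosity next to FST). Returns a
    DataFrame with columns chrom, start, end, n_snps, mean (+ ``mean_<x>``
    per extra column). Windows with no defined SNP carry NaN means.
    """
    if overlap >= window_size:
        raise ValueError("overlap must be smaller than window_size")
    values = np.asarray(values, dtype=np.float64)
    if len(values) != len(snp_map):
        raise ValueError("values not aligned to snp_map")
    if not snp_map.is_sorted():
        raise ValueError("snp_map must be sorted")
    step = window_size - overlap
    extra = extra or {}
    out = {"chrom": [], "start": [], "end": [], "n_snps": [], "mean": []}
    for name in extra:
        out[f"mean_{name}"] = []

    for c in np.unique(snp_map.chrom):
        cmask = snp_map.chrom == c
        pos = snp_map.pos_bp[cmask]
        v = values[cmask]
        ok = ~np.isnan(v)
        # prefix sums over defined values for O(1) window means
        cs = np.concatenate([[0.0], np.cumsum(np.where(ok, v, 0.0))])
        cn = np.concatenate([[0], np.cumsum(ok.astype(np.int64))])
        extra_cs = {}
        for name, arr in extra.items():
            a = np.asarray(arr, dtype=np.float64)[cmask]
            extra_cs[name] = np.concatenate([[0.0], np.cumsum(np.where(ok, a, 0.0))])
        last = int(pos.max())
        starts = np.arange(0, (last // step) * step + 1, step, dtype=np.int64)
        lo = np.searchsorted(pos, starts, side="left")
        hi = np.searchsorted(pos, starts + window_size, side="left")
        n_def = cn[hi] - cn[lo]
        with np.errstate(invalid="ignore", divide="ignore"):
            means = np.where(n_def > 0, (cs[hi] - cs[lo]) / np.maximum(n_def, 1), np.nan)
        out["chrom"].append(np.full(len(starts), c))
        out["start"].append(starts)
        out["end"].append(starts + window_size)
        out["n_snps"].append(n_def)
        out["mean"].append(means)
        for name in extra:
            e = extra_cs[name]
            with np.errstate(invalid="ignore", divide="ignore"):
                em = np.where(n_def > 0, (e[hi] - e[lo]) / np.maximum(n_def, 1), np.nan)
            out[f"mean_{name}"].append(em)
    if not out["chrom"]:
        cols = ["chrom", "start", "end", "n_snps", "mean"] + [f"mean_{n}" for n in extra]
        return pd.DataFrame({c: [] for c in cols})
    return pd.DataFrame({k: np.concatenate(vs) for k, vs in out.items()})
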