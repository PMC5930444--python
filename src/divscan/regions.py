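"""Merging flagged windows into regions, cross-test consensus, annotation.

Flagged windows on the 25-kb-step grid are merged when they overlap or
exactly abut; the consensus step reports the maximal intervals covered by
regions of at least two distinct tests (intersection footprint — the
reported coordinates are conservative). Annotation is a pure
interval-overlap join against user-supplied BED features.

Internal coordinates are half-open [start, end) on the 1-based bp axis;
BED input/output is converted explicitly (BED is 0-based half-open).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Region",
    "AnnotationHit",
    "merge_windows",
    "cross_test_consensus",
    "annotate_regions",
    "read_bed",
    "regions_to_bed",
]


@dataclass
class Region:
    chrom: int
    start: int
    end: int
    tests: frozenset = frozenset()
    n_windows: int = 0
    peak: dict = field(default_factory=dict)  # test -> peak window mean

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("region start must be < end")
        self.tests = frozenset(self.tests)

    def contains(self, chrom: int, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos < self.end


@dataclass
class AnnotationHit:
    region: Region
    feature: str
    feature_chrom: int
    feature_start: int
    feature_end: int
    overlap_bp: int


def merge_windows(windows: pd.DataFrame, test: str,
                  flag_col: str = "flagged", value_col: str | None = None) -> list:
    """Merge flagged windows that overlap or exactly abut into Regions.

    ``value_col`` (defaults to 'mean' or 'mean_1' if present) provides the
    per-window value whose maximum becomes the region's peak.
    """
    if value_col is None:
        value_col = "mean" if "mean" in windows.columns else (
            "mean_1" if "mean_1" in windows.columns else None)
    flagged = windows[windows[flag_col].astype(bool)]
    if flagged.empty:
        return []
    flagged = flagged.sort_values(["chrom", "start"], kind="mergesort")
    regions: list = []
    cur = None
    for row in flagged.itertuples(index=False):
        chrom, start, end = int(row.chrom), int(row.start), int(row.end)
        val = float(getattr(row, value_col)) if value_col else np.nan
        if cur is not None and chrom == cur["chrom"] and start <= cur["end"]:
            cur["end"] = max(cur["end"], end)
            cur["n"] += 1
            cur["peak"] = max(cur["peak"], val)
        else:
            if cur is not None:
                regions.append(cur)
            cur = {"chrom": chrom, "start": start, "end": end, "n": 1, "peak": val}
    regions.append(cur)
    return [
        Region(r["chrom"], r["start"], r["end"], tests=frozenset([test]),
               n_windows=r["n"], peak={test: r["peak"]})
        for r in regions
    ]


def cross_test_consensus(regions_by_test: dict) -> list:
    """Maximal intervals covered by regions of >= 2 distinct tests.

    ``regions_by_test`` maps test name -> list of Regions. Adjacent
    qualifying elementary segments are merged; each consensus region lists
    the union of tests covering any part of it.
    """
    all_regions = [r for regs in regions_by_test.values() for r in regs]
    out = []
    for chrom in sorted({r.chrom for r in all_regions}):
        pts = sorted({p for r in all_regions if r.chrom == chrom
                      for p in (r.start, r.end)})
        segs = []  # (start, end, tests)
        for a, b in zip(pts[:-1], pts[1:]):
            tests = {t for t, regs in regions_by_test.items()
                     for r in regs
                     if r.chrom == chrom and r.start < b and r.end > a}
            if len(tests) >= 2:
                segs.append((a, b, tests))
        cur = None
        for a, b, tests in segs:
            if cur is not None and a == cur[1]:
                cur = (cur[0], b, cur[2] | tests)
            else:
                if cur is not None:
                    out.append(cur + (chrom,))
                cur = (a, b, tests)
        if cur is not None:
            out.append(cur + (chrom,))
    return [Region(chrom, a, b, tests=frozenset(t)) for a, b, t, chrom in out]


def read_bed(bed_path) -> pd.DataFrame:
    """Read a BED file into internal coordinates (1-based half-open).

    Only the first four columns are used (chrom, start, end, name); a BED
    interval [s, e) 0-based becomes [s + 1, e + 1) on the internal axis.
    """
    rows = []
    with open(bed_path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"BED line {ln}: fewer than 3 columns")
            try:
                chrom = int(parts[0].removeprefix("chr"))
                s, e = int(parts[1]), int(parts[2])
            except ValueError:
                raise ValueError(f"BED line {ln}: malformed coordinates") from None
            if s >= e:
                raise ValueError(f"BED line {ln}: start >= end")
            name = parts[3] if len(parts) > 3 else f"feature_{ln}"
            rows.append({"chrom": chrom, "start": s + 1, "end": e + 1, "name": name})
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def annotate_regions(regions: list, features: pd.DataFrame) -> list:
    """All features with nonzero overlap with a region (half-open both sides)."""
    hits = []
    if len(features) == 0:
        return hits
    feats = features.sort_values(["chrom", "start"], kind="mergesort")
    for reg in regions:
        f = feats[feats["chrom"] == reg.chrom]
        for row in f.itertuples(index=False):
            ov = min(reg.end, row.end) - max(reg.start, row.start)
            if ov > 0:
                hits.append(AnnotationHit(reg, str(row.name), int(row.chrom),
                                          int(row.start), int(row.end), int(ov)))
    return hits


def regions_to_bed(regions: list, path) -> None:
    """Write regions as BED (convert internal 1-based half-open to BED)."""
    with open(path, "w") as fh:
        for r in sorted(regions, key=lambda r: (r.chrom, r.start)):
            name = "+".join(sorted(r.tests)) if r.tests else "."
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end - 1}\t{name}\n")
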