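"""Sample/SNP quality control and misplaced-SNP detection.

The filter pipeline follows a fixed order: sample call rate, then SNP
filters (call rate, non-autosomal, duplicated position, monomorphic in all
lines), then the iterative misplaced-SNP detector. The detector exploits
LD decay with physical distance: a SNP whose strongest genotype-r2 partners
sit tens of megabases away is almost certainly mapped to the wrong place.

Per iteration the detector (1) records, for each candidate SNP, its top-k
same-chromosome SNPs by r2; (2) adds one flag per partner further away than
the flag distance; (3) removes, per chromosome, every SNP attaining that
chromosome's maximum flag count (if >= 1); and (4) repeats on the SNPs that
were flagged but not removed, until that candidate list is empty.
r2 is computed on genotype dosages (Pearson squared over complete pairs),
since this step runs before phasing in a real pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import MISSING, GenotypeMatrix, LineAssignment, SnpMap

__all__ = [
    "QcConfig",
    "QcReport",
    "filter_samples",
    "filter_snps",
    "genotype_r2",
    "detect_misplaced_snps",
    "run_qc",
]

CATTLE_AUTOSOMES = frozenset(range(1, 30))


@dataclass
class QcConfig:
    min_sample_call_rate: float = 0.90
    min_snp_call_rate: float = 0.95
    top_k: int = 10
    flag_distance_bp: int = 10_000_000
    autosomes: frozenset = CATTLE_AUTOSOMES
    detect_misplaced: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.min_sample_call_rate <= 1 and 0 <= self.min_snp_call_rate <= 1):
            raise ValueError("call-rate thresholds must be in [0, 1]")
        if self.top_k < 1 or self.flag_distance_bp <= 0:
            raise ValueError("top_k >= 1 and flag_distance_bp > 0 required")


@dataclass
class QcReport:
    """Removed ids with one primary reason each.

    ``samples``: list of (sample_id, reason); ``snps``: list of
    (snp_id, reason, iteration, flags) where iteration/flags are only
    meaningful for reason == 'misplaced'.
    """

    samples: list = field(default_factory=list)
    snps: list = field(default_factory=list)

    def add_sample(self, sid, reason) -> None:
        self.samples.append((str(sid), reason))

    def add_snp(self, sid, reason, iteration=None, flags=None) -> None:
        self.snps.append((str(sid), reason, iteration, flags))

    def to_dataframe(self) -> pd.DataFrame:
        rows = [{"id": s, "type": "sample", "reason": r, "iteration": None,
                 "flags": None} for s, r in self.samples]
        rows += [{"id": s, "type": "snp", "reason": r, "iteration": it, "flags": fl}
                 for s, r, it, fl in self.snps]
        return pd.DataFrame(rows, columns=["id", "type", "reason", "iteration", "flags"])

    def merge(self, other: "QcReport") -> "QcReport":
        return QcReport(self.samples + other.samples, self.snps + other.snps)


def filter_samples(G: GenotypeMatrix, cfg: QcConfig = QcConfig()):
    """Remove samples whose call rate is strictly below the threshold."""
    if G.n_samples == 0:
        raise ValueError("empty genotype matrix")
    rates = G.sample_call_rates()
    keep = rates >= cfg.min_sample_call_rate
    report = QcReport()
    for i in np.nonzero(~keep)[0]:
        report.add_sample(G.samples[i], f"call_rate<{cfg.min_sample_call_rate}")
    if not keep.any():
        raise ValueError("all samples removed by the call-rate filter")
    return G.subset_samples(np.nonzero(keep)[0]), report


def filter_snps(G: GenotypeMatrix, snp_map: SnpMap, lines: LineAssignment,
                cfg: QcConfig = QcConfig()):
    """SNP filters: call rate, non-autosomal, duplicated position, monomorphic.

    A SNP is dropped as monomorphic only if it is monomorphic within every
    line simultaneously; both members of a duplicated (chrom, pos) pair are
    removed. Each removed SNP is reported once with its first matching
    reason (call rate, autosome, duplicate, monomorphic — in that order).
    """
    lines.check_covers(G.samples)
    n = len(snp_map)
    reason = np.full(n, None, dtype=object)

    low_cr = G.snp_call_rates() < cfg.min_snp_call_rate
    reason[low_cr] = f"call_rate<{cfg.min_snp_call_rate}"

    non_auto = ~np.isin(snp_map.chrom, list(cfg.autosomes))
    reason[(reason == None) & non_auto] = "non_autosomal"  # noqa: E711

    keypos = snp_map.chrom.astype(np.int64) * 10**10 + snp_map.pos_bp
    _, inv, counts = np.unique(keypos, return_inverse=True, return_counts=True)
    dup = counts[inv] > 1
    reason[(reason == None) & dup] = "duplicate_position"  # noqa: E711

    mono_all = np.ones(n, dtype=bool)
    for label in lines.lines:
        rows = G.sample_index(lines.samples_in(label))
        d = G.dosages[rows]
        called = d != MISSING
        total = np.where(called, d, 0).sum(axis=0)
        n_called = called.sum(axis=0)
        # polymorphic within the line: some allele_b and some allele_a copies
        poly = (total > 0) & (total < 2 * n_called)
        mono_all &= ~poly
    reason[(reason == None) & mono_all] = "monomorphic_all_lines"  # noqa: E711

    keep = reason == None  # noqa: E711
    report = QcReport()
    for i in np.nonzero(~keep)[0]:
        report.add_snp(snp_map.snp_id[i], reason[i])
    idx = np.nonzero(keep)[0]
    return G.subset_snps(idx), snp_map.subset(idx), report


def genotype_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of dosage vectors over complete pairs.

    Undefined (fewer than 2 complete pairs, or zero variance in either
    vector) returns NaN; ranking code treats NaN as 0.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 2:
        return float("nan")
    xs, ys = x[ok], y[ok]
    vx = xs.var()
    vy = ys.var()
    if vx == 0 or vy == 0:
        return float("nan")
    c = np.mean((xs - xs.mean()) * (ys - ys.mean()))
    return float(c * c / (vx * vy))


def _pairwise_r2(d: np.ndarray) -> np.ndarray:
    """All-pairs complete-case r2 between columns of a dosage matrix.

    NaN (undefined) entries are returned as 0 so they never enter a top-k
    list; the diagonal is set to 0.
    """
    X = d.astype(np.float64)
    M = (d != MISSING).astype(np.float64)
    X0 = np.where(d == MISSING, 0.0, X)
    n = M.T @ M
    sx = X0.T @ M
    sxy = X0.T @ X0
    sxx = (X0 * X0).T @ M
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n * sxy - sx * sx.T
        var = (n * sxx - sx**2) * (n * sxx.T - (sx.T) ** 2)
        r2 = np.where((n >= 2) & (var > 0), cov * cov / var, 0.0)
    np.fill_diagonal(r2, 0.0)
    return np.clip(r2, 0.0, 1.0)


def detect_misplaced_snps(G: GenotypeMatrix, snp_map: SnpMap,
                          cfg: QcConfig = QcConfig()):
    """Iterative r2-vs-distance misplaced-SNP detection.

    Returns ``(removed_snp_ids, QcReport)``; the report records the
    iteration index and flag count of each removal. Within the top-k
    ranking, r2 ties break toward the physically closer partner, then map
    order. Chromosomes with fewer than top_k + 1 SNPs use all available
    partners.
    """
    if not snp_map.is_sorted():
        raise ValueError("snp_map must be sorted by (chrom, pos)")
    report = QcReport()
    removed_ids: list = []

    for c in np.unique(snp_map.chrom):
        cidx = np.nonzero(snp_map.chrom == c)[0]
        pos = snp_map.pos_bp[cidx].astype(np.int64)
        m = len(cidx)
        if m < 2:
            continue
        r2 = _pairwise_r2(G.dosages[:, cidx])
        dist = np.abs(pos[:, None] - pos[None, :])
        alive = np.ones(m, dtype=bool)
        candidates = np.arange(m)
        iteration = 0
        while len(candidates) > 0:
            iteration += 1
            flags = np.zeros(m, dtype=np.int64)
            k = cfg.top_k
            for j in candidates:
                partners = np.nonzero(alive)[0]
                partners = partners[partners != j]
                if len(partners) == 0:
                    continue
                # rank by r2 desc, then distance asc, then map order
                order = np.lexsort((partners, dist[j, partners], -r2[j, partners]))
                top = partners[order[:k]]
                flags[j] = int(np.sum(dist[j, top] > cfg.flag_distance_bp))
            maxf = flags[candidates].max() if len(candidates) else 0
            if maxf < 1:
                break
            hit = [j for j in candidates if flags[j] == maxf]
            for j in hit:
                alive[j] = False
                sid = str(snp_map.snp_id[cidx[j]])
                removed_ids.append(sid)
                report.add_snp(sid, "misplaced", iteration=iteration,
                               flags=int(flags[j]))
            candidates = np.array(
                [j for j in candidates if flags[j] >= 1 and alive[j]], dtype=np.int64)
    return removed_ids, report


def run_qc(G: GenotypeMatrix, snp_map: SnpMap, lines: LineAssignment,
           cfg: QcConfig = QcConfig()):
    """Full QC: samples -> SNP filters -> misplaced-SNP detection.

    Returns ``(G', snp_map', QcReport)``. Each stage is idempotent; the
    composite therefore is as well.
    """
    G1, rep_s = filter_samples(G, cfg)
    G2, map2, rep_snp = filter_snps(G1, snp_map, lines, cfg)
    report = rep_s.merge(rep_snp)
    if cfg.detect_misplaced and len(map2) > 0:
        removed, rep_mis = detect_misplaced_snps(G2, map2, cfg)
        report = report.merge(rep_mis)
        if removed:
            keep = ~np.isin(map2.snp_id.astype(str), removed)
            idx = np.nonzero(keep)[0]
            G2, map2 = G2.subset_snps(idx), map2.subset(idx)
    return G2, map2, report
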