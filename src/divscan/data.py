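"""Core genotype/haplotype containers for the selection-scan pipeline.

Conventions used throughout the package:

* Positions are 1-based bp (VCF/PLINK-MAP convention); all window and region
  intervals are half-open ``[start, end)`` on the same bp axis.
* A genotype dosage counts copies of ``allele_b`` (0/1/2); missing is ``-1``.
* Haplotype matrices are phased and complete: row ``2*i`` and ``2*i + 1``
  are the two haplotypes of sample ``i``, values in {0, 1} where 1 is
  ``allele_b``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

__all__ = [
    "MISSING",
    "SnpMap",
    "GenotypeMatrix",
    "HaplotypeMatrix",
    "LineAssignment",
    "AlleleFreq",
    "allele_frequencies",
]


@dataclass
class SnpMap:
    """Per-SNP map: identifier, autosome number, 1-based position, alleles.

    ``allele_b`` is the counted allele (dosage = copies of ``allele_b``).
    """

    snp_id: np.ndarray
    chrom: np.ndarray
    pos_bp: np.ndarray
    allele_a: np.ndarray
    allele_b: np.ndarray

    def __post_init__(self) -> None:
        self.snp_id = np.asarray(self.snp_id, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=np.int64)
        self.pos_bp = np.asarray(self.pos_bp, dtype=np.int64)
        self.allele_a = np.asarray(self.allele_a, dtype=object)
        self.allele_b = np.asarray(self.allele_b, dtype=object)
        n = len(self.snp_id)
        for arr in (self.chrom, self.pos_bp, self.allele_a, self.allele_b):
            if len(arr) != n:
                raise ValueError("SnpMap field lengths differ")
        if np.any(self.pos_bp < 1):
            raise ValueError("positions must be 1-based (>= 1)")

    def __len__(self) -> int:
        return len(self.snp_id)

    def is_sorted(self) -> bool:
        order = np.lexsort((self.pos_bp, self.chrom))
        return bool(np.array_equal(order, np.arange(len(self))))

    def sort_order(self) -> np.ndarray:
        """Column permutation sorting by (chrom, pos); stable."""
        return np.lexsort((self.pos_bp, self.chrom))

    def subset(self, idx: np.ndarray) -> "SnpMap":
        return SnpMap(
            self.snp_id[idx],
            self.chrom[idx],
            self.pos_bp[idx],
            self.allele_a[idx],
            self.allele_b[idx],
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp_id": self.snp_id,
                "chrom": self.chrom,
                "pos_bp": self.pos_bp,
                "allele_a": self.allele_a,
                "allele_b": self.allele_b,
            }
        )


@dataclass
class GenotypeMatrix:
    """Samples x SNPs dosage matrix; dosage counts allele_b, missing = -1."""

    samples: list
    dosages: np.ndarray  # int8, shape (n_samples, n_snps)

    def __post_init__(self) -> None:
        self.samples = list(self.samples)
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2 or self.dosages.shape[0] != len(self.samples):
            raise ValueError("dosage matrix shape does not match sample list")
        bad = ~np.isin(self.dosages, [MISSING, 0, 1, 2])
        if bad.any():
            raise ValueError("dosages must be in {0,1,2} or missing (-1)")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def missing_mask(self) -> np.ndarray:
        return self.dosages == MISSING

    def sample_call_rates(self) -> np.ndarray:
        if self.n_snps == 0:
            return np.ones(self.n_samples)
        return 1.0 - self.missing_mask().mean(axis=1)

    def snp_call_rates(self) -> np.ndarray:
        if self.n_samples == 0:
            return np.ones(self.n_snps)
        return 1.0 - self.missing_mask().mean(axis=0)

    def subset_samples(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        return GenotypeMatrix(
            [self.samples[i] for i in np.arange(self.n_samples)[keep]]
            if keep.dtype == bool
            else [self.samples[i] for i in keep],
            self.dosages[keep],
        )

    def subset_snps(self, idx: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(self.samples, self.dosages[:, idx])

    def sample_index(self, ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([lookup[s] for s in ids], dtype=np.int64)
        except KeyError as e:
            raise KeyError(f"unknown sample id: {e.args[0]!r}") from None


@dataclass
class HaplotypeMatrix:
    """(2 x samples) x SNPs phased binary matrix; rows 2i, 2i+1 = sample i."""

    samples: list
    haplotypes: np.ndarray  # uint8, shape (2*n_samples, n_snps)

    def __post_init__(self) -> None:
        self.samples = list(self.samples)
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        if self.haplotypes.ndim != 2 or self.haplotypes.shape[0] != 2 * len(self.samples):
            raise ValueError("haplotype matrix must have 2 rows per sample")
        if self.haplotypes.size and self.haplotypes.max() > 1:
            raise ValueError("haplotype values must be binary")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return self.haplotypes.shape[1]

    def to_genotypes(self) -> GenotypeMatrix:
        """Collapse haplotype pairs by summation into a dosage matrix."""
        d = self.haplotypes[0::2].astype(np.int8) + self.haplotypes[1::2]
        return GenotypeMatrix(self.samples, d)

    def subset_samples(self, idx: np.ndarray) -> "HaplotypeMatrix":
        idx = np.asarray(idx, dtype=np.int64)
        rows = np.empty(2 * len(idx), dtype=np.int64)
        rows[0::2] = 2 * idx
        rows[1::2] = 2 * idx + 1
        return HaplotypeMatrix([self.samples[i] for i in idx], self.haplotypes[rows])

    def subset_snps(self, idx: np.ndarray) -> "HaplotypeMatrix":
        return HaplotypeMatrix(self.samples, self.haplotypes[:, idx])

    def sample_index(self, ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([lookup[s] for s in ids], dtype=np.int64)
        except KeyError as e:
            raise KeyError(f"unknown sample id: {e.args[0]!r}") from None

    def haplotype_rows(self, sample_ids) -> np.ndarray:
        """Row indices of both haplotypes of each listed sample."""
        idx = self.sample_index(sample_ids)
        rows = np.empty(2 * len(idx), dtype=np.int64)
        rows[0::2] = 2 * idx
        rows[1::2] = 2 * idx + 1
        return rows


@dataclass
class LineAssignment:
    """Sample-to-line mapping with one control line and >=1 selected lines."""

    mapping: dict
    control: str
    selected: list = field(default_factory=list)

    def __post_init__(self) -> None:
        labels = set(self.mapping.values())
        if self.control not in labels:
            raise ValueError(f"control line {self.control!r} has no samples")
        if not self.selected:
            self.selected = sorted(labels - {self.control})
        if not self.selected:
            raise ValueError("at least one selected line required")
        if self.control in self.selected:
            raise ValueError("control line cannot also be selected")

    @property
    def lines(self) -> list:
        return [self.control] + list(self.selected)

    def samples_in(self, line: str) -> list:
        return [s for s, l in self.mapping.items() if l == line]

    def check_covers(self, samples) -> None:
        missing = [s for s in samples if s not in self.mapping]
        if missing:
            raise ValueError(f"samples without a line label: {missing[:5]}")


@dataclass
class AlleleFreq:
    """Per-SNP called-diploid counts and allele_b frequency for one subset."""

    n_called: np.ndarray
    p_b: np.ndarray  # NaN where undefined (no calls)

    @property
    def maf(self) -> np.ndarray:
        return np.minimum(self.p_b, 1.0 - self.p_b)


def allele_frequencies(G: GenotypeMatrix, subset=None) -> AlleleFreq:
    """Allele_b frequencies ``p_b = sum(dosage) / (2 n_called)`` per SNP.

    ``subset`` is an optional list of sample ids; SNPs with no called
    genotypes in the subset get ``p_b = NaN``.
    """
    if subset is None:
        d = G.dosages
    else:
        subset = list(subset)
        if len(subset) == 0:
            raise ValueError("subset must be non-empty")
        d = G.dosages[G.sample_index(subset)]
    called = d != MISSING
    n_called = called.sum(axis=0)
    total = np.where(called, d, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_called > 0, total / (2.0 * np.maximum(n_called, 1)), np.nan)
    return AlleleFreq(n_called=n_called.astype(np.int64), p_b=p)
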