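"""Readers/writers for PLINK text PED/MAP, phased VCF, and line tables.

PED/MAP parsing is done by hand (whitespace format, 6 leading PED columns
then two allele columns per SNP); phased VCF is read through cyvcf2.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data import MISSING, GenotypeMatrix, HaplotypeMatrix, LineAssignment, SnpMap

__all__ = [
    "read_plink_text",
    "write_plink_text",
    "read_phased_vcf",
    "write_phased_vcf",
    "read_line_assignment",
    "write_line_assignment",
]


class FormatError(ValueError):
    """Malformed input file."""


def read_plink_text(ped_path, map_path):
    """Read PLINK text PED/MAP into a dosage matrix.

    Dosage counts the less frequent observed allele at load time
    (``allele_b``; ties broken toward the lexicographically larger label);
    ``0`` is the PLINK missing-allele code. Returns
    ``(GenotypeMatrix, SnpMap, sample_ids)``.
    """
    mp = pd.read_csv(
        map_path, sep=r"\s+", header=None, names=["chrom", "snp_id", "cm", "pos_bp"],
        dtype={"chrom": np.int64, "snp_id": str, "pos_bp": np.int64},
    )
    n_snps = len(mp)
    samples = []
    rows_a1 = []
    rows_a2 = []
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_snps:
                raise FormatError(
                    f"PED line {ln}: {len(parts)} fields, expected {6 + 2 * n_snps} "
                    f"for {n_snps} MAP SNPs"
                )
            samples.append(parts[1])
            rows_a1.append(parts[6::2])
            rows_a2.append(parts[7::2])
    a1 = np.asarray(rows_a1, dtype=object)
    a2 = np.asarray(rows_a2, dtype=object)
    n = len(samples)
    dosages = np.full((n, n_snps), MISSING, dtype=np.int8)
    allele_a = np.empty(n_snps, dtype=object)
    allele_b = np.empty(n_snps, dtype=object)
    for j in range(n_snps):
        col = np.concatenate([a1[:, j], a2[:, j]]) if n else np.array([], dtype=object)
        obs = col[col != "0"]
        alleles, counts = np.unique(obs, return_counts=True)
        if len(alleles) > 2:
            raise FormatError(
                f"SNP {mp.snp_id.iloc[j]!r}: more than 2 alleles observed "
                f"({', '.join(map(str, alleles))})"
            )
        if len(alleles) == 2:
            # allele_b = minor; tie -> lexicographically larger label
            if counts[0] < counts[1] or (counts[0] == counts[1] and alleles[0] > alleles[1]):
                b, a = alleles[0], alleles[1]
            else:
                b, a = alleles[1], alleles[0]
        elif len(alleles) == 1:
            a, b = alleles[0], "0"
        else:
            a, b = "0", "0"
        allele_a[j], allele_b[j] = a, b
        miss = (a1[:, j] == "0") | (a2[:, j] == "0")
        dos = (a1[:, j] == b).astype(np.int8) + (a2[:, j] == b).astype(np.int8)
        dosages[:, j] = np.where(miss, MISSING, dos)
    snp_map = SnpMap(mp.snp_id.to_numpy(object), mp.chrom.to_numpy(),
                     mp.pos_bp.to_numpy(), allele_a, allele_b)
    return GenotypeMatrix(samples, dosages), snp_map, samples


def write_plink_text(G: GenotypeMatrix, snp_map: SnpMap, ped_path, map_path,
                     lines: LineAssignment | None = None) -> None:
    with open(map_path, "w") as fh:
        for i in range(len(snp_map)):
            fh.write(f"{snp_map.chrom[i]}\t{snp_map.snp_id[i]}\t0\t{snp_map.pos_bp[i]}\n")
    a = snp_map.allele_a
    b = snp_map.allele_b
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(G.samples):
            fam = lines.mapping[sid] if lines is not None else sid
            fields = [str(fam), str(sid), "0", "0", "0", "-9"]
            d = G.dosages[i]
            for j in range(G.n_snps):
                if d[j] == MISSING:
                    fields += ["0", "0"]
                elif d[j] == 0:
                    fields += [str(a[j]), str(a[j])]
                elif d[j] == 1:
                    fields += [str(a[j]), str(b[j])]
                else:
                    fields += [str(b[j]), str(b[j])]
            fh.write(" ".join(fields) + "\n")


def read_phased_vcf(vcf_path):
    """Read a phased biallelic-SNP VCF into a HaplotypeMatrix.

    REF maps to 0 (``allele_a``), ALT to 1 (``allele_b``). Unphased,
    multiallelic or missing genotypes raise a ``FormatError`` naming the
    record. Returns ``(HaplotypeMatrix, SnpMap, sample_ids)``.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    n = len(samples)
    cols = []
    ids, chroms, poss, refs, alts = [], [], [], [], []
    for var in vcf:
        where = f"record {var.CHROM}:{var.POS}"
        if len(var.ALT) != 1:
            raise FormatError(f"{where}: not biallelic (ALT={var.ALT})")
        gts = var.genotypes  # [a0, a1, phased] per sample
        col = np.empty(2 * n, dtype=np.uint8)
        for i, g in enumerate(gts):
            if len(g) < 3 or g[0] < 0 or g[1] < 0:
                raise FormatError(f"{where}: missing genotype for sample {samples[i]}")
            if not g[-1]:
                raise FormatError(f"{where}: unphased genotype for sample {samples[i]}")
            col[2 * i] = g[0]
            col[2 * i + 1] = g[1]
        cols.append(col)
        ids.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}")
        chroms.append(int(str(var.CHROM).removeprefix("chr")))
        poss.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0])
    hap = np.column_stack(cols) if cols else np.empty((2 * n, 0), dtype=np.uint8)
    snp_map = SnpMap(np.array(ids, dtype=object), np.array(chroms), np.array(poss),
                     np.array(refs, dtype=object), np.array(alts, dtype=object))
    return HaplotypeMatrix(samples, hap), snp_map, samples


def write_phased_vcf(H: HaplotypeMatrix, snp_map: SnpMap, vcf_path) -> None:
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in sorted(set(snp_map.chrom.tolist())):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(map(str, H.samples)) + "\n")
        hp = H.haplotypes
        for j in range(len(snp_map)):
            gts = "\t".join(
                f"{hp[2 * i, j]}|{hp[2 * i + 1, j]}" for i in range(H.n_samples)
            )
            ref = snp_map.allele_a[j] if snp_map.allele_a[j] != "0" else "A"
            alt = snp_map.allele_b[j] if snp_map.allele_b[j] != "0" else "T"
            fh.write(f"{snp_map.chrom[j]}\t{snp_map.pos_bp[j]}\t{snp_map.snp_id[j]}\t"
                     f"{ref}\t{alt}\t.\tPASS\t.\tGT\t{gts}\n")


def read_line_assignment(tsv_path, control: str, selected=None) -> LineAssignment:
    """Read a two-column TSV (sample_id, line) into a LineAssignment."""
    df = pd.read_csv(tsv_path, sep="\t", dtype=str)
    if not {"sample_id", "line"}.issubset(df.columns):
        raise FormatError("line table needs columns: sample_id, line")
    mapping = dict(zip(df["sample_id"], df["line"]))
    return LineAssignment(mapping, control=control,
                          selected=list(selected) if selected else [])


def write_line_assignment(lines: LineAssignment, tsv_path) -> None:
    pd.DataFrame(
        {"sample_id": list(lines.mapping), "line": list(lines.mapping.values())}
    ).to_csv(tsv_path, sep="\t", index=False)
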