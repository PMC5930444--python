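import numpy as np
import pytest

from divscan.data import GenotypeMatrix, HaplotypeMatrix, LineAssignment, SnpMap


@pytest.fixture
def toy_map():
    """Six SNPs on two autosomes, sorted."""
    return SnpMap(
        snp_id=np.array([f"s{i}" for i in range(6)], dtype=object),
        chrom=np.array([1, 1, 1, 2, 2, 2]),
        pos_bp=np.array([100, 2000, 50_000, 100, 5000, 9000]),
        allele_a=np.array(["A"] * 6, dtype=object),
        allele_b=np.array(["G"] * 6, dtype=object),
    )


@pytest.fixture
def toy_lines():
    mapping = {"c1": "CTRL", "c2": "CTRL", "s1": "SELA", "s2": "SELA",
               "t1": "SELB", "t2": "SELB"}
    return LineAssignment(mapping, control="CTRL", selected=["SELA", "SELB"])


@pytest.fixture
def toy_genotypes(toy_lines):
    rng = np.random.default_rng(42)
    samples = list(toy_lines.mapping)
    d = rng.integers(0, 3, size=(len(samples), 6)).astype(np.int8)
    return GenotypeMatrix(samples, d)


def random_haplotypes(rng, n_samples, n_snps, p=None):
    """Random phased matrix with frequencies away from fixation."""
    if p is None:
        p = rng.uniform(0.1, 0.9, size=n_snps)
    h = (rng.random((2 * n_samples, n_snps)) < p).astype(np.uint8)
    return HaplotypeMatrix([f"smp{i}" for i in range(n_samples)], h)
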