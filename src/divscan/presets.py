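"""Desk-scale study presets for the simulator.

These configurations define the reference simulation study used by the
test-bench and the reproduction script: a compressed genome (4 chromosomes
of 12 Mb treated as ~1 Morgan each, ~250 SNPs/Mb — BovineHD-like marker
density) and line sizes chosen so the hermaphroditic truncation model
reproduces the effective-size ordering of the real experiment (control
line smallest: Ne ~ 40 for the control vs ~60/70 for the selected lines,
mirroring the 51/88/177 pattern), which is what drives the genome-wide
mean FST ordering control-vs-selected > selected-vs-selected.

The sweep scenario places one large-effect QTL (0.5 environmental SDs per
allele copy) mid-chromosome-1, with the favored allele segregating at
intermediate frequency at the line split (standing variation), and runs 10
generations of truncation selection retaining the top 20%. The neutral
scenario keeps the same genome and selection regime but no QTL (truncation
on a pure-noise trait) and smaller selected lines — a harsher, more-drift
null for false-positive checks.
"""

from __future__ import annotations

from .simulate import SimConfig

__all__ = ["desk_scale_config", "QTL_CHROM", "QTL_POS_BP"]

QTL_CHROM = 1
QTL_POS_BP = 6_000_000


def desk_scale_config(seed: int, sweep: bool = True) -> SimConfig:
    """The reference desk-scale simulation study.

    ``sweep=True`` adds the single large-effect QTL; ``sweep=False`` is the
    neutral null (truncation on a pure-noise trait).
    """
    return SimConfig(
        seed=seed,
        n_chrom=4,
        chrom_length_bp=12_000_000,
        n_snps_per_chrom=3000,
        founder_pop_size=120,
        burnin_generations=100,
        line_sizes={"NeC": 40, "NeS": 300, "NeT": 350} if sweep
        else {"NeC": 40, "NeS": 150, "NeT": 150},
        control_label="NeC",
        selection_generations=10,
        qtl_positions=[(QTL_CHROM, QTL_POS_BP)] if sweep else [],
        qtl_effects=[0.5] if sweep else [],
        env_sd=1.0,
        selected_fraction=0.2,
    )
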