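"""Forward-in-time Wright-Fisher simulator of divergently selected lines.

Emulates a cattle selection experiment: a founder population accumulates
linkage disequilibrium by drift during a burn-in phase, then splits into a
control line (parents drawn at random, mimicking stabilizing selection on
the original population mean) and one or more lines under truncation
selection for a quantitative trait controlled by known QTL. The final
generation is exported phased, together with full ground truth (QTL
positions, effects and per-line favored-allele frequencies).

Generations are discrete and non-overlapping; mating is hermaphroditic
random pairing of distinct parents. Crossovers are a Poisson process along
each chromosome at a per-bp rate (default 1e-8, i.e. ~1 cM/Mb). There is no
mutation after the founder generation, so all variation segregating at the
end descends from founder haplotypes — adequate for drift/selection signal
at the time scales modeled (tens of generations).

Artifact-injection helpers (`inject_missingness`, `relocate_snps`) create
ground truth for the QC stages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .data import MISSING, GenotypeMatrix, HaplotypeMatrix, LineAssignment, SnpMap

__all__ = [
    "SimConfig",
    "SimTruth",
    "QtlTruth",
    "simulate_lines",
    "inject_missingness",
    "relocate_snps",
]


@dataclass
class SimConfig:
    """Parameters of the line-simulation experiment.

    Defaults mirror the experimental design the simulator emulates: one
    control line of ~90 animals and two selected lines of ~190 and ~480,
    eight generations of truncation selection retaining the top 20% by
    trait value.
    """

    seed: int = 1234
    n_chrom: int = 3
    chrom_length_bp: int = 10_000_000
    n_snps_per_chrom: int = 2000
    founder_pop_size: int = 100
    burnin_generations: int = 100
    line_sizes: dict = field(
        default_factory=lambda: {"NeC": 90, "NeS": 190, "NeT": 480}
    )
    control_label: str = "NeC"
    selection_generations: int = 8
    qtl_positions: list = field(default_factory=list)  # [(chrom, pos_bp)]
    qtl_effects: list = field(default_factory=list)    # additive effect per copy of allele 1
    env_sd: float = 1.0
    selected_fraction: float = 0.2
    # Per-bp per-meiosis crossover probability. The desk-scale genome
    # compresses a ~100-Mb autosome into chrom_length_bp, so the default
    # preserves a genetic length of ~1 Morgan per chromosome
    # (1e-7 * 1e7 bp = 1 crossover per meiosis).
    recomb_rate: float = 1e-7
    # Founder frequency of allele 1 at each QTL, and the band the favored
    # allele must occupy at line split (burn-in is replayed until it does,
    # conditioning the sweep on standing variation at moderate frequency).
    qtl_founder_freq: float = 0.30
    qtl_split_band: tuple = (0.20, 0.50)
    max_burnin_attempts: int = 100

    def validate(self) -> None:
        if not (0 < self.selected_fraction <= 1):
            raise ValueError("selected_fraction must be in (0, 1]")
        if self.founder_pop_size < 2 or any(n < 2 for n in self.line_sizes.values()):
            raise ValueError("all population sizes must be >= 2")
        if self.control_label not in self.line_sizes:
            raise ValueError("control_label must be a key of line_sizes")
        if len(self.qtl_positions) != len(self.qtl_effects):
            raise ValueError("qtl_positions and qtl_effects must have equal length")
        if self.n_chrom < 1 or self.n_snps_per_chrom < 1 or self.chrom_length_bp < 2:
            raise ValueError("invalid genome dimensions")
        for c, p in self.qtl_positions:
            if not (1 <= c <= self.n_chrom) or not (1 <= p <= self.chrom_length_bp):
                raise ValueError(f"QTL ({c}, {p}) outside the simulated genome")

    @property
    def selected_labels(self) -> list:
        return [l for l in self.line_sizes if l != self.control_label]


@dataclass
class QtlTruth:
    chrom: int
    pos_bp: int
    snp_index: int
    effect: float
    favored_allele: int  # 1 if effect > 0 else 0
    freq_by_line: dict   # line -> final favored-allele frequency


@dataclass
class SimTruth:
    qtls: list
    line_assignment: LineAssignment
    warnings: list = field(default_factory=list)


def _build_map(cfg: SimConfig, rng: np.random.Generator) -> SnpMap:
    chroms, positions = [], []
    qtl_by_chrom = {}
    for c, p in cfg.qtl_positions:
        qtl_by_chrom.setdefault(c, set()).add(int(p))
    for c in range(1, cfg.n_chrom + 1):
        pos = set(qtl_by_chrom.get(c, set()))
        if len(pos) > cfg.n_snps_per_chrom:
            raise ValueError(f"more QTLs than SNPs on chromosome {c}")
        while len(pos) < cfg.n_snps_per_chrom:
            draw = rng.integers(1, cfg.chrom_length_bp + 1,
                                size=cfg.n_snps_per_chrom - len(pos))
            pos.update(int(p) for p in draw)
        p_sorted = np.array(sorted(pos), dtype=np.int64)
        chroms.append(np.full(len(p_sorted), c, dtype=np.int64))
        positions.append(p_sorted)
    chrom = np.concatenate(chroms)
    pos = np.concatenate(positions)
    ids = np.array([f"snp_{c}_{p}" for c, p in zip(chrom, pos)], dtype=object)
    return SnpMap(ids, chrom, pos,
                  np.full(len(ids), "A", dtype=object),
                  np.full(len(ids), "T", dtype=object))


def _chrom_slices(snp_map: SnpMap):
    slices = []
    for c in np.unique(snp_map.chrom):
        idx = np.nonzero(snp_map.chrom == c)[0]
        slices.append((idx[0], idx[-1] + 1))
    return slices


def _gamete(h1, h2, pos_by_chrom, slices, chrom_length, rate, rng):
    """One recombinant gamete from a parent's haplotype pair."""
    out = np.empty(h1.shape[0], dtype=np.uint8)
    for (lo, hi), pos in zip(slices, pos_by_chrom):
        k = rng.poisson(rate * chrom_length)
        start = rng.integers(0, 2)
        if k == 0:
            out[lo:hi] = h1[lo:hi] if start == 0 else h2[lo:hi]
            continue
        xovers = np.sort(rng.integers(1, chrom_length + 1, size=k))
        # segment index per SNP; alternate between the two parental haplotypes
        seg = np.searchsorted(xovers, pos, side="left")
        use_h1 = (seg + start) % 2 == 0
        out[lo:hi] = np.where(use_h1, h1[lo:hi], h2[lo:hi])
    return out


def _next_generation(haps, n_offspring, parent_pool, pos_by_chrom, slices,
                     chrom_length, rate, rng):
    """Random pairing of distinct parents from the pool; two gametes each child."""
    n_pool = len(parent_pool)
    out = np.empty((2 * n_offspring, haps.shape[1]), dtype=np.uint8)
    for i in range(n_offspring):
        pa, pb = parent_pool[rng.choice(n_pool, size=2, replace=False)]
        out[2 * i] = _gamete(haps[2 * pa], haps[2 * pa + 1], pos_by_chrom, slices,
                             chrom_length, rate, rng)
        out[2 * i + 1] = _gamete(haps[2 * pb], haps[2 * pb + 1], pos_by_chrom, slices,
                                 chrom_length, rate, rng)
    return out


def simulate_lines(cfg: SimConfig):
    """Run the full simulation.

    Returns ``(HaplotypeMatrix, SnpMap, LineAssignment, SimTruth)`` for the
    final generation of all lines pooled, phased and complete.
    """
    cfg.validate()
    ss = np.random.SeedSequence(cfg.seed)
    ss_map, ss_founder, ss_burn, ss_lines = ss.spawn(4)
    rng = np.random.default_rng(ss_map)
    snp_map = _build_map(cfg, rng)
    n_snps = len(snp_map)
    slices = _chrom_slices(snp_map)
    pos_by_chrom = [snp_map.pos_bp[lo:hi] for lo, hi in slices]

    # founder frequencies: U-shaped folded SFS, truncated to avoid fixation
    rng_f = np.random.default_rng(ss_founder)
    freqs = rng_f.beta(0.5, 0.5, size=n_snps)
    freqs = np.clip(freqs, 0.05, 0.95)

    qtl_idx = []
    for c, p in cfg.qtl_positions:
        j = int(np.nonzero((snp_map.chrom == c) & (snp_map.pos_bp == p))[0][0])
        qtl_idx.append(j)
    freqs[qtl_idx] = cfg.qtl_founder_freq

    nf = cfg.founder_pop_size
    founders = (rng_f.random((2 * nf, n_snps)) < freqs).astype(np.uint8)

    pool_all = np.arange(nf)
    truth_warnings = []

    def _qtl_ok(h) -> bool:
        lo, hi = cfg.qtl_split_band
        for j, e in zip(qtl_idx, cfg.qtl_effects):
            f1 = h[:, j].mean()
            fav = f1 if e > 0 else 1.0 - f1
            if not (lo <= fav <= hi):
                return False
        return True

    # burn-in; replayed until every QTL's favored allele sits in the split
    # band (rejection over burn-in replays conditions the sweep on standing
    # variation at moderate frequency)
    attempts = max(1, cfg.max_burnin_attempts) if qtl_idx else 1
    haps = founders
    for attempt in range(attempts):
        rng_b = np.random.default_rng(ss_burn.spawn(1)[0])
        haps = founders
        for _ in range(cfg.burnin_generations):
            haps = _next_generation(haps, nf, pool_all, pos_by_chrom, slices,
                                    cfg.chrom_length_bp, cfg.recomb_rate, rng_b)
        if not qtl_idx or _qtl_ok(haps):
            break
    else:
        truth_warnings.append(
            f"no burn-in replay out of {attempts} put every QTL's favored allele "
            f"in the split band {cfg.qtl_split_band}; using the last replay")

    for (c, p), j in zip(cfg.qtl_positions, qtl_idx):
        f = haps[:, j].mean()
        if f in (0.0, 1.0):
            truth_warnings.append(
                f"QTL {c}:{p} monomorphic at line split (freq {f:.0f}); sweep cannot proceed"
            )
    rng = np.random.default_rng(ss_lines)

    effects = np.zeros(n_snps)
    for j, e in zip(qtl_idx, cfg.qtl_effects):
        effects[j] = e

    line_haps = {}
    labels = [cfg.control_label] + cfg.selected_labels
    for label in labels:
        n_line = cfg.line_sizes[label]
        line_haps[label] = _next_generation(
            haps, n_line, pool_all, pos_by_chrom, slices,
            cfg.chrom_length_bp, cfg.recomb_rate, rng)

    any_effect = bool(qtl_idx)
    for _ in range(cfg.selection_generations):
        for label in labels:
            h = line_haps[label]
            n_line = cfg.line_sizes[label]
            if label == cfg.control_label or not any_effect:
                pool = np.arange(n_line)
                if label != cfg.control_label and cfg.selected_fraction < 1:
                    # truncation on a pure-noise trait = random subset
                    trait = rng.normal(0.0, cfg.env_sd, size=n_line)
                    n_keep = max(2, int(np.ceil(cfg.selected_fraction * n_line)))
                    pool = np.argsort(trait)[::-1][:n_keep]
            else:
                dose = h[0::2].astype(np.float64) + h[1::2]
                trait = dose @ effects + rng.normal(0.0, cfg.env_sd, size=n_line)
                n_keep = max(2, int(np.ceil(cfg.selected_fraction * n_line)))
                pool = np.argsort(trait)[::-1][:n_keep]
            line_haps[label] = _next_generation(
                h, n_line, pool, pos_by_chrom, slices,
                cfg.chrom_length_bp, cfg.recomb_rate, rng)

    samples, mapping, blocks = [], {}, []
    for label in labels:
        n_line = cfg.line_sizes[label]
        ids = [f"{label}_{i:03d}" for i in range(n_line)]
        samples.extend(ids)
        mapping.update({s: label for s in ids})
        blocks.append(line_haps[label])
    H = HaplotypeMatrix(samples, np.vstack(blocks))
    lines = LineAssignment(mapping, control=cfg.control_label,
                           selected=cfg.selected_labels)

    qtls = []
    for (c, p), j, e in zip(cfg.qtl_positions, qtl_idx, cfg.qtl_effects):
        fav = 1 if e > 0 else 0
        freq_by_line = {}
        for label in labels:
            col = line_haps[label][:, j]
            f1 = float(col.mean())
            freq_by_line[label] = f1 if fav == 1 else 1.0 - f1
        qtls.append(QtlTruth(c, p, j, float(e), fav, freq_by_line))
    truth = SimTruth(qtls=qtls, line_assignment=lines, warnings=truth_warnings)
    return H, snp_map, lines, truth


def inject_missingness(G: GenotypeMatrix, snp_rate: float = 0.0,
                       sample_rates: dict | None = None, seed: int = 0) -> GenotypeMatrix:
    """Set entries missing independently.

    ``snp_rate`` applies to every entry; ``sample_rates`` maps sample id to
    an extra per-sample rate. The two combine as independent drop chances:
    ``p_miss = 1 - (1 - snp_rate)(1 - sample_rate)``.
    """
    if not (0 <= snp_rate <= 1):
        raise ValueError("snp_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    p = np.full(G.n_samples, snp_rate)
    if sample_rates:
        for sid, r in sample_rates.items():
            if not (0 <= r <= 1):
                raise ValueError("sample rates must be in [0, 1]")
            i = G.samples.index(sid)
            p[i] = 1.0 - (1.0 - snp_rate) * (1.0 - r)
    miss = rng.random(G.dosages.shape) < p[:, None]
    d = G.dosages.copy()
    d[miss] = MISSING
    return GenotypeMatrix(G.samples, d)


def relocate_snps(snp_map: SnpMap, n: int, min_shift_bp: int, seed: int = 0,
                  chrom_length_bp: int | None = None):
    """Move ``n`` random SNPs >= ``min_shift_bp`` away on their chromosome.

    Returns ``(new_map, truth, order)``: the re-sorted map, a list of
    ``(snp_id, chrom, old_pos, new_pos)`` tuples, and the column permutation
    to apply to any aligned genotype/haplotype matrix so columns follow
    their SNPs.
    """
    rng = np.random.default_rng(seed)
    pos = snp_map.pos_bp.copy()
    chrom = snp_map.chrom
    truth = []
    if n > 0:
        chosen = rng.choice(len(snp_map), size=n, replace=False)
        taken = {(int(c), int(p)) for c, p in zip(chrom, pos)}
        for j in chosen:
            c = int(chrom[j])
            length = chrom_length_bp if chrom_length_bp is not None else int(
                pos[chrom == c].max())
            old = int(pos[j])
            lo_ok = old - min_shift_bp >= 1
            hi_ok = old + min_shift_bp <= length
            if not lo_ok and not hi_ok:
                raise ValueError(
                    f"chromosome {c} too short to shift SNP {snp_map.snp_id[j]} "
                    f"by {min_shift_bp} bp")
            for _ in range(10_000):
                new = int(rng.integers(1, length + 1))
                if abs(new - old) >= min_shift_bp and (c, new) not in taken:
                    break
            else:  # pragma: no cover - astronomically unlikely
                raise RuntimeError("could not find a relocation target")
            taken.discard((c, old))
            taken.add((c, new))
            pos[j] = new
            truth.append((str(snp_map.snp_id[j]), c, old, new))
    new_map = SnpMap(snp_map.snp_id, chrom, pos, snp_map.allele_a, snp_map.allele_b)
    order = new_map.sort_order()
    return new_map.subset(order), truth, order
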