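# Methods

`divscan` detects genomic signatures of recent directional selection in an
experimental design with one unselected control line and two or more lines
selected for a quantitative trait. Three complementary statistics are
scanned over a common sliding-window grid and combined into consensus
regions; a forward-in-time simulator generates fully ground-truthed test
data so that every stage is verifiable without any external dataset.

## Data model

Genotypes are dosage matrices (samples x SNPs, dosage = copies of the
counted `allele_b`, missing = -1); phased data are binary haplotype
matrices with two rows per sample. Positions are 1-based bp; every
interval in the package (windows, regions, annotations) is half-open
`[start, end)` on that axis. BED input/output converts explicitly between
the 0-based BED convention and the internal one. When PLINK text files
are read, the counted allele is the rarer of the two observed alleles
(ties broken toward the lexicographically larger label), which makes the
coding deterministic and independent of sample order; in phased VCF input
the ALT allele is counted.

## Quality control

Filters run in a fixed order, each idempotent:

1. samples with call rate strictly below 0.90 are removed;
2. SNPs with call rate strictly below 0.95, SNPs outside the configured
   autosome set (default 1-29, the cattle autosomes), SNPs sharing a
   (chromosome, position) pair (all copies removed — the data give no
   reason to prefer one), and SNPs monomorphic in *every* line
   simultaneously are removed;
3. misplaced-SNP detection (below).

A SNP whose strongest LD partners lie tens of megabases away is almost
certainly mapped to the wrong position. Per iteration, the detector takes
each candidate SNP's top-10 same-chromosome partners by genotype r^2
(squared Pearson correlation of dosages over complete pairs; undefined
r^2 ranks as 0; ties break toward the physically closer partner, then map
order), adds one flag per partner farther than 10 Mb, and removes every
SNP attaining its chromosome's maximum flag count (when >= 1). SNPs that
were flagged but survived become the next iteration's candidate list;
iteration stops when that list is empty. Removing *all* tied SNPs at the
maximum guarantees termination: each iteration either removes a SNP or
empties the list. r^2 is genotype-based because in a real pipeline this
step precedes phasing.

## Population structure

The genomic distance between two individuals is 1 minus the mean
proportion of alleles shared identical by state over jointly called SNPs
(per SNP: 1 for identical genotypes, 0.5 for het vs hom, 0 for opposite
homozygotes). Classical (Torgerson) MDS squares the distances,
double-centers, and eigendecomposes; coordinates are eigenvectors scaled
by the square root of their eigenvalues, axes ordered by decreasing
eigenvalue with the sign fixed so each axis's first nonzero loading is
positive. Negative eigenvalues (the IBS distance is not exactly
Euclidean) are excluded from the explained-variance denominator, so
reported fractions sum to at most 1.

## FST scan

Per SNP, the two-population Weir & Cockerham (1984) theta-hat is computed
from sample allele frequencies and called-diploid counts, with the
within-population heterozygosity term taken at its Hardy-Weinberg
expectation 2p(1-p) — the form appropriate when only genotype-derived
frequencies are available. It corrects for unequal sample sizes through
the n_c term and can be negative; SNPs monomorphic in the pooled pair are
undefined and excluded from window means. Nei & Chesser's (1983)
corrected GST is available behind `FstScanConfig(estimator="nc")` for
sensitivity analysis.

Windows are 100 kb advancing in 25-kb steps (75-kb overlap), anchored at
0 bp per chromosome and extending to the last SNP. A window is a
candidate iff, in *both* control-vs-selected comparisons, it (a) has more
than five SNPs with defined values, (b) exceeds the empirical 99th
percentile of eligible window means (strict inequality), and (c) exceeds
the upper 97.5% empirical quantile of windowed FST within its
heterozygosity bin (20 equal-count bins by windowed expected
heterozygosity 2*pbar*(1-pbar) from the unweighted mean frequency). The
heterozygosity conditioning matters because the null dispersion of FST
depends strongly on allele frequency. Only the upper tail flags
candidates: the scan targets divergence, not balancing selection;
lower-tail outliers are visible in the tables but never flagged.
Empirical quantiles use numpy's default linear interpolation between
order statistics.

## Haplotype scans

EHH at a flanking SNP x is the probability that two randomly drawn
carrier haplotypes are identical over the *inclusive* interval
[core..x]; it is computed by outward refinement of identity classes
seeded by the core-SNP allele. For allele-conditioned carrier sets
(iHS) the EHH at the core is exactly 1; for population-level curves
(XP-EHH) it is the core-site homozygosity. iHH is the trapezoid integral
of EHH against physical distance (bp; no genetic map is assumed),
accumulated outward until the first point below the 0.05 cutoff (that
trapezoid included) and summed over both sides. A core is dropped —
never integrated partially — if its EHH fails to decay below the cutoff
before a chromosome end, or if an inter-SNP gap above 200 kb is crossed
first; partial integrals at boundaries would otherwise inflate scores.
The 0.05 cutoff and 200-kb gap rule follow the established defaults of
haplotype-scan software, made explicit and configurable here.

**iHS** runs within the pooled selected lines after removing SNPs with
MAF < 0.01 (the statistic is undefined near fixation). A reference
allele is assigned uniformly at random per SNP (seeded; no ancestral
information is required, and the absolute value is used downstream). The
raw score ln(iHH_ref / iHH_alt) is standardized to mean 0, SD 1 within
20 equal-count reference-allele-frequency bins — equal-count rather than
equal-width so every bin is estimable; bins with fewer than two scores
merge into their nearest neighbor. |iHS| is taken after standardization.

**XP-EHH** contrasts each selected line against the control. Both
population-level integrals truncate where the *combined* two-population
EHH decays below the cutoff, so they share limits; cores whose combined
EHH is below the cutoff at the core site itself are dropped. The raw
ln(iHH_selected / iHH_control) is z-scored genome-wide; positive scores
mean longer haplotype homozygosity (recent selection) in the selected
line.

Both scans are averaged on the same window grid as FST (window means use
only scored SNPs, which is also what the SNP count gates). A window is
flagged when the mean |iHS| exceeds 2.58 with at least six scored SNPs,
or when the mean standardized XP-EHH exceeds 2.58 in *both* comparisons
with at least six scored SNPs in each; negative XP-EHH windows are never
flagged (long homozygosity in the small control line reflects its
drift, not selection in the study lines).

## Regions and consensus

Flagged windows that overlap or exactly abut on a chromosome merge into
one region per test (the 25-kb grid makes flagged runs overlap; including
exact abutment covers grid-edge cases). The consensus step reports the
maximal intervals covered by regions of at least two distinct tests, with
the union of supporting tests; because the reported interval is the
covered footprint rather than the union of the contributing regions, the
coordinates are conservative. Annotation is a pure interval-overlap join
against user BED features with overlap lengths; no database retrieval.

## The simulator

`simulate_lines` is a discrete-generation Wright-Fisher forward simulator:

1. *Founders.* Per-SNP allele frequencies are drawn from Beta(0.5, 0.5)
   truncated to [0.05, 0.95] (a realistic U-shaped folded SFS for array
   SNPs) and haplotypes are sampled independently per site.
2. *Burn-in.* ~100 generations of random mating in a population of ~100
   diploids build linkage disequilibrium by drift. LD comes from the
   finite-population bottleneck, not a coalescent backend: simpler,
   dependency-free, and sufficient for EHH-scale LD at desk scale.
3. *Split and selection.* The population splits into lines. Each
   generation every line's trait is sum(QTL effect x dosage) +
   N(0, env_sd); selected lines retain the top `selected_fraction` as
   parents (truncation selection), the control line draws parents
   uniformly. Mating is hermaphroditic random pairing of distinct
   parents; offspring haplotypes recombine with crossovers as a Poisson
   process along each chromosome. The real experiment's sire/dam herd
   structure is deliberately not modeled — it affects effective size,
   not the correctness of the statistics.
4. *Export.* The final generation is exported phased and complete,
   with ground truth (QTL positions, effects, per-line favored-allele
   frequencies, warnings).

Two modeling choices deserve emphasis:

* **Compressed chromosomes.** A desk-scale chromosome of ~10-12 Mb
  stands in for a ~100-Mb cattle autosome. The per-bp crossover rate
  default is therefore 1e-7 — about one crossover per chromosome per
  meiosis, i.e. ~1 Morgan of genetic length, matching the real autosome
  it represents. Using the literal 1 cM/Mb rate on a 10-Mb chromosome
  would give ~0.1 crossovers per meiosis; whole-chromosome haplotype
  copies then accumulate under drift and population EHH never decays
  below the 0.05 cutoff, invalidating every haplotype-scan core.
* **QTL conditioning.** The QTL founder frequency defaults to 0.30 and
  burn-in is replayed (with fresh random substreams) until the favored
  allele segregates within (0.20, 0.50) at the line split — the sweep is
  conditioned on standing variation at intermediate frequency, as in
  standard forward-simulation practice. Without conditioning, drift
  during burn-in frequently loses the allele outright, or leaves the
  *control* line to drift to homozygosity at the QTL, which erases the
  cross-population contrast for reasons unrelated to the statistics
  under test.

`inject_missingness` and `relocate_snps` create ground truth for the QC
stages (call-rate filters and the misplaced-SNP detector).

## The desk-scale reference study

`divscan.presets.desk_scale_config` fixes the simulation study used by
the test-bench and the reproduction script: 4 chromosomes x 12 Mb x
3,000 SNPs (~250 SNPs/Mb, BovineHD-like density; >= 5,000 SNPs survive
QC), founder population 120 with 100 burn-in generations, and 10
generations of truncation selection retaining the top 20%. Line censuses
are 40 (control) / 300 / 350: under the hermaphroditic truncation model
a selected line's effective size is roughly selected_fraction x census,
so these censuses reproduce the *effective-size ordering* of the
experiment the simulator emulates (control smallest, Ne ~ 40/60/70) —
the property that drives the genome-wide mean-FST ordering
control-vs-selected > selected-vs-selected. Mirroring the census ratio
instead would invert the Ne ordering and, with it, that FST ordering.
The sweep scenario has one QTL of effect 0.5 environmental SDs per
allele copy (explaining ~10% of phenotypic variance at the split
frequency) mid-chromosome-1. The neutral scenario drops the QTL and
uses smaller selected lines (40/150/150), a harsher (more drift, hence
more false-positive-prone) null for calibration checks.

What the simulator does *not* emulate: real pedigree structure
(overlapping generations, sire rotation, family sizes), gene flow
between selected lines, mutation after the founder generation, genotyping
error, and a genetic map distinct from physical distance. Passing tests
therefore demonstrate the statistics' behavior under idealized
drift + truncation-selection data of realistic LD scale — not
performance on any particular real dataset.

## Numerical and policy choices

* Empirical quantiles: numpy linear interpolation; all threshold
  comparisons are strict (`>`), so degenerate constant inputs flag
  nothing.
* Undefined values (monomorphic FST, dropped haplotype cores, zero-call
  frequencies) are NaN and excluded from means and SNP counts.
* One integer seed governs each stochastic component (simulator,
  missingness injection, SNP relocation, iHS reference alleles) and is
  recorded in the outputs; pipeline reruns with the same configuration
  are byte-identical.
* Window grids anchor at 0 bp per chromosome; a window is eligible only
  with more than five defined SNPs.
* The iHS reference-allele assignment makes |iHS| invariant in
  distribution to the seed; per-SNP values vary slightly through bin
  composition.

## Known limitations

* The misplaced-SNP iteration semantics (remove all tied SNPs at the
  per-chromosome maximum; candidate list = flagged-but-surviving SNPs)
  is one consistent reading of a loosely specified algorithm;
  alternatives differ on ties.
* With a completed hard sweep and a small, drifty control line, XP-EHH
  window means can sit just below the 2.58 cut-off even when the raw
  contrast at the QTL is clearly elevated: genome-wide z-scoring is
  noisy when drift is strong and the genome is short. FST flags such
  regions reliably; the consensus then depends on a second test
  clearing its threshold.
* iHS has little power at completed sweeps (its classical regime is
  partial sweeps); near-fixed cores are MAF-filtered or dropped.
* The IBS/MDS stage assumes enough jointly called SNPs per sample pair;
  pairs sharing none raise an error rather than imputing.
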