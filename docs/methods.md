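# Methods

This note documents the models and procedures `editsweep` implements, the
choices made where the design was genuinely open, and what the synthetic
studies do and do not establish about real data.

## The analysis chain

**Editing caller.** A reference A site (A on +, T on −) is called edited when
the strand-aware edited-read fraction (G over A+G on +, C over T+C on −)
exceeds `min_g_fraction` (default 0.01) in strictly more than
`min_sample_fraction` (default 0.5) of the covered samples, and the site is
not present in the known-SNP list at frequency above `snp_freq_cutoff`
(default 0.5). Both inequalities are strict. Samples with zero depth at a
site are excluded from the sample-fraction denominator (and counted); no
minimum per-sample depth is imposed by default. The editing level is the
pooled edited-read fraction across samples.

**SNP calling and frequencies.** Pooled sites are polymorphic when total
reads `r ≥ 10` and alternative reads `g ≥ 2`. Derived-G frequency is
`GT_G/(GT_G + GT_A)` over homozygous lines in panel mode — residual
heterozygotes and missing genotypes are excluded from the denominator — and
`g/r` in pool mode. Coverage diagnostics (rank-sum of coverage by editing
class; Spearman correlation of coverage with minor-allele frequency) guard
against the low-coverage frequency inflation that pool-seq can produce.

**Polarization under ascertainment.** Editing is only annotatable on a
homozygous-A background, so every comparable polymorphism has sense-A as the
focal reference. Direction A→G keeps sense A,G SNPs whose reference is A and
whose outgroup allele set is exactly {A} (derived G); direction G→A keeps
the same reference-A sites with outgroup exactly {G} (ancestral G, derived
A, frequency complemented). Every input SNP either passes or carries exactly
one failure reason (`not_AG`, `ref_not_A`, `uncovered`,
`outgroup_polymorphic`, `outgroup_mismatch`, `too_few_outgroup_lines`).
"Monomorphic in the outgroup" means all covered outgroup alleles agree and
at least `min_outgroup_lines` (default 1) alleles are observed. Without an
explicit strand column, purine-reference SNPs are read on + and
pyrimidine-reference SNPs on − (a genomic T,C pair is the sense A,G pair).

**Coding effects and rates.** Each coding-sense A inside a CDS is classified
by translating its codon before and after an A→G substitution (standard
nuclear code). At positions covered by several transcripts the merge is
conservative: synonymous only if synonymous in every frame, otherwise the
most consequential label (stop_gain > stop_loss > nonsynonymous) wins.
Stop gains/losses count as nonsynonymous in the rate table. Rates are
`f = polymorphic/potential` per class; fold ratios are reported both from
3-decimal rounded rates (the printed-table convention) and exactly. The
excess test is one-sided binomial: `P(X ≥ k), X ~ Binomial(n, f_neutral)`.

**Spectra.** The resampling null draws, per replicate, as many unedited
sites as there are edited sites, without replacement, and bins their derived
frequencies into 10 equal-width bins on (0,1] (right-closed). Because only
bin counts enter the spectrum, the per-replicate binned draw follows the
multivariate hypergeometric distribution over the binned unedited
frequencies, which is sampled directly — exactly equivalent to resampling
individual sites, and cheap enough for the default 100,000 replicates.
Nearest-control matching takes the same-chromosome candidate minimizing
absolute distance, ties broken downstream (larger coordinate) for
determinism. Spectrum comparisons use the Wilcoxon rank-sum test with
normal approximation and tie correction.

**Windows and ANCOVA.** SNPs are counted in `[c − w/2, c + w/2)` around each
polarized core (default w = 10 kb), the core itself excluded; windows
truncated at contig ends are flagged. The HKA-style ratio divides the SNP
count by the fixed-difference count in the same window (missing when
divergence is zero; the window is kept). Recombination is piecewise-linear
in the map anchors, clamped with a warning outside the span. The covariate
model is OLS of the polymorphism/divergence ratio on the editing factor plus
recombination rate and GC, with a type-II F-test for the factor and an
optional minimum derived frequency at the central site.

**EHH / iHS.** EHH at marker x is the probability that two random carrier
haplotypes of the core allele are identical over the stretch from the core
to x, computed per flank; EHH at the core is 1. iHH integrates EHH over
genetic distance (cM; physical distance scaled at 2 cM/Mb is the fallback
when no map is supplied) by the trapezoid rule, truncated at the first
marker where EHH falls below `ehh_floor` (default 0.05, that segment
included). `uiHS = ln(iHH_A/iHH_D)`; standardization subtracts the mean and
divides by the sample SD within derived-frequency bins of width 0.05, so
strongly negative values mark unusually long derived-allele haplotypes.
Bins with fewer than `min_bin_n` (default 10) sites keep only the
unstandardized score; inbred lines count as one haplotype each. Note that
standardization is relative to the scanned cohort: in a scan where half the
cores carry planted sweeps, neutral cores acquire positive scores of the
same magnitude — the informative quantity is the edited−unedited (or
planted−neutral) contrast, not either median alone.

**Balancing-selection input.** For each focal polarized site the nearest 100
informative sites (intra-species polymorphism or fixed interspecies
difference) per side are emitted with type flags and pairwise interpolated
genetic distances — 200 sites per window, shorter windows flagged near
contig ends. The composite-likelihood test itself is external software and
out of scope; only its input preparation is provided. The "100 per side vs
100 total" ambiguity in the source description is resolved as 100 per side,
configurable via `window_sites`.

**Profiles.** Flanks of − strand sites are reverse-complemented before
tallying so offset −1 always means 5′ of the edited A. Offset 0 (always A at
genuine edit sites) is reported as a sanity row. Sites whose flank overruns
a contig end are excluded and counted. The background band resamples
strand-specific site counts (defaults a = 1,657 A sites and t = 1,549
T sites, the annotated editome's strand mix) 100 times and reports the
per-offset mean and 2.5/97.5 percentiles.

## The synthetic-data generator

The generator emulates the study design the pipeline targets — an
inbred-line panel (haploid-equivalent homozygous genotypes), pooled DNA-seq
populations, an outgroup site table, a recombination map, and multi-sample
RNA pileups — with every effect planted as a parameter. Defaults are the
study conditions the method is meant to detect:

| parameter | default | meaning |
|---|---|---|
| `genome_length` / `n_chromosomes` | 2 Mb / 2 | uniform-composition genome at `gc_fraction` 0.42 |
| `n_lines` | 100 | inbred panel size |
| `n_edit_sites` | 3,581 | the annotated editome's size; ~30% placed on coding-sense A inside CDS |
| `p_poly_edited` / `p_poly_unedited` | 0.21 / 0.02 | per-site polymorphism probabilities by class |
| `alt_allele_probs_edited` | (0.980, 0.004, 0.016) | sense G/C/T composition at edited sites |
| `alt_allele_probs_unedited` | (0.448, 0.195, 0.357) | transition/transversion mix at unedited sites |
| `derived_freq_shift` | 0.12 | planted increase in mean derived-G frequency |
| `sweep_diversity_factor` / `sweep_radius` | 0.85 / 5 kb | flank thinning around polymorphic edited sites |
| `mean_editing_level` | 0.23 | Beta(2.3, 7.7) per-site levels |
| `outgroup_divergence` | 0.05 | substitutions/site to the outgroup |
| `error_rate` / `rna_depth` | 0.001 / 100 | RNA sequencing error and mean depth |

Derived-allele counts follow the standard neutral spectrum
`P(count = i) ∝ 1/i` over `1..n−1`. The edited-site shift is an exponential
tilt of the same support, `w_i ∝ e^{λi}/i`, with λ solved (Brent) so the
mean frequency rises by exactly `derived_freq_shift`; infeasible targets
fail loudly. No generative model for edited-site frequencies is claimed by
the source analysis — the tilt is a stand-in chosen as the minimal
controllable-mean modification of the neutral law.

The editome size (3,581) matters for verification power: the tilted
spectrum's SD is ≈ 0.31, so recovering a 0.12 shift to ±0.03 needs several
hundred edited polymorphisms (SEM ≈ 0.012 at ~750), which a 2 Mb genome only
yields at roughly this editome density. This is denser per-megabase than a
real genome — the inherent cost of a scaled-down study.

Sweep thinning removes unedited polymorphisms within `sweep_radius` of a
polymorphic edited site with probability `1 − sweep_diversity_factor`,
*after* the polymorphism draw; the bundle records the thinned count so
planted-rate recovery is checked on the pre-thinning scale. At the default
editome density the 10 kb footprints tile the genome, so window-deficit and
ANCOVA demonstrations use dedicated sparse-editome configurations
(~300 centers per class) where footprints are resolvable.

Haplotype structure for the iHS scan is planted block-wise
(`simulate_haplotypes`): haplotypes are mosaics of founder patterns with
geometric block switching; under a planted sweep the derived-core carriers
are near-copies of one founder, giving them the long shared flank the
statistic detects. This is deliberately not a coalescent with recombination.

"Noise-free" pileups (the regime in which the caller is provably exact) use
deterministic read composition — depth exactly `rna_depth`, edited reads
`round(depth × level)` — as well as zero error rate: under binomial read
sampling a level-0.05 site yields zero edited reads in a sample with
probability ≈ 0.05 at depth 60, so exact recall is not attainable surely at
any finite depth.

**What passing synthetic tests does not show.** The generator has no linkage
disequilibrium outside the planted haplotype blocks, no demography, no
indels or multiallelic sites, uniform base composition, and independent
sites within a class. Recovery of planted parameters validates the
estimators and decision rules, not their behavior under real genomic
heterogeneity (mutation-rate variation, biased gene conversion, mapping
artifacts).

## Numerical and reproducibility choices

- All randomness flows from `numpy.random.default_rng` seeded from the
  bundle/stage seed; fixed seed ⇒ byte-identical output files (regression
  tested by checksums).
- Internal coordinates are 0-based half-open everywhere; dialect conversion
  happens once at each file boundary.
- Frequency bins are right-closed on (0,1]; window intervals are half-open;
  matching ties break to the larger coordinate.
- Rounding follows the printed-table conventions where tables are being
  reproduced (integer percentages; 3-decimal rates; folds from rounded
  rates) with exact values reported alongside.
- The packaged published-count tables contain a few cells that are
  internally inconsistent with their own raw counts (one rate, two
  percentages); the table checker recomputes everything from counts and
  flags these rather than asserting them.

## Default problem sizes

Unit tests run on a 200 kb / 50-line study; the acceptance suite uses the
full default conditions (2 Mb, 100 lines, 3,581 edit sites), a 4 Mb
sparse-editome simulation for the window scan, 500-replicate ANCOVA null
calibration, ~1,000 random instances for the EHH oracle, and 600 neutral
cores for iHS standardization checks. The complete suite runs in well under
a minute on one CPU; the full default pipeline run takes ~15 s.
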