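# Methods

This note documents the models behind each scan, the synthetic-cohort
generator that exercises them, the numerical choices, and what the test
suite does and does not demonstrate.

## Scope and data model

The package operates on biallelic SNP genotypes (allele counts 0/1/2 with
missing data) for a cohort partitioned into populations, optionally with
phased haplotypes. Site positions are 1-based as in VCF; windows, bins and
tract coordinates are 0-based half-open (BED convention), so a site at
position p falls in window [start, end) iff start < p ≤ end. All floating
tables are written at six significant digits; a fixed seed makes every
pipeline artifact byte-identical across runs.

## Site-level filters

Three filters define the scan SNP set: missingness above 30% of samples,
non-biallelic records (dropped at VCF parse time), and heterozygote excess.
The excess test is the one-sided exact Hardy–Weinberg test (Levene–Haldane
conditional distribution of the heterozygote count given the minor-allele
count), BH-corrected across all sites genome-wide and thresholded at
FDR < 0.01. Genome-wide rather than per-chromosome correction is used; for
the desk-scale single-chromosome cohorts the two coincide, and genome-wide
is the stricter, simpler convention. The BH step-up property guarantees the
filter is idempotent: rerunning it on a filtered matrix removes nothing.

A minor-allele-frequency cut (default 0.05) and greedy sliding-window r²
pruning (window 100 SNPs, step 10, r² > 0.2 drops the later site; pairwise-
complete genotype correlations) are available for analyses that need
unlinked markers — supervised ancestry estimation in particular. The main
genome scans run on the un-pruned set, so the pipeline's default filter
config sets `min_maf = 0`: rare variants carry most of the derived-allele
sharing signal.

## Windowed diversity

Per site, π uses the unbiased pairwise estimator 2c(n−c)/(n(n−1)) on allele
counts; D_XY uses p₁(1−p₂)+p₂(1−p₁); Hudson's F_ST is the ratio of sums over
the window of (p₁−p₂)² − p₁(1−p₁)/(n₁−1) − p₂(1−p₂)/(n₂−1) over
p₁(1−p₂)+p₂(1−p₁). Ratio-of-sums is stable at low SNP counts; F_ST is not
clamped and may be slightly negative near panmixia. π and D_XY denominators
use the full window length in bp (absent positions are assumed invariant).
When D_XY is requested for a population against itself, self-pairs are
excluded so that the identity D_XY(X, X) = π(X) holds exactly.

## Outgroup polarization

The ancestral allele at a site is the outgroup majority allele; sites where
the outgroup minor-allele frequency exceeds 0.1, or the outgroup is fully
missing, are left unpolarized and excluded from derived-allele statistics
(but retained for folded ones). Polarization error is real and simulated:
the generator's outgroup carries a fraction of fixed derived differences, so
a few percent of sites are systematically mispolarized, as in real data.

## Four-taxon introgression scan

With derived frequencies (p₁, p₂, p₃, p_O) for (P1, P2, P3, outgroup):

* ABBA = (1−p₁)p₂p₃(1−p_O), BABA = p₁(1−p₂)p₃(1−p_O) (frequency-weighted
  site patterns, the windowed formulation).
* D = Σ(ABBA−BABA)/Σ(ABBA+BABA).
* f_dM uses the dynamic-donor denominator: each site contributes the
  magnitude of its maximal attainable numerator, substituting
  p_D = max(p₂,p₃) into the P2 and P3 slots when P2 is the candidate
  recipient (p₂ ≥ p₁) and max(p₁,p₃) into the P1 and P3 slots otherwise.
  Summing nonnegative contributions keeps the window ratio in [−1, 1] and
  makes the statistic exactly antisymmetric under P1↔P2.
* The distance fraction combines the f-type numerator with a pairwise-
  distance normalization: d_f = Σ(ABBA−BABA) / Σ p₃(1−p_O)·d_xy(P1,P2).
  Because |p₂−p₁| ≤ d_xy(P1,P2) at every site, d_f is bounded in [−1, 1];
  it is antisymmetric under P1↔P2, zero when p₁=p₂ everywhere, 1 for pure
  (0,1,1,0) windows, and positive under P3→P2 gene flow. This is the
  package's own definition, chosen for those provable properties.

Windows with fewer than 100 usable SNPs are masked. Outlier calling pools
all windows genome-wide, converts the chosen statistic to Z-scores, takes a
one-sided normal p-value in the configured direction, and BH-corrects.
The null location and scale default to the median and MAD: on a small
genome a strong signal tract is a non-negligible fraction of all windows
and would inflate a mean/SD null enough to mask its own edges; median/MAD
is immune to that contamination and agrees with mean/SD under the null
(`robust=False` restores the plain version). Both FDR 0.05 and 0.01 are in
common use for this scan; 0.05 is the default.

## Supervised ancestry and the local-ancestry HMM

Global ancestry proportions solve, per sample, a nonnegative least-squares
fit of genotype dosages to a convex mixture of donor-panel allele
frequencies (sum-to-one enforced by a heavily weighted constraint row).

Local ancestry uses a single-layer HMM over two donor panels — a
deliberately transparent surrogate for two-layer haplotype-cluster models,
exactly testable against exhaustive path enumeration and sufficient for
dosage-level conclusions. Hidden states are donor origins; emissions are
Bernoulli in error-adjusted panel frequencies q = (1−ε)p + ε(1−p) with
ε = 0.02 and panel frequencies smoothed by a 0.5 pseudocount; transitions
between adjacent sites at distance d re-draw from the stationary prior with
probability 1−exp(−g·r·d), with g = 100 generations of admixture and
r = 4×10⁻⁸ per bp per generation. Phased input decodes each haplotype with
a two-state forward–backward pass; unphased input uses the ordered-diploid
four-state chain and collapses posteriors to genotype dosages. Sites where
a panel is entirely missing are excluded from the chain and their dosages
linearly interpolated.

Dosages are per-haplotype-averaged, so each sample's two donor dosages lie
in [0, 1] and sum to one exactly; ADD is the absolute difference of the two
population-mean dosages, in [0, 1] and invariant to donor relabeling. The
high-ADD mask uses the empirical quantile (linear interpolation, tie rule
≥) at q = 0.75.

## HAF / SAFE / iSAFE sweep scan

HAF(h) = Σ over derived alleles carried by haplotype h of that allele's
derived count in the sample. For variant m in a window, φ(m) is the HAF
mass of its carriers over the total, κ(m) the fraction of distinct
haplotypes carrying it, and SAFE(m) = (φ−κ)/√(κ(1−κ)), set to 0 when
κ ∈ {0,1}. Windows hold 300 variants with 50% overlap (the window unit is
variants; a bp unit can be emulated by slicing the region first). Regions
shorter than one window fall back to a single window.

iSAFE aggregates windows as iSAFE(m) = ρ̄(m)·SAFE_best(m): ρ̄ is the
support-weighted mean of m's normalized SAFE ranks over the windows
containing it (weights α_w = positive part of the window's maximum SAFE,
the window's sweep evidence), and SAFE_best is m's own strongest SAFE.
The rank factor lies in (0,1] and the evidence factor inherits SAFE's
scale, which is empirically well calibrated: neutral cohorts stay well
below the conventional 0.1 significance line (strict inequality), while
favored variants top high-evidence windows and exceed it. Scores are
deterministic and invariant to haplotype order. This aggregation was
validated by simulation recovery and null calibration, not by
bit-compatibility with any external implementation.

Case/control contrast pools the case haplotypes with an evenly spaced
(deterministic) subsample of control haplotypes and multiplies SAFE by
(f_case − f_control)₊ before ranking — variants at similar frequency in the
controls are thereby down-weighted, which is what distinguishes an
introgression-driven sweep from regionally shared structure. When the
sweep is shared with a donor population, the sharpest localization of the
favored mutation comes from contrasting against populations that do not
share the sweep.

## Folded-β balancing-selection scan

For each core SNP with folded frequency f_core ≥ 0.1 (the `-fold -m 0.1`
semantics), flanking SNPs within ±1 kb contribute triangular-kernel weights
w = max(0, 1 − |f − f_core|/maxdiff). The similarity-weighted mutation
estimate θ̂_B divides the kernel mass by C_n(f_core) = Σ_j w(j/n)·E[η*_j]/θ,
the expected kernel mass per unit θ under the neutral folded spectrum
E[η*_j] = θ(1/j + 1/(n−j))/(1+δ_{j,n−j}); β = θ̂_B − θ_null, where θ_null is
the genome-wide per-bp Watterson estimate scaled to the 2-kb flank. An
isolated core SNP therefore scores negative; a cluster of frequency-matched
SNPs scores high; folding makes β invariant to allele-label flips.

maxdiff defaults to 0.15: sample folded frequencies at panel sizes of
24–50 haplotypes carry binomial noise with standard deviation ≈ 0.07–0.10,
and the kernel tolerance should sit near twice that, or genuinely matched
frequencies are rejected. Per-population p-values are one-sided normal
tails of a robust Z (genome-wide median/MAD of β — an outlier-robust
summary of the empirical genome-wide distribution that still permits FDR
rejections), BH-corrected per population over a common site universe.

Shared balanced sites are the intersection of per-population q < 0.01 sets;
10-kb bins qualify at ≥ 15 shared sites and are contrasted in mean π
against the genome-wide window mean. β×ADD classification calls a
significant site donor-derived when ADD ≥ 0.5 (signed by the donor with the
larger mean dosage) and shared-standing otherwise; the ADD q0.75 threshold
is reported alongside for low-ADD intersection summaries. Sites lacking an
ADD value are 'unscored'.

## The synthetic cohort generator

The generator is a mosaic-frequency model, not a coalescent: fast,
analytically transparent, and sufficient for every downstream statistic.

* Ancestral derived frequencies are Uniform(0.05, 0.95); each donor
  population draws Balding–Nichols Beta(p(1−F)/F, (1−p)(1−F)/F)
  frequencies, F = 0.2 by default. The outgroup is fixed ancestral at 80%
  of sites, fixed derived at 5% (so polarization error exists), and
  otherwise polymorphic at low derived frequency.
* Hybrid haplotypes are Markov ancestry mosaics: the donor state re-draws
  from its stationary distribution (probability α for donor A) at rate
  4×10⁻⁶ per bp — the coherent product of g = 100 generations and
  r = 4×10⁻⁸, giving ≈ 250-kb ancestry segments. Alleles are Bernoulli in
  the state's donor frequency. Defaults: a northern hybrid with α = 0.45
  (slightly donor-B-leaning, near-balanced) and a southern hybrid with
  α = 0.60, mirroring admixed populations whose genome-wide ADD is small.
* The introgressed sweep tract (4.5–4.9 Mb of a 5-Mb chromosome) forces
  95% of northern-hybrid haplotypes to donor-B ancestry and to a shared
  core haplotype. Sites escape the core back to donor-pool draws with
  probability 1−(1−base)·exp(−r·T·d) at distance d from the focal allele —
  hitchhiking decay for a sweep sojourn of T = 25 generations (base 0.01).
  The sweep is shared with donor B: 70% of donor-B haplotypes carry an
  older, more decayed copy (T = 40, base 0.03). The favored focal allele is
  planted rare (frequency 0.02) outside sweeping haplotypes: it arose once
  on the swept lineage. Escapes draw from donor-B frequencies, so local
  ancestry inside the tract is unaffected.
* Balancing-selection clusters hold 35 SNPs within 2 kb at folded
  frequency ≈ 0.5 (jitter 0.015) in every donor population; hybrids
  inherit the intermediate frequency through the mosaic. Three clusters
  are species-wide; one sits inside the tract (donor-derived by ancestry).
  Cluster width is kept below twice the β kernel halfwidth so every
  cluster SNP sees most of its cluster, and tight frequency matching is
  the signature of an old balanced polymorphism.
* Default cohort: 60,000 SNPs (≈ 120 per 10-kb window, comparable to
  dense resequencing) and 93 samples (donors 25+25, outgroup 8, hybrids
  20+15). Mutation rate 2.5×10⁻⁹ /bp/generation and a 15-year generation
  time are carried as cohort metadata.

The truth object records per-sample donor dosages, the tract, the focal
site, the balanced loci and all population frequencies, enabling
parameter-recovery tests with no circularity.

What the generator does **not** emulate: coalescent genealogies and linked
drift (background LD is weaker than in real data), recombination-map
heterogeneity, selection dynamics (sweeps and balanced clusters are imposed
as endpoint patterns, not evolved), sequencing error or depth-dependent
genotype uncertainty. Passing tests therefore demonstrate that each method
recovers the statistical pattern it targets at realistic effect sizes and
sample sizes — not that it is robust to every artifact of real
resequencing data.

## Test scale and calibration

Null calibration uses 20 neutral cohorts (no planted signal) of 5,000 SNPs
and 60 samples on a 400-kb chromosome — dense enough that 10-kb windows
clear the 100-SNP mask and ≥ 30 windows feed the Z null. Signal-recovery
batteries use 10–20 default cohorts. The whole suite runs in under three
minutes on one core; problem sizes were chosen so each battery completes in
seconds while leaving clear margins between planted-signal and null
behavior.

## Known limitations

* The d_f definition is this package's own distance-normalized statistic;
  numerical values are not comparable to other software's distance
  fraction, though sign, bounds and antisymmetry match.
* The iSAFE aggregation is rank-based and scale-calibrated empirically; it
  targets rank recovery of the favored variant, not score parity with the
  original tool.
* The ancestry HMM assumes two donors and conditional independence of
  sites given ancestry (no within-panel LD); with very sparse panels its
  dosages shrink toward the prior.
* β p-values are robust-Z normal tails, a pragmatic choice for small
  genomes; with millions of sites an empirical-tail approach would be
  preferable.
* The excess-heterozygosity test assumes a panmictic cohort; strong
  population structure (Wahlund effect) biases it toward heterozygote
  deficit, which the one-sided excess test safely ignores.
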