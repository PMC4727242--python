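# Methods

This note documents the measurement models implemented in `locuspipe`, the
parameter choices that matter, what the synthetic generators do and do not
emulate, and the numerical conventions used throughout.

## qPCR measurement model

All absolute quantification rests on the linear response of the cycle
threshold to log template quantity:

    Ct = intercept + slope · log10(q_pg),    slope = −1 / log10(1 + E)

with fractional amplification efficiency E ∈ (0, 1] (E = 1 is perfect
doubling, slope ≈ −3.3219 cycles per decade).  Standard curves are fitted by
ordinary least squares of Ct on log10(quantity) over a dilution series
(≥ 3 distinct positive quantities required); quantities invert as
q = 10^((Ct − intercept)/slope).  Because every assay is calibrated against
a dilution series of the *same* BAC template measured on the same plate,
quantities from primer pairs with different efficiencies and intercepts are
comparable in absolute picograms — this is what makes cross-entity ratios
(bypass fraction, read-through yield) meaningful.  Cross-plate comparisons
without a shared calibrator are deliberately unsupported.

Replicate handling: technical-replicate Cts are aggregated by arithmetic
mean *before* any ΔCt or inversion; wells beyond the censoring limit
(default 40 cycles) are treated as missing and excluded from the mean, and a
group with no uncensored well propagates as a flagged missing value (reason
code), never as a silent drop.  When several loading controls are used, the
per-control-normalised folds are combined by geometric mean
(`combine_control_folds`).

Spearman correlation uses average ranks for ties; the p-value is an exact
permutation enumeration for n < 10 (all n! orderings, vectorised) and the
usual t approximation for n ≥ 10.  Zero rank variance yields an undefined
rho, flagged rather than silently zero.

## Condition presets and the transcript chain

The read-through pipeline quantifies five entities:
pri_PTPN6 (averaged over its two primer assays), PTPN6_dpA (spanning the
polyA signal; reported but not used in the bypass ratio, whose numerator is
the dedicated intermediate assay), intermediate, pri_miR (intronic) and
pri_miR_EST (stable exonic isoform).  The generator presets fix ground-truth
picogram quantities per condition.  The absolute scale is arbitrary — only
the ratios carry meaning — and the ratios encode the locus biology:

| preset      | bypass | yield | pri-PTPN6 fold vs basal | EST/intronic |
|-------------|--------|-------|-------------------------|--------------|
| SKOV3_NT    | 1.00   | 1.00  | —                       | 12.5         |
| SKOV3_H2O2  | 0.56   | 1.00  | 5.0                     | 12.5         |
| IGROV1      | 1.00   | 1.00  | —                       | 12.0         |

The stressed intermediate induction is 2.8-fold (0.14/0.05), the value
consistent with a fivefold primary-transcript induction at 56% bypass; a
rounded "threefold" would make the two printed ratios mutually
inconsistent.  The IGROV-1 EST quantity is set so that the IGROV-1 /
stressed-SKOV3 EST fold is 2.4.

Ratio uncertainty uses the delta method on the log scale: the standard
error of log10(q) is se(Ct)/|slope|, so se(x/y) ≈ (x/y)·√(cv_x² + cv_y²).

## Synthetic generators

All generators draw from a private `numpy` Generator seeded explicitly, so
a fixed seed reproduces byte-identical tables, and `ct_sd = 0` makes every
downstream result deterministic (the noise-free round trip recovers preset
truths to ≤ 1e−6 relative error; this is the main correctness oracle).

* **Locus plates** — per-assay efficiencies 0.91–1.00 and intercepts
  28–33.1 cycles (deliberately heterogeneous so BAC calibration is actually
  exercised), 3 technical replicates by default (a typical bench layout; the
  replicate count is configurable), Gaussian cycle noise, censoring at 40
  cycles, and a 6-point 10-fold dilution series (1000 → 0.01 pg) per assay.
* **Expression cohorts** — genes on a single toy chromosome at 10 kb
  spacing; a co-expression block shares a latent factor giving pairwise
  correlation ≈ ρ; a CNV block adds ±magnitude to the expression of
  amplified/deleted samples on the log scale and writes the matching
  SEG segments, with truth labels returned.  Default cohort used in the
  calibration tests: 1000 genes × 50 samples (null) and 120–200 genes ×
  200 samples (block recovery) — sizes at which every analysis runs in
  seconds on one core.
* **3C tables** — junction quantity ∝ primer_bias(f) · (d/d₀)^−α with
  distance d between fragment midpoints (α = 1 by default, a typical
  short-range contact decay), multiplied by the loop fold where a loop
  applies; the BAC control carries the primer bias only (equimolar
  junctions), so dividing sample by BAC cancels the bias exactly in the
  noise-free limit.
* **Enrichment tables** — region IP recovery = unmeth + truth·(meth −
  unmeth) with spike-in control rows; ChIP Ct pairs constructed so the
  H3-normalised ratio equals the truth occupancy.  A separate cohort
  generator produces per-sample methylated fractions with a shared latent
  factor for co-methylated promoter groups (logistic link, keeping
  fractions in (0, 1) while preserving rank correlation).

What the generators do **not** emulate: probe-level fluorescence,
inter-plate batch effects, PCR inhibitors, microarray probe effects,
segmentation noise in copy-number profiles, crosslinking chemistry or
ligation-efficiency variation in 3C, and antibody cross-reactivity.
Passing recovery tests therefore demonstrates the correctness of the
estimators under their stated measurement model, not robustness to every
artefact of real bench data.

## Transcription Correlation Score

TCS(g) = Σ ρ(g, neighbour) over the n = 10 neighbours on each side of g in
genomic order, restricted to g's chromosome and truncated at its ends (a
plain sum over the available neighbours, with the count reported — no
rescaling, which would change the score's null distribution).  With average
ranks, Spearman's ρ is the Pearson correlation of rank vectors, so the
implementation ranks each gene once, centres and unit-normalises, and takes
dot products; a naive double loop over `scipy.stats.spearmanr` is kept as
the test oracle.  Constant genes contribute 0.

The significance threshold randomizes the assignment of expression profiles
to genomic positions genome-wide (within-chromosome shuffling would be a
stricter null but the genome here is a single toy chromosome), recomputes
all TCS per randomization, pools the null scores and takes the empirical
(1 − p) quantile with linear interpolation at p = 0.001.  Five
randomizations of a 1000-gene cohort give 5000 pooled null scores ≥ 1/p.
Type-I calibration is verified over 20 seeds: the pooled count of
above-threshold genes stays inside the central 95% binomial band.

Probeset reduction keeps, per gene, the probeset with maximal interquartile
range across samples (a robust variability proxy), ties broken to the
lexicographically smallest probeset id; genes without a genomic position
are excluded with a warning.  Whether "2n neighbours" means n per side or
the 2n nearest regardless of side is ambiguous in general; n per side is
implemented (symmetric, order-reversal invariant) and exposed as the single
`n` parameter.

## Copy-number subgrouping

A sample is **amplified** if any segment overlapping the locus window has
seg_mean > +0.3, else **deleted** if any < −0.3, else **unchanged**.  Any
base-pair overlap counts (coordinates 0-based half-open, so an abutting
segment does not overlap); a sample with no overlapping segment is labelled
unchanged with a coverage warning.  When both thresholds are crossed,
amplified takes precedence — downstream analyses pool amplified and deleted
into one "altered" group, so the precedence never affects the
unchanged-vs-altered contrast.  The default window is 150 kb.  Subgroup
correlations are reported for {all, altered, unchanged}; subgroups under
5 samples are flagged `low_n` rather than dropped.

## 3C-qPCR

In-silico digestion scans the forward strand for exact NcoI motifs
(CCATGG, its own reverse complement) and cuts at offset 1 (C^CATGG);
fragments are the 0-based half-open intervals between cuts, and their
concatenation reconstructs the input exactly.  Restriction efficiency from
non-ligated controls is 1 − across_site/reference, clipped to [0, 1].

Junction quantification mirrors the locus pipeline: per-junction standard
curves from the BAC dilution series, mean Ct aggregation, inversion, then
normalized = q_sample/q_BAC.  The relative profile divides by the first
measured fragment 3′ of the anchor, which is therefore pinned to 1.

Loop peaks are called where the relative frequency is ≥ `min_fold` (default
2) times the median of the `flank` (default 2) fragments on each side,
contiguous calls merged.  Three fragments are never candidates: the anchor
itself (self-ligation is excluded upstream), the 3′ reference (pinned to 1
by construction) and the fragment immediately 5′ of the anchor.  The last
exclusion deserves a note: immediately adjacent fragments sit at near-zero
genomic distance where signal is dominated by random-collision background —
standard practice in 3C viewpoint analyses — and under pure distance decay
the 5′-adjacent fragment sits exactly at the calling boundary, so including
it would turn measurement noise into coin-flip false calls.  With the
exclusions, a fold-3 loop at 0.3-cycle noise is recovered in ≥ 95% of
seeds and no-loop scenarios call nothing in ≥ 95% of seeds (both verified
over 200/100 seeds in the suite).

## MeDIP / ChIP

Percent methylation interpolates the region's IP/input recovery linearly
between the unmethylated (0%) and fully methylated (100%) spike-in
recoveries, clipped to [0, 1] with a warning outside the control range.
The commercial kit's internal normalization is proprietary; the two-point
linear model is the simplest monotone map exact at both controls, and the
raw recovery is reported alongside.  ChIP %input is
100 · 2^((input_Ct − log2(1/dilution)) − ip_Ct) with a 1% input aliquot by
default (configurable; the dilution factor must be supplied, it cannot be
inferred from the data), and histone marks are divided by the H3 %input at
the same region.

## Numerical conventions and degenerate inputs

* Coordinates are 0-based half-open everywhere; fragment and gene midpoints
  use floor division.
* Missing values are NaN plus a machine-readable reason (censored,
  missing_input, zero_denominator); ratios with zero denominators are
  undefined and flagged, not raised.
* Quantile type for the TCS threshold: linear interpolation (numpy
  default).
* Standard-curve fits reject non-negative slopes, < 3 distinct quantities
  and non-positive quantities.
* Seeds are explicit arguments on every stochastic path; no global RNG
  state is touched.

## Known limitations

* The locus presets encode one fixed biological scenario; they are anchored
  to between-entity and between-condition ratios, not to absolute molarity.
* The TCS null randomizes gene-position assignment globally; on a real
  multi-chromosome genome a within-chromosome option exists but the
  toy cohorts use one chromosome.
* Loop calling is a local-background heuristic intended for
  single-viewpoint profiles with ≲ a few dozen fragments, not a
  genome-wide interaction caller.
* The enrichment model treats IP efficiency as region-independent; real
  antibodies show sequence- and density-dependent capture that the
  spike-ins only partially absorb.
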