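# Methods

This note documents the statistical model behind `aneuscore`, the
assumptions baked into its defaults, what the synthetic-data generator does
and does not emulate, and the design decisions taken where the construction
was genuinely open.

## Arm model

Chromosome arms are half-open intervals `[start, end)` derived from
cytoband annotations: the p arm runs from 0 to the start of the first
centromeric (`acen`) band, the q arm from the end of the last `acen` band
to the chromosome end. Reads are assigned to the unique arm containing
their leftmost aligned position; reads in the centromeric gap, below the
mapping-quality cutoff (default 30, configurable — LINE-1-derived amplicons
need confident placement), or on contigs outside the model are discarded
rather than imputed. The acrocentric short arms 13p, 14p, 15p, 21p, 22p and
both Y arms carry too few LINE-1 amplicons to be informative; their counts
are retained in profiles for diagnostics but never enter normalization or
scoring, leaving 41 scored arms. A sample passes QC when its included-arm
total reaches 90,000 reads (boundary inclusive).

## GWA score

Included-arm counts are normalized to fractions and Z-scored against
per-arm control means and SDs (sample SD, n−1 denominator). Two numerical
guards matter:

- **SD floor.** Per-arm SDs are floored at 10% of the smallest control mean
  fraction (configurable). Without it, a low-variance arm in a small
  control panel can blow up a single Z-score; in practice the floor binds
  only on the shortest arms. The floor deflates sensitivity slightly but
  cannot miscalibrate the score, because the control sum distribution is
  estimated with the same floor.
- **Leave-one-out standardization.** The raw sum of 41 squared Z-scores has
  a null expectation near 41, which is incompatible with a decision
  threshold of 5; the reported score is therefore the sum re-standardized
  against the control distribution of sums. Each control's sum is computed
  against a reference built from the *other* controls: with 17 controls,
  resubstitution visibly shrinks the estimated null spread and would push
  the effective threshold tighter than intended. A raw mode is retained for
  inspection.

A score exactly equal to the threshold is called high. A control cohort
with no variation (identical profiles) produces a constructible reference
whose standardized scoring refuses to run (`s_sd = 0`); raw-mode scoring
still works.

The X arms are scored: the control panel is male, matching the ploidy of a
prostate-cancer cohort, and Xq in particular carries the AR locus whose
amplification is a hallmark of castration resistance. Only Y is excluded.

## Tissue concordance

Purity-adjusted segments are collapsed per arm by a length-weighted mean
over segment/arm intersections (the simplest aggregator consistent with an
arm-level deviation estimate; a median would discard sub-arm structure
asymmetrically). Arms with less than 50% segment coverage are flagged
missing rather than estimated. Arm copy number is expressed as
log2(max(cn, 0.1)/expected), with expected 2 for autosomes and 1 for X
(male cohort); the 0.1-copy floor bounds the transform for homozygous
deletions. Concordance with cfDNA is the per-sample Spearman correlation
over shared arms (≥10 required; average ranks for ties).

With an integer arm-level tumor profile, arms sharing a copy number are
exact rank ties in noise-free tissue, so Spearman's ceiling sits strictly
below 1 (≈0.91 for the built-in prostate preset). The noise-free,
high-depth concordance check therefore asserts approach to that tie bound
(median ρ ≥ 0.9), not ρ = 1.

## Survival models

Kaplan–Meier, log-rank and Cox machinery come from lifelines. Cox fits use
the Efron tie approximation (least biased of the common defaults; no tie
rule is canonical for this design) and report Wald 95% CIs and p-values,
matching the usual "HR (95% CI), P" table shape. The interaction model
fits treatment (taxane vs ARSI reference), GWA status (high vs low
reference) and their product; every treatment × status cell must be
populated. The dynamics model fits GWAswitch and GWAhigh dummies against
the GWAlow reference and warns on single-record groups. Estimators are
endpoint-agnostic: FFS (ARSI) and TTNT (taxane) are both plain
(time, event) pairs, and a patient contributing several treatment lines is
treated as independent records — a limitation inherited from the design,
flagged here. Complete separation (|log-HR| > 15) and non-convergence are
reported as errors suggesting an exact or penalized fit. The test suite
verifies the fitter against an independently coded Efron partial
likelihood (grid-search maximizer) and the log-rank statistic against the
hand-coded Cox score test at β = 0.

## Digital PCR

Partition counts are Poisson-corrected (λ = −ln(1 − positive fraction)) and
the AR/AGO1 ratio is the concentration ratio (equal partition volumes — a
duplexed assay — by default). The CI propagates each well's binomial
uncertainty on the log-ratio scale by the delta method, standard dPCR
practice in the absence of a stated uncertainty model. Because AR sits on
chrX (one germline copy in males) and AGO1 on 1p (two copies), an
unamplified male sample has an expected *raw* ratio of about 0.5; the
package reports the raw λ ratio and leaves any renormalization to a
1.0 baseline to the caller, since conventions differ between assays.

## Synthetic-data generator

The generator is first-class, tested code; it defines the conditions under
which every statistical property of the pipeline is demonstrated.

**Count model.** Expected arm mass is `w_a · ((1−f)·N_a + f·T_a)` with
weights `w_a` proportional to arm length — a documented stand-in for the
unpublished per-arm LINE-1 amplicon densities — `N_a` the normal male copy
number and `T_a` the tumor arm copy number. Counts are Dirichlet-
multinomial at depth 100,000 reads with concentration 200,000, i.e. about
1.5× multinomial variance at default depth: modest technical
overdispersion, consistent with an assay whose published sensitivity puts
GWA > 5 at tumor fractions above ~10%. Setting the concentration to `None`
drops the Dirichlet layer entirely.

**Tumor preset.** `prostate_high` is a broadly aneuploid mCRPC-like
genome — 20 of 41 arms altered, including the hallmark 8p loss, 8q gain
(cn 4) and Xq gain (cn 3, modeling AR amplification), chr7/1q/3q/9q gains,
and the recurrent losses (2q, 4p, 5q, 6q, 9p, 10q, 12p, 13q, 16q, 17p,
18q, 20p). GWA-high tumors in this disease setting show high ploidy and
structural-variant burdens, so a sparse profile would understate the
realistic rank signal available to the concordance analysis.

**Cohort model.** Baseline tumor fraction is a two-component mixture:
probability 0.48 of f ~ U(0.10, 0.40) (echoing the roughly half GWA-high
prevalence at baseline), else f ~ U(0, 0.05). A sample is truly high when
f ≥ 0.10. Half the patients respond, shrinking f at the early timepoint by
a U(0, 0.3) factor — which makes the switch group predominantly
high-to-low, as observed. Event times are exponential with log-hazard
β_trt·I[taxane] + β_gwa·I[high] + β_int·I[taxane]·I[high] on the *true*
baseline status; defaults (−ln 2.36, ln 2.63, −ln 2.58) reproduce the
reported effect structure under the ARSI/GWA-low reference coding: a
strong GWA effect under ARSI and essentially none under taxanes at
baseline. Censoring is administrative at the empirical (1 − rate) quantile
of the drawn event times (default 20% censored), which fixes the censoring
fraction exactly at the cost of a data-derived cutoff. The ARSI share
defaults to 154/196. Records carry the true statuses; measured statuses
come from scoring the emitted count profiles.

**Determinism.** All randomness derives from one master seed through
spawn-keyed child generators, so identical configurations reproduce
byte-identical datasets, and the emitted truth table (f values, true
statuses, generative betas) suffices to score downstream estimates without
reading generator internals.

**What the generator does not emulate.** Sub-arm (focal) copy-number
events, GC and fragment-length biases, germline CNVs, subclonal tumor
heterogeneity (single clone per patient), PSA kinetics, and any coupling
between tumor fraction and clinical covariates beyond the hazard model.
Passing tests demonstrate the pipeline's statistical behavior under this
generative model, not assay performance on real plasma.

## Problem sizes

Monte Carlo checks use 100–1,000 replicates per property (1,000 for null
calibration; 200 for threshold, concordance and dPCR coverage; 100 for
monotonicity, interaction and HR recovery; cohorts of 300–2,000 patients
for survival recovery) — sizes at which the asserted margins are
comfortably resolved while the whole suite runs in well under a minute of
simulation time.
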