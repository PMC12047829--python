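# Methods

## Per-nucleus classification

A nucleus with R red (target) and G green (control) spots is classified
by its ratio R/G using exact integer cross-multiplication (R/G < 3/4
iff 4R < 3G), so band boundaries such as 3/4 or 2/4 are decided
exactly, never by floating-point rounding. Bands partition [0, ∞):
deletion (< 0.75), instability ([0.75, 1)), normal (= 1),
polysomy-without-deletion (> 1); G = 0 is uninterpretable and excluded
from every denominator.

The deletion boundary is strict (< 0.75) by default. The inclusive
variant (≤ 0.75) is exposed as `strict_deletion_boundary=False` on the
classifier and pipeline config, because both conventions circulate in
FISH practice; the strict form is normative here. The only pairs it
affects are exact-0.75 ratios (3/4, 6/8, 9/12, ...).

The control-polysomy flag is G ≥ 3 regardless of band: the polysomy
definition counts control-arm copies only, so ratio-1 nuclei such as
3/3 do contribute to a sample's polysomy fraction. The four
deletion+polysomy categories (homozygous R/G = 0, hemizygous < 0.5,
polyploid pattern = 0.5, instability pattern 0.5–0.75) require both
the deletion band and G ≥ 3; the plain codeleted signature 1/2 can
never carry one since G = 2.

## Sample-level calling

Fractions are computed over interpretable nuclei (G ≥ 1) and compared
inclusively (≥) against the cut-offs — deletion 55%, polysomy 30%,
CDKN2A hemizygous 40% / homozygous 30% — as exact rationals
(`Fraction(n, d) >= Fraction("0.55")`), so a fraction of exactly 55%
flips the call. The CDKN2A homozygous pattern (R = 0, G ≥ 1) takes
precedence over the hemizygous one (R ≥ 1, G ≥ 2, R < G): the calls
are mutually exclusive and homozygous loss is the more severe state.
`calibrate_cutoff` implements the mean + 3·SD rule over non-neoplastic
control samples with the sample (n − 1) standard deviation; at least
two controls are required.

Ploidy extrapolation from the two chromosome assays needs a notion of
a sample's "dominant" >2n pattern, which the idealised description
(pure 2R4G on both chromosomes = tetraploid, 3R6G = hexaploid, 1R2G on
one with a gain on the other = polysomic) leaves open for real
mixtures. The convention adopted here: an assay is >2n when its
control-polysomy fraction reaches the 30% cut-off; its dominant
signature is the modal R/G pattern among G ≥ 3 nuclei provided that
mode covers more than half of them, else "mixed". Identical dominant
2/4 (3/6) on both assays gives tetraploid (hexaploid); unequal or
mixed >2n patterns give polyploid_mixed; one >2n assay with a plain 2n
partner gives polysomic. This majority rule is a declared convention
of this package, chosen to degrade gracefully on the heterogeneous
mixtures real tumours show.

## Signature profiles and cohort summaries

Profiles are exact empirical frequencies over interpretable nuclei.
Cohort summaries average per-sample fractions (every tumour weighted
equally) rather than pooling cells, because per-cohort signal
percentages are naturally reported per tumour; the pooled-cell
alternative — which weights big samples more — is available via
`pooled=True`. Two-group comparisons use the Mann–Whitney rank-sum
test on the per-sample fractions. In serialised reports, signatures
with both counts above 12 are pooled into an "other" bin to keep
output bounded; in-memory fractions are never binned.

## Concordance

The manual rater is emulated by drawing 100 interpretable nuclei
uniformly without replacement and applying the identical cut-offs; no
inter-observer error model is applied by default, so any manual/
automated discordance arises from sampling depth alone, which is the
dominant mechanism in practice (manual false negatives near the 30%
cut-off that deeper automated counts reclassify). Cohen's kappa is the
unweighted two-category form; the degenerate case p_e = 1 returns 1
under perfect agreement.

## Cohort statistics

Chi-square defaults to the uncorrected Pearson statistic; the Yates
continuity correction for 2×2 tables sits behind a `yates` flag.
Kaplan–Meier estimation, the unweighted log-rank test and Cox
regression are delegated to lifelines; Cox ties are handled by Efron's
method (lifelines' default). Multivariate Cox models include exactly
the covariates whose univariate log-rank p-value is below 0.05 — the
classical two-stage screen. Covariates with unknown values are
excluded listwise per analysis. Fixed survival horizons are 12, 60,
120, 180 and 240 months (1–20 years); a stratum's median is undefined
when its curve never crosses 0.5. Constant covariates and event-free
data raise errors rather than returning non-identifiable fits.

## Synthetic cohort generator

Each nucleus carries a latent state fixing its true per-assay counts:
normal (2,2), codeleted (1,2), tetraploid codeleted (2,4), hexaploid
codeleted (3,6), or codeleted-with-polysomy, which draws a >2n
signature per assay from a fixed mixture weighted toward the three
dominant polysomy patterns — 1/3 (0.28), 2/4 (0.28), 2/3 (0.22), then
1/4, 2/5 (0.08 each) and 0/3, 0/4 (0.03 each). Observation noise
models FFPE artefacts: each true spot is lost independently with
probability `p_truncation` (nuclear truncation by the ~5 µm section),
each observed spot is double-counted with probability `p_split`, and
Poisson background speckles are added per channel with mean
`background_rate`. Defaults 0.10 / 0.02 / 0.05 are this package's
choice of a realistic FFPE operating point; the noise-free limit
reproduces the true counts exactly.

Cohort composition defaults: 79 grade-2 and 66 grade-3 tumours;
polysomy prevalence 0.24 (O2) and 0.59 (O3); polysomic cases split
0.76 / 0.21 / 0.03 between copolysomy, 1p-alone and 19q-alone (the
unaffected chromosome of a single-polysomy case shows the plain 1/2
pattern); polysomy-state nucleus fraction 0.43 in polysomic samples
versus 0.18 in non-polysomic ones, matching the observed cohort
averages of deletion+G≥3 signals; per-sample nucleus counts log-normal
with median ≈ 1000, clipped to [265, 2285]. CDKN2A status is drawn per
grade (O2: 97/3/0%, O3: 71/15/14% normal/hemi/homo) with (2,2), (1,2)
and (0,2) patterns. Clinical covariates are drawn per grade at the
frequencies of the emulated series.

Survival follows a Weibull proportional-hazards model: recurrence time
with shape 1.2 and scale 190 months, log-hazard-ratios ln 2.5 for
grade O3 and ln 2.0 for polysomy; death is recurrence plus an
independent residual draw (scale 120 months, same covariate effects),
which guarantees EFS ≤ OS per subject; administrative censoring is
uniform on [12, 240] months, emulating staggered study entry. The
model ignores death-before-recurrence, treatment effects and clonal
evolution — passing recovery tests therefore demonstrates that the
calling and survival stages invert this generative model, not that
they capture every feature of real cohorts (no overlapping nuclei, no
spatial heterogeneity, no probe-specific hybridisation failure).

All randomness flows from a single seed through one
`numpy.random.Generator`; identical configurations give byte-identical
outputs.

## Image simulator

Nuclei are non-overlapping ellipses on a grid; spots are isotropic
Gaussian blobs (default sigma 1.5 px) rejection-sampled inside the
ellipse with pairwise separation ≥ 4 sigma. Detection smooths each
channel at half the PSF scale and counts `peak_local_max` maxima
(minimum distance 1.5 sigma, relative threshold 0.25) inside each
nucleus mask. On clean renders this recovers every count exactly;
detection degrades monotonically with additive background noise. The
detector is a testable stand-in, deliberately simple — no chromatic
shift, z-stacks or real-microscope artefact modelling.

## Problem sizes in tests and the acceptance script

The test suite and `scripts/acceptance.py` use cohorts of 145 samples
with 500–2285 nuclei per sample for recovery checks, 100 replicates of
n = 500 for Cox coverage, 200 replicates of n = 200 for log-rank null
calibration, and 1000 random two-nucleus fields for the image round
trip — sizes at which the binomial sampling error of every fraction is
far smaller than its distance to the nearest cut-off, so the checks
are sharp while the whole suite stays fast.

## Known limitations

- Single-observer manual emulation only; no multi-rater statistics.
- No tumour-purity correction of fractions and no per-sample
  confidence intervals on calls.
- The ploidy majority rule is a convention; mixtures near 50%
  dominance flip between tetraploid and polyploid_mixed.
- The survival generator's recurrence→death chain cannot represent
  death without recurrence.
- No competing risks, time-varying covariates, or multiplicity
  adjustment across association tests.
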