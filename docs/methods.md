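# Methods

## Scope and data model

The package analyses trial-structured extracellular spike data recorded
serially in up to three pharmacological conditions (baseline, drug,
recovery) under three interleaved stimulus protocols: a single looming
stimulus (S1) at several azimuths, S1 paired with a distant competitor
(S2, > 30° away), and centered horizontal bars of increasing length
(fixed 3° height).  The atomic record is a trial: spike times in ms
relative to stimulus onset (negative times fall in the pre-onset epoch),
plus stimulus and condition metadata.  Sessions are stored as plain CSV
(trials / spikes / sites) or a single JSON file; both round-trip
losslessly.

## Evoked rates

Evoked rate = spike count in a response window divided by its length,
minus the rate in a pre-stimulus baseline window.  Default count windows
are region- and protocol-specific: loom tuning 125–275 ms (Imc) and
100–250 ms (OT10); bar profiles 65–175 ms for both regions.  A
documented alternative bar window of 75–175 ms can be selected through
the window policy; both appear in the provenance record of every rate
table and neither is treated as uniquely correct.  The baseline window
defaults to the 200 ms immediately preceding onset, estimated per trial —
the estimation procedure is a package choice, since only "subtracting the
baseline firing rate" is specified by the experimental convention.
Rates are not rectified: baseline subtraction may go negative and all
downstream statistics tolerate that.

## Headline statistics

**Suppression index.**  SI = (peak − asymptote)/peak on the mean
bar-length profile; peak = maximum of the per-length means (not of a
fitted curve), asymptote = mean response to exactly the three widest
presented bars.  SI is undefined (flagged, site excluded) when the peak
is ≤ 0, and is deliberately not clipped to [0, 1]: a negative asymptote
after baseline subtraction can push SI above 1, and such values are
reported with a flag rather than altered.  SI is exactly invariant to
multiplicative scaling of the profile, which is why the progressive
response run-down over ~2–3 h sessions does not bias it.

**Competition slope.**  OLS fit with a free intercept of per-azimuth mean
S1&S2 responses on mean S1-alone responses, restricted to in-RF azimuths,
requiring ≥ 3 points and positive x-variance.  The free intercept is the
conservative reading of a "best linear fit"; fitting on per-azimuth means
matches the plotted mean ± SEM scatter convention.

**RF estimation.**  An azimuth is in-RF iff its per-repetition evoked
rates exceed zero by a one-sided Wilcoxon signed-rank test at α = 0.05
and it belongs to the contiguous run of significant azimuths containing
the peak-response azimuth.  The significance criterion and contiguity
rule are package choices (the qualitative definition — locations driven
above baseline — fixes neither a test nor a threshold); a nonparametric
per-location test matches the rest of the statistical machinery, and
contiguity suppresses spurious isolated islands.  Gaussian tuning-curve
fits (offset + amplitude Gaussian, bounded σ, fixed initialisation) are
descriptive only; non-convergence is flagged, never fatal.

## Permutation tests

For each site and statistic the null is built by reassigning the pooled
per-repetition rates (SI test) or (S1, S1&S2) rate-pairs shuffled as
units (slope test) at each stimulus value independently into two
pseudo-conditions of the original sizes, recomputing the statistic, and
taking the difference; 500 shuffles by default.  The one-sided p-value is
the literal proportion of shuffled differences ≥ the observed difference:
ties count toward the null, the all-equal degenerate case gives p = 1,
and p = 0 is possible because the observed value is not added to the null
set.  Orientation defaults: SI difference as baseline − drug (surround
weakening positive), slope difference as drug − baseline (release from
competition positive); both orientations are selectable.  An exact mode
enumerates all balanced reassignments when the per-stimulus repetition
counts are small; it exists for verification and for very small designs,
while the Monte-Carlo mode is the experimental convention.

## Population statistics

Outliers are removed in a single pass from the per-site difference values
(drug − baseline): points outside the closed interval median ± 1.5·IQR,
with linearly interpolated quartiles (the rule is quartile-method
sensitive, so the method is fixed and stated).  Which variable the rule
targets is configurable; differences are the default because the
population analyses are difference analyses.  Paired condition
comparisons use the two-sided Wilcoxon sign-rank test (zero differences
dropped; exact null for n ≤ 25 without ties, else normal approximation
with continuity correction).  Three-condition recovery analyses run the
three pairwise sign-rank tests and report both raw and Holm-Bonferroni
corrected p-values, because published summaries are often ambiguous about
which is quoted.  A Kolmogorov–Smirnov gate (against a normal with the
sample mean/SD — conservative with estimated parameters, which is
accepted and documented) routes data to parametric or nonparametric
tests; Kruskal–Wallis comparisons are followed up with Dunn pairwise
z-tests under a Šidák adjustment.

Paired-recording designs additionally gate site pairs on drug efficacy at
the distant site: a pair is analysed only if site B's per-repetition
rates at its best stimulus are reduced under drug by a one-sided rank-sum
test at α = 0.05 ("significant reduction" made operational).

## Generative model (simulator)

Spatial receptive field: difference of Gaussians with a strong, narrow
excitatory center (amplitude `amp_exc`, width `sigma_exc`) and a weaker,
broader inhibitory surround (`amp_inh` < `amp_exc`, `sigma_inh` >
`sigma_exc`).  The expected response to a centered bar of length L is the
DoG mass covered by the bar, `amp_exc·Φ(L;σe) − amp_inh·Φ(L;σi)` with
`Φ(L;σ) = erf(L / (2√2σ))`, clipped at zero; azimuthal tuning of the loom
response is the Gaussian `amp_exc·exp(−(az−c)²/2σe²)`.  A distant
competitor acts purely divisively — its entire effect is a multiplicative
gain g ∈ [0, 1.05] on the in-RF response; S2 is not separately simulated
as a stimulus drive.  Both choices (Gaussian drive, multiplicative
competition) are modelling decisions consistent with, but not dictated
by, the measured tuning-curve and scatter shapes.

Drug conditions are hard switches (no dose–response data exists to
support anything richer): `competition_gain_drug` models GABA-A blockade
at the recorded site or inactivation of the distant competitor's
encoding site; `surround_scale_drug` scales the surround amplitude
(< 1 flattens the classical surround, the OT10-blockade effect; default 1
so drug at an Imc site leaves SI untouched); `evoked_scale_drug` scales
the whole evoked drive (kynurenic silencing).  Run-down is a
multiplicative factor per serial condition (default 0.9), compounding
baseline → drug → recovery.

Spiking: per trial, the evoked count is Poisson(rate × 250 ms) with
spikes placed uniformly in [latency, latency + 250 ms] (latency 50 ms);
spontaneous spikes are Poisson (default 10 sp/s) throughout the epoch
from 200 ms before onset to 450 ms after.  Because the analysis uses only
window counts, uniform placement is statistically sufficient; PSTH shape,
adaptation, bursting, and non-Poisson variability are deliberately not
modelled.  The pre-onset epoch is fixed at 200 ms — it must be positive
and fit in the 1500 ms inter-stimulus interval; nothing else constrains
it.  Within each condition, trials of all protocols are pseudo-randomly
interleaved; identical (config, seed) pairs reproduce sessions exactly.

Paired-site scenarios: in the OT10–Imc design the Imc site's bar profile
is a pure gain of the OT10 site's (shape inherited, amplitudes scaled),
so OT10 drug flattens both surrounds; in the Imc–Imc design RF centers
must be ≥ 30° apart, drug sets site A's competition gain to its
configured drug value and scales site B's evoked drive by an
inactivation factor (default 0.1); the spread control pins site A's
expected rates across conditions.

### Default parameters

| parameter | default | rationale |
|---|---|---|
| `amp_exc` / `amp_inh` | 250 / 212.5 sp/s | high looming-evoked midbrain rates; ratio 0.85 gives SI ≈ 0.33 on the 0.5–40° grid, inside the observed 0.3–0.6 range |
| `sigma_exc` / `sigma_inh` | 5° / 12° | narrow center, broad surround; puts the bar-profile peak near 15° and ~5 significant azimuths on a 5° grid |
| `spont_rate` | 10 sp/s | modest spontaneous activity; exercises baseline subtraction |
| `competition_gain` | 0.6 baseline, 0.95 drug | strong competitive suppression largely released by the drug |
| `rundown_per_condition` | 0.9 | visible but moderate run-down per ~45 min condition |
| `n_reps`, duration, ISI epoch | 15, 250 ms, 200 ms pre-onset | the experimental protocol's values |
| azimuth grid | RF center ± 25° in 5° steps (11 points) | spans the RF and its flanks |
| bar lengths | 0.5–40°, 12 values | the protocol's typical range |

One σ pair serves both the 1-D bar model and the azimuthal tuning curve:
they describe the same receptive field, read out as integrated mass by
bars and as a point sample by looming stimuli.

## Numerical choices

* Expected-SI ground truth uses bounded golden-section maximization of
  the continuous DoG profile (xatol 1e-10) for the peak and the three
  widest configured lengths for the asymptote; it agrees with a
  quadrature-based oracle to < 1e-6.
* The OLS slope is computed from centered sums (numerically exact for
  noise-free inputs to ~1e-15 relative), not via a general polynomial
  fitter.
* Shuffled SI profiles with non-positive peaks return the raw ratio
  (possibly infinite) inside the permutation null rather than erroring,
  so the null always has exactly `n_perm` members; the *observed* SI must
  satisfy the preconditions or the site is excluded.
* Exact enumeration refuses instances above 3×10⁵ assignments rather
  than silently subsampling.
* Session/metric CSVs round-trip floats at better than 1e-12.

## Problem sizes in the validation suite

The test suite and acceptance script validate at sizes chosen to make
Monte-Carlo error small relative to the tolerances: 2000 null runs for
type-I calibration, 1000 (tests) / 500 (script) simulated sites for slope
recovery, populations of 40 (slope) and 28 (SI) sites for the end-to-end
dissociation, and exhaustive permutation checks at 2–3 repetitions per
condition where full enumeration is feasible.

## What passing tests do and do not show

The simulator reproduces the statistical structure the analysis assumes —
Poisson counts, divisive competition, multiplicative run-down, hard drug
switches.  Real recordings violate several of these (non-Poisson
dispersion, adaptation and habituation, partial drug effects, RF drift,
elevation structure).  Passing parameter-recovery tests therefore shows
the *analysis chain* is correct and calibrated under its own assumptions;
it does not certify those assumptions for any particular dataset.
Ingesting real sessions requires only the documented CSV/JSON layout; a
converter from any specific deposit's native format is left to the user.
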