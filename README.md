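# surroundkit

Analysis toolkit for **classical and extraclassical inhibitory surrounds**
of midbrain (optic tectum / nucleus isthmi) neurons, built for
trial-structured extracellular spike data from iontophoresis experiments
(baseline / drug / recovery conditions), together with a synthetic
spiking-session generator that gives every stage of the analysis a known
ground truth.

It is aimed at sensory neurophysiologists who measure:

* **bar-length response profiles** — responses to a centered bar of
  increasing length rise to a peak and fall to an asymptote as the bar
  engages the inhibitory surround.  The classical surround is quantified
  by the **suppression index**

  $$\mathrm{SI} = \frac{R_{\text{peak}} - R_{\text{asym}}}{R_{\text{peak}}},$$

  with the asymptote estimated as the mean response to the three widest
  bars.  SI is invariant to multiplicative response run-down over long
  recording sessions.

* **paired-stimulus tuning curves** — responses to a looming stimulus S1
  across azimuths, with and without a second, distant competitor S2.  The
  extraclassical (competitive) surround is quantified by the
  **competition slope**: the OLS slope of mean S1&S2 responses against
  mean S1-alone responses over in-RF azimuths ($b = 1$: no competition;
  $b < 1$: divisive suppression).

Per-site condition comparisons use **repetition-shuffling permutation
tests** (rates, or rate-pairs shuffled as units, reassigned at each
stimulus value; 500 shuffles by default, with an exhaustive-enumeration
mode for small designs).  Population comparisons use a median ± 1.5·IQR
outlier rule, two-sided Wilcoxon sign-rank tests, and Holm-Bonferroni
correction across the baseline/drug/recovery pairs.

The simulator draws Poisson spike trains from a difference-of-Gaussians
receptive field with purely divisive competition, condition switches for
GABA-A blockade (bicuculline) and glutamatergic silencing (kynurenic
acid), spontaneous firing, and progressive run-down — so parameter
recovery (slope = configured gain, SI = closed form) is testable end to
end.

## Worked example

```python
import surroundkit as sk

cfg = sk.SimulatorConfig()            # competition gain 0.6 -> 0.95 under drug
rec = sk.simulate_session(cfg, seed=1)
table = sk.build_rate_table(rec)      # per-repetition evoked rates

print(sk.CompetitionModel(table).fit(seed=2).summary())
print(sk.BarLengthSurroundModel(table).fit(seed=3).summary())
```

prints

```
Competitive-suppression slope (extraclassical surround)
========================================================
condition   slope       intercept     n_points
baseline    0.581       -0.21         6
drug        1.028       3.48          6

permutation test (baseline vs drug, b_minus_a, n_perm=500): observed dslope = 0.4469, p = 0
Bar-length suppression index (classical surround)
==================================================
condition   peak sp/s     asym sp/s     SI
baseline    124.94        81.66         0.346
drug        112.55        70.96         0.370

permutation test (baseline vs drug, a_minus_b, n_perm=500): observed dSI = -0.0231, p = 0.606
```

The fitted slopes recover the configured competition gains (0.6 baseline,
0.95 drug): the drug releases the site from competitive suppression, and
no shuffled slope difference reached the observed one (p = 0, literal
proportion over 500 shuffles).  The suppression index is statistically
unchanged (p = 0.61) because this simulated drug touches only the
competition gain, not the classical surround — the dissociation the
package is designed to measure.

A CLI wraps the same pipeline:

```
surroundkit simulate --seed 3 --out session/
surroundkit analyze --trials session/trials.csv --spikes session/spikes.csv \
    --sites session/sites.csv --design imc_gaba_barlength --out results/
surroundkit recover --design imc_gaba_competition --n-sites 40 --seed 1
```

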