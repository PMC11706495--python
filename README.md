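# psgequiv

Equivalence and test–retest reliability analysis for two-site crossover
polysomnography (PSG) studies.

## The problem

When a new sleep-recording environment is introduced — a second laboratory,
a mobile recording unit, a different bedroom — the question is not whether
the two sites *differ* but whether they measure sleep *interchangeably*.
`psgequiv` implements the full analysis chain for the standard design used
to answer that question: each of *n* participants sleeps two consecutive
nights in each of two laboratories (order randomized in near-equal arms,
four nights total), yielding five natural night-pair comparisons per sleep
variable:

| label | pair | reference mean |
|---|---|---|
| HSL1-HSL2 | lab A night 1 vs night 2 | lab A night-1 mean |
| MSL1-MSL2 | lab B night 1 vs night 2 | lab B night-1 mean |
| HSL1-MSL1 | the two labs on night 1 | lab A night-1 mean |
| HSL2-MSL2 | the two labs on night 2 | lab A night-2 mean |
| N3-N4 | study night 3 vs night 4 | night-3 mean of the lab-A arm |

("HSL" = conventional human sleep lab, "MSL" = mobile sleep lab; the labels
generalize to any pair of sites.)

## What it computes

* **Sleep variables** from staged hypnograms (30-s epochs, AASM stages
  W/N1/N2/N3/R): TST, SE = TST/TRT×100, SL, WASO, stage percentages of TST,
  NREM stage latencies from lights-off, stage-R latency from sleep onset,
  and the arousal index ArI = arousals/TST×60.
* **EEG band powers** from EDF recordings: 0.3–35 Hz zero-phase band-pass,
  ten 4-s Hann-windowed FFTs per 30-s epoch (1-s overlap), natural-log band
  powers for SO (0.5–1 Hz), SWA (0.5–4), delta (1–4), theta (4–8), alpha
  (8–12), sigma (12–16) and beta (16–30 Hz), with night-level NREM SWA,
  N3 SWA and slow-wave energy (SWE).
* **Test–retest reliability**: ICC(A,1) — two-way model, absolute
  agreement, single measurement — with F-based 95% CI, significance, and
  Koo–Li interpretation (poor < 0.5 ≤ moderate < 0.75 ≤ good < 0.9 ≤
  excellent).
* **CI-inclusion equivalence** adapted from generic-drug bioequivalence:
  the two conditions are equivalent for a variable when the 90% CI of the
  within-subject mean difference, as a percentage of the reference mean,
  lies within ±20%.
* **Surrounding statistics**: the crossover linear mixed model
  (order + place + timepoint + place:timepoint; REML with CS/AR(1)/
  unstructured residual covariance selected by AIC; Satterthwaite df),
  Friedman tests over the four place×time cells (asymptotic or exact),
  Wilcoxon signed-rank in the centred convention (S ∈ ±n'(n'+1)/4, exact
  p for n' ≤ 20), Bonferroni correction, Cohen's d (raw and LS-means
  forms), Pearson/Spearman correlations, Box-Cox normalization, and
  hourly/CV summaries of bedroom environment logs.
* **A synthetic study generator** that emulates the whole design — Markov
  stage dynamics, subject/site/first-night effects on deep-sleep
  propensity, stage-dependent synthetic EEG, environment logs with site
  structure, self-report factor scores — so every stage of the pipeline can
  be validated against known ground truth without any recorded data.

## Worked example

```python
from psgequiv import Hypnogram, compute_sleep_variables

hyp = Hypnogram(
    stages=["W", "W", "N1", "N2", "N2", "N3", "R", "W", "N2", "W"],
    arousals=[(120.0, 5.0)],
)
sv = compute_sleep_variables(hyp)
print(sv.tst_min, sv.se_pct, sv.sl_min, sv.waso_min, sv.pct_n2, sv.ari_per_h)
```

prints

```
3.0 60.0 1.0 1.0 50.0 20.0
```

— 6 of 10 epochs are sleep (TST 3.0 min, SE 60%), sleep onset is at epoch 2
(SL 1.0 min), two W epochs follow onset (WASO 1.0 min), half the sleep is
N2, and one arousal in 3 minutes of sleep is 20 events per hour.

The `examples/` directory has one short script per capability (sleep
variables, spectral bands, ICC, equivalence, mixed model, full pipeline);
each prints what it computes and what the numbers mean.  The same stages
are available from the shell:

```sh
psgequiv simulate --config cfg.yaml
psgequiv score --config cfg.yaml
psgequiv reliability --config cfg.yaml
psgequiv equivalence --config cfg.yaml
psgequiv compare --config cfg.yaml
psgequiv report --config cfg.yaml
```

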