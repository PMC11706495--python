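# Methods

This note documents the models, conventions and numerical choices behind
`psgequiv`, and what the synthetic validation does and does not show.

## Sleep variables

A hypnogram is one stage label per 30-s epoch over the lights-off →
lights-on interval (TRT); epoch *i* covers `[lights_off + 30i, lights_off +
30(i+1))` seconds.  Sleep onset is the first non-W epoch.  Definitions:

* TST = 0.5 min × number of epochs in {N1, N2, N3, R}; SE = TST/TRT × 100.
* SL = 0.5 × onset epoch index (from lights-off).
* WASO counts every W epoch strictly after onset, **including terminal
  wake**, so SL + TST + WASO = TRT whenever onset exists.  This is the
  AASM-consistent accounting; the alternative (stopping WASO at final
  sleep) breaks the decomposition.
* Stage percentages are minutes in stage / TST × 100.
* N1/N2/N3 latencies run from lights-off; stage-R latency from sleep onset.
  A latency is missing (NaN) iff the stage never occurs; missing values
  propagate through the statistics by pairwise deletion with counts logged.
* ArI = arousal events / TST × 60 (events per hour of sleep).  Arousals are
  counted per event regardless of the stage of the epoch they fall in.
* Epochs flagged as artifact keep their stage for these metrics; artifact
  exclusion applies only to spectral analysis.

## Spectral pipeline

Referenced derivations (e.g. F3−M2) are filtered with separate order-4
Butterworth high-pass (0.3 Hz) and low-pass (35 Hz) sections applied
forward-backward (`sosfiltfilt`), giving zero phase, a monotone passband,
and ≥ 40 dB attenuation at 0.1 and 70 Hz.

Each 30-s epoch is covered by ten 4-s windows with 1-s overlap.  Ten such
windows cannot tile 30 s exactly; windows start at 0, 3, …, 27 s and the
tenth reads 1 s into the next epoch.  The final epoch of a record has no
look-ahead second and falls back to nine windows (`n_windows_used`
records this).

Each window is mean-subtracted (DC removal), Hann-weighted, and
periodogram-normalized so that integrated power is conserved: the band
power is the sum of 0.25-Hz bins whose **centre** frequency falls in the
half-open interval [lo, hi).  Under this convention a full-scale in-band
sinusoid of amplitude A recovers A²/2 summed over its spectral
neighbourhood (within 1%), and the SO [0.5, 1) and delta [1, 4) bands
partition SWA [0.5, 4) exactly.

Per-band epoch values are the mean over windows of ln(power); windows with
nonpositive band power are excluded from that band's mean (never −∞).
Night summaries are taken over non-artifact epochs: NREM means over N2+N3,
the N3 mean over N3.  Slow-wave energy sums **linear** per-epoch SWA over
NREM epochs and reports the natural log (an energy is physically a linear
sum); `swe_convention="log_sum"` exposes the alternative of summing the
log values, and every output labels the convention used.  Artifact input
is an explicit per-epoch mask; an optional amplitude heuristic
(|x| > 500 µV anywhere in the epoch) exists for synthetic pipelines and is
off by default.

## ICC(A,1)

Test–retest reliability uses the two-way, absolute-agreement,
single-measurement ICC.  With rows = subjects, columns = sessions, k = 2:

    ICC = (MSR − MSE) / (MSR + (k−1)·MSE + (k/n)(MSC − MSE))

with the McGraw–Wong F-based 95% CI and the F = MSR/MSE test of ICC > 0 on
(n−1, (n−1)(k−1)) df.  No multiplicity adjustment is applied across
variables (per-variable significance is reported).  Koo–Li category
boundaries are assigned half-open upward (0.75 → good, 0.9 → excellent)
because the published ranges overlap at the printed boundaries; the
`boundary` argument exposes the downward alternative.  Pairs with a
missing night are dropped pairwise with `n_used`/`n_dropped` reported.

## Equivalence

For each of the five comparisons the within-subject mean difference
(first-listed member minus second-listed) gets a two-sided 90% CI from the
paired-t construction — identical to the mixed-model interval for a
two-level within-subject contrast under compound symmetry, and free of
covariance-structure nondeterminism.  Both CI bounds are divided by the
comparison's reference mean (table in the README) and the verdict is
"equivalent" iff both percentage bounds lie in ±20%.  A zero reference
mean leaves the verdict missing; a negative one is used in absolute value
with a warning.  The margin is symmetric, so the difference's sign
convention does not affect verdicts.  No sample-size adequacy gate is
imposed; `n_used` accompanies every verdict because the procedure is
anticonservative at small n.

## Crossover mixed model

The repeated-measures model is marginal: for subject *i* with the four
nightly observations stacked in night order, y_i = X_i β + e_i,
e_i ~ N(0, Σ), with fixed effects intercept, order (crossover arm), place,
timepoint (first/second night at a place) and place×timepoint, and a 4×4
residual covariance shared across subjects (the subject is the block; a
random intercept is implied by a CS structure with positive correlation).
Candidate structures:

* **CS** — σ²[(1−ρ)I + ρJ], ρ ∈ (−1/3, 1); 2 parameters.
* **AR(1)** — σ²ρ^|j−k| over night lag; 2 parameters.
* **UN** — unrestricted SPD matrix via log-Cholesky; 10 parameters.

Each is estimated by REML (Nelder-Mead for the 2-parameter structures,
L-BFGS-B with a Nelder-Mead fallback for UN, started from the OLS residual
covariance).  A fit survives if the optimizer converged and the numerical
Hessian of the objective is positive definite; the minimum-AIC survivor is
selected, with AIC = −2·restricted log-likelihood + 2 × (number of
covariance parameters), the REML convention, which is valid here because
all candidates share identical fixed effects.  Per-effect Wald F tests
(df1 = 1) use **Satterthwaite** denominator df via the delta method on the
covariance parameters with the observed information; Kenward–Roger is not
implemented in this backend and results are flagged accordingly
(`kenward_roger_available=False`).  Under CS the Satterthwaite df
reproduce the expected between/within split (≈ n−2 for order, ≈ 3(n−1) for
the within-subject effects).  Subjects with incomplete nights are dropped
(the covariance is defined over the full 4-night profile) and counted.

Degenerate inputs (constant response, non-SPD updates) yield a
`selected=None` result carrying per-candidate diagnostics rather than an
exception.

## Other statistics

* **Friedman** over the four place×time cells: midranks within rows,
  tie-corrected chi-square with df = 3.  `exact=True` enumerates all
  (k!)^n products of within-row permutations (feasible for n ≤ 5, k ≤ 4)
  for the permutation p.
* **Wilcoxon signed-rank**: the centred convention S = W⁺ − n'(n'+1)/4
  over the n' nonzero differences, so extremes at n' = 15 are ±60; the
  plain W⁺ is an option.  Exact two-sided p by dynamic programming over
  doubled midranks (valid with ties) for n' ≤ 20; otherwise a normal
  approximation with midrank tie correction and 0.5 continuity
  correction.  All-zero differences give S = 0, p = 1.
* **Bonferroni**: p × m capped at 1.
* **Cohen's d**: raw form (mean difference / df-pooled SD, pairing
  ignored) and the LS-means form d = (LSM₁ − LSM₂)/(SE_diff·√n), where
  SE_diff·√n plays the role of the per-subject SD of the contrast.
* **Box-Cox**: λ by profile likelihood on the fixed grid [−3, 3] step
  0.01; transform (x^λ − 1)/λ, ln x at λ = 0; Shapiro–Wilk (α = 0.05,
  delegated to scipy) before and after.  Requires strictly positive,
  nonconstant input.  Note λ is weakly identified when the coefficient of
  variation is small — any power transform is then locally linear.
* **Environment summaries**: hourly means partition [lights_off,
  lights_on) into whole clock hours (eight for the standard 8-h window);
  the night CV is SD/|mean| × 100 over the full window.  Missing samples
  are excluded with per-parameter counts; they are never imputed.

The per-variable inference route in the pipeline's `compare` stage follows
the normality gate: Shapiro–Wilk on the raw values; if non-normal and all
values positive, Box-Cox and re-check; mixed model when (transformed)
normal, otherwise Friedman with Wilcoxon/Bonferroni post-hocs and the raw
Cohen's d.

## Synthetic study generator

The generator produces the full crossover bundle with known structure so
that every analysis stage can be validated by parameter recovery
("generator–analyzer closure").

* **Stage dynamics**: first-order Markov chain over {W, N1, N2, N3, R} at
  the 30-s epoch scale, starting in W.  The default transition matrix was
  chosen once to give realistic healthy-adult architecture (SE ≈ 91%,
  %N1 ≈ 6, %N2 ≈ 57, %N3 ≈ 20, %R ≈ 17, ArI ≈ 10/h).  This is a
  deliberate non-physiological simplification: there is no ultradian
  cycling, sleep latency is shorter and wake bouts more fragmented than in
  real nights.  Passing recovery tests therefore demonstrates correctness
  of the statistical machinery under the assumed covariance structure, not
  fidelity to human sleep biology.
* **Deep-sleep modulation**: the N2→N3 entry probability is shifted on the
  logit scale by a per-subject effect u_i ~ N(0, subject_sd_n3), a site
  effect for MSL nights, and an optional first-night effect; the remainder
  of the N2 row is renormalized proportionally.  The defaults
  (subject_sd_n3 = 0.44, place_effect_n3 = −0.19) were calibrated once by
  forward simulation so the mobile lab reduces mean %N3 by ≈ 3 points and
  the true test–retest ICC of %N3 is ≈ 0.7, and then frozen.
* **Arousals**: per-epoch Poisson with stage-specific hourly rates
  (N1 25, N2 10, N3 4, R 14, W 0 by default).
* **EEG**: per epoch, a sum of band-limited Gaussian noise components with
  stage-dependent RMS weights (N3 SO/delta-dominant, N2 with sigma, R
  theta-mixed, W alpha/beta); mastoid channels are zero so a derivation
  equals its active channel.  Optional artifact epochs inject a 1-s
  high-amplitude transient that the amplitude heuristic detects exactly.
* **Environment**: per-minute series with a +10 %RH humidity offset in the
  conventional lab, a +3 dB first-hour sound bump in the mobile lab, slow
  overnight temperature drift, and Gaussian noise.
* **Self-report**: factor 2 ("initiation and maintenance of sleep", on the
  standardized-score scale, intercept 50, noise SD 9) tracks the night's
  %N3 with slope 0.6 points per %N3 point (Pearson r ≈ 0.3 at the
  generator's %N3 spread); the other four factors are pure noise.
* **Seeding**: `SeedSequence(master_seed)` spawns per-subject streams which
  spawn per-night substreams, so enlarging the study never perturbs
  existing subjects, and identical configs give byte-identical output
  files.

## Problem sizes used in validation

The recovery and calibration checks run the full pipeline on replicated
default-size studies (15 subjects × 4 nights): 200 replicates for the site
effect, ICC recovery and null-equivalence rate, and 1000 replicates for
the type-I error of the mixed-model place test (accepted band
[0.025, 0.085] at nominal 0.05).  Spectral and worked-example checks are
closed-form and run on seconds of synthetic signal.

## Known limitations

* The mixed model uses Satterthwaite df, not Kenward–Roger; at n = 15 the
  two can differ slightly for unbalanced or UN fits (the type-I
  calibration above bounds the practical impact).
* The equivalence CI is paired-t by default; a model-based CI from the
  mixed model matches it exactly only under compound symmetry.
* The EDF codec writes plain continuous EDF (int16, 1-s records,
  per-channel physical scaling from the data); discontinuous EDF+ is
  rejected by design.  Trailing samples that do not fill a whole 1-s
  record are padded on write.
* Whether slow-wave energy should sum linear or log SWA is ambiguous in
  common usage; both conventions are implemented and labelled, linear sum
  being the default on physical grounds.
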