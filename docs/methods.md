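# Methods

## Surprise models

For a category of events (an unexpected cue of a given modality, or any
unexpected cue), the surprise on trial *i* is

```
surprise_i = log2( posterior / prior ),
prior     = k / n        (category events among the n prior trials)
posterior = (k+1)/(n+1)
```

The posterior/prior ratio lies in [1, 2], so surprise lies in [0, 1];
the first occurrence of a category (prior 0) is assigned the maximum
surprise of 1. Three variants are implemented:

* **separate** — one counter per sensory modality, each referenced to
  all elapsed trials. The denominator convention (all trials, not just
  same-modality trials) is fixed by the worked arithmetic: one
  unexpected cue among 10 prior trials must give a prior of .1.
* **common** — a single counter over unexpected events of either
  modality.
* **separate_exclusive** — per-modality counters referenced to the
  trial base that excludes the *other* modality's unexpected trials
  (`prior_A = k_A / (n − k_B)`), encoding the design's mutual
  exclusivity (no cue is unexpected in both modalities). Only prose
  descriptions of this variant exist; the implemented formula is the
  declared choice, and its near-identity with the separate model
  (r > .99 on generated sequences) is a tested property rather than a
  formula-level claim.

Scoring standard-cue trials (`include_standards=True`) treats standards
as their own event category; because standards are frequent, their
surprise is near zero, and flooding the predictor with near-zero values
demonstrably shrinks the fitted betas — kept as a switch to reproduce
that degradation, off by default.

## Single-trial mapping

Per subject and channel, epochs (−100..700 ms, 500 Hz) are averaged in
ten 48 ms windows centered at 50..500 ms after baseline subtraction
(−100..0 ms). Window endpoints are inclusive: 25 samples per window.
Surprise term and window vector are z-scored across trials (sample SD,
n−1) and fit by iteratively reweighted least squares with Tukey
bisquare weights (tuning constant 4.685, scale = median |residual| /
0.6745 re-estimated per iteration, intercept included, tolerance 1e−8,
max 50 iterations); the standardized slope is the subject's beta. The
IRLS is vectorized across all 640 channel × window cells; it is
validated against statsmodels' RLM with the same norm and scale
estimator. Cells with zero variance on either side are recorded absent
(NaN) with a warning; fits require at least 8 trials.

Group inference: one-sample t per cell for each model, paired t for the
model comparison; all three 640-test families are pooled into a single
Benjamini–Hochberg step-up threshold at family alpha .01 (the adjusted
alpha is the largest p(k) ≤ k·α/m over the pooled, sorted p-values, or
0 when none qualifies). Reconstruction-variant refits pool their own
included sets at the same family alpha. The resulting thresholds are
data-dependent. Behavioral follow-ups use a Bonferroni helper
(α/m). The RT analysis applies the identical z-score + robust-fit
contract with RT as the response, optionally restricted to blocks 1–2
where the surprise-linked slowing is modelled as still present.

## Stop-signal task and SSRT

Stopping is an independent race: go finish times are ex-Gaussian
(μ = 400, σ = 50, τ = 100 ms, mean 500 ms), SSRT is normal
(250 ± 30 ms), plus 2.6% go misses and 1% choice errors. A response
escapes on a stop trial iff the go time is below SSD + SSRT. SSDs
staircase independently per go direction from 200 ms in 50 ms steps
(+50 after successful stops, −50 after failed, floor 0), which
converges on ~50% stopping success. SSRT is estimated with the
integration method: misses replaced by the slowest observed go RT, the
sorted go distribution read at rank ⌈p(respond|stop)·n⌉, minus the mean
SSD. At 10,000 trials the estimate recovers the generative 250 ms
within ±15 ms.

The stop-P3 onset is measured on the stop-minus-go difference of the
FCz/Cz-average waveform: peak in 200–400 ms post-signal, then backward
sample-by-sample steps while a per-sample two-sample t across single
trials (stop vs go) stays below p = .05; the onset is the last
significant sample. The per-subject significance criterion (a
two-sample t over raw 500 Hz samples, no smoothing) is a declared
choice; degenerate zero-variance samples count as significant only when
the condition means differ. If the peak itself is not significant the
onset is undefined and the subject is excluded pairwise downstream.

## ERP panel and cross-task coupling

Condition ERPs are baseline-corrected trial means. P3 amplitude is the
largest positive deflection 250–500 ms on the FCz/Cz average; N1 the
largest negative deflection 100–300 ms on the Oz/O1/O2 average
(channels are averaged *before* peak detection — the per-electrode
alternative is not implemented; ties break to the earliest sample).
N1 columns are sign-inverted before correlating so all pairs share one
directionality. The bootstrap difference test permutes each measure's
column independently across subjects (preserving marginals, destroying
coupling) and reports the one-sided proportion of null differences ≥
the observed difference, with ≥ in the tail count and no add-one
correction; 5000 scrambles by default. Partial regressions are
ordinary multiple linear regressions of the criterion amplitude on the
stop-P3 plus the control amplitudes, reporting the stop-P3
coefficient's t-test.

## Component space

Decompositions arrive from outside (ground truth here; any blind-source
separation in general) as mixing/unmixing matrices; estimating them is
out of scope. Synthetic decompositions are square and exactly
invertible, so completeness and additivity of back-projection are exact
identities. The 9-ROI scalp grid maps channels by prefix
(Fp/AF/F → anterior; FT/FC/C/T → central; TP/CP/P/PO/O/I → posterior)
and suffix (z or index 1–2 → midline; odd ≥ 3 → left; even ≥ 4 →
right), which reproduces the fronto-central cell
{FCz, Cz, FC1, FC2, C1, C2} exactly.

Stop-P3 component selection: step 1 keeps components whose
back-projected stop-minus-go topography (mean over the selection
window, default 200–300 ms post-signal — the window is configurable
because the published description is ambiguous; cell means, not single
channels, are compared) peaks in the fronto-central cell; step 2 picks
the keeper whose fronto-central mean time-course best correlates with
the all-component difference ERP over the same window. Reconstruction
variants: selected-only, all-but-selected, one seeded random
non-selected component, and the non-selected component with maximal
explained channel-data variance.

## Synthetic cohorts

Oddball sequences satisfy the design constraints exactly (first three
trials of each block standard; no two consecutive unexpected cues —
enforced within blocks and automatically across block boundaries; equal
per-block modality counts), with non-adjacent positions sampled
uniformly by the gap construction. Epochs contain:

* a fronto-central P3 source (asymmetric raised-cosine, 250–325–450 ms
  for cues; 200–300–400 ms for stop signals, failed-stop onsets 30 ms
  later by default) whose single-trial oddball amplitude is
  `gain_subject × modality_gain × (b0 + b1·surprise)` plus 2 µV trial
  noise, with b0 = 5 µV, b1 = 8 µV per surprise unit (the package's
  moderate-effect calibration: single-trial predictor–response
  correlations ≈ .4 at FCz, detectable at n = 30) and an
  auditory/visual gain ratio of 1.4. Standard cues evoke the same
  baseline response (5 µV) without the surprise-scaled addition, under
  a subject gain independent of the stop/surprise gains — every
  audio-visual cue elicits a fronto-central deflection, surprise only
  modulates it, and the standard-cue P3 stays uncorrelated with the
  stop-P3 across subjects. This is also what makes scoring standard
  trials dilute rather than sharpen the fit: the 80% of trials with
  near-zero surprise contribute response variance without predictor
  variance;
* an occipital N1 source (negative bump 120–170–220 ms) to visual
  arrow stimuli;
* four distractor sources with smooth random topographies and 2 µV
  low-pass (~100 ms Hann) activity;
* spatially correlated Gaussian sensor noise, SD 5 µV, obtained by
  smoothing white noise over the sensor layout (positions from the
  standard 10-20 montage). When only a channel subset is rendered the
  noise is drawn from the exact subset covariance via its Cholesky
  factor — the same distribution at a fraction of the cost.

Subject-level stop-P3 and surprise-P3 gains are bivariate normal
(mean 1, SD .3, correlation `shared_gain_rho`, default .5, clipped at
0.2), inducing the cross-task amplitude correlation; the N1 gain is
independent. Each subject's P3-onset latency jitter (SD 20 ms) is added
both to the stop-P3 kernel and to the subject's mean SSRT, coupling
neural onset with stopping speed. Every epoch set is rendered directly
at its own lock event (cue, target, go, stop) with independent noise;
no analysis crosses lock events, so only marginal statistics matter.
Regeneration under a fixed seed is bit-identical.

What the generator does **not** emulate: continuous recordings,
filtering artifacts, eye movements or channel artifacts, non-Gaussian
noise, latency variability of the P3 within subject, volatility in the
event statistics, or estimation error of a real ICA. Passing tests
therefore show that the analysis code recovers known structure under
the stated noise model — not that the scientific conclusions hold in
recorded data.

## Problem sizes and numerical choices

Recovery and dissociation checks run at the sizes documented in the
tests: 30 subjects for model recovery, 10 for the component
dissociation, 50 repeated 55-subject cohorts (1000 bootstrap scrambles
each; the pipeline default stays at 5000) for the cross-task coupling.
At 30 subjects and 48 unexpected trials the cellwise model-comparison
contrast is marginal by construction (the two surprise terms correlate
≈ .88, so their paired difference is noisy even when the model-vs-zero
maps are overwhelming); the recovery checks therefore test the
contrast at the fronto-central cluster level with the direction fixed
a priori by the generative truth, alongside cellwise FDR significance
of both model-vs-zero maps.
The pipeline streams one subject at a time so memory stays flat at any
cohort size. Degenerate inputs (zero-variance cells, empty selections,
undefined onsets, single-component decompositions) are flagged and
excluded rather than fatal, per the module contracts; exact collinearity
in partial regressions and infeasible sequence constraints raise
errors. All randomness flows from a single root seed through named
per-stage seed sequences.

## Known limitations

* The adjusted FDR thresholds are data-dependent by construction and
  are not comparable across cohort sizes.
* The exclusive surprise variant is one defensible formalization of the
  prose description; alternatives (e.g. renormalizing posteriors) would
  differ in the third decimal on these designs.
* The bootstrap difference test treats measures as exchangeable across
  subjects under the null; it does not model within-subject noise
  correlations between measures.
* Selection between two components that both carry fronto-central
  stop-locked activity degrades gracefully (the better-correlated one
  wins) but is not guaranteed to match a physiological ground truth.
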