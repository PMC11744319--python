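# Methods

## Spectral representation

All spectra live on a uniform wavelength grid, by default 300–750 nm at 1 nm
(the span of stomatopod spectral sensitivity). Inputs are resampled on load:
linear interpolation inside the measured range, zero outside it. Linear
interpolation is monotone and conservative for measured curves; zero
extrapolation keeps out-of-range products exactly zero. Reflectance and
transmittance values outside [0, 1] are clipped with a logged warning —
measurement noise, not signal. Quantum catches use the trapezoid rule on the
session grid; on smooth fixtures it agrees with a 100×-finer Riemann sum to
better than 1e-6 relative (asserted in the tests). Filter stacks multiply
per-layer transmittance (Beer–Lambert), so a double-layer tent is the
single-layer curve squared and two OD-0.3 neutral-density layers equal one
OD-0.6 filter exactly.

Irradiance is treated throughout as a photon-number distribution. No
quantal/energy conversion is applied; users supplying energy-calibrated
irradiance must convert first.

## Retina

Sensitivities come from a single-parameter A1 visual-pigment absorbance
template (Govardovskii-type, alpha band only), peak-normalized on the grid,
or from user-supplied curves re-normalized to peak 1. The beta band is
omitted: it adds UV mass irrelevant to the 400–750 nm opponency analyses,
and the UV-sensitive R8 cells are modelled as separate channels anyway.

The default λmax table is a **placeholder**. The species' measured
sensitivities exist only as published figures, so the packaged values
(R8 315/330/345/380; distal/proximal per row: 420/450, 460/520, 570/690,
535/575 nm) were chosen once to reproduce the qualitative structure of the
study system — distal < proximal within every row, a long-wavelength-only
row 3, peaks spanning roughly 400–700 nm, R2P the largest catch for a bright
grey under natural light, only row 3 activated under red tent illumination
and row 3 silenced under blue/green tents — and are not presented as the
species' true values. Any channel can be overridden by config (`lambda_max_nm`
or `sensitivity_file`).

R8 channels are built but excluded from the opponent pairs: the
(distal, proximal) comparison is defined over the R1–R7 tiers, and how UV
signals enter the opponent system is an open physiological question. R8
participates in binning patterns (`include_r8=True` by default).

## Opponent and binning readouts

The per-row activity profile defaults to the log difference
A = ln Q_distal − ln Q_proximal; an alternative normalized form
(Q_d − Q_p)/(Q_d + Q_p) is available via `activity_profile(..., form=
"normalized")`. The log form makes contrast differences strictly invariant
to any common scaling of the catches, so CD is the same whether computed
from raw or normalized tables; the normalized form is not, which is why the
choice is exposed rather than hidden.

Numerical floor: catches below 1e-12 of the normalization reference (or of
the table maximum for raw tables) mark the row **undefined** rather than
producing −∞; undefined rows propagate through CD as missing data, not
errors. Separately, a row is **activated** for a stimulus only when both of
its opponent channels exceed an activation threshold, default 0.05 of the
reference catch (R2P viewing the OD-0.15 grey under natural light, the
convention used for all normalized catch reporting). The threshold is a
modelling construct: narrowband tents drive some channels to essentially
zero catch, whose log-ratios exist numerically but carry no usable signal.
Contrast tables report signed CD, |CD|, and the activated-row subset; 0.5
is the configurable annotation threshold for "high" contrast.

Binning patterns are catch vectors rescaled to unit maximum; the dominant
channel is the argmax with exact ties broken toward the lower channel index
and flagged. Pattern comparison uses the Chebyshev (max-channel) distance
with a default discriminability tolerance of 0.1. Flat greys of any two
optical densities are exact metamers under both readouts — zero CD in every
row and zero pattern distance — which the test suite asserts under natural
light and every tent.

## Synthetic fixtures

The generator emulates the study's optics, not its exact gels:

* daylight — a log-normal hump peaking at 490 nm (width 0.22 in log-λ),
  strictly positive, unit peak; a smooth stand-in for shallow-water
  downwelling light. Deterministic.
* colour filters — logistic band edges with softness 8 nm, peak
  transmittance 0.95, ≥ 0.9 deep in the passband and ≤ 0.01 beyond three
  softness widths. Stimulus bands: blue 360–550, green 500–560, red > 610 nm.
  Tent bands: blue 360–590, green 450–600, red > 590 nm. Double tents are
  the squared single-layer curves.
* neutral-density filters — flat 10^(−OD) at OD 0.15/0.3/0.6/0.9, with an
  optional long-wavelength leak rising logistically above ~680 nm toward a
  0.8 ceiling, mimicking real ND gels' failure to attenuate deep red (the
  reason ND-tent tests are not meaningful for a red target).
* stimuli — a flat 0.9 white base through the corresponding stimulus filter
  (colours) or ND attenuation (greys).

What the fixtures do **not** capture: water-column attenuation and veiling
light, measurement noise, the real gels' ripple and side lobes, and any
deviation of the real stimuli from spectral flatness. Consequently the
synthetic greys are *perfect* metamers; passing the metamer tests
demonstrates the algebra of the readouts, not that real grey cable ties are
indistinguishable. Likewise the contrast values computed with the
placeholder retina reproduce the qualitative row structure (which rows are
high/low, activated/silenced) rather than any measured CD magnitudes.

## Chooser

The simulated animal learns the target's activity profile under the training
illuminant (natural light) and keeps that signature fixed through testing —
memory without an assumption of colour constancy. At test, each presented
stimulus is scored by −max over activated rows of |A_row(stimulus) −
A_row(signature)|; a stimulus with no activated, mutually defined row scores
−∞ (no chromatic evidence, never preferred), and if all three stimuli are
washed out the choice is uniform. Choice probabilities are
softmax(β · score) mixed with a lapse rate (uniform choice) and a no-choice
rate; β = 0 degrades exactly to the uniform chooser.

β defaults to 2·ln 6 ≈ 3.58, calibrated so that a single row separating
target from distractors by |CD| = 0.5 yields a 75% success probability
(1/(1+2e^(−β·0.5)) = 3/4) — a documented modelling choice linking the
"high contrast" annotation to a behaviourally meaningful accuracy, not a
measured constant. Defaults: lapse 0.02, no-choice 0.05; no-choice trials
are excluded from every success-rate denominator.

One consequence of activation gating worth noting: a very dark grey under a
dim tent can lose the rows that would signal its mismatch and thereby score
*better* than a brighter grey — an echo of the real tendency to confuse dim
targets with dark distractors — so grey distractors tie exactly only when
their activated-row sets coincide.

## Experiment simulation

Three trials per day. Priming (default 3 days) promotes at ≥ 80%
participation over the last 5 trials and removes below 50% overall
participation. Training (default 5 days, natural light) is assessed from the
9th choice onward: promote above 80% success over the last 6 trials (5/6
promotes), remove below 30% overall, continue otherwise; animals never
promoted are recorded as removed. Testing (default 12 days) runs natural
light only on day 1, then one natural-light and two coloured-illumination
trials per day in shuffled order, with one reinforcement trial (flagged,
excluded from analysis) after every six testing trials. Pseudo-randomization
forbids the target position or the distractor combination from repeating on
more than two consecutive trials; the six distractor combinations are the
pairs of OD 0.15/0.3/0.6/0.9. After testing, an individual's coloured data
are included only if its natural-light success exceeds 50%.

Window lengths (5 for priming, 6 for training) follow the operative protocol
text and are configurable. All randomness flows from one seed; each
individual gets an independent substream keyed by a CRC-32 hash of its id,
so whole experiments are reproducible record-for-record.

## Statistics

Success rates are percentages of correct first choices among
non-reinforcement trials where a choice was made, reported to two decimals
with half-up rounding; empty cells are reported as absent, never 0%. The
chance-level test is the Pearson goodness-of-fit of (correct, incorrect)
counts against (n/3, 2n/3), df = 1, no continuity correction — small-sample
exact-test variants give different p-values, and only the Pearson form is
reported. Its exact type-I error at n = 100 and α = 0.05 is 0.0556 by
binomial enumeration, inside the 5% ± 1.5% band the tests check by
simulation.

The choice model is a binomial logit with fixed effects for illumination
condition, distractor combination and choice position, and a random
intercept per individual. It is fitted by maximum likelihood with 21-node
Gauss–Hermite quadrature over the random effect; standard errors come from
the numerical Hessian, p-values are Wald. (No installed Python library
provides this ML fit: statsmodels' mixed binomial models are variational/
MAP Bayes, whose intervals measured slightly anticonservative at these
design sizes; the VB route is retained as `method="vb"` and the tests
cross-check the ML fit against both VB and lme4's `glmer`.) Fits flag
non-convergence and complete separation (|coef| > 10) instead of reporting
silently. Sex is accepted as an optional effect but excluded from the
default model. Individuals with fewer than two levels of a factor drop that
factor; a single-individual dataset is an error (the intercept variance is
unidentifiable).

## Problem sizes

The test suite and acceptance script use desk-scale sizes chosen as
sufficient for their tolerances: 10^5 chooser draws for the chance-level
calibration (Monte-Carlo s.e. ≈ 0.15 percentage points), 10^4 null groups of
100 trials for the type-I error, 6 replicates of 20 individuals × 200 trials
for effect recovery and 100 replicates of 12 × 60 for null coverage of the
mixed model, and simulated experiments of 3–10 individuals per group.

## Known limitations

* The default λmax table is a stand-in; quantitative CD values depend on it
  and should not be read as species measurements.
* No receptor noise, no ΔS/JND-style discriminability model, no
  colour-constancy transform, no within-training learning dynamics, no
  spatial/acuity effects.
* The chooser is one defensible link from contrast to behaviour, not a
  fitted psychophysical model; its β calibration fixes only one point of the
  psychometric function.
* Quantal-unit irradiance is assumed, not checked.
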