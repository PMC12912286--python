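# Methods

`shortsep` compares ten strategies for regressing short-separation-channel
(SC) signals out of long-channel (LC) fNIRS recordings in a block-design GLM,
using simulated sessions with known ground truth and two Bayes-factor
validation metrics. This note documents the models, the defaults and why they
were chosen, the numerical decisions, and what the simulations can and cannot
establish about real data.

## The problem and the design

Continuous-wave fNIRS long channels (25–40 mm source–detector separation) mix
cortical hemodynamics with superficial, systemic physiology — Mayer waves
(~0.05–0.15 Hz), slow blood-pressure drift, cardiac (~1.2 Hz) and respiratory
(~0.25 Hz) pulsations. Band-pass filtering removes the fast components but not
the slow ones, which overlap spectrally with block-design responses. Short
channels (8 mm) sample mainly the superficial layers and can serve as nuisance
regressors. How many SCs to use and how to combine them (nearest, most
correlated, averaged, pooled raw, pooled via PCA) is exactly what the ten
pipelines vary:

1. no SC; 2–5. three SCs (one per lobe: C5, POz, CP6) with nearest /
most-correlated / mean / pooled-PCA; 6–10. all eight SCs with nearest /
most-correlated / mean / pooled-raw / pooled-PCA.

The montage covers the occipital lobe (channels 5–11), the left (1–4) and the
right (12–15) temporal lobes, plus one excluded right-posterior channel (16),
with one 8-mm SC per source. The exact source/detector label pairing in
`data/montage_standard.json` is a nominal 10–20 reconstruction; only ROI
membership, the one-SC-per-source rule, and the three limited-subset sources
affect any computation, and the file's provenance field says so.

## Synthetic sessions

A session is 45 trials (15 per condition A/V/AV; every consecutive triplet
contains all three conditions in random order), 10 s stimuli, ISIs uniform on
[8, 12] s (the maximum-entropy reading of "jittered between 8 and 12 s"), a
60 s initial baseline and a 30 s tail, sampled at 7.81 Hz at 760/850 nm.

Per channel, in µM hemoglobin units:

* **Neural:** HRF-convolved boxcars × true amplitudes. Defaults: ΔHbO 0.5 µM
  for the modality-appropriate conditions (V and AV in occipital channels, A
  and AV in temporal ones), zero otherwise; ΔHbR = −1/3 × ΔHbO; between-subject
  SD 0.1 µM on the HbO amplitudes. Long channels only; SCs carry no neural
  signal.
* **Shared systemic:** four global components — a stochastic narrow-band Mayer
  wave (0.095 Hz center, 0.035 Hz bandwidth, amplitude 30 µM), cardiac
  (1.2 Hz, 2 µM), respiratory (0.25 Hz, 1.5 µM), and low-frequency drift
  (low-passed white noise at 0.02 Hz, 1200 µM) — loading on every channel with
  per-channel loadings 1 ± 0.3. Short channels receive the full systemic
  signal; long channels receive a `superficial_share` of 0.7. HbR receives
  0.05 × the HbO systemic signal (systemic physiology predominantly perturbs
  HbO, which is what lets HbR-based inference survive without SC correction).
* **Local noise:** channel-local slow noise (0.3 µM, independent between
  chromophores, not shared with the SCs — this is the part no SC regression
  can remove) and white sensor noise (0.4 µM).
* **Motion:** Poisson events (0.5/min) shared in time across channels, either
  1–3-sample spikes (5 µM × N(0,1) per channel) or, with probability 0.25,
  step changes.

Hemoglobin maps to optical density through the same MBLL constants the
preprocessing inverts, and to intensity as I = exp(−ΔOD) with I₀ = 1 (only
ratios matter after OD conversion).

The systemic amplitudes are free parameters with no single empirical
reference value. They were chosen once so that the simulation
reproduces, as its operating regime, the qualitative findings the pipelines
are meant to discriminate: with these defaults the no-SC pipeline's HbO
inference collapses (group Bayes factors fall below the evidence threshold
because the shared drift/Mayer noise inflates the across-subject beta
variance roughly twenty-fold), every SC-regression pipeline restores it, and
HbR is far less affected. The µM scale of the drift looks large because the
fixed pathlength factor of 0.1 inflates all recovered concentrations by the
same factor; only ratios of neural signal to in-band systemic noise matter.

What the simulator does **not** model: photon transport and partial-volume
optics, task-locked superficial responses (SC traces are task-free by
construction, so the no-SC failure here is a variance effect, not the bias
effect real scalp responses can add), serially correlated sensor noise,
session/run nesting, and eye movements. Passing tests therefore show that the
pipelines behave correctly under the stated noise model, not that they will
rank identically on any given real dataset.

## Preprocessing

`intensity → ΔOD → TDDR → band-pass 0.01–0.12 Hz → MBLL`, identical for long
and short channels; any other stage order raises a configuration error.

* ΔOD(t) = −ln(I(t)/mean_t I), natural log.
* **TDDR** (temporal derivative distribution repair): the series is split at
  0.5 Hz; on the low-frequency part a robust mean/scale of the first
  difference is estimated by iteratively reweighted Tukey biweight (c = 4.685,
  MAD-based sigma, convergence when the weight vector changes by < 1e-3
  relative, at most 50 iterations). Derivative samples beyond **twice** the
  Tukey cutoff are replaced by the robust mean derivative; everything else
  passes verbatim, so artifact-free signals pass through exactly unchanged.
  The repair point was placed at 2 c·σ after measuring the statistic on both
  signal classes: noise-free block-design signals reach |dev|/(c·σ) ≈ 1.3
  (their derivative distribution is heavy-tailed even without artifacts, and a
  soft reweighting or a cutoff at 1 visibly shrinks the neural signal), while
  spike and step artifacts measure ≥ 2.5. One-to-two-sample spikes are mostly
  above the 0.5 Hz split and are finished off by the band-pass.
* **Band-pass:** 4th-order Butterworth, applied forward–backward
  (zero-phase, effective 8th order), odd-reflection padding of 3/low seconds —
  the 0.01 Hz corner has a multi-minute transient. Steady-state attenuation
  at 1.2 Hz exceeds 100 dB.
* **MBLL:** per time point, the 2×2 system ΔOD_λ = ε_λ,c · ΔHb_c · d · ppf is
  inverted with Gratzer-compiled extinction coefficients (760 nm: 586 /
  1548.52; 850 nm: 1058 / 691.32 cm⁻¹M⁻¹), d the source–detector distance in
  cm and a fixed, wavelength-independent pathlength factor of 0.1. Whether
  such a factor is a DPF or a combined DPF×partial-volume term varies between
  toolboxes; the forward simulator and the inverse use the same convention, so
  recovery is unit-consistent and only the absolute µM scale is arbitrary.

## GLM

One OLS model per subject × long channel × chromophore: three HRF-convolved
condition regressors (canonical double-gamma: delays 6/16 s, dispersions 1 s,
undershoot ratio 1/6, 32 s kernel, peak-normalized), an intercept (always —
it also makes the pooled-raw/pooled-PCA span argument exact), and the
pipeline's nuisance set. No prewhitening and no autocorrelation correction, by
design. The condition regressors are passed through the same zero-phase
band-pass as the data (the intercept is not): the filter removes sub-0.01 Hz
content from the data that an unfiltered regressor would still predict, and
the matched filtering is what makes noise-free recovery exact rather than
biased by a few percent.

Nuisance construction: *nearest* and *most correlated* use a single
same-chromophore SC trace (Pearson correlation over the whole preprocessed
recording, ties to the lowest SC id); *mean* uses the scope's SC average per
chromophore (2 regressors); *pooled raw* uses all 16 SC traces; *pooled PCA*
column-centers the [time × 6 or × 16] SC matrix and keeps **all** principal
components (SVD scores; components below 1e-10 of the leading singular value
are dropped with a warning as a rank guard). The PCA basis depends only on the
subject's SC data, so it is computed once per subject and shared across
channels and chromophores. Because the intercept absorbs the centering and
the PCA scores span the centered SC columns, pipelines 9 and 10 necessarily
produce identical condition betas on full-rank data; the package asserts this
rather than trying to reproduce toolbox-specific conditioning differences.

OLS is solved by SVD least squares; rank-deficient designs fall back to the
minimum-norm solution with a warning; an all-zero series against a
zero-variance design raises.

## Bayes-factor metrics

Group inference uses Jeffreys–Zellner–Siow default Bayes factors: a Cauchy
prior with scale √2/2 on the standardized effect, a point null, and one-sided
tests by truncating the prior to the stated direction. The marginal likelihood
∫ f_nct(t; ν, δ√n_eff) π(δ) dδ is evaluated by adaptive quadrature after the
substitution δ = r·tanθ, which turns the Cauchy weight into a flat measure on
a bounded interval (relative tolerance 1e-6); by construction the two
one-sided factors average exactly to the two-sided one. Two-sample tests use
the pooled-variance t with n_eff = n₁n₂/(n₁+n₂). The between-condition
contrasts use independent-sample tests (not the arguably more natural paired
design), the convention this comparison protocol fixes; it and the prior are
the main caveats when comparing BF magnitudes with other software.

* **Metric 1 (emergence):** a channel counts when the directional BF₁₀ against
  zero exceeds 3 for a modality-appropriate condition — A or AV in temporal
  channels, V or AV in occipital ones; positive direction for HbO, negative
  for HbR.
* **Metric 2 (contrasts):** evaluated only within metric-1 channels — A>V or
  AV>V (temporal), V>A or AV>A (occipital) for HbO, reversed for HbR; flagged
  when any directional BF₁₀ > 3. Non-emergent channels are "not evaluated",
  not "false".

No multiplicity correction is applied anywhere, deliberately. Conventional
evidence labels (weak/positive/strong/decisive at 1, 3, 10, 100 and their
null-side mirror at 0.33, 0.01, 0.001) are provided by a pure categorizer.

Under a standard-normal null, the one-sided BF>3 rule at n = 16 flags ~1–2% of
tests, comfortably calibrated below the 5% reference line (checked by a
200-replicate null simulation in the test suite and acceptance script).

## Block averages

Epochs span −5 to +25 s around onsets, mean-centered on the −5 to 0 s
baseline; averaging proceeds epochs → channels within ROI → subjects (orders
coincide in expectation with equal epoch counts), SEM across subjects. Epochs
extending past the recording are dropped and counted. SC correction prior to
averaging residualizes each long channel on the pipeline's nuisance set plus
an intercept — an orthogonal projection, hence idempotent, and a no-op for the
no-SC pipeline beyond mean removal.

## Problem sizes used by the test suite and acceptance script

Structural and oracle checks run on toy problems in seconds. The headline
comparison runs the full study geometry — 16 subjects × 10 pipelines × 45
trials at 7.81 Hz — per replicate, with 5 seeded replicates; the reported
success fraction is the share of replicates in which (a) the no-SC pipeline's
HbO metric-1 count is strictly below full pooled-PCA's and (b) nonselective
pipelines' mean count is at least the selective pipelines' mean. The
calibration check uses 200 null replicates of a 16-subject beta table. Unit
tests use shortened sessions (2–5 trials per condition) where the property
under test does not depend on the full design.

## Known limitations

* The absolute µM scale is conventional (ppf = 0.1, I₀ = 1); compare ratios,
  not magnitudes, with other toolchains.
* BF magnitudes depend on the (here: JZS, r = √2/2, equal-variance) family;
  other implementations will differ in the second digit or more.
* The TDDR repair point (2 c·σ) is calibrated for block-design hemodynamics at
  7.81 Hz; data whose clean derivative is even heavier-tailed could need a
  higher point.
* `pooled_raw` and `pooled_pca` are provably identical here; any observed
  difference between them on real data reflects numerical conditioning in the
  toolbox used, which this package intentionally does not emulate.
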