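# shortsep

Short-separation channel (SC) regression strategies for fNIRS GLM analysis:
simulate ecological block-design sessions with known ground truth, preprocess
them, fit ten GLM variants that differ only in how SC nuisance regressors are
built, and score every variant with directional Bayes-factor validation
metrics.

## Who this is for

fNIRS methodologists and analysts who need to decide *how* to use short
channels — one nearest SC? the most correlated one? the average of all SCs?
all of them raw, or their principal components? — and want a controlled,
ground-truth-based testbed rather than intuition. The package encodes an
occipital + bilateral temporal montage (15 analyzed long channels, 8 short
8-mm channels, one per source) and a 45-trial auditory/visual/audiovisual
block design, and makes the whole comparison reproducible from a single seed.

## The model in brief

Long-channel signals are modeled as

    y_c(t) = Σ_k β_{c,k} · (boxcar_k * HRF)(t) + s·Σ_j l_{c,j} g_j(t) + ε_c(t)

where `g_j` are globally shared systemic components (Mayer wave ~0.1 Hz, slow
drift, cardiac, respiratory), `l_{c,j}` per-channel loadings, `s` the
superficial share, and the short channels measure the same `g_j` without any
task term. Preprocessing is the standard chain ΔOD → TDDR motion repair →
0.01–0.12 Hz zero-phase band-pass → modified Beer–Lambert law (pathlength
factor 0.1). Each of the ten pipelines fits, per subject × channel ×
chromophore, the OLS GLM

    y = X_task β + X_SC γ + intercept + ε

with `X_SC` empty (pipeline 1), a single nearest/most-correlated SC trace, the
per-chromophore SC means, all 16 raw SC traces, or all principal components of
the pooled SC matrix (6 in the 3-SC scenario, 16 in the 8-SC scenario).
Group evidence per channel uses one-sided Jeffreys–Zellner–Siow Bayes factors
(Cauchy prior scale √2/2): **metric 1** counts channels with BF₁₀ > 3 for a
modality-appropriate condition against zero (A/AV temporal, V/AV occipital;
positive for HbO, negative for HbR); **metric 2** counts, within those
channels, directional between-condition contrasts (e.g. V > A occipital) with
BF₁₀ > 3.

## Worked example

Run the full comparison — simulate a 16-subject cohort, preprocess once, fit
all ten pipelines, score both metrics:

```bash
shortsep compare --seed 11 --pipelines 1,10 --out results/demo
```

or in Python:

```python
from shortsep.compare import run_comparison
from shortsep.bayes import metric_total

res = run_comparison(seed=11, pipelines=[1, 10])
for pid in (1, 10):
    print(pid, [metric_total(res.summary, pid, c, 1) for c in ("HbO", "HbR")])
```

prints

```
1 [0, 15]
10 [15, 15]
```

i.e. with this seed the no-SC pipeline (1) detects **0 of 15** channels from
the HbO signal — the shared superficial noise swamps the group t-statistics —
while full pooled-PCA SC regression (10) recovers all 15; HbR, which the
systemic noise perturbs far less, yields 15/15 with or without SC regression.
`results/demo/` contains `summary.csv` (counts per pipeline × ROI ×
chromophore × metric), `verdicts.csv` (per-channel Bayes factors), and
`betas.csv` (the full beta table).

Other subcommands: `shortsep simulate` (write SNIRF/CSV sessions plus the
ground-truth table), `preprocess`, `fit`, `evaluate`, `block-average`
(event-locked −5…25 s ROI averages, SC-corrected before averaging). All accept
`--config run.yaml` to override session, noise, and ground-truth parameters.

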