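# combosyn

Loewe-additivity synergy scoring and machine-learning synergy prediction for
anti-cancer drug-combination screens.

## The problem

High-throughput combination screens measure two drugs on a cancer cell line
over a factorial ("checkerboard") dose grid, alongside separate single-agent
titrations. Two questions follow:

1. **Scoring** — how far does each measured surface deviate from what
   *additivity* predicts? Under Loewe additivity the expected response `E`
   at doses `(a, b)` solves

   ```
   a / A(E) + b / B(E) = 1
   ```

   where `A` and `B` are the inverse single-agent dose–response functions
   (4-parameter Hill curves `E(c) = E_inf + (E_0 − E_inf) · EC50^h / (EC50^h + c^h)`).
   The synergy score of a surface is the summed deviation
   `Σ (reference − observed)` over the 16 nonzero-dose wells; positive
   scores mean more growth inhibition than additivity predicts.

2. **Prediction** — given scores for measured combinations, predict the
   score of an *unmeasured* combination from the chemistry of the two drugs
   (fingerprint counts, physico-chemical descriptors, toxicophore flags)
   and the untreated gene-expression profile of the cell line. The core
   model is a feed-forward ReLU regression network over the concatenated
   `[drug A ‖ drug B ‖ cell line]` features. Because a combination is an
   unordered pair, every training sample is presented in both drug orders
   and predictions average the two orientations — the output is exactly
   invariant to swapping the drugs. A median-polish baseline (mean of the
   two drug medians and the cell-line median) and a modified MinMax kernel
   for mixed count/binary/continuous features accompany it.

Model quality is estimated by stratified nested cross-validation in four
regimes — random, leave-combination-out (novel pairs), leave-drug-out and
leave-cell-line-out — with MSE/RMSE/Pearson r and a classification panel
(ROC/PR AUC, accuracy, balanced accuracy, precision, sensitivity,
specificity, Cohen's κ) after thresholding measured scores at 30 synergy
units.

The package is aimed at computational groups analysing their own
checkerboard screens or benchmarking synergy predictors; a synthetic-screen
generator provides full test coverage without any external download.

## Worked example

Score a small simulated screen (3 + 1 drugs × 2 cell lines, 2 % measurement
noise, known planted deviations):

```python
import numpy as np
from combosyn.simulate import DesignSpec, generate_design, generate_surfaces
from combosyn.surfaces import score_screen

_, skeleton = generate_design(DesignSpec(3, 1, 2))
rng = np.random.default_rng(0)
planted = rng.normal(0, 40, size=len(skeleton))
corpus = generate_surfaces(skeleton, planted_totals=planted, seed=0, noise_sd=2.0)
scores = score_screen(corpus.single_agent, corpus.checkerboards)
print(scores.assign(planted=planted.round(2)).to_string(index=False))
```

```
drug_a drug_b cell_line    synergy  planted
    E1     E2        C1 -13.761463     5.03
    E1     E2        C2  -1.922648    -5.28
    E1     E3        C1  20.324830    25.62
    E1     E3        C2   6.018274     4.20
    E2     E3        C1 -48.907890   -21.43
    E2     E3        C2  12.837366    14.46
    S1     E1        C1  51.950803    52.16
    S1     E1        C2  41.960351    37.88
    S1     E2        C1 -47.222146   -28.15
    S1     E2        C2 -54.000370   -50.62
    S1     E3        C1 -31.651012   -24.93
    S1     E3        C2  -4.527280     1.65
```

Each row is one (drug pair, cell line) quartet: `synergy` is the recovered
sum of Loewe deviations over the 16 wells, `planted` the value the
generator injected. Individual quartets scatter because summing 16 wells
amplifies both replicate noise and Hill-fit error in the reference; across
200 quartets the recovered scores regress on the planted totals with slope
≈ 0.98 (see the acceptance script below). With `noise_sd=0` the round trip
is exact to numerical tolerance.

The same pipeline is available from the shell:

```sh
combosyn simulate -o corpus --seed 4
combosyn score-surfaces corpus/single_agent.csv corpus/checkerboards.csv -o scores.csv
combosyn train run.yaml -o model --seed 1
combosyn predict model run.yaml -o predictions.csv
combosyn evaluate run.yaml -o report --scheme leave_combination
```

## Layout

| module | contents |
| --- | --- |
| `combosyn.surfaces` | Hill fits, Loewe reference (bisection), surface assembly, synergy scores, screen CSV dialects |
| `combosyn.featurize` | ECFP counts, physico-chemical panel, toxicophore SMARTS flags, expression loading, zero-variance filter |
| `combosyn.preprocess` | `norm` / `norm+tanh` / `norm+tanh+norm` column normalizers with train-only statistics |
| `combosyn.models` | symmetric feed-forward network (NumPy SGD), median polish, MinMax kernel, pluggable scikit-learn learners |
| `combosyn.evaluate` | four split schemes, nested CV harness, metric panel, threshold selection, Wilcoxon comparison |
| `combosyn.simulate` | design/world/dose-response generators with planted ground truth |
| `combosyn.cli` | `combosyn` command group |

See `docs/methods.md` for the modelling choices and their rationale.
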