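# synergykit

Deterministic muscle-synergy extraction and sEMG-driven continuous
joint-angle estimation.

## The problem

Surface EMG (sEMG) is attractive as a control signal for rehabilitation
robots, but it drifts: electrode placement, skin impedance and muscle
state change between sessions, so a regression model trained on one
day's recordings degrades on later days.  Muscle-synergy analysis
factorizes the m-channel envelope matrix **D** (channels × samples) as

    D ≈ C S,    C ∈ ℝ^{m×r}_{≥0},  S ∈ ℝ^{r×n}_{≥0}

where the columns of **C** are synergies (fixed relative activation
weights across muscles) and the rows of **S** are their activation
coefficients over time.  Synergies for a repeated task are relatively
stable across sessions, so activation coefficients make robust neural-
network features — *if* the factorization itself is reproducible.
Random-start NMF is not: its factors change order, scale and shape from
run to run.

`synergykit` implements a deterministic alternative — **MCR-ALS**
(multivariate curve resolution–alternating least squares) initialized by
**SIMPLISMA** pure-variable selection:

1. Rank every time sample by purity `p_i = ω_i σ_i / (μ_i + α·max μ)`
   (μ_i, σ_i: mean/sd of column i across channels; ω_i a determinant
   weight that suppresses samples collinear with earlier picks; α a
   noise offset, 1–5%).  The r purest columns seed the synergy matrix C.
2. Alternate exact non-negative least-squares updates of S and C until
   the relative objective change |Q| = 100·|f_{l+1}−f_l|/f_l ≤ 0.01% or
   1000 iterations.

No random state anywhere: repeated decompositions are bit-identical.
NMF (Lee–Seung multiplicative updates) and PCA (channel-covariance
eigendecomposition) are included as the classical baselines.  The
synergy count r is chosen as the smallest rank whose reconstruction
passes `VAF = 1 − ‖D−M‖²_F/‖D−mean(D)‖²_F > 80%`.

Downstream, the elbow angle is derived from a tri-axial accelerometer
(`θ = 90° − arccos(Ax/g)` under quasi-static motion, with gravity
calibration and zero-phase low-pass), and a sequence-to-sequence
**Bi-LSTM** (five bidirectional layers × 48 hidden units, dropout 0.3,
implemented in numpy with manual backpropagation through time) maps the
activation-coefficient features to the continuous angle.  Accuracy is
Pearson CC between predicted and measured angle; cross-day synergy
stability is the mean CC of greedily matched, unit-normalized synergy
columns.

Because no public dataset accompanies the method, the package ships a
first-class synthetic generator: multi-subject, multi-day envelope-level
sEMG for a cyclic 0–90° elbow flexion/extension task with known ground
truth (raised-cosine activation bursts with rest phases, per-day channel
gain drift, amplitude groups, matched accelerometer traces).

## Worked example

```python
import numpy as np
from synergykit import (
    make_ground_truth, synthesize_session, select_order, mcr_als, nmf,
    mean_matched_cc,
)

truth = make_ground_truth(seed=7)               # 3 muscles, 2 synergies
emg, accel = synthesize_session(truth, day=1, seed=8)

r = select_order(emg.values, vaf_threshold=0.80)
dec = mcr_als(emg.values, r)
print("selected r =", r)
print("VAF = %.4f after %d iterations" % (dec.vaf, dec.n_iter))
print("recovery CC vs truth = %.4f" % mean_matched_cc(truth.C_true, dec.C))

runs = [mcr_als(emg.values, r) for _ in range(3)]
print("bit-identical repeats:", all(np.array_equal(runs[0].C, d.C) for d in runs))
```

prints

```
selected r = 2
VAF = 0.9992 after 3 iterations
recovery CC vs truth = 0.9803
bit-identical repeats: True
```

i.e. the VAF criterion recovers the generating synergy count, the
reconstruction explains 99.9% of the across-channel variance, the
extracted synergy columns correlate 0.98 with the generating ones
despite 5% envelope noise, and repeated extractions agree exactly.

The same flow is available from the shell:

```
synergykit simulate --subjects 2 --days 5 --seed 7 --out sessions/
synergykit extract sessions/sub01_day1_set1.csv --r auto --out dec.json
synergykit run --seed 7 --out runs/demo
```

`synergykit run` executes the whole protocol — extract synergies per
session, derive angles from the accelerometer, train the Bi-LSTM on
day 1, predict days 2–5 — and prints the per-day CC/MAE table.

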