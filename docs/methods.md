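# Methods

## Signal model

Envelope-level sEMG is modelled as D = C S + E: D (m × n) holds m
channel envelopes over n samples, C (m × r) the non-negative synergy
weights, S (r × n) the non-negative activation coefficients, E additive
noise.  Envelopes are produced from raw sEMG by a zero-phase 4th-order
Butterworth band-pass (default 20–450 Hz), full-wave rectification, a
zero-phase 4th-order Butterworth low-pass (default 4 Hz) and clipping at
zero.  The band edges and envelope cutoff are configurable; the chain is
the standard synergy-literature pipeline, and the envelope operator is
positively homogeneous, so later amplitude normalization commutes with
it.  Channels are optionally normalized to unit maximum before
decomposition (default on); per-channel positive scaling changes C's
rows but not the correlation-based comparisons used throughout.

## SIMPLISMA initialization

Candidate pure variables are *time samples* (columns of D): a sample at
which only one synergy is active has a channel-intensity vector
proportional to that synergy's column.  With only m = 3 channels the
transposed reading (channels as pure variables) could never produce an
m × r synergy matrix, so the column reading is the only consistent one.
Purity of column i is

    p_i = ω_i · σ_i / (μ_i + α · max_j μ_j)

with μ_i, σ_i the across-channel mean and (population) standard
deviation.  The offset α (default 0.03, sensible range 0.01–0.05)
damps the purity of low-intensity, noise-dominated columns; it is
interpreted *relative to the largest column mean*, the standard
SIMPLISMA convention — the absolute-offset alternative would make the
selection depend on measurement units.  The first selection uses ω ≡ 1;
afterwards ω_i is the determinant of the correlation-around-the-origin
matrix of the length-scaled candidate column joined with the already
selected columns (length scale λ_i = sqrt(μ_i² + (σ_i + α·max μ)²)),
which is zero for any column collinear with a previous pick.  Exact
purity ties resolve to the lowest column index.  If fewer than r
distinguishable directions exist the selection raises a degeneracy
error rather than silently duplicating a direction.

## MCR-ALS

From the SIMPLISMA initial C, the two conditional problems

    S ← argmin_{S ≥ 0} ‖D − C S‖_F,   C ← argmin_{C ≥ 0} ‖D − C S‖_F

are solved alternately.  Each subproblem is an exact non-negative
least-squares solve, implemented by enumerating active sets (exact for
r ≤ 8, vectorized across all columns; scipy's Lawson–Hanson solver is
the fallback beyond and the independent oracle in the tests).  Exact
subproblem solves make the objective f = ½‖D − CS‖²_F provably
non-increasing.  A "project" mode implementing the plain normal-equation
updates C = D Sᵀ(S Sᵀ)⁻¹, S = (CᵀC)⁻¹CᵀD with negatives clipped to zero
is provided for comparison; it is cheaper but monotonicity is not
guaranteed there.  Iteration stops when the percent objective change
satisfies |Q| = 100·|f_{l+1} − f_l|/f_l ≤ q_tol (default 0.01%) or
after max_iter = 1000 iterations; Q is signed in its raw form
(negative while descending), so the stopping rule uses its magnitude.
An additional floor stops iteration when f falls 24 orders of magnitude
below the data energy — an exactly factorizable D would otherwise make
Q a 0/0.  The whole procedure has no random state: repeated runs are
bit-identical, which is the property the package exists to exploit.

## NMF and PCA baselines

NMF minimizes the same objective by Lee–Seung multiplicative updates
from uniform(0, 1] random factors (caller-seeded), with an ε = 1e−12
floor in the denominators, and the same |Q| stopping rule.  Different
seeds can end in differently ordered/scaled factors and occasionally
different local optima — the instability that motivates MCR-ALS.

PCA diagonalizes the m × m covariance of the channel signals over time
(divisor n − 1; the divisor affects only the eigenvalue scale).  The
top-k eigenvectors form C, sign-fixed so each eigenvector's largest-
magnitude entry is positive; S = Cᵀ(D − D̄) and the reconstruction adds
the channel means back.  Repeated eigenvalues are flagged in the
decomposition record since the eigenbasis is then not unique.

## Synergy count

`select_order` returns the smallest r whose reconstruction VAF
exceeds the threshold (default 0.80), where
VAF = 1 − ‖D−M‖²_F / ‖D−mean(D)‖²_F and mean(D) replaces each column by
its across-channel mean.  If nothing qualifies it returns r_max with a
warning.  On the default synthetic fixture (2 generating synergies, 5%
noise) the criterion selects r = 2.

## Accelerometer angle

Under quasi-static motion the sensor reads gravity only, so
θ = 90° − arccos(Ax/g).  g comes either from the recording metadata
(synthetic sessions store the generating gravity reference) or from
`calibrate_gravity`, the mean acceleration magnitude over ≥ 0.5 s of
rest (segments whose magnitude fluctuates more than 5% are rejected).
Ax is low-pass filtered (zero-phase, default 2 Hz) to suppress dynamic
contamination instead of fusing gyroscope data, and the arccos argument
is clamped to [−1, 1] so endpoint noise cannot produce NaN.  θ is a
non-decreasing function of Ax, and on noiseless synthetic sessions the
inversion reproduces the generating angle to < 0.01°.

## Bi-LSTM angle regressor

Architecture: five stacked bidirectional LSTM layers, 48 hidden units
per direction, inverted dropout 0.3 after every recurrent layer, and a
per-timestep linear readout (242,401 parameters for 2-feature input).
The network is implemented directly in numpy — batched forward pass,
manual backpropagation through time, Adam (lr 1e−3, gradient clipped at
global norm 5), float32 — and its gradients are verified against finite
differences in the test suite.  Features are the activation-coefficient
rows, multiplied by their synergy column's Euclidean norm (the scale
split between C_k and S_k is not identifiable; absorbing it makes
features comparable across sessions), reordered by greedy maximum-CC
matching against the training-day reference decomposition, and
standardized with training-set statistics inside the estimator.  The
target is the standardized angle; the loss is MSE; the reported metric
(Pearson CC) is invariant to both standardizations.

Training-loop defaults — window 200 samples (one movement cycle),
stride 50, 40 epochs, minibatch 64 — were chosen so a full protocol
trains in a few minutes of single-core BLAS time while converging well
past the accuracy bounds checked in the tests; all are configurable.
Prediction processes a whole session in one pass (the recurrent network
is length-agnostic) with dropout disabled, so inference is
deterministic; model serialization round-trips bit-exactly.

## Synthetic study

The generator emulates the acquisition protocol end to end: subjects ×
days × sets (two sets on day 1 for train/same-day test, one set on each
later day), default 3 channels, 2 synergies, 30 cycles of 200 samples
(4-s cycles at a 50 Hz envelope rate).  Activation time courses are
raised-cosine bursts, one per synergy per cycle, centred at phases
(k+½)/r with width 0.8/r of the cycle, with lognormal-style per-cycle
amplitude jitter (sd 0.10) and phase jitter (sd 0.01 cycles).  Bursts
cover under half the cycle, so every synergy has true rest intervals —
the single-synergy-active samples SIMPLISMA needs actually exist.  The
synergy matrix gives each synergy a dominant channel plus smaller
shared loads; subjects get multiplicative perturbations of it, and a
high-amplitude group option scales it 1.5× (the amplitude ratio between
groups is a free parameter, not an empirical value).  Cross-day drift is
modelled as per-channel multiplicative gains (lognormal, sd 0.10) plus
mild additive perturbations of C (sd 5% of its maximum); day 1 is the
unperturbed reference.  Envelope noise is zero-mean Gaussian at 5% of
each channel's RMS, clipped so envelopes stay non-negative; the
accelerometer receives Gaussian noise truncated at 3 sd.  At these
defaults the generating rank-2 reconstruction scores VAF ≈ 0.99 against
the noisy data, comfortably above the 0.80 selection threshold — the
noise level stresses the pipeline without making the criterion
ambiguous.

What the generator does *not* model: motor-unit interference patterns
(it works at envelope level, which is what the factorization consumes),
electromechanical delay between EMG and motion, fatigue within a
session, co-contraction outside the synergy model, and real sensor
artifacts.  Passing tests therefore demonstrate correctness of the
algorithms and the claimed determinism/robustness mechanism under the
stated generative model, not clinical performance on human data.

## Pipeline and evaluation

The end-to-end run extracts synergies per session, trains one regressor
per amplitude group on the day-1 first-set data of all its subjects
(pooled along time), and predicts every other session.  Features of the
deterministic methods (MCR-ALS, PCA) are matched to each subject's
day-1 reference decomposition; NMF features keep their native
per-session order, because feeding the unstable random factor order to
the network is precisely the baseline behaviour being compared against
— re-matching them would repair the baseline with machinery the
baseline does not have.  On the default fixture this reproduces the
qualitative contrast: MCR-ALS features hold per-day CC ≈ 0.99 across
all held-out days, while NMF features collapse on any day whose factor
order happens to flip.

Cross-day stability is the mean ± sd over unordered day pairs of the
mean matched-synergy CC, computed on unit-normalized columns (raw-
amplitude CC would be dominated by the non-identifiable factor scale).
Accuracy reports give per-day CC and MAE plus mean ± sd.  Group-level
inferential statistics on such tables (t-tests, ANOVA) are standard
routines and are left to statsmodels/scipy rather than re-implemented.

## Numerical conventions and edge cases

- VAF of a constant matrix (zero denominator) raises rather than
  returning ±inf; CC of a constant series likewise.
- `pearson_cc` returns exactly ±1.0 when the centered inputs are
  bit-identical up to sign, so "identical decompositions have stability
  1" holds without floating-point slack.
- All-zero channels pass through max-normalization untouched.
- Seeds: every stochastic component (generator, NMF initialization,
  network initialization/dropout/shuffling) takes an explicit seed;
  session-level seeds are derived with `numpy.random.SeedSequence`.

## Known limitations

- The exact NNLS enumeration is exponential in r; it is intended for
  the small channel counts typical of synergy analysis (it switches to
  Lawson–Hanson per column above r = 8).
- The α offset convention (relative to max μ) and the purity axis
  (time samples) are choices documented above; other SIMPLISMA
  traditions exist, and results at very low α can differ.
- The quasi-static angle formula ignores dynamic acceleration beyond
  what the low-pass removes; fast movements would need sensor fusion.
- The Bi-LSTM is trained per amplitude group on one day; no
  hyperparameter search, transfer learning or attention variants.
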