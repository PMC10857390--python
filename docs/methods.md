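# Methods

`gaitforce` studies whether deep sequence regressors can recover lower-limb
muscle forces from wearable-grade kinematics. Because individual gait
recordings from the motivating experiments are not publicly available, the
package generates its own fully synthetic benchmark: a gait-kinematics
simulator, a transparent musculoskeletal reference model that defines the
ground-truth forces, and three neural estimators (CNN, LSTM, CNN–LSTM)
trained to invert the mapping. This note documents the models, the
parameters that matter, and what the synthetic benchmark can and cannot
show.

## Synthetic gait kinematics

Each gait cycle is represented by 12 channels — {left, right} × {hip,
knee, ankle} × {angle, angular velocity} in the sagittal plane — over one
heel-strike-to-heel-strike stride, resampled to a fixed `T = 100` samples
(the nominal sensor rate is 100 Hz and cycle durations are near one
second, so one sample ≈ one hundredth of a cycle).

Angles are truncated 4-harmonic Fourier series of the cycle phase φ ∈
[0, 1] with normative-shaped coefficients (hip flexion–extension ≈ ±0.35
rad, knee flexion ≈ 0–1.1 rad, ankle ≈ ±0.3 rad). Velocities are the
analytic time derivatives of the same series, so noiseless cycles satisfy
the derivative and periodicity invariants exactly. Right-leg channels are
the left-leg templates shifted by half a cycle. Speed enters twice:

* harmonic amplitudes scale by `1 + 0.25 (v − 1.5 m/s)`, so joint
  excursions grow smoothly with speed;
* cycle duration falls linearly, 1.15 s at 1.2 m/s to 0.95 s at 1.8 m/s.

Inter-cycle and inter-subject variability comes from a seeded ±5 % (1 SD)
multiplicative jitter on each harmonic amplitude, a stable per-subject
amplitude factor (±2 %), and a 5 % amplitude reduction for the elderly
cohort. Cycles are heel-strike aligned: phase 0 is always the same gait
event. Sensor noise emulating IMU error is additive Gaussian per channel
class, default 0.02 rad on angles and 0.1 rad/s on velocities; noise is
applied only to the *observed* cycles fed to the estimators, while the
clean kinematics drive the reference-force computation — mirroring a
laboratory in which an optical system, not the IMUs, feeds the
musculoskeletal analysis.

Subjects are drawn from cohort anthropometric distributions (young: mass
61.4 ± 11.3 kg, height 167.2 ± 12.5 cm; elderly: 58.7 ± 10.7 kg,
165.8 ± 9.5 cm), truncated at ±3 SD and at zero. Thigh and shank lengths
are the standard fractions 0.245 and 0.246 of height.

## Musculoskeletal reference model

Ground-truth forces for gluteus maximus (GM), rectus femoris (RF),
gastrocnemius (GAST) and soleus (SOL) come from per-sample static
optimization on a planar 8-muscle model (the four targets plus iliopsoas,
hamstrings, vasti and tibialis anterior, so every joint has an
agonist/antagonist pair and the redundancy problem is nontrivial):

1. **Joint torques.** Smooth sagittal torque templates over the cycle
   phase (hip extension burst in early stance, stance knee extension, a
   plantarflexion push-off burst, swing-phase hip flexion and
   dorsiflexion), scaled exactly linearly by body mass and affinely by
   speed (`0.7 + 0.2 v`). A torque template replaces full inverse
   dynamics, which would require ground-reaction forces the simulator
   does not produce; what matters for the estimator study is a smooth,
   deterministic kinematics + anthropometrics → force mapping.
2. **Moment arms.** `r(θ) = c0 + c1 cos θ` per spanned joint, with signs
   giving the torque direction; magnitudes stay below 0.08 m over
   physiological angles.
3. **Static optimization.** Per sample, minimise Σ aᵢ² subject to
   `R diag(f_max) a = τ` and `0 ≤ aᵢ ≤ 1`, the classic
   activation-squared redundancy resolution with ideal force generators
   (force = activation × f_max, with f_max proportional to body mass: GM
   30, RF 20, GAST 25, SOL 45, ILIO 25, HAM 30, VAS 40, TA 15 N/kg).

The QP is solved exactly by an active-set method: start from the
minimum-norm equality-constrained solution, clamp one bound violation at
a time, release clamped variables with wrong-signed KKT multipliers, and
fall back to exhaustive active-set enumeration (exact for this small
muscle count) in the rare event the greedy order fails. Feasibility is
certified by bounded least squares before clamping begins; torques
outside the feasible polytope raise an explicit error rather than being
clipped. Tests verify the solver against a dense grid-search oracle, the
interior two-muscle Lagrange closed form, and an independent SLSQP
solve. Solutions are deterministic, and because both τ and f_max scale
linearly with mass, activations are mass-invariant and forces scale
linearly — a property the test suite asserts.

No Hill-type activation or contraction dynamics, tendon compliance, or
3-D geometry: samples are independent, as in classic static optimization.

## Estimators

Input is a T × 16 sequence: the 12 kinematic channels plus height, mass,
thigh and shank length broadcast over time. Channels are min–max
normalized to [−1, 1] using extrema of the *training split only*
(`x̃ = 2 (x − x_min)/(x_max − x_min) − 1`); degenerate channels map to 0;
validation values may leave [−1, 1]. Target forces are scaled to [0, 1]
by training-set per-muscle maxima for the loss and unscaled (and clipped
at 0 N, forces being physically nonnegative) for reporting.

All three networks are implemented in NumPy with explicit
forward/backward passes (verified against central finite differences):

* **CNN** — conv(64 kernels, 3×1, stride 1, ReLU) → max-pool(2×1,
  stride 1) → conv(128) → max-pool → flatten → one fully connected layer
  emitting all T × 4 outputs. Convolutions are valid (no padding)
  cross-correlations, the deep-learning convention. The flatten head
  treats estimation as a whole-image decoding problem with no temporal
  weight sharing.
* **LSTM** — two stacked LSTM layers of 128 tanh units, then a per-step
  dense layer to 4 outputs.
* **CNN–LSTM** — conv(64 kernels, stride 2, ReLU) → LSTM(128) → per-step
  dense(4) → fixed linear interpolation back to T samples (valid
  convolution with stride 2 shortens the sequence to 49 steps; the
  upsampling operator is linear, so its backward pass is the exact
  transpose).

Training minimises mean absolute error with Adam (learning rate 1e-3,
batch 32, early stopping on validation MAE with patience 20; forget-gate
biases initialised to 1). Everything is seeded — parameter init, batch
shuffling — and single-threaded deterministic, so identical
configurations reproduce identical loss histories.

Both pooling strides are 1, which barely downsamples; that is the
configured structure of the standard CNN here, with the stride exposed in
`ModelSpec` for anyone wanting conventional stride-2 pooling.

## Evaluation

Two metrics compare estimated to reference forces: percentage RMSE
(`√Σ(x−y)² / √Σx² × 100`, not clamped at 100 %) and Pearson's r
(undefined — an error, not 0 — for constant series). Metrics are computed
per gait cycle and averaged across cycles; a concatenation mode exists
for sensitivity checks. Four-muscle "Average" rows are always recomputed
as arithmetic means of the per-muscle cells, never stored.

Three protocols mirror the benchmark designs of the motivating study:

* **training/validation** — per speed, an 8/2 per-subject split of 10
  cycles per subject (40 subjects → 400 cycles per speed, 320 train / 80
  validation);
* **intrasession** — all speeds fused (1200 cycles → 960/240 with the
  same per-subject split applied per speed), one model across speeds;
* **intersession** — the intrasession model evaluated without retraining
  on 6 unseen subjects (3 young, 3 elderly): 2 cycles × 3 training
  speeds = 36 cycles ("seen speeds") and 2 cycles × 2 held-out speeds
  (1.1 and 1.6 m/s) = 24 cycles ("unseen speeds").

## Benchmark sizes used in tests and the acceptance script

Full-scale designs (400 cycles per speed) are used for the count and
split arithmetic, which is cheap. The stochastic learning properties run
on reduced designs chosen once as the package's benchmark sizes:

* recovery/ordering: 10 subjects × 20 cycles at 1.5 m/s (200 cycles,
  160/40 split), CNN–LSTM and CNN, ≤ 60 epochs with early stopping,
  3 seeds;
* generalization: 10 subjects × 4 cycles × 3 speeds fused (120 cycles,
  96 train) for training, then the standard 36/24-cycle intersession
  evaluation.

## What the synthetic benchmark does and does not show

The generator produces smooth, periodic, speed- and
anthropometrics-conditioned kinematics with additive sensor noise, and
the reference model is a deterministic smooth function of phase, mass,
speed and joint angles. Passing tests therefore demonstrate that the
estimators can invert a mapping with the *structure* of the real problem
(redundant muscles, nonlinear moment arms, per-subject scaling, noisy
inputs) at the stated sample sizes. They do not demonstrate performance
on real gait: real kinematics contain step-to-step temporal correlation,
soft-tissue artefact, sensor drift and inter-subject variability far
richer than harmonic jitter, and real muscle coordination includes
co-contraction and activation dynamics that static optimization by
construction minimises. Correlations on the synthetic benchmark are
accordingly higher than the 0.90–0.98 range reported on real data, and
per-cycle Pearson r is shape-dominated, so differences between estimators
appear mostly in RMSE% and in the unseen-condition protocols.

## Numerical choices and degenerate inputs

* SO solver tolerances: bound tolerance 1e-9; residual acceptance
  1e-6·(1 + |τ|); active-set iteration cap 200 with exact enumeration
  fallback.
* Normalization: degenerate channels (x_max = x_min, e.g. anthropometric
  columns in a single-subject training set) map to 0 rather than raising.
* Max-pool ties route the gradient to the first maximal element.
* MAE uses the sign subgradient (0 at exact zeros).
* Non-finite training loss aborts with the epoch and batch in the
  message rather than continuing silently.
* All derived RNG seeds are drawn from `numpy.random.default_rng(seed)`
  streams and kept below 2³¹.
* Benchmark trainings run in float32 (configurable); the
  gradient-check tests run the same layers in float64.

## Known limitations

Single-plane kinematics and torques; no ground-reaction forces; a
torque template instead of inverse dynamics; 8 muscles instead of a full
lower-limb muscle set; no EMG, no activation dynamics; fixed one-cycle
windows of T = 100 samples (sequence length is an open choice —
sliding-window inputs are not implemented).
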