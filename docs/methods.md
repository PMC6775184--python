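# Methods

`arrayemg` decodes continuous finger joint angles from a 96-channel surface
EMG array wrapped around the forearm. This note describes the models and
procedures the package implements, the synthetic data it is validated on,
and the numerical and design choices behind them.

## The decoding problem

Finger muscles are small and lie deep in the forearm, so a single bipolar
EMG electrode placed by hand often misses them. A high-density array
sidesteps placement: every muscle projects onto many electrodes at once,
and the recording becomes a linear spatial mixture of muscle sources plus
interference. The pipeline recovers per-finger flexor and extensor drive
signals from that mixture and maps them to joint angles with one of two
decoders.

Processing order is fixed: average re-reference → 5–200 Hz band-pass →
resample to 500 Hz → ICA → rectified 3-Hz low-pass envelopes of either raw
channels or independent components. All filters are 4th-order Butterworth
applied forward–backward, so nothing is time-shifted relative to the
kinematics; this matters because both channel and component selection rely
on zero-lag correlation with the measured motion.

## Ground-truth angle construction

The instructed protocol alternates 2-s phases (flexion, rest, extension,
rest; 8 s per motion cycle). The measured kinematic quantity is the
normalized root-mean-square displacement (NRMSD) of the finger's joints
from a calibration pose, a unitless value in [0, 1]:

    NRMSD_f(t) = sqrt(mean_j ||p_j(t) − p_j^cal||²) / L_f

with `L_f` the finger length and the calibration pose the mean pose over
the rest segment that opens every experiment. The protocol trigger supplies
direction and scale:

    θ_f(t) = T_dir(t) · NRMSD_f(t),   T_dir ∈ {2.094, 0, −0.523} rad

(flexion, rest, extension). The trajectory is then median-filtered (0.5 s
window; the window size is a package choice — it removes single-frame pose
glitches without distorting 2-s plateaus) and low-passed at 1 Hz,
zero-phase. Angles are radians everywhere; degrees appear only in reports.

Pose estimation itself is out of scope: the kinematics module accepts
joint-position tables (or NRMSD series directly, as the simulator
provides).

## The equilibrium-point decoder (MSM)

Each finger is one rotational joint actuated by an antagonist
flexor/extensor pair of spring-like muscles. With contraction levels
u₁, u₂ ≥ 0 the joint torque is

    τ(θ) = Σₙ aₙ (k0ₙ + k1ₙ uₙ)(l0ₙ + l1ₙ uₙ − aₙ θ)

with moment arms a₁ > 0 > a₂ and positive stiffness (k) and length (l)
constants. The decoded angle is the torque-balancing equilibrium. Solving
τ(θ) = 0 exactly gives

    θ_eq = Σₙ aₙ Kₙ Lₙ / Σₙ aₙ² Kₙ,   Kₙ = k0ₙ + k1ₙ uₙ, Lₙ = l0ₙ + l1ₙ uₙ.

Note the squared moment arm in the denominator: a frequently quoted
first-power variant is *not* the root of the torque equation and its
denominator can vanish for valid parameters; the squared form cannot. The
package uses the exact root, so the identity τ(θ_eq) = 0 holds to machine
precision and is enforced as a test invariant (≤ 1e−8 over 1000 random
draws).

**Identifiability.** θ_eq is invariant to a common positive rescaling of
all four k constants, so the flexor k0 is pinned to 1 during fitting; that
removes a flat optimizer direction. Fitted parameter values are therefore
meaningful only up to this normalization — predictions, not parameters, are
the comparable output.

**Fitting.** Constrained nonlinear least squares on the RMSE between θ_eq
and the observed angle. Constraints are enforced by a log
parameterization (k, l = exp(·); a₁ = exp(·), a₂ = −exp(·)); the solver is
scipy's trust-region-reflective least squares with multi-start (default 10
restarts: the log-space origin plus seeded log-uniform draws in
[e⁻², e²]), best-of by training RMSE. Log parameters are clipped to ±40
before exponentiation so exploratory steps cannot overflow float64.
Degenerate inputs (constant angle and activations) are flagged in the
diagnostics rather than raised.

## The linear decoder (LRM)

Ordinary least squares on the design [1, u_flex, u_ext]:

    θ = β₀ + β₁ u₁ + β₂ u₂ + ε.

Rank-deficient designs (e.g. identical flexor and extensor inputs) are
solved by the minimum-norm solution and flagged as collinear. The fit is
cross-checked in tests against the normal-equation solution.

## Source separation and selection

A single-model super-Gaussian ICA stands behind the decomposition
contract: PCA whitening truncated at the rank explaining 1 − 1e−6 of the
variance (this absorbs the rank deficiency introduced by average
re-referencing and any duplicated channels), followed by FastICA with a
logcosh contrast, seeded and deterministic. The mixing matrix is the
pseudo-inverse of the composed unmixing; unmixing·mixing ≈ I on the
retained subspace to 1e−6. Separation quality is scored by the Amari
index of W·A (0 iff a scaled permutation). Near-Gaussian sources — for
which ICA is not identifiable — are flagged, not rejected.

Components and channels are vetted and selected as follows:

- **Topology heuristics.** Each component's mixing column is placed on the
  two 4×12 electrode panels. `spread` = fraction of channels at ≥ half the
  peak |weight|; spread > 0.5 flags motion noise (signal painted over a
  large area). A single dominant electrode with an opposite-sign neighbour
  at ≥ half the peak flags a detached sensor. These flags replace the
  human visual inspection step in an interactive workflow.
- **Correlation ranking.** Candidate envelopes are correlated with the
  direction-specific half-wave-rectified target (flexion: max(θ, 0);
  extension: max(−θ, 0)); rectifying the target makes the
  flexor/extensor assignment well-defined. CC is computed on envelopes,
  not raw broadband signals, because raw EMG is zero-mean noise-like and
  carries the motion information in its amplitude. The top 16 candidates
  are returned; the chosen component is the best unflagged one, ties going
  to the lower index.
- **Channel masks.** Raw-channel candidates are restricted to the
  anatomical mask of the finger: by default a contiguous 4-row × 2-column
  electrode block per finger per panel, ordered Thumb→Pinky along the
  grid. Masks are data (YAML), not code, because electrode-to-anatomy
  correspondence is a property of the montage, not of the algorithm.
  Ties break toward the lower grid row, then column.

ICA is fit once per subject on the concatenation of all that subject's
preprocessed experiments (selection and model fitting still use only the
designated training data; ICA itself is unsupervised).

## Synthetic data: what it emulates, what it does not

The simulator generates the full study: per subject, 25 train experiments
(5 per finger, Thumb→Pinky) and 5 mixed test experiments, each opening
with a 4-s rest calibration segment; 96 channels at 2048 Hz by default.

- **Activations.** Trapezoidal bursts with 0.3-s raised-cosine ramps,
  amplitude jittered in [0.92, 1], resting baseline ε = 0.02. Adjacent
  fingers receive exactly `crosstalk` × the instructed burst — a stylized
  version of the mechanical interconnection that makes isolated finger
  motion impossible.
- **Ground truth.** Subject-specific MSM parameters are drawn from
  realistic unitless ranges, with length constants solved so the
  equilibrium is exactly 0 at baseline and reaches the trigger angles
  (2.094 / −0.523 rad) at full drive; angles are the model equilibrium of
  the activations, so the generating process *is* the decoder's model
  class. Truth series are stored at 250 Hz.
- **EMG.** Each muscle source is its activation times an independent
  unit-RMS 20–250 Hz noise carrier (independent carriers ⇒ independent
  sources, satisfying the ICA model by construction). Sources project to
  the panels through Gaussian blobs (σ = 1.5 grid units) centred on the
  finger's mask block, so neighbouring fingers overlap spatially. Added on
  top: a 50-Hz mains sinusoid (20 % of signal RMS, per-channel gain),
  white sensor noise scaled to the configured broadband SNR, and < 5-Hz
  motion-artifact bursts during movement phases with random spatial
  profiles.

Not emulated: motor-unit firing statistics, conduction velocity and fatigue
effects, skin-impedance drift, electrode-to-skin nonstationarity, and any
camera/pose-estimation error model beyond the NRMSD abstraction. Passing
tests therefore demonstrate that the pipeline is correct and behaves as
designed under its own model assumptions — they do not certify performance
on human recordings, where the EMG–angle relation is noisier and only
approximately within the MSM model class.

## Evaluation protocols

Envelopes and ground truth are compared at 25 Hz (envelope content lives
below the 3-Hz cutoff, so this decimation is lossless for the comparison
and keeps the optimizer fast). Per experiment, envelope offsets are
removed using the calibration-segment mean; per fitted model, flexor and
extensor inputs are normalized by their training-segment maximum (the same
constants are applied at test time).

- **Protocol A** fits each finger's decoders on that finger's single-finger
  train experiments and scores CC and RMSE on every mixed test experiment.
  A `test_refit` variant that fits on the test experiments themselves (the
  optimal-situation reading) is available by configuration.
- **Protocol B** fits on exactly one mixed test experiment and scores on
  the remaining ones — the small-training-data regime of a practical
  prosthesis calibration.

Results are per (subject, finger, method ∈ {MSM, LRM} × {ICA, EMG},
protocol) rows with CC and RMSE in degrees, aggregated as mean ± std
across subjects. A paired two-sided t-test (α = 0.05) on (subject, finger)
CC pairs compares the ICA and EMG variants of the same decoder. The
harness asserts that fitting and evaluation experiment sets are disjoint.

## Study problem sizes

The bundled studies (`arrayemg.studies`) fix scaled problem sizes chosen
so each study completes in minutes on one core while keeping the protocol
structure intact:

- MSM recovery: noiseless activations/angles, 2 × 3-motion experiments per
  finger, fit on one, scored held-out on the other.
- ICA separation: 3–6 Laplacian sources, 8 channels, 60 s at 500 Hz,
  5 seeds.
- IC selection: one subject per seed, one 2-motion train experiment per
  finger at 1024 Hz, 16-component ICA, 5 seeds at 10 dB SNR.
- IC-vs-EMG advantage: 10 subjects, one 3-motion train experiment per
  finger plus two 5-cycle test experiments at 1024 Hz, 5 dB SNR,
  cross-talk 0.2, 24-component ICA, 4 optimizer restarts. Only the sign of
  the mean CC difference is claimed, not its magnitude.

## Numerical choices and edge cases

- Filters: Butterworth order 4, `sosfiltfilt` with reflect padding;
  envelope values are clamped at 0 after filtering so u ≥ 0 holds.
- Resampling: polyphase with the exact rational rate ratio; triggers are
  mapped by nearest source sample; duration is preserved within a sample.
- NRMSD is clipped to [0, 1]; trajectories to ±π.
- Zero-variance series make CC undefined: it is returned as NaN and
  ignored (NaN-mean) in aggregation rather than silently zeroed.
- Whitening rank: eigenvalues below 1e−12 of the largest are never
  retained, independent of the explained-variance threshold.
- Seeds: every stochastic stage (simulation, ICA, optimizer restarts)
  takes an explicit seed; per-subject and per-experiment streams are
  spawned from a root seed sequence, so datasets are bit-reproducible.

## Known limitations

- The MSM assumes instantaneous activation-to-angle equilibrium; real
  muscle has activation dynamics and load-dependent behaviour the model
  ignores.
- Heuristic topology flags approximate, but cannot fully replace, expert
  visual vetting of components on real data.
- EDF/BDF files are read, not written; the writable interchange format is
  the delimited table + JSON sidecar.
- The simulator's sources match the ICA model exactly; real EMG mixtures
  are only approximately linear and stationary, so measured separation
  quality on synthetic data is an upper bound.
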