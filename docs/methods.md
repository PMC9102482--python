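# Methods

This note documents the models, parameter choices and numerical
conventions behind each stage of the pipeline, and what the synthetic
benchmark does and does not establish about real recordings.

## Synthetic sEMG generator

Surface EMG over the biceps brachii during isometric contraction is
modeled as amplitude-modulated, band-limited Gaussian noise. A voluntary
burst is white Gaussian noise passed through an 8th-order Butterworth
band-pass whose design corners sit slightly inside the nominal 20–450 Hz
band (25–430 Hz), so that despite the finite roll-off at least 95% of
burst power lies inside the band itself; the burst is multiplied by a
trapezoidal envelope with 100 ms linear ramps and peak-normalized to the
session amplitude (default 2 mV, within the physiological 0.1–5 mV
range). Class durations are 1 s (SMP), 3 s (SMP3) and 5 s (SMP5), each
jittered by ±15% (uniform) so that adjacent classes overlap slightly and
classification is not a table lookup. Events are separated by 5 s rest:
white noise at 0.05 mV RMS (an additional floor of the same RMS is added
over the whole session; samples are clipped to amplitude + 5σ as a hard
guard, a bound the Gaussian tails essentially never reach).

The NIM (rest / involuntary movement) class renders a 3 s activity slot
with two faces, matching its definition: with probability 0.35 the slot
is quiet (rest plus baseline wander — a 0.1–0.5 Hz sinusoid at 10% of
the session amplitude); otherwise it carries erratic 0.3–1.5 s bursts at
10–40% of the voluntary amplitude with irregular gaps. All randomness
flows from a single `numpy` Generator seeded by the session plan, so
equal seeds give bit-identical sessions.

What the generator does *not* emulate: motor-unit action-potential
structure, electrode–skin impedance and motion artifacts beyond a DC
offset, signal nonstationarity due to fatigue, and inter-subject
variability. A classifier that is perfect here is therefore evidence
that the pipeline, features and training loop work — not that real
four-class sEMG separates this cleanly.

## Filter and spectrum

The run-time filter is the discrete first-order low-pass
`v_o[n] = a v_o[n-1] + (1-a) v_in[n-1]` with `a = exp(-2π f_c T)`. Two
conventions are fixed: the first output sample equals the caller-supplied
initial state (default 0), and the input enters with one sample of
delay, exactly as the difference equation is written — hence the
closed-form gain `|H| = (1-a)/|e^{jωT} - a|` and exact unit DC gain.
For any cutoff below Nyquist, 0 < a < 1, so stability is unconditional.

Spectra are plain rectangular-window DFTs by default, which keeps the
Parseval identity exact against the raw samples; an optional Hann flag
tapers the series first when leakage matters more than exact energy
bookkeeping. The one-sided energy-per-bin weighting is chosen so the
spectrum energies sum to the (windowed) time-domain energy to machine
precision. The
dominant interference component is the non-DC bin with maximal energy
(ties resolve to the lower frequency). Cutoff tuning policy: if the
dominant component lies above the 450 Hz band edge, f_c is the geometric
mean of the band edge and the interference frequency (log-equidistant
from both); otherwise f_c stays at the band edge, with a warning when
the interference falls inside the band, where a low-pass cannot help.
This placement rule is this package's explicit policy; only its
endpoints (pass the band, attenuate the interference) are dictated by
the problem.

## Segmentation and features

Bursts are detected from the 100 ms moving-RMS envelope crossing 3× the
rest level, estimated as the median envelope (rest dominates the
protocol timeline, making the median a robust rest statistic). Bursts
separated by < 0.5 s merge; bursts < 0.3 s are discarded as candidate
involuntary blips; quiet stretches ≥ 2 s are emitted as rest segments so
the classifier also encounters the NIM class at inference time. Only
burst segments carry command intent downstream — sustained rest must not
move (or deactivate) the robot; a *detected burst* classified NIM is
what triggers the safety deactivation.

The feature vector is [duration_s, RMS, MAV, zero-crossing rate]. The
classifier input dimension is fixed at four; duration is the quantity
that defines the classes, and RMS/MAV/ZCR are the standard sEMG
time-domain features that separate voluntary bursts from weak
involuntary activity. Features are standardized to zero mean and unit
population standard deviation using statistics of the training split
only.

## MLP classifier

Architecture 4–4–4: ReLU hidden layer, softmax output, one-hot targets,
mean categorical cross-entropy (the conventional negated form, so the
loss is minimized toward zero). Weights initialize uniformly in
[-0.5, 0.5) from the training seed. Optimization is full-batch Adam
(lr 0.01, β₁ = 0.9, β₂ = 0.999, ε = 1e-8, bias-corrected) for 3000
epochs — at ~10² training examples full-batch is cheap and removes
mini-batch noise, which is why the loss decreases essentially
monotonically (tests check monotonicity at 500-epoch checkpoints).
The data split is a seeded shuffle: 20% test, then the trailing 10% of
the remainder as validation (keras-style `validation_split` semantics).
Training refuses to proceed if any class is absent from the training
split. Predicted probabilities are clipped at 1e-12 inside the log;
exact argmax ties resolve to the lowest class index. Back-propagation is
verified against central finite differences to 1e-5 relative in tests,
and an off-the-shelf sklearn MLP on the same features serves as an
independent baseline cross-check, never as the implementation.

Class coding is NIM = 0, SMP = 1, SMP3 = 2, SMP5 = 3 throughout.

## Mealy machine

Inputs are one-hot 4-bit words ordered [NIM, SMP3, SMP5, SMP] from most
to least significant bit. The eight motion states carry fixed Cartesian
set-points (see the table in the state-machine module); HOME is the
deactivated state. The transition policy — SMP always stops (→ S1),
SMP3 moves along the vertical/diagonal axis (a second SMP3 from an upper
diagonal reaches the lower diagonals), SMP5 cycles horizontally, NIM
deactivates from everywhere — ships as a versioned JSON asset. The
design constraints it satisfies, enforced by tests: all eight motion
states reachable from S1, each state's output bit-exact, NIM absorbing
until an explicit reset, all-zero words are no-ops. The symbolic input
codes IN1–IN8 name the (state, class) edges of the table; IN9 is the NIM
word. A per-event timed semantics (asynchronous transitions) is out of
scope.

## Manipulator

Geometry: rotary base (q1) plus a planar two-link arm (q2 shoulder, q3
elbow). Forward kinematics uses the full link lengths l2, l3 (centers of
mass enter only the dynamics), which makes FK and IK exact inverses.
IK solves q1 = atan2(py, px) (the px = py = 0 base singularity resolves
to q1 = 0 with a warning), then q2 from the half-angle form of
a cos q2 + b sin q2 = c with a = 2 l2 r, b = 2 l2 u,
c = r² + u² + l2² − l3² (r radial, u vertical wrist offset; the elbow
branch is the ± of the discriminant root), and q3 from the wrist
residual atan2 — closing the chain exactly, so FK∘IK is identity to
round-off (< 1e-9 m enforced on 1000 random reachable points and all
eight set-points, both branches).

Dynamics: the inertia matrix is assembled from kinetic energy; the base
row/column couples to the arm only through configuration-dependent terms
(M12 = M13 = 0 for this mechanism — the base axis is orthogonal to the
arm plane), M11 = I1+I2+I3 + m2 (lc2 cos q2)² + m3 (l2 cos q2 + lc3
cos(q2+q3))², M22 = I2+I3+m2 lc2²+(l2²+lc3²+2 l2 lc3 cos q3) m3,
M23 = I3 + (lc3² + l2 lc3 cos q3) m3, M33 = I3 + lc3² m3. The Coriolis
matrix comes from the Christoffel symbols of M with analytic ∂M/∂q, so
Ṁ − 2C is skew-symmetric by construction (tested to 1e-8 against a
finite-difference Ṁ). Gravity is the gradient of
U = g (m2 lc2 sin q2 + m3 (l2 sin q2 + lc3 sin(q2+q3))); its first
component is identically zero. Energy conservation under zero
gravity/friction/torque holds to ~1e-14 relative over 5 s at dt = 1 ms.

Parameters are desk-scale defaults chosen once so every set-point is
reachable: l = (0.30, 0.25, 0.25) m, lc = l/2, m = (1.0, 1.0, 0.8) kg,
I = 0.01 kg·m² per link, B = 0.1 N·m·s/rad, g = 9.81 m/s². Gains
Kp = 100·I₃, Kv = 20·I₃ give well-damped settling in well under 5 s at
this scale. Both ship as a JSON config.

Control and integration: PD+ (PD feedback plus full-model feedforward).
For the constant set-points emitted by the state machine, q̇_d = q̈_d = 0
and the law reduces to PD with exact gravity compensation, whose
equilibrium is exactly q_d — hence regulation errors at round-off rather
than at some controller-dependent floor. Integration is fixed-step RK4;
dt is capped at 2 ms (default 1 ms), halving dt moves the final state by
< 1e-6 rad, and the simulator aborts with a diagnostic if ‖q̇‖ exceeds
10³ rad/s.

## Evaluation harness

The trajectory protocol is scripted rather than human: a simulated user
issues the shortest command path (BFS over the transition table) to the
next waypoint, erring with a per-trial mistake probability that decays
geometrically (default 0.35, factor 0.65) across repetitions; each
visited state that is not the next expected waypoint counts one penalty,
and the task repeats until a zero-penalty completion (cap 50).
Response time is the duration implied by the EMG timeline — contraction
plus 5 s rest per command — never host wall-clock, so results are
hardware-independent. Percent decrease is 100 (t_first − t_last)/t_first
to two decimals. The decaying-error model is a caricature of motor
learning chosen for determinism; the harness demonstrates the metric
machinery, not human learning rates.

## Problem sizes and limitations

Default experiment sizes: classifier benchmark 40 bursts/class
(≈ 35 min of signal at 10 kHz, ≈ 21 M samples, generated and processed
in a few seconds), regulation runs 6 s at dt = 1 ms per set-point,
energy checks 5 s. These sizes give stable statistics while keeping the
full suite fast.

Known limitations: the surrogate signal model above; a single EMG
channel (no electrode-array spatial information); set-point (not
trajectory-interpolated) robot motion; no actuator saturation or joint
limits; and the scripted user model. The human-subject results of the
underlying protocol (absolute trial times, repetitions to mastery) are
inherently not desk-reproducible; the harness reproduces their metric
definitions and arithmetic on scripted sessions instead.
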