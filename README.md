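# myohmi

A fully simulated, single-channel surface-EMG (sEMG) human–machine
interface: muscle contractions recorded over the biceps brachii are
classified by contraction *duration* and drive the end effector of a
3-DOF anthropomorphic manipulator between fixed set-points.

The package is for researchers and students in biomedical signal
processing and assistive robotics who want a complete, testable desk
model of such an interface — every stage from the raw voltage series to
the closed-loop robot is implemented and verifiable without hardware or a
recorded dataset.

## What it implements

**Signal model.** Synthetic sessions emulate isometric biceps
contractions: band-limited Gaussian noise (20–450 Hz) with a trapezoidal
envelope, amplitudes 0.1–5 mV at 10 kHz, in four classes — a sharp ~1 s
pulse (SMP), smooth 3 s and 5 s pulses (SMP3, SMP5), and a
rest/involuntary-movement class (NIM). Seeded generation returns exact
ground-truth intervals.

**Filtering and tuning.** The real-time smoother is the first-order IIR
low-pass derived by difference equation,

    v_o[n] = a v_o[n-1] + (1 - a) v_in[n-1],      a = e^{-2π f_c T},

with unit DC gain. A rectangular-window DFT locates the dominant
interference component, and the cutoff f_c is placed between the signal
band and that component.

**Classifier.** Detected bursts are summarized by four features
(duration, RMS, MAV, zero-crossing rate), standardized to zero mean and
unit variance, and classified by a 4–4–4 multilayer perceptron (ReLU
hidden layer, softmax output, one-hot targets) trained with full-batch
Adam on the categorical cross-entropy — implemented from scratch, with
sklearn/keras-free portable JSON weights.

**Command automaton.** Classes become one-hot 4-bit words
([NIM, SMP3, SMP5, SMP], MSB first) feeding an eight-state Mealy machine
whose states are Cartesian set-points (stop, up, left/right, four
diagonals). NIM deactivates the machine from any state — involuntary
movement must never move the robot.

**Robot.** A waist–shoulder–elbow arm with closed-form forward and
inverse kinematics, Euler–Lagrange dynamics
τ = M(q)q̈ + C(q,q̇)q̇ + g(q) + Bq̇ (Coriolis via Christoffel symbols),
and the PD+ law

    τ = Kp q̃ + Kv q̃̇ + M(q) q̈_d + C(q,q̇) q̇_d + B q̇_d + g(q),

integrated with fixed-step RK4, drives the joint error q̃ = q_d − q to
zero for every set-point.

**Evaluation.** A scripted-user harness replays the point-to-point
trajectory protocol (penalties for wrong commands, repetition until a
clean run) and reports the percent decrease in response time.

## Worked example

```python
import numpy as np
import myohmi as m

# 40 labeled bursts per class from the seeded generator, filtered and
# segmented exactly as at inference time
segments = m.make_benchmark_segments(n_per_class=40, seed=42)
fit = m.EmgClassifier.from_segments(segments).fit(m.TrainConfig())
print(fit.summary())
```

```
EMG contraction classifier (4-4-4 softmax MLP, Adam)
======================================================
examples: 160 (train 115 / val 13 / test 32)
epochs: 3000   lr: 0.01   seed: 42
final train loss: 0.0001   final val loss: 0.0001
held-out accuracy: 1.000

confusion matrix (rows true / cols predicted):
      NIM  SMP  SMP3  SMP5
NIM     8    0     0     0
SMP     0    8     0     0
SMP3    0    0     9     0
SMP5    0    0     0     7
```

Every held-out burst is classified correctly and the training loss has
fallen to ~1e-4, i.e. the four duration classes are cleanly separable
under the generator's ±15% duration jitter.

```python
# drive the arm to the "up" set-point of state S2
robot = m.Manipulator()
qd = robot.inverse_kinematics(np.asarray(m.MachineState.S2.output))
sim = robot.simulate(np.array([0.0, np.pi/4, -np.pi/4]), qd,
                     dt=1e-3, duration=6.0)
print(sim.summary())
```

```
PD+ closed-loop simulation
========================================
duration: 6.000 s   steps: 6000   dt: 0.001 s
target q_d (rad): [-1.5708  2.1405 -2.344 ]
final joint error (rad): [-0.  0. -0.]
final |error|_inf: 1.50e-13 rad
final Cartesian error: 0.0000 mm
```

The PD+ controller with exact gravity compensation settles on the
set-point with a final joint error at numerical round-off — the
"tendency to zero" tracking objective, made quantitative.

The same stages are available from the shell:

```bash
myohmi generate --classes SMP,SMP3,SMP5,NIM --reps 10 --seed 1 \
    --out session.csv --truth-out labels.json
myohmi train --in session.csv --truth labels.json --model model.json
myohmi run --in session.csv --model model.json --out trace.jsonl
```

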