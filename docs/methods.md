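# Methods

## Problem and data model

A wearable altimeter reports the height h (meters) of the worn device above
the floor. A *descent incident* starts at the wearer's sensor height h₀ and
ends at floor contact; the task is to decide whether it was an involuntary
fall or a voluntary lean-over (bend). An `Incident` is the ordered sample
sequence (t, h) with t in seconds from incident onset.

Floor contact is defined as the first sample with h ≤ 0.01 m
(`H_FLOOR_TOL`): real barometric sensors never read exactly zero, and the
first-contact convention makes the total time well defined for trajectories
that linger at the floor. Upward wiggles of up to 0.02 m between consecutive
samples (`RISE_TOL`) are accepted as sensor noise; anything larger is
rejected as not being a descent event. Heights are meters throughout — the
interval [0, 1.72] makes physical sense only as meters (1.72 m is a standing
sensor height; 1.72 cm is not).

## Duration model and parameter sets

Total descent times are modeled per class as normal distributions truncated
to their observed supports. Two published parameterizations exist for the
same underlying measurements and they disagree; the package bundles both and
makes the choice explicit (`duration_models(parameter_set=...)`):

| set | μ_F (s) | μ_B (s) | r (s) |
|---|---|---|---|
| `"text"` (default) | 1.86 | 3.14 | 2.5 |
| `"table"` | 1.3 | 2.1 | 1.7 |

The printed spread values 0.39 s and 0.48 s are written in variance notation
but carry time units; the package reads them as variances by default
(σ = √0.39 ≈ 0.62 s, σ = √0.48 ≈ 0.69 s) and `spread_is_variance=False`
selects the standard-deviation reading.

The stated supports are exactly μ ± spread ([1.47, 2.25] = 1.86 ± 0.39;
[2.66, 3.62] = 3.14 ± 0.48). That pattern is adopted as the general
convention whenever a support is not stated: support = μ ± spread. Symmetric
truncation keeps the truncated mean equal to μ, so fitting sample means on
simulated data recovers the configured parameters without bias.

## The simulator

`generate_dataset(SimulationConfig(...))` draws a duration T per incident
from the class truncated normal and renders the trajectory at
`sample_rate` = 30 Hz (the NTSC video-frame clock the reference measurements
derive from, and a realistic wearable rate):

* fall: h(t) = h₀ (1 − (t/T)²) — starts at rest, accelerates;
* bend: h(t) = h₀ (1 − t/T)² — starts at speed 2h₀/T, decelerates to zero.

The observed fall durations (1.47–2.25 s) are much longer than ballistic
free fall from 1.72 m (~0.59 s) — people topple rather than drop — so "free
fall" is treated as a statement about the accelerating shape, with the
duration set by the sampled T.

Defaults are the study conditions: 41 falls, 45 lean-overs, h₀ = 1.72 m.
Numerical conventions:

* **Terminal sample.** The last sample is exactly (T, 0), so floor contact
  is well defined at any rate and the measured total time equals T.
* **Near-floor guard.** Interior samples whose noiseless height is within
  `H_FLOOR_TOL + clip` of the floor (clip = 2·noise sd) are suppressed.
  The decelerating bend profile spends its last ~8% of T below the 0.01 m
  floor tolerance; without the guard, first-contact semantics would truncate
  bend durations to ≈ 0.92 T and distort the configured distribution. The
  guard emulates the annotation convention that the event ends at floor
  contact. No checkpoint of the default K = 20 grid lies inside the guard
  band, so crossing times are unaffected.
* **Noise.** Gaussian height noise (default sd 5 mm, a plausible smoothed
  barometric resolution; no published value exists) is added to interior
  samples only and clipped at ±2σ, bounding the worst-case upward wiggle at
  0.02 m = `RISE_TOL` so every generated incident satisfies its own
  invariants. Timestamps carry no noise: a frame clock is effectively exact.

What the simulator does *not* emulate: pre-fall activity, partial or
recovered ("near-fall") descents, sensor drift and temperature effects,
pressure-to-altitude conversion error, or biomechanical articulation. Tests
passing on this generator show the inference machinery is correct under the
stated duration/shape model; they do not certify accuracy on real sensor
data, where class separation is known to be far weaker.

## CM-I

`TotalTimeThresholdClassifier.fit` computes each class's sample mean and
standard deviation of total time and sets r = (μ_F + μ_B)/2; `predict`
returns FALL iff t_I < r. The boundary t_I = r classifies as BEND (the
strict inequality), as does every tie in CM-II: the conservative default
treats an ambiguous incident as routine movement. Published PDFs can be
supplied directly (`fall_model=` / `bend_model=`), bypassing estimation.
Fitting does not enforce μ_F < μ_B, so that cross-validation on degenerate
or label-shuffled folds (used as a chance-level oracle) remains well
defined; the ordering is validated when explicit models are supplied.

## CM-II

Trajectories of different lengths are made comparable by indexing on
*height*, the one axis the altimeter shares across incidents: checkpoint j
is a fixed height level, and t_Xj is the first time a trajectory crosses it,
linearly interpolated between the bracketing 30 Hz samples (higher-order
interpolation is immaterial at this rate; interpolation error is ≪ one
sampling interval).

`CheckpointVoteClassifier.fit` places K = 20 checkpoints at heights
h₀(1 − j/K), j = 1..K — equally spaced with spacing h₀/K, ending at 0 (where
the crossing time is the total time). The start height h₀ is deliberately
*not* a checkpoint: every trajectory crosses it at t = 0 with zero distance
to both references, which would cast one guaranteed tie→BEND vote per
incident and bias the majority; with an even K that single wasted vote can
flip extreme-but-legitimate incidents. Reference vectors t_F, t_B are the
per-class element-wise means of the training crossing times, re-estimated
inside every CV fold.

A consequence of the two profile shapes worth noting: the bend reference
crosses *upper* checkpoints earlier than the fall reference (the bend starts
fast, the fall starts at rest); t_Fj < t_Bj holds only below the crossover
height ≈ 0.23 h₀ (solve 1.86√(1+s) = 3.14√(1−s), s = √(h/h₀)) and at the
floor checkpoint. Classification is unaffected — votes compare the incident
to *both* references, so shape similarity, not element-wise ordering, drives
the decision — and it is exactly this shape contrast that lets CM-II
separate classes whose total durations overlap, where CM-I fails.

Votes are unweighted (one per checkpoint, no depth weighting). The streaming
variant (`StreamVoter`) applies the same first-crossing interpolation sample
by sample and is exactly equivalent to the batch path; before floor contact
its state is explicitly undecided.

## Evaluation harness

FALL is the positive class: s_p counts correctly detected falls, the
clinically actionable event. Accuracy is (s_p + s_n)/n.

`cross_validate` runs stratified k-fold CV (each class shuffled and
partitioned separately, remainders spread round-robin, so the printed
4-falls + 4-bends test fold / 78-incident training fold arithmetic of the
86-incident design is honored), repeated `iterations` = 100 times with fresh
shuffles, classifier refitted per fold. The reported figure is the grand
mean of fold accuracies. Incidents are sorted by id before the seeded
shuffles, so results are invariant to input ordering; everything is
deterministic given `seed`.

`mcnemar_test` tallies discordant pairs b (A wrong, B right) and c (A right,
B wrong) and uses the exact two-sided binomial test when b + c < 25, else
the continuity-corrected χ² statistic (|b−c|−1)²/(b+c) on 1 df; the result
records which variant ran. At the b + c = 25 boundary the two variants agree
to < 0.02 for every split. With b = c = 0 the test is degenerate and p = 1.

## Problem sizes and known limitations

The test and acceptance suites run the full protocol (10 folds × 100
iterations) at the study's own scale of 86 incidents, and parameter-recovery
checks at 5 000 incidents per class; both complete in seconds.

The published real-data accuracies (0.62 for CM-I, 0.98 for CM-II) were
measured on a video-derived dataset that was never deposited and cannot be
recomputed; under this package's synthetic study conditions both models hit
the 1.0 ceiling because the default duration supports are disjoint. The
qualitative ordering is instead demonstrated on an overlap-stressed regime
(class means moved to 2.3 s and 2.7 s, spreads unchanged), where CM-I falls
to ≈ 0.72 mean CV accuracy while CM-II stays at ≈ 1.0. How the real data
produced 0.62 for CM-I is not modeled — durations drawn from the published
PDFs would separate far better — which underlines that the PDFs are a
summary, not a generative account, of the real measurements.
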