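# Methods

## Model

Each gene's mRNA level obeys a mass balance `dx/dt = r(t) − d·x` with
transcription rate

    r(t) = r0 (A^n + e) / (1 + I^n + A^n + e),

where `A` and `I` are the activator and inhibitor sums `Σ x_i(t−τ)/K_i`
evaluated on the regulators' trajectories at a fixed delay `τ`. The form
encodes competitive binding of activating and inhibiting transcription
factors with cooperativity `n` and saturation: the rate is bounded by `r0`,
non-decreasing in `A` and non-increasing in `I`; `e` represents external
stimulation or constitutive transcription and also sets the basal rate
`r0·e/(1+e)` when no activator is bound.

Assumptions baked into the implementation:

- A regulator acts on a given target in one role only (activator or
  inhibitor); allowing both would double-count its concentration in the
  competition denominator.
- The Hill exponent is a model constant (`n = 2` everywhere), not a fitted
  parameter, and `τ` is known and shared by all genes (1 h by default).
- Delay history: `x(t) = x0` for `t ≤ t0`. Initial expression is 1 in the
  benchmark protocol, and the pre-experiment past is taken constant at that
  value.

## Parameters

| symbol | meaning | units | default / range |
|---|---|---|---|
| r0 | maximal transcription rate | expr·h⁻¹ | generator: log-uniform [0.5, 2] |
| d | degradation rate | h⁻¹ | generator: log-uniform [0.5, 2] |
| e | external / constitutive drive | — | 0; stimulated genes U[1, 21] |
| K | per-edge binding constant | expr | generator: U[0.25, 9.75] |
| n | Hill cooperativity | — | 2 (fixed) |
| τ | transcription/translation delay | h | 1 (fixed) |

Fitting searches all per-edge K plus r0, d and e in log-space within
[10⁻², 10²]; τ and n stay fixed.

## Numerical integration

**Single-target models** (candidate fits) are linear in the state once the
regulator splines are fixed: `dx/dt = r(t) − d·x` with `r` a known function
of time. The fitting path exploits this: regulator values `x_i(t−τ)` are
pre-tabulated once per dataset on a refined grid (each observation interval
split into `substeps` equal steps, 25 by default), and each step is advanced
with the exact one-step solution for piecewise-linear `r`, evaluated as a
linear recurrence in C (`scipy.signal.lfilter`). A residual evaluation costs
a few array operations, which is what makes ~10³–10⁴ trial fits per gene
feasible on one CPU core. `integrate_target` also exposes the adaptive
LSODA path (`rtol 1e-6`, `atol 1e-9`) as the reference integrator; the two
agree to ~10⁻⁵ relative at the default grid and are cross-checked against a
fixed-step RK4 oracle in the tests.

**Full networks** are delay differential systems, integrated by the method
of steps: on each `τ`-length segment the delayed state is read from the
dense output of previously solved segments (constant history before t0), and
each segment is solved with LSODA. Cyclic dependence is expected — the delay
breaks algebraic loops. Non-finite states abort with the offending gene ids.

## Ensemble search

Candidate regulator sets draw activator and inhibitor counts uniformly on
{0..3}×{0..3} excluding (0,0), then regulators uniformly without replacement
among the other genes. Each trial starts from a single random log-uniform
iterate within the bounds — the trial budget buys restarts implicitly — and
is fitted with bounded trust-region least squares (`method="trf"`,
`max_nfev` 60, `ftol` 1e-4 by default; precision studies use `substeps=100`
and a larger evaluation budget). The fit cost is RMSE normalized by the mean
of the target series. A trial is accepted when its cost falls below the
acceptance threshold (default 0.05, i.e. a 5% normalized misfit); trials
that exhaust the optimizer's evaluation budget but already sit below the
threshold count as accepted, since the achieved residual is what defines
"effectively fits the data". Optimizer failures are consumed as rejected
trials, never fatal.

Per-trial RNG streams are seeded by (master seed, gene, trial index), so
results are independent of batch size, execution order and worker count; the
batch size (1600 by default) only controls chunking.

Edge scores are frequencies over the **accepted** ensemble. The binomial
null uses the analytic per-role inclusion probability
`p0 = E[role size]/(N−1)` implied by the candidate-size distribution
(= 1.6/(N−1) at the defaults), removing Monte-Carlo noise from significance
calls; the survival function is evaluated exactly. Cutoff comparisons are
inclusive (frequency ≥ cutoff; CV informative iff CV > 0.05 strictly).

## Multi-experiment combination

Union and intersection act per (target, regulator, role). The CV-gated
intersection uses the coefficient of variation (sample standard deviation,
n−1 denominator, over mean) of the target's own time course to decide which
experiments can say anything about that gene: intersection over informative
experiments; a single informative experiment stands alone; if neither
experiment is informative the gate makes no call and the plain intersection
is kept. With this rule the gated prediction always contains the plain
intersection, so gating can only add recovery (at the price of extra false
positives), which is the intended behavior of the gate.

Evaluation is role-aware by default (an activator prediction must match an
activator edge); a role-agnostic mode is available. Metrics are the
percentage of true edges recovered and false positives per gene.

## Benchmark generator

The generator emulates the standard in-silico protocol: per-gene in-degrees
from a truncated discrete power law `P(k) ∝ k^(−γ)`, k ∈ [1, 20], with γ
calibrated numerically so the mean in-degree is 3.7 (≈3700 edges at 1000
genes); regulators wired uniformly at random with no self or duplicate
edges; each edge an activator with probability 0.5; K ~ U[0.25, 9.75];
r0 and d log-uniform on [0.5, 2] (chosen so trajectories neither flatline
nor blow up over the 11 h window — the protocol states only that they are
random); out-degrees emergent. Each experiment stimulates a random subset of
genes (250 and 200 at N = 1000, scaled proportionally by the CLI for
smaller N) with e ~ U[1, 21]; unstimulated genes have e = 0. Data are the
DDE solution at 12 equally spaced timepoints over [0, 11] h with x(0) = 1,
and are noise-free.

What the generator does **not** emulate: measurement noise, unobserved
regulators, non-uniform sampling, and biological variation between
replicates. Tests passing on this generator therefore demonstrate
correctness of the machinery and the qualitative behavior of the combination
strategies, not expected recovery rates on real expression data.

## Identifiability and the ten-gene test fixture

With constant external drives and x(0) = 1, randomly wired instances relax
toward steady state within a few hours, and monotone target profiles are
uninformative: any candidate can reproduce them by tuning the free constant
drive `e`, the amplitude `r0` and its own exponential transient through `d`.
Regulator identification requires non-monotone target dynamics whose shape
only the true regulators can supply — and mutually substitutable shapes in
the candidate pool (e.g. two oscillators a fraction of a period apart, or
several parallel monotone trends) re-create the degeneracy. The dedicated
identification fixture is built accordingly: the two oscillatory true
regulators themselves form a delayed negative-feedback pair (two distinct
phases), the remaining true regulators carry a lagged mixed waveform and a
slow pure decay, and every decoy gene sits exactly at steady state. On this
fixture a 2000-trial ensemble at a 0.006 acceptance threshold ranks all four
true edges (frequency 1.0) above every false edge (≤ 0.5).

## Problem sizes and numerical choices in the test suite

The suite runs at desk scale: DDE correctness on twenty random 10-gene
instances against a second-order fixed-step method-of-steps oracle
(dt = 10⁻³ h); parameter recovery on twenty single-target problems with ten
restarts each; the ten-gene identification fixture at 2000 trials; and the
two-experiment combination study at N = 20 with 150 trials per gene,
binomial selection at p < 0.01. The generator calibration check counts edges
in full 1000-gene topologies (topology only, no integration).

## Known limitations

- Recovery on randomly generated benchmark instances is modest by
  construction (weakly informative profiles, see above); the method's
  strength is ranking edges for well-perturbed, dynamic targets.
- The acceptance threshold is a normalized-RMSE heuristic; with noisy real
  data it would need recalibration against replicate variance.
- τ and n are not fitted; misspecifying them biases the recovered binding
  constants.
- The binomial null treats accepted subnetworks as independent draws from
  the candidate sampler, which overstates significance when the accepted
  ensemble is small or strongly clustered.
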