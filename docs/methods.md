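# Methods

## Model and metrics

A dataset is a non-negative matrix **X** ∈ ℝ≥0^{m×n} (rows = samples,
columns = features) with an exhaustive, mutually exclusive partition of the
rows into L groups; **X**ℓ denotes group ℓ's block and **W**ℓ the matching
rows of the loading matrix. All norms are Frobenius and *unsquared* unless
squared explicitly. Two metrics drive everything:

* relative reconstruction error: ‖**X**ℓ − **W**ℓ**H**‖ / ‖**X**ℓ‖;
* relative reconstruction loss: (‖**X**ℓ − **W**ℓ**H**‖ − E_ℓ) / ‖**X**ℓ‖.

E_ℓ is the *standalone baseline*: the expected achieved error of a
randomized rank-r NMF trained on **X**ℓ alone, estimated as the mean of T
independent multiplicative-update fits (uniform(0,1) initialization, the
same stopping rule as the main fits, seeds derived deterministically from a
master seed). T = 5 by default. Because E_ℓ averages a particular
randomized solver, it is an upper-bound-style reference: a shared model can
beat it, and the loss is then negative. Non-converged baseline runs are
averaged anyway and flagged. The fairness objective is
f(**W**, **H**) = max_ℓ loss_ℓ; ties in the argmax break toward the lowest
group index, deterministically.

Normalizing by ‖**X**ℓ‖ (not by group size) makes the loss insensitive to
group magnitude; subtracting E_ℓ makes it insensitive to intrinsic group
complexity — a group that is merely hard to reconstruct is not treated as
wronged, only one that is reconstructed worse than it would be on its own.

Before any fit, features (columns of the full matrix) are scaled to unit
Euclidean norm; all-zero columns are left unchanged. Column scaling
commutes with the row partition, so normalization precedes the group
split harmlessly.

## Alternating minimization

With **W** fixed, minimizing f over **H** ≥ 0 is the epigraph program

    min t   s.t.   ‖X_ℓ − W_ℓ H‖ ≤ t ‖X_ℓ‖ + E_ℓ  ∀ℓ,   H ≥ 0,

a second-order cone program. With **H** fixed, f under-determines **W**
(only the worst group's block is pinned), so **W** is chosen as the full
NNLS minimizer of ‖**X** − **WH**‖², which solves min ‖X_ℓ − W_ℓH‖ for
every group independently. The H-step cannot increase f by construction;
the W-step lowers every group's error simultaneously, hence also cannot
increase f — the f-trace is non-increasing up to solver tolerance, which
the suite checks at 1e−6.

Numerics:

* Each cone is compressed through a thin QR of **W**ℓ:
  ‖X_ℓ − W_ℓH‖² = ‖Q_ℓᵀX_ℓ − R_ℓH‖² + d_ℓ², reducing the cone dimension
  from m_ℓ·n + 1 to r·n + 2 regardless of group size.
* The primary solver is ECOS; on any non-optimal status the step is
  retried as a SciPy SLSQP epigraph solve warm-started at the incumbent
  **H**, and a step is rejected outright if it would worsen f by more than
  1e−12 (approximate solvers near convergence). The reported epigraph
  value t is recomputed from the returned (zero-clipped) **H**, so it
  agrees with the metric table by construction.
* Tiny negative entries returned by the conic solver (~1e−9) are clipped
  to 0.
* The NNLS kernel is a multi-right-hand-side block-principal-pivoting
  solver with a shared Gram matrix and grouping of columns by active-set
  pattern; it is validated against `scipy.optimize.nnls` per column at
  1e−8 and falls back to it for any column that fails to terminate.
* Initialization: **H** random uniform(0,1); **W** immediately set by the
  NNLS W-step, so the under-determination rule holds from iteration 0.

## Weighted multiplicative updates

f equals the maximum over simplex weights c of Σℓ cℓ·lossℓ. The scheme
alternates: pick the worst group ℓ* (the vertex maximizer), move c toward
that vertex with a decreasing step size — implemented in the equivalent
unnormalized form c ← c + e_{ℓ*}, since the H update is invariant to
positive rescaling of c — then update **H** by one standard multiplicative
sweep on the stacked surrogate ‖X̃ − W̃H‖² with blocks cℓ·Xℓ/‖Xℓ‖ and
cℓ·Wℓ/‖Xℓ‖, and each **W**ℓ by one multiplicative sweep on its own
unscaled block. The stacked surrogate replaces the weighted sum of
unsquared norms by a weighted sum of squares — a tractable proxy whose
optimum is within a bounded factor of the true weighted objective.

**Weight mixing.** Multiplicative updates make exact zeros absorbing. In
the first iterations the weight vector is a single vertex, and when groups
occupy orthogonal feature supports (as in the first benchmark) one stacked
H sweep would zero the unweighted group's dictionary columns *exactly*;
the group's loadings then zero out in the same iteration and no later
weight can resurrect either — the fit deadlocks with that group at loss
≈ 1. The stacked matrices are therefore built from c + (µ/L)·Σℓcℓ with
µ = 0.05: five percent of the weight mass spread uniformly. This is linear
in c (rescaling invariance is preserved exactly), leaves the multiplicative
form intact (zeros of **H** with interior weights are still preserved; the
L = 1 case still reduces exactly to the standard update), bounds the
per-sweep shrinkage of an unweighted group's columns so they remain
recoverable, and biases the surrogate weights by at most (µ/L)² relative
at convergence. µ = 0.05 was chosen as a small value that reliably
prevents the degenerate absorption; alternatives tried and rejected are a
positivity floor on the factors (both factors collapse together and the
coupled multiplicative dynamics cannot regrow them) and additive numerator
guards (regrowth works but is explosive).

**Exact-c mode** (`FitConfig(c_rule="exact")`) sets c = e_{ℓ*} every
iteration with *no* mixing — the literal vertex rule, kept as a
demonstration of why the decreasing step size matters. On the orthogonal
benchmark it deadlocks as described (final max-loss ≈ 1.0 versus ≈ 0.58
for the decreasing rule), and because the collapse is an absorbing state
the failure is nearly deterministic across seeds rather than oscillatory.

MU denominators carry a relative guard, eps × (largest denominator entry)
with eps = 1e−10, rather than an absolute constant: a relative guard scales
with the data, which is what makes the stacked update exactly invariant
under rescaling of c and the single-group reduction exact.

## Stopping

Both solvers iterate until, for every group, the change of its
reconstruction error within one iteration is below 1e−4 times its current
error. A group at exactly zero error counts as converged. On exactly
factorable data the ratio never settles, so an optional floor marks a group
converged once its relative error drops below 0.1%; the floor is enabled
automatically for the synthetic benchmarks and off for user data. Fits
that hit the iteration cap (default 500) return with `converged=False`
and full traces; they never raise. Standard NMF on an ungrouped matrix is
the L = 1 case of the same rule, so standard and fair fits share one
convergence criterion.

## Synthetic benchmarks

Each group block is **X**ℓ = **W**ℓ**H**ℓ with rows of **W**ℓ drawn
uniformly from the standard basis — every sample is a uniformly chosen
dictionary row, optionally plus Gaussian noise truncated at zero.

* Dataset 1 (complexity imbalance): two groups of 500 × 12; group 1 has
  the six singleton dictionary rows e1…e6, group 2 the three two-feature
  rows e7+e10, e8+e11, e9+e12. The groups are exactly orthogonal, the
  blocks have ranks 6 and 3, and the combined matrix is exactly rank 9
  (the sampled indicator loadings witness an exact non-negative
  factorization), which grounds the 0.1%-floor benchmark.
* Dataset 2 (subspace crowding): three rank-3 groups of 500 × 12; groups
  1 and 2 share one dictionary (group 2 perturbed by N(0, 0.1²) noise,
  truncated at zero), group 3 is orthogonal to both.

The generators are pure functions of their seed. They emulate exact
low-dimensional group structure with controlled overlap — they do not
emulate heavy-tailed feature scales, sparsity patterns of text data, or
correlated noise, so passing benchmarks here demonstrates the solvers'
behavior under clean group structure, not performance on any particular
real dataset.

## Experiment protocol

A sweep runs every (method, rank, trial) cell: per (rank, trial) the
baselines are re-estimated from a derived seed and every method starts
from one shared derived initialization seed, so method comparisons are
paired. Derived seeds depend only on (master seed, rank, trial) — never on
the method list — so adding a method never changes existing cells. Tables
report errors both as fractions and percent; aggregation is mean ± sample
standard deviation over trials (10 by default). Failed fits are recorded
per cell and excluded from aggregates, with a non-zero exit from the CLI.

The benchmark script reports the rank-9 maximum per-group relative error
over 16 multiplicative restarts (plus 10 alternating-NNLS restarts if none
reaches the floor), taking the best. Restarts are integral to the
measurement: random-initialization NMF lands in topic-allocation local
minima on this dataset roughly two-thirds of the time, and the quantity of
interest is the reconstructability of the data at rank 9, not the
trapping frequency.

## Limitations

* Group membership must be known a priori and forms a hard partition.
* The loss uses unsquared norms throughout; squared-loss conventions from
  related dimensionality-reduction fairness work are not interchangeable.
* E_ℓ inherits the bias of its randomized estimator; with small T the
  loss zero-point is noisy, and negative losses partly reflect estimator
  variance.
* The alternating solver's per-iteration cost (one SOCP + one NNLS) grows
  quickly with m·n; the multiplicative scheme is the practical choice for
  large matrices.
* Dense matrices only; no missing values; features must be non-negative
  reals (integer-coded categoricals are accepted as-is, not encoded).
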