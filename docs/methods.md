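# Methods

## Model

Brain activity is coarse-grained into a finite state space `{1..k}` and
modeled as a first-order Markov chain. The baseline ("uncontrolled")
dynamics is the resting-state kernel `Q_{j|i}`; every condition, rest
included, additionally contributes a marginal state distribution. The cost
of a transition from distribution `π` to distribution `π′` over horizon `T`
is the minimum KL divergence of any controlled path law from the baseline
path law, subject to the endpoint constraints `p(X_0) = π`, `p(X_T) = π′`.

Two exact reductions shape the implementation:

1. **Endpoint reduction.** The path KL decomposes as
   `D_KL(p‖q) = D_KL(P‖Q) + E_P[D_KL(p(interior|ends) ‖ q(interior|ends))]`.
   The second term is minimized to zero by adopting the baseline bridge in
   the interior, so only the endpoint coupling `P` is optimized. For `T > 1`
   the uncontrolled endpoint joint uses the `T`-step kernel (matrix power);
   nothing else changes.
2. **Entropy-regularized OT form.** With cost matrix `C_ij = −log Q_ij`,
   `D_KL(P‖Q) = ⟨C, P⟩ − H(P)`. The problem is strongly convex with a unique
   optimum of Gibbs form `P*_ij = e^{α_i+β_j} Q_ij`.

## Solver

The multipliers are found by alternating updates

```
α_i = log π_i  − logsumexp_j(β_j + log Q_ij)
β_j = log π′_j − logsumexp_i(α_i + log Q_ij)
```

i.e. Sinkhorn iteration in the log domain, which is immune to underflow
when `Q` has very small entries. The normalization constant is a gauge
freedom shared between `α`, `β`; we fold it into `α`, so `P* = e^{α⊕β} ∘ Q`
holds with no separate constant. Convergence is declared when the maximum
absolute marginal residual of the candidate coupling falls below `tol`
(default 1e-10); the iteration budget is 1e5 sweeps, and exceeding it
raises an error carrying the last residual rather than returning a
half-converged answer. The solver is fully deterministic.

Numerical conventions:

- natural log everywhere; costs in nats, with a bits conversion on the
  solution object;
- `0·log 0 = 0`; mass of `P` outside the support of `Q` is a named
  infeasibility error, never a silent `inf`;
- zeros of `Q` are preserved exactly in `P*` (no epsilon smoothing by
  default). An explicit `smoothing=λ` option mixes `Q` with the uniform
  joint for callers who want to regularize empirical zeros — off by
  default because it changes the reported cost;
- infeasible marginals (target mass on states with zero column mass in `Q`)
  are detected up front and reported with the offending state indices.
  Support patterns that defeat the marginals in subtler (Hall-condition)
  ways surface as non-convergence with the residual attached;
- a `−∞ − (−∞)` corner (a zero-probability state on a zero row) is pinned
  to `−∞` so the iteration never propagates NaN;
- state indices are 0-based internally; serialized reports use 1-based
  labels.

The full controlled path is reconstructed from `P*` by backward recursion:
`h_t(s) = Σ_j (kernel^{T−t})_{s,j} e^{β_j}` (computed in the log domain)
gives time-inhomogeneous step kernels
`K_t(s,s′) = kernel(s,s′) h_{t+1}(s′)/h_t(s)`. Rows with `h_t(s) = 0`
(states the controlled path never visits at time `t`) keep the baseline
row so every kernel stays row-stochastic.

## Estimation and bootstrap

Transition pairs are consecutive-frame pairs pooled over subjects within
the baseline condition; pairs never span a subject boundary. One bootstrap
replicate draws `n` pairs uniformly with replacement (default `n` = number
of available pairs — the natural resampling count given that a
concatenated series of `L` frames over `S` subjects yields `L − S` valid
pairs), bins them into a joint, and row-normalizes to a kernel.
Distributions are resampled the same way over single frames. Within one
replicate the kernel and every condition distribution come from
independent child streams of one replicate seed (spawned from the master
seed via `numpy` SeedSequence), which keeps replicates exchangeable and
the whole ensemble bitwise reproducible from the master seed. A replicate
whose resampled quantities are infeasible (e.g. a state never observed as
a source) is recorded with a named status and excluded from mean/SD, never
silently dropped. Default replicate count: 100.

The pooled `bootstrap_cost_table` resamples each quantity once per
replicate and reuses it across all ordered condition pairs, so
per-replicate tables are internally consistent.

Significance between two replicate ensembles uses the pooled-variance
two-sample t statistic with `df = n_a + n_b − 2` (100 + 100 replicates give
df = 198). Bootstrap replicates are not independent samples, so these
tests are anti-conservative; the result object carries that caveat and
reports the number of comparisons (no multiple-testing correction is
applied).

## Coarse-graining

Cosine k-means is realized as spherical k-means: frames and centroids are
unit-normalized and assignment is by maximum dot product, equivalently
minimum squared chordal distance `‖x − c‖² = 2 − 2cos`. Initialization is
k-means++ seeding on the sphere; 10 restarts by default, best objective
kept; an emptied cluster is reseeded at the worst-fit frame. Ties in
assignment break to the lowest state index, and the final assignment is
recomputed against the final centroids so the model invariant holds
exactly.

Explained variance is `1 − within/total` dispersion under squared chordal
distance, with total dispersion measured about the normalized mean
direction (the `k = 1` solution), which pins the value to 0 at `k = 1` and
1 when every frame has its own centroid. Two diagnostics guide `k`: the
explained-variance curve (plateaus at the true number of directional
clusters) and the occupancy check (flags subject × condition sessions
missing any state — the criterion that caps `k`). Frames are used as given;
no internal z-scoring. `balance_frames` truncates every condition to the
minimum available count, keeping first frames, so unequal session lengths
cannot bias the clustering.

## Synthetic generator

The generator emulates the shape of a multi-subject study while staying
desk-sized: default 40 subjects × 180 frames per condition (k = 8,
25 channels), giving ~7 000 within-subject rest transition pairs — enough
for the bootstrap to be informative without making tests slow. The rest
condition is a Markov chain from the true kernel started at stationarity;
task conditions are i.i.d. draws from tilt distributions. Task conditions
carry no planted temporal structure because nothing downstream uses task
dynamics — only marginals. Activity places one orthogonal unit direction
per state (requires channels ≥ k) plus isotropic Gaussian noise with
per-channel SD `1/concentration`; the default concentration 6 yields
well-separated but noisy clusters (~99.9% recoverable).

`make_planted_hierarchy` draws candidate ergodic kernels (Dirichlet rows
with diagonal persistence 0.45) from deterministic child streams of the
master seed and keeps the first whose induced rest/easy/hard system
satisfies, exactly and with margin, the strict cost ordering from rest,
the easy↔hard asymmetry, and full ordering consistency — all computed with
the bridge solver on the true kernel. The easy (weight 0.25) and hard
(weight 0.60) conditions tilt the stationary law toward its rarest states,
which is what makes reaching them costly and makes returning cheap. The
true costs ship with the spec as oracle values.

What passing synthetic tests does **not** show: real recordings have
autocorrelated, non-spherical noise, states are not exactly orthogonal
directions, task dynamics are not i.i.d., and the true `k` is unknown.
The synthetic results certify the correctness of the machinery, not the
neuroscience.

## Design choices on genuinely open points

- **Log base**: natural log (nats), matching the stochastic-thermodynamics
  convention; bits offered as a view.
- **Bootstrap draw count**: the number of available items (pairs or
  frames), resolving the `L` vs `L − 1` ambiguity in favor of "resample as
  many as you have".
- **Replicate coupling**: kernel and marginals resampled independently
  within a replicate (independent child streams), since any joint coupling
  convention would be arbitrary.
- **t-test variant**: pooled-variance Student form (df = 198 with
  100 + 100 replicates implies the pooled form, and replicate ensembles
  share the resampling design, so equal variances are plausible).
- **Ordering-consistency ties**: pairs with exactly equal baseline costs
  contribute no pair rather than counting as satisfied.

## Known limitations

- The bridge cost is a lower bound on any physical control cost; it has no
  explicit control-input model.
- Bootstrap-based t statistics overstate evidence (see above).
- Sinkhorn converges slowly when the target puts mass on states that are
  nearly unreachable (tiny `Q` column mass); the iteration budget and
  residual reporting make this visible rather than fatal.
- `explained_variance` is defined under chordal distance on the sphere;
  other software may report Euclidean variance ratios that differ in level
  (though not in plateau location) on the same data.
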