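# Methods

This note records the models, algorithms, numerical choices and known
limitations behind chordwalk, in enough detail that results can be reasoned
about without reading the source.

## The sampling problem

The target is a probability density known up to a constant through a
log-density `f`, supported on a bounded convex polytope in half-space form,
`P = {θ ∈ Rⁿ : A·θ ≤ b}` with one constraint per row of `A`.  Boundedness and
a nonempty interior are assumed *after preprocessing* and are certified by
the Chebyshev LP (below); integrability of `exp f` over `P` is the user's
responsibility and is not checked.  `f` may return `−∞` (zero density); `NaN`
is always treated as a bug and raised with the offending point.

All shipped kernels are chord samplers: from the current point a direction
`d` is drawn, the feasible interval `[λ_min, λ_max]` of `θ + λ·d` is computed
exactly from the constraint slacks (one division per constraint row), and the
candidate is a point on that segment.  Candidates therefore satisfy the
support by construction; the engine nevertheless re-checks membership at
tolerance 1e-9 and rejects violators without evaluating the model.

## Geometry and preprocessing

**Strict interior.**  Chord computation and chain starts require slack
`b_i − a_i·θ ≥ 1e-12·(1 + |b_i|)` on every row.  The relative margin avoids
zero-length chords for points that sit on the boundary to rounding error.

**Feasibility / Chebyshev center.**  The largest inscribed ball is found by
the standard LP (maximize `r` s.t. `a_i·x + r‖a_i‖ ≤ b_i`, `r ≥ 0`, solved
with HiGHS).  Infeasibility of this LP *is* the emptiness certificate;
unboundedness of the LP certifies an unbounded polytope; radius 0 flags a
degenerate (flat) feasible set.

**Redundancy removal.**  Exact duplicates are removed first (rows compared
after normalizing by their Euclidean norm, keys rounded to 12 decimals) —
necessary because the LP test below cannot distinguish a duplicate from the
row it duplicates.  Then each remaining row `i` is tested by maximizing
`a_i·x` over the other retained rows (capped by `b_i + 1` so the test LP is
never unbounded) and dropped iff the optimum stays below `b_i − tol`,
default `tol = 1e-9` (above LP solver tolerance, below meaningful constraint
differences).  The sweep is sequential, so of two mutually redundant rows
exactly one survives, and the operation is idempotent.

**Equality embedding.**  An equality system `S·θ = c` is eliminated by
restriction to its affine solution set: a least-squares particular solution
`x₀` (consistency required to `1e-8·(1+‖c‖∞)`), an orthonormal null-space
basis `N` (SVD with the standard numerical-rank threshold
`max(m,n)·ε·σ_max`), and the reduced polytope `{z : (A N) z ≤ b − A x₀}`.
Rows annihilated by the projection are constants: dropped if satisfied,
infeasibility otherwise.  The change of variables is carried by a
`TransformRecord(basis, shift)` with `full = basis·reduced + shift`; records
compose, so equality embedding followed by rounding is a single affine map.

**Standard polytopes.**  The simplex factory returns the full-dimensional
form `{θ ≥ 0, Σθ ≤ 1}` by default; a flag emits the probability-simplex form
(`Σθ = 1` plus nonnegativity on n+1 coordinates) for use with the embedding.
The Birkhoff factory builds the n² nonnegativity rows and the 2n row/column
sums (rank 2n−1) and embeds them, giving the intrinsic dimension (n−1)².

## Rounding

An anisotropic support makes isotropic directions useless: almost every
chord is clipped by the thin directions.  Rounding finds an invertible
affine reparametrization under which `P` is near-isotropic.  Two methods sit
behind one interface:

- **ellipsoid** (deterministic, default): iterate {translate the analytic
  center to the origin; rescale by `H^{−1/2}` where
  `H = Σ a_i a_iᵀ / s_i²` is the slack-weighted constraint Gram matrix}.
  `H` is the shape of the Dikin ellipsoid, which is inscribed in `P` at any
  interior point, so each step is safe.  The analytic center (damped Newton
  on `−Σ log s_i`, started at the Chebyshev center) is used as the
  evaluation point because the Chebyshev center can be non-unique (any point
  on the optimal face of the LP), which makes the weights lopsided for
  box-like bodies.
- **covariance_svd** (stochastic): alternate short uniform
  coordinate-hit-and-run pre-sampling (50·n steps per pass) with an
  eigendecomposition `U Σ Uᵀ` of the sample covariance (regularized by
  `1e-12·tr/n` on the diagonal), composing the transform with `U Σ^{1/2}`,
  until the covariance condition number changes by less than `tol = 0.05`
  between passes.  Adaptation error is harmless because rounding only
  reparametrizes; it never changes the point set.

Both methods finish by translating the Chebyshev center to the origin and
scaling so the rounded polytope contains a unit ball there.  Iteration stops
early when the quality proxy — inscribed radius over the maximum axis
half-chord through the center — reaches 0.2 (an engineering default).  The
proxy is measured *after* a Dikin step because axis chords are blind to
rotated elongation on the raw body.

## Proposal kernels

All kernels satisfy one contract: `state` (never mutated by `propose`),
`propose(rng) → candidate`, `log_acceptance_correction()` (log ratio of
reverse to forward proposal densities, 0 when symmetric), an optional
`step_size` marking tunability, and `move_to` called by the engine on
acceptance.  Directions shorter than 1e-300 are redrawn.

- **hit_and_run_uniform** — sphere-uniform direction, chord-uniform `λ`.
  The chord through x and x′ is the same segment seen from both ends, so the
  draw is its own reverse and the correction is 0 for *any* target
  (hit-and-run within Metropolis: the acceptance ratio is the density
  ratio).
- **coordinate_hit_and_run** — direction is a uniformly chosen axis;
  with rounding and engine thinning this is the CHRRT scheme.
- **gaussian_hit_and_run** — `λ ~ N(0, s²)` truncated to the chord by
  rejection (≤ 100 tries, then the kernel proposes to stay and counts the
  event).  This kernel is *not* symmetric: the truncation normalizer
  `Z(y) = Φ(hi_y/s) − Φ(lo_y/s)` differs along the chord, and ignoring it
  measurably under-disperses draws near the boundary (on the unit hypercube
  the uniform variance came out several standard errors low).  The exact
  correction `log Z(x) − log Z(x′)` is therefore computed per proposal; the
  normal kernel itself cancels by evenness.  Default step size is the
  inscribed-ball radius of the support (scale-aware).
- **over_relaxed_hit_and_run** — deterministic reflection through the chord
  midpoint, `λ′ = λ_min + λ_max`.  Self-inverse with unit Jacobian, so the
  uniform law is preserved; construction against a non-uniform model raises,
  since the move is only valid for flat targets.  The antithetic effect is
  exact in one dimension (lag-1 autocorrelation −1); in higher dimension
  only the projection on the drawn direction is reflected, so the
  per-coordinate antithetic signal dilutes and can change sign, while the
  invariant law remains correct.
- **adaptive_svd** — maintains a running mean/covariance (Welford) of
  visited states; every `update_interval` (default 100) steps, while fewer
  than `adaptation_horizon` (default 2000) steps have been taken, recomputes
  `U Σ^{1/2}` of the regularized covariance and draws directions as
  normalized `U Σ^{1/2} z`.  After the horizon the shape is frozen, making
  the kernel a fixed, valid hit-and-run; finite adaptation was chosen over
  diminishing-adaptation schedules because correctness after the freeze is
  verifiable.  With fewer than two observations the shape falls back to the
  identity.  The engine reports the freeze point as burn-in
  (`meta['burn_in_draws']`) and only discards it on request — transparency
  over convenience.

## Engine

The Metropolis filter accepts with
`log α = min(0, (f(θ′) − f(θ))/T + correction)`; `T` is the chain
temperature (1 for ordinary sampling).  Chains cache the untempered
log-density of their position.  Randomness comes from numpy's PCG64 (64-bit
permuted congruential generator, 128-bit state, period 2¹²⁸); chain `c` of a
run uses the stream spawned as `SeedSequence(seed, spawn_key=(c,))`, so
results are a function of `(seed, stream)` alone, independent of scheduling.
Default starts are the Chebyshev center jittered uniformly within 0.1× the
inscribed ball, per chain.  Recorded draws are mapped to original
coordinates through the problem's transform; every recorded state took
`thinning` transitions.

**Tuning** is Robbins–Monro on the log step size: after each batch of 100
steps, `log s ← log s + γ_k (rate − target)` with `γ_k = 2/(k+1)`; default
target rate 0.234.

**Parallel tempering** runs one chain per temperature targeting `f/T_k` on
the *same* polytope — the support is never tempered, so the hottest chain
tends to uniform-on-P rather than escaping it.  The ladder must start at 1
and be non-decreasing (equal temperatures are allowed; they make swaps
certain, a useful degenerate check).  Every `swap_interval` sweeps, adjacent
pairs — alternating even/odd pairings — propose an exchange accepted with
`log α = (1/T_i − 1/T_j)(f(θ_j) − f(θ_i))`, drawn from a dedicated swap
stream.  Cold-chain draws and per-pair swap rates are returned.  Geometric
ladders (e.g. 1, 4, 16, 64) are a sensible default for well-separated
Gaussian modes.

**Checkpointing** serializes position, cached log-density, kernel internals,
RNG state, counters and temperature into a blob with a magic header, schema
tag and SHA-256 checksum.  The model itself is *not* serialized (user
log-densities may be unpicklable closures); restore takes the problem,
re-evaluates the log-density and rejects a stale cache at 1e-12.  A resumed
chain reproduces the uninterrupted draw stream bit-for-bit.

## Diagnostics

Classic split-R̂ (not rank-normalized, which is noted as a possible
extension): each chain is halved, `W` is the mean within-half variance, `B`
the between-half variance of means scaled by the half-length, and
`R̂ = sqrt(((N−1)/N·W + B/N)/W)`.  Constant chains make the statistic
undefined; NaN plus a warning is returned rather than a crash.

ESS: autocorrelations are computed per chain by FFT on centered draws and
averaged across chains; Geyer's initial positive sequence truncates the sum
(adjacent pairs `ρ_{2m} + ρ_{2m+1}` accumulated while positive), and
`ESS = C·N/τ`, capped at `C·N`.  Constant dimensions report ESS 1 with a
degeneracy flag.  Against the AR(1) closed form `N(1−ρ)/(1+ρ)` at ρ = 0.9
the estimator is accurate to a few percent at N = 10⁵.

## Synthetic fixtures and what they do (not) show

The fixture generator emulates the *geometry* of real applications at desk
scale: boxes, simplices, Birkhoff polytopes, randomly cut bounded polytopes,
a rotated anisotropic box (30° rotation by default — axis-aligned anisotropy
is free for coordinate walks, so the rotation is what makes the fixture
hard), and a bimodal Gaussian on the unit square (modes at (0.2, 0.2) and
(0.8, 0.8), sd 0.03, equal weights).  Manifests record analytic ground truth
(uniform moments, dimensions, Chebyshev data) and are re-verified against
the library at generation time.

What passing on these fixtures does *not* show: behavior at the dimensions
of genome-scale metabolic models (hundreds to thousands), targets whose
evaluation dominates runtime (simulator-backed posteriors), or severely
ill-conditioned constraint systems from real stoichiometries.  The fixtures
validate correctness of the law and the relative ordering of kernels, not
absolute performance at scale.

## Problem sizes used in the shipped checks

Moment recovery uses 2·10⁴ draws per kernel; the binned stationarity oracle
uses 10⁶ transitions of the 1-D chain with 50 bins; tempering uses 2·10⁴
sweeps of a 4-temperature ladder against a single chain at 8·10⁴ steps
(matched model evaluations); the rounding comparison uses 10⁴ transitions on
the rotated box.  These sizes give standard errors comfortably inside the
assertion bands while keeping a full run in the minutes range on one core.

## Known limitations

- Rounding is approximate: the Dikin-based method needs a few iterations on
  strongly skewed bodies, and no maximum-volume-ellipsoid optimality is
  claimed.
- The curvature slot of the model contract is validated but unused: no
  shipped kernel is Riemannian.
- Over-relaxation is restricted to uniform targets by construction.
- V-representations, vertex enumeration, volume computation and exact
  rational arithmetic are out of scope.
- Chains execute serially; determinism is defined over RNG streams, so a
  parallel driver could be added without changing results.
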