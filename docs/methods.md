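# Methods

## Data model

A dataset couples an N×K matrix of serum concentrations (μg/mL, one
column per chemical component, one row per sampling time) with one or
more length-N pharmacodynamic (PD) vectors.  The bundled tables for
Moutan Cortex (`mc_training.csv`) and its charcoal (`mcc_training.csv`)
have N = 12 rows (0.08–12 h) and K = 10 components, with endpoints TXB2
and 6-keto-PGF1α.  PD values are percentages normalized against the
disease-model and blank-control animals,
(C_treated − C_model)/(C_model − C_black) × 100, so they are
dimensionless, of order 1, and may be negative.  Values are stored
exactly as printed (two decimals); the raw control concentrations
behind the normalization are not available, so the normalization
function is provided but the fixtures are not re-derived.  The charcoal
table's oxpaeoniflorin column is identically zero — the constituent is
destroyed by charring — and serves as the canonical zero-variance case.

## ε-SVR with Gaussian kernel

The regression function is the kernel expansion
f(x) = Σ β_i K(x_i, x) + b with K(x, x′) = exp(−‖x−x′‖²/(2σ²)).
σ is a kernel *width* (length scale), not the γ = 1/(2σ²) rate used by
some libraries; `sigma_to_gamma`/`gamma_to_sigma` convert.  Training
minimizes the dual

    ½ βᵀKβ − yᵀβ + ε Σ|β_i|,   Σβ_i = 0,  |β_i| ≤ c,

where β_i collapses the usual (α_i, α_i*) pair.  Residuals inside the
ε tube are free; c bounds each coefficient.

Solver: pairwise coordinate descent.  A step along e_i − e_j preserves
the equality constraint; the one-dimensional objective is piecewise
quadratic (kinks where β_i or β_j crosses zero), and the exact minimizer
over the feasible interval is found by evaluating each segment.  Sweeps
over all pairs repeat until no pair improves the objective by more than
a gain tolerance scaled to c·max|y| (≈1e−13 relative).  Because the
feasible directions of this polytope are spanned by the pair moves,
pairwise stationarity implies global optimality of this convex problem.
A finishing Newton step then solves the KKT linear system on the
identified free set exactly (kept only if it respects the
classification and does not worsen the objective); this removes the
slow tail of coordinate descent and makes the solution agree with a
dense QP solve to machine precision on small problems.  The inner loop
is compiled with numba.

The offset b is the mean of the KKT-exact values over free support
vectors (residual on the tube edge); with no free vector, the midpoint
of the feasible interval implied by the bound/inactive constraints.
Support vectors are the β_i ≠ 0 rows; a table of identical rows is
flagged `degenerate` and yields a constant predictor.

Feature scaling: component columns are standardized (zero mean, unit
variance on the training rows) by default, because raw concentrations
span ~0.17–455 μg/mL and unscaled RBF distances would be dominated by
the largest columns.  Zero-variance columns get scale 1 and a flag.
Predictions are invariant to affine rescaling of raw inputs when the
scaler is refit.  `scale=False` trains in raw units; this matters for
reproducing previously published hyperparameters, whose σ values
(9.9–88.9) are raw-space length scales — standardized distances on
these tables are O(1–10), so those widths only make sense unscaled (see
"Reproduction notes").

ε defaults to 0.1 (a common solver default; the source analysis does
not state its value) and is exposed everywhere; the acceptance sweep
covers {0.01, 0.05, 0.1}.

## Hyperparameter search

Canonical global-best PSO over (c, σ):
v ← w·v + a·r₁·(pbest − x) + a·r₂·(gbest − x), positions clipped to the
box, velocities clamped to 20% of each dimension's range.  Defaults
follow the study conditions: 20 particles, 200 iterations, search box
[0, 100]² (floored at 1e−3 so the kernel and box constraint stay
defined), shared acceleration a = 1.5.  No inertia schedule was stated;
the common linear 0.9 → 0.4 ramp is used and is configurable.  One seed
drives initialization and every random draw, so runs are exactly
reproducible; known-good points can be injected into the initial swarm,
which guarantees the result is at least as good as any injected point.

The fitness of a candidate (c, σ) is the mean squared residual of the
SVR it induces.  The default scheme evaluates on the training rows
(mirroring a fitness summed over the data set); with 10-12 rows this
rewards interpolation, so a 3-fold cross-validation scheme is available
(`scheme="cv3"`).  The exact published cost form (MSE vs RMSE vs sum)
is not recoverable; these are monotone-equivalent for the search, and
MSE is used.  The fast path precomputes the scaled squared-distance
matrix once and re-exponentiates per σ probe (~0.1 ms per candidate),
so a full swarm run costs a fraction of a second.

## Sensitivity / contribution analysis

The gradient of the expansion is analytic:
∂f/∂x_k = Σ_i β_i K(x, x_i)(x_ik − x_k)/σ².  The per-feature weight is
the signed mean of this gradient over all 12 rows of the herb's table;
an absolute-mean variant exists for magnitude ranking, and the signed
mean is what determines reported directions.  Contributions rescale the
signed weights by a positive normalizer — none, L1 (Σ|contribution| = 1,
the default) or max — so the sign pattern is normalization-invariant.
Gradients are taken in standardized space by default (comparability
across 100-fold concentration scales); raw-space values follow by the
chain rule (divide by the feature scale).  Zero-variance components are
pinned to exactly zero.  Contributions are model sensitivities, not
causal claims.

## Synthetic data

Each component follows a Bateman curve A(e^{−k_e t} − e^{−k_a t}) on
the fixtures' 12-point time grid: non-negative, single peak, the shape
of first-order absorption/elimination.  Amplitudes are log-uniform over
~3–320 (two orders of magnitude, like the real tables).  Rates are
log-uniform — k_e ∈ [0.04, 1.2] h⁻¹, k_a/k_e ∈ [3, 100] — so peak times
span roughly 0.1–6 h, matching the kinetic diversity of the measured
tables; with narrower rate ranges all columns peak together and become
nearly collinear, which the real data is not.  The PD response is
Σ_k size_k·sign_k·g(z_tk) + noise with z the standardized columns, g
the identity or the saturating z/(1+|z|), noise SD 0.2 (PD values span
roughly −0.8–4), effect size 1.0.  Two active components per endpoint
by default, mirroring the domain expectation that a couple of dominant
effective substances drive each marker.  A charcoal-like preset zeroes
one component's dose to exercise the zero-variance path.  Everything is
reproducible from the ground-truth seed.

What the generator does *not* emulate: measurement noise on the
concentrations (columns are smooth and exactly unimodal, hence more
mutually correlated than real noisy columns), multi-compartment
kinetics, and any mechanistic concentration–effect dynamics (effect
compartments, hysteresis).  Passing sign-recovery tests therefore shows
the attribution machinery works when the data-generating process
matches the model's additive assumptions at realistic size/noise — not
that the real tables satisfy those assumptions.

For attribution studies on these 12-row tables the package uses a
smooth model (c = 30, σ = 10 in standardized space — the near-linear
kernel regime): with 10 features on 12 rows, flexible fits attribute
noise.  Under the default conditions this recovers all active signs in
≥90% of seeded replicates (checked across disjoint seed ranges).
Inert components stay below the largest active contribution in ~85–90%
of component–seed pairs; the remainder is structural — an inert curve
strongly correlated with an active one absorbs part of its sensitivity,
which no per-feature gradient method can fully avoid at this sample
size.

## Evaluation protocol

APE = |obs − pred|/|obs| × 100 per sample; MAPE is its mean; RMSE is in
PD percent units.  Observations with |obs| < 0.05 are excluded from
percentage metrics with a warning (the MC TXB2 series contains −0.02),
since APE diverges at zero; RMSE always uses all rows.  The split
protocol draws round(N/6) ≥ 1 rows (2 of 12) at random as a held-out
test set.  Because the source analysis tested on samples drawn from the
full table (overlapping training) while describing a 5:1 split, every
evaluation here is reported under both labels: `held-out` (the 2 unseen
rows) and `in-sample` (all 12 rows).  The two differ by an order of
magnitude on these tables, which is exactly why both are shown.

## Reproduction notes

With the shipped reference (c, σ) pairs, raw-space training at
ε = 0.01 reproduces the published error magnitudes in-sample
(RMSE ≈ 0.010 vs published 0.029–0.042; MAPE ≈ 3.5% vs 5.31%), while
standardized-space training at those same widths under-fits badly —
the basis for reading the published σ as raw-space widths.  Genuinely
held-out APE after a full PSO search is far above the published 9%
bound (median over 20 replicates ≈ 250%): with two unseen rows from a
12-point noisy series, percentage errors of a few percent are not
reachable, and the published figure is consistent only with test
samples that overlap the training data.  The acceptance script reports
this quantity honestly from the held-out protocol.  Published
contribution *sign* patterns are reproduced only partially (~22/40
signs; the hemostatic signature of the charcoal — gallic acid and
5-HMF positive to TXB2, negative to 6-keto-PGF1α — does reproduce in
raw space); the exact normalization, scaling and tube width behind the
published table are not recoverable, so signs are treated as a
best-effort surface, with the zero-variance rule (oxpaeoniflorin ≡ 0)
the only hard requirement.

## Numerical choices

- KKT slack for classifying multipliers: 1e−6 (box/equality hold to
  ~1e−8 after polish); support vectors are |β| > 1e−8·max(1, c).
- SMO gain tolerance 1e−13·c·max|y|; sweep cap 5000 (never reached on
  these problem sizes).
- Gram diagonals are set to exactly 1; squared distances are clipped at
  0 before exponentiation.
- Degenerate (all-identical-row) designs return the flagged constant
  model rather than an error.
- PSO lower bound 1e−3, velocity clamp 0.2×range, inertia 0.9 → 0.4.
- Fitness of a failed fit is +inf (the particle is repelled), logged.
- Problem sizes in the test and acceptance runs are the study's own:
  12-row tables, 20-particle/200-iteration swarms, 20 seeded
  replicates.

## Known limitations

- N = 12 rows bounds everything: held-out error estimates have two
  points, attribution is regularization-dependent, and the PSO's
  training-set fitness overfits by construction (use `cv3` to temper).
- One model per endpoint; no shared multi-output structure.
- Only the Gaussian kernel and ε-insensitive loss are implemented.
- Contributions are global averaged sensitivities; time-resolved or
  interaction effects are out of scope.
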