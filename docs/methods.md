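# Methods

`lapdyn` learns the dynamics of spatially distributed neurodegeneration
biomarkers — amyloid-β (A), tau (τ), neurodegeneration (N), and a scalar
cognitive score (C) — directly from sparse longitudinal observations on a
brain geometry, and uses the learned model for per-patient forecasting and
in-silico treatment optimization.  This note records the model, the
numerical choices, the synthetic data model, and the limitations a user
should know about.

## Model

On a domain Ω (a triangulated 2D geometry or a weighted region-by-region
connectivity graph) each biomarker field obeys an unknown
reaction–diffusion law

    ∂A/∂t − α_A Δ A = F₁(A),
    ∂τ/∂t − α_τ Δ τ = F₂(A, τ),
    ∂N/∂t − α_N Δ N = F₃(A, τ, N),
    dC/dt           = F₄(N),

with no-flux boundary conditions.  Δ is the Laplace–Beltrami operator on
meshes (discretized with P1 finite elements) and the negative combinatorial
graph Laplacian −L = −(D − W) on graphs.  The nesting of arguments encodes
the amyloid-cascade ordering (amyloid drives tau drives neurodegeneration
drives cognitive decline), and the operators are trained strictly in that
sequence: F₁ from A data alone, then F₂ with A supplied as an observed
input, then F₃, then F₄.

All fields are represented in the basis of the lowest `P` Laplacian
eigenfunctions φ_i (generalized eigenpairs `K φ = λ M φ` on meshes,
`L φ = λ φ` on graphs; M-orthonormal, ascending eigenvalues, sign fixed by
making the largest-magnitude component positive).  Projection is
`β_i = φ_iᵀ M u` (Euclidean on graphs).  The default is `P = 48` modes for
a 68-region graph; on meshes `P` is a user choice.

Time stepping is semi-implicit: over a substep of length `dt`,

    (β − β_prev)/dt + α Λ β = G(x_prev; θ),

solved in closed form per mode because Λ = diag(λ_i).  `G` is the learned
spectral reaction operator and `x` stacks the coefficients of the
variable's inputs; the diffusion coefficient α ≥ 0 is learnable through a
softplus parameterization.  Visits are irregularly spaced; every interval
uses its own `Δt`, subdivided into uniform substeps of at most 0.1 year.

### Operator parameterization

Two parameterizations of `G` are provided:

* **nodal** (default): `G(β) = Φᵀ M f(u₁, …, u_v)` with `u_j = Φ β_j` the
  nodal reconstructions and `f` a small network (two tanh layers of width
  16) applied *at every node with shared weights*.  Reactions in
  reaction–diffusion systems are local, and this weight tying is the
  corresponding inductive bias.  It is decisive in the data-poor regime:
  with cohorts of 20 patients a dense spectral network memorizes the
  training trajectories (held-out-patient forecast accuracy plateaus near
  0.85 regardless of training length), while the node-shared operator
  generalizes to unseen patients (≈ 0.95–0.97).
* **dense**: an unconstrained tanh MLP on the stacked spectral
  coefficients (two hidden layers, width `2P` by default).  Required when
  the reaction is nonlocal — for example a prescribed spectral-diagonal
  linear map — and appropriate when much more data is available.

The cognitive rate `F₄` uses the analogous permutation-invariant read-out
`h(meanᵢ g(u_N,i))` ("pooled"): a shared per-node feature map followed by
mean pooling and a small head.  Aggregate functionals of a field are
exactly of this form.  A dense variant exists for completeness.

All networks standardize their inputs (per-dimension mean/spread from the
training data, floored so near-constant dimensions are not amplified) and
scale their outputs by the RMS data velocity; these affine wrappers are
frozen, not trained.

### Training loss

For each variable the loss combines, with unit weights,

* a **trajectory-fit term**: the scheme is rolled from each patient's
  first visit across all training visits (upstream variables linearly
  interpolated between their observed values) and the relative L2 mismatch
  `‖β̃ⁿ − βⁿ‖/‖βⁿ‖` is averaged over visits and patients;
* a **residual term**: the discrete residual
  `Rⁿ = (βⁿ − βⁿ⁻¹)/Δt + αΛβⁿ` of the observed data over each interval is
  matched by the operator, `‖Rⁿ − Ḡ‖/‖Rⁿ‖`, where by default
  `Ḡ = (G(xⁿ⁻¹) + G(xⁿ))/2` (trapezoid form).  The secant over a 1–2 year
  visit gap approximates the *mean* derivative over the interval, which
  the two-endpoint average matches to second order; it also supervises the
  operator at each patient's most advanced state — exactly where forecasts
  launch.  The one-sided form `Ḡ = G(xⁿ⁻¹)` is available
  (`residual_form="left"`) and is what the standalone `residual_loss`
  operation computes.

Gradients are exact reverse-mode sweeps through the rollout, hand-written
on numpy arrays (no autodiff framework is used anywhere).  Three numerical
conventions matter:

* The `1/‖Rⁿ‖` normalization of the residual term is treated as a frozen
  weight — no gradient flows through the denominator.  Letting the
  optimizer inflate `‖R‖` (for instance by dragging α or the patient clock)
  lowers the ratio without improving the fit and badly distorts the
  recovered diffusion coefficient when true reactions are small.
* α is updated by an exact weighted least-squares solve of the interval
  residual identity (it enters linearly) instead of gradient steps.  The
  decomposition of the dynamics into diffusion and reaction is not
  identifiable from trajectories alone — adding `cΛβ` to `G` and `−c` to α
  changes nothing — so the package reports the *minimal-reaction
  representative*: α is the weighted least-squares fit of the diffusion
  term to the data secants, and a small ridge on `‖G‖²` at observed states
  (normalized by the squared data-velocity scale) keeps the network on the
  same representative.
* Optimization is Adam with cosine learning-rate decay, a
  residual-regression warm start for the first 30% of iterations (the
  regression landscape is benign and avoids the bad basins the rollout
  loss alone can fall into), best-of-2 restarts selected on training loss,
  and input-noise augmentation (5–10% of the per-dimension spread, targets
  left clean) that smooths the operator between the sparse observed states
  and makes it robust to consuming its own forecasts.

### Personalization

Progression speed is patient-specific.  During cohort training each
patient carries a learnable clock multiplier ξ (their intervals enter the
scheme as ξ·Δt); the log-multipliers are re-centred to mean zero after
every step because a common factor is indistinguishable from rescaling
`(G, α)`.  After training, each patient's γ is refit against all three
frozen operators jointly — the affine disease-progression clock
`s = γ t + offset` — by monotone backtracking descent on log γ with three
starts (0.5, 1, 2).  Two deliberate choices:

* the γ fit minimizes the trajectory-fit term only.  The relative residual
  `‖R − G‖/‖R‖` is monotonically biased toward slow clocks (shrinking γ
  inflates `‖R‖`), and including it can destroy the γ optimum outright;
* the intercept is stored but not fitted by default: the learned dynamics
  are autonomous, so only `γ·Δt` is observable and the intercept is
  unidentifiable.

Forecasts roll all three operators jointly (each variable consuming the
others' predicted coefficients) from the last observation at the patient's
pace, and are averaged over a 2-member ensemble of independently
initialized fits, which damps initialization-dependent wiggle.  The
cognitive score is integrated along the forecast neurodegeneration path.

### Treatment

Anti-amyloid and anti-tau interventions enter as clearance terms
`−d_A(t)·A` and `−d_τ(t)·τ`.  Doses are spatially uniform scalars, so the
sinks are exact in spectral coordinates.  Each schedule is a one-hidden-
layer time network squashed by a sigmoid and scaled by a hard cap
`d_max` (default 1/year), so bounds hold for any weights.  Schedules
minimize `−C(T) + η_A ∫d_A² + η_τ ∫d_τ²` (terminal score against
quadratic burden, η default 0.1) by backtracking gradient descent with
exact gradients through the coupled treated rollout; the line search only
accepts decreasing steps, so objective traces are monotone.  A
mean-over-horizon score objective is not provided; terminal score was
chosen for interpretability.

### Mechanistic read-out

`jacobian_analysis` differentiates a trained operator at a representative
state (analytically, through the standardization chain) and conjugates
each input block back to nodal space, `Φ (∂G/∂β_w) Φᵀ M` — the effective
inter-regional coupling matrix of variable `w` onto the operator's
variable.  Finite differences agree to the expected precision.

## Synthetic cohorts

The generator integrates the reaction–diffusion system with logistic-type
couplings

    F₁ = λ_A A (K_A − A),
    F₂ = (λ_τA A + λ_ττ τ)(K_τ − τ),
    F₃ = (λ_Nτ τ + λ_NN N)(K_N − N),
    dC/dt = (λ_CN ⟨N⟩ + λ_CC)(K_C − C),

with ⟨N⟩ the domain integral on meshes and the regional mean on graphs,
using the same semi-implicit discretization as the learner at a fine
internal step (0.01 year).  Defaults: growth rates 0.2–0.3 /year,
carrying capacities 2.0 (SUVR-like), diffusion 0.05 /year on a connectome
normalized to unit mean degree.  The cognitive equation uses K_C = 0 (the
floor of the score), c₀ = 29, λ_CN = 0.1, λ_CC = 0.02: the score starts
MMSE-like near 29 and declines toward 0 at roughly 1.5–4 points/year as
neurodegeneration accumulates.  With the saturation target above the
starting value the score would *rise*, which contradicts both the
declining-score convention of the cognitive instruments being emulated and
the premise that reducing pathology should preserve cognition, so the
floor form is the default; every parameter is configurable.

Virtual patients draw multiplicative lognormal jitter (σ = 0.05) on all
kinetic rates, a progression rate γ (lognormal, σ = 0.2, or an explicit
range), smooth nonnegative initial fields (a constant level plus a
low-pass combination of the first 8 eigenfunctions, clipped positive),
3–5 visits at a baseline age of 60–75 with gaps of 0.8–2 years, and
multiplicative Gaussian observation noise (σ = 0.02, the scale of PET
test–retest variability).  A patient's fields at age t equal the base
dynamics at their personal disease time γ·(t − t₀), which makes the
time-rescaling construction of the transfer experiments exact.  Noise-free
truth and all generating parameters are retained for evaluation.

What the generator does *not* emulate: scanner physics, spatially
heterogeneous (region-specific) kinetics, tractography realism,
missingness/dropout, or floor/ceiling censoring of scores.  Passing the
synthetic benchmarks therefore demonstrates that the machinery can recover
and forecast dynamics of this family from sparse noisy visits — not that
it handles every pathology of clinical data.

## Evaluation

Accuracies: `Acc2 = 1 − ‖u − û‖/‖u‖` and the mean pointwise relative
accuracy `Acc1` (zero-valued locations excluded and counted).  Norms use
the mass inner product on meshes.  Cohort summaries average *errors*
first and transform to accuracies afterwards.  The error suite reports the
relative solution error E_L2, the relative residual error E_Res (one-sided
residual, as defined above), the nonlinear-term recovery error E_Nonlinear
(against the true reaction — synthetic data only; reported as unavailable
otherwise, never as zero), and their held-out counterparts.  Identifying
the reaction term is strictly harder than fitting trajectories, and the
reports keep the two visible separately; on our fixtures E_L2 is an order
of magnitude below E_Nonlinear.

Reference experiment sizes (all reproduced by `scripts/acceptance.py`):
the main study uses 20 patients on a 68-region connectome with 4 visits
and the last visit held out; transfer uses 10 unseen patients with
γ ∈ [0.5, 2] drawn without kinetic jitter, so they differ from the
training base only by their clock — the cleanest test of the rescaling
mechanism; diffusion recovery uses 8 noise-free patients on a 30-node
graph; linear-map recovery uses 40 patients with full-rank initial
spectra, because its estimand is a dense 20×20 interaction matrix and
smaller designs leave it genuinely under-determined.

## Known limitations

* The learned cognitive rate depends on the neurodegeneration profile
  only.  Any dependence of the true rate on the score itself is absorbed
  only through the co-evolution of N and C; over long extrapolation
  horizons the integrated score can cross the floor of the instrument
  (there is no built-in saturation), so treatment comparisons are best run
  over moderate horizons.
* The diffusion coefficient is reported in the minimal-reaction
  convention.  When the true reaction has a component proportional to
  `Λβ`, that component is attributed to diffusion (clamped at α ≥ 0); the
  *dynamics* are unaffected.
* The nodal operator assumes spatially homogeneous kinetics.  Per-region
  heterogeneity requires the dense architecture and correspondingly more
  data.
* Eigenvectors within a numerically degenerate eigenvalue cluster are
  solver-ordered; comparisons across implementations should use spectral
  projectors, as the tests do.
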