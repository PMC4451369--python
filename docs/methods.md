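# Methods

## Models

`netflux` works with three linear model classes on a shared set of node
identifiers:

* **Temporal pathway model** `y(t+1) = C y(t) + H + B u(t) − B_m m(t) + w(t)`
  — protein expressions `y` (M nodes), interaction abilities `C` (c_ij:
  effect of protein j on protein i at the next time step), basal levels
  `H`, extracellular signals `u` (l signals) bound through `B`, optional
  inhibitory signals `m` (methylation, microRNA and similar repressors)
  bound through `B_m`, and residual `w`. Time points are consecutive and
  equispaced; there is no continuous-time variant.
* **Static pathway model** `y(k) = C y(k) + H + B u(k) + w(k)` — the
  fixed-point analogue for independent samples k = 1..K taken at a single
  time point, solved as `y = (I − C)⁻¹(Bu + H + w)`.
* **GRN model** `x(t+1) = A x(t) + v(t)` (or its static analogue) — a
  square regulatory matrix; a_ij > 0 marks gene j as an activator of
  gene i, a_ij < 0 as an inhibitor. This sign convention is documented,
  not enforced: fitted matrices carry whatever signs the data support.

Inhibitor bindings `B_m` are stored nonnegative by convention and applied
with an explicit minus sign, so inhibition is never conflated with
excitation; in the identification step the inhibitor regressor is negated
so the estimated coefficient is `B_m` itself. Inhibitors deliberately do
not enter gain channels: they shift trajectories but not the
input-to-output amplification from `u`.

## Information flow and transductivity

Subtracting the basal recursion `ŷ(t+1) = C ŷ(t) + H + w(t)` from the
driven one leaves the input-driven deviation ỹ = y − ŷ with
`ỹ(t+1) = C ỹ(t) + B u(t)` and ỹ(0) = 0, whose solution is the
convolution sum ỹ(t+1) = Σ_{j≤t} C^{t−j} B u(j) (`flow_response`).
The *transductivity* of a channel (A, B, D) — D is the identity for an
all-protein output or a unit row for a single protein; for a GRN channel
gene j's column of A becomes the input matrix and the remaining matrix
the state matrix, an exact decomposition satisfying
A_sub + B_sub·e_jᵀ = A — is the worst-case l₂ input-to-output gain.

**Dynamic engine (temporal models).** Energy-gain level ρ is certified by
the discrete-time bounded real lemma: feasibility of

    [[AᵀPA − P + DᵀD, AᵀPB], [BᵀPA, BᵀPB − ρI]] ⪯ 0,  P = Pᵀ ≻ 0.

The minimal ρ is located by bisection (bracket doubled upward from
max(1, σ_max(DB)²) until feasible, then halved to relative width 1e-10).
Each feasibility test builds the candidate P from the bounded-real
discrete algebraic Riccati equation — the Schur complement of the block
at equality — via `scipy.linalg.solve_discrete_are` with the indefinite
weight −ρI, refines it by Newton (Hewer-type) iteration on the
equivalent Stein equation (the deflating-subspace solution can carry
residuals around 1e-5 on strongly non-normal networks, enough to make
valid levels look infeasible), and then validates it against the
explicit block: a level counts as feasible only if the evaluated block's
maximum eigenvalue is ≤ 1e-8 on a scale set by ρ and ‖P‖, P's minimum
eigenvalue is ≥ −1e-9 on the same scale, and ρI − BᵀPB ≻ 0. The reported
transductivity is the amplitude gain √ρ_min — consistent with the
un-squared singular-value formula of the static engine — and the raw
energy bound ρ_min is reported alongside, since both conventions appear
in practice. The LMI bound is horizon-independent: it certifies the
energy ratio over every finite horizon at once. Channels with spectral
radius ≥ 1 − 1e-9 report gain +∞ with `feasible=False` instead of
raising, so batch tables over fitted networks always complete.

An independent oracle (`hinf_oracle`) evaluates
max_ω σ_max(D(e^{iω}I − A)⁻¹B) on a 4096-point grid over [0, π] with
golden-section refinement around the grid maximum; it shares no code
path with the Riccati/LMI route and is used to cross-validate it.

**Static engine (sample models).** T = D(I − A_sub)⁻¹B_sub by linear
solve (never an explicit inverse; condition numbers ≥ 1e12 raise), gain
= σ_max(T), or |T| for scalar channels. On a directed tree this gain
equals the product of edge weights along the unique path — the sanity
check that fixed the channel decomposition above: the alternative
reading with a unit feedthrough would make every single-edge gain 1
regardless of the edge weight, contradicting the meaning of regulatory
ability.

## Identification

Each node is fitted independently by recursive least squares on the
regression `y_i(t+1) ~ [y(t), u(t), −m(t), 1]` (temporal) or
`y_i(k) ~ [y_{j≠i}(k), u(k), −m(k), 1]` (static); GRN fits drop the
input and constant blocks. The update order follows the classic
covariance-first form: ε = y − φᵀθ, P ← P − PφφᵀP/(1 + φᵀPφ),
θ ← θ + Pφε, with P symmetrized each step (observed asymmetry stays
below 1e-10 over 10⁴ updates). One full pass equals the ridge-penalized
batch solution with penalty P0⁻¹, so RLS here is ordinary least squares
with a vanishing prior, run online.

Key choices:

* **Static diagonal.** The literal static regression includes y_i(k) on
  its own right-hand side, admitting the degenerate perfect fit θ = e_i;
  the diagonal is therefore excluded (c_ii = a_ii = 0) in sample mode by
  default. `include_static_diagonal=True` restores the literal behavior
  with a loud warning.
* **Rounds.** When data are short, full passes are repeated with the
  previous round's θ as the warm start and P reset to `P0_scale · I`
  (fresh confidence, warm-started parameters) until the max-norm
  parameter change drops below `tol` (default 1e-8) or `max_rounds`
  (default 50) is reached. The round iteration contracts the parameter
  error by 1/(1 + P0_scale·λ_min(XᵀX)) per round; the default
  `P0_scale = 1e6` keeps both the one-pass ridge bias and the number of
  rounds needed on weakly excited regression directions negligible.
  Sample-mode observation order is exchangeable; a seeded shuffle option
  exists because finite-round RLS is order-dependent.
* **Structure masks.** A declared network structure removes disallowed
  regressor columns before fitting (masked coefficients are exactly
  zero), rather than zeroing afterwards — smaller regressions avoid the
  bias of unidentifiable columns.
* **Diagnostics.** Residuals ŵ = y − φθ̂ double as the noise estimate.
  `residual_diagnostics` reports Pearson correlations between each
  residual series and every regressor series and the fraction with
  |r| ≤ 0.2; a well-specified least-squares fit leaves residuals nearly
  orthogonal to the regressors. Residual series whose standard deviation
  is at machine-precision scale relative to the data are flagged and
  assigned correlation 0. The interpretation of "noise vs. parameter"
  correlation as residual-vs-regressor correlation is this package's
  computable reading.

Identification caveats worth knowing: in static mode the residual enters
the same equation it excites, so sample-mode parameter estimates carry a
bias that grows with the noise variance (the estimator is not consistent
for the structural coefficients under simultaneity); the *transfer
matrix* T, and hence the per-protein transductivities, are nevertheless
identified exactly in the noise-free limit even when individual
parameters are not (any exact-fitting (C̃, B̃) satisfies
(I − C̃)⁻¹B̃ = T). Temporal-mode fits regress t+1 on t and are free of
this issue. Static GRN fits (no exogenous input) rely on sample-to-sample
variation of the residual drive and share the simultaneity caveat.

## Synthetic data

A `SynthScenario` fixes the study conditions: network size (default 8
nodes, 2 inputs), edge density 0.3, spectral radius rescaled to 0.8
(stable, finite gains), coefficient scale 1 with symmetric ± signs so
both activators and inhibitors occur, basal scale 0.5, Gaussian noise
s.d. 0.1, and 100 observations, with i.i.d. standard-Gaussian input
excitation by default (persistently exciting; impulse, step and sinusoid
processes exist for closed-form checks). Expression units are arbitrary
throughout. These defaults are conventions chosen to represent a
mid-sized, clearly stable, moderately sparse signaling module with
noise an order of magnitude below signal scale; nothing in the source
problem pins them down. Sparse draws can be nilpotent (a DAG), in which
case the spectral radius stays 0 and a warning is emitted rather than
forcing a rescale.

Every generator is a pure function of (scenario, seed); replicate r of
an experiment uses seed + r so single replicates re-run in isolation.
`recovery_experiment` runs generate → fit → transductivity against the
known ground truth and aggregates per-parameter bias/RMSE and
per-channel gain errors; gain errors on channels whose true gain is
(near) zero are judged against 0.1% of the table's largest gain rather
than their own vanishing denominator. `perturb_edge` builds matched
condition pairs (the synthetic analogue of a normal-vs-disease
comparison) differing in a single coupling.

The generator emulates the *data regime* of the models — linear
dynamics, additive i.i.d. Gaussian noise, known inputs — not microarray
physics: no probe effects, platform normalization artifacts,
heteroscedasticity, or realistic marginal distributions. Passing tests
therefore demonstrate correctness of the estimation and gain machinery
under the model's own assumptions, not robustness to real-data model
mismatch.

## Problem sizes and numerical conventions

The validation suite and `scripts/acceptance.py` use 50 random stable
systems (n ≤ 8, spectral radius ≤ 0.9) for the LMI-vs-sweep comparison,
20 random directed trees (n ≤ 12) for path products, 4-node/2-input
networks with 80 noise-free observations for exact recovery
(observations ≥ 10 × parameters per node), 20 replicates per condition
for the error trends over K ∈ {50, 200, 1000} and σ ∈ {0.05, 0.1, 0.2},
100 random cases for superposition, and a 5-node branched cascade with
500 samples per condition for the differential workflow — sizes chosen
so the whole battery completes in well under a minute while leaving each
trend statistically unambiguous at its replicate count.

Tie-breaks and degenerate inputs: all-zero regressor matrices return the
initial θ with a `no_information` flag; single-sample static fits are
flagged `underdetermined`; constant datasets are flagged rank-deficient
(any (C, H) with (I − C)c = H fits a constant trajectory equally well);
comparison ratios with a zero denominator report +∞ with a
`zero_denominator` flag; self-loop GRN channels (source = target) are
computed, not forbidden, and flagged. Differential flags use a relative
threshold (default 5% change in gain) so exact-arithmetic comparisons
flag only true changes while noisy refits are not drowned in spurious
flags.

## Limitations

Linearity is the central approximation: saturating kinetics, switch-like
activation and multiplicative regulation are outside the model class,
and transductivities are meaningful only within the linear regime of the
data used to fit them. Sample-mode parameter bias grows with noise
variance (see above). Unstable fitted channels have unbounded worst-case
gain by definition; the package reports them as such rather than
attempting a finite-horizon alternative. No preprocessing is applied to
expression values beyond an optional log2(1 + x) switch at the interface
layer; normalization choices are the caller's responsibility.
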