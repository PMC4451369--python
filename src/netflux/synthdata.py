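"""Ground-truth network generators and recovery experiments.

Everything downstream of this module is testable without any external
data: a scenario fixes a network size, sparsity, stability margin, noise
level and input excitation; the generator draws a random stable network
with known coefficients; datasets are simulated from it (temporal
recursion or static fixed-point sampling); and recovery experiments run
the full generate -> fit -> transductivity pipeline against the known
ground truth.

All generators are pure functions of (scenario, seed): the same scenario
reproduces the same network and data bit-for-bit.  Replicate r of an
experiment uses seed ``scenario.seed + r`` so any single replicate can be
re-run in isolation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import NetfluxError
from .identify import RLSConfig, fit_grn, fit_static_pathway, fit_temporal_pathway
from .netmodel import (ExpressionDataset, GRNModel, PathwayModel,
                       simulate_temporal, steady_state_sample)
from .transduct import SolverConfig, transductivity_table

INPUT_PROCESSES = ("impulse", "step", "iid_gaussian", "sinusoid")


@dataclass
class SynthScenario:
    """Conditions of a synthetic study.

    n_nodes / n_inputs: network size; n_inputs = 0 yields a GRN (square
        regulatory matrix only), n_inputs > 0 a pathway model.
    edge_density: probability of each off-diagonal interaction existing.
    spectral_radius_target: the coefficient matrix is rescaled to this
        spectral radius (< 1, so flows converge and gains are finite).
    coefficient_scale / basal_scale: magnitude of sampled couplings and
        basal levels (expression units are arbitrary throughout).
    noise_sigma: s.d. of the additive Gaussian process/measurement noise.
    n_observations: time points (temporal) or samples (sample mode).
    input_process: excitation shape for the exogenous signals.
    seed: mandatory; every random draw is derived from it.
    """

    n_nodes: int = 8
    n_inputs: int = 2
    edge_density: float = 0.3
    spectral_radius_target: float = 0.8
    coefficient_scale: float = 1.0
    basal_scale: float = 0.5
    noise_sigma: float = 0.1
    n_observations: int = 100
    mode: str = "temporal"
    input_process: str = "iid_gaussian"
    seed: int = 0

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("scenario seed is mandatory")
        if not (0.0 < self.edge_density <= 1.0):
            raise ValueError("edge_density must lie in (0, 1]")
        if not (0.0 < self.spectral_radius_target < 1.0):
            raise ValueError("spectral_radius_target must lie in (0, 1)")
        if self.mode not in ("temporal", "sample"):
            raise ValueError(f"mode must be temporal|sample, got {self.mode!r}")
        if self.input_process not in INPUT_PROCESSES:
            raise ValueError(f"input_process must be one of {INPUT_PROCESSES}")
        for name in ("coefficient_scale", "basal_scale", "noise_sigma"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and nonnegative")


@dataclass
class RecoveryReport:
    """Aggregate of a parameter/gain recovery experiment.

    Per-parameter bias and RMSE are taken over replicates, on the flat
    coefficient vector (C|B|H for pathways, A for GRNs).  Gains compare
    the per-node (pathway) or per-pair (GRN) transductivities of the
    fitted model against those of the generating model.
    """

    scenario: SynthScenario
    replicates: int
    param_bias: np.ndarray
    param_rmse: np.ndarray
    true_gains: np.ndarray
    est_gains: np.ndarray
    failures: list = field(default_factory=list)

    @property
    def param_rmse_overall(self) -> float:
        return float(np.sqrt(np.mean(self.param_rmse ** 2)))

    @property
    def gain_max_rel_error(self) -> float:
        # channels with (near-)zero true gain are judged relative to the
        # table scale, not their own vanishing denominator
        scale = max(float(np.max(np.abs(self.true_gains), initial=0.0)), 1e-12)
        denom = np.maximum(np.abs(self.true_gains), 1e-3 * scale)
        return float(np.max(np.abs(self.est_gains - self.true_gains) / denom))


def _flat_params(model) -> np.ndarray:
    if isinstance(model, PathwayModel):
        return np.concatenate([model.C.ravel(), model.B.ravel(), model.H])
    return model.A.ravel()


def random_stable_network(scenario: SynthScenario):
    """Draw a random sparse stable network for the scenario.

    Off-diagonal couplings exist independently with probability
    ``edge_density`` and carry symmetric +/- signs (activators and
    inhibitors both occur); the matrix is rescaled so its spectral
    radius hits ``spectral_radius_target`` (within 1e-6).  With
    n_inputs > 0 each input signal binds one distinct "receptor" node
    and a PathwayModel (with basal levels) is returned; n_inputs = 0
    returns a GRNModel.
    """
    rng = np.random.default_rng(scenario.seed)
    n = scenario.n_nodes
    mask = rng.random((n, n)) < scenario.edge_density
    np.fill_diagonal(mask, rng.random(n) < scenario.edge_density)
    coeff = rng.normal(0.0, scenario.coefficient_scale, size=(n, n)) * mask
    radius = float(np.max(np.abs(np.linalg.eigvals(coeff)))) if np.any(coeff) else 0.0
    if radius > 1e-12:
        coeff *= scenario.spectral_radius_target / radius
    elif np.any(mask):
        # nilpotent draw (e.g. a DAG): spectral radius is 0 and cannot be
        # rescaled to target; keep the sampled magnitudes
        warnings.warn("sampled coefficient matrix is nilpotent; spectral radius "
                      "stays 0 instead of the target", UserWarning, stacklevel=2)
    else:
        warnings.warn("edge density produced an empty network", UserWarning,
                      stacklevel=2)

    node_ids = [f"g{i+1}" for i in range(n)]
    semantics = "temporal" if scenario.mode == "temporal" else "static"
    if scenario.n_inputs == 0:
        return GRNModel(A=coeff, node_ids=node_ids, semantics=semantics)
    l = scenario.n_inputs
    receptors = rng.choice(n, size=min(l, n), replace=False)
    B = np.zeros((n, l))
    for j in range(l):
        sign = rng.choice([-1.0, 1.0])
        B[receptors[j % len(receptors)], j] = sign * rng.uniform(0.5, 1.5) \
            * scenario.coefficient_scale
    H = rng.normal(0.0, scenario.basal_scale, size=n)
    return PathwayModel(C=coeff, H=H, B=B, node_ids=node_ids,
                        input_ids=[f"u{j+1}" for j in range(l)],
                        semantics=semantics)


def make_input_series(scenario: SynthScenario, n_inputs: int, T: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Excitation series of shape (n_inputs, T) for the chosen process."""
    if scenario.input_process == "impulse":
        u = np.zeros((n_inputs, T))
        if T:
            u[:, 0] = 1.0
        return u
    if scenario.input_process == "step":
        return np.ones((n_inputs, T))
    if scenario.input_process == "sinusoid":
        t = np.arange(T)
        phases = rng.uniform(0, 2 * np.pi, size=n_inputs)
        return np.sin(0.3 * np.pi * t[None, :] + phases[:, None])
    return rng.normal(0.0, 1.0, size=(n_inputs, T))


def generate_dataset(model, scenario: SynthScenario) -> ExpressionDataset:
    """Simulate an expression dataset from a ground-truth model.

    Temporal mode runs the one-step recursion from a zero initial state
    for ``n_observations`` time points; sample mode draws
    ``n_observations`` independent (u, w) pairs and solves the static
    fixed point for each.  Inputs are stored alongside the expressions.
    """
    if model.semantics != ("temporal" if scenario.mode == "temporal" else "static"):
        raise NetfluxError(
            f"model semantics {model.semantics!r} does not match scenario "
            f"mode {scenario.mode!r}")
    rng = np.random.default_rng(scenario.seed + 1)
    is_pathway = isinstance(model, PathwayModel)
    n = model.n_nodes
    N = scenario.n_observations

    if scenario.mode == "temporal":
        T = N - 1
        u = make_input_series(scenario, model.n_inputs, T, rng) if is_pathway else None
        traj = simulate_temporal(model, u_series=u, y0=np.zeros(n),
                                 noise_sigma=scenario.noise_sigma,
                                 seed=scenario.seed + 2,
                                 n_steps=None if u is not None else T)
        inputs = None
        if is_pathway and model.n_inputs:
            # align inputs with observations: u(t) drove the t -> t+1 step
            inputs = np.hstack([u, np.zeros((model.n_inputs, 1))])
        return ExpressionDataset(node_ids=model.node_ids, values=traj,
                                 mode="temporal", inputs=inputs,
                                 input_ids=model.input_ids if is_pathway else None)

    if not is_pathway:
        raise NetfluxError("sample-mode generation needs a pathway model with "
                           "exogenous inputs; a static GRN has no free excitation")
    K = N
    u_draws = rng.normal(0.0, 1.0, size=(model.n_inputs, K)) \
        if scenario.input_process == "iid_gaussian" \
        else make_input_series(scenario, model.n_inputs, K, rng)
    noise_rng = np.random.default_rng(scenario.seed + 2)
    values = np.empty((n, K))
    for k in range(K):
        w = noise_rng.normal(0.0, scenario.noise_sigma, size=n) \
            if scenario.noise_sigma > 0 else np.zeros(n)
        values[:, k] = steady_state_sample(model, u_draws[:, k], w)
    return ExpressionDataset(node_ids=model.node_ids, values=values,
                             mode="sample", inputs=u_draws,
                             input_ids=model.input_ids)


def generate_grn_sample_dataset(grn: GRNModel, scenario: SynthScenario,
                                drive_sigma: float = 1.0) -> ExpressionDataset:
    """Sample-mode GRN data: fixed points of (I - A) x = v with v drawn
    as independent per-sample drive (residual) of s.d. ``drive_sigma``
    plus measurement noise of s.d. ``noise_sigma``.

    The static GRN model x(k) = A x(k) + v(k) has no exogenous input
    block; identifiability comes from sample-to-sample variation of the
    residual drive v(k).
    """
    rng = np.random.default_rng(scenario.seed + 3)
    n = grn.n_nodes
    K = scenario.n_observations
    ImA = np.eye(n) - grn.A
    drive = rng.normal(0.0, drive_sigma, size=(n, K))
    values = np.linalg.solve(ImA, drive)
    if scenario.noise_sigma > 0:
        values = values + rng.normal(0.0, scenario.noise_sigma, size=(n, K))
    return ExpressionDataset(node_ids=grn.node_ids, values=values, mode="sample")


def perturb_edge(model, regulator: str, target: str, factor: float):
    """Return a copy of the model with one coupling coefficient scaled.

    The synthetic analogue of a disease condition: weakening (factor < 1)
    or strengthening one edge while leaving the rest of the network
    untouched.
    """
    j = model.node_index(regulator)
    i = model.node_index(target)
    if isinstance(model, PathwayModel):
        C = model.C.copy()
        C[i, j] *= factor
        return PathwayModel(C=C, H=model.H.copy(), B=model.B.copy(),
                            node_ids=list(model.node_ids),
                            input_ids=list(model.input_ids),
                            semantics=model.semantics,
                            B_m=None if model.B_m is None else model.B_m.copy(),
                            inhibitor_ids=model.inhibitor_ids)
    A = model.A.copy()
    A[i, j] *= factor
    return GRNModel(A=A, node_ids=list(model.node_ids), semantics=model.semantics,
                    B_m=None if model.B_m is None else model.B_m.copy(),
                    inhibitor_ids=model.inhibitor_ids)


def _fit_for(dataset: ExpressionDataset, is_pathway: bool, config: RLSConfig):
    if is_pathway:
        if dataset.mode == "temporal":
            return fit_temporal_pathway(dataset, config=config)
        return fit_static_pathway(dataset, config=config)
    return fit_grn(dataset, config=config)


def recovery_experiment(scenario: SynthScenario, replicates: int = 1,
                        rls_config: RLSConfig | None = None,
                        solver_config: SolverConfig | None = None,
                        compute_gains: bool = True) -> RecoveryReport:
    """End-to-end generate -> fit -> transductivity recovery study.

    Each replicate r reruns the pipeline under seed ``scenario.seed + r``
    and records the flat parameter error (estimate minus truth) and,
    optionally, the per-channel gains of the fitted vs. the generating
    model.  Stage errors are recorded per replicate without aborting the
    batch.  Bias and RMSE are aggregated per parameter over replicates.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rls_config = rls_config or RLSConfig()
    errors, true_gain_rows, est_gain_rows, failures = [], [], [], []
    for r in range(replicates):
        sc = replace(scenario, seed=scenario.seed + r)
        try:
            truth = random_stable_network(sc)
            is_pathway = isinstance(truth, PathwayModel)
            if is_pathway:
                dataset = generate_dataset(truth, sc)
            else:
                dataset = (generate_dataset(truth, sc) if sc.mode == "temporal"
                           else generate_grn_sample_dataset(truth, sc))
            report = _fit_for(dataset, is_pathway, rls_config)
            errors.append(_flat_params(report.model) - _flat_params(truth))
            if compute_gains:
                t_true = transductivity_table(truth, solver_config=solver_config)
                t_est = transductivity_table(report.model,
                                             solver_config=solver_config)
                true_gain_rows.append(t_true["gain"].to_numpy())
                est_gain_rows.append(t_est["gain"].to_numpy())
        except Exception as exc:  # recorded, not fatal to the batch
            failures.append({"replicate": r, "seed": sc.seed,
                             "error": f"{type(exc).__name__}: {exc}"})
    if not errors:
        raise NetfluxError(f"all {replicates} replicates failed: {failures}")
    E = np.vstack(errors)
    return RecoveryReport(
        scenario=scenario, replicates=replicates,
        param_bias=E.mean(axis=0),
        param_rmse=np.sqrt((E ** 2).mean(axis=0)),
        true_gains=(np.concatenate(true_gain_rows) if true_gain_rows
                    else np.array([])),
        est_gains=(np.concatenate(est_gain_rows) if est_gain_rows
                   else np.array([])),
        failures=failures)
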