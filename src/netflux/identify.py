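"""Recursive least-squares identification of pathway and GRN models.

Each node is fitted independently by regressing its expression on the
expressions of all (or structurally permitted) nodes plus, for pathway
models, the exogenous input signals and a constant basal term:

* temporal pathway:  y_i(t+1) ~ [y_1(t)..y_M(t), u_1(t)..u_l(t), 1]
* static pathway:    y_i(k)   ~ [y_(j!=i)(k),    u_1(k)..u_l(k), 1]
* temporal GRN:      x_i(t+1) ~ [x_1(t)..x_n(t)]
* static GRN:        x_i(k)   ~ [x_(j!=i)(k)]

In static (sample) mode the node's own value is excluded from its
regressors by default: including it admits the degenerate perfect fit
theta = e_i (coefficient one on itself, all else zero), which dominates
any least-squares criterion and makes the diagonal unidentifiable.  The
``include_static_diagonal`` switch restores the literal regression with a
loud warning.

The estimator is the classic exponentially-unweighted RLS recursion
(innovation epsilon = y - phi'theta; covariance update
P <- P - P phi phi' P / (1 + phi' P phi); parameter update
theta <- theta + P phi epsilon with the *updated* P).  One full pass over
the data equals the ridge-regularized batch solution with penalty
P0^-1; when the data are short, several warm-started rounds are run
until the parameter change falls below tolerance, resetting P to
``P0_scale * I`` at each round (fresh confidence, warm-started theta).

Inhibitor signals (if present in the dataset) enter the regression with a
negated regressor, so the estimated coefficient is the nonnegative-by-
convention inhibitory binding strength B_m itself.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import DimensionError, NetfluxError
from .netmodel import (ExpressionDataset, GRNModel, NetworkStructure,
                       PathwayModel)


@dataclass
class RLSConfig:
    """Settings for the recursive least-squares fits.

    theta0: initial parameter vector (defaults to zeros).
    P0_scale: initial covariance P(0) = P0_scale * I; acts as an inverse
        ridge penalty (larger = flatter prior).  The warm-started rounds
        contract the parameter error by 1/(1 + P0_scale * lambda_min(X'X))
        per round, so a flat prior also buys fast multi-round convergence
        on weakly excited regression directions.
    max_rounds / tol: multi-round refinement stops when the max-norm
        parameter change between rounds drops below ``tol`` or after
        ``max_rounds`` full passes.
    shuffle / seed: optionally shuffle observation order per round in
        sample mode (RLS at finite rounds is order-dependent).
    include_static_diagonal: keep the node's own value as a regressor in
        static mode (degenerate; see module docstring).
    """

    theta0: np.ndarray | None = None
    P0_scale: float = 1e6
    max_rounds: int = 50
    tol: float = 1e-8
    shuffle: bool = False
    seed: int | None = None
    include_static_diagonal: bool = False

    @classmethod
    def from_dict(cls, d: dict) -> "RLSConfig":
        return cls(**{k: v for k, v in d.items() if k in cls.__dataclass_fields__})


@dataclass
class RLSState:
    """State of one RLS recursion: parameters, covariance, innovations."""

    theta: np.ndarray
    P: np.ndarray
    round: int = 0
    innovations: list = field(default_factory=list)

    def __post_init__(self):
        self.theta = np.asarray(self.theta, dtype=float).reshape(-1)
        self.P = np.asarray(self.P, dtype=float)
        p = self.theta.shape[0]
        if self.P.shape != (p, p):
            raise DimensionError(f"P shape {self.P.shape} != ({p}, {p})")


def rls_step(state: RLSState, phi, y_obs: float) -> RLSState:
    """One RLS update for a single observation (phi, y_obs).

    Computes the innovation with the prior parameters, updates the
    covariance first, then the parameters with the updated covariance
    (equivalently: Kalman gain P phi / (1 + phi' P phi)).
    """
    phi = np.asarray(phi, dtype=float).reshape(-1)
    if not np.all(np.isfinite(phi)) or not np.isfinite(y_obs):
        raise NetfluxError("rls_step received non-finite regressor or response")
    if phi.shape[0] != state.theta.shape[0]:
        raise DimensionError(
            f"regressor length {phi.shape[0]} != parameter length {state.theta.shape[0]}")
    eps = float(y_obs - phi @ state.theta)
    Pphi = state.P @ phi
    denom = 1.0 + float(phi @ Pphi)
    P_new = state.P - np.outer(Pphi, Pphi) / denom
    P_new = 0.5 * (P_new + P_new.T)  # symmetrize against roundoff drift
    theta_new = state.theta + P_new @ phi * eps
    return RLSState(theta=theta_new, P=P_new, round=state.round,
                    innovations=state.innovations + [eps])


def rls_fit_node(regressors, responses, config: RLSConfig | None = None):
    """Multi-round RLS fit of one node's parameter vector.

    Runs full passes over (regressors, responses), warm-starting theta
    from the previous round and resetting P to ``P0_scale * I``, until the
    max-norm parameter change between rounds is below ``tol``.  Returns
    ``(theta, diagnostics)`` where diagnostics reports rounds run, the
    final inter-round change, convergence and degeneracy flags, and the
    regressor condition number.
    """
    config = config or RLSConfig()
    X = np.atleast_2d(np.asarray(regressors, dtype=float))
    y = np.asarray(responses, dtype=float).reshape(-1)
    if X.shape[0] != y.shape[0]:
        raise DimensionError(
            f"observation axis: {X.shape[0]} regressor rows, {y.shape[0]} responses")
    if X.shape[0] < 1:
        raise DimensionError("observation axis: need at least one observation")
    p = X.shape[1]
    theta = (np.zeros(p) if config.theta0 is None
             else np.asarray(config.theta0, dtype=float).reshape(-1).copy())
    if theta.shape[0] != p:
        raise DimensionError(f"theta0 length {theta.shape[0]} != {p} regressors")

    diagnostics = {
        "rounds": 0, "converged": False, "final_change": np.inf,
        "no_information": False, "underdetermined": X.shape[0] < p,
        "rank_deficient": False,
        "condition": float(np.linalg.cond(X)) if X.size else np.inf,
        "innovations": [],
    }
    if not np.any(X):
        diagnostics["no_information"] = True
        diagnostics["converged"] = True
        return theta, diagnostics
    diagnostics["rank_deficient"] = (
        np.linalg.matrix_rank(X) < min(X.shape) or diagnostics["condition"] > 1e10)

    rng = np.random.default_rng(config.seed)
    order = np.arange(X.shape[0])
    for rnd in range(config.max_rounds):
        if config.shuffle:
            rng.shuffle(order)
        state = RLSState(theta=theta.copy(), P=config.P0_scale * np.eye(p), round=rnd)
        for k in order:
            state = rls_step(state, X[k], y[k])
        change = float(np.max(np.abs(state.theta - theta)))
        theta = state.theta
        diagnostics["rounds"] = rnd + 1
        diagnostics["final_change"] = change
        diagnostics["innovations"] = state.innovations
        if change < config.tol:
            diagnostics["converged"] = True
            break
    return theta, diagnostics


# ---------------------------------------------------------------------------
# model-level fits
# ---------------------------------------------------------------------------

@dataclass
class FitReport:
    """Result of a model fit: the model, per-node estimates and diagnostics.

    ``residuals`` is the modeling-error matrix w_hat = y - phi theta_hat,
    shaped like the fitted responses (nodes x effective observations); it
    doubles as the noise estimate.
    """

    model: PathwayModel | GRNModel
    theta_by_node: dict
    residuals: np.ndarray
    convergence: dict
    conditioning: dict
    flags: dict
    regressor_matrix: np.ndarray | None = None
    regressor_labels: list | None = None

    def to_json(self) -> str:
        from .netmodel import model_to_json
        doc = {
            "model": json.loads(model_to_json(self.model)),
            "theta_by_node": {k: list(v) for k, v in self.theta_by_node.items()},
            "convergence": self.convergence,
            "conditioning": self.conditioning,
            "flags": {k: bool(v) for k, v in self.flags.items()},
        }
        return json.dumps(doc, indent=1)


def _design_blocks(dataset: ExpressionDataset, temporal: bool):
    """Regressor blocks shared by all nodes, plus per-node responses.

    Temporal fits regress observation t+1 on observation t; static fits
    regress each sample on itself (diagonal handling is done per node).
    Inhibitor rows are negated so their coefficients estimate B_m >= 0.
    """
    Y = dataset.values
    if temporal:
        if dataset.n_observations < 2:
            raise DimensionError("temporal fit needs consecutive pairs (N >= 2)")
        X_nodes = Y[:, :-1].T               # (N-1, M)
        responses = Y[:, 1:]                # (M, N-1)
        u = None if dataset.inputs is None else dataset.inputs[:, :-1].T
        m = None if dataset.inhibitors is None else dataset.inhibitors[:, :-1].T
    else:
        X_nodes = Y.T                       # (K, M)
        responses = Y
        u = None if dataset.inputs is None else dataset.inputs.T
        m = None if dataset.inhibitors is None else dataset.inhibitors.T
    return X_nodes, responses, u, (None if m is None else -m)


def _fit_nodes(dataset, structure, config, *, with_inputs, with_basal, temporal):
    """Generic node-by-node RLS fit; returns coefficient blocks + report parts."""
    config = config or RLSConfig()
    M = dataset.n_nodes
    l = dataset.n_inputs
    q = 0 if dataset.inhibitors is None else dataset.inhibitors.shape[0]
    X_nodes, responses, Xu, Xm = _design_blocks(dataset, temporal)
    n_obs = X_nodes.shape[0]

    static_drop_diag = (not temporal) and (not config.include_static_diagonal)
    if (not temporal) and config.include_static_diagonal:
        warnings.warn(
            "static fit includes each node's own value as a regressor; the "
            "degenerate solution theta = e_i fits perfectly and the diagonal "
            "is unidentifiable", UserWarning, stacklevel=3)

    node_mask = None
    input_mask = None
    inhib_mask = None
    if structure is not None:
        node_mask = structure.adjacency_mask(dataset.node_ids)
        if with_inputs and l:
            input_mask = structure.binding_mask(dataset.node_ids, dataset.input_ids)
        if q:
            inhib_mask = structure.binding_mask(
                dataset.node_ids, dataset.inhibitor_ids, kind="inhibitor")

    coef_nodes = np.zeros((M, M))
    coef_inputs = np.zeros((M, l)) if with_inputs and l else None
    coef_inhib = np.zeros((M, q)) if q else None
    basal = np.zeros(M) if with_basal else None
    residuals = np.empty((M, n_obs))
    theta_by_node, convergence, conditioning = {}, {}, {}
    flags = {"rank_deficient": False, "underdetermined": False, "no_information": False}

    for i, node in enumerate(dataset.node_ids):
        keep_nodes = np.ones(M, dtype=bool) if node_mask is None else node_mask[i].copy()
        if static_drop_diag:
            keep_nodes[i] = False
        cols = [X_nodes[:, keep_nodes]]
        keep_inputs = None
        if coef_inputs is not None:
            keep_inputs = (np.ones(l, dtype=bool) if input_mask is None
                           else input_mask[i])
            cols.append(Xu[:, keep_inputs])
        keep_inhib = None
        if coef_inhib is not None:
            keep_inhib = (np.ones(q, dtype=bool) if inhib_mask is None
                          else inhib_mask[i])
            cols.append(Xm[:, keep_inhib])
        if with_basal:
            cols.append(np.ones((n_obs, 1)))
        X = np.hstack(cols)
        y = responses[i]

        theta, diag = rls_fit_node(X, y, config)
        theta_by_node[node] = theta
        convergence[node] = {"rounds": diag["rounds"], "converged": diag["converged"],
                             "final_change": diag["final_change"]}
        conditioning[node] = diag["condition"]
        for f in ("rank_deficient", "underdetermined", "no_information"):
            flags[f] = flags[f] or diag[f]

        pos = 0
        nsel = int(keep_nodes.sum())
        coef_nodes[i, keep_nodes] = theta[pos:pos + nsel]
        pos += nsel
        if coef_inputs is not None:
            isel = int(keep_inputs.sum())
            coef_inputs[i, keep_inputs] = theta[pos:pos + isel]
            pos += isel
        if coef_inhib is not None:
            qsel = int(keep_inhib.sum())
            coef_inhib[i, keep_inhib] = theta[pos:pos + qsel]
            pos += qsel
        if with_basal:
            basal[i] = theta[pos]
        residuals[i] = y - X @ theta

    return coef_nodes, coef_inputs, coef_inhib, basal, residuals, \
        theta_by_node, convergence, conditioning, flags


def fit_temporal_pathway(dataset: ExpressionDataset,
                         structure: NetworkStructure | None = None,
                         config: RLSConfig | None = None) -> FitReport:
    """Fit the temporal pathway recursion node by node.

    Assembles C (row i = interaction abilities of node i), B (binding
    abilities), H (basal levels) and optionally B_m from per-node RLS
    fits.  A structure mask removes disallowed regressor columns (masked
    coefficients are exactly zero in the result).
    """
    if dataset.mode != "temporal":
        raise ValueError("fit_temporal_pathway requires a temporal-mode dataset")
    C, B, B_m, H, resid, thetas, conv, cond, flags = _fit_nodes(
        dataset, structure, config, with_inputs=True, with_basal=True, temporal=True)
    l = dataset.n_inputs
    model = PathwayModel(
        C=C, H=H, B=B if B is not None else np.zeros((dataset.n_nodes, l)),
        node_ids=dataset.node_ids,
        input_ids=dataset.input_ids or [],
        semantics="temporal", B_m=B_m, inhibitor_ids=dataset.inhibitor_ids)
    return FitReport(model=model, theta_by_node=thetas, residuals=resid,
                     convergence=conv, conditioning=cond, flags=flags)


def fit_static_pathway(dataset: ExpressionDataset,
                       structure: NetworkStructure | None = None,
                       config: RLSConfig | None = None) -> FitReport:
    """Fit the static fixed-point pathway model from sample-mode data.

    Identical regression per node except observations are exchangeable
    samples and the node's own value is excluded from its regressors by
    default (c_ii fixed at 0); see module docstring.
    """
    if dataset.mode != "sample":
        raise ValueError("fit_static_pathway requires a sample-mode dataset")
    C, B, B_m, H, resid, thetas, conv, cond, flags = _fit_nodes(
        dataset, structure, config, with_inputs=True, with_basal=True, temporal=False)
    l = dataset.n_inputs
    model = PathwayModel(
        C=C, H=H, B=B if B is not None else np.zeros((dataset.n_nodes, l)),
        node_ids=dataset.node_ids,
        input_ids=dataset.input_ids or [],
        semantics="static", B_m=B_m, inhibitor_ids=dataset.inhibitor_ids)
    return FitReport(model=model, theta_by_node=thetas, residuals=resid,
                     convergence=conv, conditioning=cond, flags=flags)


def fit_grn(dataset: ExpressionDataset,
            structure: NetworkStructure | None = None,
            config: RLSConfig | None = None) -> FitReport:
    """Fit the GRN regulatory matrix A (no inputs, no basal term).

    Temporal datasets use the one-step regression x_i(t+1) ~ x(t); sample
    datasets use the static regression with the diagonal excluded by
    default (same degeneracy as the static pathway fit).
    """
    temporal = dataset.mode == "temporal"
    A, _, B_m, _, resid, thetas, conv, cond, flags = _fit_nodes(
        dataset, structure, config, with_inputs=False, with_basal=False,
        temporal=temporal)
    model = GRNModel(A=A, node_ids=dataset.node_ids,
                     semantics="temporal" if temporal else "static",
                     B_m=B_m, inhibitor_ids=dataset.inhibitor_ids)
    return FitReport(model=model, theta_by_node=thetas, residuals=resid,
                     convergence=conv, conditioning=cond, flags=flags)


def residual_diagnostics(report: FitReport, dataset: ExpressionDataset) -> dict:
    """Residual-vs-regressor orthogonality summary.

    Computes the Pearson correlation between each node's residual series
    and every regressor series (all node expressions, plus inputs if the
    model has them), and reports the fraction of coefficients with
    |r| <= 0.2 — residuals of a well-specified least-squares fit are
    nearly uncorrelated with the regressors.  Constant series yield a
    correlation of 0 with a flag.
    """
    temporal = report.model.semantics == "temporal"
    X_nodes, _, Xu, Xm = _design_blocks(dataset, temporal)
    blocks, labels = [X_nodes], [f"y:{n}" for n in dataset.node_ids]
    if Xu is not None and isinstance(report.model, PathwayModel):
        blocks.append(Xu)
        labels += [f"u:{n}" for n in dataset.input_ids]
    if Xm is not None:
        blocks.append(Xm)
        labels += [f"m:{n}" for n in dataset.inhibitor_ids]
    X = np.hstack(blocks)
    R = report.residuals
    if R.shape[1] != X.shape[0]:
        raise DimensionError(
            "report residuals do not match this dataset's observation count")

    n_nodes = R.shape[0]
    corr = np.zeros((n_nodes, X.shape[1]))
    constant_flags = np.zeros((n_nodes, X.shape[1]), dtype=bool)
    # residuals at machine-precision scale are numerically zero series:
    # correlating them against regressors would report pure roundoff noise
    scale = 1.0 + float(np.max(np.abs(dataset.values)))
    for i in range(n_nodes):
        r = R[i]
        r_sd = np.std(r)
        for j in range(X.shape[1]):
            x_sd = np.std(X[:, j])
            if r_sd < 1e-12 * scale or x_sd < 1e-12 * scale:
                constant_flags[i, j] = True
                corr[i, j] = 0.0
            else:
                corr[i, j] = float(np.corrcoef(r, X[:, j])[0, 1])
    informative = ~constant_flags
    frac = (float(np.mean(np.abs(corr[informative]) <= 0.2))
            if informative.any() else 1.0)
    return {"residuals": R, "correlations": corr, "regressor_labels": labels,
            "fraction_within_0.2": frac, "constant_flags": constant_flags}
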