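"""Domain types and forward models for cellular information flow.

Two families of linear models are supported:

* **Pathway models** couple extracellular signals ``u`` to protein
  expression ``y`` through an interaction matrix ``C``, basal levels ``H``
  and binding matrix ``B``.  In *temporal* semantics the model is the
  recursion ``y(t+1) = C y(t) + H + B u(t) [- B_m m(t)] + w(t)``; in
  *static* (sample) semantics it is the fixed-point relation
  ``y(k) = C y(k) + H + B u(k) + w(k)``.
* **GRN models** describe transcription-factor-to-gene regulation with a
  single square matrix ``A`` (``x(t+1) = A x(t) + v(t)`` or its static
  analogue).  A positive ``a_ij`` marks gene *j* as an activator of gene
  *i*, a negative one as an inhibitor.

The module also extracts single input/output *channels* from a full
network (one signal or one regulator gene in, one protein or gene out),
which is the object the gain computations in :mod:`netflux.transduct`
consume, and computes input-driven information-flow trajectories (the
convolution response from a zero initial state).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DimensionError, SingularModelError, UnknownNodeError

MODEL_FORMAT_VERSION = "netflux-model-v1"

#: condition-number ceiling above which a static (I - C) is treated as singular
STATIC_COND_LIMIT = 1e12


def _as_matrix(x, name: str) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.ndim == 1:
        a = a.reshape(1, -1) if name in ("D_out",) else a.reshape(-1, 1)
    if a.ndim != 2:
        raise DimensionError(f"{name} must be 2-dimensional, got ndim={a.ndim}")
    if not np.all(np.isfinite(a)):
        raise DimensionError(f"{name} contains non-finite values")
    return a


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = list(ids)
    seen, dups = set(), []
    for i in ids:
        if i in seen:
            dups.append(i)
        seen.add(i)
    if dups:
        raise DimensionError(f"duplicate {what}: {sorted(set(dups))}")
    return ids


# ---------------------------------------------------------------------------
# datasets and structures
# ---------------------------------------------------------------------------

@dataclass
class ExpressionDataset:
    """Node x observation expression matrix, temporal or sample mode.

    ``values`` has shape (M nodes, N observations).  In temporal mode the
    observations are consecutive equispaced time points; in sample mode
    they are exchangeable independent samples.  Optional ``inputs``
    (extracellular signals, shape (l, N)) and ``inhibitors`` (nonnegative
    repressor expressions such as methylation or microRNA levels, shape
    (q, N)) ride along with matching observation counts.
    """

    node_ids: list[str]
    values: np.ndarray
    mode: str
    inputs: np.ndarray | None = None
    input_ids: list[str] | None = None
    inhibitors: np.ndarray | None = None
    inhibitor_ids: list[str] | None = None

    def __post_init__(self):
        if self.mode not in ("temporal", "sample"):
            raise ValueError(f"mode must be 'temporal' or 'sample', got {self.mode!r}")
        self.node_ids = _check_unique(self.node_ids, "node_ids")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DimensionError("values must be a 2-D (nodes x observations) matrix")
        if not np.all(np.isfinite(self.values)):
            raise DimensionError("expression values contain missing/non-finite entries")
        m, n = self.values.shape
        if m != len(self.node_ids):
            raise DimensionError(
                f"node axis: {len(self.node_ids)} node_ids but {m} value rows")
        if n < 1:
            raise DimensionError("observation axis: need N >= 1 observations")
        for name in ("inputs", "inhibitors"):
            mat = getattr(self, name)
            ids = getattr(self, name[:-1] + "_ids")
            if mat is None:
                continue
            mat = np.asarray(mat, dtype=float)
            if mat.ndim != 2 or mat.shape[1] != n:
                raise DimensionError(
                    f"observation axis: {name} has shape {mat.shape}, expected (*, {n})")
            if not np.all(np.isfinite(mat)):
                raise DimensionError(f"{name} contain non-finite entries")
            if ids is None:
                ids = [f"{name[:-1]}_{i+1}" for i in range(mat.shape[0])]
            ids = _check_unique(ids, name[:-1] + "_ids")
            if len(ids) != mat.shape[0]:
                raise DimensionError(
                    f"{name} axis: {len(ids)} ids but {mat.shape[0]} rows")
            setattr(self, name, mat)
            setattr(self, name[:-1] + "_ids", ids)

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    @property
    def n_observations(self) -> int:
        return self.values.shape[1]

    @property
    def n_inputs(self) -> int:
        return 0 if self.inputs is None else self.inputs.shape[0]

    def node_index(self, name: str) -> int:
        try:
            return self.node_ids.index(name)
        except ValueError:
            raise UnknownNodeError(f"unknown node {name!r}") from None


@dataclass
class NetworkStructure:
    """Directed wiring restricting which coefficients are estimable.

    ``edges`` are (regulator, target) pairs, optionally signed (+1/-1);
    an edge j -> i licenses coefficient c_ij (or a_ij).  ``input_bindings``
    and ``inhibitor_bindings`` are (signal_id, target node) pairs.
    Self-loops are allowed.
    """

    nodes: list[str]
    edges: list[tuple] = field(default_factory=list)
    input_bindings: list[tuple] = field(default_factory=list)
    inhibitor_bindings: list[tuple] = field(default_factory=list)

    def __post_init__(self):
        self.nodes = _check_unique(self.nodes, "structure nodes")
        norm = []
        seen = set()
        for e in self.edges:
            reg, tgt = e[0], e[1]
            sign = e[2] if len(e) > 2 else None
            if reg not in self.nodes:
                raise UnknownNodeError(f"edge regulator {reg!r} not a declared node")
            if tgt not in self.nodes:
                raise UnknownNodeError(f"edge target {tgt!r} not a declared node")
            if (reg, tgt) in seen:
                raise DimensionError(f"duplicate edge {reg!r} -> {tgt!r}")
            seen.add((reg, tgt))
            norm.append((reg, tgt, sign))
        self.edges = norm
        for sid, tgt in self.input_bindings + self.inhibitor_bindings:
            if tgt not in self.nodes:
                raise UnknownNodeError(f"binding target {tgt!r} not a declared node")

    def adjacency_mask(self, node_ids: Sequence[str]) -> np.ndarray:
        """Boolean (M, M) mask; mask[i, j] True iff edge j -> i is declared."""
        idx = {n: i for i, n in enumerate(node_ids)}
        mask = np.zeros((len(node_ids), len(node_ids)), dtype=bool)
        for reg, tgt, _ in self.edges:
            if reg in idx and tgt in idx:
                mask[idx[tgt], idx[reg]] = True
        return mask

    def binding_mask(self, node_ids: Sequence[str], signal_ids: Sequence[str],
                     kind: str = "input") -> np.ndarray:
        """Boolean (M, l) mask of declared signal -> node bindings."""
        bindings = self.input_bindings if kind == "input" else self.inhibitor_bindings
        nidx = {n: i for i, n in enumerate(node_ids)}
        sidx = {s: i for i, s in enumerate(signal_ids)}
        mask = np.zeros((len(node_ids), len(signal_ids)), dtype=bool)
        for sid, tgt in bindings:
            if sid in sidx and tgt in nidx:
                mask[nidx[tgt], sidx[sid]] = True
        return mask


# ---------------------------------------------------------------------------
# models
# ---------------------------------------------------------------------------

@dataclass
class PathwayModel:
    """Linear coupling-pathway model (C, H, B[, B_m]).

    ``semantics`` selects the interpretation: ``"temporal"`` for the
    one-step recursion, ``"static"`` for the fixed-point sample model.
    ``B_m`` holds inhibitory binding strengths (stored nonnegative by
    convention; they enter the dynamics with an explicit minus sign so
    inhibition is never conflated with excitation).
    """

    C: np.ndarray
    H: np.ndarray
    B: np.ndarray
    node_ids: list[str]
    input_ids: list[str]
    semantics: str = "temporal"
    B_m: np.ndarray | None = None
    inhibitor_ids: list[str] | None = None

    def __post_init__(self):
        self.C = _as_matrix(self.C, "C")
        m = self.C.shape[0]
        if self.C.shape != (m, m):
            raise DimensionError(f"C must be square, got {self.C.shape}")
        self.H = np.asarray(self.H, dtype=float).reshape(-1)
        if self.H.shape[0] != m:
            raise DimensionError(f"H length {self.H.shape[0]} != {m} nodes")
        self.B = np.asarray(self.B, dtype=float)
        if self.B.ndim == 1:
            self.B = self.B.reshape(m, -1)
        if self.B.shape[0] != m:
            raise DimensionError(f"B rows {self.B.shape[0]} != {m} nodes")
        self.node_ids = _check_unique(self.node_ids, "node_ids")
        if len(self.node_ids) != m:
            raise DimensionError(f"{len(self.node_ids)} node_ids for {m}-node C")
        self.input_ids = _check_unique(self.input_ids, "input_ids")
        if len(self.input_ids) != self.B.shape[1]:
            raise DimensionError(
                f"{len(self.input_ids)} input_ids but B has {self.B.shape[1]} columns")
        if self.semantics not in ("temporal", "static"):
            raise ValueError(f"semantics must be temporal|static, got {self.semantics!r}")
        if self.B_m is not None:
            self.B_m = np.asarray(self.B_m, dtype=float)
            if self.B_m.ndim == 1:
                self.B_m = self.B_m.reshape(m, -1)
            if self.B_m.shape[0] != m:
                raise DimensionError(f"B_m rows {self.B_m.shape[0]} != {m} nodes")
            if self.inhibitor_ids is None:
                self.inhibitor_ids = [f"inhibitor_{i+1}" for i in range(self.B_m.shape[1])]

    @property
    def n_nodes(self) -> int:
        return self.C.shape[0]

    @property
    def n_inputs(self) -> int:
        return self.B.shape[1]

    @property
    def spectral_radius(self) -> float:
        return float(np.max(np.abs(np.linalg.eigvals(self.C)))) if self.n_nodes else 0.0

    @property
    def is_stable(self) -> bool:
        """Spectral radius below one: the temporal recursion converges."""
        return self.spectral_radius < 1.0

    @property
    def static_condition(self) -> float:
        return float(np.linalg.cond(np.eye(self.n_nodes) - self.C))

    @property
    def is_invertible(self) -> bool:
        return self.static_condition < STATIC_COND_LIMIT

    def node_index(self, name: str) -> int:
        try:
            return self.node_ids.index(name)
        except ValueError:
            raise UnknownNodeError(f"unknown node {name!r}") from None

    def input_index(self, name: str) -> int:
        try:
            return self.input_ids.index(name)
        except ValueError:
            raise UnknownNodeError(f"unknown input signal {name!r}") from None


@dataclass
class GRNModel:
    """Linear gene-regulatory-network model with regulatory matrix ``A``.

    a_ij is the regulatory ability of gene j on gene i (activator if
    positive, inhibitor if negative — a documented convention, not an
    enforced constraint).  ``B_m`` optionally carries microRNA-mediated
    repression strengths.
    """

    A: np.ndarray
    node_ids: list[str]
    semantics: str = "temporal"
    B_m: np.ndarray | None = None
    inhibitor_ids: list[str] | None = None

    def __post_init__(self):
        self.A = _as_matrix(self.A, "A")
        n = self.A.shape[0]
        if self.A.shape != (n, n):
            raise DimensionError(f"A must be square, got {self.A.shape}")
        self.node_ids = _check_unique(self.node_ids, "node_ids")
        if len(self.node_ids) != n:
            raise DimensionError(f"{len(self.node_ids)} node_ids for {n}-gene A")
        if self.semantics not in ("temporal", "static"):
            raise ValueError(f"semantics must be temporal|static, got {self.semantics!r}")
        if self.B_m is not None:
            self.B_m = np.asarray(self.B_m, dtype=float)
            if self.B_m.ndim == 1:
                self.B_m = self.B_m.reshape(n, -1)
            if self.B_m.shape[0] != n:
                raise DimensionError(f"B_m rows {self.B_m.shape[0]} != {n} genes")

    @property
    def n_nodes(self) -> int:
        return self.A.shape[0]

    @property
    def spectral_radius(self) -> float:
        return float(np.max(np.abs(np.linalg.eigvals(self.A)))) if self.n_nodes else 0.0

    @property
    def is_stable(self) -> bool:
        return self.spectral_radius < 1.0

    def node_index(self, name: str) -> int:
        try:
            return self.node_ids.index(name)
        except ValueError:
            raise UnknownNodeError(f"unknown node {name!r}") from None


@dataclass
class IOSubsystem:
    """One extracted input/output channel of a network model.

    ``A_sub`` is the state matrix, ``B_sub`` the input column(s) and
    ``D_out`` the output selector (identity for all nodes, a unit row for
    a single node).  ``source``/``target`` are human-readable channel
    descriptors; ``self_loop`` flags a gene-to-itself channel.
    """

    A_sub: np.ndarray
    B_sub: np.ndarray
    D_out: np.ndarray
    source: str = "all-inputs"
    target: str = "all-nodes"
    self_loop: bool = False

    def __post_init__(self):
        self.A_sub = _as_matrix(self.A_sub, "A_sub")
        n = self.A_sub.shape[0]
        self.B_sub = np.asarray(self.B_sub, dtype=float)
        if self.B_sub.ndim == 1:
            self.B_sub = self.B_sub.reshape(-1, 1)
        if self.B_sub.shape[0] != n:
            raise DimensionError(
                f"B_sub rows {self.B_sub.shape[0]} != state dimension {n}")
        self.D_out = np.asarray(self.D_out, dtype=float)
        if self.D_out.ndim == 1:
            self.D_out = self.D_out.reshape(1, -1)
        if self.D_out.shape[1] != n:
            raise DimensionError(
                f"D_out columns {self.D_out.shape[1]} != state dimension {n}")

    @property
    def label(self) -> str:
        return f"{self.source}->{self.target}"

    @property
    def spectral_radius(self) -> float:
        return float(np.max(np.abs(np.linalg.eigvals(self.A_sub))))


@dataclass
class FlowTrajectory:
    """Input-driven information-flow trajectory from a zero initial state."""

    times: np.ndarray
    values: np.ndarray  # (len(times), n_outputs)
    channel: IOSubsystem | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[0] != self.times.shape[0]:
            self.values = self.values.T
        if self.values.shape[0] != self.times.shape[0]:
            raise DimensionError("times and values lengths differ")


# ---------------------------------------------------------------------------
# forward simulation
# ---------------------------------------------------------------------------

def _dynamics(model):
    """Return (A, H, B, B_m) of the one-step recursion for either model kind."""
    if isinstance(model, PathwayModel):
        return model.C, model.H, model.B, model.B_m
    if isinstance(model, GRNModel):
        n = model.n_nodes
        return model.A, np.zeros(n), None, model.B_m
    raise TypeError(f"unsupported model type {type(model).__name__}")


def simulate_temporal(model, u_series=None, m_series=None, y0=None,
                      noise_sigma: float = 0.0, seed: int | None = None,
                      n_steps: int | None = None) -> np.ndarray:
    """Simulate the one-step recursion for ``n_steps`` transitions.

    Returns an (M, T+1) matrix whose column 0 is ``y0``.  ``u_series``
    (shape (l, T)) and ``m_series`` (shape (q, T)) supply inputs and
    inhibitor expressions per step; inhibitors act subtractively
    (``- B_m m(t)``).  Gaussian noise of s.d. ``noise_sigma`` is added
    i.i.d. per node per step, reproducibly under ``seed``.
    """
    if model.semantics != "temporal":
        raise ValueError("simulate_temporal requires a temporal-semantics model")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be nonnegative")
    A, H, B, B_m = _dynamics(model)
    n = A.shape[0]

    T = None
    if u_series is not None:
        u_series = np.atleast_2d(np.asarray(u_series, dtype=float))
        if B is None:
            raise DimensionError("input axis: model has no input matrix B")
        if u_series.shape[0] != B.shape[1]:
            raise DimensionError(
                f"input axis: u_series has {u_series.shape[0]} rows, "
                f"model expects {B.shape[1]} input signals")
        T = u_series.shape[1]
    if m_series is not None:
        m_series = np.atleast_2d(np.asarray(m_series, dtype=float))
        if B_m is None:
            raise DimensionError("inhibitor axis: model has no B_m matrix")
        if m_series.shape[0] != B_m.shape[1]:
            raise DimensionError(
                f"inhibitor axis: m_series has {m_series.shape[0]} rows, "
                f"model expects {B_m.shape[1]} inhibitor signals")
        if T is not None and m_series.shape[1] != T:
            raise DimensionError("time axis: u_series and m_series lengths differ")
        T = m_series.shape[1] if T is None else T
    if T is None:
        if n_steps is None:
            raise ValueError("need u_series, m_series, or n_steps to fix the horizon")
        T = int(n_steps)
    elif n_steps is not None and int(n_steps) != T:
        raise DimensionError("time axis: n_steps conflicts with series length")

    y0 = np.zeros(n) if y0 is None else np.asarray(y0, dtype=float).reshape(-1)
    if y0.shape[0] != n:
        raise DimensionError(f"state axis: y0 length {y0.shape[0]} != {n} nodes")

    rng = np.random.default_rng(seed)
    traj = np.empty((n, T + 1))
    traj[:, 0] = y0
    for t in range(T):
        nxt = A @ traj[:, t] + H
        if u_series is not None:
            nxt += B @ u_series[:, t]
        if m_series is not None:
            nxt -= B_m @ m_series[:, t]
        if noise_sigma > 0:
            nxt += rng.normal(0.0, noise_sigma, size=n)
        traj[:, t + 1] = nxt
    return traj


def simulate_basal(model: PathwayModel, y0=None, noise_sigma: float = 0.0,
                   seed: int | None = None, n_steps: int = 0) -> np.ndarray:
    """Simulate the basal recursion (inputs and inhibitors identically zero)."""
    return simulate_temporal(model, u_series=None, m_series=None, y0=y0,
                             noise_sigma=noise_sigma, seed=seed, n_steps=n_steps)


def flow_response(C, B_sub, D_out, u_series) -> FlowTrajectory:
    """Information-flow trajectory: the zero-state response to ``u_series``.

    Implements the convolution sum  ytilde(t+1) = sum_{j<=t} C^(t-j) B u(j)
    by running the recursion ytilde(t+1) = C ytilde(t) + B u(t) from
    ytilde(0) = 0, and reports D_out * ytilde(t) for t = 0..T.
    """
    C = _as_matrix(C, "C")
    n = C.shape[0]
    B_sub = np.asarray(B_sub, dtype=float)
    if B_sub.ndim == 1:
        B_sub = B_sub.reshape(-1, 1)
    if B_sub.shape[0] != n:
        raise DimensionError(f"B_sub rows {B_sub.shape[0]} != state dimension {n}")
    D_out = np.asarray(D_out, dtype=float)
    if D_out.ndim == 1:
        D_out = D_out.reshape(1, -1)
    if D_out.shape[1] != n:
        raise DimensionError(f"D_out columns {D_out.shape[1]} != state dimension {n}")
    u_series = np.atleast_2d(np.asarray(u_series, dtype=float))
    if u_series.shape[0] != B_sub.shape[1]:
        raise DimensionError(
            f"input axis: u_series has {u_series.shape[0]} rows, "
            f"B_sub has {B_sub.shape[1]} columns")
    T = u_series.shape[1]
    state = np.zeros(n)
    out = np.empty((T + 1, D_out.shape[0]))
    out[0] = D_out @ state
    for t in range(T):
        state = C @ state + B_sub @ u_series[:, t]
        out[t + 1] = D_out @ state
    channel = IOSubsystem(A_sub=C, B_sub=B_sub, D_out=D_out)
    return FlowTrajectory(times=np.arange(T + 1), values=out, channel=channel)


def steady_state_sample(model: PathwayModel, u, w=None) -> np.ndarray:
    """Solve the static fixed point  (I - C) y = B u + H + w  for one sample."""
    if model.semantics != "static":
        raise ValueError("steady_state_sample requires a static-semantics model")
    n = model.n_nodes
    u = np.asarray(u, dtype=float).reshape(-1)
    if u.shape[0] != model.n_inputs:
        raise DimensionError(f"input axis: u length {u.shape[0]} != {model.n_inputs}")
    w = np.zeros(n) if w is None else np.asarray(w, dtype=float).reshape(-1)
    if w.shape[0] != n:
        raise DimensionError(f"noise axis: w length {w.shape[0]} != {n}")
    ImC = np.eye(n) - model.C
    if not model.is_invertible:
        raise SingularModelError(
            f"static model non-invertible: cond(I - C) = {model.static_condition:.3e}")
    return np.linalg.solve(ImC, model.B @ u + model.H + w)


# ---------------------------------------------------------------------------
# channel extraction
# ---------------------------------------------------------------------------

def extract_pathway_channel(model: PathwayModel, target=None,
                            input_signal=None) -> IOSubsystem:
    """Channel from extracellular signal(s) to protein(s).

    ``target=None`` keeps all nodes (identity output); a node name selects
    the unit-row output for that protein.  ``input_signal=None`` keeps the
    full binding matrix B; a signal name selects its binding column B_l.
    """
    m = model.n_nodes
    if target is None:
        D = np.eye(m)
        tgt = "all-nodes"
    else:
        i = model.node_index(target)
        D = np.zeros((1, m))
        D[0, i] = 1.0
        tgt = target
    if input_signal is None:
        Bsub = model.B
        src = "all-signals"
    else:
        l = model.input_index(input_signal)
        Bsub = model.B[:, [l]]
        src = input_signal
    return IOSubsystem(A_sub=model.C, B_sub=Bsub, D_out=D, source=src, target=tgt)


def extract_grn_channel(grn: GRNModel, source: str, target: str) -> IOSubsystem:
    """Channel treating gene ``source``'s expression as the input signal.

    The regulatory matrix is split exactly: A_sub is A with the source
    column zeroed, B_sub is that column, so A_sub X + B_sub x_j == A X for
    any state X.  The output selector is the unit row of ``target``.  A
    source == target channel is permitted and flagged as a self-loop.
    """
    j = grn.node_index(source)
    i = grn.node_index(target)
    A_sub = grn.A.copy()
    B_sub = grn.A[:, [j]].copy()
    A_sub[:, j] = 0.0
    D = np.zeros((1, grn.n_nodes))
    D[0, i] = 1.0
    return IOSubsystem(A_sub=A_sub, B_sub=B_sub, D_out=D,
                       source=source, target=target, self_loop=(i == j))


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def model_to_json(model) -> str:
    """Serialize a PathwayModel or GRNModel to the v1 JSON document."""
    doc = {"version": MODEL_FORMAT_VERSION, "semantics": model.semantics,
           "node_ids": model.node_ids}
    if isinstance(model, PathwayModel):
        doc.update(kind="pathway", input_ids=model.input_ids,
                   C=model.C.tolist(), H=model.H.tolist(), B=model.B.tolist())
    elif isinstance(model, GRNModel):
        doc.update(kind="grn", A=model.A.tolist())
    else:
        raise TypeError(f"unsupported model type {type(model).__name__}")
    if model.B_m is not None:
        doc["B_m"] = model.B_m.tolist()
        doc["inhibitor_ids"] = model.inhibitor_ids
    return json.dumps(doc, indent=1)


def model_from_json(text: str):
    doc = json.loads(text)
    if doc.get("version") != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model document version {doc.get('version')!r}")
    common = dict(semantics=doc["semantics"],
                  B_m=np.array(doc["B_m"]) if "B_m" in doc else None,
                  inhibitor_ids=doc.get("inhibitor_ids"))
    if doc["kind"] == "pathway":
        return PathwayModel(C=np.array(doc["C"]), H=np.array(doc["H"]),
                            B=np.array(doc["B"]), node_ids=doc["node_ids"],
                            input_ids=doc["input_ids"], **common)
    if doc["kind"] == "grn":
        return GRNModel(A=np.array(doc["A"]), node_ids=doc["node_ids"], **common)
    raise ValueError(f"unknown model kind {doc['kind']!r}")


def trajectory_to_frame(traj: np.ndarray, node_ids: Sequence[str]) -> pd.DataFrame:
    """(M, T+1) trajectory -> tidy frame with a leading 't' column."""
    traj = np.atleast_2d(traj)
    if traj.shape[0] != len(node_ids):
        raise DimensionError(
            f"node axis: {traj.shape[0]} trajectory rows, {len(node_ids)} node_ids")
    frame = pd.DataFrame(traj.T, columns=list(node_ids))
    frame.insert(0, "t", np.arange(traj.shape[1]))
    return frame
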