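"""File formats and run configuration.

Expression matrices travel as delimited text with nodes in rows and
observations in columns (the microarray convention; a transpose flag
covers the other orientation).  Network structures are edge lists with
optional ``@nodes`` / ``@input`` / ``@inhibitor`` sections.  Models and
result tables use the JSON/TSV writers of the other modules.  Readers
reject malformed input (missing cells, duplicate ids, non-numeric
values) rather than coercing it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import DataError
from .netmodel import ExpressionDataset, NetworkStructure


def read_expression_matrix(path, mode: str, delimiter: str = "\t",
                           orientation: str = "nodes_in_rows",
                           input_ids=None, inhibitor_ids=None,
                           log2: bool = False) -> ExpressionDataset:
    """Read a delimited node x observation matrix into a dataset.

    Rows named in ``input_ids`` / ``inhibitor_ids`` are split out of the
    expression block into the dataset's exogenous-input / inhibitor
    blocks.  ``log2`` applies log2(1 + x) to the expression values only.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    frame = pd.read_csv(path, sep=delimiter, index_col=0,
                        float_precision="round_trip")
    if orientation == "observations_in_rows":
        frame = frame.T
    elif orientation != "nodes_in_rows":
        raise ValueError(f"unknown orientation {orientation!r}")

    ids = [str(i) for i in frame.index]
    dups = sorted({i for i in ids if ids.count(i) > 1})
    if dups:
        raise DataError(f"duplicate row ids: {dups}")

    bad_cells = []
    values = np.empty(frame.shape)
    for r, (_, row) in enumerate(frame.iterrows()):
        for c, v in enumerate(row):
            try:
                fv = float(v)
            except (TypeError, ValueError):
                bad_cells.append((ids[r], frame.columns[c], repr(v)))
                continue
            if not np.isfinite(fv):
                bad_cells.append((ids[r], frame.columns[c], repr(v)))
            values[r, c] = fv
    if bad_cells:
        listing = "; ".join(f"row {r!r} col {c!r}: {v}" for r, c, v in bad_cells[:20])
        raise DataError(f"{len(bad_cells)} missing/non-numeric cells: {listing}")

    input_ids = list(input_ids or [])
    inhibitor_ids = list(inhibitor_ids or [])
    for sid in input_ids + inhibitor_ids:
        if sid not in ids:
            raise DataError(f"declared signal row {sid!r} not found in file")
    is_input = np.array([i in input_ids for i in ids])
    is_inhib = np.array([i in inhibitor_ids for i in ids])
    is_node = ~(is_input | is_inhib)

    expr = values[is_node]
    if log2:
        if np.any(expr < 0):
            raise DataError("log2 preprocessing requires nonnegative expressions")
        expr = np.log2(1.0 + expr)
    return ExpressionDataset(
        node_ids=[i for i, keep in zip(ids, is_node) if keep],
        values=expr, mode=mode,
        inputs=values[is_input] if is_input.any() else None,
        input_ids=[i for i in ids if i in input_ids] or None,
        inhibitors=values[is_inhib] if is_inhib.any() else None,
        inhibitor_ids=[i for i in ids if i in inhibitor_ids] or None)


def write_expression_matrix(dataset: ExpressionDataset, path,
                            delimiter: str = "\t") -> None:
    """Write a dataset (expressions, then input/inhibitor rows) to text."""
    blocks = [pd.DataFrame(dataset.values, index=dataset.node_ids)]
    if dataset.inputs is not None:
        blocks.append(pd.DataFrame(dataset.inputs, index=dataset.input_ids))
    if dataset.inhibitors is not None:
        blocks.append(pd.DataFrame(dataset.inhibitors, index=dataset.inhibitor_ids))
    out = pd.concat(blocks)
    out.columns = [f"obs{c+1}" for c in range(out.shape[1])]
    out.index.name = "id"
    out.to_csv(path, sep=delimiter, float_format="%.17g")


def read_network_structure(path, delimiter: str = "\t",
                           nodes=None) -> NetworkStructure:
    """Parse an edge-list file into a NetworkStructure.

    Plain lines are ``regulator<TAB>target[<TAB>sign]`` edges.  Optional
    section headers switch the meaning of subsequent lines: ``@nodes``
    (one node name per line, declaring the universe), ``@input`` and
    ``@inhibitor`` (``signal<TAB>target`` bindings).  Without an
    ``@nodes`` section the node universe is inferred from the edges and
    bindings (or taken from the ``nodes`` argument).
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    declared_nodes: list[str] = list(nodes or [])
    edges, input_bindings, inhibitor_bindings = [], [], []
    section = "edges"
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("@"):
            section = line[1:].strip().lower()
            if section not in ("nodes", "edges", "input", "inhibitor"):
                raise DataError(f"line {lineno}: unknown section @{section}")
            continue
        parts = [p.strip() for p in line.split(delimiter)]
        if section == "nodes":
            declared_nodes.extend(parts[:1])
        elif section == "edges":
            if len(parts) < 2:
                raise DataError(f"line {lineno}: edge needs regulator and target")
            sign = None
            if len(parts) >= 3 and parts[2] != "":
                if parts[2] not in ("+", "-", "+1", "-1", "1"):
                    raise DataError(f"line {lineno}: malformed sign {parts[2]!r}")
                sign = -1 if parts[2].startswith("-") else 1
            edges.append((parts[0], parts[1], sign))
        else:
            if len(parts) < 2:
                raise DataError(f"line {lineno}: binding needs signal and target")
            (input_bindings if section == "input" else inhibitor_bindings).append(
                (parts[0], parts[1]))
    if not declared_nodes:
        seen = []
        for reg, tgt, _ in edges:
            for x in (reg, tgt):
                if x not in seen:
                    seen.append(x)
        for _, tgt in input_bindings + inhibitor_bindings:
            if tgt not in seen:
                seen.append(tgt)
        declared_nodes = seen
    return NetworkStructure(nodes=declared_nodes, edges=edges,
                            input_bindings=input_bindings,
                            inhibitor_bindings=inhibitor_bindings)


def write_network_structure(structure: NetworkStructure, path,
                            delimiter: str = "\t") -> None:
    lines = ["@nodes"] + list(structure.nodes) + ["@edges"]
    for reg, tgt, sign in structure.edges:
        row = [reg, tgt] + ([{1: "+", -1: "-"}[sign]] if sign else [])
        lines.append(delimiter.join(row))
    if structure.input_bindings:
        lines.append("@input")
        lines += [delimiter.join(b) for b in structure.input_bindings]
    if structure.inhibitor_bindings:
        lines.append("@inhibitor")
        lines += [delimiter.join(b) for b in structure.inhibitor_bindings]
    Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class RunConfig:
    """One pipeline run: data locations, mode, engine, solver settings.

    ``engine="auto"`` resolves to the dynamic LMI engine for temporal
    data and the static singular-value engine for sample data — the two
    branches of the estimation workflow.
    """

    mode: str = "temporal"
    engine: str = "auto"
    expression: str | None = None
    inputs: list = field(default_factory=list)
    inhibitors: list = field(default_factory=list)
    structure: str | None = None
    output_dir: str = "."
    rls: dict = field(default_factory=dict)
    solver: dict = field(default_factory=dict)
    log_level: str = "INFO"
    log2: bool = False

    def __post_init__(self):
        if self.mode not in ("temporal", "sample"):
            raise ValueError(f"mode must be temporal|sample, got {self.mode!r}")
        if self.engine not in ("dynamic", "static", "auto"):
            raise ValueError(f"engine must be dynamic|static|auto, got {self.engine!r}")

    @property
    def resolved_engine(self) -> str:
        if self.engine != "auto":
            return self.engine
        return "dynamic" if self.mode == "temporal" else "static"

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        doc = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        return cls(**{k: v for k, v in (doc or {}).items()
                      if k in cls.__dataclass_fields__})

    def to_file(self, path) -> None:
        doc = {k: getattr(self, k) for k in self.__dataclass_fields__}
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))
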