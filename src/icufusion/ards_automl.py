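"""Stage-graph feature extraction and majority-voting ensemble classification.

Feature extraction is organized as an ordered list of stages over named
feature columns.  Stage 0 is the raw sensor features of the input table;
each later stage holds nodes that either call a built-in clinical
computation (predicted body weight, ventilatory ratio), copy a feature
through unchanged (bypass), or evaluate a restricted arithmetic expression
(operators ``+ - * /``, parentheses, feature names, numeric literals).  A
node may consume only features produced at earlier stages or by same-stage
predecessors already evaluated, and exactly one column is flagged as the
label.  Built-in nodes delegate to :mod:`icufusion.clinical_indices`
per-row, so their outputs are bit-identical to direct calls.

The classification scaffold trains a configurable set of members — support
vector machine, gradient-boosted trees (XGBoost), multi-layer perceptron —
on a train/validation split, reports a selection metric per member, and
fuses predictions by majority vote (ties in even-member votes break toward
the positive, i.e. ARDS, class — clinically conservative — with a logged
warning) or by probability averaging.
"""

from __future__ import annotations

import ast
import operator
import warnings
from dataclasses import dataclass, field
from typing import Any, Callable, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import accuracy_score, f1_score, precision_score, roc_auc_score
from sklearn.model_selection import train_test_split
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from xgboost import XGBClassifier

from . import clinical_indices

__all__ = [
    "GraphValidationError",
    "StageNode",
    "StageGraph",
    "FeatureExtractionResult",
    "EnsembleSpec",
    "EnsembleResult",
    "validate_graph",
    "extract_features",
    "default_ards_graph",
    "train_ensemble",
    "majority_vote",
    "select_best",
    "evaluate_expression",
]

NODE_KINDS = ("builtin", "bypass", "user_expression")
BUILTINS = ("pbw", "ventilatory_ratio")
METRICS = ("auc", "f1", "precision", "accuracy")
MEMBER_KINDS = ("svm", "xgb", "mlp")


class GraphValidationError(ValueError):
    """A stage-graph specification violates an invariant."""


@dataclass(frozen=True)
class StageNode:
    kind: str  # builtin | bypass | user_expression
    inputs: tuple[str, ...]
    output: str
    function: str = ""  # builtin name or expression text

    def __post_init__(self) -> None:
        if self.kind not in NODE_KINDS:
            raise GraphValidationError(f"unknown node kind {self.kind!r}")
        if self.kind == "builtin" and self.function not in BUILTINS:
            raise GraphValidationError(f"unknown builtin {self.function!r}")
        if self.kind == "bypass" and len(self.inputs) != 1:
            raise GraphValidationError("bypass nodes take exactly one input")
        if not self.inputs:
            raise GraphValidationError(f"node {self.output!r} declares no inputs")


@dataclass(frozen=True)
class StageGraph:
    source_features: tuple[str, ...]  # Stage 0 columns of the input table
    stages: tuple[tuple[StageNode, ...], ...]
    label: str

    @property
    def output_features(self) -> tuple[str, ...]:
        return tuple(node.output for stage in self.stages for node in stage)


# -- restricted arithmetic expressions --------------------------------------

_BIN_OPS: dict[type, Callable[[Any, Any], Any]] = {
    ast.Add: operator.add,
    ast.Sub: operator.sub,
    ast.Mult: operator.mul,
    ast.Div: operator.truediv,
}


def _eval_node(node: ast.AST, env: dict[str, Any]) -> Any:
    if isinstance(node, ast.Expression):
        return _eval_node(node.body, env)
    if isinstance(node, ast.BinOp) and type(node.op) in _BIN_OPS:
        return _BIN_OPS[type(node.op)](_eval_node(node.left, env), _eval_node(node.right, env))
    if isinstance(node, ast.UnaryOp) and isinstance(node.op, (ast.USub, ast.UAdd)):
        value = _eval_node(node.operand, env)
        return -value if isinstance(node.op, ast.USub) else value
    if isinstance(node, ast.Constant) and isinstance(node.value, (int, float)):
        return node.value
    if isinstance(node, ast.Name):
        if node.id not in env:
            raise GraphValidationError(f"expression references unknown feature {node.id!r}")
        return env[node.id]
    raise GraphValidationError(f"unsupported expression element {ast.dump(node)}")


def evaluate_expression(expression: str, env: dict[str, Any]) -> Any:
    """Evaluate a restricted arithmetic expression over feature columns."""
    try:
        tree = ast.parse(expression, mode="eval")
    except SyntaxError as exc:
        raise GraphValidationError(f"invalid expression {expression!r}: {exc}") from exc
    return _eval_node(tree, env)


def _expression_names(expression: str) -> set[str]:
    try:
        tree = ast.parse(expression, mode="eval")
    except SyntaxError as exc:
        raise GraphValidationError(f"invalid expression {expression!r}: {exc}") from exc
    return {n.id for n in ast.walk(tree) if isinstance(n, ast.Name)}


# -- graph validation --------------------------------------------------------


def validate_graph(spec: dict) -> StageGraph:
    """Validate a stage-graph specification and fix its evaluation order.

    ``spec`` has ``source_features`` (Stage 0 columns), ``stages`` (list of
    lists of node dicts with ``kind``, ``inputs``, ``output`` and optionally
    ``function``/``expression``), and ``label``.  Raises
    :class:`GraphValidationError` on cycles (a node consuming its own
    output), dangling inputs, duplicate outputs or a missing label.
    """
    try:
        source = tuple(spec["source_features"])
        raw_stages = spec["stages"]
        label = spec["label"]
    except KeyError as exc:
        raise GraphValidationError(f"missing graph key: {exc}") from exc
    if not label:
        raise GraphValidationError("a label column must be flagged")

    stages: list[tuple[StageNode, ...]] = []
    available = set(source)
    outputs_seen: set[str] = set(source)
    for stage_index, raw_stage in enumerate(raw_stages, start=1):
        stage_nodes = []
        for raw in raw_stage:
            node = StageNode(
                kind=raw["kind"],
                inputs=tuple(raw["inputs"]),
                output=raw["output"],
                function=raw.get("function", raw.get("expression", "")),
            )
            if node.output in outputs_seen and node.kind != "bypass":
                raise GraphValidationError(f"duplicate output feature {node.output!r}")
            if node.output in node.inputs and node.kind != "bypass":
                raise GraphValidationError(
                    f"cycle: node {node.output!r} consumes its own output"
                )
            for name in node.inputs:
                if name not in available:
                    raise GraphValidationError(
                        f"stage {stage_index} node {node.output!r} input {name!r} "
                        "is not available from earlier stages"
                    )
            if node.kind == "user_expression":
                unknown = _expression_names(node.function) - available
                if unknown:
                    raise GraphValidationError(
                        f"expression for {node.output!r} references unknown "
                        f"feature(s): {sorted(unknown)}"
                    )
            stage_nodes.append(node)
            available.add(node.output)
            outputs_seen.add(node.output)
        stages.append(tuple(stage_nodes))

    graph = StageGraph(source_features=source, stages=tuple(stages), label=label)
    if label not in set(graph.output_features) | set(source):
        raise GraphValidationError(f"label column {label!r} is not produced by the graph")
    return graph


def default_ards_graph() -> StageGraph:
    """The standard two-stage ventilation graph: Stage 1 computes predicted
    body weight and bypasses the six sensor features (FiO2, PCO2, PO2, Ve,
    Vt, label); Stage 2 computes the ventilatory ratio."""
    return validate_graph(
        {
            "source_features": ["FiO2", "PCO2", "PO2", "Ve", "Vt", "height", "sex", "label"],
            "stages": [
                [
                    {"kind": "builtin", "function": "pbw", "inputs": ["sex", "height"], "output": "PBW"},
                    {"kind": "bypass", "inputs": ["FiO2"], "output": "FiO2"},
                    {"kind": "bypass", "inputs": ["PCO2"], "output": "PCO2"},
                    {"kind": "bypass", "inputs": ["PO2"], "output": "PO2"},
                    {"kind": "bypass", "inputs": ["Ve"], "output": "Ve"},
                    {"kind": "bypass", "inputs": ["Vt"], "output": "Vt"},
                    {"kind": "bypass", "inputs": ["label"], "output": "label"},
                ],
                [
                    {
                        "kind": "builtin",
                        "function": "ventilatory_ratio",
                        "inputs": ["Ve", "PCO2", "Vt", "PBW"],
                        "output": "ventilatory_ratio",
                    }
                ],
            ],
            "label": "label",
        }
    )


@dataclass
class FeatureExtractionResult:
    table: pd.DataFrame
    n_dropped: int


def _run_builtin(node: StageNode, columns: dict[str, pd.Series]) -> pd.Series:
    if node.function == "pbw":
        sex_col, height_col = node.inputs[0], node.inputs[1]
        # Accept (sex, height) in either declared order.
        if columns[sex_col].dtype.kind in "fiu":
            sex_col, height_col = height_col, sex_col
        return pd.Series(
            [
                clinical_indices.pbw(s, h)
                for s, h in zip(columns[sex_col], columns[height_col])
            ],
            index=columns[sex_col].index,
        )
    if node.function == "ventilatory_ratio":
        ve, pco2, vt, pbw_col = (columns[name] for name in node.inputs)
        return pd.Series(
            [
                clinical_indices.ventilatory_ratio(a, b, c, d)
                for a, b, c, d in zip(ve, pco2, vt, pbw_col)
            ],
            index=ve.index,
        )
    raise GraphValidationError(f"unknown builtin {node.function!r}")


def extract_features(graph: StageGraph, records: pd.DataFrame) -> FeatureExtractionResult:
    """Evaluate the stage graph over a table of Stage-0 sensor features.

    Rows with missing values in any source feature are dropped and counted.
    The output table contains exactly the graph's output features, in stage
    order.  Referentially transparent: same records and graph, same table.
    """
    missing_cols = [c for c in graph.source_features if c not in records.columns]
    if missing_cols:
        raise GraphValidationError(f"records lack source feature(s): {missing_cols}")
    frame = records.loc[:, list(graph.source_features)]
    complete = frame.dropna()
    n_dropped = len(frame) - len(complete)
    columns: dict[str, pd.Series] = {name: complete[name] for name in graph.source_features}
    for stage in graph.stages:
        for node in stage:
            if node.kind == "bypass":
                columns[node.output] = columns[node.inputs[0]]
            elif node.kind == "builtin":
                columns[node.output] = _run_builtin(node, columns)
            else:
                env = {name: columns[name] for name in _expression_names(node.function)}
                columns[node.output] = pd.Series(
                    evaluate_expression(node.function, env), index=complete.index
                )
    table = pd.DataFrame({name: columns[name] for name in graph.output_features})
    return FeatureExtractionResult(table=table, n_dropped=n_dropped)


# ---------------------------------------------------------------------------
# Ensemble training, voting, selection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EnsembleSpec:
    members: tuple[str, ...] = ("svm", "xgb", "mlp")
    train_fraction: float = 0.8
    fusion: str = "majority_vote"  # or "averaging"
    metric: str = "auc"
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("at least one ensemble member required")
        unknown = set(self.members) - set(MEMBER_KINDS)
        if unknown:
            raise ValueError(f"unknown member kind(s): {sorted(unknown)}")
        if not 0 < self.train_fraction < 1:
            raise ValueError(f"train_fraction must be in (0, 1), got {self.train_fraction}")
        if self.fusion not in ("majority_vote", "averaging"):
            raise ValueError(f"unknown fusion rule {self.fusion!r}")
        if self.metric not in METRICS:
            raise ValueError(f"unknown metric {self.metric!r}; choose from {METRICS}")


@dataclass
class EnsembleResult:
    models: dict
    member_metrics: dict
    ensemble_metric: float
    manifest: dict
    declaration_order: tuple[str, ...]


def _make_member(kind: str, seed: int, hyperparameters: dict):
    params = dict(hyperparameters.get(kind, {}))
    if kind == "svm":
        return make_pipeline(
            StandardScaler(), SVC(probability=True, random_state=seed, **params)
        )
    if kind == "xgb":
        params.setdefault("n_estimators", 200)
        params.setdefault("verbosity", 0)
        return XGBClassifier(random_state=seed, **params)
    if kind == "mlp":
        params.setdefault("max_iter", 800)
        return make_pipeline(StandardScaler(), MLPClassifier(random_state=seed, **params))
    raise ValueError(f"unknown member kind {kind!r}")


def _score(metric: str, y_true: np.ndarray, y_pred: np.ndarray, y_prob: np.ndarray) -> float:
    if metric == "auc":
        return float(roc_auc_score(y_true, y_prob))
    if metric == "f1":
        return float(f1_score(y_true, y_pred))
    if metric == "precision":
        return float(precision_score(y_true, y_pred, zero_division=0))
    return float(accuracy_score(y_true, y_pred))


def majority_vote(predictions: Sequence[Sequence[int]] | np.ndarray) -> np.ndarray:
    """Modal label per row of an (n_samples, n_members) prediction matrix.

    Ties (possible with an even member count) break toward the positive
    class with a warning — conservatively treating a split vote as ARDS.
    """
    votes = np.asarray(predictions)
    if votes.ndim == 1:
        votes = votes.reshape(1, -1)
    if votes.size == 0 or votes.shape[1] == 0:
        raise ValueError("at least one member prediction per row is required")
    positive = votes.sum(axis=1)
    m = votes.shape[1]
    ties = positive * 2 == m
    if ties.any():
        warnings.warn(
            f"{int(ties.sum())} tied vote(s) with {m} members broken toward the "
            "positive class",
            stacklevel=2,
        )
    return (positive * 2 >= m).astype(int)


def train_ensemble(
    table: pd.DataFrame, spec: EnsembleSpec, seed: int = 0
) -> EnsembleResult:
    """Fit the member classifiers and score them and the fused rule.

    The feature matrix is every numeric non-label column of ``table``; the
    split is stratified with ``train_fraction`` of rows for training.
    Deterministic under a fixed seed.  Raises ``ValueError`` when the table
    holds a single class.
    """
    if "label" not in table.columns:
        raise ValueError("table must contain a 'label' column")
    y = table["label"].to_numpy().astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("training table must contain both classes")
    features = [
        c for c in table.columns if c != "label" and table[c].dtype.kind in "fiu"
    ]
    X = table[features].to_numpy(dtype=float)
    X_train, X_val, y_train, y_val = train_test_split(
        X, y, train_size=spec.train_fraction, random_state=seed, stratify=y
    )
    models, member_metrics = {}, {}
    val_probs, val_preds = [], []
    for kind in spec.members:
        model = _make_member(kind, seed, spec.hyperparameters)
        model.fit(X_train, y_train)
        prob = model.predict_proba(X_val)[:, 1]
        pred = (prob >= 0.5).astype(int)
        models[kind] = model
        member_metrics[kind] = _score(spec.metric, y_val, pred, prob)
        val_probs.append(prob)
        val_preds.append(pred)
    # Label-type metrics score the fused labels; AUC needs a continuous
    # score, so it always uses the averaged member probabilities (a
    # three-member vote fraction only takes four values).
    fused_prob = np.column_stack(val_probs).mean(axis=1)
    if spec.fusion == "majority_vote":
        fused_pred = majority_vote(np.column_stack(val_preds))
    else:
        fused_pred = (fused_prob >= 0.5).astype(int)
    ensemble_metric = _score(spec.metric, y_val, fused_pred, fused_prob)
    manifest = {
        "seed": seed,
        "train_fraction": spec.train_fraction,
        "n_train": int(len(y_train)),
        "n_validation": int(len(y_val)),
        "members": list(spec.members),
        "fusion": spec.fusion,
        "metric": spec.metric,
        "features": features,
        "hyperparameters": {k: dict(spec.hyperparameters.get(k, {})) for k in spec.members},
    }
    return EnsembleResult(
        models=models,
        member_metrics=member_metrics,
        ensemble_metric=ensemble_metric,
        manifest=manifest,
        declaration_order=tuple(spec.members),
    )


def select_best(result: EnsembleResult, metric: Optional[str] = None) -> str:
    """Member with the best recorded metric; declaration order breaks ties."""
    requested = metric or result.manifest.get("metric")
    if requested != result.manifest.get("metric"):
        raise ValueError(
            f"metric {requested!r} was not computed (recorded: "
            f"{result.manifest.get('metric')!r})"
        )
    best, best_value = None, -np.inf
    for kind in result.declaration_order:
        value = result.member_metrics[kind]
        if value > best_value:
            best, best_value = kind, value
    return best
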