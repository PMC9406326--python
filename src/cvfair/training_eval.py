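"""Stratified 10-fold training of the paired networks and metric extraction.

Both structures are trained on byte-identical fold splits and batch orders
(the fairness contract): the split and shuffling randomness derives only
from the training configuration, never from the model. Evaluation treats
the abnormal class (label 1) as positive and extracts F1, Precision,
Recall/Sensitivity, Accuracy and Specificity from the fold confusion
matrix.

The optimizer is ADAM with a complex correction: for a complex parameter
the first moments are tracked per component while the second-moment
accumulator is shared between the two components and driven by the squared
gradient modulus ``gR^2 + gI^2``, with the usual bias corrections. Real
parameters fall back to standard ADAM.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .architectures import ArchitectureSpec, build_network, Network
from .complex_core import Parameter
from .domain_transform import normalize_image
from .exceptions import DegenerateInputError, StratificationError, TrainingError

__all__ = [
    "TrainingConfig",
    "FoldMetricTable",
    "AdamState",
    "kfold_split",
    "complex_adam_step",
    "train_fold",
    "confusion_metrics",
    "evaluate_scores",
    "run_experiment",
]

METRIC_COLUMNS = ("F1", "Precision", "Recall", "Accuracy", "Specificity")


@dataclass
class TrainingConfig:
    """Hyperparameters of one cross-validated training run."""

    learning_rate: float = 0.001
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1e-8
    epochs: int = 15
    batch_size: int = 16
    k: int = 10
    seed: int = 0
    loss: str = "cross_entropy"

    def __post_init__(self):
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.learning_rate < 0:
            raise ValueError("learning rate must be non-negative")


@dataclass
class FoldMetricTable:
    """Per-fold metric table (k rows x 5 metrics) for one dataset/structure."""

    df: pd.DataFrame
    dataset_id: str = ""
    structure_id: str = ""

    def __post_init__(self):
        missing = [c for c in METRIC_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"missing metric columns: {missing}")
        self.df = self.df[list(METRIC_COLUMNS)].astype(float)

    @classmethod
    def from_rows(cls, rows: list[dict], dataset_id: str = "",
                  structure_id: str = "") -> "FoldMetricTable":
        df = pd.DataFrame(rows, index=pd.RangeIndex(1, len(rows) + 1, name="fold"))
        return cls(df, dataset_id, structure_id)

    @classmethod
    def from_csv(cls, path, dataset_id: str = "", structure_id: str = "") -> "FoldMetricTable":
        df = pd.read_csv(path)
        if "fold" in df.columns:
            df = df.set_index("fold")
        return cls(df, dataset_id, structure_id)

    def to_csv(self, path) -> None:
        self.df.rename_axis("fold").to_csv(path)

    def means(self) -> pd.Series:
        """Recomputed summary row (never stored)."""
        return self.df.mean()

    def column(self, metric: str) -> np.ndarray:
        return self.df[metric].to_numpy()

    @property
    def n_folds(self) -> int:
        return len(self.df)


def kfold_split(manifest_or_labels, k: int = 10, seed: int = 0):
    """Stratified k-fold partition -> list of (train_idx, val_idx).

    Accepts a DatasetManifest or a plain label array. Every record appears
    in exactly one validation fold and per-fold class ratios are within one
    item of the global ratio (sklearn stratification).
    """
    labels = np.asarray(getattr(manifest_or_labels, "labels", manifest_or_labels))
    counts = np.bincount(labels, minlength=2)
    if counts.min() < k:
        raise StratificationError(
            f"smallest class has {counts.min()} members, fewer than k={k}"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [(tr, va) for tr, va in skf.split(np.zeros(len(labels)), labels)]


@dataclass
class AdamState:
    """Optimizer state; second moments are shared per complex parameter."""

    t: int = 0
    m_r: list = field(default_factory=list)
    m_i: list = field(default_factory=list)
    v: list = field(default_factory=list)

    @classmethod
    def for_params(cls, params: list[Parameter]) -> "AdamState":
        st = cls()
        for p in params:
            st.m_r.append(np.zeros_like(p.real))
            st.m_i.append(None if p.imag is None else np.zeros_like(p.imag))
            st.v.append(np.zeros_like(p.real))
        return st


def complex_adam_step(params: list[Parameter], grads=None,
                      state: AdamState | None = None,
                      config: TrainingConfig | None = None) -> AdamState:
    """One ADAM step over ``params`` (in place); returns the updated state.

    ``grads`` may be omitted, in which case each parameter's accumulated
    ``grad_real``/``grad_imag`` is used. For complex parameters the shared
    second moment is driven by ``gR^2 + gI^2``.
    """
    config = config or TrainingConfig()
    if state is None:
        state = AdamState.for_params(params)
    b1, b2, eps, lr = config.beta1, config.beta2, config.epsilon, config.learning_rate
    state.t += 1
    t = state.t
    for idx, p in enumerate(params):
        if grads is None:
            g_r, g_i = p.grad_real, p.grad_imag
        else:
            g = grads[idx]
            g_r, g_i = (g if isinstance(g, tuple) else (g, None))
        if not np.all(np.isfinite(g_r)) or (g_i is not None and not np.all(np.isfinite(g_i))):
            raise TrainingError("non-finite gradient encountered")
        state.m_r[idx] = b1 * state.m_r[idx] + (1 - b1) * g_r
        if p.is_complex:
            state.m_i[idx] = b1 * state.m_i[idx] + (1 - b1) * g_i
            sq = g_r * g_r + g_i * g_i  # squared gradient modulus
        else:
            sq = g_r * g_r
        state.v[idx] = b2 * state.v[idx] + (1 - b2) * sq
        m_hat_r = state.m_r[idx] / (1 - b1**t)
        v_hat = state.v[idx] / (1 - b2**t)
        denom = np.sqrt(v_hat) + eps
        p.real -= lr * m_hat_r / denom
        if p.is_complex:
            m_hat_i = state.m_i[idx] / (1 - b1**t)
            p.imag -= lr * m_hat_i / denom
    return state


def _softmax(scores: np.ndarray) -> np.ndarray:
    z = scores - scores.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _cross_entropy(scores: np.ndarray, y: np.ndarray):
    """Mean cross-entropy over softmax of the class scores, and its gradient."""
    p = _softmax(scores)
    n = len(y)
    eps = 1e-12
    loss = -np.log(p[np.arange(n), y] + eps).mean()
    grad = p.copy()
    grad[np.arange(n), y] -= 1.0
    return loss, grad / n


def train_fold(model: Network, train_data, config: TrainingConfig,
               rng: np.random.Generator | None = None):
    """Mini-batch cross-entropy training; returns the per-epoch loss trace.

    ``train_data`` is ``(X, y)`` with X of shape (N, C, H, W). Fully
    reproducible: batch order derives from ``rng`` (or ``config.seed``).
    """
    X, y = train_data
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(X) == 0:
        raise DegenerateInputError("empty training data")
    rng = rng or np.random.default_rng(config.seed)
    params = model.parameters()
    state = AdamState.for_params(params)
    trace = []
    for _ in range(config.epochs):
        order = rng.permutation(len(X))
        epoch_loss = 0.0
        for start in range(0, len(X), config.batch_size):
            idx = order[start : start + config.batch_size]
            scores = model.forward(X[idx])
            loss, gscores = _cross_entropy(scores, y[idx])
            if not np.isfinite(loss):
                raise TrainingError("training diverged: non-finite loss")
            epoch_loss += loss * len(idx)
            if config.learning_rate > 0:
                model.zero_grad()
                model.backward(gscores)
                state = complex_adam_step(params, state=state, config=config)
        trace.append(epoch_loss / len(X))
    return model, trace


def confusion_metrics(TP: int, FP: int, TN: int, FN: int) -> dict:
    """The five study metrics from confusion counts (positive = abnormal).

    Zero-denominator ratios are reported as 0.0 and listed under the
    ``flagged`` key; an all-zero confusion matrix is a degenerate input.
    """
    if min(TP, FP, TN, FN) < 0:
        raise ValueError("confusion counts must be non-negative")
    total = TP + FP + TN + FN
    if total == 0:
        raise DegenerateInputError("all confusion counts are zero")
    flagged = []

    def ratio(num, den, name):
        if den == 0:
            flagged.append(name)
            return 0.0
        return num / den

    precision = ratio(TP, TP + FP, "Precision")
    recall = ratio(TP, TP + FN, "Recall")
    f1 = ratio(2 * precision * recall, precision + recall, "F1")
    accuracy = (TP + TN) / total
    specificity = ratio(TN, TN + FP, "Specificity")
    if flagged:
        warnings.warn(f"zero-denominator metrics reported as 0: {flagged}",
                      RuntimeWarning, stacklevel=2)
    return {"F1": f1, "Precision": precision, "Recall": recall,
            "Accuracy": accuracy, "Specificity": specificity, "flagged": flagged}


def evaluate_scores(scores: np.ndarray, y: np.ndarray) -> dict:
    """Confusion-matrix metrics from class scores (argmax decision)."""
    pred = scores.argmax(axis=1)
    y = np.asarray(y)
    TP = int(np.sum((pred == 1) & (y == 1)))
    FP = int(np.sum((pred == 1) & (y == 0)))
    TN = int(np.sum((pred == 0) & (y == 0)))
    FN = int(np.sum((pred == 0) & (y == 1)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        out = confusion_metrics(TP, FP, TN, FN)
    # decomposition identity: accuracy is the prevalence-weighted mean of
    # sensitivity and specificity (guards the extraction code on every fold)
    P, N = TP + FN, TN + FP
    if P > 0 and N > 0:
        lhs = out["Accuracy"]
        rhs = (P * out["Recall"] + N * out["Specificity"]) / (P + N)
        assert abs(lhs - rhs) < 1e-12
    return out


def _prepare_images(manifest) -> np.ndarray:
    """Stack manifest images as a normalized (N, C, H, W) float array."""
    out = []
    for img, _ in manifest.records:
        px = normalize_image(np.asarray(img, dtype=float)).pixels  # (H, W, C)
        out.append(np.moveaxis(px, 2, 0))
    return np.stack(out) if out else np.empty((0, 0, 0, 0))


def run_experiment(manifest, cspec: ArchitectureSpec, rspec: ArchitectureSpec,
                   config: TrainingConfig | None = None):
    """Train both structures across stratified folds on identical splits.

    Returns ``(complex_table, real_table)``: one FoldMetricTable per
    structure with ``config.k`` rows, positive class = abnormal (label 1).
    """
    config = config or TrainingConfig()
    X = _prepare_images(manifest)
    y = manifest.labels
    splits = kfold_split(y, k=config.k, seed=config.seed)
    rows = {"complex": [], "real": []}
    dataset_id = getattr(getattr(manifest, "profile", None), "name", "")
    for fold_id, (tr, va) in enumerate(splits):
        for name, spec in (("complex", cspec), ("real", rspec)):
            model = build_network(spec, seed=config.seed * 1000 + fold_id)
            # identical batch-order stream for both structures
            batch_rng = np.random.default_rng(
                np.random.SeedSequence([config.seed, fold_id, 3])
            )
            model, _ = train_fold(model, (X[tr], y[tr]), config, rng=batch_rng)
            metrics = evaluate_scores(model.forward(X[va]), y[va])
            rows[name].append({k: metrics[k] for k in METRIC_COLUMNS})
    ctab = FoldMetricTable.from_rows(rows["complex"], dataset_id, "complex")
    rtab = FoldMetricTable.from_rows(rows["real"], dataset_id, "real")
    return ctab, rtab
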