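"""Dual-branch PointNet severity regressor.

Two parallel PointNet branches embed the rest and peak point clouds: a
shared per-point MLP (Dense + BatchNorm + ReLU stacks applied identically to
every point) lifts each 3-D point to feature space, and a symmetric max
aggregation pools the point features into one global descriptor per cloud.
No learned input/feature transforms are used — the clouds arrive already
Procrustes-aligned, which plays the role of a canonicalising T-net.

The two global descriptors are concatenated with the one-hot expression
code and passed through a fully connected head (Dense + BatchNorm + ReLU,
linear output) that emits one score per expression.  The prediction for a
sample is the score at its own expression slot, and the training loss is
the half mean squared error of those selected scores.  Optimisation is
plain Adam over shuffled mini-batches.

The estimator follows scikit-learn conventions (``fit`` / ``predict`` /
``get_params``) and accepts lists of :class:`palsy3d.dataset.Sample`.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.metrics import mean_squared_error, r2_score
from sklearn.utils.validation import check_is_fitted

from .capture import EXPRESSIONS
from .dataset import N_EXPRESSIONS, Sample
from .nn import (
    DTYPE,
    Adam,
    BatchNorm,
    Dense,
    ReLU,
    Sequential,
    max_pool_backward,
    max_pool_points,
)

GRADE_MIN, GRADE_MAX = 1, 5


class TrainingError(RuntimeError):
    """Raised when optimisation diverges; carries the history so far."""

    def __init__(self, message: str, history: pd.DataFrame):
        super().__init__(message)
        self.history = history


@dataclass
class NetworkConfig:
    """Architecture and optimisation settings.

    The default sizing is the canonical PointNet: per-point MLP
    3→64→64→128→1024 per branch, head 2053→512→256→5.  ``desk()`` returns a
    reduced configuration sized for CPU-only runs (per-point MLP
    3→64→64→128, head 261→128→64→5, 512-point subsampling) that preserves
    the architecture and training protocol at a fraction of the cost.
    """

    branch_widths: tuple[int, ...] = (64, 64, 128, 1024)
    head_widths: tuple[int, ...] = (512, 256)
    epochs: int = 200
    batch_size: int = 8
    learning_rate: float = 1e-3
    betas: tuple[float, float] = (0.9, 0.999)
    lr_decay: float = 0.3
    lr_milestones: tuple[float, ...] = (0.5, 0.8)
    n_points: int | None = None
    resample_points: bool = False
    eval_subsets: int = 1
    train_jitter_fraction: float = 0.02
    loss_mode: str = "masked"
    seed: int = 0

    @classmethod
    def desk(cls, epochs: int = 100, seed: int = 0) -> "NetworkConfig":
        return cls(
            branch_widths=(64, 64, 128),
            head_widths=(128, 64),
            epochs=epochs,
            n_points=512,
            seed=seed,
        )


def samples_to_arrays(
    samples: list[Sample],
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Stack samples into (rest, peak, expression-index, grade) arrays."""
    rest = np.stack([s.rest_points for s in samples]).astype(DTYPE)
    peak = np.stack([s.peak_points for s in samples]).astype(DTYPE)
    expr = np.array([s.expression_index for s in samples], dtype=np.int64)
    grade = np.array([s.target_grade for s in samples], dtype=DTYPE)
    return rest, peak, expr, grade


def half_mse_loss(
    predictions: np.ndarray, targets: np.ndarray, expression_idx: np.ndarray
) -> tuple[float, np.ndarray]:
    """Half mean squared error on each sample's own expression slot.

    Returns the scalar loss and its gradient with respect to the full
    ``(batch, 5)`` prediction matrix (zero outside the selected slots).
    """
    n = predictions.shape[0]
    rows = np.arange(n)
    selected = predictions[rows, expression_idx]
    err = selected - targets
    loss = 0.5 * float(np.mean(err**2))
    grad = np.zeros_like(predictions)
    grad[rows, expression_idx] = err / n
    return loss, grad


def half_mse_loss_all_slots(
    predictions: np.ndarray, targets: np.ndarray, expression_idx: np.ndarray
) -> tuple[float, np.ndarray]:
    """Alternative loss supervising all five slots with the replicated target."""
    n = predictions.shape[0]
    err = predictions - targets[:, None]
    loss = 0.5 * float(np.mean(err**2))
    return loss, err / err.size


class PointNetGradeRegressor(RegressorMixin, BaseEstimator):
    """Severity-grade regressor over (rest cloud, peak cloud, expression).

    Parameters mirror :class:`NetworkConfig`; ``fit`` accepts a list of
    :class:`~palsy3d.dataset.Sample` (targets taken from the samples when
    ``y`` is omitted).  Fitted attributes carry the trailing underscore:
    ``branch1_``, ``branch2_``, ``head_`` (layer stacks), ``history_``
    (per-epoch RMSE and loss), ``point_indices_`` (subsampling), and
    ``iterations_per_epoch_``.
    """

    def __init__(
        self,
        branch_widths: tuple[int, ...] = (64, 64, 128, 1024),
        head_widths: tuple[int, ...] = (512, 256),
        epochs: int = 200,
        batch_size: int = 8,
        learning_rate: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        lr_decay: float = 0.3,
        lr_milestones: tuple[float, ...] = (0.5, 0.8),
        n_points: int | None = None,
        resample_points: bool = False,
        eval_subsets: int = 1,
        train_jitter_fraction: float = 0.02,
        loss_mode: str = "masked",
        seed: int = 0,
    ):
        self.branch_widths = branch_widths
        self.head_widths = head_widths
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.betas = betas
        self.lr_decay = lr_decay
        self.lr_milestones = lr_milestones
        self.n_points = n_points
        self.resample_points = resample_points
        self.eval_subsets = eval_subsets
        self.train_jitter_fraction = train_jitter_fraction
        self.loss_mode = loss_mode
        self.seed = seed

    @classmethod
    def from_config(cls, config: NetworkConfig) -> "PointNetGradeRegressor":
        return cls(**asdict(config))

    # ------------------------------------------------------------------
    # architecture
    # ------------------------------------------------------------------
    def _build(self, rng: np.random.Generator) -> None:
        def mlp(widths: tuple[int, ...], n_in: int) -> Sequential:
            layers: list = []
            for w in widths:
                layers += [Dense(n_in, w, rng), BatchNorm(w), ReLU()]
                n_in = w
            return Sequential(layers)

        self.branch1_ = mlp(tuple(self.branch_widths), 3)
        self.branch2_ = mlp(tuple(self.branch_widths), 3)
        global_dim = 2 * self.branch_widths[-1] + N_EXPRESSIONS
        head_layers: list = []
        n_in = global_dim
        for w in self.head_widths:
            head_layers += [Dense(n_in, w, rng), BatchNorm(w), ReLU()]
            n_in = w
        head_layers.append(Dense(n_in, N_EXPRESSIONS, rng))
        self.head_ = Sequential(head_layers)

    def _embed(
        self, branch: Sequential, cloud: np.ndarray, training: bool
    ) -> tuple[np.ndarray, np.ndarray]:
        b, n, _ = cloud.shape
        feats = branch.forward(cloud.reshape(b * n, 3), training)
        feats = feats.reshape(b, n, -1)
        return max_pool_points(feats)

    def _forward(
        self,
        rest: np.ndarray,
        peak: np.ndarray,
        expr: np.ndarray,
        training: bool,
    ) -> tuple[np.ndarray, dict]:
        onehot = np.zeros((len(expr), N_EXPRESSIONS), dtype=DTYPE)
        onehot[np.arange(len(expr)), expr] = 1.0
        g1, arg1 = self._embed(self.branch1_, rest, training)
        g2, arg2 = self._embed(self.branch2_, peak, training)
        concat = np.concatenate([g1, g2, onehot], axis=1)
        out = self.head_.forward(concat, training)
        cache = {"arg1": arg1, "arg2": arg2, "n_points": rest.shape[1]}
        return out, cache

    def _backward(self, d_out: np.ndarray, cache: dict) -> None:
        d_concat = self.head_.backward(d_out)
        f = self.branch_widths[-1]
        d_g1, d_g2 = d_concat[:, :f], d_concat[:, f : 2 * f]
        n = cache["n_points"]
        for branch, d_g, arg in (
            (self.branch1_, d_g1, cache["arg1"]),
            (self.branch2_, d_g2, cache["arg2"]),
        ):
            d_feats = max_pool_backward(d_g, arg, n)
            b = d_feats.shape[0]
            branch.backward(d_feats.reshape(b * n, -1))

    def _params_and_grads(self) -> list[tuple[np.ndarray, np.ndarray]]:
        out: list[tuple[np.ndarray, np.ndarray]] = []
        for module in (self.branch1_, self.branch2_, self.head_):
            out.extend(module.params_and_grads())
        return out

    # ------------------------------------------------------------------
    # training
    # ------------------------------------------------------------------
    def fit(self, X, y=None) -> "PointNetGradeRegressor":
        rest, peak, expr, grades = self._coerce(X, y)
        if len(rest) == 0:
            raise ValueError("empty training set")
        if self.loss_mode not in ("masked", "all"):
            raise ValueError("loss_mode must be masked|all")
        loss_fn = half_mse_loss if self.loss_mode == "masked" else half_mse_loss_all_slots

        rng = np.random.default_rng(self.seed)
        n_total_points = rest.shape[1]
        subsample = self.n_points is not None and self.n_points < n_total_points
        if subsample:
            # several fixed evaluation subsets: predictions are averaged over
            # them, shrinking the point-selection noise of the max aggregation
            k = max(1, int(self.eval_subsets))
            self.point_indices_ = np.stack(
                [
                    np.sort(rng.choice(n_total_points, self.n_points, replace=False))
                    for _ in range(k)
                ]
            )
        else:
            self.point_indices_ = np.arange(n_total_points)[None, :]
        resample = subsample and self.resample_points
        if not resample:
            rest = rest[:, self.point_indices_[0]]
            peak = peak[:, self.point_indices_[0]]

        self._build(rng)
        optimizer = Adam(lr=self.learning_rate, betas=tuple(self.betas))
        n = len(rest)
        # fresh measurement jitter per iteration: trains the network under the
        # same noise process the evaluation clouds carry, instead of letting it
        # memorize the finite set of frozen noise draws
        centered = rest - rest.mean(axis=1, keepdims=True)
        jitter_sigma = (
            self.train_jitter_fraction
            * np.sqrt((centered**2).sum(axis=2).mean(axis=1))[:, None, None]
        ).astype(DTYPE)
        self.iterations_per_epoch_ = int(np.ceil(n / self.batch_size))

        milestones = sorted(int(f * self.epochs) for f in self.lr_milestones)
        history = []
        for epoch in range(self.epochs):
            optimizer.lr = self.learning_rate * self.lr_decay ** sum(
                epoch >= m for m in milestones
            )
            if resample:
                # fresh point subset every epoch: the network sees the whole
                # mesh over training instead of one fixed decimation
                pts = np.sort(rng.choice(n_total_points, self.n_points, replace=False))
                rest_ep, peak_ep = rest[:, pts], peak[:, pts]
            else:
                rest_ep, peak_ep = rest, peak
            order = rng.permutation(n)
            sq_err_sum, loss_sum, n_seen = 0.0, 0.0, 0
            for it in range(self.iterations_per_epoch_):
                idx = order[it * self.batch_size : (it + 1) * self.batch_size]
                rest_b, peak_b = rest_ep[idx], peak_ep[idx]
                if self.train_jitter_fraction > 0:
                    sig = jitter_sigma[idx]
                    rest_b = rest_b + (rng.standard_normal(rest_b.shape, dtype=DTYPE) * sig)
                    peak_b = peak_b + (rng.standard_normal(peak_b.shape, dtype=DTYPE) * sig)
                out, cache = self._forward(rest_b, peak_b, expr[idx], True)
                loss, d_out = loss_fn(out, grades[idx], expr[idx])
                if not np.isfinite(loss):
                    raise TrainingError(
                        f"non-finite loss at epoch {epoch}, iteration {it}",
                        pd.DataFrame(history, columns=["epoch", "rmse", "loss"]),
                    )
                sel = out[np.arange(len(idx)), expr[idx]]
                sq_err_sum += float(np.sum((sel - grades[idx]) ** 2))
                loss_sum += loss * len(idx)
                n_seen += len(idx)
                self._backward(d_out.astype(DTYPE), cache)
                optimizer.step(self._params_and_grads())
            history.append((epoch, np.sqrt(sq_err_sum / n_seen), loss_sum / n_seen))
        self.history_ = pd.DataFrame(history, columns=["epoch", "rmse", "loss"])
        self.n_features_in_ = 3
        return self

    # ------------------------------------------------------------------
    # inference
    # ------------------------------------------------------------------
    def _coerce(self, X, y=None):
        if isinstance(X, (list, tuple)) and len(X) and isinstance(X[0], Sample):
            rest, peak, expr, grades = samples_to_arrays(list(X))
        elif isinstance(X, tuple) and len(X) == 3:
            rest, peak, expr = (np.asarray(a) for a in X)
            rest, peak = rest.astype(DTYPE), peak.astype(DTYPE)
            grades = None
        else:
            raise ValueError(
                "X must be a list of Sample or a (rest, peak, expression) tuple"
            )
        if y is not None:
            grades = np.asarray(y, dtype=DTYPE)
        return rest, peak, expr, grades

    def predict_scores(self, X) -> np.ndarray:
        """Full length-5 score vector for each input sample.

        When clouds were subsampled at fit time, scores are averaged over the
        fitted evaluation subsets, which damps the point-selection noise of
        the max aggregation.
        """
        check_is_fitted(self, "head_")
        rest, peak, expr, _ = self._coerce(X)
        subsets = np.atleast_2d(self.point_indices_)
        if rest.shape[1] == subsets.shape[1]:
            subsets = [slice(None)]  # already at model point count
        out = np.zeros((len(rest), N_EXPRESSIONS), dtype=np.float64)
        chunk = 256
        for pts in subsets:
            r, p = rest[:, pts], peak[:, pts]
            for i in range(0, len(rest), chunk):
                sl = slice(i, i + chunk)
                scores, _ = self._forward(r[sl], p[sl], expr[sl], False)
                out[sl] += scores
        return (out / len(subsets)).astype(DTYPE)

    def predict(self, X) -> np.ndarray:
        """Predicted severity grade: the score at each sample's expression slot."""
        rest, peak, expr, _ = self._coerce(X)
        scores = self.predict_scores(X)
        return scores[np.arange(len(scores)), expr].astype(np.float64)

    # ------------------------------------------------------------------
    # persistence
    # ------------------------------------------------------------------
    def save(self, path: str | Path) -> Path:
        """Write a checkpoint (npz weights + embedded JSON config)."""
        check_is_fitted(self, "head_")
        path = Path(path)
        arrays: dict[str, np.ndarray] = {}
        for name, module in (
            ("branch1", self.branch1_),
            ("branch2", self.branch2_),
            ("head", self.head_),
        ):
            for i, layer in enumerate(module.layers):
                if isinstance(layer, Dense):
                    arrays[f"{name}.{i}.W"] = layer.W
                    arrays[f"{name}.{i}.b"] = layer.b
                elif isinstance(layer, BatchNorm):
                    arrays[f"{name}.{i}.gamma"] = layer.gamma
                    arrays[f"{name}.{i}.beta"] = layer.beta
                    arrays[f"{name}.{i}.rmean"] = layer.running_mean
                    arrays[f"{name}.{i}.rvar"] = layer.running_var
        arrays["point_indices"] = self.point_indices_
        arrays["config"] = np.frombuffer(
            json.dumps(self.get_params()).encode(), dtype=np.uint8
        )
        np.savez_compressed(path, **arrays)
        return path

    @classmethod
    def load(cls, path: str | Path) -> "PointNetGradeRegressor":
        data = np.load(Path(path))
        params = json.loads(bytes(data["config"]).decode())
        for key in ("branch_widths", "head_widths", "betas", "lr_milestones"):
            params[key] = tuple(params[key])
        est = cls(**params)
        est._build(np.random.default_rng(est.seed))
        for name, module in (
            ("branch1", est.branch1_),
            ("branch2", est.branch2_),
            ("head", est.head_),
        ):
            for i, layer in enumerate(module.layers):
                if isinstance(layer, Dense):
                    layer.W = data[f"{name}.{i}.W"]
                    layer.b = data[f"{name}.{i}.b"]
                elif isinstance(layer, BatchNorm):
                    layer.gamma = data[f"{name}.{i}.gamma"]
                    layer.beta = data[f"{name}.{i}.beta"]
                    layer.running_mean = data[f"{name}.{i}.rmean"]
                    layer.running_var = data[f"{name}.{i}.rvar"]
        est.point_indices_ = data["point_indices"]
        est.history_ = pd.DataFrame(columns=["epoch", "rmse", "loss"])
        est.iterations_per_epoch_ = 0
        return est


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    """Per-expression accuracy under the |error| < threshold rule, confusion
    matrices over rounded 1-5 grade bins, and overall MSE / R²."""

    accuracy: dict[str, float]
    confusion: dict[str, np.ndarray]
    n_samples: dict[str, int]
    mse: float
    r2: float
    threshold: float = 0.5

    @property
    def min_accuracy(self) -> float:
        return min(self.accuracy.values())

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "mse": self.mse,
            "r2": self.r2,
            "accuracy": self.accuracy,
            "n_samples": self.n_samples,
            "confusion": {k: v.tolist() for k, v in self.confusion.items()},
        }


def evaluate(
    model: PointNetGradeRegressor, samples: list[Sample], threshold: float = 0.5
) -> EvaluationReport:
    """Score a model on held-out samples.

    A prediction is correct when |prediction - grade| < threshold (strictly:
    an error of exactly 0.5 counts as wrong).  Confusion matrices bin the
    predictions by rounding to the nearest integer grade, clipped to 1-5,
    with rows indexed by the (rounded) true grade; expressions absent from
    the test set are simply not reported.
    """
    if not samples:
        raise ValueError("empty evaluation set")
    preds = model.predict(samples)
    targets = np.array([s.target_grade for s in samples])
    expr = np.array([s.expression_index for s in samples])

    accuracy: dict[str, float] = {}
    confusion: dict[str, np.ndarray] = {}
    n_samples: dict[str, int] = {}
    for e, expression in enumerate(EXPRESSIONS):
        mask = expr == e
        if not mask.any():
            continue
        p, t = preds[mask], targets[mask]
        accuracy[expression.value] = float(np.mean(np.abs(p - t) < threshold))
        cm = np.zeros((5, 5), dtype=np.int64)
        p_bin = np.clip(np.round(p), GRADE_MIN, GRADE_MAX).astype(int)
        t_bin = np.clip(np.round(t), GRADE_MIN, GRADE_MAX).astype(int)
        for tb, pb in zip(t_bin, p_bin):
            cm[tb - 1, pb - 1] += 1
        confusion[expression.value] = cm
        n_samples[expression.value] = int(mask.sum())
    return EvaluationReport(
        accuracy=accuracy,
        confusion=confusion,
        n_samples=n_samples,
        mse=float(mean_squared_error(targets, preds)),
        r2=float(r2_score(targets, preds)),
        threshold=threshold,
    )
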