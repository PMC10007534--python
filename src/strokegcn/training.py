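"""Experiment harness: splits, training loop, metrics, repeated runs,
leave-one-out cross-validation and the with/without-racket comparison.

The experimental protocol mirrors the study design: stratified random
60/20/20 train/validation/test splits, 20 independent repetitions per
condition summarized as mean/max/min/SD, per-class precision/recall/F1
from the 4x4 confusion matrix, LOOCV summarized by an RMSE between one-hot
truth and predicted probability vectors, and a Welch two-sample t-test on
the per-run accuracies of the two input conditions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from . import autodiff as ad
from .dataset import CLASS_NAMES, TrialSet
from .graph import SkeletonGraph
from .network import (ModelConfig, ModelParams, model_forward,
                      preprocess_coords, sparse_cce_loss)

__all__ = [
    "SplitSpec",
    "TrainConfig",
    "ConfusionMatrix",
    "RunSummary",
    "LoocvResult",
    "stratified_split",
    "prepare_inputs",
    "train_model",
    "evaluate",
    "metrics",
    "repeated_runs",
    "loocv",
    "rmse_from_records",
    "compare_conditions",
    "welch_from_summary",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SplitSpec:
    """Stratified split fractions; default 60/20/20."""

    fractions: tuple[float, float, float] = (0.60, 0.20, 0.20)
    stratified: bool = True

    def __post_init__(self):
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings (not printed in the method description;
    package defaults)."""

    lr: float = 1e-3
    batch_size: int = 16
    epochs: int = 200
    patience: int = 20        # early stop on validation loss
    seed: int = 0


def stratified_split(ts: TrialSet, spec: SplitSpec,
                     rng: np.random.Generator) -> tuple[TrialSet, TrialSet, TrialSet]:
    """Random stratified partition; per class, floor(frac*n) trials go to
    train and validation and the remainder to test."""
    labels = ts.labels
    parts: tuple[list[int], list[int], list[int]] = ([], [], [])
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        if len(idx) < 3:
            raise ValueError(f"class {CLASS_NAMES[c]} has only {len(idx)} trials; "
                             "need at least 3 for a 3-way split")
        idx = rng.permutation(idx)
        n_train = int(np.floor(spec.fractions[0] * len(idx)))
        n_val = int(np.floor(spec.fractions[1] * len(idx)))
        parts[0].extend(idx[:n_train])
        parts[1].extend(idx[n_train:n_train + n_val])
        parts[2].extend(idx[n_train + n_val:])
    return tuple(ts[sorted(p)] for p in parts)  # type: ignore[return-value]


def prepare_inputs(ts: TrialSet, config: ModelConfig,
                   nf: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Preprocess (centre, rescale) each trial, then zero-pad to ``nf``."""
    processed = [preprocess_coords(t.coords, list(ts.marker_names), config)
                 for t in ts]
    nf = nf if nf is not None else max(p.shape[0] for p in processed)
    M = ts.n_markers
    X = np.zeros((len(ts), nf, M, 3))
    for i, p in enumerate(processed):
        X[i, :min(p.shape[0], nf)] = p[:nf]
    return X, ts.labels


@dataclass
class ConfusionMatrix:
    """4x4 counts, rows = true class, columns = predicted class."""

    counts: np.ndarray
    class_names: tuple[str, ...] = CLASS_NAMES

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.class_names)
        if self.counts.shape != (k, k):
            raise ValueError(f"confusion matrix must be {k}x{k}")
        if (self.counts < 0).any():
            raise ValueError("negative counts")

    @classmethod
    def from_predictions(cls, y_true, y_pred,
                         class_names=CLASS_NAMES) -> "ConfusionMatrix":
        k = len(class_names)
        counts = np.zeros((k, k), dtype=np.int64)
        for t, p in zip(np.asarray(y_true), np.asarray(y_pred)):
            counts[int(t), int(p)] += 1
        return cls(counts, class_names)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def tp(self) -> np.ndarray:
        return np.diag(self.counts)

    def fp(self) -> np.ndarray:
        return self.counts.sum(axis=0) - np.diag(self.counts)

    def fn(self) -> np.ndarray:
        return self.counts.sum(axis=1) - np.diag(self.counts)

    def as_percent(self) -> np.ndarray:
        """Row-normalized percentages (true-class conditional)."""
        row = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(row > 0, 100.0 * self.counts / row, 0.0)


def metrics(cm: ConfusionMatrix) -> dict:
    """Accuracy plus per-class precision/recall/F1 and one-vs-rest accuracy.

    Undefined 0/0 ratios are reported as 0 with a warning.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    tp, fp, fn = cm.tp(), cm.fp(), cm.fn()
    accuracy = float(np.trace(cm.counts)) / cm.total

    def safe_div(num, den, what):
        out = np.zeros_like(num, dtype=np.float64)
        ok = den > 0
        out[ok] = num[ok] / den[ok]
        if (~ok).any():
            log.warning("%s undefined (0/0) for class(es) %s; reported as 0",
                        what, [cm.class_names[i] for i in np.flatnonzero(~ok)])
        return out

    precision = safe_div(tp, tp + fp, "precision")
    recall = safe_div(tp, tp + fn, "recall")
    f1 = safe_div(2 * precision * recall, precision + recall, "F1")
    tn = cm.total - tp - fp - fn
    per_class_accuracy = (tp + tn) / cm.total
    return {
        "accuracy": accuracy,
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "per_class_accuracy": per_class_accuracy,
        "class_names": cm.class_names,
    }


# ---------------------------------------------------------------------------
# training loop


def _forward_loss(X, y, graph, params):
    pred = model_forward(X, graph, params)
    return pred, sparse_cce_loss(pred, y)


def train_model(train: TrialSet, val: TrialSet, graph: SkeletonGraph,
                model_cfg: ModelConfig | None = None,
                train_cfg: TrainConfig | None = None) -> tuple[ModelParams, dict]:
    """Adam training with early stopping on validation loss.

    Returns the best-validation-loss checkpoint and per-epoch curves.
    Raises ``FloatingPointError`` on divergence (non-finite loss).
    """
    model_cfg = model_cfg or ModelConfig()
    train_cfg = train_cfg or TrainConfig()
    if len(train) == 0 or len(val) == 0:
        raise ValueError("train and validation sets must be nonempty")
    rng = np.random.default_rng(train_cfg.seed)
    nf = max(train.nf, val.nf)
    Xtr, ytr = prepare_inputs(train, model_cfg, nf)
    Xva, yva = prepare_inputs(val, model_cfg, nf)
    params = ModelParams.init(rng, graph.n_nodes, model_cfg)
    opt = ad.Adam(params.as_list(), lr=train_cfg.lr)

    curves = {"train_loss": [], "train_acc": [], "val_loss": [], "val_acc": []}
    best = {"val_loss": np.inf, "state": params.copy_data(), "epoch": -1}
    n = len(train)
    for epoch in range(train_cfg.epochs):
        order = rng.permutation(n)
        ep_loss, ep_correct = 0.0, 0
        for start in range(0, n, train_cfg.batch_size):
            b = order[start:start + train_cfg.batch_size]
            pred, loss = _forward_loss(Xtr[b], ytr[b], graph, params)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"training diverged at epoch {epoch} (loss={loss.data})")
            opt.zero_grad()
            loss.backward()
            opt.step()
            ep_loss += float(loss.data) * len(b)
            ep_correct += int((pred.data.argmax(axis=1) == ytr[b]).sum())
        pred_va, loss_va = _forward_loss(Xva, yva, graph, params)
        va_loss = float(loss_va.data)
        va_acc = float((pred_va.data.argmax(axis=1) == yva).mean())
        curves["train_loss"].append(ep_loss / n)
        curves["train_acc"].append(ep_correct / n)
        curves["val_loss"].append(va_loss)
        curves["val_acc"].append(va_acc)
        if va_loss < best["val_loss"]:
            best = {"val_loss": va_loss, "state": params.copy_data(),
                    "epoch": epoch}
        elif epoch - best["epoch"] >= train_cfg.patience:
            log.info("early stop at epoch %d (best %d)", epoch, best["epoch"])
            break
    params.load_data(best["state"])
    curves["best_epoch"] = best["epoch"]
    return params, curves


def evaluate(params: ModelParams, test: TrialSet, graph: SkeletonGraph
             ) -> tuple[ConfusionMatrix, np.ndarray]:
    """Argmax predictions on a held-out set; returns the confusion matrix
    and the per-trial probability vectors."""
    X, y = prepare_inputs(test, params.config)
    probs = model_forward(X, graph, params).data
    cm = ConfusionMatrix.from_predictions(y, probs.argmax(axis=1),
                                          test.class_names)
    return cm, probs


# ---------------------------------------------------------------------------
# repeated runs and summaries


@dataclass
class RunSummary:
    """Mean/max/min/SD of metrics over repeated independent runs."""

    metric_names: list[str]
    values: np.ndarray          # runs x metrics (percent scale)
    excluded_runs: list[int] = field(default_factory=list)

    def table(self):
        import pandas as pd

        v = self.values
        return pd.DataFrame({
            "Mean": v.mean(axis=0), "Max": v.max(axis=0),
            "Min": v.min(axis=0), "SD": v.std(axis=0, ddof=1),
        }, index=self.metric_names)

    def accuracies(self) -> np.ndarray:
        return self.values[:, self.metric_names.index("accuracy")]


def repeated_runs(ts: TrialSet, graph: SkeletonGraph,
                  spec: SplitSpec | None = None,
                  model_cfg: ModelConfig | None = None,
                  train_cfg: TrainConfig | None = None,
                  k: int = 20, base_seed: int = 0) -> RunSummary:
    """``k`` independent split+train+evaluate cycles (default 20).

    Each run uses its own seed ``base_seed + run``.  Metrics are collected
    on the percent scale, overall and per class; divergent runs are
    excluded from the summary and flagged.
    """
    if k < 2:
        raise ValueError("need at least 2 runs for a summary")
    spec = spec or SplitSpec()
    model_cfg = model_cfg or ModelConfig()
    base_train = train_cfg or TrainConfig()
    names = (["accuracy"]
             + [f"accuracy_{c}" for c in CLASS_NAMES]
             + [f"precision_{c}" for c in CLASS_NAMES]
             + [f"recall_{c}" for c in CLASS_NAMES]
             + [f"f1_{c}" for c in CLASS_NAMES])
    rows, excluded = [], []
    for run in range(k):
        seed = base_seed + run
        rng = np.random.default_rng(seed)
        train, val, test = stratified_split(ts, spec, rng)
        try:
            params, _ = train_model(train, val, graph, model_cfg,
                                    replace(base_train, seed=seed))
        except FloatingPointError as err:
            log.warning("run %d diverged and was excluded: %s", run, err)
            excluded.append(run)
            continue
        cm, _ = evaluate(params, test, graph)
        m = metrics(cm)
        rows.append([100.0 * m["accuracy"], *(100.0 * m["per_class_accuracy"]),
                     *(100.0 * m["precision"]), *(100.0 * m["recall"]),
                     *(100.0 * m["f1"])])
    if not rows:
        raise RuntimeError("all runs diverged")
    return RunSummary(names, np.array(rows), excluded)


def rmse_from_records(records) -> float:
    """Entry-wise RMSE between one-hot truths and predicted probability
    vectors over all folds (the LOOCV summary statistic)."""
    sq = np.concatenate([(np.asarray(y) - np.asarray(p)) ** 2
                         for y, p in records])
    return float(np.sqrt(sq.mean()))


@dataclass
class LoocvResult:
    """Leave-one-out summary: RMSE between one-hot truth and predicted
    probability vectors, entry-wise over all folds."""

    rmse: float
    sd_fold_rmse: float
    n_folds: int
    records: list[tuple[np.ndarray, np.ndarray]]


def loocv(ts: TrialSet, graph: SkeletonGraph,
          model_cfg: ModelConfig | None = None,
          train_cfg: TrainConfig | None = None,
          val_fraction: float = 0.2) -> LoocvResult:
    """Leave-one-out cross-validation.

    For each trial, train on the remainder (with a stratified validation
    carve-out for early stopping) and record the one-hot truth ``y_i`` and
    predicted probability vector ``y_hat_i``.  MSE is the mean squared
    entry-wise difference; RMSE its square root.
    """
    if len(ts) < 4:
        raise ValueError("need at least 4 trials for LOOCV")
    model_cfg = model_cfg or ModelConfig()
    base_train = train_cfg or TrainConfig()
    k = len(CLASS_NAMES)
    records = []
    fold_rmse = []
    for i in range(len(ts)):
        rest = ts[[j for j in range(len(ts)) if j != i]]
        rng = np.random.default_rng(base_train.seed + i)
        spec = SplitSpec((1.0 - val_fraction, val_fraction, 0.0))
        train, val, _ = stratified_split(rest, spec, rng)
        try:
            params, _ = train_model(train, val, graph, model_cfg,
                                    replace(base_train, seed=base_train.seed + i))
        except FloatingPointError as err:
            log.warning("LOOCV fold %d diverged: %s", i, err)
            continue
        _, probs = evaluate(params, ts[[i]], graph)
        y = np.zeros(k)
        y[ts[i].label] = 1.0
        records.append((y, probs[0]))
        fold_rmse.append(float(np.sqrt(np.mean((y - probs[0]) ** 2))))
    if not records:
        raise RuntimeError("all LOOCV folds diverged")
    rmse = rmse_from_records(records)
    sd = float(np.std(fold_rmse, ddof=1)) if len(fold_rmse) > 1 else 0.0
    return LoocvResult(rmse, sd, len(records), records)


def compare_conditions(acc_a, acc_b) -> tuple[float, float]:
    """Welch two-sample t-test on per-run accuracies; sign convention a-b.

    With zero variance in both samples the statistic is undefined and
    (nan, nan) is returned with a warning.
    """
    a, b = np.asarray(acc_a, dtype=float), np.asarray(acc_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 values per sample")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if np.allclose(a.mean(), b.mean()):
            log.warning("both samples constant and equal: t undefined")
            return float("nan"), float("nan")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def welch_from_summary(mean_a: float, sd_a: float, n_a: int,
                       mean_b: float, sd_b: float, n_b: int) -> tuple[float, float]:
    """Welch t from summary statistics (used to check printed tables)."""
    res = stats.ttest_ind_from_stats(mean_a, sd_a, n_a, mean_b, sd_b, n_b,
                                     equal_var=False)
    return float(res.statistic), float(res.pvalue)
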