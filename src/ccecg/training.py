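"""Training protocol and evaluation suite.

Training follows the study protocol: the minority (shockable) class is
oversampled six-fold, the data are shuffled into batches of 256, the loss
is binary cross-entropy under the Adam optimizer (learning rate 0.001,
beta1 0.9, beta2 0.999), at most 400 epochs with early stopping after 150
epochs without improvement of the validation balanced accuracy, and the
weights of the best-validation epoch are retained.

Evaluation reports sensitivity Se = TP/(TP+FN) over shockable strips,
specificity Sp = TN/(TN+FP) over non-shockable strips (overall and per
rhythm), balanced accuracy BAC = (Se+Sp)/2, the ROC curve with its area,
the operating threshold maximizing BAC on the validation ROC, and Se/Sp
stratified by SNR band and compression-rate range with Wilson 95%
confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .arch import ConvNet
from .exceptions import InvalidInputError, InvalidParameterError, UndefinedMetricError
from .metrics import cc_rate_bin, snr_bin
from .sim import Dataset, Rhythm

#: Decision threshold used for the per-epoch training/validation BAC; the
#: operating threshold is selected separately from the validation ROC.
EPOCH_BAC_THRESHOLD = 0.5


@dataclass(frozen=True)
class TrainConfig:
    """Optimizer and schedule settings (defaults follow the protocol)."""

    batch_size: int = 256
    max_epochs: int = 400
    early_stop_patience: int = 150
    learning_rate: float = 0.001
    beta1: float = 0.9
    beta2: float = 0.999
    oversample_factor: int = 6
    seed: int = 0

    def __post_init__(self):
        if self.early_stop_patience >= self.max_epochs:
            raise InvalidParameterError("patience must be below max_epochs")
        if self.oversample_factor < 1:
            raise InvalidParameterError("oversample factor must be >= 1")


def oversample_balance(dataset: Dataset, factor: int = 6, seed: int = 0) -> Dataset:
    """Replicate the minority class ``factor`` times, then shuffle.

    The minority class (shockable in the study databases) ends up with
    ``factor`` times its original count; majority strips are untouched.
    """
    if factor < 1:
        raise InvalidParameterError("factor must be >= 1")
    y = dataset.labels()
    if len(np.unique(y)) < 2:
        raise InvalidInputError("oversampling requires both classes present")
    n_pos, n_neg = int((y == 1).sum()), int((y == 0).sum())
    minority = 1 if n_pos <= n_neg else 0
    idx = list(range(len(dataset)))
    minority_idx = [i for i in idx if y[i] == minority]
    idx = idx + minority_idx * (factor - 1)
    rng = np.random.default_rng(seed)
    rng.shuffle(idx)
    return dataset.subset(idx)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def sensitivity_specificity(tp: int, fn: int, tn: int, fp: int) -> Tuple[float, float]:
    """Se = TP/(TP+FN), Sp = TN/(TN+FP); exact ratios."""
    if tp + fn == 0 or tn + fp == 0:
        raise UndefinedMetricError("empty class: Se/Sp undefined")
    return tp / (tp + fn), tn / (tn + fp)


def balanced_accuracy(se: float, sp: float) -> float:
    """BAC = (Se + Sp) / 2."""
    if not (0.0 <= se <= 1.0 and 0.0 <= sp <= 1.0):
        raise InvalidParameterError("se and sp must lie in [0, 1]")
    return 0.5 * (se + sp)


@dataclass(frozen=True)
class RocCurve:
    """Operating points (threshold, se, sp) and trapezoidal AUC."""

    thresholds: np.ndarray
    se: np.ndarray
    sp: np.ndarray
    auc: float

    def __len__(self) -> int:
        return len(self.thresholds)


def roc(scores: Sequence[float], labels: Sequence[int]) -> RocCurve:
    """ROC over all unique score thresholds (decision: score >= threshold).

    The curve starts at an unattainable threshold above the maximal score
    (se=0, sp=1) and descends through every unique score; AUC is the
    trapezoidal integral over (1 - sp, se), which equals the Mann-Whitney
    pair statistic with ties counted one half.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("ROC requires both classes present")
    uniq = np.unique(scores)[::-1]
    thresholds = np.concatenate(([uniq[0] + 1.0], uniq))
    se = np.empty(len(thresholds))
    sp = np.empty(len(thresholds))
    for i, thr in enumerate(thresholds):
        pred = scores >= thr
        se[i] = (pred & (labels == 1)).sum() / n_pos
        sp[i] = (~pred & (labels == 0)).sum() / n_neg
    fpr = 1.0 - sp
    auc = float(np.trapezoid(se, fpr))
    return RocCurve(thresholds=thresholds, se=se, sp=sp, auc=auc)


def select_threshold(curve: RocCurve) -> float:
    """Operating threshold maximizing BAC = (se+sp)/2 on the curve.

    Ties are broken in favor of higher sensitivity, then lower threshold.
    """
    if len(curve) == 0:
        raise InvalidInputError("empty ROC curve")
    bac = 0.5 * (curve.se + curve.sp)
    best = 0
    for i in range(1, len(curve)):
        if (bac[i], curve.se[i], -curve.thresholds[i]) > (
            bac[best], curve.se[best], -curve.thresholds[best]
        ):
            best = i
    return float(curve.thresholds[best])


def _wilson(correct: int, total: int) -> Tuple[float, float]:
    lo, hi = proportion_confint(correct, total, alpha=0.05, method="wilson")
    return float(lo), float(hi)


@dataclass
class EvalReport:
    """Full evaluation of a model at a fixed operating threshold."""

    pthr: float
    tp: int
    fn: int
    tn: int
    fp: int
    se: float
    sp: float
    bac: float
    auc: float
    se_ci: Tuple[float, float]
    sp_ci: Tuple[float, float]
    per_rhythm_sp: Dict[str, dict] = field(default_factory=dict)
    by_snr: pd.DataFrame = None
    by_cc_rate: pd.DataFrame = None
    roc: RocCurve = None

    def summary(self) -> str:
        lines = [
            f"Se  (VF)        {100 * self.se:5.1f}%  ({self.tp}/{self.tp + self.fn})",
            f"Sp  (NSh)       {100 * self.sp:5.1f}%  ({self.tn}/{self.tn + self.fp})",
        ]
        for rhythm, d in self.per_rhythm_sp.items():
            lines.append(
                f"Sp  ({rhythm:<8})  {100 * d['sp']:5.1f}%  ({d['tn']}/{d['n']})"
            )
        lines.append(f"BAC             {100 * self.bac:5.1f}%")
        lines.append(f"ROC-AUC         {self.auc:.3f}")
        lines.append(f"pTHR            {self.pthr:.2f}")
        return "\n".join(lines)


def _stratified_table(frame: pd.DataFrame, key: str) -> pd.DataFrame:
    """Per-bin, per-rhythm correct-decision rates with Wilson 95% CIs.

    Strips without the stratification key are left out; bins with no
    members are simply absent from the table.
    """
    rows = []
    sub = frame.dropna(subset=[key])
    for (band, rhythm), grp in sub.groupby([key, "rhythm"], observed=True):
        n = len(grp)
        correct = int(grp["correct"].sum())
        lo, hi = _wilson(correct, n)
        metric = "se" if rhythm == Rhythm.VF.value else "sp"
        rows.append(
            {
                key: band,
                "rhythm": rhythm,
                "metric": metric,
                "n": n,
                "correct": correct,
                "rate": correct / n,
                "ci_low": lo,
                "ci_high": hi,
            }
        )
    return pd.DataFrame(rows)


def evaluate(model: ConvNet, test_ds: Dataset, pthr: float) -> EvalReport:
    """Evaluate at a fixed threshold (selected on validation, never here)."""
    if len(test_ds) == 0:
        raise InvalidInputError("empty test dataset")
    if not 0.0 < pthr < 1.0:
        raise InvalidParameterError("pthr must lie strictly inside (0, 1)")
    scores = model.predict_proba(test_ds.waveforms())
    y = test_ds.labels()
    pred = scores >= pthr
    tp = int((pred & (y == 1)).sum())
    fn = int((~pred & (y == 1)).sum())
    tn = int((~pred & (y == 0)).sum())
    fp = int((pred & (y == 0)).sum())
    se, sp = sensitivity_specificity(tp, fn, tn, fp)
    bac = balanced_accuracy(se, sp)
    curve = roc(scores, y)

    man = test_ds.manifest()
    man["correct"] = pred == (y == 1)
    man["snr_band"] = [
        snr_bin(v).value if v is not None and np.isfinite(v) else None
        for v in man["snr_db"]
    ]
    man["cc_rate_band"] = [
        cc_rate_bin(v).value if v is not None and np.isfinite(v) else None
        for v in man["cc_rate_cpm"]
    ]

    per_rhythm = {}
    for rhythm in (Rhythm.OR, Rhythm.ASYSTOLE):
        grp = man[man["rhythm"] == rhythm.value]
        if len(grp) == 0:
            continue
        tn_r = int(grp["correct"].sum())
        lo, hi = _wilson(tn_r, len(grp))
        per_rhythm[rhythm.value] = {
            "tn": tn_r,
            "n": len(grp),
            "sp": tn_r / len(grp),
            "ci": (lo, hi),
        }

    return EvalReport(
        pthr=float(pthr),
        tp=tp, fn=fn, tn=tn, fp=fp,
        se=se, sp=sp, bac=bac,
        auc=curve.auc,
        se_ci=_wilson(tp, tp + fn),
        sp_ci=_wilson(tn, tn + fp),
        per_rhythm_sp=per_rhythm,
        by_snr=_stratified_table(man, "snr_band"),
        by_cc_rate=_stratified_table(man, "cc_rate_band"),
        roc=curve,
    )


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

class _Adam:
    def __init__(self, params: List[np.ndarray], lr: float, b1: float, b2: float,
                 eps: float = 1e-7):
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: List[np.ndarray], grads: List[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= (self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)).astype(p.dtype)


class StopAtValidationBac:
    """Callback stopping training once validation BAC reaches a target."""

    def __init__(self, target: float):
        self.target = target

    def __call__(self, epoch: int, logs: dict) -> bool:
        return logs["val_bac"] is not None and logs["val_bac"] >= self.target


def _bac_at_half(scores: np.ndarray, y: np.ndarray) -> Optional[float]:
    """BAC at threshold 0.5; one-sided if only one class is present."""
    pred = scores >= EPOCH_BAC_THRESHOLD
    parts = []
    if (y == 1).any():
        parts.append((pred & (y == 1)).sum() / (y == 1).sum())
    if (y == 0).any():
        parts.append((~pred & (y == 0)).sum() / (y == 0).sum())
    return float(np.mean(parts)) if parts else None


@dataclass
class TrainResult:
    model: ConvNet
    history: pd.DataFrame
    best_epoch: int          # 1-based epoch whose weights were retained
    best_val_bac: float
    stopped_early: bool


def train(model: ConvNet, train_ds: Dataset, val_ds: Dataset,
          cfg: TrainConfig = TrainConfig(),
          callbacks: Sequence = ()) -> TrainResult:
    """Fit a model under the study protocol.

    Per epoch: mini-batch Adam on binary cross-entropy; full validation
    pass scoring BAC at threshold 0.5; the weights of the best-validation
    epoch are retained and restored at the end.  Training stops early if
    the validation BAC has not strictly improved for
    ``cfg.early_stop_patience`` epochs, or when any callback (called with
    the epoch index and the epoch's log row) returns True.
    """
    if len(train_ds) == 0 or len(val_ds) == 0:
        raise InvalidInputError("training and validation sets must be non-empty")
    rng = np.random.default_rng(cfg.seed)
    balanced = (
        oversample_balance(train_ds, cfg.oversample_factor, seed=int(rng.integers(2**31)))
        if len(np.unique(train_ds.labels())) == 2
        else train_ds
    )
    x_train = balanced.waveforms()
    y_train = balanced.labels()
    x_val = val_ds.waveforms()
    y_val = val_ds.labels()

    opt = _Adam(model.parameters, cfg.learning_rate, cfg.beta1, cfg.beta2)
    best_bac = -np.inf
    best_epoch = 0
    best_weights = model.get_weights()
    rows = []
    stopped_early = False
    n = len(x_train)
    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(n)
        losses, preds, targets = [], [], []
        for start in range(0, n, cfg.batch_size):
            sel = order[start: start + cfg.batch_size]
            loss, grads, p = model.loss_and_gradients(
                x_train[sel], y_train[sel], dropout_rng=rng
            )
            opt.step(model.parameters, grads)
            losses.append(loss * len(sel))
            preds.append(p)
            targets.append(y_train[sel])
        train_loss = float(np.sum(losses) / n)
        train_bac = _bac_at_half(np.concatenate(preds), np.concatenate(targets))

        p_val = model.predict_proba(x_val)
        eps = 1e-12
        val_loss = float(
            -np.mean(y_val * np.log(p_val + eps) + (1 - y_val) * np.log(1 - p_val + eps))
        )
        val_bac = _bac_at_half(p_val, y_val)
        logs = {
            "epoch": epoch,
            "train_loss": train_loss,
            "train_bac": train_bac,
            "val_loss": val_loss,
            "val_bac": val_bac,
        }
        rows.append(logs)
        if val_bac is not None and val_bac > best_bac:
            best_bac = val_bac
            best_epoch = epoch
            best_weights = model.get_weights()
        if epoch - best_epoch > cfg.early_stop_patience:
            stopped_early = True
            break
        if any(cb(epoch, logs) for cb in callbacks):
            break
    model.set_weights(best_weights)
    return TrainResult(
        model=model,
        history=pd.DataFrame(rows),
        best_epoch=best_epoch,
        best_val_bac=float(best_bac) if np.isfinite(best_bac) else float("nan"),
        stopped_early=stopped_early,
    )
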