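"""Training recipe and evaluation metrics.

Training follows the published recipe: sigmoid binary cross-entropy per
class, Adam with learning rate 1e-4 and default moments, batch size 64,
up to 100 epochs, from-scratch initialisation.  Evaluation is class-wise
and average AUROC (the Mann–Whitney statistic computed from midranks, so
P(score⁺ > score⁻) + ½·P(tie)), macro-averaged F1 at threshold 0.5, and
nonparametric case-resampling percentile bootstrap confidence intervals
for per-class AUROC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import rankdata

from . import nn
from .errors import ConfigurationError, ShapeError, UndefinedMetricError
from .network import SqueezeViT, save_checkpoint

__all__ = [
    "TrainSpec",
    "EvalReport",
    "EpochRecord",
    "bce_loss",
    "train",
    "auroc",
    "classwise_auroc",
    "f1_average",
    "bootstrap_ci",
    "abnormality_score",
]


@dataclass(frozen=True)
class TrainSpec:
    """The optimisation recipe."""

    batch_size: int = 64
    epochs: int = 100
    learning_rate: float = 1e-4
    adam_betas: tuple[float, float] = (0.9, 0.999)
    adam_eps: float = 1e-8
    seed: int = 0
    early_stop: bool = False
    early_stop_patience: int = 10
    # start the (zero-initialised) classifier at the label-prior log-odds
    # so the first gradients carry class contrast instead of prevalence
    prior_bias_init: bool = True

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ConfigurationError("learning rate must be positive")
        if self.batch_size < 1 or self.epochs < 1:
            raise ConfigurationError("batch size and epochs must be >= 1")


@dataclass
class EpochRecord:
    epoch: int
    loss: float
    auroc: float | None
    f1: float | None
    val_loss: float | None = None
    val_auroc: float | None = None
    val_f1: float | None = None


@dataclass
class EvalReport:
    """Per-class and average AUROC with the bookkeeping around them."""

    classes: tuple[str, ...]
    per_class_auroc: np.ndarray          # NaN where undefined
    average_auroc: float
    f1: float
    n_pos: np.ndarray
    n_neg: np.ndarray
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "average_auroc": self.average_auroc,
            "f1": self.f1,
            "per_class": {
                c: {
                    "auroc": None if np.isnan(a) else float(a),
                    "n_pos": int(p), "n_neg": int(q),
                    **({"ci95": list(self.ci[c])} if c in self.ci else {}),
                }
                for c, a, p, q in zip(self.classes, self.per_class_auroc,
                                      self.n_pos, self.n_neg)
            },
        }


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def bce_loss(logits, labels) -> float | nn.Tensor:
    """Mean binary cross-entropy on logits (numerically stable form).

    Accepts plain arrays (returns a float) or a Tensor of logits (returns
    the differentiable scalar used by the training loop).
    """
    if isinstance(logits, nn.Tensor):
        return nn.bce_with_logits(logits, np.asarray(labels))
    z = np.asarray(logits, dtype=np.float64)
    y = np.asarray(labels, dtype=np.float64)
    if z.shape != y.shape:
        raise ShapeError(f"logits {z.shape} vs labels {y.shape}")
    sp = np.maximum(z, 0) + np.log1p(np.exp(-np.abs(z)))
    return float((sp - y * z).mean())


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def auroc(scores, labels) -> float:
    """AUROC as the midrank Mann–Whitney statistic.

    Equals the probability that a random positive outscores a random
    negative, counting ties as half wins.
    """
    s = np.asarray(scores, dtype=float).ravel()
    y = np.asarray(labels).ravel().astype(int)
    if s.shape != y.shape:
        raise ShapeError("scores and labels must have equal length")
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError(
            f"AUROC undefined: {n_pos} positives, {n_neg} negatives"
        )
    ranks = rankdata(s)                      # midranks
    rank_sum = ranks[y == 1].sum()
    return float((rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def classwise_auroc(scores, labels,
                    classes: tuple[str, ...] | None = None,
                    threshold: float = 0.5) -> EvalReport:
    """Per-class AUROC; the average is over classes with both labels present."""
    s = np.atleast_2d(np.asarray(scores, dtype=float))
    y = np.atleast_2d(np.asarray(labels)).astype(int)
    if s.shape != y.shape:
        raise ShapeError(f"score matrix {s.shape} vs label matrix {y.shape}")
    L = s.shape[1]
    classes = classes or tuple(f"class_{j}" for j in range(L))
    per = np.full(L, np.nan)
    n_pos = y.sum(axis=0)
    n_neg = len(y) - n_pos
    for j in range(L):
        try:
            per[j] = auroc(s[:, j], y[:, j])
        except UndefinedMetricError:
            warnings.warn(
                f"class {classes[j]!r} has a single label value; skipped "
                "from the average AUROC", stacklevel=2)
    if np.isnan(per).all():
        raise UndefinedMetricError("no class has both labels present")
    return EvalReport(
        classes=tuple(classes),
        per_class_auroc=per,
        average_auroc=float(np.nanmean(per)),
        f1=f1_average(s, y, threshold),
        n_pos=n_pos, n_neg=n_neg,
    )


def f1_average(scores, labels, threshold: float = 0.5) -> float:
    """Macro-averaged F1 of thresholded scores.

    A class with no predicted and no true positives contributes F1 = 0.
    """
    if not (0.0 < threshold < 1.0):
        raise ConfigurationError("threshold must lie in (0, 1)")
    s = np.atleast_2d(np.asarray(scores, dtype=float))
    y = np.atleast_2d(np.asarray(labels)).astype(int)
    if s.shape != y.shape:
        raise ShapeError(f"score matrix {s.shape} vs label matrix {y.shape}")
    pred = (s >= threshold).astype(int)
    tp = ((pred == 1) & (y == 1)).sum(axis=0)
    fp = ((pred == 1) & (y == 0)).sum(axis=0)
    fn = ((pred == 0) & (y == 1)).sum(axis=0)
    denom = 2 * tp + fp + fn
    f1 = np.where(denom > 0, 2 * tp / np.maximum(denom, 1), 0.0)
    return float(f1.mean())


def _auroc_rows(s: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Vectorised midrank AUROC over rows of (B, n) resample matrices."""
    ranks = rankdata(s, axis=1)
    n_pos = y.sum(axis=1)
    n_neg = y.shape[1] - n_pos
    rank_sum = (ranks * y).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    out[(n_pos == 0) | (n_neg == 0)] = np.nan
    return out


def bootstrap_ci(scores, labels, B: int = 2000, alpha: float = 0.05,
                 seed: int = 0) -> tuple[float, float]:
    """Percentile bootstrap interval for AUROC under case resampling.

    Resamples with a single-class outcome are redrawn (up to 10 attempts
    each); any still-degenerate replicates are dropped with a warning.
    """
    s = np.asarray(scores, dtype=float).ravel()
    y = np.asarray(labels).ravel().astype(int)
    auroc(s, y)  # raises if undefined on the full sample
    if B < 100:
        warnings.warn(f"B={B} bootstrap replicates is too few for a stable "
                      "percentile interval", stacklevel=2)
    rng = np.random.default_rng(seed)
    n = len(s)
    idx = rng.integers(0, n, size=(B, n))
    vals = _auroc_rows(s[idx], y[idx])
    for _ in range(10):
        bad = np.flatnonzero(np.isnan(vals))
        if len(bad) == 0:
            break
        redraw = rng.integers(0, n, size=(len(bad), n))
        vals[bad] = _auroc_rows(s[redraw], y[redraw])
    dropped = int(np.isnan(vals).sum())
    if dropped:
        warnings.warn(f"{dropped} degenerate bootstrap replicates dropped "
                      "after 10 redraw attempts", stacklevel=2)
        vals = vals[~np.isnan(vals)]
    lo, hi = np.quantile(vals, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


def abnormality_score(probabilities: np.ndarray) -> np.ndarray:
    """Max-over-classes abnormality score of a multi-label model.

    A convenience for screening-style use of a 14-class model; the
    published binary task instead retrains a single-logit head.
    """
    return np.asarray(probabilities).max(axis=1)


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

def train(model: SqueezeViT, images: np.ndarray, labels: np.ndarray,
          spec: TrainSpec | None = None,
          val_images: np.ndarray | None = None,
          val_labels: np.ndarray | None = None,
          checkpoint_path: str | Path | None = None,
          track_metrics: bool = True,
          verbose: bool = False) -> list[EpochRecord]:
    """Run the recipe; returns one history record per epoch.

    Shuffling, initial weights and therefore the whole loss history are
    functions of (model seed, spec seed) alone on a given machine.
    """
    spec = spec or TrainSpec()
    images = np.asarray(images, dtype=np.float32)
    labels = np.atleast_2d(np.asarray(labels)).astype(np.float32)
    if len(images) == 0:
        raise ConfigurationError("refusing to train on an empty dataset")
    if labels.shape[0] != len(images):
        raise ShapeError(f"{len(images)} images vs {labels.shape[0]} label rows")
    if labels.shape[1] != model.cfg.num_labels:
        raise ShapeError(
            f"labels have {labels.shape[1]} classes, model head has "
            f"{model.cfg.num_labels}")
    if (labels == labels[0]).all():
        raise ConfigurationError(
            "refusing to train: every label row is identical (constant "
            "labels give no ranking signal)")
    if spec.prior_bias_init and not model.fc_b.data.any():
        n = len(labels)
        pi = np.clip(labels.mean(axis=0), 1 / (2 * n), 1 - 1 / (2 * n))
        model.fc_b.data = np.log(pi / (1 - pi)).astype(np.float32)
    rng = np.random.default_rng(spec.seed)
    opt = nn.Adam(model.parameters(), lr=spec.learning_rate,
                  betas=spec.adam_betas, eps=spec.adam_eps)
    history: list[EpochRecord] = []
    best_val = np.inf
    stale = 0
    for epoch in range(spec.epochs):
        order = rng.permutation(len(images))
        losses = []
        for lo in range(0, len(images), spec.batch_size):
            sel = order[lo:lo + spec.batch_size]
            opt.zero_grad()
            logits = model(images[sel])
            loss = nn.bce_with_logits(logits, labels[sel])
            loss.backward()
            opt.step()
            losses.append(loss.item())
        rec = EpochRecord(epoch=epoch, loss=float(np.mean(losses)),
                          auroc=None, f1=None)
        if track_metrics:
            probs = model.predict_proba(images, batch_size=spec.batch_size)
            try:
                rep = classwise_auroc(probs, labels)
                rec.auroc, rec.f1 = rep.average_auroc, rep.f1
            except UndefinedMetricError:
                pass
        if val_images is not None and val_labels is not None:
            vprobs = model.predict_proba(val_images, batch_size=spec.batch_size)
            rec.val_loss = _probs_bce(vprobs, val_labels)
            try:
                vrep = classwise_auroc(vprobs, np.atleast_2d(val_labels))
                rec.val_auroc, rec.val_f1 = vrep.average_auroc, vrep.f1
            except UndefinedMetricError:
                pass
        history.append(rec)
        if verbose:
            print(f"epoch {epoch:3d}  loss {rec.loss:.4f}"
                  + (f"  auroc {rec.auroc:.3f}" if rec.auroc is not None else ""))
        if spec.early_stop and rec.val_loss is not None:
            if rec.val_loss < best_val - 1e-6:
                best_val, stale = rec.val_loss, 0
            else:
                stale += 1
                if stale >= spec.early_stop_patience:
                    break
    if checkpoint_path is not None:
        save_checkpoint(model, checkpoint_path)
    return history


def _probs_bce(probs: np.ndarray, labels: np.ndarray) -> float:
    p = np.clip(np.asarray(probs, dtype=np.float64), 1e-12, 1 - 1e-12)
    y = np.atleast_2d(np.asarray(labels)).astype(np.float64)
    return float(-(y * np.log(p) + (1 - y) * np.log(1 - p)).mean())


def history_frame(history: list[EpochRecord]):
    """The per-epoch history as a pandas DataFrame (for CSV export)."""
    import pandas as pd

    return pd.DataFrame([vars(r) for r in history])
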