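"""Classification metrics from confusion matrices, with fold aggregation.

Convention: confusion counts are indexed [predicted][true], so column sums
are the per-class true occurrences t_k and row sums the per-class
prediction counts p_k.  Macro F1 averages the per-class harmonic mean of
precision and recall (a zero denominator contributes F1 = 0); the
multiclass Matthews correlation coefficient is

    MCC = (c*s - sum_k p_k t_k)
          / sqrt((s^2 - sum_k p_k^2) * (s^2 - sum_k t_k^2))

with c the correct count and s the total, and defined as 0 when either
factor under the root vanishes (single-class predictions or truth).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionMatrix",
    "MetricsRow",
    "confusion",
    "accuracy",
    "macro_f1",
    "mcc",
    "evaluate_model",
    "aggregate_folds",
    "TARGET_MEAN",
]

TARGET_MEAN = "target_mean"


@dataclass
class ConfusionMatrix:
    """K x K counts, rows = predicted class, columns = true class."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("confusion matrix must be square")
        if (c < 0).any():
            raise ValueError("confusion counts must be non-negative")
        if c.sum() < 1:
            raise ValueError("confusion matrix must contain at least one sample")
        self.counts = c.astype(np.int64)

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class MetricsRow:
    accuracy: float
    macro_f1: float
    mcc: float
    n: int
    domain: str
    fold: int

    def as_dict(self) -> dict:
        return {
            "domain": self.domain,
            "fold": self.fold,
            "n": self.n,
            "accuracy": self.accuracy,
            "macro_f1": self.macro_f1,
            "mcc": self.mcc,
        }


def confusion(true_labels, predicted, n_classes: int) -> ConfusionMatrix:
    """Tally counts[pred][true] over paired label sequences."""
    t = np.asarray(true_labels, dtype=np.int64)
    p = np.asarray(predicted, dtype=np.int64)
    if t.shape != p.shape or t.ndim != 1 or len(t) < 1:
        raise ValueError("true and predicted labels must be equal-length 1D, n >= 1")
    for name, arr in (("true", t), ("predicted", p)):
        bad = np.where((arr < 0) | (arr >= n_classes))[0]
        if len(bad):
            raise ValueError(
                f"{name} label out of range 0..{n_classes - 1} at index {bad[0]}"
            )
    counts = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(counts, (p, t), 1)
    return ConfusionMatrix(counts=counts)


def accuracy(m: ConfusionMatrix) -> float:
    return float(np.trace(m.counts) / m.total)


def macro_f1(m: ConfusionMatrix) -> float:
    """Unweighted mean over classes of 2PR/(P+R); degenerate classes 0."""
    c = m.counts.astype(np.float64)
    diag = np.diag(c)
    col = c.sum(axis=0)
    row = c.sum(axis=1)
    f1s = np.zeros(m.n_classes)
    for k in range(m.n_classes):
        p_k = diag[k] / col[k] if col[k] > 0 else 0.0
        r_k = diag[k] / row[k] if row[k] > 0 else 0.0
        if p_k + r_k > 0:
            f1s[k] = 2.0 * p_k * r_k / (p_k + r_k)
    return float(f1s.mean())


def mcc(m: ConfusionMatrix) -> float:
    """Multiclass Matthews correlation coefficient; 0 on degenerate input."""
    c = m.counts.astype(np.float64)
    t_k = c.sum(axis=0)  # true occurrences per class (column sums)
    p_k = c.sum(axis=1)  # predicted occurrences per class (row sums)
    s = c.sum()
    corr = np.trace(c)
    num = corr * s - (p_k * t_k).sum()
    d1 = s**2 - (p_k**2).sum()
    d2 = s**2 - (t_k**2).sum()
    if d1 <= 0 or d2 <= 0:
        return 0.0
    return float(num / np.sqrt(d1 * d2))


def _row_from_matrix(m: ConfusionMatrix, domain: str, fold: int) -> MetricsRow:
    return MetricsRow(
        accuracy=accuracy(m),
        macro_f1=macro_f1(m),
        mcc=mcc(m),
        n=m.total,
        domain=domain,
        fold=fold,
    )


def evaluate_model(
    model,
    datasets: dict[str, list],
    fold: int = 0,
    target_domains: list[str] | None = None,
) -> list[MetricsRow]:
    """Per-domain metrics plus an unweighted mean row over target domains.

    ``datasets`` maps domain name to a list of samples; ``target_domains``
    defaults to every domain present.  Empty domains are skipped.
    """
    import warnings

    if not datasets:
        raise ValueError("need at least one dataset")
    rows: list[MetricsRow] = []
    for domain, samples in datasets.items():
        if not samples:
            warnings.warn(f"domain {domain!r} is empty; skipped", stacklevel=2)
            continue
        true = [s.label for s in samples]
        pred = [model.predict(s.volume) for s in samples]
        rows.append(
            _row_from_matrix(
                confusion(true, pred, model.config.n_classes), domain, fold
            )
        )
    targets = target_domains if target_domains is not None else [r.domain for r in rows]
    tr = [r for r in rows if r.domain in targets]
    if tr:
        rows.append(
            MetricsRow(
                accuracy=float(np.mean([r.accuracy for r in tr])),
                macro_f1=float(np.mean([r.macro_f1 for r in tr])),
                mcc=float(np.mean([r.mcc for r in tr])),
                n=int(sum(r.n for r in tr)),
                domain=TARGET_MEAN,
                fold=fold,
            )
        )
    return rows


def aggregate_folds(rows: list[MetricsRow]) -> pd.DataFrame:
    """Mean and population std per (domain, metric) over folds."""
    df = pd.DataFrame([r.as_dict() for r in rows])
    out = df.groupby("domain")[["accuracy", "macro_f1", "mcc"]].agg(
        ["mean", lambda x: float(np.std(x, ddof=0))]
    )
    out.columns = [f"{m}_{'mean' if s == 'mean' else 'std'}" for m, s in out.columns]
    return out.reset_index()
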