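"""Pixel-level evaluation: confusion matrix and precision/recall/Dice.

Metrics follow the conventions of multiclass semantic segmentation with
sparse ground truth: only pixels whose true label is annotated enter the
confusion matrix; per-class precision, recall and Sørensen–Dice are
derived from the matrix; group and overall scores are micro-pooled
(TP/FP/FN summed over the member classes before taking ratios).  For a
single-label prediction pooled over *all* classes this forces
precision = recall = Dice = overall pixel accuracy (the micro identity).

Undefined ratios (0/0) are reported as NaN rather than 0 so that sparse
runs do not silently corrupt averages.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .taxonomy import UNANNOTATED, ClassTaxonomy

__all__ = [
    "ConfusionMatrix",
    "MetricsTable",
    "confusion",
    "row_normalize",
    "class_metrics",
    "pooled_metrics",
    "macro_dice",
    "report",
]


@dataclass
class ConfusionMatrix:
    """Pixel counts; rows are true classes, columns predicted classes."""

    counts: np.ndarray  # (K, K) int64

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if (self.counts < 0).any():
            raise ValueError("confusion counts must be non-negative")

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(self.counts + other.counts)


def confusion(
    true_labels: np.ndarray,
    predicted_labels: np.ndarray,
    taxonomy: ClassTaxonomy,
) -> ConfusionMatrix:
    """Tally a confusion matrix over annotated pixels.

    ``true_labels`` may contain the reserved unannotated value; those
    pixels are skipped.  Predicted labels must always be class ids.
    """
    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if t.shape != p.shape:
        raise ValueError(f"shape mismatch: {t.shape} vs {p.shape}")
    k = taxonomy.n_classes
    mask = t != UNANNOTATED
    t = t[mask].astype(np.int64)
    p = p[mask].astype(np.int64)
    if t.size and (t.max() >= k or p.max() >= k or t.min() < 0 or p.min() < 0):
        raise ValueError("labels outside taxonomy range")
    counts = np.bincount(t * k + p, minlength=k * k).reshape(k, k)
    return ConfusionMatrix(counts)


def row_normalize(cm: ConfusionMatrix) -> np.ndarray:
    """Divide each row by its sum; rows with no pixels become NaN.

    The diagonal of the result is the per-class recall, as shown in a
    row-normalized confusion heatmap.
    """
    counts = cm.counts.astype(float)
    sums = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = counts / sums
    frac[sums[:, 0] == 0] = np.nan
    return frac


def _prf(tp: float, fp: float, fn: float) -> tuple[float, float, float]:
    precision = tp / (tp + fp) if tp + fp > 0 else math.nan
    recall = tp / (tp + fn) if tp + fn > 0 else math.nan
    dice = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn > 0 else math.nan
    return precision, recall, dice


def class_metrics(cm: ConfusionMatrix, class_id: int) -> tuple[float, float, float]:
    """Precision, recall and Dice for one class.

    TP = diagonal cell, FP = rest of the column, FN = rest of the row.
    Ratios with zero denominator come back as NaN (undefined), not 0.
    """
    c = cm.counts
    tp = float(c[class_id, class_id])
    fp = float(c[:, class_id].sum() - tp)
    fn = float(c[class_id, :].sum() - tp)
    return _prf(tp, fp, fn)


def pooled_metrics(
    cm: ConfusionMatrix, class_subset: Sequence[int]
) -> tuple[float, float, float]:
    """Micro-pooled precision/recall/Dice over a subset of classes.

    TP, FP and FN are summed over the subset before the ratios are
    taken.  With the subset equal to all classes this reduces to overall
    pixel accuracy three times over.
    """
    subset = list(class_subset)
    if not subset:
        raise ValueError("class subset must be non-empty")
    c = cm.counts
    tp = fp = fn = 0.0
    for k in subset:
        tp += float(c[k, k])
        fp += float(c[:, k].sum() - c[k, k])
        fn += float(c[k, :].sum() - c[k, k])
    return _prf(tp, fp, fn)


def macro_dice(cm: ConfusionMatrix, class_ids: Iterable[int] | None = None) -> float:
    """Mean per-class Dice over classes whose Dice is defined."""
    ids = range(cm.n_classes) if class_ids is None else class_ids
    vals = [class_metrics(cm, k)[2] for k in ids]
    vals = [v for v in vals if not math.isnan(v)]
    return float(np.mean(vals)) if vals else math.nan


@dataclass
class MetricsTable:
    """Per-class, per-group and overall precision/recall/Dice."""

    rows: pd.DataFrame  # index: row label; columns: precision, recall, dice

    def rounded(self, ndigits: int = 2) -> pd.DataFrame:
        """Half-up decimal rounding for display."""

        def r(v: float) -> float:
            if isinstance(v, float) and math.isnan(v):
                return v
            q = Decimal(1).scaleb(-ndigits)
            return float(Decimal(repr(v)).quantize(q, rounding=ROUND_HALF_UP))

        return self.rows.map(r)


def report(
    cm: ConfusionMatrix,
    taxonomy: ClassTaxonomy,
    out_dir: str | Path | None = None,
) -> MetricsTable:
    """Build the full metrics table and optionally render it to disk.

    Rows: the 15 classes in canonical order, then the two groups
    (micro-pooled), then the overall score.  When ``out_dir`` is given,
    writes ``metrics.csv`` (rounded), ``metrics.json`` (full precision)
    and ``confusion.png`` (row-normalized heatmap).
    """
    records = {}
    for c in taxonomy.classes:
        records[c.name] = class_metrics(cm, c.id)
    for gname, members in taxonomy.groups.items():
        records[gname] = pooled_metrics(cm, members)
    records["Overall score"] = pooled_metrics(cm, list(range(taxonomy.n_classes)))
    table = MetricsTable(
        pd.DataFrame.from_dict(
            records, orient="index", columns=["precision", "recall", "dice"]
        )
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.rounded().to_csv(out / "metrics.csv", na_rep="undefined")
        full = {
            name: {
                k: (None if math.isnan(v) else v)
                for k, v in zip(("precision", "recall", "dice"), vals)
            }
            for name, vals in (
                (idx, tuple(row)) for idx, row in table.rows.iterrows()
            )
        }
        (out / "metrics.json").write_text(json.dumps(full, indent=2))
        _heatmap(cm, taxonomy, out / "confusion.png")
    return table


def _heatmap(cm: ConfusionMatrix, taxonomy: ClassTaxonomy, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    frac = row_normalize(cm)
    fig, ax = plt.subplots(figsize=(8, 7))
    im = ax.imshow(frac, vmin=0, vmax=1, cmap="viridis")
    ax.set_xticks(range(taxonomy.n_classes), taxonomy.names, rotation=90)
    ax.set_yticks(range(taxonomy.n_classes), taxonomy.names)
    ax.set_xlabel("predicted class")
    ax.set_ylabel("true class")
    fig.colorbar(im, ax=ax, label="fraction of true-class pixels")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
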