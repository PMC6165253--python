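"""Confusion-matrix construction and accuracy statistics.

Convention (stated once, used everywhere): rows of the confusion matrix are
the *classified* class, columns the *reference* class — so user's accuracy
(UA) lives on rows and producer's accuracy (PA) on columns.  One-vs-rest
TP/FN/TN/FP rates derive per class: the TP rate equals PA, FN = 1 - PA,
FP rate = (row_sum - diagonal) / (total - column_sum), TN = 1 - FP.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .classify import NODATA, ClassMap, TrainingSet

__all__ = [
    "ConfusionMatrix",
    "AccuracyReport",
    "confusion",
    "metrics",
    "load_reference_confusion",
]


@dataclass
class ConfusionMatrix:
    """K x K pixel-count table, rows = classified, columns = reference."""

    counts: np.ndarray
    legend: dict[int, str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        k = len(self.legend)
        if self.counts.shape != (k, k):
            raise ValueError(f"counts shape {self.counts.shape} != ({k}, {k})")
        if (self.counts < 0).any():
            raise ValueError("negative counts")
        if self.counts.sum() == 0:
            raise ValueError("empty confusion matrix")

    @property
    def class_ids(self) -> list[int]:
        return list(self.legend)

    def to_frame(self) -> pd.DataFrame:
        names = [self.legend[i] for i in self.legend]
        return pd.DataFrame(self.counts, index=names, columns=names)


@dataclass
class AccuracyReport:
    """Overall accuracy, kappa, and per-class UA/PA and one-vs-rest rates.

    Fractions in [0, 1]; classes whose UA or PA is undefined (empty row or
    column) carry NaN there and are listed in ``undefined``.
    """

    overall_accuracy: float
    kappa: float
    user_accuracy: dict[str, float]
    producer_accuracy: dict[str, float]
    tp_rate: dict[str, float]
    fn_rate: dict[str, float]
    fp_rate: dict[str, float]
    tn_rate: dict[str, float]
    undefined: list[str] = field(default_factory=list)

    def to_dict(self, percent: bool = False) -> dict:
        f = (lambda v: round(100.0 * v, 4)) if percent else (lambda v: v)
        return {
            "overall_accuracy": f(self.overall_accuracy),
            "kappa": self.kappa,
            "user_accuracy": {k: f(v) for k, v in self.user_accuracy.items()},
            "producer_accuracy": {k: f(v) for k, v in self.producer_accuracy.items()},
            "tp_rate": dict(self.tp_rate),
            "fn_rate": dict(self.fn_rate),
            "fp_rate": dict(self.fp_rate),
            "tn_rate": dict(self.tn_rate),
            "undefined": list(self.undefined),
        }


def confusion(pred: ClassMap, ref: ClassMap | TrainingSet) -> ConfusionMatrix:
    """Count pixels classified i with reference j; nodata excluded.

    The reference may be a full label raster or a sparse testing set; the
    legends must agree on shared class ids.
    """
    if isinstance(ref, TrainingSet):
        ref_labels = ref.labels
        pred_labels = pred.labels[ref.rows, ref.cols]
        legend = dict(ref.legend)
    else:
        if pred.labels.shape != ref.labels.shape:
            raise ValueError("prediction and reference grids differ")
        legend = dict(ref.legend)
        pred_labels = pred.labels.ravel()
        ref_labels = ref.labels.ravel()
    for cid, name in pred.legend.items():
        if cid in legend and legend[cid] != name:
            raise ValueError(
                f"legend mismatch for class {cid}: {name!r} vs {legend[cid]!r}"
            )
        legend.setdefault(cid, name)
    legend = dict(sorted(legend.items()))
    keep = (pred_labels != NODATA) & (ref_labels != NODATA)
    if not keep.any():
        raise ValueError("no overlapping valid pixels between prediction and reference")
    ids = np.array(list(legend))
    lut = np.full(ids.max() + 2, -1)
    lut[ids] = np.arange(ids.size)
    pi = lut[pred_labels[keep]]
    ri = lut[ref_labels[keep]]
    counts = np.zeros((ids.size, ids.size), dtype=np.int64)
    np.add.at(counts, (pi, ri), 1)
    return ConfusionMatrix(counts=counts, legend=legend)


def metrics(cm: ConfusionMatrix) -> AccuracyReport:
    """Derive OA, kappa, UA/PA and one-vs-rest rates from a confusion matrix.

    OA = trace/total; kappa = (Po - Pe) / (1 - Pe) with chance agreement
    Pe = sum_i row_i * col_i / total^2.  Empty rows/columns yield NaN for the
    affected UA/PA (flagged in ``undefined``) rather than propagating.
    """
    c = cm.counts.astype(float)
    total = c.sum()
    diag = np.diag(c)
    rows = c.sum(axis=1)
    cols = c.sum(axis=0)
    po = diag.sum() / total
    pe = float(rows @ cols) / total**2
    kappa = (po - pe) / (1.0 - pe) if pe < 1.0 else 1.0
    names = [cm.legend[i] for i in cm.legend]
    with np.errstate(divide="ignore", invalid="ignore"):
        ua = np.where(rows > 0, diag / np.where(rows > 0, rows, 1), np.nan)
        pa = np.where(cols > 0, diag / np.where(cols > 0, cols, 1), np.nan)
        fp = np.where(
            total - cols > 0,
            (rows - diag) / np.where(total - cols > 0, total - cols, 1),
            np.nan,
        )
    undefined = [n for n, r, col in zip(names, rows, cols) if r == 0 or col == 0]
    return AccuracyReport(
        overall_accuracy=float(po),
        kappa=float(kappa),
        user_accuracy=dict(zip(names, ua)),
        producer_accuracy=dict(zip(names, pa)),
        tp_rate=dict(zip(names, pa)),
        fn_rate=dict(zip(names, 1.0 - pa)),
        fp_rate=dict(zip(names, fp)),
        tn_rate=dict(zip(names, 1.0 - fp)),
        undefined=undefined,
    )


def load_reference_confusion() -> ConfusionMatrix:
    """Load the shipped Dongting Lake eight-class reference confusion table.

    Pixel counts of the published integrated-data classification over the
    Dongting Lake basin test fields (water, two rice crops, watermelon,
    lotus, bare soil, forest, grass), used as a fixture for the accuracy
    statistics and as a worked example.
    """
    path = resources.files("polcropsar.data").joinpath("dongting_confusion.csv")
    with resources.as_file(path) as p:
        df = pd.read_csv(p, index_col=0)
    legend = {i: name for i, name in enumerate(df.index)}
    return ConfusionMatrix(counts=df.to_numpy(dtype=np.int64), legend=legend)
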