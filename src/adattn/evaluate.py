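"""Label design and evaluation metrics.

A prediction is three subtype severities in [0, 1] (Logopenic Variant,
Posterior Cortical Atrophy, Frontal Variant).  A subtype is called present
when its severity is >= τ (default 0.5).  Overall severity is the arithmetic
mean of the three severities and is binned into four ordinal levels by
upper-edge thresholds: [0, 0.25] asymptomatic, (0.25, 0.5] mild,
(0.5, 0.75] moderate, (0.75, 1] severe.  Per-subtype metrics use the
standard 2×2 confusion-matrix definitions; per-level severity accuracy is
class-conditional (among patients whose true level is L, the fraction
predicted L); every "overall" figure is the unweighted mean of its
per-class values.  Percentages are formatted to one decimal,
round-half-away-from-zero.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import ID_COLUMN, SUBTYPES

SEVERITY_LEVELS = ("asymptomatic", "mild", "moderate", "severe")
SEVERITY_THRESHOLDS = (0.25, 0.5, 0.75, 1.0)
SUBTYPE_NAMES = {
    "lv": "Logopenic Variant",
    "pca": "Posterior Cortical Atrophy",
    "fv": "Frontal Variant",
}


class EvaluationError(ValueError):
    pass


def overall_severity(y: np.ndarray) -> np.ndarray | float:
    """Overall disease severity: the mean of the three subtype severities."""
    arr = np.asarray(y, dtype=float)
    if arr.shape[-1] != 3:
        raise EvaluationError("expected three subtype severities")
    if (arr < 0).any() or (arr > 1).any():
        raise EvaluationError("severities must lie in [0, 1]")
    out = arr.mean(axis=-1)
    return float(out) if out.ndim == 0 else out


def call_subtypes(y: np.ndarray, tau: float = 0.5) -> np.ndarray:
    """Presence calls: severity >= τ (boundary counts as present)."""
    if not (0.0 < tau < 1.0):
        raise EvaluationError(f"presence threshold must be in (0, 1), got {tau}")
    arr = np.asarray(y, dtype=float)
    if (arr < 0).any() or (arr > 1).any():
        raise EvaluationError("severities must lie in [0, 1]")
    return arr >= tau


def bin_severity(s: np.ndarray | float) -> np.ndarray | int:
    """Map severity in [0, 1] to an ordinal level index 0..3.

    Upper-edge bins: [0, 0.25] → 0 (asymptomatic), (0.25, 0.5] → 1 (mild),
    (0.5, 0.75] → 2 (moderate), (0.75, 1] → 3 (severe).
    """
    arr = np.asarray(s, dtype=float)
    if (arr < 0).any() or (arr > 1).any():
        raise EvaluationError("severity must lie in [0, 1]")
    # searchsorted with side='left' places s == threshold into the lower level
    levels = np.searchsorted(np.asarray(SEVERITY_THRESHOLDS[:-1]), arr, side="left")
    return int(levels) if levels.ndim == 0 else levels


def f1(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 (with a warning) when both 0."""
    if not (0.0 <= precision <= 1.0 and 0.0 <= recall <= 1.0):
        raise EvaluationError("precision and recall must lie in [0, 1]")
    if precision == 0.0 and recall == 0.0:
        warnings.warn("F1 undefined at precision = recall = 0; reporting 0")
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def round_percent(rate: float, decimals: int = 1) -> float:
    """Rate → percentage to ``decimals`` places, round-half-away-from-zero."""
    x = rate * 100.0 * 10.0**decimals
    return np.sign(x) * np.floor(np.abs(x) + 0.5) / 10.0**decimals


@dataclass(frozen=True)
class BinaryMetrics:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n

    @property
    def precision(self) -> float:
        denom = self.tp + self.fp
        return self.tp / denom if denom else 0.0

    @property
    def recall(self) -> float:
        denom = self.tp + self.fn
        return self.tp / denom if denom else 0.0

    @property
    def f1(self) -> float:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return f1(self.precision, self.recall)

    @property
    def confusion(self) -> np.ndarray:
        """2×2 matrix [[TN, FP], [FN, TP]] (rows: truth, cols: prediction)."""
        return np.array([[self.tn, self.fp], [self.fn, self.tp]])


def subtype_metrics(
    pred_calls: np.ndarray, true_calls: np.ndarray
) -> dict[str, BinaryMetrics]:
    """Per-subtype accuracy/precision/recall/F1 and confusion counts."""
    pred = np.asarray(pred_calls, dtype=bool)
    true = np.asarray(true_calls, dtype=bool)
    if pred.shape != true.shape or pred.ndim != 2 or pred.shape[1] != 3:
        raise EvaluationError("calls must be aligned (n, 3) boolean arrays")
    if pred.shape[0] == 0:
        raise EvaluationError("cannot evaluate an empty cohort")
    out = {}
    for j, name in enumerate(SUBTYPES):
        p, t = pred[:, j], true[:, j]
        out[name] = BinaryMetrics(
            tp=int((p & t).sum()),
            fp=int((p & ~t).sum()),
            fn=int((~p & t).sum()),
            tn=int((~p & ~t).sum()),
        )
    return out


def overall_subtype_accuracy(accuracies: dict[str, float] | np.ndarray) -> float:
    """Unweighted mean of the three per-subtype accuracies."""
    if isinstance(accuracies, dict):
        vals = [accuracies[s] for s in SUBTYPES]
    else:
        vals = list(np.asarray(accuracies, dtype=float))
    if len(vals) != 3:
        raise EvaluationError("expected three per-subtype accuracies")
    return float(np.mean(vals))


def severity_accuracy(
    pred_levels: np.ndarray, true_levels: np.ndarray
) -> tuple[dict[str, float], float]:
    """Class-conditional per-level accuracies and their unweighted mean.

    A level absent from the truth is reported as NaN with a warning and
    excluded from the overall mean.
    """
    pred = np.asarray(pred_levels, dtype=int)
    true = np.asarray(true_levels, dtype=int)
    if pred.shape != true.shape or pred.ndim != 1:
        raise EvaluationError("levels must be aligned 1-d arrays")
    per_level: dict[str, float] = {}
    present: list[float] = []
    for lvl, name in enumerate(SEVERITY_LEVELS):
        sel = true == lvl
        if not sel.any():
            warnings.warn(f"true level {name!r} absent; excluded from overall")
            per_level[name] = float("nan")
            continue
        acc = float((pred[sel] == lvl).mean())
        per_level[name] = acc
        present.append(acc)
    overall = float(np.mean(present)) if present else float("nan")
    return per_level, overall


@dataclass
class EvaluationReport:
    """Aggregate of all evaluation conventions for one prediction set."""

    per_subtype: dict[str, dict[str, float]]
    confusions: dict[str, list[list[int]]]
    overall_subtype_accuracy: float
    per_level_accuracy: dict[str, float]
    overall_severity_accuracy: float
    n_patients: int
    tau: float = 0.5

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.__dict__, indent=2, allow_nan=True)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "EvaluationReport":
        try:
            is_file = Path(str(text_or_path)).exists()
        except (OSError, ValueError):
            is_file = False
        text = (
            Path(str(text_or_path)).read_text(encoding="utf-8")
            if is_file
            else str(text_or_path)
        )
        return cls(**json.loads(text))

    def subtype_frame(self) -> pd.DataFrame:
        """Per-subtype metric table (accuracy/precision/recall/F1, in %)."""
        rows = []
        for key in SUBTYPES:
            m = self.per_subtype[key]
            rows.append(
                {
                    "subtype": SUBTYPE_NAMES[key],
                    **{
                        k: round_percent(m[k])
                        for k in ("accuracy", "precision", "recall", "f1")
                    },
                }
            )
        return pd.DataFrame(rows)

    def severity_frame(self) -> pd.DataFrame:
        row = {k: round_percent(v) for k, v in self.per_level_accuracy.items()}
        row["overall"] = round_percent(self.overall_severity_accuracy)
        return pd.DataFrame([row])


def make_report(
    pred: pd.DataFrame, truth: pd.DataFrame, tau: float = 0.5
) -> EvaluationReport:
    """Build the full report from aligned prediction and truth label tables.

    Both tables carry columns patient_id, lv, pca, fv; rows are joined on
    patient_id and must match one-to-one.
    """
    for df, label in ((pred, "pred"), (truth, "truth")):
        missing = [c for c in (ID_COLUMN, *SUBTYPES) if c not in df.columns]
        if missing:
            raise EvaluationError(f"{label} table missing column(s) {missing}")
    if set(pred[ID_COLUMN]) != set(truth[ID_COLUMN]):
        raise EvaluationError("prediction and truth patient ids do not match")
    t = truth.set_index(ID_COLUMN).loc[pred[ID_COLUMN].tolist()]
    y_pred = pred[list(SUBTYPES)].to_numpy(dtype=float)
    y_true = t[list(SUBTYPES)].to_numpy(dtype=float)

    metrics = subtype_metrics(call_subtypes(y_pred, tau), call_subtypes(y_true, tau))
    per_subtype = {
        k: {
            "accuracy": m.accuracy,
            "precision": m.precision,
            "recall": m.recall,
            "f1": m.f1,
        }
        for k, m in metrics.items()
    }
    confusions = {k: m.confusion.tolist() for k, m in metrics.items()}
    overall_acc = overall_subtype_accuracy(
        {k: m.accuracy for k, m in metrics.items()}
    )
    per_level, overall_sev = severity_accuracy(
        bin_severity(overall_severity(y_pred)),
        bin_severity(overall_severity(y_true)),
    )
    return EvaluationReport(
        per_subtype=per_subtype,
        confusions=confusions,
        overall_subtype_accuracy=overall_acc,
        per_level_accuracy=per_level,
        overall_severity_accuracy=overall_sev,
        n_patients=int(y_pred.shape[0]),
        tau=tau,
    )
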