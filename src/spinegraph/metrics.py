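"""Per-structure segmentation evaluation and paired significance testing.

Metrics are the standard overlap trio: Dice similarity coefficient
``DSC = 2|P∩G| / (|P| + |G|)``, precision ``|P∩G|/|P|`` and recall
``|P∩G|/|G|`` per structure and subject.  Structures empty in the ground
truth are marked absent (NaN) and excluded from cohort summaries -- real
cohorts frequently lack the cranial levels, and the phantom cohort emulates
that.  Summaries are grouped as vertebrae / IVDs / all structures and
reported on the 0-100 percent scale; internal values stay in [0, 1].
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .volumes import as_array

__all__ = [
    "dice_coefficient",
    "precision_recall",
    "evaluate_labelmaps",
    "summarize_cohort",
    "paired_ttest",
]


def _counts(pred, gt, class_id):
    p = as_array(pred)
    g = as_array(gt)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs gt {g.shape}")
    pm = p == class_id
    gm = g == class_id
    return int(np.logical_and(pm, gm).sum()), int(pm.sum()), int(gm.sum())


def dice_coefficient(pred, gt, class_id: int) -> float:
    """DSC in [0, 1]; NaN (absent) when the class is empty in ground truth."""
    inter, np_, ng = _counts(pred, gt, class_id)
    if ng == 0:
        return float("nan")
    return 2.0 * inter / (np_ + ng)


def precision_recall(pred, gt, class_id: int) -> tuple[float, float]:
    """(precision, recall); each NaN when its denominator is empty."""
    inter, np_, ng = _counts(pred, gt, class_id)
    precision = inter / np_ if np_ > 0 else float("nan")
    recall = inter / ng if ng > 0 else float("nan")
    return precision, recall


def evaluate_labelmaps(pred, gt, schema, subject: str = "sub-000") -> pd.DataFrame:
    """Per-structure metric rows for one subject.

    Columns: subject, structure (id), name, kind, dsc, precision, recall,
    present (class non-empty in ground truth).
    """
    rows = []
    for lab in schema:
        dsc = dice_coefficient(pred, gt, lab.id)
        prec, rec = precision_recall(pred, gt, lab.id)
        rows.append({"subject": subject, "structure": lab.id, "name": lab.name,
                     "kind": lab.kind, "dsc": dsc, "precision": prec,
                     "recall": rec, "present": not np.isnan(dsc)})
    return pd.DataFrame(rows)


def _agg(values: pd.Series) -> tuple[float, float]:
    vals = values.dropna().to_numpy()
    if vals.size == 0:
        return float("nan"), float("nan")
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    return float(vals.mean()), sd


def summarize_cohort(table: pd.DataFrame, schema) -> dict:
    """Cohort summary: per-structure and per-group mean ± SD (percent scale).

    Absent entries are excluded; SD uses the n-1 denominator (0 for a single
    sample).  Groups pool all present (subject, structure) entries.
    """
    if table.empty:
        raise ValueError("metrics table is empty")
    kinds = {lab.id: lab.kind for lab in schema}
    out: dict = {"per_structure": {}, "groups": {}}
    for lab in schema:
        sub = table[table["structure"] == lab.id]
        for metric in ("dsc", "precision", "recall"):
            mean, sd = _agg(sub[metric])
            out["per_structure"].setdefault(lab.name, {})[metric] = (
                mean * 100.0, sd * 100.0)
    groups = {
        "vertebrae": table[table["structure"].map(kinds) == "vertebra"],
        "ivds": table[table["structure"].map(kinds) == "disc"],
        "all": table,
    }
    for gname, sub in groups.items():
        out["groups"][gname] = {}
        for metric in ("dsc", "precision", "recall"):
            mean, sd = _agg(sub[metric])
            out["groups"][gname][metric] = (mean * 100.0, sd * 100.0)
    return out


def paired_ttest(scores_a, scores_b) -> tuple[float, float]:
    """Classical paired t-test on per-subject score differences.

    Returns (t statistic, two-sided p) with df = n - 1.  Degenerate cases:
    all differences zero -> (0, 1); zero variance with nonzero mean ->
    (+/-inf, 0).
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired scores must be equal-length 1D vectors")
    if a.size < 2:
        raise ValueError("need at least 2 paired observations")
    d = a - b
    if np.allclose(np.std(d, ddof=1), 0.0):
        if np.allclose(d.mean(), 0.0):
            return 0.0, 1.0
        return float(np.sign(d.mean()) * np.inf), 0.0
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)
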