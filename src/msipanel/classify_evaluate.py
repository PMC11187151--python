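"""MSI status classification and diagnostic evaluation vs dMMR labels.

A tumor is MSI-H when at least ``min_unstable`` (default two) of the panel's
mononucleotide loci are called unstable; otherwise MSS/MSI-L. No-call loci
count as stable, which biases toward specificity. Predictions are scored
against immunohistochemistry-style dMMR/pMMR labels with the usual
confusion-matrix metrics (dMMR / MSI-H is the positive class); percentages
are reported to two decimals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .panel_selection import PanelModel

MSI_H = "MSI-H"
MSS = "MSS/MSI-L"

PREDICTION_COLUMNS = ["sample_id", "msi_status", "n_unstable", "n_no_call"]


@dataclass
class Prediction:
    sample_id: str
    msi_status: str
    n_unstable: int
    n_no_call: int


@dataclass
class ConfusionStats:
    """TP/FN/FP/TN counts and the four diagnostic percentages.

    Metrics with a zero denominator are ``None`` and listed in
    ``undefined`` rather than coerced to a number.
    """

    tp: int
    fn: int
    fp: int
    tn: int
    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    undefined: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "fn": self.fn, "fp": self.fp, "tn": self.tn,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "ppv": self.ppv, "npv": self.npv, "undefined": list(self.undefined),
        }

    def format_table(self) -> str:
        def f(v):
            return "NA" if v is None else f"{v:.2f}%"
        return (
            f"            MSI-H  {MSS}\n"
            f"dMMR        {self.tp:5d}  {self.fn:9d}\n"
            f"pMMR        {self.fp:5d}  {self.tn:9d}\n"
            f"sensitivity {f(self.sensitivity)}  specificity {f(self.specificity)}\n"
            f"PPV         {f(self.ppv)}  NPV         {f(self.npv)}"
        )


def classify_sample(
    panel: PanelModel, calls: Mapping[str, tuple[bool, bool]], sample_id: str
) -> Prediction:
    """Classify one tumor from its per-locus (unstable, no_call) pairs.

    ``calls`` must contain an entry for every panel locus; absent loci must
    be passed as explicit no-calls by the caller.
    """
    n_unstable = 0
    n_no_call = 0
    for lid in panel.locus_ids:
        if lid not in calls:
            raise KeyError(f"no call provided for panel locus {lid!r}")
        unstable, no_call = calls[lid]
        if no_call:
            n_no_call += 1
        elif unstable:
            n_unstable += 1
    status = MSI_H if n_unstable >= panel.min_unstable else MSS
    return Prediction(sample_id, status, n_unstable, n_no_call)


def classify_cohort(panel: PanelModel, calls: pd.DataFrame) -> pd.DataFrame:
    """Classify every sample present in a long calls table."""
    preds = []
    for sid, grp in calls.groupby("sample_id", sort=True, observed=True):
        per_locus = {
            r.locus_id: (bool(r.unstable), bool(r.no_call))
            for r in grp.itertuples(index=False)
        }
        p = classify_sample(panel, per_locus, str(sid))
        preds.append((p.sample_id, p.msi_status, p.n_unstable, p.n_no_call))
    return pd.DataFrame(preds, columns=PREDICTION_COLUMNS)


def _pct(num: int, den: int) -> float | None:
    return None if den == 0 else round(100.0 * num / den, 2)


def confusion_from_counts(tp: int, fn: int, fp: int, tn: int) -> ConfusionStats:
    """Confusion metrics from raw counts (dMMR/MSI-H positive)."""
    if min(tp, fn, fp, tn) < 0:
        raise ValueError("counts must be non-negative")
    stats = ConfusionStats(
        tp=tp, fn=fn, fp=fp, tn=tn,
        sensitivity=_pct(tp, tp + fn),
        specificity=_pct(tn, tn + fp),
        ppv=_pct(tp, tp + fp),
        npv=_pct(tn, tn + fn),
    )
    stats.undefined = [
        name
        for name, v in (
            ("sensitivity", stats.sensitivity), ("specificity", stats.specificity),
            ("ppv", stats.ppv), ("npv", stats.npv),
        )
        if v is None
    ]
    return stats


def confusion_metrics(predictions: pd.DataFrame, labels: pd.Series) -> ConfusionStats:
    """Score MSI-H predictions against dMMR/pMMR labels.

    ``predictions`` needs sample_id and msi_status columns; ``labels`` maps
    sample_id -> {dMMR, pMMR} and must cover every predicted sample.
    """
    missing = set(predictions["sample_id"]) - set(labels.index)
    if missing:
        raise ValueError(f"labels missing for samples: {sorted(missing)[:5]}")
    pred_pos = predictions.set_index("sample_id")["msi_status"] == MSI_H
    lab = labels.loc[pred_pos.index]
    truth_pos = lab == "dMMR"
    tp = int((pred_pos & truth_pos).sum())
    fn = int((~pred_pos & truth_pos).sum())
    fp = int((pred_pos & ~truth_pos).sum())
    tn = int((~pred_pos & ~truth_pos).sum())
    return confusion_from_counts(tp, fn, fp, tn)
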