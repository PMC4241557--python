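"""Firing-pattern classification from the ISI coefficient of variation.

Spontaneous activity falls into three classes separated by two CV_ISI
thresholds: regular pacemaking (CV_ISI < 20%), irregular tonic firing
(20% <= CV_ISI <= 80%) and bursting (CV_ISI > 80%).  The boundary values
themselves are assigned to the middle (irregular) class.
"""

from __future__ import annotations

import warnings

import pandas as pd

__all__ = ["PATTERN_LABELS", "classify_firing", "pattern_proportions"]

PATTERN_LABELS: tuple[str, ...] = ("regular", "irregular", "bursting")

CV_LOW = 20.0
CV_HIGH = 80.0


def classify_firing(cv_isi: float) -> str:
    """Label a neuron's firing pattern from its CV_ISI (percent)."""
    if cv_isi < 0:
        raise ValueError(f"cv_isi must be >= 0, got {cv_isi}")
    if cv_isi < CV_LOW:
        return "regular"
    if cv_isi <= CV_HIGH:
        return "irregular"
    return "bursting"


def pattern_proportions(cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-stage fractions of the three firing-pattern labels.

    ``cohort`` needs columns ``stage`` and ``cv_isi``; rows with null CV are
    skipped.  Returns a frame indexed by stage (in cohort order of first
    appearance) with one fraction column per label plus ``n``; fractions sum
    to 1 per stage.
    """
    rows = []
    for stage, grp in cohort.groupby("stage", sort=False):
        cvs = grp["cv_isi"].dropna()
        if cvs.empty:
            warnings.warn(f"stage {stage}: no neurons with CV_ISI; excluded")
            continue
        labels = cvs.map(classify_firing)
        n = len(labels)
        counts = labels.value_counts()
        rows.append({
            "stage": stage,
            **{lab: counts.get(lab, 0) / n for lab in PATTERN_LABELS},
            "n": n,
        })
    return pd.DataFrame(rows).set_index("stage")
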