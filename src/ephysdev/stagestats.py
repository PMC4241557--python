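"""Pairwise-stage significance testing and the statistical stacking table.

Every parameter is analyzed separately with a one-way fixed-effects ANOVA
across developmental stages followed by Tukey's HSD (Tukey-Kramer for the
unbalanced stage groups).  The pairwise codes follow the protected post-hoc
convention: Tukey p-values are reported only when the omnibus ANOVA is
significant at 0.05; otherwise the parameter's whole family of comparisons
is non-significant.

The stacking table is the long-form analogue of the published grid: one row
per (stage pair, parameter) with the adjusted p and a 4-level significance
code (``ns``, ``p<0.05``, ``p<0.01``, ``p<0.001``; strict-inequality
binning).  Parameters without enough data in a stage are coded ``nm``
("not measured"), distinct from ``ns``.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .features import FEATURE_NAMES

__all__ = [
    "anova_tukey",
    "significance_code",
    "build_stacking_table",
    "CODES",
]

CODES = ("ns", "p<0.05", "p<0.01", "p<0.001")


def significance_code(p: float) -> str:
    """Finest strict significance bound satisfied by ``p``."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value {p} outside [0, 1]")
    if p < 0.001:
        return "p<0.001"
    if p < 0.01:
        return "p<0.01"
    if p < 0.05:
        return "p<0.05"
    return "ns"


def anova_tukey(
    groups: dict[str, np.ndarray],
) -> tuple[float, pd.DataFrame]:
    """One-way ANOVA p plus Tukey-HSD adjusted p for every group pair.

    Groups with fewer than 2 values are dropped with a warning.  If the data
    are degenerate (all values identical), every adjusted p is 1 rather than
    an error.  Returns ``(anova_p, frame)`` with frame columns
    ``group_a, group_b, p_adj``.
    """
    clean: dict[str, np.ndarray] = {}
    for name, vals in groups.items():
        v = np.asarray(pd.Series(vals).dropna(), dtype=float)
        if v.size < 2:
            warnings.warn(f"group {name!r} has < 2 values; dropped")
            continue
        clean[name] = v
    if len(clean) < 2:
        raise ValueError("need >= 2 groups with >= 2 values each")

    names = list(clean)
    samples = [clean[n] for n in names]
    pooled = np.concatenate(samples)
    if np.allclose(pooled, pooled[0]):
        rows = [(a, b, 1.0) for a, b in itertools.combinations(names, 2)]
        return 1.0, pd.DataFrame(rows, columns=["group_a", "group_b", "p_adj"])

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f_res = stats.f_oneway(*samples)
        anova_p = float(f_res.pvalue)
        if np.isnan(anova_p):
            anova_p = 1.0
        tk = stats.tukey_hsd(*samples)
    rows = []
    for i, j in itertools.combinations(range(len(names)), 2):
        p = float(tk.pvalue[i, j])
        if np.isnan(p):
            p = 1.0
        rows.append((names[i], names[j], min(max(p, 0.0), 1.0)))
    return anova_p, pd.DataFrame(rows, columns=["group_a", "group_b", "p_adj"])


def build_stacking_table(
    cohort: pd.DataFrame,
    parameters: tuple[str, ...] = FEATURE_NAMES,
    gate_on_anova: bool = True,
) -> pd.DataFrame:
    """All stage-pair x parameter significance codes.

    ``cohort`` needs a ``stage`` column plus the parameter columns.  Returns
    long-form columns ``stage_a, stage_b, parameter, p_adj, code`` covering
    all S*(S-1)/2 stage pairs for each parameter; pairs that could not be
    tested (parameter missing in a stage) carry ``p_adj = NaN`` and code
    ``nm``.
    """
    stages = list(dict.fromkeys(cohort["stage"]))
    if len(stages) < 2:
        raise ValueError("cohort must contain >= 2 stages")
    all_pairs = list(itertools.combinations(stages, 2))

    out = []
    for param in parameters:
        if param not in cohort.columns or cohort[param].dropna().empty:
            for a, b in all_pairs:
                out.append((a, b, param, np.nan, "nm"))
            continue
        groups = {s: cohort.loc[cohort["stage"] == s, param] for s in stages}
        if gate_on_anova:
            # protected procedure: when the omnibus ANOVA is not significant
            # the whole family is ns and the pairwise tests are not run
            clean = [np.asarray(pd.Series(v).dropna(), dtype=float)
                     for v in groups.values()]
            clean = [v for v in clean if v.size >= 2]
            if len(clean) >= 2:
                pooled = np.concatenate(clean)
                if np.allclose(pooled, pooled[0]):
                    omni = 1.0
                else:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        omni = float(stats.f_oneway(*clean).pvalue)
                if np.isnan(omni) or omni >= 0.05:
                    for a, b in all_pairs:
                        out.append((a, b, param, np.nan, "ns"))
                    continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            anova_p, pairs = anova_tukey(groups)
        lookup = {(r.group_a, r.group_b): r.p_adj
                  for r in pairs.itertuples(index=False)}
        for a, b in all_pairs:
            p = lookup.get((a, b), lookup.get((b, a)))
            if p is None:
                out.append((a, b, param, np.nan, "nm"))
                continue
            if gate_on_anova and anova_p >= 0.05:
                code = "ns"
            else:
                code = significance_code(p)
            out.append((a, b, param, p, code))
    return pd.DataFrame(
        out, columns=["stage_a", "stage_b", "parameter", "p_adj", "code"]
    )
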