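"""Pharmacology / dynamic-clamp perturbation emulation.

The study reverses developmental phenotypes with three manipulations, all of
which act on quantities this package represents as generator parameters:

* **apamin** blocks the SK-mediated afterhyperpolarization: AHP depth is
  scaled by (1 - block fraction) and, because the AHP controls firing
  regularity, the spike-train CV rises through an explicit monotone coupling
  CV' = CV * (1 + kappa * block_fraction) with a configurable gain
  ``kappa`` (a package construct; the study quantifies the coupling only
  through the measured features);
* **low-dose TTX** reduces the spike sodium current: AP amplitude and both
  10-90% slopes are scaled by ``sodium_scale``;
* a **dynamic-clamp leak** with reversal -65 mV shifts the apparent input
  resistance; the conductance required to reach a target R_in (1600 MOhm,
  the neonatal value) is pure conductance arithmetic:
  g = 1000/target - 1000/R_in (nS with MOhm inputs), negative (leak
  subtraction) for neurons leakier than the target.

Perturbed cohorts are projected into a reference PCA space as supplementary
observations; the resulting mean shift vector quantifies the phenotype
change, optionally translated ("locked") onto a pair of class centroids for
display.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .multivariate import PCAModel, project_supplementary
from .patterns import classify_firing
from .synth import NeuronGroundTruth, SpikeTrainParams, _solve_burst_structure

__all__ = [
    "LeakSpec",
    "PharmacologySpec",
    "PhenotypeShift",
    "leak_for_target",
    "apparent_r_in",
    "apply_perturbation",
    "phenotype_shift",
]


@dataclass
class LeakSpec:
    """Dynamic-clamp leak: signed conductance in nS (negative = leak
    subtraction), reversal -65 mV, adjusted per neuron to a target R_in."""

    target_r_in: float = 1600.0   # MOhm
    e_rev: float = -65.0          # mV

    def __post_init__(self) -> None:
        if self.target_r_in <= 0:
            raise ValueError("target input resistance must be > 0")


@dataclass
class PharmacologySpec:
    ahp_block_fraction: float = 0.0  # in [0, 1]
    sodium_scale: float = 1.0        # in (0, 1]
    label: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.ahp_block_fraction <= 1.0:
            raise ValueError("ahp_block_fraction must be in [0, 1]")
        if not 0.0 < self.sodium_scale <= 1.0:
            raise ValueError("sodium_scale must be in (0, 1]")


def leak_for_target(r_in: float, spec: LeakSpec | None = None) -> float:
    """Leak conductance (nS) turning ``r_in`` into the target apparent R_in."""
    spec = spec or LeakSpec()
    if r_in <= 0:
        raise ValueError("input resistance must be > 0")
    return 1000.0 / spec.target_r_in - 1000.0 / r_in


def apparent_r_in(r_in: float, g_nS: float) -> float:
    """Apparent input resistance (MOhm) with an added leak of ``g_nS``."""
    total = 1.0 / r_in + g_nS / 1000.0  # uS
    if total <= 0:
        raise ValueError("total conductance must stay positive")
    return 1.0 / total


def apply_perturbation(
    truth: NeuronGroundTruth,
    leak: LeakSpec | None = None,
    pharm: PharmacologySpec | None = None,
    kappa: float = 4.0,
) -> NeuronGroundTruth:
    """Return a perturbed copy of a neuron's ground-truth parameters.

    With neither spec given this is the identity.  Scaled parameters must
    stay invariant-legal (e.g. the sodium scale cannot push the AP peak
    below the detectable range) or a validation error is raised.
    """
    out = copy.deepcopy(truth)
    if pharm is not None:
        f = pharm.ahp_block_fraction
        ap = out.ap
        ap.ahp_depth *= (1.0 - f)
        ap.amplitude *= pharm.sodium_scale
        ap.rise_slope *= pharm.sodium_scale
        ap.decay_slope *= pharm.sodium_scale
        # keep the template feasible and the trough aligned with the new AHP
        ap.baseline = ap.threshold - ap.ahp_depth + min(3.0, 0.5 * ap.ahp_depth)
        from .synth import min_feasible_half_width
        ap.half_width = max(ap.half_width,
                            min_feasible_half_width(ap.amplitude,
                                                    ap.rise_slope,
                                                    ap.decay_slope))
        if ap.threshold + ap.amplitude <= -15.0:
            raise ValueError("sodium scaling pushed the AP peak below the "
                             "detectable range")
        cv = out.train.target_cv * (1.0 + kappa * f)
        regime = classify_firing(cv)
        m = out.train.mean_isi
        if regime == "bursting":
            n, intra, pause, sigma = _solve_burst_structure(m, cv)
            out.train = SpikeTrainParams(regime, m, cv, spikes_per_burst=n,
                                         intra_burst_isi=intra,
                                         inter_burst_interval=pause,
                                         pause_jitter=sigma)
        else:
            out.train = SpikeTrainParams(regime, m, cv)
    if leak is not None:
        g = leak_for_target(out.passive.r_in, leak)
        r_app = apparent_r_in(out.passive.r_in, g)
        out.passive.r_in = r_app
    return out


@dataclass
class PhenotypeShift:
    before_mean: np.ndarray       # mean (F1, F2) of the control condition
    after_mean: np.ndarray
    shift: np.ndarray             # after - before
    locked: tuple[np.ndarray, np.ndarray] | None = None  # anchored vector


def phenotype_shift(
    model: PCAModel,
    before: pd.DataFrame,
    after: pd.DataFrame,
    anchors: tuple[np.ndarray, np.ndarray] | None = None,
) -> PhenotypeShift:
    """Mean phenotype displacement of a paired before/after cohort.

    ``before``/``after`` are raw-unit feature tables indexed by neuron id
    (paired); both are projected as supplementary observations.  ``anchors``
    optionally locks the displayed vector onto a pair of class centroids (the
    vector is translated, its components unchanged).
    """
    if not before.index.equals(after.index):
        raise ValueError("before/after cohorts must be paired by neuron id")
    sb = project_supplementary(model, before)[:, :2]
    sa = project_supplementary(model, after)[:, :2]
    mb, ma = sb.mean(axis=0), sa.mean(axis=0)
    shift = ma - mb
    locked = None
    if anchors is not None:
        start = np.asarray(anchors[0], dtype=float)[:2]
        locked = (start, start + shift)
    return PhenotypeShift(before_mean=mb, after_mean=ma, shift=shift,
                          locked=locked)
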