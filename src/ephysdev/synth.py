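"""Synthetic cohort generator calibrated to the published stage statistics.

No raw recordings were deposited with the study this package operationalizes,
so the pipeline is exercised on synthetic neurons whose per-stage parameter
distributions are calibrated to the published descriptive table (mean/SD/N of
the 16 electrophysiological parameters over 15 postnatal stages, P2-P29; the
transcription ships as ``data/table1_calibration.csv``).

The generative choices (none of which the source study specifies) are the
simplest processes able to hit the calibration targets:

* spike trains: gamma-renewal ISIs for regular/irregular regimes (CV is
  controlled in closed form, CV = 1/sqrt(shape)); an alternating burst/pause
  renewal process for bursting neurons, with the burst structure solved so
  that the composite ISI mean and CV hit their targets;
* action potentials: an analytic piecewise template (cosine rise of
  prescribed 10-90% mean slope, piecewise-linear decay, eased
  afterhyperpolarization trough) constructed so that every extracted metric
  has a closed-form target — the generator/extractor round trip is the
  package's primary correctness surface;
* passive responses: ideal RC charging curves; sag responses: a
  double-exponential relaxation solved numerically so the measured sag equals
  the requested amplitude; f-I responses: spike trains whose first/last
  instantaneous frequencies equal the gain-implied targets exactly, with a
  geometric interspike-interval bridge emulating adaptation.

Parameters are drawn from truncated normals per stage; truncation intervals
are symmetrized around the mean so sample means remain unbiased estimators of
the calibration means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .features import FEATURE_NAMES
from .patterns import classify_firing
from .traces import STAGE_BINS, RecordingSet, VoltageTrace

__all__ = [
    "APShapeParams",
    "SpikeTrainParams",
    "PassiveGroundTruth",
    "GainGroundTruth",
    "NeuronGroundTruth",
    "StageCalibration",
    "load_default_calibration",
    "sample_neuron_params",
    "gen_spike_times",
    "render_ap",
    "render_spontaneous",
    "gen_passive_pulse",
    "gen_sag_pulse",
    "gen_fi_set",
    "generate_recording",
    "generate_cohort",
    "iter_cohort",
    "sample_feature_cohort",
    "default_plan",
    "ground_truth_features",
]

#: band-time factor of the cosine rise: time spent between the 10% and 90%
#: amplitude levels is DTHETA/pi of the rise duration.
_DTHETA = math.acos(-0.8) - math.acos(0.8)
_RISE_FACTOR = 0.8 * math.pi / _DTHETA  # T_rise = _RISE_FACTOR * A / slope


# ---------------------------------------------------------------------------
# Parameter containers


@dataclass
class APShapeParams:
    """Analytic AP template parameters (all closed-form extraction targets)."""

    threshold: float       # mV
    amplitude: float       # mV, threshold -> peak
    half_width: float      # ms at half height
    rise_slope: float      # mV/ms, 10-90% mean
    decay_slope: float     # mV/ms, negative
    ahp_depth: float       # mV, threshold -> trough
    ahp_duration: float = 25.0   # ms, trough -> baseline relaxation
    baseline: float = -60.0      # mV, inter-spike voltage

    def __post_init__(self) -> None:
        if self.amplitude <= 0 or self.half_width <= 0:
            raise ValueError("amplitude and half_width must be > 0")
        if not (self.rise_slope > 0 > self.decay_slope):
            raise ValueError("need rise_slope > 0 > decay_slope")
        if self.ahp_depth < 0:
            raise ValueError("ahp_depth must be >= 0")
        if self.baseline >= self.threshold:
            raise ValueError("baseline must lie below threshold")


@dataclass
class SpikeTrainParams:
    """Spontaneous spike-train description.

    ``mean_isi`` in seconds, ``target_cv`` in percent.  The regime must be
    consistent with the 20/80% CV classification.  Burst structure fields are
    used only for the bursting regime.
    """

    regime: str
    mean_isi: float
    target_cv: float
    spikes_per_burst: int = 0
    intra_burst_isi: float = 0.0   # s
    inter_burst_interval: float = 0.0  # s (pause mean)
    pause_jitter: float = 0.0      # s (pause SD)

    def __post_init__(self) -> None:
        if self.mean_isi <= 0 or self.target_cv < 0:
            raise ValueError("mean_isi must be > 0 and target_cv >= 0")
        if self.regime != classify_firing(self.target_cv):
            raise ValueError(
                f"regime {self.regime!r} inconsistent with CV "
                f"{self.target_cv:.1f}% under the 20/80% rule"
            )
        if self.regime == "bursting":
            if self.spikes_per_burst < 2:
                raise ValueError("bursting needs >= 2 spikes per burst")
            if self.inter_burst_interval <= self.intra_burst_isi:
                raise ValueError("burst pause must exceed the intra-burst ISI")


@dataclass
class PassiveGroundTruth:
    r_in: float            # MOhm
    c_m: float             # pF
    sag_amp: float         # mV
    sag_tau: float         # ms
    rebound_delay: float   # ms
    resting: float = -60.0  # mV

    def __post_init__(self) -> None:
        if self.r_in <= 0 or self.c_m <= 0:
            raise ValueError("r_in and c_m must be > 0")

    @property
    def tau_m(self) -> float:
        """Implied membrane time constant, ms (R_in * C_m)."""
        return self.r_in * self.c_m * 1e-3


@dataclass
class GainGroundTruth:
    gain_start: float      # Hz/100 pA
    gain_end: float        # Hz/100 pA
    rheobase: float        # pA
    saturation: float      # pA

    def __post_init__(self) -> None:
        if self.gain_start <= 0 or self.gain_end <= 0:
            raise ValueError("gains must be > 0")

    @property
    def sfa_index(self) -> float:
        return self.gain_start / self.gain_end


@dataclass
class NeuronGroundTruth:
    ap: APShapeParams
    train: SpikeTrainParams
    passive: PassiveGroundTruth
    gain: GainGroundTruth


class StageCalibration:
    """Per-stage (mean, SD, N) of the 16 parameters."""

    def __init__(self, table: pd.DataFrame):
        required = {"stage", "parameter", "mean", "sd", "n"}
        if not required.issubset(table.columns):
            raise ValueError(f"calibration table needs columns {sorted(required)}")
        if (table["sd"] < 0).any():
            raise ValueError("calibration SDs must be >= 0")
        self.table = table.set_index(["stage", "parameter"])
        self.stages = list(dict.fromkeys(table["stage"]))

    @classmethod
    def from_csv(cls, path) -> "StageCalibration":
        return cls(pd.read_csv(path))

    def get(self, stage: str, parameter: str) -> tuple[float, float, int]:
        try:
            row = self.table.loc[(stage, parameter)]
        except KeyError:
            raise KeyError(f"no calibration for ({stage!r}, {parameter!r})") from None
        return float(row["mean"]), float(row["sd"]), int(row["n"])

    def maturation_directions(self) -> dict[str, float]:
        """Sign of each parameter's developmental trend (late vs early stage).

        Used to orient the latent within-stage maturation factor: +1 for
        parameters that grow with age, -1 for those that shrink, 0 for
        parameters whose early/late difference is small against the SD.
        """
        first, last = self.stages[0], self.stages[-1]
        out = {}
        for param in {p for _, p in self.table.index}:
            m0, s0, _ = self.get(first, param)
            m1, s1, _ = self.get(last, param)
            delta = m1 - m0
            scale = 0.5 * (s0 + s1)
            out[param] = 0.0 if abs(delta) < 0.5 * scale else math.copysign(1.0, delta)
        return out


def load_default_calibration() -> StageCalibration:
    """The shipped transcription of the published stage statistics."""
    with resources.files("ephysdev.data").joinpath(
        "table1_calibration.csv"
    ).open() as fh:
        return StageCalibration(pd.read_csv(fh))


# ---------------------------------------------------------------------------
# Parameter sampling


def _sym_trunc_normal(
    rng: np.random.Generator, mean: float, sd: float,
    lo: float = -np.inf, hi: float = np.inf,
) -> float:
    """Normal draw truncated to an interval symmetric about the mean.

    The symmetric interval (half-width = min(mean-lo, hi-mean, 4 sd)) keeps
    the truncated mean equal to ``mean``; the SD shrinks slightly when a legal
    bound lies within ~2 sd of the mean.
    """
    if sd == 0:
        return mean
    half = min(mean - lo, hi - mean, 4.0 * sd)
    if half <= 0:
        raise ValueError(f"mean {mean} not interior to bounds [{lo}, {hi}]")
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if abs(x - mean) <= half:
            return x
    return mean  # pragma: no cover - p(reject all) astronomically small


#: invariant-legal (and instrument-visible) sampling bounds per parameter.
_BOUNDS: dict[str, tuple[float, float]] = {
    "isi_avg": (0.15, np.inf),
    "cv_isi": (0.0, np.inf),
    "r_in": (50.0, np.inf),
    "c_m": (20.0, np.inf),
    "sag": (0.0, np.inf),
    "rebound": (20.0, np.inf),
    "ap_threshold": (-70.0, -25.0),
    "ap_amplitude": (25.0, np.inf),
    "ap_half_width": (0.5, np.inf),
    # the spike detector's 10 mV/ms criterion cannot see APs with peak dV/dt
    # below ~14 mV/ms; the published rise slopes never reach that low
    "ap_rise_slope": (12.0, np.inf),
    "ap_decay_slope": (-np.inf, -6.0),
    "ahp": (0.5, np.inf),
    "gain_start": (1.0, np.inf),
    "gain_end": (1.0, np.inf),
}

_INTRA_BURST_ISI = 0.08   # s, default intra-burst ISI preset
_MAX_SPIKES_PER_BURST = 10


def _solve_burst_structure(mean_isi: float, cv_pct: float) -> tuple[int, float, float, float]:
    """Burst structure (n, intra, pause, pause SD) hitting mean and CV.

    With n spikes per burst, fixed intra-burst ISI i and pause mean p
    (p = n*m - (n-1)*i so the composite mean is m), the composite CV**2 is
    ((n-1) d**2 + sigma**2/n) / m**2 with d = m - i and sigma the pause SD.
    The deterministic part sqrt(n-1)*d/m grows with n: pick the largest n
    whose deterministic CV does not overshoot, then add pause jitter to make
    up the difference; if even two-spike bursts overshoot at the preset
    intra-burst ISI, lengthen the intra-burst ISI instead.
    """
    cv = cv_pct / 100.0
    m = mean_isi
    intra = _INTRA_BURST_ISI
    if intra >= m:
        intra = 0.5 * m
    d = m - intra
    if d / m > cv:  # even n=2 overshoots: lengthen the intra-burst ISI
        n = 2
        intra = m * (1.0 - cv)
        d = m - intra
        sigma = 0.0
    else:
        n = 2
        for cand in range(3, _MAX_SPIKES_PER_BURST + 1):
            if math.sqrt(cand - 1) * d / m <= cv:
                n = cand
            else:
                break
        sigma2 = n * ((m * cv) ** 2 - (n - 1) * d ** 2)
        sigma = math.sqrt(max(0.0, sigma2))
    pause = n * m - (n - 1) * intra
    return n, intra, pause, sigma


def min_feasible_half_width(amplitude: float, rise_slope: float,
                            decay_slope: float) -> float:
    """Smallest half-width renderable for the given amplitude and slopes."""
    t_rise = _RISE_FACTOR * amplitude / rise_slope
    t_band = 0.8 * amplitude / abs(decay_slope)
    # rise half + minimum plateau + upper-fall segment + 10% of the band
    return t_rise / 2.0 + 0.1 + 0.1 * t_band + 0.1 * t_band


def sample_neuron_params(
    stage: str,
    calibration: StageCalibration,
    rng: np.random.Generator,
    maturation_rho: float = 0.6,
) -> NeuronGroundTruth:
    """Draw one neuron's ground-truth parameters for a stage.

    Each parameter comes from a mean-preserving truncated normal around the
    stage calibration.  A latent per-neuron maturation factor (loading
    ``maturation_rho`` on every trending parameter, oriented by the
    calibration's developmental direction) couples the parameters within a
    neuron — a cell that is more mature than its stage-mates in one property
    is more mature in the others — while leaving every marginal mean and SD
    exactly as calibrated.  The firing regime follows from the drawn CV via
    the 20/80% rule; the AP half-width is clipped into the template-feasible
    range implied by the drawn amplitude and slopes (the clipped value is
    the ground truth of record).
    """
    if stage not in calibration.stages:
        raise KeyError(f"unknown stage {stage!r}")
    if not 0.0 <= maturation_rho < 1.0:
        raise ValueError("maturation_rho must be in [0, 1)")
    directions = calibration.maturation_directions()
    u = rng.normal()  # latent maturation of this neuron within its stage
    resid = math.sqrt(1.0 - maturation_rho ** 2)

    def draw(param: str) -> float:
        mean, sd, _ = calibration.get(stage, param)
        lo, hi = _BOUNDS.get(param, (-np.inf, np.inf))
        d = directions.get(param, 0.0)
        if sd == 0:
            return mean
        half = min(mean - lo, hi - mean, 4.0 * sd)
        if half <= 0:
            raise ValueError(f"{param}: mean not interior to bounds")
        for _ in range(1000):
            z = rng.normal()
            x = mean + sd * (maturation_rho * d * u + resid * z) if d \
                else mean + sd * z
            if abs(x - mean) <= half:
                return x
        return mean  # pragma: no cover

    # AP shape; re-draw until the peak is visible to the spike detector
    for _ in range(100):
        thr = draw("ap_threshold")
        amp = draw("ap_amplitude")
        if thr + amp > -15.0:
            break
    rise = draw("ap_rise_slope")
    decay = draw("ap_decay_slope")
    ahp = draw("ahp")
    hw = max(draw("ap_half_width"), min_feasible_half_width(amp, rise, decay))
    baseline = thr - ahp + min(3.0, 0.5 * ahp)
    ap = APShapeParams(threshold=thr, amplitude=amp, half_width=hw,
                       rise_slope=rise, decay_slope=decay, ahp_depth=ahp,
                       baseline=baseline)

    mean_isi = draw("isi_avg")
    cv = draw("cv_isi")
    regime = classify_firing(cv)
    if regime == "bursting":
        n, intra, pause, sigma = _solve_burst_structure(mean_isi, cv)
        train = SpikeTrainParams(regime, mean_isi, cv, spikes_per_burst=n,
                                 intra_burst_isi=intra,
                                 inter_burst_interval=pause,
                                 pause_jitter=sigma)
    else:
        train = SpikeTrainParams(regime, mean_isi, cv)

    passive = PassiveGroundTruth(
        r_in=draw("r_in"), c_m=draw("c_m"),
        sag_amp=draw("sag"),
        sag_tau=_sym_trunc_normal(rng, 120.0, 20.0, 40.0),
        rebound_delay=draw("rebound"),
        resting=_sym_trunc_normal(rng, -60.0, 2.0, -75.0, -50.0),
    )
    gain = GainGroundTruth(
        gain_start=draw("gain_start"), gain_end=draw("gain_end"),
        rheobase=_sym_trunc_normal(rng, 25.0, 8.0, 5.0, 45.0),
        saturation=400.0,
    )
    return NeuronGroundTruth(ap=ap, train=train, passive=passive, gain=gain)


# ---------------------------------------------------------------------------
# Spike trains


def gen_spike_times(
    params: SpikeTrainParams,
    duration_s: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Spontaneous spike times (seconds) over ``duration_s``.

    Regular/irregular regimes use a gamma-renewal process (shape
    1/CV**2, so the ISI CV equals the target in closed form; CV = 0 gives a
    perfectly periodic train).  Bursting uses the alternating burst/pause
    process described by the train parameters.
    """
    if duration_s < 60.0:
        raise ValueError("duration must be >= 60 s (40 s analysis window)")
    m = params.mean_isi
    if params.regime in ("regular", "irregular"):
        cv = params.target_cv / 100.0
        n = int(duration_s / m * 1.5) + 30
        if cv == 0:
            isis = np.full(n, m)
        else:
            shape = 1.0 / cv ** 2
            isis = rng.gamma(shape, m * cv ** 2, size=n)
        t = np.cumsum(isis)
        return t[t <= duration_s]

    # bursting: bursts of fixed intra-burst ISIs separated by jittered pauses
    nb, intra, pause, sigma = (params.spikes_per_burst, params.intra_burst_isi,
                               params.inter_burst_interval, params.pause_jitter)
    times: list[float] = []
    t = 0.3 * pause
    while t <= duration_s:
        for k in range(nb):
            tk = t + k * intra
            if tk > duration_s:
                break
            times.append(tk)
        if sigma > 0:
            shape = (pause / sigma) ** 2
            p = rng.gamma(shape, sigma ** 2 / pause)
            p = max(p, 1.5 * intra)
        else:
            p = pause
        t = t + (nb - 1) * intra + p
    return np.asarray(times)


# ---------------------------------------------------------------------------
# AP template


@dataclass
class APTemplate:
    """Rendered analytic AP waveform (starts and ends at the baseline)."""

    voltage: np.ndarray
    time_step: float
    peak_index: int
    params: APShapeParams = field(repr=False, default=None)  # type: ignore

    @property
    def support_ms(self) -> float:
        return self.voltage.size * self.time_step


def render_ap(
    shape: APShapeParams,
    time_step: float,
    approach_ms: float = 8.0,
) -> APTemplate:
    """Render the analytic AP template on a uniform grid.

    Construction (all segments analytic, times in ms):

    1. *fast foot*: half-cosine from baseline toward threshold, peak
       velocity capped at 7 mV/ms (below the detector criterion);
    2. *slow approach* (``approach_ms``): half-cosine covering the last
       stretch below threshold with velocity < 5% of the rise's peak dV/dt,
       so the threshold criterion lands at ``threshold``;
    3. *rise*: half-cosine from threshold to threshold+amplitude over
       T_r = 1.3552 A / rise_slope, whose 10-90% time-average slope equals
       ``rise_slope`` exactly;
    4. *plateau*: a short flat peak whose duration absorbs the half-width
       degree of freedom;
    5. *decay*: three linear segments (peak->90%, 90%->50%, 50%->10% of
       amplitude above threshold) whose durations are solved so that the
       half-width and the 10-90% mean decay slope both hit their targets;
    6. *AHP*: linear descent to the trough with a quadratic easing (so the
       sampled minimum equals threshold - ahp_depth), then a half-cosine
       relaxation to baseline over ``ahp_duration``.
    """
    if time_step > 0.1:
        raise ValueError("AP rendering needs time_step <= 0.1 ms")
    p = shape
    A, thr, b = p.amplitude, p.threshold, p.baseline

    t_rise = _RISE_FACTOR * A / p.rise_slope
    s_max = math.pi * A / (2.0 * t_rise)
    t_band = 0.8 * A / abs(p.decay_slope)

    # half-width bookkeeping: rise half + plateau + (peak->90%) + (90%->50%)
    tau_p = 0.1
    t_f1 = 0.1 * t_band
    needed = p.half_width - t_rise / 2.0 - tau_p - t_f1
    if needed < 0.05 * t_band:
        raise ValueError(
            f"half_width {p.half_width:.2f} ms too small for amplitude "
            f"{A:.1f} mV with slopes ({p.rise_slope:.1f}, {p.decay_slope:.1f})"
        )
    if needed > 0.95 * t_band:
        tau_a = 0.5 * t_band
        tau_p += needed - tau_a
    else:
        tau_a = needed
    tau_b = t_band - tau_a
    s2b = 0.4 * A / tau_b  # |slope| of the 50%->10% segment

    # slow approach gap: velocity < 5% of s_max with 20% margin
    gap = min(thr - b, 0.04 * s_max * 2.0 * approach_ms / math.pi)
    h_fast = thr - b - gap
    t_fast = math.pi * h_fast / (2.0 * 7.0) if h_fast > 1e-9 else 0.0

    # AHP: linear from 10% level to the eased trough
    drop3 = 0.1 * A + p.ahp_depth
    ease = min(0.4, 2.0 * drop3 / s2b) if s2b > 0 else 0.0
    drop_lin = drop3 - s2b * ease / 2.0
    t_f3 = max(drop_lin, 0.0) / s2b if s2b > 0 else 0.0

    dt = time_step
    trough = thr - p.ahp_depth
    # segments as (duration, v(t_local)) in continuous time; the grid is
    # sampled afterwards so no per-segment rounding error accumulates
    segments: list[tuple[float, object]] = []

    def cosine(v0: float, v1: float, T: float) -> None:
        if T > 0:
            segments.append(
                (T, lambda tl, v0=v0, v1=v1, T=T:
                    v0 + (v1 - v0) * 0.5 * (1.0 - np.cos(math.pi * tl / T))))

    def linear(v0: float, v1: float, T: float) -> None:
        if T > 0:
            segments.append(
                (T, lambda tl, v0=v0, v1=v1, T=T: v0 + (v1 - v0) * tl / T))

    cosine(b, b + h_fast, t_fast)                      # fast foot
    cosine(b + h_fast, thr, approach_ms)               # slow approach
    cosine(thr, thr + A, t_rise)                       # rise
    # the plateau carries a 0.03 mV dome so the peak sample is unambiguous
    # even when the template sits on a slowly drifting baseline
    segments.append(
        (tau_p, lambda tl, T=tau_p:
            thr + A + 0.03 * (1.0 - np.abs(tl - T / 2.0) / (T / 2.0))))
    linear(thr + A, thr + 0.9 * A, t_f1)               # peak -> 90%
    linear(thr + 0.9 * A, thr + 0.5 * A, tau_a)        # 90% -> 50%
    linear(thr + 0.5 * A, thr + 0.1 * A, tau_b)        # 50% -> 10%
    if t_f3 > 0:
        linear(thr + 0.1 * A, trough + s2b * ease / 2.0, t_f3)
    if ease > 0:
        segments.append(
            (ease, lambda tl, E=ease:
                trough + (s2b / (2.0 * E)) * (tl - E) ** 2))
    cosine(trough, b, p.ahp_duration)                  # recovery

    total = sum(T for T, _ in segments)
    n = int(math.floor(total / dt)) + 2
    t = np.arange(n) * dt
    v = np.full(n, b)
    t0 = 0.0
    for T, fn in segments:
        mask = (t >= t0) & (t < t0 + T)
        if mask.any():
            v[mask] = fn(t[mask] - t0)
        t0 += T
    peak_index = int(np.argmax(v))
    return APTemplate(voltage=v, time_step=dt, peak_index=peak_index, params=p)


def render_spontaneous(
    spike_times_s: np.ndarray,
    shape: APShapeParams,
    duration_s: float,
    time_step: float = 0.05,
    noise_sd: float = 0.3,
    rng: np.random.Generator | None = None,
    label: str = "spontaneous",
) -> VoltageTrace:
    """Paste AP templates at the given spike times over a (noisy) baseline.

    Spikes closer together than the template support are rejected; spikes
    whose template does not fit inside the trace are dropped.
    """
    tpl = render_ap(shape, time_step)
    dt = time_step
    n = int(round(duration_s * 1000.0 / dt))
    times_ms = np.asarray(spike_times_s, dtype=float) * 1000.0
    if times_ms.size > 1 and np.min(np.diff(times_ms)) < tpl.support_ms:
        raise ValueError(
            f"spikes closer than the template support ({tpl.support_ms:.1f} ms)"
        )
    if noise_sd > 0:
        if rng is None:
            raise ValueError("rng required when noise_sd > 0")
        v = rng.normal(0.0, noise_sd, size=n)
    else:
        v = np.zeros(n)
    v += shape.baseline
    rel = tpl.voltage - shape.baseline
    m = rel.size
    for t_ms in times_ms:
        start = int(round(t_ms / dt)) - tpl.peak_index
        if start < 0 or start + m > n:
            continue
        v[start:start + m] += rel
    return VoltageTrace(dt, v, label=label)


# ---------------------------------------------------------------------------
# Current-injection protocols


def gen_passive_pulse(
    truth: PassiveGroundTruth,
    step_pA: float,
    duration_ms: float = 1000.0,
    time_step: float = 0.05,
    pre_ms: float = 200.0,
    post_ms: float = 300.0,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> VoltageTrace:
    """Ideal RC response to a small hyperpolarizing pulse (no sag).

    V(t) = resting + step * R_in * (1 - exp(-t/tau)), tau = R_in * C_m; the
    plateau must stay below the 10 mV inclusion rule.
    """
    dv = step_pA * truth.r_in * 1e-3  # mV
    if abs(dv) >= 10.0:
        raise ValueError(
            f"step {step_pA:.0f} pA would deflect {abs(dv):.1f} mV "
            "(>= 10 mV rule)"
        )
    tau = truth.tau_m
    dt = time_step
    n_pre, n_pulse, n_post = (int(round(x / dt)) for x in
                              (pre_ms, duration_ms, post_ms))
    t = np.arange(n_pulse) * dt
    pulse = truth.resting + dv * (1.0 - np.exp(-t / tau))
    t2 = np.arange(n_post) * dt
    off = truth.resting + (pulse[-1] - truth.resting) * np.exp(-t2 / tau)
    v = np.concatenate([np.full(n_pre, truth.resting), pulse, off])
    if noise_sd > 0:
        if rng is None:
            raise ValueError("rng required when noise_sd > 0")
        v = v + rng.normal(0.0, noise_sd, size=v.size)
    c = np.zeros(v.size)
    c[n_pre:n_pre + n_pulse] = step_pA
    return VoltageTrace(dt, v, c, label="passive_pulse")


def gen_sag_pulse(
    truth: PassiveGroundTruth,
    shape: APShapeParams,
    pulse_ms: float = 1000.0,
    time_step: float = 0.05,
    pre_ms: float = 200.0,
    post_ms: float = 1200.0,
    end_voltage: float = -85.0,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> VoltageTrace:
    """Hyperpolarizing pulse with a sag relaxation and a rebound spike.

    The response is a double exponential — a fast RC hyperpolarization
    overshooting to a trough plus a slower depolarizing relaxation
    (``sag_tau``) — with the two amplitudes solved numerically so the trace
    ends at ``end_voltage`` and the measured sag (mean of the last 50 ms
    minus the trough) equals ``sag_amp``.  A rebound AP is pasted
    ``rebound_delay`` ms after pulse offset.
    """
    r = truth.resting
    if r <= end_voltage:
        raise ValueError("resting potential must lie above the -85 mV target")
    tau1 = truth.tau_m
    # the sag relaxation must be slower than the membrane charge for a
    # trough to exist; high-R_in neonatal neurons can have tau_m > sag_tau
    tau2 = max(truth.sag_tau, 2.0 * tau1)
    dt = time_step
    n_pulse = int(round(pulse_ms / dt))
    t = np.arange(n_pulse) * dt
    e1 = 1.0 - np.exp(-t / tau1)
    e2 = 1.0 - np.exp(-t / tau2)
    n_tail = max(1, int(round(50.0 / dt)))

    def pulse_for(S: float) -> np.ndarray:
        D = (end_voltage - r - S * e2[-1]) / e1[-1]
        return r + D * e1 + S * e2

    def sag_of(S: float) -> float:
        v = pulse_for(S)
        return float(np.mean(v[-n_tail:]) - np.min(v))

    if truth.sag_amp <= sag_of(0.0) + 1e-9:
        S = 0.0
    else:
        hi = 2.0 * truth.sag_amp + 5.0
        for _ in range(30):
            if sag_of(hi) > truth.sag_amp:
                break
            hi *= 1.5
        else:
            raise ValueError(
                f"sag amplitude {truth.sag_amp:.1f} mV not reachable with "
                "the available hyperpolarization"
            )
        S = brentq(lambda s: sag_of(s) - truth.sag_amp, 0.0, hi, xtol=1e-6)
    pulse = pulse_for(S)

    n_pre = int(round(pre_ms / dt))
    n_post = int(round(post_ms / dt))
    t2 = np.arange(n_post) * dt
    off = r + (pulse[-1] - r) * np.exp(-t2 / tau1)
    v = np.concatenate([np.full(n_pre, r), pulse, off])

    # rebound AP pasted with its peak rebound_delay after pulse offset; a
    # slow depolarizing ramp lifts the (still recovering) trajectory onto the
    # template baseline so the spike peaks at its physiological height
    tpl = render_ap(shape, dt)
    rel = tpl.voltage - shape.baseline
    start = n_pre + n_pulse + int(round(truth.rebound_delay / dt)) - tpl.peak_index
    if start >= 0 and start + rel.size <= v.size:
        i_off = n_pre + n_pulse
        delta = shape.baseline - v[start]
        if start > i_off:
            v[i_off:start] += delta * np.linspace(0.0, 1.0, start - i_off)
        v[start:start + rel.size] += delta
        n_back = min(int(round(200.0 / dt)), v.size - start - rel.size)
        if n_back > 0:
            j = start + rel.size
            v[j:j + n_back] += delta * np.linspace(1.0, 0.0, n_back)
        v[start:start + rel.size] += rel

    if noise_sd > 0:
        if rng is None:
            raise ValueError("rng required when noise_sd > 0")
        v = v + rng.normal(0.0, noise_sd, size=v.size)
    step_pA = (end_voltage - r) / (truth.r_in * 1e-3)
    c = np.zeros(v.size)
    c[n_pre:n_pre + n_pulse] = step_pA
    return VoltageTrace(dt, v, c, label="sag_pulse")


def _narrow_template(time_step: float) -> APTemplate:
    """Compact AP used for f-I trains (only spike *times* matter there)."""
    shape = APShapeParams(threshold=-45.0, amplitude=65.0, half_width=0.9,
                          rise_slope=150.0, decay_slope=-80.0, ahp_depth=6.0,
                          ahp_duration=4.0, baseline=-52.0)
    return render_ap(shape, time_step, approach_ms=2.0)


def _fi_isi_ladder(d_start: float, d_end: float, pulse_ms: float) -> np.ndarray:
    """Increments whose cumulative sum gives the pulse's spike times (ms).

    The first element is the latency to the first spike (one start period);
    the two following interspike intervals equal ``d_start`` and the final
    ones ``d_end``, with a geometric bridge between, filling ``pulse_ms``.
    """
    base = 3 * d_start + 2 * d_end
    if base > pulse_ms:
        # too slow to express the adaptation profile: emit at most 3 spikes
        # at the start period so downstream gain fits exclude the pulse
        # rather than read a biased frequency from it
        n = min(3, int(pulse_ms // d_start))
        return np.full(max(n, 1), d_start)
    best = [d_start, d_start, d_start, d_end, d_end]
    m = 1
    while True:
        r = (d_end / d_start) ** (1.0 / (m + 1))
        mid = [d_start * r ** k for k in range(1, m + 1)]
        cand = [d_start, d_start, d_start] + mid + [d_end, d_end]
        if sum(cand) > pulse_ms:
            break
        best = cand
        m += 1
    while sum(best) + d_end <= pulse_ms:
        best.append(d_end)
    return np.asarray(best)


def gen_fi_set(
    truth: GainGroundTruth,
    currents: list[float],
    pulse_ms: float = 1000.0,
    time_step: float = 0.05,
    pre_ms: float = 200.0,
    post_ms: float = 200.0,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> list[tuple[VoltageTrace, float]]:
    """Responses to incremental 1 s depolarizing pulses.

    In the linear regime (rheobase < I < saturation) the instantaneous
    frequency decays from gain_start*I/100 to gain_end*I/100 Hz during the
    pulse; the first/last interspike intervals equal the implied start/end
    periods exactly.  Above saturation (or when the implied rate outruns the
    spike template) firing ceases 400 ms into the pulse, emulating
    depolarization block.
    """
    if not currents:
        raise ValueError("empty current list")
    tpl = _narrow_template(time_step)
    dt = time_step
    n_pre, n_pulse, n_post = (int(round(x / dt)) for x in
                              (pre_ms, pulse_ms, post_ms))
    out = []
    for amp in currents:
        v = np.full(n_pre + n_pulse + n_post, -60.0)
        ramp = min(400, n_pulse)  # 20 ms depolarization to a -55 mV plateau
        v[n_pre:n_pre + ramp] += np.linspace(0.0, 5.0, ramp)
        v[n_pre + ramp:n_pre + n_pulse] += 5.0
        v[n_pre + n_pulse:] = -60.0

        spike_ms: np.ndarray | None = None
        if amp > truth.rheobase:
            f_s = truth.gain_start * amp / 100.0
            f_e = truth.gain_end * amp / 100.0
            d_s, d_e = 1000.0 / f_s, 1000.0 / f_e
            if amp >= truth.saturation or min(d_s, d_e) < tpl.support_ms:
                d_block = max(min(d_s, d_e), tpl.support_ms)
                n_spk = int(0.4 * pulse_ms / d_block)
                spike_ms = d_block * np.arange(1, n_spk + 1)
            else:
                spike_ms = np.cumsum(_fi_isi_ladder(d_s, d_e, pulse_ms))
        if spike_ms is not None:
            rel = tpl.voltage - (-55.0)
            for t_ms in spike_ms:
                start = n_pre + int(round(t_ms / dt)) - tpl.peak_index
                if start >= 0 and start + rel.size <= v.size:
                    v[start:start + rel.size] += rel
        if noise_sd > 0:
            if rng is None:
                raise ValueError("rng required when noise_sd > 0")
            v = v + rng.normal(0.0, noise_sd, size=v.size)
        c = np.zeros(v.size)
        c[n_pre:n_pre + n_pulse] = amp
        out.append((VoltageTrace(dt, v, c, label=f"fi_{amp:.0f}pA"), amp))
    return out


# ---------------------------------------------------------------------------
# Cohort assembly


def ground_truth_features(truth: NeuronGroundTruth) -> dict[str, float]:
    """The 16 feature values the extractor should recover for this neuron."""
    return {
        "isi_avg": truth.train.mean_isi,
        "cv_isi": truth.train.target_cv,
        "tau_m": truth.passive.tau_m,
        "r_in": truth.passive.r_in,
        "c_m": truth.passive.c_m,
        "sag": truth.passive.sag_amp,
        "rebound": truth.passive.rebound_delay,
        "ap_threshold": truth.ap.threshold,
        "ap_amplitude": truth.ap.amplitude,
        "ap_half_width": truth.ap.half_width,
        "ap_rise_slope": truth.ap.rise_slope,
        "ap_decay_slope": truth.ap.decay_slope,
        "ahp": truth.ap.ahp_depth,
        "gain_start": truth.gain.gain_start,
        "gain_end": truth.gain.gain_end,
        "sfa_index": truth.gain.sfa_index,
    }


_FI_CURRENTS = [50.0, 100.0, 150.0, 200.0, 250.0, 300.0]


def _fi_currents_for(gain: GainGroundTruth, pulse_ms: float = 1000.0,
                     n_steps: int = 6, step: float = 50.0) -> list[float]:
    """Auto-ranged pulse amplitudes: slow low-gain neurons need stronger
    currents before a 1 s pulse holds enough APs for the gain fit."""
    i_need = (3.0 / gain.gain_start + 2.0 / gain.gain_end) \
        * 1000.0 * 100.0 / pulse_ms
    i0 = step * max(1, math.ceil(i_need / step))
    return [i0 + step * k for k in range(n_steps)]


def generate_recording(
    neuron_id: str,
    stage: str,
    truth: NeuronGroundTruth,
    rng: np.random.Generator,
    duration_s: float = 60.0,
    noise_sd: float = 0.3,
    time_step: float = 0.05,
) -> tuple[RecordingSet, dict[str, float]]:
    """Render the full protocol set for one neuron.

    Returns the recording plus the neuron's ground-truth feature dict, in
    which ``isi_avg``/``cv_isi`` are the *realized* statistics of the emitted
    spike train (the quantity a perfect extractor would recover).
    """
    lo, hi = STAGE_BINS[stage]
    age = int(rng.integers(lo, hi + 1))

    spikes_s = gen_spike_times(truth.train, duration_s, rng)
    spikes_s = spikes_s[(spikes_s > 0.2) & (spikes_s < duration_s - 0.2)]
    # refractory thinning: drop spikes closer than the template support
    tpl = render_ap(truth.ap, time_step)
    min_sep = (tpl.support_ms + 1.0) / 1000.0
    kept = [spikes_s[0]] if spikes_s.size else []
    for t in spikes_s[1:]:
        if t - kept[-1] >= min_sep:
            kept.append(t)
    spikes_s = np.asarray(kept)
    spont = render_spontaneous(spikes_s, truth.ap, duration_s, time_step,
                               noise_sd=noise_sd, rng=rng)
    step = -5.0 * 1000.0 / truth.passive.r_in  # -5 mV deflection
    passive = [
        (gen_passive_pulse(truth.passive, step, time_step=time_step,
                           noise_sd=noise_sd, rng=rng), step)
        for _ in range(2)
    ]
    sag_tr = gen_sag_pulse(truth.passive, truth.ap, time_step=time_step,
                           noise_sd=noise_sd, rng=rng)
    sag_step = float(sag_tr.current.min())
    currents = _fi_currents_for(truth.gain)
    truth.gain.saturation = max(truth.gain.saturation, currents[-1] + 50.0)
    fi = gen_fi_set(truth.gain, currents, time_step=time_step,
                    noise_sd=noise_sd, rng=rng)

    rec = RecordingSet(neuron_id=neuron_id, age_days=age, stage=stage,
                       spontaneous=spont, passive_pulses=passive,
                       sag_pulse=(sag_tr, sag_step), fi_pulses=fi)

    gt = ground_truth_features(truth)
    if spikes_s.size >= 3:
        isis = np.diff(spikes_s * 1000.0) / 1000.0
        gt["isi_avg"] = float(np.mean(isis))
        gt["cv_isi"] = 100.0 * float(np.std(isis, ddof=1)) / gt["isi_avg"]
    gt["age_days"] = age
    return rec, gt


def default_plan(
    calibration: StageCalibration | None = None,
    total: int = 263,
) -> list[tuple[str, int]]:
    """Stage plan mirroring the published cohort size.

    Per-stage weights are the minimum N over the 8 spontaneous-activity
    parameters (the neurons for which the multivariate table is complete),
    apportioned to ``total`` neurons by largest remainder.
    """
    from .features import SPONTANEOUS_FEATURES

    calibration = calibration or load_default_calibration()
    weights = []
    for stage in calibration.stages:
        ns = [calibration.get(stage, p)[2] for p in SPONTANEOUS_FEATURES]
        weights.append(min(ns))
    w = np.asarray(weights, dtype=float)
    quota = total * w / w.sum()
    counts = np.floor(quota).astype(int)
    remainder = quota - counts
    for i in np.argsort(-remainder)[: total - counts.sum()]:
        counts[i] += 1
    return list(zip(calibration.stages, counts.tolist()))


def iter_cohort(
    plan: list[tuple[str, int]] | None = None,
    calibration: StageCalibration | None = None,
    seed: int = 0,
    duration_s: float = 60.0,
    noise_sd: float = 0.3,
    time_step: float = 0.05,
):
    """Yield (RecordingSet, ground-truth row dict) one neuron at a time.

    Streaming keeps memory flat (a 60 s spontaneous trace at 20 kHz is
    ~20 MB per neuron; a full cohort held at once would not fit in memory).
    """
    calibration = calibration or load_default_calibration()
    plan = plan if plan is not None else default_plan(calibration)
    if not plan or any(n <= 0 for _, n in plan):
        raise ValueError("plan must list (stage, n) pairs with n > 0")
    rng = np.random.default_rng(seed)
    idx = 0
    for stage, n in plan:
        for _ in range(n):
            nid = f"n{idx:04d}"
            truth = sample_neuron_params(stage, calibration, rng)
            rec, gt = generate_recording(nid, stage, truth, rng,
                                         duration_s=duration_s,
                                         noise_sd=noise_sd,
                                         time_step=time_step)
            yield rec, {"neuron_id": nid, "stage": stage,
                        "regime": truth.train.regime, **gt}
            idx += 1


def generate_cohort(
    plan: list[tuple[str, int]] | None = None,
    calibration: StageCalibration | None = None,
    seed: int = 0,
    duration_s: float = 60.0,
    noise_sd: float = 0.3,
    time_step: float = 0.05,
) -> tuple[list[RecordingSet], pd.DataFrame]:
    """Generate a seeded cohort of recordings plus its ground-truth table.

    Materializes every recording; for cohorts larger than a few dozen
    neurons prefer :func:`iter_cohort`.
    """
    recs: list[RecordingSet] = []
    rows: list[dict] = []
    for rec, gt in iter_cohort(plan, calibration, seed, duration_s,
                               noise_sd, time_step):
        recs.append(rec)
        rows.append(gt)
    gt_table = pd.DataFrame(rows)
    cols = (["neuron_id", "age_days", "stage", "regime"]
            + [c for c in FEATURE_NAMES])
    return recs, gt_table[cols]


def sample_feature_cohort(
    plan: list[tuple[str, int]] | None = None,
    calibration: StageCalibration | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Feature-level cohort: ground-truth feature vectors without rendering
    traces (fast path for the statistical and multivariate stages)."""
    calibration = calibration or load_default_calibration()
    plan = plan if plan is not None else default_plan(calibration)
    if not plan or any(n <= 0 for _, n in plan):
        raise ValueError("plan must list (stage, n) pairs with n > 0")
    rng = np.random.default_rng(seed)
    rows = []
    idx = 0
    for stage, n in plan:
        lo, hi = STAGE_BINS[stage]
        for _ in range(n):
            truth = sample_neuron_params(stage, calibration, rng)
            rows.append({
                "neuron_id": f"n{idx:04d}",
                "age_days": int(rng.integers(lo, hi + 1)),
                "stage": stage,
                "regime": truth.train.regime,
                **ground_truth_features(truth),
            })
            idx += 1
    return pd.DataFrame(rows)
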