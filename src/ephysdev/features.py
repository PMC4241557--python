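"""Extraction of the 16 electrophysiological parameters from voltage traces.

The parameters, in canonical order (the fixed header order of feature
tables):

===============  ==========  ====================================================
name             unit        definition
===============  ==========  ====================================================
isi_avg          s           mean interspike interval over >= 40 s of
                             spontaneous firing
cv_isi           %           100 * SD(ISI) / ISI_avg (sample SD, n-1)
tau_m            ms          membrane time constant from a mono-exponential fit
r_in             MOhm        input resistance from the same fit
c_m              pF          tau_m / r_in
sag              mV          hyperpolarization sag: mean V over the last 50 ms
                             of the pulse minus the minimum V during the pulse
rebound          ms          delay from pulse offset to the first spike peak
ap_threshold     mV          V where dV/dt first reaches 5% of its peak
ap_amplitude     mV          threshold-to-peak height of the averaged AP
ap_half_width    ms          width at threshold + amplitude/2
ap_rise_slope    mV/ms       average dV/dt between the 10% and 90% amplitude
                             levels on the rising limb
ap_decay_slope   mV/ms       likewise on the falling limb (negative)
ahp              mV          threshold minus the post-spike voltage trough
gain_start       Hz/100 pA   slope of the f-I regression using the first three
                             APs of each depolarizing pulse
gain_end         Hz/100 pA   likewise for the last three APs
sfa_index        --          gain_start / gain_end
===============  ==========  ====================================================

Spike detection (the acquisition criterion is a package convention, exposed
as configuration): an event starts where the coarse derivative exceeds
10 mV/ms, the event time is the sample of the voltage maximum, events whose
peak stays below -20 mV are rejected, and a 2 ms refractory period is
enforced.

All level crossings are linearly interpolated between samples.  The 10-90%
"average slope" is computed as the amplitude span divided by the time between
the interpolated level crossings, i.e. the time-average of dV/dt over the
band.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields

import numpy as np
from scipy.optimize import curve_fit

from .traces import RecordingSet, VoltageTrace

__all__ = [
    "FEATURE_NAMES",
    "SPONTANEOUS_FEATURES",
    "FeatureVector",
    "ISIStats",
    "APFeatures",
    "PassiveFit",
    "SagRebound",
    "ExcitabilityFeatures",
    "InsufficientDataError",
    "ShapeError",
    "detect_spikes",
    "isi_statistics",
    "average_ap",
    "measure_ap_threshold",
    "measure_ap_features",
    "fit_passive",
    "measure_sag_rebound",
    "compute_gain",
    "extract_features",
]

#: Canonical order of the 16 parameters in feature tables.
FEATURE_NAMES: tuple[str, ...] = (
    "isi_avg", "cv_isi", "tau_m", "r_in", "c_m", "sag", "rebound",
    "ap_threshold", "ap_amplitude", "ap_half_width", "ap_rise_slope",
    "ap_decay_slope", "ahp", "gain_start", "gain_end", "sfa_index",
)

#: The 8 spontaneous-activity parameters, in the fixed column order used by
#: the multivariate (clustering / PCA) stages.
SPONTANEOUS_FEATURES: tuple[str, ...] = (
    "isi_avg", "cv_isi", "ap_threshold", "ap_amplitude", "ap_rise_slope",
    "ap_decay_slope", "ap_half_width", "ahp",
)


class InsufficientDataError(ValueError):
    """A measurement's inclusion rule is not met (e.g. < 40 s of firing)."""


class ShapeError(ValueError):
    """The waveform does not have the geometry the measurement assumes."""


@dataclass
class FeatureVector:
    """The 16 named parameters of one neuron; ``None`` when the protocol that
    measures a field is absent."""

    isi_avg: float | None = None
    cv_isi: float | None = None
    tau_m: float | None = None
    r_in: float | None = None
    c_m: float | None = None
    sag: float | None = None
    rebound: float | None = None
    ap_threshold: float | None = None
    ap_amplitude: float | None = None
    ap_half_width: float | None = None
    ap_rise_slope: float | None = None
    ap_decay_slope: float | None = None
    ahp: float | None = None
    gain_start: float | None = None
    gain_end: float | None = None
    sfa_index: float | None = None

    def to_dict(self) -> dict[str, float | None]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass
class ISIStats:
    isi_avg: float       # s
    cv_isi: float        # %
    n_isi: int
    span: float          # s, first to last spike


@dataclass
class APFeatures:
    threshold: float
    amplitude: float
    half_width: float
    rise_slope: float
    decay_slope: float
    ahp: float
    n_averaged: int = 1


@dataclass
class PassiveFit:
    tau_m: float         # ms
    r_in: float          # MOhm
    c_m: float           # pF
    residual_rms: float  # mV


@dataclass
class SagRebound:
    sag: float             # mV
    rebound: float | None  # ms; None when no rebound spike occurred


@dataclass
class ExcitabilityFeatures:
    gain_start: float
    gain_end: float
    sfa_index: float
    fit_range: tuple[float, float]
    r2_start: float
    r2_end: float


# ---------------------------------------------------------------------------
# Spike detection and ISI statistics


def detect_spikes(
    trace: VoltageTrace,
    dvdt_threshold: float = 10.0,
    v_min: float = -20.0,
    refractory_ms: float = 2.0,
) -> np.ndarray:
    """Detect action-potential peak times (ms) in a voltage trace.

    The derivative used for the crossing criterion is a coarse symmetric
    difference over ~0.5 ms, which keeps the detector usable on traces with
    realistic recording noise; the event time is the sample of the voltage
    maximum following each threshold crossing.
    """
    v = trace.voltage
    dt = trace.time_step
    k = max(1, int(round(0.25 / dt)))
    d = np.empty_like(v)
    d[k:-k] = (v[2 * k:] - v[:-2 * k]) / (2 * k * dt)
    d[:k] = d[k]
    d[-k:] = d[-k - 1]

    above = d > dvdt_threshold
    if not above.any():
        return np.array([])
    onsets = np.flatnonzero(above & ~np.roll(above, 1))
    if above[0]:
        onsets = np.concatenate([[0], onsets[onsets != 0]])

    search = max(1, int(round(15.0 / dt)))  # upper bound on onset->peak time
    refr = refractory_ms / dt
    neg = d < 0.0
    peaks: list[int] = []
    for i in onsets:
        j = min(i + search, v.size)
        # the event's own peak: search only until the derivative turns over
        turn = np.flatnonzero(neg[i:j])
        if turn.size:
            j = min(i + turn[0] + k + 1, v.size)
        p = i + int(np.argmax(v[i:j]))
        if v[p] <= v_min:
            continue
        if peaks and p - peaks[-1] < refr:
            continue
        peaks.append(p)
    return np.asarray(peaks, dtype=float) * dt


def isi_statistics(spike_times_ms: np.ndarray, min_span_s: float = 40.0) -> ISIStats:
    """ISI mean (s) and coefficient of variation (%) of a spike train.

    Requires at least 3 spikes spanning ``min_span_s`` seconds, mirroring the
    40 s stable-recording inclusion rule.
    """
    t = np.asarray(spike_times_ms, dtype=float)
    if t.size < 3:
        raise InsufficientDataError(f"need >= 3 spikes, got {t.size}")
    span_s = (t[-1] - t[0]) / 1000.0
    if span_s < min_span_s:
        raise InsufficientDataError(
            f"spike train spans {span_s:.1f} s < required {min_span_s:.0f} s"
        )
    isis = np.diff(t) / 1000.0
    mean = float(np.mean(isis))
    cv = 100.0 * float(np.std(isis, ddof=1)) / mean
    return ISIStats(isi_avg=mean, cv_isi=cv, n_isi=isis.size, span=span_s)


# ---------------------------------------------------------------------------
# AP waveform measurements


@dataclass
class AveragedAP:
    """Averaged spike-aligned waveform (aligned on the peak sample)."""

    voltage: np.ndarray
    time_step: float
    peak_index: int
    n_averaged: int


def average_ap(
    trace: VoltageTrace,
    spike_times_ms: np.ndarray,
    window_before_ms: float = 10.0,
    window_after_ms: float = 60.0,
) -> AveragedAP:
    """Pointwise mean of peak-aligned AP windows; truncated windows are
    excluded."""
    dt = trace.time_step
    nb = int(round(window_before_ms / dt))
    na = int(round(window_after_ms / dt))
    lag = max(1, int(round(0.25 / dt)))  # re-alignment search, +-0.25 ms
    idx = np.round(np.asarray(spike_times_ms, dtype=float) / dt).astype(int)
    idx = idx[(idx - nb - lag >= 0) & (idx + na + lag < trace.n_samples)]
    if idx.size == 0:
        raise InsufficientDataError("no spike with a complete averaging window")
    windows = np.stack([trace.voltage[i - nb:i + na + 1] for i in idx])
    if idx.size > 1:
        # second pass: recording noise jitters the per-spike peak sample, so
        # re-align each window on the first-pass average before re-averaging
        ref = windows.mean(axis=0)
        shifts = np.arange(-lag, lag + 1)
        realigned = []
        for i in idx:
            seg = trace.voltage[i - nb - lag:i + na + lag + 1]
            sse = [np.sum((seg[lag + s:lag + s + ref.size] - ref) ** 2)
                   for s in shifts]
            s = shifts[int(np.argmin(sse))]
            realigned.append(seg[lag + s:lag + s + ref.size])
        windows = np.stack(realigned)
    return AveragedAP(
        voltage=windows.mean(axis=0), time_step=dt, peak_index=nb,
        n_averaged=idx.size,
    )


def _cross_backward(y: np.ndarray, start: int, level: float) -> float:
    """Fractional index of the last upward crossing of ``level`` at or before
    ``start`` (walking backward); raises ShapeError if y never drops below."""
    for i in range(start, -1, -1):
        if y[i] < level:
            if i == start:
                break
            frac = (level - y[i]) / (y[i + 1] - y[i])
            return i + frac
    raise ShapeError("waveform never falls below the requested level")


def _cross_forward(y: np.ndarray, start: int, level: float) -> float:
    """Fractional index of the first downward crossing of ``level`` at or
    after ``start``."""
    below = np.flatnonzero(y[start:] < level)
    if below.size == 0:
        raise ShapeError("waveform never falls below the requested level")
    i = start + below[0]
    if i == start:
        return float(i)
    frac = (y[i - 1] - level) / (y[i - 1] - y[i])
    return i - 1 + frac


def measure_ap_threshold(wave: AveragedAP) -> float:
    """AP threshold: V where dV/dt first reaches 5% of its peak.

    Searches backward from the dV/dt peak for the interpolated 5% crossing.
    A waveform with constant dV/dt (no crossing) raises :class:`ShapeError`.
    """
    v = wave.voltage
    d = np.gradient(v, wave.time_step)
    ipk = int(np.argmax(d))
    if d[ipk] <= 0:
        raise ShapeError("waveform has no positive dV/dt peak")
    level = 0.05 * d[ipk]
    x = _cross_backward(d, ipk, level)
    i = int(np.floor(x))
    return float(v[i] + (x - i) * (v[min(i + 1, v.size - 1)] - v[i]))


def measure_ap_features(wave: AveragedAP, threshold: float) -> APFeatures:
    """Amplitude, half-width, 10-90% slopes and AHP of an averaged AP."""
    v = wave.voltage
    dt = wave.time_step
    ipk = int(np.argmax(v))
    peak = v[ipk]
    if threshold >= peak:
        raise ShapeError("threshold must lie below the AP peak")
    amp = peak - threshold

    def rising(level: float) -> float:
        return _cross_backward(v, ipk, level) * dt

    def falling(level: float) -> float:
        return _cross_forward(v, ipk, level) * dt

    half = threshold + amp / 2.0
    t_half_rise = rising(half)
    t_half_fall = falling(half)  # ShapeError if falling limb truncated
    half_width = t_half_fall - t_half_rise

    t10r = rising(threshold + 0.1 * amp)
    t90r = rising(threshold + 0.9 * amp)
    rise_slope = 0.8 * amp / (t90r - t10r)

    t90f = falling(threshold + 0.9 * amp)
    t10f = falling(threshold + 0.1 * amp)
    decay_slope = -0.8 * amp / (t10f - t90f)

    trough = float(np.min(v[ipk:]))
    ahp = max(0.0, threshold - trough)

    return APFeatures(
        threshold=threshold, amplitude=float(amp), half_width=float(half_width),
        rise_slope=float(rise_slope), decay_slope=float(decay_slope),
        ahp=float(ahp), n_averaged=wave.n_averaged,
    )


# ---------------------------------------------------------------------------
# Passive properties


def fit_passive(trace: VoltageTrace, step_pA: float) -> PassiveFit:
    """Mono-exponential fit of a small hyperpolarizing pulse.

    Fits ``V(t) = V0 + dV (1 - exp(-t/tau))`` over the pulse epoch; the pulse
    window is taken from the trace's current command.  The plateau must stay
    below 10 mV (the inclusion rule for passive measurements) and the step
    must be hyperpolarizing.
    """
    if step_pA >= 0:
        raise ValueError("passive pulses must be hyperpolarizing (step < 0)")
    on_ms, off_ms = trace.pulse_window()
    dt = trace.time_step
    i0, i1 = int(round(on_ms / dt)), int(round(off_ms / dt))
    v = trace.voltage[i0:i1]
    t = np.arange(v.size) * dt

    v0 = float(np.mean(trace.voltage[max(0, i0 - int(50 / dt)):i0])) \
        if i0 > 1 else float(v[0])
    dv0 = float(np.mean(v[-max(1, v.size // 5):]) - v0)
    if abs(dv0) >= 10.0:
        raise ValueError(
            f"plateau deflection {abs(dv0):.1f} mV exceeds the 10 mV rule"
        )
    if dv0 >= 0:
        raise ShapeError("voltage deflection has the wrong sign for the step")
    # tau init: time to reach 63% of the plateau
    target = v0 + 0.632 * dv0
    below = np.flatnonzero(v <= target)
    tau0 = t[below[0]] if below.size else t[-1] / 3.0

    def model(tt, v0_, dv_, tau_):
        return v0_ + dv_ * (1.0 - np.exp(-tt / tau_))

    try:
        popt, _ = curve_fit(model, t, v, p0=[v0, dv0, max(tau0, dt)],
                            maxfev=10000)
    except RuntimeError as e:
        raise ShapeError(f"passive fit failed to converge: {e}") from None
    _, dv, tau = popt
    if dv >= 0 or tau <= 0:
        raise ShapeError("passive fit returned a non-hyperpolarizing response")
    r_in = abs(dv / step_pA) * 1000.0          # mV/pA -> MOhm
    c_m = tau / r_in * 1000.0                  # ms/MOhm -> pF
    rms = float(np.sqrt(np.mean((v - model(t, *popt)) ** 2)))
    return PassiveFit(tau_m=float(tau), r_in=float(r_in), c_m=float(c_m),
                      residual_rms=rms)


def measure_sag_rebound(
    trace: VoltageTrace,
    pulse_window_ms: tuple[float, float] | None = None,
) -> SagRebound:
    """Sag amplitude and post-inhibitory rebound delay.

    sag = (mean V over the last 50 ms of the pulse) - (minimum V during the
    pulse); rebound = time from pulse offset to the first spike peak, ``None``
    if no spike follows within the trace.
    """
    if pulse_window_ms is None:
        pulse_window_ms = trace.pulse_window()
    on_ms, off_ms = pulse_window_ms
    dt = trace.time_step
    i0, i1 = int(round(on_ms / dt)), int(round(off_ms / dt))
    if i0 < 0 or i1 > trace.n_samples or i1 - i0 < 2:
        raise ValueError("pulse window not contained in trace")
    seg = trace.voltage[i0:i1]
    baseline = float(np.mean(trace.voltage[max(0, i0 - int(50 / dt)):i0])) \
        if i0 > 1 else float(seg[0])
    # 1 ms boxcar before the min: the raw extreme of 2e4 noisy samples would
    # bias the sag upward by ~3.5 sigma
    w = max(1, int(round(1.0 / dt)))
    smooth = np.convolve(seg, np.ones(w) / w, mode="valid")
    vmin = float(np.min(smooth))
    if vmin >= baseline - 1.0:
        raise ShapeError("no hyperpolarizing response during the pulse")
    tail = seg[-max(1, int(round(50.0 / dt))):]
    sag = float(np.mean(tail)) - vmin

    spikes = detect_spikes(trace)
    after = spikes[spikes > off_ms]
    rebound = float(after[0] - off_ms) if after.size else None
    return SagRebound(sag=sag, rebound=rebound)


# ---------------------------------------------------------------------------
# Excitability (f-I gain)


def _mean_inst_freq(isis_ms: np.ndarray) -> float:
    """Mean instantaneous frequency (Hz) over a pair of leading/trailing ISIs."""
    return float(np.mean(1000.0 / isis_ms))


def compute_gain(
    responses: list[tuple[np.ndarray, float]],
    pulse_ms: float = 1000.0,
) -> ExcitabilityFeatures:
    """GS, GE and the SFA index from incremental depolarizing pulses.

    ``responses`` holds ``(spike_times_ms_relative_to_pulse_onset, I_pA)``
    pairs.  Per pulse, the starting frequency is the mean instantaneous
    frequency of the first three APs (two leading ISIs) and the ending
    frequency that of the last three.  Saturating pulses — spike count lower
    than the preceding (smaller) pulse's, or firing that ceases during the
    final 200 ms — are excluded; the regression f vs I runs over the maximal
    leading non-saturating run.
    """
    if not responses:
        raise ValueError("empty current list")
    responses = sorted(responses, key=lambda r: r[1])

    retained: list[tuple[float, float, float]] = []  # (I, f_start, f_end)
    prev_count: int | None = None
    for times, amp in responses:
        times = np.asarray(times, dtype=float)
        count = times.size
        if count < 4:
            if prev_count is not None and count < prev_count:
                break  # saturation: fewer spikes than the previous pulse
            prev_count = max(prev_count or 0, count)
            continue
        if prev_count is not None and count < prev_count:
            break
        isis = np.diff(times)
        end_gap = pulse_ms - times[-1]
        if end_gap > max(200.0, 2.5 * float(np.median(isis))):
            break  # firing ceased before the end: depolarization block
        prev_count = count
        retained.append(
            (amp, _mean_inst_freq(isis[:2]), _mean_inst_freq(isis[-2:]))
        )

    if len(retained) < 3:
        raise InsufficientDataError(
            f"only {len(retained)} non-saturating pulses with >= 4 spikes "
            "(need 3)"
        )
    arr = np.asarray(retained)
    I, fs, fe = arr[:, 0], arr[:, 1], arr[:, 2]

    def ols(y: np.ndarray) -> tuple[float, float]:
        slope, intercept = np.polyfit(I, y, 1)
        pred = slope * I + intercept
        ss_res = float(np.sum((y - pred) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        return float(slope), r2

    slope_s, r2_s = ols(fs)
    slope_e, r2_e = ols(fe)
    gs, ge = 100.0 * slope_s, 100.0 * slope_e
    if ge <= 0:
        raise ShapeError(f"gain-end regression slope is non-positive ({ge:.3g})")
    return ExcitabilityFeatures(
        gain_start=gs, gain_end=ge, sfa_index=gs / ge,
        fit_range=(float(I[0]), float(I[-1])), r2_start=r2_s, r2_end=r2_e,
    )


# ---------------------------------------------------------------------------
# Composition


def extract_features(
    rec: RecordingSet,
    min_span_s: float = 40.0,
    dvdt_threshold: float = 10.0,
    v_min: float = -20.0,
) -> FeatureVector:
    """Run every measurement whose protocol exists in ``rec``.

    Failures in optional protocols leave the corresponding fields ``None``
    (with a warning); a failure on the spontaneous trace is fatal for the
    neuron.
    """
    fv = FeatureVector()

    # spontaneous activity: ISI statistics + averaged AP shape (fatal on error)
    spikes = detect_spikes(rec.spontaneous, dvdt_threshold, v_min)
    stats = isi_statistics(spikes, min_span_s=min_span_s)
    fv.isi_avg, fv.cv_isi = stats.isi_avg, stats.cv_isi
    wave = average_ap(rec.spontaneous, spikes)
    thr = measure_ap_threshold(wave)
    ap = measure_ap_features(wave, thr)
    fv.ap_threshold = thr
    fv.ap_amplitude = ap.amplitude
    fv.ap_half_width = ap.half_width
    fv.ap_rise_slope = ap.rise_slope
    fv.ap_decay_slope = ap.decay_slope
    fv.ahp = ap.ahp

    if rec.passive_pulses:
        try:
            fits = [fit_passive(tr, amp) for tr, amp in rec.passive_pulses]
            fv.tau_m = float(np.mean([f.tau_m for f in fits]))
            fv.r_in = float(np.mean([f.r_in for f in fits]))
            fv.c_m = fv.tau_m / fv.r_in * 1000.0
        except (ValueError, ShapeError) as e:
            warnings.warn(f"{rec.neuron_id}: passive fit failed: {e}")

    if rec.sag_pulse is not None:
        try:
            sr = measure_sag_rebound(rec.sag_pulse[0])
            fv.sag = sr.sag
            fv.rebound = sr.rebound
        except (ValueError, ShapeError) as e:
            warnings.warn(f"{rec.neuron_id}: sag measurement failed: {e}")

    if rec.fi_pulses:
        try:
            resp = []
            for tr, amp in rec.fi_pulses:
                on_ms, off_ms = tr.pulse_window()
                st = detect_spikes(tr, dvdt_threshold, v_min)
                st = st[(st >= on_ms) & (st <= off_ms + 5.0)] - on_ms
                resp.append((st, amp))
            ex = compute_gain(resp, pulse_ms=off_ms - on_ms)
            fv.gain_start, fv.gain_end = ex.gain_start, ex.gain_end
            fv.sfa_index = ex.sfa_index
        except (ValueError, ShapeError) as e:
            warnings.warn(f"{rec.neuron_id}: gain measurement failed: {e}")

    return fv
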