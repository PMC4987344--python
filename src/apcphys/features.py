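"""Intrinsic electrophysiological feature extraction.

Eight properties characterise each cell: input resistance (R_in), membrane
time constant (tau_m), sag, rheobase, spike width, maximum firing rate,
adaptation ratio (AR), and the coefficient of variation of the interspike
interval (CV_ISI).  The first three are measured from a -50..+50 pA
subthreshold step family; the remaining five from a 0..1000 pA suprathreshold
family.

Conventions (the underlying definitions admit some freedom; these are the ones
this package adopts and tests):

* Spike detection: upward crossing of a fixed voltage threshold (0 mV) with a
  1 ms merge window; the spike time is the local maximum after the crossing.
* R_in: OLS slope of steady-state voltage deflection (mean over the last
  100 ms of the step, minus pre-step baseline) against injected current.
* tau_m: monoexponential least-squares fit of the falling (charging) phase of
  the -50 pA response, from step onset to five initial-guess time constants.
* Sag: mean over the last 100 ms of the -50 pA step minus the most
  hyperpolarised sample in the first 50 ms; positive when the membrane
  relaxes back toward baseline (an I_h signature).
* Spike width: full width at half height, where half height is the midpoint
  between the spike peak and the detection threshold; crossings are linearly
  interpolated between samples.
* AR = last ISI / first ISI and CV_ISI = sd(ISI)/mean(ISI) (sample sd, n-1),
  both on the sweep 100 pA above rheobase; if that sweep is missing the
  highest available sweep is used and the deviation flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields
from typing import Sequence

import numpy as np
from scipy import optimize

from .recordings import ProtocolError, SweepSet

__all__ = [
    "SpikeTrain",
    "IntrinsicFeatures",
    "FitFailureError",
    "FEATURE_NAMES",
    "detect_spikes",
    "input_resistance",
    "time_constant",
    "sag",
    "rheobase",
    "spike_width",
    "max_firing_rate",
    "isi_stats",
    "extract_features",
]

#: Canonical feature order, used by the clustering module.
FEATURE_NAMES = (
    "r_in",
    "tau_m",
    "sag",
    "rheobase",
    "spike_width",
    "max_firing_rate",
    "adaptation_ratio",
    "cv_isi",
)

SUBTHRESHOLD_FEATURES = ("r_in", "tau_m", "sag")

# Analysis windows (seconds)
SAG_ONSET_WINDOW = 0.050
STEADY_WINDOW = 0.100
DEFAULT_DETECT_THRESHOLD = 0.0  # mV
MERGE_WINDOW = 0.001  # s


class FitFailureError(RuntimeError):
    """An exponential fit failed to converge; carries the residuals."""

    def __init__(self, message: str, residuals: np.ndarray | None = None):
        super().__init__(message)
        self.residuals = residuals


@dataclass(frozen=True)
class SpikeTrain:
    """Spike times (s) detected within one sweep."""

    spike_times: tuple[float, ...]
    threshold: float = DEFAULT_DETECT_THRESHOLD
    merge_window: float = MERGE_WINDOW

    def __post_init__(self) -> None:
        t = np.asarray(self.spike_times)
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("spike times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.spike_times)

    def isis(self) -> np.ndarray:
        return np.diff(np.asarray(self.spike_times))


@dataclass
class IntrinsicFeatures:
    """The eight-parameter phenotype vector of one cell.

    Each field has a matching entry in ``valid``; an invalid feature is NaN.
    """

    r_in: float = np.nan            # MOhm
    tau_m: float = np.nan           # ms
    sag: float = np.nan             # mV
    rheobase: float = np.nan        # pA
    spike_width: float = np.nan     # ms
    max_firing_rate: float = np.nan  # Hz
    adaptation_ratio: float = np.nan
    cv_isi: float = np.nan
    valid: dict[str, bool] = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in FEATURE_NAMES:
            self.valid.setdefault(name, np.isfinite(getattr(self, name)))

    def to_array(self, names: Sequence[str] = FEATURE_NAMES) -> np.ndarray:
        return np.array([getattr(self, n) for n in names], dtype=float)

    def to_dict(self) -> dict:
        return {n: getattr(self, n) for n in FEATURE_NAMES} | {
            f"{n}_valid": self.valid[n] for n in FEATURE_NAMES
        }


def detect_spikes(
    trace: np.ndarray,
    sampling_rate: float,
    threshold: float = DEFAULT_DETECT_THRESHOLD,
    merge_window: float = MERGE_WINDOW,
    method: str = "voltage",
    dvdt_threshold: float = 20.0,
) -> SpikeTrain:
    """Detect spikes as threshold crossings.

    ``method="voltage"`` (default) marks upward crossings of ``threshold``
    (mV); ``method="dvdt"`` marks upward crossings of ``dvdt_threshold``
    (mV/ms) of the first derivative.  Each suprathreshold excursion yields one
    spike, timed at the local maximum; events closer than ``merge_window``
    are merged.
    """
    trace = np.asarray(trace, dtype=float)
    if not np.all(np.isfinite(trace)):
        raise ValueError("trace contains non-finite samples")
    if method == "voltage":
        signal = trace
        thr = threshold
    elif method == "dvdt":
        signal = np.gradient(trace) * sampling_rate / 1000.0  # mV/ms
        thr = dvdt_threshold
    else:
        raise ValueError(f"unknown detection method {method!r}")

    above = signal >= thr
    crossings = np.nonzero(above[1:] & ~above[:-1])[0] + 1
    if crossings.size == 0:
        return SpikeTrain(())

    merge_n = max(int(round(merge_window * sampling_rate)), 1)
    peaks: list[int] = []
    for idx in crossings:
        # local maximum of the voltage over the suprathreshold excursion
        end = idx
        while end < len(trace) and signal[end] >= thr:
            end += 1
        peak = idx + int(np.argmax(trace[idx:end])) if end > idx else idx
        if peaks and peak - peaks[-1] < merge_n:
            continue
        peaks.append(peak)
    times = tuple(p / sampling_rate for p in peaks)
    return SpikeTrain(times, threshold=thr, merge_window=merge_window)


def _baseline(sweeps: SweepSet, trace: np.ndarray) -> float:
    onset = sweeps.protocol.onset_index
    if onset == 0:
        return float(trace[0])
    return float(np.mean(trace[:onset]))


def _steady_state(sweeps: SweepSet, trace: np.ndarray) -> float:
    proto = sweeps.protocol
    n_win = int(round(STEADY_WINDOW * proto.sampling_rate))
    return float(np.mean(trace[proto.offset_index - n_win : proto.offset_index]))


def input_resistance(subthreshold_sweeps: SweepSet) -> float:
    """OLS slope of steady-state voltage deflection vs injected current, MOhm.

    Uses every sweep with amplitude in [-50, +50] pA; at least three distinct
    amplitudes are required.  Sweeps containing spikes are excluded from the
    fit (provided at least three spike-free sweeps remain), since resets and
    spike waveforms corrupt the steady-state estimate.
    """
    amps = [a for a in subthreshold_sweeps.amplitudes if -50.0 <= a <= 50.0]
    if len(amps) < 3:
        raise ProtocolError(
            "input resistance needs >= 3 amplitudes in -50..+50 pA, "
            f"got {len(amps)}"
        )
    fs = subthreshold_sweeps.protocol.sampling_rate
    quiet = [
        a
        for a in amps
        if len(detect_spikes(subthreshold_sweeps.get(a), fs)) == 0
    ]
    if len(quiet) >= 3:
        amps = quiet
    dv = np.array(
        [
            _steady_state(subthreshold_sweeps, subthreshold_sweeps.get(a))
            - _baseline(subthreshold_sweeps, subthreshold_sweeps.get(a))
            for a in amps
        ]
    )
    i = np.array(amps)
    slope = np.polyfit(i, dv, 1)[0]  # mV/pA == GOhm
    return float(slope * 1000.0)  # MOhm


def time_constant(
    sweeps: SweepSet,
    amplitude: float = -50.0,
    fit_window_factor: float = 5.0,
) -> float:
    """Membrane time constant (ms) from a monoexponential fit.

    Fits V(t) = v_inf + (v0 - v_inf) exp(-t/tau) to the falling phase of the
    response at ``amplitude`` (default -50 pA), from step onset to
    ``fit_window_factor`` initial-guess time constants.
    """
    trace = sweeps.get(amplitude)
    proto = sweeps.protocol
    fs = proto.sampling_rate
    onset, offset = proto.onset_index, proto.offset_index
    base = _baseline(sweeps, trace)

    seg = trace[onset:offset]
    # initial guess from the time to reach 63% of the early extremum
    n_early = min(int(round(0.150 * fs)), len(seg))
    early = seg[:n_early]
    ext = float(np.min(early)) if amplitude < 0 else float(np.max(early))
    depth = ext - base
    if abs(depth) < 1e-12:
        raise FitFailureError("no deflection to fit")
    target = base + 0.632 * depth
    crossed = np.nonzero((early - target) * np.sign(depth) >= 0)[0]
    tau_guess = (crossed[0] + 1) / fs if crossed.size else 0.010

    n_fit = int(round(min(fit_window_factor * tau_guess, proto.step_duration) * fs))
    n_fit = max(n_fit, 10)
    t = np.arange(n_fit) / fs
    y = seg[:n_fit]

    def model(t, v_inf, amp, tau):
        return v_inf + amp * np.exp(-t / tau)

    try:
        popt, _ = optimize.curve_fit(
            model,
            t,
            y,
            p0=(ext, base - ext, tau_guess),
            maxfev=5000,
        )
    except RuntimeError as exc:
        raise FitFailureError(f"exponential fit did not converge: {exc}") from exc
    tau = float(popt[2]) * 1000.0  # ms
    if not np.isfinite(tau) or tau <= 0:
        raise FitFailureError(
            "exponential fit diverged", residuals=y - model(t, *popt)
        )
    return tau


def sag(sweeps: SweepSet, amplitude: float = -50.0) -> float:
    """Sag (mV) on the ``amplitude`` step: late steady mean minus early extremum.

    Positive when the early hyperpolarisation exceeds the late steady state,
    i.e. when the trace relaxes back toward baseline.
    """
    proto = sweeps.protocol
    if proto.step_duration < SAG_ONSET_WINDOW + STEADY_WINDOW:
        raise ProtocolError("step too short for sag (needs >= 150 ms)")
    trace = sweeps.get(amplitude)
    fs = proto.sampling_rate
    onset, offset = proto.onset_index, proto.offset_index
    n_on = int(round(SAG_ONSET_WINDOW * fs))
    n_ss = int(round(STEADY_WINDOW * fs))
    early_min = float(np.min(trace[onset : onset + n_on]))
    late = float(np.mean(trace[offset - n_ss : offset]))
    return late - early_min


def _step_window_spikes(sweeps: SweepSet, amp: float, **detect_kw) -> SpikeTrain:
    proto = sweeps.protocol
    train = detect_spikes(sweeps.get(amp), proto.sampling_rate, **detect_kw)
    t0 = proto.baseline_pre
    t1 = proto.baseline_pre + proto.step_duration
    times = tuple(t for t in train.spike_times if t0 <= t <= t1)
    return SpikeTrain(times, threshold=train.threshold, merge_window=train.merge_window)


def rheobase(suprathreshold_sweeps: SweepSet, **detect_kw) -> float:
    """Smallest step amplitude (pA) whose sweep contains at least one spike.

    Returns NaN (feature invalid) when no sweep spikes.
    """
    for amp in suprathreshold_sweeps.amplitudes:
        if len(_step_window_spikes(suprathreshold_sweeps, amp, **detect_kw)) >= 1:
            return float(amp)
    return float("nan")


def spike_width(
    suprathreshold_sweeps: SweepSet,
    rheo: float | None = None,
    detect_threshold: float = DEFAULT_DETECT_THRESHOLD,
) -> float:
    """Mean full width at half height (ms) of spikes on the rheobase sweep.

    Half height is the midpoint between the spike peak and the detection
    threshold; the crossings are linearly interpolated.
    """
    if rheo is None:
        rheo = rheobase(suprathreshold_sweeps, threshold=detect_threshold)
    if not np.isfinite(rheo):
        return float("nan")
    proto = suprathreshold_sweeps.protocol
    fs = proto.sampling_rate
    trace = suprathreshold_sweeps.get(rheo)
    train = _step_window_spikes(
        suprathreshold_sweeps, rheo, threshold=detect_threshold
    )
    widths = []
    for t_sp in train.spike_times:
        k = int(round(t_sp * fs))
        peak = trace[k]
        half = 0.5 * (peak + detect_threshold)
        # walk left and right from the peak to the half-height crossings
        left = k
        while left > 0 and trace[left] > half:
            left -= 1
        right = k
        while right < len(trace) - 1 and trace[right] > half:
            right += 1
        if trace[left] > half or trace[right] > half:
            continue  # truncated spike at the trace edge
        # linear interpolation of the crossing positions
        tl = left + (half - trace[left]) / (trace[left + 1] - trace[left])
        tr = right - 1 + (half - trace[right - 1]) / (trace[right] - trace[right - 1])
        widths.append((tr - tl) / fs * 1000.0)
    return float(np.mean(widths)) if widths else float("nan")


def max_firing_rate(suprathreshold_sweeps: SweepSet, **detect_kw) -> float:
    """Maximum over sweeps of spike count divided by step duration (Hz)."""
    proto = suprathreshold_sweeps.protocol
    counts = [
        len(_step_window_spikes(suprathreshold_sweeps, amp, **detect_kw))
        for amp in suprathreshold_sweeps.amplitudes
    ]
    if not any(counts):
        return float("nan")
    return float(max(counts) / proto.step_duration)


def isi_stats(
    suprathreshold_sweeps: SweepSet,
    rheo: float | None = None,
    offset_pa: float = 100.0,
    **detect_kw,
) -> tuple[float, float, list[str]]:
    """(adaptation ratio, CV_ISI, notes) on the sweep ``offset_pa`` above rheobase.

    AR is the last ISI over the first ISI; CV is sample sd over mean.  If the
    target sweep is absent the highest available sweep is used and noted.
    Returns NaNs when fewer than two ISIs exist.
    """
    notes: list[str] = []
    if rheo is None:
        rheo = rheobase(suprathreshold_sweeps, **detect_kw)
    if not np.isfinite(rheo):
        return float("nan"), float("nan"), ["no spikes: ISI stats unavailable"]
    target = rheo + offset_pa
    if not suprathreshold_sweeps.has(target):
        available = suprathreshold_sweeps.amplitudes
        target = available[-1]
        notes.append(
            f"sweep at rheobase+{offset_pa:g} pA absent; used {target:g} pA"
        )
    train = _step_window_spikes(suprathreshold_sweeps, target, **detect_kw)
    isis = train.isis()
    if isis.size < 2:
        return float("nan"), float("nan"), notes + ["fewer than 2 ISIs"]
    ar = float(isis[-1] / isis[0])
    cv = float(np.std(isis, ddof=1) / np.mean(isis))
    return ar, cv, notes


def extract_features(
    subthreshold: SweepSet,
    suprathreshold: SweepSet | None = None,
    detect_threshold: float = DEFAULT_DETECT_THRESHOLD,
) -> IntrinsicFeatures:
    """Compute all available features; missing data flags, never aborts.

    The subthreshold sweep set yields R_in, tau_m and sag; the suprathreshold
    set (if given, and if the cell spikes) yields the remaining five.  Cells
    recorded with a sodium-channel blocker in the pipette simply have no
    suprathreshold set and get the subthreshold trio only.
    """
    feats = IntrinsicFeatures()
    kw = {"threshold": detect_threshold}

    def attempt(name, fn):
        try:
            value = fn()
        except (ProtocolError, FitFailureError) as exc:
            feats.notes.append(f"{name}: {exc}")
            value = float("nan")
        setattr(feats, name, value)
        feats.valid[name] = bool(np.isfinite(value))

    attempt("r_in", lambda: input_resistance(subthreshold))
    attempt("tau_m", lambda: time_constant(subthreshold))
    attempt("sag", lambda: sag(subthreshold))

    if suprathreshold is not None:
        rheo = rheobase(suprathreshold, **kw)
        attempt("rheobase", lambda: rheo)
        attempt("spike_width", lambda: spike_width(suprathreshold, rheo=rheo))
        attempt("max_firing_rate", lambda: max_firing_rate(suprathreshold, **kw))
        ar, cv, notes = (
            isi_stats(suprathreshold, rheo=rheo, **kw)
            if np.isfinite(rheo)
            else (float("nan"), float("nan"), [])
        )
        feats.notes.extend(notes)
        attempt("adaptation_ratio", lambda: ar)
        attempt("cv_isi", lambda: cv)
    else:
        for name in FEATURE_NAMES[3:]:
            feats.valid[name] = False
            setattr(feats, name, float("nan"))
    return feats
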