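"""Optogenetically evoked IPSC quantification and pharmacological decomposition.

IPSCs recorded at 0 mV are outward currents; traces are stored
baseline-subtracted with outward positive, so "the area under the IPSC" is a
positive integral (pA*s).  Strength is quantified as charge over a fixed
response window (default: light onset to onset + 500 ms); averaged IPSCs with
peak below 10 pA are excluded as indistinguishable from noise.

The three-condition gabazine (GZ) experiment decomposes a pyramidal cell's
inhibition: with Q_base, Q_soma and Q_both the charges at baseline, under
somatic GZ and under somatic+L1B GZ,

    other   = Q_both / Q_base * 100          (block-resistant residual)
    somatic = (Q_base - Q_soma) / Q_base * 100
    distal  = (Q_soma - Q_both) / Q_base * 100

which sum to 100 exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from . import stats as _stats

__all__ = [
    "IPSCMeasurement",
    "InhibitionDecomposition",
    "PairedComparison",
    "average_trials",
    "charge",
    "peak_amplitude",
    "include_filter",
    "decompose",
    "compare_within_slice",
    "MIN_PEAK_PA",
    "DEFAULT_RESPONSE_WINDOW_S",
    "DEFAULT_BASELINE_WINDOW_S",
]

MIN_PEAK_PA = 10.0
DEFAULT_RESPONSE_WINDOW_S = 0.5
DEFAULT_BASELINE_WINDOW_S = 0.1


@dataclass
class IPSCMeasurement:
    """Trial-averaged IPSC for one cell under one condition.

    ``trace`` is the baseline-subtracted mean across trials (pA, outward
    positive) on the time base ``time`` (s, stimulus onset at t=0).
    """

    condition: str
    time: np.ndarray
    trace: np.ndarray
    baseline_current: float
    peak_amplitude: float
    charge: float
    n_trials: int = 1
    cell_id: str = ""
    notes: list[str] = field(default_factory=list)


def _window_mask(time: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    lo, hi = window
    tol = (time[1] - time[0]) if len(time) > 1 else 1e-9  # one-sample slack
    if lo < time[0] - tol or hi > time[-1] + tol:
        raise ValueError(
            f"window {window} outside trace span ({time[0]:.4g}..{time[-1]:.4g} s)"
        )
    return (time >= lo) & (time <= hi)


def peak_amplitude(
    time: np.ndarray,
    trace: np.ndarray,
    window: tuple[float, float] = (0.0, DEFAULT_RESPONSE_WINDOW_S),
) -> float:
    """Maximum outward current (pA) within the response window."""
    return float(np.max(trace[_window_mask(time, window)]))


def charge(
    measurement_or_trace,
    window: tuple[float, float] = (0.0, DEFAULT_RESPONSE_WINDOW_S),
    time: np.ndarray | None = None,
) -> float:
    """Charge (pA*s): trapezoidal integral of the outward (positive) current.

    Accepts an :class:`IPSCMeasurement` or a bare baseline-subtracted trace
    plus ``time``.  Inward (negative) excursions do not cancel outward
    charge; they are clipped to zero before integration.
    """
    if isinstance(measurement_or_trace, IPSCMeasurement):
        time = measurement_or_trace.time
        trace = measurement_or_trace.trace
    else:
        trace = np.asarray(measurement_or_trace, dtype=float)
        if time is None:
            raise ValueError("charge on a bare trace needs a time base")
    mask = _window_mask(time, window)
    return float(np.trapezoid(np.clip(trace[mask], 0.0, None), time[mask]))


def average_trials(
    trials: np.ndarray | Sequence[np.ndarray],
    time: np.ndarray,
    condition: str = "baseline",
    cell_id: str = "",
    baseline_window_s: float = DEFAULT_BASELINE_WINDOW_S,
    response_window_s: float = DEFAULT_RESPONSE_WINDOW_S,
) -> IPSCMeasurement:
    """Point-wise trial average with pre-stimulus baseline subtraction.

    ``time`` must place the stimulus onset at t=0; the baseline is the mean
    current over the ``baseline_window_s`` before onset.
    """
    arr = np.asarray(trials, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    if arr.shape[0] < 1:
        raise ValueError("need at least one trial")
    if arr.shape[1] != len(time):
        raise ValueError(
            f"trials have {arr.shape[1]} samples but the time base has {len(time)}"
        )
    mean = arr.mean(axis=0)
    pre = (time >= -baseline_window_s) & (time < 0.0)
    if not pre.any():
        raise ValueError("no pre-stimulus samples for baseline estimation")
    base = float(mean[pre].mean())
    trace = mean - base
    window = (0.0, response_window_s)
    return IPSCMeasurement(
        condition=condition,
        time=time,
        trace=trace,
        baseline_current=base,
        peak_amplitude=peak_amplitude(time, trace, window),
        charge=charge(trace, window, time=time),
        n_trials=arr.shape[0],
        cell_id=cell_id,
    )


def include_filter(
    measurements: Iterable[IPSCMeasurement], min_peak: float = MIN_PEAK_PA
) -> list[IPSCMeasurement]:
    """Retain averaged IPSCs with peak amplitude >= ``min_peak`` pA."""
    return [m for m in measurements if m.peak_amplitude >= min_peak]


@dataclass(frozen=True)
class InhibitionDecomposition:
    """Percent contributions to baseline inhibition; sums to 100 exactly."""

    somatic_percent: float
    distal_percent: float
    other_percent: float
    ordering_violated: bool = False

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.somatic_percent, self.distal_percent, self.other_percent)


def decompose(
    q_baseline: float, q_gz_soma: float, q_gz_both: float
) -> InhibitionDecomposition:
    """Somatic / distal / residual split from the three gabazine charges.

    The residual surviving dual application is subtracted from the somatic
    and distal estimates by construction of the formulas.  A non-physical
    ordering (Q_soma > Q_base or Q_both > Q_soma) is flagged with a warning
    but the percentages are still returned.
    """
    if q_baseline <= 0:
        raise ValueError("baseline charge must be positive")
    other = q_gz_both / q_baseline * 100.0
    somatic = (q_baseline - q_gz_soma) / q_baseline * 100.0
    distal = (q_gz_soma - q_gz_both) / q_baseline * 100.0
    violated = q_gz_soma > q_baseline or q_gz_both > q_gz_soma
    if violated:
        warnings.warn(
            "non-physical charge ordering (expected Q_base >= Q_soma >= Q_both); "
            "percentages returned as-is",
            stacklevel=2,
        )
    return InhibitionDecomposition(somatic, distal, other, ordering_violated=violated)


@dataclass
class PairedComparison:
    """Within-slice paired comparison of IPSC strength between cell classes."""

    mean_a: float
    mean_b: float
    difference: float
    n_pairs: int
    test: _stats.TestResult


def compare_within_slice(
    paired_charges: Sequence[tuple[float, float]],
    label_a: str = "pPV",
    label_b: str = "other",
) -> PairedComparison:
    """Per-group means and a Wilcoxon signed-rank test on within-slice pairs."""
    if len(paired_charges) < 1:
        raise ValueError("need at least one within-slice pair")
    a = np.array([p[0] for p in paired_charges], dtype=float)
    b = np.array([p[1] for p in paired_charges], dtype=float)
    test = _stats.run_test("WSR", [a, b])
    return PairedComparison(
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        difference=float(a.mean() - b.mean()),
        n_pairs=len(a),
        test=test,
    )
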