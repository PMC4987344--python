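"""Recording containers: stimulus protocols and sweep sets.

Current-clamp recordings are represented as a :class:`SweepSet` — one trace per
stimulus amplitude, all sharing a common time base defined by a
:class:`StimulusProtocol`.  Voltages are in mV (current clamp) and currents in
pA (voltage clamp); stimulus amplitudes are always in pA; time is in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np

__all__ = [
    "StimulusProtocol",
    "SweepSet",
    "subthreshold_protocol",
    "suprathreshold_protocol",
    "ProtocolError",
]


class ProtocolError(ValueError):
    """A sweep set does not satisfy the protocol required by an analysis."""


@dataclass(frozen=True)
class StimulusProtocol:
    """A square-step stimulus family.

    Parameters
    ----------
    step_amplitudes
        Ordered step amplitudes in pA.
    step_duration
        Step length in seconds (default 1 s).
    baseline_pre, baseline_post
        Pre- and post-step baseline durations in seconds.
    sampling_rate
        Samples per second (default 10 kHz).
    """

    step_amplitudes: tuple[float, ...]
    step_duration: float = 1.0
    baseline_pre: float = 0.1
    baseline_post: float = 0.1
    sampling_rate: float = 10_000.0

    def __post_init__(self) -> None:
        if len(self.step_amplitudes) == 0:
            raise ValueError("protocol needs at least one step amplitude")
        if len(set(self.step_amplitudes)) != len(self.step_amplitudes):
            raise ValueError("step amplitudes must be unique")
        for name in ("step_duration", "baseline_pre", "baseline_post"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def dt(self) -> float:
        return 1.0 / self.sampling_rate

    @property
    def total_duration(self) -> float:
        return self.baseline_pre + self.step_duration + self.baseline_post

    @property
    def n_samples(self) -> int:
        return int(round(self.total_duration * self.sampling_rate))

    @property
    def onset_index(self) -> int:
        return int(round(self.baseline_pre * self.sampling_rate))

    @property
    def offset_index(self) -> int:
        return int(round((self.baseline_pre + self.step_duration) * self.sampling_rate))

    def time(self) -> np.ndarray:
        """Sample times in seconds, t=0 at sweep start."""
        return np.arange(self.n_samples) * self.dt

    def stimulus_matrix(self) -> np.ndarray:
        """(n_sweeps, n_samples) array of injected current in pA."""
        out = np.zeros((len(self.step_amplitudes), self.n_samples))
        out[:, self.onset_index : self.offset_index] = np.asarray(
            self.step_amplitudes
        )[:, None]
        return out

    def to_dict(self) -> dict[str, Any]:
        return {
            "step_amplitudes": list(self.step_amplitudes),
            "step_duration": self.step_duration,
            "baseline_pre": self.baseline_pre,
            "baseline_post": self.baseline_post,
            "sampling_rate": self.sampling_rate,
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "StimulusProtocol":
        return cls(
            step_amplitudes=tuple(float(a) for a in d["step_amplitudes"]),
            step_duration=float(d["step_duration"]),
            baseline_pre=float(d["baseline_pre"]),
            baseline_post=float(d["baseline_post"]),
            sampling_rate=float(d["sampling_rate"]),
        )


def subthreshold_protocol(sampling_rate: float = 10_000.0) -> StimulusProtocol:
    """-50..+50 pA in 10 pA increments, 1 s steps."""
    return StimulusProtocol(
        step_amplitudes=tuple(float(a) for a in range(-50, 60, 10)),
        sampling_rate=sampling_rate,
    )


def suprathreshold_protocol(sampling_rate: float = 10_000.0) -> StimulusProtocol:
    """0..1000 pA in 100 pA increments, 1 s steps."""
    return StimulusProtocol(
        step_amplitudes=tuple(float(a) for a in range(0, 1100, 100)),
        sampling_rate=sampling_rate,
    )


@dataclass
class SweepSet:
    """A family of traces recorded under one protocol.

    ``sweeps`` maps stimulus amplitude (pA) to the sampled trace.  ``units`` is
    "mV" for current clamp and "pA" for voltage clamp.  ``meta`` carries
    provenance (generator ground truth, sidecar fields, ...).
    """

    protocol: StimulusProtocol
    sweeps: dict[float, np.ndarray]
    units: str = "mV"
    clamp_mode: str = "current"
    cell_id: str = ""
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = self.protocol.n_samples
        for amp, trace in self.sweeps.items():
            if len(trace) != n:
                raise ValueError(
                    f"sweep at {amp} pA has {len(trace)} samples, protocol "
                    f"defines {n}"
                )

    @property
    def amplitudes(self) -> list[float]:
        return sorted(self.sweeps)

    def time(self) -> np.ndarray:
        return self.protocol.time()

    def get(self, amplitude: float, atol: float = 1e-6) -> np.ndarray:
        for amp, trace in self.sweeps.items():
            if abs(amp - amplitude) <= atol:
                return trace
        raise ProtocolError(f"no sweep at {amplitude} pA")

    def has(self, amplitude: float, atol: float = 1e-6) -> bool:
        return any(abs(a - amplitude) <= atol for a in self.sweeps)
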