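"""Charge-balanced biphasic stimulus construction.

Builds the four pulse shapes used throughout the package -- rectangular
(``REC``) and three linearly ramped variants (``RAMP_UP``, ``RAMP_DOWN``,
``RAMP_LONG``) -- as sampled current waveforms, plus pulse trains and
charge-per-phase bookkeeping.

Conventions
-----------
* Anodic current is positive; cathodic negative.  ``ANODIC_FIRST`` pulses
  lead with the positive phase.
* Currents are in microamperes, times in microseconds, charges in
  nanocoulombs (1 uA * 1 us = 1e-3 nC).
* Ideal ramps are sampled at grid-cell midpoints so that the discrete
  integral of a single ramped phase equals ``amplitude * duration / 2``
  exactly.
* Hardware-quantized ramps (``quant_step_ua > 0``) are staircases of
  equal-duration plateaus whose values are multiples of the step; the
  second phase reuses the mirrored first-phase plan of the same shape
  rule, so charge balance is exact.  Rectangular amplitudes are not
  quantized.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np

__all__ = [
    "PulseShape",
    "Polarity",
    "PulseSpec",
    "TrainSpec",
    "Waveform",
    "make_pulse",
    "make_train",
    "charge_per_phase",
    "DegenerateAmplitudeError",
]

#: nC carried by 1 uA flowing for 1 us.
NC_PER_UA_US = 1e-3


class PulseShape(str, Enum):
    """The four tested pulse shapes."""

    REC = "rec"
    RAMP_UP = "ramp_up"
    RAMP_DOWN = "ramp_down"
    RAMP_LONG = "ramp_long"

    @property
    def is_ramped(self) -> bool:
        return self is not PulseShape.REC


class Polarity(str, Enum):
    ANODIC_FIRST = "anodic_first"
    CATHODIC_FIRST = "cathodic_first"

    def flipped(self) -> "Polarity":
        return (
            Polarity.CATHODIC_FIRST
            if self is Polarity.ANODIC_FIRST
            else Polarity.ANODIC_FIRST
        )


class DegenerateAmplitudeError(ValueError):
    """Peak amplitude below one quantization step in hardware mode."""


@dataclass(frozen=True)
class PulseSpec:
    """Parametric description of one charge-balanced biphasic pulse.

    Parameters
    ----------
    shape : PulseShape
    polarity : Polarity
        Leading-phase polarity; anodic current is positive by convention.
    phase_duration_us : float
        Duration of each of the two phases (us); must be positive.
    interphase_gap_us : float
        Zero-current interval between the phases (us); >= 0.
    peak_amplitude_ua : float
        Peak current of each phase (uA); >= 0.
    quant_step_ua : float
        Hardware current step for ramp interiors (uA).  ``0`` selects the
        ideal (smooth) ramp.
    grid_resolution_us : float
        Sampling grid of the generated waveform (us).
    """

    shape: PulseShape
    polarity: Polarity = Polarity.ANODIC_FIRST
    phase_duration_us: float = 25.0
    interphase_gap_us: float = 10.0
    peak_amplitude_ua: float = 100.0
    quant_step_ua: float = 0.0
    grid_resolution_us: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape", PulseShape(self.shape))
        object.__setattr__(self, "polarity", Polarity(self.polarity))
        if self.phase_duration_us <= 0:
            raise ValueError("phase_duration_us must be positive")
        if self.peak_amplitude_ua < 0:
            raise ValueError("peak_amplitude_ua must be non-negative")
        if self.interphase_gap_us < 0:
            raise ValueError("interphase_gap_us must be non-negative")
        if self.quant_step_ua < 0:
            raise ValueError("quant_step_ua must be non-negative")
        if self.grid_resolution_us <= 0:
            raise ValueError("grid_resolution_us must be positive")

    def with_polarity(self, polarity: Polarity) -> "PulseSpec":
        return replace(self, polarity=Polarity(polarity))

    def with_amplitude(self, peak_amplitude_ua: float) -> "PulseSpec":
        return replace(self, peak_amplitude_ua=peak_amplitude_ua)


@dataclass(frozen=True)
class TrainSpec:
    """A periodic train of identical pulses."""

    pulse: PulseSpec
    rate_pps: float = 23.3
    n_pulses: int = 1

    def __post_init__(self) -> None:
        if self.rate_pps <= 0:
            raise ValueError("rate_pps must be positive")
        if self.n_pulses < 1:
            raise ValueError("n_pulses must be >= 1")

    @property
    def period_us(self) -> float:
        return 1e6 / self.rate_pps


@dataclass
class Waveform:
    """Uniformly sampled current trace.

    ``samples_ua[k]`` is the current over the grid cell starting at
    ``t0_us + k * sample_interval_us``.
    """

    samples_ua: np.ndarray
    sample_interval_us: float
    t0_us: float = 0.0

    def __post_init__(self) -> None:
        self.samples_ua = np.asarray(self.samples_ua, dtype=float)
        if not np.all(np.isfinite(self.samples_ua)):
            raise ValueError("waveform samples must be finite")

    def __len__(self) -> int:
        return self.samples_ua.size

    @property
    def times_us(self) -> np.ndarray:
        return self.t0_us + np.arange(len(self)) * self.sample_interval_us

    @property
    def duration_us(self) -> float:
        return len(self) * self.sample_interval_us

    @property
    def charge_nc(self) -> float:
        """Net signed charge (nC); ~0 for charge-balanced stimuli."""
        return float(self.samples_ua.sum()) * self.sample_interval_us * NC_PER_UA_US

    def value_at(self, t_us: np.ndarray) -> np.ndarray:
        """Zero-order-hold evaluation at arbitrary times (0 outside)."""
        t = np.asarray(t_us, dtype=float) - self.t0_us
        idx = np.floor(t / self.sample_interval_us).astype(int)
        out = np.zeros_like(t)
        ok = (idx >= 0) & (idx < len(self))
        out[ok] = self.samples_ua[idx[ok]]
        return out

    def to_text(self, path) -> None:
        """Write as two-column delimited text (time_us, current_ua)."""
        np.savetxt(
            path,
            np.column_stack([self.times_us, self.samples_ua]),
            delimiter="\t",
            header="time_us\tcurrent_ua",
        )


def _ideal_phase(shape: PulseShape, which: int, n: int, amplitude: float) -> np.ndarray:
    """Unsigned current samples of one ideal phase (midpoint-sampled)."""
    up = amplitude * (np.arange(n) + 0.5) / n
    if shape is PulseShape.REC:
        return np.full(n, amplitude)
    if shape is PulseShape.RAMP_UP:
        return up
    if shape is PulseShape.RAMP_DOWN:
        return up[::-1]
    # RAMP_LONG: declining first phase, rising second phase
    return up[::-1] if which == 0 else up


def _quantized_phase(
    shape: PulseShape, which: int, n: int, amplitude: float, step: float
) -> np.ndarray:
    """Staircase approximation of one ramped phase.

    Plateau values are positive multiples of ``step`` and plateaus share
    equal (integer-rounded) durations.  The descending plan is the exact
    reversal of the ascending plan, so opposite-slope phases carry equal
    charge and the biphasic pulse stays balanced.
    """
    if shape is PulseShape.REC:
        # Open question resolved: hardware quantization applies to ramp
        # interiors only (printed rectangular charges imply non-multiple
        # amplitudes such as 144 uA).
        return np.full(n, amplitude)
    n_plateaus = int(round(amplitude / step))
    if n_plateaus < 1:
        raise DegenerateAmplitudeError(
            f"peak amplitude {amplitude} uA is below one quantization step "
            f"({step} uA); the ramp degenerates to zero"
        )
    n_plateaus = min(n_plateaus, n)
    plateau_of = (np.arange(n) * n_plateaus) // n
    ascending = step * (plateau_of + 1.0)
    if shape is PulseShape.RAMP_UP:
        return ascending
    if shape is PulseShape.RAMP_DOWN:
        return ascending[::-1]
    return ascending[::-1] if which == 0 else ascending


def make_pulse(spec: PulseSpec) -> Waveform:
    """Sample one charge-balanced biphasic pulse on a uniform grid.

    The two phases have opposite sign and are separated by the interphase
    gap.  The net signed charge integrates to zero by construction, for
    both ideal and quantized ramps.
    """
    dt = spec.grid_resolution_us
    n = int(round(spec.phase_duration_us / dt))
    if n < 1:
        raise ValueError(
            "phase_duration_us shorter than one grid cell; refine the grid"
        )
    n_gap = int(round(spec.interphase_gap_us / dt))
    amp = spec.peak_amplitude_ua

    if spec.quant_step_ua > 0 and amp > 0:
        phase = [
            _quantized_phase(spec.shape, w, n, amp, spec.quant_step_ua)
            for w in (0, 1)
        ]
    else:
        phase = [_ideal_phase(spec.shape, w, n, amp) for w in (0, 1)]

    s1 = 1.0 if spec.polarity is Polarity.ANODIC_FIRST else -1.0
    samples = np.concatenate([s1 * phase[0], np.zeros(n_gap), -s1 * phase[1]])
    return Waveform(samples_ua=samples, sample_interval_us=dt)


def charge_per_phase(spec: PulseSpec) -> float:
    """Charge per phase (nC) by the ideal-shape convention.

    Rectangular: ``duration * amplitude``; ramped: ``duration * amplitude
    / 2``.  The ideal formula is used regardless of hardware quantization.
    """
    q = spec.phase_duration_us * spec.peak_amplitude_ua * NC_PER_UA_US
    return q / 2.0 if spec.shape.is_ramped else q


def make_train(train: TrainSpec) -> Waveform:
    """Place ``n_pulses`` copies of the pulse at the train period."""
    pulse = make_pulse(train.pulse)
    dt = pulse.sample_interval_us
    period_n = int(round(train.period_us / dt))
    if len(pulse) > period_n:
        raise ValueError(
            f"pulse ({pulse.duration_us:.1f} us) longer than the "
            f"inter-onset interval ({train.period_us:.1f} us)"
        )
    out = np.zeros(period_n * train.n_pulses)
    for k in range(train.n_pulses):
        out[k * period_n : k * period_n + len(pulse)] = pulse.samples_ua
    return Waveform(samples_ua=out, sample_interval_us=dt)
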