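"""Wave metrics, thresholds and dB quantities from evoked traces.

Amplitude is the voltage difference between a wave's positive peak and
the following trough; latency is the timing of the peak; threshold is the
lowest tested charge level whose wave amplitude exceeds 0.1 uV
(strictly).  All dB values use the 20*log10 (amplitude) convention, so a
doubling is +6.0206 dB.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .preprocess import EvokedTrace
from .stimulus import Polarity, PulseShape

__all__ = [
    "WaveMetrics",
    "LevelPoint",
    "GrowthSeries",
    "ThresholdResult",
    "find_wave",
    "detect_threshold",
    "to_db",
    "level_at_db_above_threshold",
    "WAVE_SEARCH_WINDOWS_MS",
    "TROUGH_SPAN_MS",
    "CRITERION_UV",
    "BoundaryWarning",
]

#: Default per-wave peak search windows (ms post-onset); configurable.
WAVE_SEARCH_WINDOWS_MS = {
    "II": (0.7, 1.4),
    "III": (1.3, 1.9),
    "IV": (1.8, 2.6),
}
TROUGH_SPAN_MS = 0.6
CRITERION_UV = 0.1
DB_PER_DOUBLING = 20.0 * math.log10(2.0)


class BoundaryWarning(UserWarning):
    """A requested level sits at the boundary of the tested range."""


@dataclass(frozen=True)
class WaveMetrics:
    wave_id: str
    peak_latency_ms: float
    trough_latency_ms: float
    amplitude_uv: float
    present: bool

    def __post_init__(self) -> None:
        if self.present:
            if self.trough_latency_ms <= self.peak_latency_ms:
                raise ValueError("trough must follow the peak")
            if self.amplitude_uv < 0:
                raise ValueError("amplitude must be >= 0 when present")


def find_wave(
    trace: EvokedTrace,
    wave_id: str = "II",
    search_window_ms: tuple[float, float] | None = None,
    trough_span_ms: float = TROUGH_SPAN_MS,
) -> WaveMetrics:
    """Locate a wave's peak and following trough inside a search window."""
    if search_window_ms is None:
        search_window_ms = WAVE_SEARCH_WINDOWS_MS[wave_id]
    idx = trace.window_indices(search_window_ms)
    y = trace.samples_uv
    t = trace.time_ms
    p = idx[int(np.argmax(y[idx]))]
    peak_t = t[p]
    after = np.nonzero((t > peak_t) & (t <= peak_t + trough_span_ms))[0]
    if after.size == 0:
        return WaveMetrics(wave_id, peak_t, peak_t, 0.0, False)
    q = after[int(np.argmin(y[after]))]
    amplitude = float(y[p] - y[q])
    is_local_max = (p > 0 and p < len(trace) - 1
                    and y[p] >= y[p - 1] and y[p] >= y[p + 1])
    present = amplitude > 0 and is_local_max
    return WaveMetrics(
        wave_id=wave_id,
        peak_latency_ms=float(peak_t),
        trough_latency_ms=float(t[q]),
        amplitude_uv=amplitude if present else max(amplitude, 0.0),
        present=present,
    )


@dataclass(frozen=True)
class LevelPoint:
    """Wave metrics at one tested level."""

    charge_nc: float
    current_ua: float
    metrics: WaveMetrics
    above_facial_nerve: bool = False


@dataclass
class GrowthSeries:
    """Wave metrics across an ordered series of charge levels."""

    shape: PulseShape
    polarity: Polarity | str  # a Polarity, or "averaged"
    phase_duration_us: float
    interphase_gap_us: float
    wave_id: str
    points: list[LevelPoint] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.points = sorted(self.points, key=lambda p: p.charge_nc)
        charges = [p.charge_nc for p in self.points]
        if any(b <= a for a, b in zip(charges, charges[1:])):
            raise ValueError("levels must be strictly increasing in charge")

    @property
    def usable_points(self) -> list[LevelPoint]:
        """Levels below the facial-nerve onset (analysis set)."""
        return [p for p in self.points if not p.above_facial_nerve]

    @property
    def facial_nerve_truncation(self) -> int | None:
        for i, p in enumerate(self.points):
            if p.above_facial_nerve:
                return i
        return None

    def charges(self) -> np.ndarray:
        return np.array([p.charge_nc for p in self.usable_points])

    def currents(self) -> np.ndarray:
        return np.array([p.current_ua for p in self.usable_points])

    def amplitudes(self) -> np.ndarray:
        return np.array([p.metrics.amplitude_uv for p in self.usable_points])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        pol = self.polarity.value if isinstance(self.polarity, Polarity) else self.polarity
        for p in self.points:
            rows.append(
                {
                    "shape": self.shape.value,
                    "polarity": pol,
                    "phase_duration_us": self.phase_duration_us,
                    "interphase_gap_us": self.interphase_gap_us,
                    "wave": self.wave_id,
                    "charge_nc": p.charge_nc,
                    "current_ua": p.current_ua,
                    "amplitude_uv": p.metrics.amplitude_uv,
                    "peak_latency_ms": p.metrics.peak_latency_ms,
                    "trough_latency_ms": p.metrics.trough_latency_ms,
                    "present": p.metrics.present,
                    "above_facial_nerve": p.above_facial_nerve,
                }
            )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class ThresholdResult:
    threshold_charge_nc: float | None
    threshold_current_ua: float | None
    criterion_uv: float
    defined: bool


def detect_threshold(
    series: GrowthSeries, criterion_uv: float = CRITERION_UV
) -> ThresholdResult:
    """Lowest tested charge level with amplitude strictly above criterion."""
    if not series.points:
        raise ValueError("series has no levels")
    for p in series.usable_points:
        if p.metrics.amplitude_uv > criterion_uv:
            return ThresholdResult(
                threshold_charge_nc=p.charge_nc,
                threshold_current_ua=p.current_ua,
                criterion_uv=criterion_uv,
                defined=True,
            )
    return ThresholdResult(None, None, criterion_uv, False)


def to_db(value: float, reference: float = 1.0) -> float:
    """20*log10(value/reference); a doubling is +6.0206 dB."""
    if value <= 0 or reference <= 0:
        raise ValueError("to_db needs positive value and reference")
    return 20.0 * math.log10(value / reference)


def level_at_db_above_threshold(
    series: GrowthSeries,
    delta_db: float = 3.0,
    threshold: ThresholdResult | None = None,
    criterion_uv: float = CRITERION_UV,
) -> LevelPoint:
    """Tested level nearest (in dB of charge) to threshold + delta_db.

    Ties resolve toward the lower level.  If the threshold sits at the top
    of the tested range the top level is returned with a warning.
    """
    if threshold is None:
        threshold = detect_threshold(series, criterion_uv)
    if not threshold.defined:
        raise ValueError("no defined threshold for this series")
    pts = series.usable_points
    target_db = to_db(threshold.threshold_charge_nc) + delta_db
    if threshold.threshold_charge_nc >= pts[-1].charge_nc:
        warnings.warn(
            "threshold at the top tested level; returning that level",
            BoundaryWarning,
            stacklevel=2,
        )
        return pts[-1]
    best = min(
        pts,
        key=lambda p: (round(abs(to_db(p.charge_nc) - target_db), 12), p.charge_nc),
    )
    if best.charge_nc >= pts[-1].charge_nc:
        warnings.warn(
            "3-dB-above-threshold level is the top tested level",
            BoundaryWarning,
            stacklevel=2,
        )
    return best
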