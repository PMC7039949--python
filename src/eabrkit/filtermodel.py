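"""Lowpass-filter threshold-prediction model.

The electric waveform of one stimulus period is passed through a
biquadratic IIR lowpass whose magnitude target is flat to 110 Hz,
-6 dB/octave from 110 Hz to 4 kHz and -3 dB/octave beyond.  The filtered
period is multiplied by sliding 10 ms Hanning windows (hop = 1/10 of the
window, wrapping periodically) and the threshold is taken inversely
proportional to the maximum windowed RMS, reported as
``-20*log10(max RMS)`` plus a calibration offset.

The -3 dB/octave (half-order) tail cannot be realized exactly by a
rational biquad.  The realization used here is a single pole-zero cell:
poles at ``corner1`` and ``4 * zero``, zero at ``9/8 * corner2`` -- the
one-cell fractional-slope approximation, with the cell offset slightly
above the corner to center the ripple.  The design report carries the
maximum deviation from the piecewise-linear target over [10 Hz, 20 kHz].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal

from .stimulus import PulseSpec, Waveform, charge_per_phase, make_pulse

__all__ = [
    "FilterModelSpec",
    "ModelFilter",
    "ModelPrediction",
    "design_model_filter",
    "target_magnitude_db",
    "predict_relative_threshold",
    "relative_threshold_for_spec",
    "calibrate",
    "predict_table",
    "ZeroWaveformError",
]


class ZeroWaveformError(ValueError):
    """An all-zero stimulus has no finite predicted threshold."""


@dataclass(frozen=True)
class FilterModelSpec:
    corner1_hz: float = 110.0
    corner2_hz: float = 4000.0
    mid_slope_db_per_octave: float = -6.0
    high_slope_db_per_octave: float = -3.0
    window_ms: float = 10.0
    hop_fraction: float = 0.1
    rate_pps: float = 23.3
    fs_model_hz: float = 1_000_000.0

    def __post_init__(self) -> None:
        if not self.corner1_hz < self.corner2_hz < self.fs_model_hz / 2:
            raise ValueError("need corner1 < corner2 < fs_model/2")
        if self.window_ms <= 0:
            raise ValueError("window_ms must be positive")
        if not 0 < self.hop_fraction <= 1:
            raise ValueError("hop_fraction must be in (0, 1]")

    @property
    def period_s(self) -> float:
        return 1.0 / self.rate_pps

    @property
    def zero_hz(self) -> float:
        return self.corner2_hz * 9.0 / 8.0

    @property
    def pole2_hz(self) -> float:
        return 4.0 * self.zero_hz


def target_magnitude_db(f_hz: np.ndarray, spec: FilterModelSpec = FilterModelSpec()) -> np.ndarray:
    """Piecewise log-linear magnitude target (dB)."""
    f = np.asarray(f_hz, dtype=float)
    out = np.zeros_like(f)
    mid = (f > spec.corner1_hz) & (f <= spec.corner2_hz)
    out[mid] = spec.mid_slope_db_per_octave * np.log2(f[mid] / spec.corner1_hz)
    hi = f > spec.corner2_hz
    at_c2 = spec.mid_slope_db_per_octave * math.log2(spec.corner2_hz / spec.corner1_hz)
    out[hi] = at_c2 + spec.high_slope_db_per_octave * np.log2(f[hi] / spec.corner2_hz)
    return out


@dataclass
class ModelFilter:
    """Realized biquad plus its magnitude-fidelity report."""

    sos: np.ndarray
    spec: FilterModelSpec
    report: dict = field(default_factory=dict)

    def magnitude_db(self, f_hz: np.ndarray) -> np.ndarray:
        _, h = signal.sosfreqz(self.sos, worN=np.atleast_1d(f_hz).astype(float),
                               fs=self.spec.fs_model_hz)
        return 20.0 * np.log10(np.abs(h))


def design_model_filter(spec: FilterModelSpec = FilterModelSpec()) -> ModelFilter:
    """Deterministic biquad realization of the magnitude target."""
    w = lambda f: 2.0 * math.pi * f
    zeros = [-w(spec.zero_hz)]
    poles = [-w(spec.corner1_hz), -w(spec.pole2_hz)]
    gain = w(spec.corner1_hz) * w(spec.pole2_hz) / w(spec.zero_hz)  # unity DC gain
    zd, pd, kd = signal.bilinear_zpk(zeros, poles, gain, spec.fs_model_hz)
    sos = signal.zpk2sos(zd, pd, kd)
    assert sos.shape == (1, 6)  # one biquad section

    freqs = np.logspace(1, math.log10(20000.0), 200)
    mf = ModelFilter(sos=sos, spec=spec)
    dev = mf.magnitude_db(freqs) - target_magnitude_db(freqs, spec)
    mf.report = {
        "freqs_hz": freqs,
        "deviation_db": dev,
        "max_abs_deviation_db": float(np.abs(dev).max()),
        "zero_hz": spec.zero_hz,
        "pole2_hz": spec.pole2_hz,
        "note": "half-order (-3 dB/oct) tail approximated by one "
        "pole-zero cell; see module docstring",
    }
    return mf


def _resample_to_model_grid(waveform: Waveform, spec: FilterModelSpec) -> np.ndarray:
    """One full stimulus period sampled at fs_model."""
    n_period = int(round(spec.fs_model_hz * spec.period_s))
    dt_us = 1e6 / spec.fs_model_hz
    if abs(waveform.sample_interval_us - dt_us) < 1e-12:
        x = waveform.samples_ua
    else:
        t_us = np.arange(int(round(waveform.duration_us / dt_us))) * dt_us
        x = waveform.value_at(t_us + waveform.t0_us)
    if x.size > n_period:
        raise ValueError(
            f"waveform ({x.size} samples at fs_model) exceeds one period "
            f"({n_period} samples)"
        )
    period = np.zeros(n_period)
    period[: x.size] = x
    return period


def predict_relative_threshold(
    waveform: Waveform,
    spec: FilterModelSpec = FilterModelSpec(),
    model: ModelFilter | None = None,
    calibration_offset_db: float = 0.0,
) -> float:
    """Relative threshold (dB) of one stimulus period.

    The period is filtered (periodic steady state), multiplied by sliding
    Hanning windows spanning the period, and the threshold is
    ``-20*log10(max window RMS)`` plus the calibration offset.
    """
    if model is None:
        model = design_model_filter(spec)
    period = _resample_to_model_grid(waveform, spec)
    if not np.any(period):
        raise ZeroWaveformError("all-zero waveform: threshold undefined")
    n = period.size
    # third repetition ~= periodic steady state (settling << period)
    y = signal.sosfilt(model.sos, np.tile(period, 3))[2 * n :]
    n_win = int(round(spec.window_ms * 1e-3 * spec.fs_model_hz))
    hop = max(1, int(round(n_win * spec.hop_fraction)))
    win = np.hanning(n_win)
    y2 = np.concatenate([y, y])  # final partial windows wrap periodically
    max_rms = 0.0
    for start in range(0, n, hop):
        seg = y2[start : start + n_win] * win
        max_rms = max(max_rms, math.sqrt(float(np.mean(seg * seg))))
    return -20.0 * math.log10(max_rms) + calibration_offset_db


def relative_threshold_for_spec(
    pulse_spec: PulseSpec,
    spec: FilterModelSpec = FilterModelSpec(),
    model: ModelFilter | None = None,
) -> float:
    """Relative threshold of a pulse shape at unit (1 uA) peak amplitude."""
    unit = pulse_spec.with_amplitude(1.0)
    return predict_relative_threshold(make_pulse(unit), spec, model)


def calibrate(
    reference_spec: PulseSpec,
    reference_threshold_current_ua: float,
    spec: FilterModelSpec = FilterModelSpec(),
    model: ModelFilter | None = None,
) -> float:
    """Offset (dB) anchoring the model to a measured reference threshold.

    After calibration the model's predicted threshold current for the
    reference condition equals ``reference_threshold_current_ua`` exactly;
    all other predictions shift by the same additive constant.
    """
    if reference_threshold_current_ua <= 0:
        raise ValueError("reference threshold current must be positive")
    rel = relative_threshold_for_spec(reference_spec, spec, model)
    return 20.0 * math.log10(reference_threshold_current_ua) - rel


@dataclass(frozen=True)
class ModelPrediction:
    pulse_spec: PulseSpec
    relative_db: float
    calibrated_threshold_current_ua: float
    calibrated_threshold_charge_nc: float


def predict_table(
    conditions: Sequence[PulseSpec],
    spec: FilterModelSpec = FilterModelSpec(),
    model: ModelFilter | None = None,
    calibration_offset_db: float = 0.0,
) -> list[ModelPrediction]:
    """Calibrated current and charge threshold predictions per condition."""
    if model is None:
        model = design_model_filter(spec)
    out = []
    for ps in conditions:
        rel = relative_threshold_for_spec(ps, spec, model)
        current = 10.0 ** ((rel + calibration_offset_db) / 20.0)
        charge = charge_per_phase(ps.with_amplitude(current))
        out.append(
            ModelPrediction(
                pulse_spec=ps,
                relative_db=rel,
                calibrated_threshold_current_ua=current,
                calibrated_threshold_charge_nc=charge,
            )
        )
    return out
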