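"""End-to-end orchestration: simulate -> preprocess -> quantify -> fit -> model.

Each stage is a pure function so the CLI subcommands compose to exactly
the same result as one ``run_pipeline`` call.  Identical config + seed
give identical output tables; every table embeds the config hash and the
seed.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from . import growthfit, quantify
from .config import StudyConfig
from .filtermodel import (
    FilterModelSpec,
    calibrate,
    design_model_filter,
    predict_table,
)
from .preprocess import (
    DEFAULT_BASELINE_WINDOW_MS,
    DEFAULT_EXP_FIT_WINDOWS_MS,
    DEFAULT_ONSET_WINDOW_MS,
    EvokedTrace,
    FilterSettings,
    alternating_polarity_average,
    preprocess_condition,
)
from .quantify import GrowthSeries, LevelPoint, WaveMetrics
from .stimulus import Polarity, PulseShape, PulseSpec
from .synthdata import (
    Condition,
    GenParams,
    HARDWARE_DELAYS_US,
    SweepSet,
    simulate_sweepset,
)

__all__ = [
    "PipelineResult",
    "PipelineError",
    "run_pipeline",
    "build_gen_params",
    "stage_simulate",
    "stage_preprocess",
    "stage_quantify",
    "stage_fit",
    "stage_model",
]

AVERAGED = "averaged"


class PipelineError(RuntimeError):
    def __init__(self, stage: str, condition: str, cause: Exception) -> None:
        super().__init__(f"stage '{stage}' failed on {condition}: {cause}")
        self.stage = stage
        self.condition = condition


@dataclass
class PipelineResult:
    tables: dict[str, pd.DataFrame]
    provenance: dict
    config_hash: str
    seed: int

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, table in self.tables.items():
            table.to_csv(out / f"{name}.csv", index=False)
        (out / "provenance.json").write_text(
            json.dumps(self.provenance, indent=2, default=str)
        )


def build_gen_params(config: StudyConfig) -> GenParams:
    overrides = dict(config.generator)
    params = GenParams.from_dict(overrides) if overrides else GenParams()
    params.seed = config.seed
    return params


def _filter_settings(config: StudyConfig) -> FilterSettings:
    pp = config.preprocess
    return FilterSettings(
        low_cut_hz=pp.get("low_cut_hz", 100.0),
        high_cut_hz=pp.get("high_cut_hz", 3000.0),
        order=pp.get("order", 4),
        zero_phase=pp.get("zero_phase", True),
    )


def _iter_condition_groups(
    config: StudyConfig, params: GenParams
) -> Iterator[tuple[Condition, list[SweepSet]]]:
    """Yield (condition, four delay-tagged sweep sets) lazily."""
    for shape, pw, pol, q in itertools.product(
        config.shapes, config.phase_durations_us, config.polarities,
        config.charge_levels_nc,
    ):
        cond = Condition.from_charge(
            PulseShape(shape), Polarity(pol), q, pw, config.interphase_gap_us
        )
        group = [
            simulate_sweepset(params, cond, d, seed=config.seed)
            for d in HARDWARE_DELAYS_US
        ]
        yield cond, group


def stage_simulate(config: StudyConfig) -> list[SweepSet]:
    """Materialize every sweep set of the study (small configs only)."""
    params = build_gen_params(config)
    return [ss for _, group in _iter_condition_groups(config, params) for ss in group]


def _clean_one(group: list[SweepSet], config: StudyConfig) -> EvokedTrace:
    pp = config.preprocess
    return preprocess_condition(
        group,
        baseline_window_ms=tuple(
            pp.get("baseline_window_ms", DEFAULT_BASELINE_WINDOW_MS)
        ),
        onset_window_ms=tuple(pp.get("onset_window_ms", DEFAULT_ONSET_WINDOW_MS)),
        exp_fit_windows_ms=[
            tuple(w) for w in pp.get("exp_fit_windows_ms", DEFAULT_EXP_FIT_WINDOWS_MS)
        ],
        filter_settings=_filter_settings(config),
    )


def stage_preprocess(
    sweepsets: Sequence[SweepSet], config: StudyConfig
) -> list[EvokedTrace]:
    """Clean per-condition traces from materialized sweep sets."""
    groups: dict[tuple, list[SweepSet]] = {}
    for ss in sweepsets:
        groups.setdefault(ss.condition.key(), []).append(ss)
    traces = []
    for key, group in groups.items():
        try:
            traces.append(_clean_one(group, config))
        except Exception as exc:  # pragma: no cover - error path
            raise PipelineError("preprocess", str(key), exc) from exc
    return traces


def _facial_flag(trace: EvokedTrace, params: GenParams) -> bool:
    onset = params.facial_nerve_onset_nc
    return onset is not None and trace.condition.charge_nc >= onset


def _quantify_rows(
    trace: EvokedTrace,
    polarity_label: str,
    config: StudyConfig,
    params: GenParams,
) -> list[dict]:
    qc = config.quantify
    windows = qc.get("search_windows_ms", quantify.WAVE_SEARCH_WINDOWS_MS)
    trough_span = qc.get("trough_span_ms", quantify.TROUGH_SPAN_MS)
    cond = trace.condition
    rows = []
    for wave_id, window in windows.items():
        m = quantify.find_wave(trace, wave_id, tuple(window), trough_span)
        rows.append(
            {
                "shape": cond.shape.value,
                "polarity": polarity_label,
                "phase_duration_us": cond.phase_duration_us,
                "interphase_gap_us": cond.interphase_gap_us,
                "wave": wave_id,
                "charge_nc": cond.charge_nc,
                "current_ua": cond.current_ua,
                "amplitude_uv": m.amplitude_uv,
                "peak_latency_ms": m.peak_latency_ms,
                "trough_latency_ms": m.trough_latency_ms,
                "present": m.present,
                "above_facial_nerve": _facial_flag(trace, params),
            }
        )
    return rows


def stage_quantify(
    traces: Sequence[EvokedTrace], config: StudyConfig
) -> pd.DataFrame:
    """Tidy per-level wave metrics, including polarity-averaged rows."""
    params = build_gen_params(config)
    rows: list[dict] = []
    by_cond: dict[tuple, EvokedTrace] = {}
    for tr in traces:
        cond = tr.condition
        rows.extend(_quantify_rows(tr, cond.polarity.value, config, params))
        by_cond[cond.key()] = tr
    # polarity-averaged traces (artifact-cancelling control)
    seen = set()
    for tr in traces:
        cond = tr.condition
        base = (cond.shape.value, cond.phase_duration_us,
                cond.interphase_gap_us, round(cond.current_ua, 9))
        if base in seen:
            continue
        other_key = cond.key()[:1] + (cond.polarity.flipped().value,) + cond.key()[2:]
        other = by_cond.get(other_key)
        if other is None:
            continue
        seen.add(base)
        avg = alternating_polarity_average(tr, other)
        rows.extend(_quantify_rows(avg, AVERAGED, config, params))
    df = pd.DataFrame(rows)
    return df.sort_values(
        ["shape", "phase_duration_us", "polarity", "wave", "charge_nc"]
    ).reset_index(drop=True)


def _series_from_frame(sub: pd.DataFrame) -> GrowthSeries:
    first = sub.iloc[0]
    pol = first["polarity"]
    points = []
    for _, r in sub.iterrows():
        present = bool(r["present"])
        metrics = WaveMetrics(
            wave_id=r["wave"],
            peak_latency_ms=float(r["peak_latency_ms"]),
            trough_latency_ms=float(r["trough_latency_ms"])
            if present
            else float(r["peak_latency_ms"]) + 1e-9,
            amplitude_uv=float(r["amplitude_uv"]),
            present=present,
        )
        points.append(
            LevelPoint(
                charge_nc=float(r["charge_nc"]),
                current_ua=float(r["current_ua"]),
                metrics=metrics,
                above_facial_nerve=bool(r["above_facial_nerve"]),
            )
        )
    return GrowthSeries(
        shape=PulseShape(first["shape"]),
        polarity=pol if pol == AVERAGED else Polarity(pol),
        phase_duration_us=float(first["phase_duration_us"]),
        interphase_gap_us=float(first["interphase_gap_us"]),
        wave_id=first["wave"],
        points=points,
    )


def stage_fit(levels: pd.DataFrame, config: StudyConfig) -> dict[str, pd.DataFrame]:
    """Thresholds, growth fits, 3-dB-above latencies and SD regressions."""
    qc = config.quantify
    wave = qc.get("wave", "II")
    criterion = qc.get("criterion_uv", quantify.CRITERION_UV)
    fc = config.fit
    delta_db = fc.get("latency_delta_db", 3.0)
    override = fc.get("override")

    thr_rows, fit_rows, lat_rows = [], [], []
    sub_levels = levels[levels["wave"] == wave]
    group_cols = ["shape", "phase_duration_us", "interphase_gap_us", "polarity"]
    for (shape, pw, gap, pol), sub in sub_levels.groupby(group_cols, sort=True):
        series = _series_from_frame(sub.sort_values("charge_nc"))
        thr = quantify.detect_threshold(series, criterion)
        row = {
            "shape": shape, "phase_duration_us": pw,
            "interphase_gap_us": gap, "polarity": pol, "wave": wave,
            "defined": thr.defined,
            "threshold_charge_nc": thr.threshold_charge_nc,
            "threshold_current_ua": thr.threshold_current_ua,
        }
        if thr.defined:
            row["threshold_db_re_1nc"] = quantify.to_db(thr.threshold_charge_nc)
            row["threshold_db_re_1ua"] = quantify.to_db(thr.threshold_current_ua)
        thr_rows.append(row)

        for basis in ("charge", "current"):
            try:
                lin = growthfit.fit_linear(series, basis, criterion)
            except ValueError:
                continue
            try:
                broken = growthfit.fit_broken_stick(series, basis, criterion)
                chosen = growthfit.select_model(
                    lin, broken, alpha=fc.get("alpha", 0.05), override=override
                )
            except ValueError:
                broken, chosen = None, lin
            fit_rows.append(
                {
                    "shape": shape, "phase_duration_us": pw,
                    "interphase_gap_us": gap, "polarity": pol, "wave": wave,
                    "basis": basis, "model": chosen.model,
                    "slope1": chosen.slope1, "intercept1": chosen.intercept1,
                    "slope2": chosen.slope2, "knee": chosen.knee,
                    "r_squared": chosen.r_squared, "n_points": chosen.n_points,
                    "linear_slope": lin.slope1, "linear_r_squared": lin.r_squared,
                }
            )

        if thr.defined:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", quantify.BoundaryWarning)
                point = quantify.level_at_db_above_threshold(
                    series, delta_db, thr, criterion
                )
            lat_rows.append(
                {
                    "shape": shape, "phase_duration_us": pw,
                    "interphase_gap_us": gap, "polarity": pol, "wave": wave,
                    "delta_db": delta_db,
                    "level_charge_nc": point.charge_nc,
                    "level_current_ua": point.current_ua,
                    "peak_latency_ms": point.metrics.peak_latency_ms,
                    "amplitude_uv": point.metrics.amplitude_uv,
                }
            )

    thresholds = pd.DataFrame(thr_rows)
    # per-shape value reported by the analysis: mean across the two
    # single-polarity thresholds
    mean_rows = []
    single = thresholds[
        thresholds["polarity"].isin([p.value for p in Polarity])
    ]
    for (shape, pw, gap), sub in single.groupby(
        ["shape", "phase_duration_us", "interphase_gap_us"]
    ):
        ok = sub[sub["defined"]]
        if len(ok) == 0:
            continue
        mean_rows.append(
            {
                "shape": shape, "phase_duration_us": pw,
                "interphase_gap_us": gap, "polarity": "mean", "wave": wave,
                "defined": len(ok) == len(sub),
                "threshold_charge_nc": ok["threshold_charge_nc"].mean(),
                "threshold_current_ua": ok["threshold_current_ua"].mean(),
                "threshold_db_re_1nc": quantify.to_db(
                    ok["threshold_charge_nc"].mean()
                ),
                "threshold_db_re_1ua": quantify.to_db(
                    ok["threshold_current_ua"].mean()
                ),
            }
        )
    thresholds = pd.concat(
        [thresholds, pd.DataFrame(mean_rows)], ignore_index=True
    )

    sd_rows = []
    mean_thr = thresholds[thresholds["polarity"] == "mean"]
    for (shape, gap), sub in mean_thr.groupby(["shape", "interphase_gap_us"]):
        sub = sub[sub["defined"]]
        if sub["phase_duration_us"].nunique() < 2:
            continue
        charge_map = dict(
            zip(sub["phase_duration_us"], sub["threshold_charge_nc"])
        )
        current_map = dict(
            zip(sub["phase_duration_us"], sub["threshold_current_ua"])
        )
        fit_c = growthfit.strength_duration_fit(charge_map, basis="dB re 1 nC")
        fit_i = growthfit.strength_duration_fit(current_map, basis="dB re 1 uA")
        for f in (fit_c, fit_i):
            sd_rows.append(
                {
                    "shape": shape, "interphase_gap_us": gap, "wave": wave,
                    "basis": f.basis,
                    "slope_db_per_doubling": f.slope_db_per_doubling,
                    "intercept_db": f.intercept_db,
                    "r_squared": f.r_squared, "n_durations": f.n_points,
                }
            )

    return {
        "thresholds": thresholds,
        "growth_fits": pd.DataFrame(fit_rows),
        "latencies_3db": pd.DataFrame(lat_rows),
        "strength_duration": pd.DataFrame(sd_rows),
    }


def stage_model(
    config: StudyConfig, reference_current_ua: float | None = None
) -> pd.DataFrame:
    """Filter-model threshold predictions for the study's conditions."""
    mc = config.model or {}
    spec_kwargs = {
        k: mc[k]
        for k in (
            "corner1_hz", "corner2_hz", "window_ms", "hop_fraction",
            "rate_pps", "fs_model_hz",
        )
        if k in mc
    }
    spec = FilterModelSpec(**spec_kwargs)
    model = design_model_filter(spec)
    ref = mc.get("reference", {})
    ref_spec = PulseSpec(
        shape=PulseShape(ref.get("shape", "rec")),
        polarity=Polarity.ANODIC_FIRST,
        phase_duration_us=ref.get("phase_duration_us", 25.0),
        interphase_gap_us=ref.get("interphase_gap_us", 10.0),
        peak_amplitude_ua=1.0,
    )
    if reference_current_ua is None:
        reference_current_ua = mc.get("reference_current_ua")
    offset = (
        calibrate(ref_spec, reference_current_ua, spec, model)
        if reference_current_ua
        else 0.0
    )
    conds = [
        PulseSpec(
            shape=PulseShape(shape),
            polarity=Polarity.ANODIC_FIRST,
            phase_duration_us=pw,
            interphase_gap_us=config.interphase_gap_us,
            peak_amplitude_ua=1.0,
        )
        for shape in config.shapes
        for pw in config.phase_durations_us
    ]
    preds = predict_table(conds, spec, model, offset)
    return pd.DataFrame(
        [
            {
                "shape": p.pulse_spec.shape.value,
                "phase_duration_us": p.pulse_spec.phase_duration_us,
                "interphase_gap_us": p.pulse_spec.interphase_gap_us,
                "relative_db": p.relative_db,
                "predicted_current_ua": p.calibrated_threshold_current_ua,
                "predicted_charge_nc": p.calibrated_threshold_charge_nc,
                "calibrated": bool(reference_current_ua),
                "max_filter_deviation_db": model.report["max_abs_deviation_db"],
            }
            for p in preds
        ]
    )


def _stamp(tables: dict[str, pd.DataFrame], config: StudyConfig) -> None:
    h = config.config_hash()
    for t in tables.values():
        if len(t):
            t["config_hash"] = h
            t["seed"] = config.seed
        else:
            t["config_hash"] = pd.Series(dtype=str)
            t["seed"] = pd.Series(dtype=int)


def run_pipeline(config: StudyConfig, out_dir=None) -> PipelineResult:
    """Execute the full study; streams the simulation per condition."""
    params = build_gen_params(config)
    traces: list[EvokedTrace] = []
    for cond, group in _iter_condition_groups(config, params):
        try:
            traces.append(_clean_one(group, config))
        except Exception as exc:
            raise PipelineError("preprocess", str(cond.key()), exc) from exc
    try:
        levels = stage_quantify(traces, config)
    except Exception as exc:
        raise PipelineError("quantify", "all", exc) from exc
    tables = {"levels": levels}
    try:
        tables.update(stage_fit(levels, config))
    except Exception as exc:
        raise PipelineError("fit", "all", exc) from exc

    provenance: dict = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": ["simulate", "preprocess", "quantify", "fit"],
    }
    if config.model is not None:
        ref_current = None
        mc = config.model
        if mc.get("reference_current_ua") is None:
            # calibrate against the measured polarity-mean reference threshold
            thr = tables["thresholds"]
            ref = mc.get("reference", {})
            sel = thr[
                (thr["shape"] == ref.get("shape", "rec"))
                & (thr["phase_duration_us"] == ref.get("phase_duration_us", 25.0))
                & (thr["polarity"] == "mean")
                & thr["defined"]
            ]
            if len(sel):
                ref_current = float(sel.iloc[0]["threshold_current_ua"])
        try:
            tables["model_predictions"] = stage_model(config, ref_current)
        except Exception as exc:
            raise PipelineError("model", "all", exc) from exc
        provenance["stages"].append("model")
    else:
        provenance["model_stage"] = "skipped (no model section)"

    _stamp(tables, config)
    result = PipelineResult(
        tables=tables,
        provenance=provenance,
        config_hash=config.config_hash(),
        seed=config.seed,
    )
    if out_dir is not None:
        result.write(out_dir)
    return result
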