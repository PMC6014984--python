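"""End-to-end workflow: simulate → fit → predict → classify.

The pipeline mirrors how a sensor panel is characterized and used: each
cell line is transfected with the negative control and one single-input
sensor per miRNA in the design; binned curves are fitted to (M, K_m); the
fits predict the multi-input sensor under every combination rule; and a
simulated co-culture transfected with the full design is scored as a
classifier.  Every stage is deterministic given the configuration seed,
and every output table records the package version, config hash and seed
in its header.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify as _classify
from . import combine as _combine
from . import fit as _fit
from . import io as _io
from .model import Calibration, RateConstants, free_mrna
from .simulate import (DEFAULT_CALIBRATION, CellLineProfile, NoiseModel,
                       SensorDesign, simulate_coculture,
                       simulate_sensor_events)

STAGES = ("simulate", "fit", "predict", "classify")


class DependencyError(RuntimeError):
    """An upstream artifact required by a requested stage is missing."""


@dataclass
class RunConfig:
    """Everything a pipeline run needs; loadable from YAML via
    :func:`load_run_config`."""

    design: SensorDesign
    profiles: list[tuple[CellLineProfile, int]]
    rates: RateConstants = RateConstants()
    calibration: dict[str, Calibration] | None = None
    noise: NoiseModel = NoiseModel()
    truth_rule: str = "ant_syn"
    cells_per_sensor: int = 20_000
    coculture_cells: int = 20_000
    bins_per_decade: int = _fit.DEFAULT_BINS_PER_DECADE
    min_count: int = _fit.DEFAULT_MIN_COUNT
    ebfp2_threshold: float = 300.0
    mkate2_threshold: float = _classify.DEFAULT_MKATE2_THRESHOLD
    seed: int = 0
    outdir: Path = Path("mirsensor_out")
    meta: dict = field(default_factory=dict)


def load_run_config(path) -> RunConfig:
    """Build a RunConfig from a YAML file referencing design/profile/rate
    files by path (resolved relative to the config file)."""
    raw = _io._load_structured(path) or {}
    base = Path(path).parent

    def resolve(p):
        p = Path(p)
        return p if p.is_absolute() else base / p

    rates, calib = (RateConstants(), None)
    if "rates" in raw:
        rates, calib = _io.read_rates_config(resolve(raw["rates"]))
    design = _io.read_design(resolve(raw["design"]))
    profiles = _io.read_profiles(resolve(raw["profiles"]))
    n_cells = raw.get("cells_per_line", {})
    cfg = RunConfig(
        design=design,
        profiles=[(p, int(n_cells.get(p.name, raw.get("coculture_cells",
                                                      20_000))))
                  for p in profiles],
        rates=rates, calibration=calib or None,
        noise=NoiseModel(**(raw.get("noise") or {})),
        meta={"config_hash": _io.config_hash(raw)},
    )
    for key in ("truth_rule", "cells_per_sensor", "coculture_cells",
                "bins_per_decade", "min_count", "ebfp2_threshold",
                "mkate2_threshold", "seed"):
        if key in raw:
            setattr(cfg, key, type(getattr(cfg, key))(raw[key]))
    cfg.outdir = Path(raw.get("outdir", cfg.outdir))
    return cfg


def _single_input_designs(design: SensorDesign) -> list[SensorDesign]:
    seen, singles = set(), []
    for inp in design.inputs:
        if inp.mirna_id not in seen:
            seen.add(inp.mirna_id)
            singles.append(SensorDesign((inp,), label=inp.mirna_id))
    return singles


def _events_path(outdir: Path, line: str, sensor: str) -> Path:
    return outdir / f"events_{line}_{sensor}.csv"


def _meta(config: RunConfig) -> dict:
    return {"seed": config.seed, **config.meta}


def stage_simulate(config: RunConfig) -> list[Path]:
    """Simulate control, single-input and co-culture event tables."""
    out = []
    seeds = iter(np.random.SeedSequence(config.seed).spawn(
        len(config.profiles) * (len(_single_input_designs(config.design)) + 1)
        + 1))
    for profile, _n in config.profiles:
        for design in [SensorDesign((), label="neg"),
                       *_single_input_designs(config.design)]:
            events = simulate_sensor_events(
                design, profile, config.rates, config.noise,
                config.cells_per_sensor, np.random.default_rng(next(seeds)),
                truth_rule=config.truth_rule, calibration=config.calibration)
            out.append(_io.write_events(
                events, _events_path(config.outdir, profile.name, design.label),
                **_meta(config)))
    coculture = simulate_coculture(
        [(p, config.coculture_cells) for p, _ in config.profiles],
        config.design, config.rates, config.noise,
        np.random.default_rng(next(seeds)), truth_rule=config.truth_rule,
        calibration=config.calibration)
    out.append(_io.write_events(coculture, config.outdir / "events_coculture.csv",
                                **_meta(config)))
    return out


def stage_fit(config: RunConfig) -> Path:
    """Bin every single-input table against its line's control and fit."""
    activities = []
    for profile, _n in config.profiles:
        neg_path = _events_path(config.outdir, profile.name, "neg")
        if not neg_path.exists():
            raise DependencyError(f"missing upstream artifact {neg_path}; "
                                  "run the simulate stage first")
        neg_events = _io.read_events(neg_path)
        edges = _fit.default_bin_edges(neg_events, config.bins_per_decade)
        neg = _fit.bin_events(neg_events, edges, config.min_count)
        calib = {**DEFAULT_CALIBRATION, **(config.calibration or {})}
        bg = calib["mkate2"].background
        mbg = calib["ebfp2"].background
        for single in _single_input_designs(config.design):
            path = _events_path(config.outdir, profile.name, single.label)
            if not path.exists():
                raise DependencyError(f"missing upstream artifact {path}; "
                                      "run the simulate stage first")
            curve = _fit.bin_events(_io.read_events(path), edges,
                                    config.min_count)
            activities.append(_fit.fit_activity(
                curve, neg, config.rates, mirna_id=single.label,
                cell_line=profile.name, background=bg + config.noise.background,
                marker_background=mbg + config.noise.background))
    return _io.write_activity_table(activities,
                                    config.outdir / "activities.csv",
                                    **_meta(config))


def predictions_from_activities(design: SensorDesign,
                                activities: list, rates: RateConstants,
                                grid) -> pd.DataFrame:
    """Per-bin multi-input predictions under all four combination rules."""
    lookup = {a.mirna_id: a for a in activities}
    grid = np.asarray(grid, dtype=float)
    neg = rates.k_trs * grid / rates.delta_m
    inputs = []
    for inp in design.inputs:
        if inp.mirna_id not in lookup:
            raise KeyError(f"no fitted activity for miRNA {inp.mirna_id!r}")
        inputs.append(_combine.SensorInput(
            inp.mirna_id, inp.utr_position,
            np.maximum(free_mrna(grid, lookup[inp.mirna_id], rates), 1e-300)))
    curves = _combine.AlignedCurves(grid=grid, neg=neg, inputs=tuple(inputs))
    table = {"bin": grid, "m_neg": neg}
    for rule, col in (("antagonistic", "m_ant"), ("additive", "m_add"),
                      ("synergistic", "m_syn"), ("ant_syn", "m_ant_syn")):
        table[col] = _combine.combine(curves, rule).output
    return pd.DataFrame(table)


def predict_binned_output(design: SensorDesign, activities: list,
                          rates: RateConstants, neg, rule: str,
                          background: float = 0.0,
                          marker_background: float = 0.0):
    """Predict a multi-input sensor's binned fluorescence from fits.

    ``neg`` is the negative control :class:`~mirsensor.fit.BinnedCurve`
    from the same experiment; its per-bin output fixes both the
    fluorescence scale and the plasmid-count proxy, exactly as in
    :func:`~mirsensor.fit.fit_activity`.  Returns ``(bin_index, predicted
    fluorescence)`` for the control's retained bins.
    """
    lookup = {a.mirna_id: a for a in activities}
    x_neg = np.asarray(neg.ebfp2, float) - marker_background
    y_neg = np.asarray(neg.mkate2, float) - background
    scale = float(np.exp(np.mean(np.log(y_neg) - np.log(x_neg))))
    n_bin = y_neg / scale
    inputs = []
    for inp in design.inputs:
        if inp.mirna_id not in lookup:
            raise KeyError(f"no fitted activity for miRNA {inp.mirna_id!r}")
        inputs.append(_combine.SensorInput(
            inp.mirna_id, inp.utr_position,
            np.maximum(free_mrna(n_bin, lookup[inp.mirna_id], rates), 1e-300)))
    curves = _combine.AlignedCurves(grid=n_bin,
                                    neg=rates.k_trs * n_bin / rates.delta_m,
                                    inputs=tuple(inputs))
    m_pred = _combine.combine(curves, rule).output
    pref = scale * rates.delta_m / rates.k_trs
    return np.asarray(neg.bin_index), pref * m_pred + background


def stage_predict(config: RunConfig) -> Path:
    """Predict the multi-input sensor from fitted single-input activities."""
    act_path = config.outdir / "activities.csv"
    if not act_path.exists():
        raise DependencyError(f"missing upstream artifact {act_path}; "
                              "run the fit stage first")
    activities = _io.read_activity_table(act_path)
    line = config.profiles[0][0].name
    acts = [a for a in activities if a.cell_line == line]
    lo = min(a.K_m for a in acts) / 100.0
    hi = max(max(a.M for a in acts), max(a.K_m for a in acts)) * 100.0
    grid = np.logspace(np.log10(max(lo, 1e-3)), np.log10(hi), 60)
    frame = predictions_from_activities(config.design, acts, config.rates, grid)
    return _io.write_table(frame, config.outdir / "predictions.csv",
                           cell_line=line, **_meta(config))


def stage_classify(config: RunConfig) -> list[Path]:
    """Score the simulated co-culture at the fixed thresholds, plus a ROC."""
    path = config.outdir / "events_coculture.csv"
    if not path.exists():
        raise DependencyError(f"missing upstream artifact {path}; "
                              "run the simulate stage first")
    events = _io.read_events(path)
    positive = next((p.name for p, _ in config.profiles
                     if p.lineage_marker_on), config.profiles[0][0].name)
    score = _classify.gate_and_score(
        events, config.ebfp2_threshold, config.mkate2_threshold,
        positive_label=positive)
    scores = pd.DataFrame([{
        "sensitivity": score.sensitivity, "specificity": score.specificity,
        "accuracy": score.accuracy,
        "rt_pos": score.counts.rt_pos, "rt_neg": score.counts.rt_neg,
        "rb_pos": score.counts.rb_pos, "rb_neg": score.counts.rb_neg,
        "l": score.counts.l,
        "ebfp2_threshold": config.ebfp2_threshold,
        "mkate2_threshold": config.mkate2_threshold,
    }])
    out1 = _io.write_table(scores, config.outdir / "scores.csv",
                           **_meta(config))
    mk = np.asarray(events["mkate2"], dtype=float)
    grid = np.logspace(np.log10(max(mk.min(), 1e-2)), np.log10(mk.max()), 50)
    roc = _classify.roc_curve(events, config.ebfp2_threshold, grid,
                              positive_label=positive)
    roc_frame = pd.DataFrame({"threshold": roc.thresholds,
                              "fpr": roc.fpr, "tpr": roc.tpr})
    out2 = _io.write_table(roc_frame, config.outdir / "roc.csv",
                           auc=f"{roc.auc:.6f}", **_meta(config))
    return [out1, out2]


_STAGE_FUNCS = {"simulate": stage_simulate, "fit": stage_fit,
                "predict": stage_predict, "classify": stage_classify}


def run_pipeline(config: RunConfig, stages=STAGES) -> list[Path]:
    """Run the requested stages in canonical order; returns artifact paths.

    Stage dependencies are checked before any computation: a stage whose
    upstream artifact is absent (and whose producer is not requested
    earlier in the same run) raises :class:`DependencyError`.
    """
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages {sorted(unknown)}")
    stages = [s for s in STAGES if s in stages]
    if not stages:
        raise ValueError("no valid stages requested")
    requested = set(stages)
    # pre-flight dependency check, before any compute
    if "fit" in requested and "simulate" not in requested:
        p = _events_path(config.outdir, config.profiles[0][0].name, "neg")
        if not p.exists():
            raise DependencyError(f"fit requires {p}; run simulate first")
    if "predict" in requested and "fit" not in requested:
        if not (config.outdir / "activities.csv").exists():
            raise DependencyError("predict requires activities.csv; "
                                  "run fit first")
    if "classify" in requested and "simulate" not in requested:
        if not (config.outdir / "events_coculture.csv").exists():
            raise DependencyError("classify requires events_coculture.csv; "
                                  "run simulate first")
    artifacts: list[Path] = []
    for stage in stages:
        result = _STAGE_FUNCS[stage](config)
        artifacts.extend(result if isinstance(result, list) else [result])
    return artifacts
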