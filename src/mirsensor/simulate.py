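"""Synthetic flow-cytometry event generator for miRNA sensor experiments.

Emulates the statistical structure the downstream analysis assumes:

* per-cell plasmid copy number is log-normal (transfection spread),
* each cell's reporter levels follow the steady-state repression model,
  with multi-input designs combined by a chosen ground-truth rule
  (Ant/Syn by default),
* measured fluorescence adds multiplicative log-normal instrument noise
  and additive autofluorescence background per channel,
* co-cultures concatenate per-cell-line simulations, with a binary
  lineage marker (EYFP) and a ground-truth lineage label.

Measured fluorescence spread is log-normal with a geometric SD of about
2.8 in the unrepressed channel.  That total is split between plasmid-copy
spread (default geometric SD 2.7) and per-channel measurement noise
(default geometric SD 1.3), which compose to ≈ 2.8; the split is
configurable and only matters for recovery-study realism.

Not emulated: cytometer artifacts such as doublets, spectral spillover
and acquisition-time drift, and scatter-gate debris — real data need a
scatter gate and possibly compensation before these tools apply.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .combine import (THREE_PRIME, UTR_POSITIONS, AlignedCurves,
                      SensorInput, combine)
from .model import Calibration, MiRNAActivity, RateConstants, free_mrna

#: total fluorescence spread observed in cytometry data (geometric SD)
TOTAL_GEOMETRIC_SD = 2.8
#: default split: copy-number spread × measurement noise ≈ total
DEFAULT_COPY_GSD = 2.7
DEFAULT_NOISE_GSD = 1.3
DEFAULT_MEDIAN_COPIES = 100.0

#: default per-channel affine calibration (gain a.u./protein, background a.u.)
DEFAULT_CALIBRATION = {
    "ebfp2": Calibration(gain=1e-3, background=5.0),
    "mkate2": Calibration(gain=1e-3, background=5.0),
}

#: EYFP lineage marker: two well-separated log-normal modes (median a.u.)
EYFP_ON_MEDIAN = 1e4
EYFP_OFF_MEDIAN = 10.0
EYFP_GSD = 2.0

TRUTH_RULES = ("ant_syn", "antagonistic", "synergistic", "additive")


@dataclass(frozen=True)
class NoiseModel:
    """Measurement noise: multiplicative log-normal spread plus background."""

    geometric_sd: float = DEFAULT_NOISE_GSD
    background: float = 0.0

    def __post_init__(self) -> None:
        if self.geometric_sd < 1.0:
            raise ValueError("geometric_sd must be >= 1")
        if self.background < 0.0:
            raise ValueError("background must be >= 0")


@dataclass(frozen=True)
class DesignInput:
    """One miRNA target-site set of a sensor design."""

    mirna_id: str
    utr_position: str = THREE_PRIME

    def __post_init__(self) -> None:
        if self.utr_position not in UTR_POSITIONS:
            raise ValueError(f"unknown utr_position {self.utr_position!r}")


@dataclass(frozen=True)
class SensorDesign:
    """A (multi-input) sensor: which target-site sets sit in which UTR."""

    inputs: tuple[DesignInput, ...] = ()
    label: str = "sensor"

    def __post_init__(self) -> None:
        object.__setattr__(self, "inputs", tuple(self.inputs))


@dataclass(frozen=True)
class CellLineProfile:
    """miRNA activity profile of one cell line, plus its lineage marker state."""

    name: str
    activities: dict[str, MiRNAActivity] = field(default_factory=dict)
    lineage_marker_on: bool = False


def sample_plasmid_counts(n_cells: int, median_n: float, geometric_sd: float,
                          seed) -> np.ndarray:
    """Log-normal per-cell plasmid copy numbers.

    ``ln(count) ~ Normal(ln median_n, (ln geometric_sd)^2)``; a geometric
    SD of 1 collapses to the median.  ``seed`` may be an int or a Generator.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if median_n <= 0 or geometric_sd < 1.0:
        raise ValueError("median_n must be > 0 and geometric_sd >= 1")
    rng = np.random.default_rng(seed)
    return np.exp(rng.normal(np.log(median_n), np.log(geometric_sd), n_cells))


def _combined_free_mrna(n: np.ndarray, design: SensorDesign,
                        profile: CellLineProfile, rates: RateConstants,
                        truth_rule: str) -> np.ndarray:
    """Per-cell free mKate2 mRNA for a design under one combination rule."""
    m_neg = rates.k_trs * n / rates.delta_m
    if not design.inputs:
        return m_neg
    inputs = []
    for inp in design.inputs:
        if inp.mirna_id not in profile.activities:
            raise KeyError(
                f"profile {profile.name!r} has no activity for miRNA "
                f"{inp.mirna_id!r}")
        m_i = free_mrna(n, profile.activities[inp.mirna_id], rates)
        inputs.append(SensorInput(inp.mirna_id, inp.utr_position,
                                  np.maximum(m_i, 1e-300)))
    curves = AlignedCurves(grid=n, neg=m_neg, inputs=tuple(inputs))
    return combine(curves, truth_rule).output


def simulate_sensor_events(design: SensorDesign, profile: CellLineProfile,
                           rates: RateConstants, noise: NoiseModel,
                           n_cells: int, seed,
                           truth_rule: str = "ant_syn",
                           median_n: float = DEFAULT_MEDIAN_COPIES,
                           copy_gsd: float = DEFAULT_COPY_GSD,
                           calibration: dict[str, Calibration] | None = None,
                           ) -> pd.DataFrame:
    """Simulate one transfection of a sensor design into one cell line.

    Per cell: draw a plasmid count, evaluate the steady-state model for
    each input, combine per ``truth_rule``, then map proteins to measured
    fluorescence with per-channel gain, log-normal noise and additive
    background.  EBFP2 reflects only the plasmid count (never miRNA
    activity); EYFP is high iff the profile's lineage marker is on.
    """
    if truth_rule not in TRUTH_RULES:
        raise ValueError(f"truth_rule must be one of {TRUTH_RULES}")
    calib = {**DEFAULT_CALIBRATION, **(calibration or {})}
    rng = np.random.default_rng(seed)
    n = sample_plasmid_counts(n_cells, median_n, copy_gsd, rng)

    m_out = _combined_free_mrna(n, design, profile, rates, truth_rule)
    p_mkate2 = rates.k_tln_mkate2 * m_out / rates.delta_p
    p_ebfp2 = rates.k_tln_ebfp2 * (rates.k_trs * n / rates.delta_m) / rates.delta_p

    sd = np.log(noise.geometric_sd)

    def measure(protein, channel):
        c = calib[channel]
        signal = c.gain * protein * np.exp(rng.normal(0.0, sd, n_cells))
        return signal + c.background + noise.background

    ebfp2 = measure(p_ebfp2, "ebfp2")
    mkate2 = measure(p_mkate2, "mkate2")
    eyfp_median = EYFP_ON_MEDIAN if profile.lineage_marker_on else EYFP_OFF_MEDIAN
    eyfp = np.exp(rng.normal(np.log(eyfp_median), np.log(EYFP_GSD), n_cells))
    return pd.DataFrame({"ebfp2": ebfp2, "mkate2": mkate2, "eyfp": eyfp})


def simulate_coculture(profiles: list[tuple[CellLineProfile, int]],
                       design: SensorDesign, rates: RateConstants,
                       noise: NoiseModel, seed,
                       truth_rule: str = "ant_syn",
                       median_n: float = DEFAULT_MEDIAN_COPIES,
                       copy_gsd: float = DEFAULT_COPY_GSD,
                       calibration: dict[str, Calibration] | None = None,
                       ) -> pd.DataFrame:
    """Simulate a transfected co-culture of several cell lines.

    Concatenates per-profile simulations; ``lineage_label`` carries the
    true cell line of every event.  All randomness descends from ``seed``.
    """
    if not profiles:
        raise ValueError("need at least one profile")
    if isinstance(seed, np.random.Generator):
        children = seed.spawn(len(profiles))
    else:
        children = [np.random.default_rng(s)
                    for s in np.random.SeedSequence(seed).spawn(len(profiles))]
    frames = []
    for (profile, n_cells), child in zip(profiles, children):
        events = simulate_sensor_events(
            design, profile, rates, noise, n_cells, child,
            truth_rule=truth_rule, median_n=median_n, copy_gsd=copy_gsd,
            calibration=calibration)
        events["lineage_label"] = profile.name
        frames.append(events)
    return pd.concat(frames, ignore_index=True)


def example_profiles() -> list[CellLineProfile]:
    """Three cell-line profiles with low/medium/high activity tiers.

    Activity ratios M/K_m are 0.2 : 2 : 20 (1:10:100), mirroring the
    low/high/very-high tiers used when characterizing sensor panels; all
    three lines share the same effective miRNA amount so that only K_m
    (repression strength per molecule) differs.
    """
    def acts(name, km):
        return {
            mirna: MiRNAActivity(mirna, name, M=600.0, K_m=km[i])
            for i, mirna in enumerate(("miR-A", "miR-B", "miR-C"))
        }
    return [
        CellLineProfile("line_low", acts("line_low", (3000.0, 3000.0, 3000.0)),
                        lineage_marker_on=True),
        CellLineProfile("line_med", acts("line_med", (300.0, 300.0, 300.0))),
        CellLineProfile("line_high", acts("line_high", (30.0, 30.0, 30.0))),
    ]
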