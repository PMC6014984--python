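"""Ready-made classifier design scenarios on synthetic co-cultures.

Two canonical experiments exercise the Ant/Syn design rules end to end:

* **Target-set position** — a 3-input classifier that distinguishes a
  marker-positive target line (low activity for every sensed miRNA) from
  an off-target line (high activity).  Variant one puts all three
  target-site sets in the 3′ UTR (antagonism caps their combined
  activity); variant two moves the strongest set to the 5′ UTR, buying
  synergy across UTRs and deeper off-target knockdown, hence better
  classification.

* **Target-set duplication** — a 2-input classifier sensing one miRNA
  that is high only in the off-target line and one of medium activity in
  both lines.  Duplicating both sets across the two UTRs squares each
  fold repression: off-target output drops further (higher specificity)
  but the medium-activity miRNA now also represses the target line below
  threshold (lower sensitivity).  Single sets in separate UTRs trade the
  other way.

Activity tiers are expressed as M/K_m ratios (low 0.1–0.2, medium ≈ 1.4,
high ≈ 20 at fixed M), giving maximal fold repressions of roughly 1.5–2,
8 and 100 under the default rate constants.
"""

from __future__ import annotations

import numpy as np

from .classify import DEFAULT_MKATE2_THRESHOLD, gate_and_score, roc_curve
from .model import MiRNAActivity, RateConstants
from .simulate import (CellLineProfile, DesignInput, NoiseModel, SensorDesign,
                       simulate_coculture)

#: L-gate boundary (a.u.): excludes under-transfected events.  The default
#: calibration puts the unrepressed marker median near 3.3e3 a.u.
DEFAULT_EBFP2_THRESHOLD = 300.0

TARGET_LINE = "target_line"
OFF_LINE = "off_line"


def _profile(name, ratios: dict[str, float], marker_on: bool,
             M: float = 600.0) -> CellLineProfile:
    acts = {mid: MiRNAActivity(mid, name, M=M, K_m=M / r)
            for mid, r in ratios.items()}
    return CellLineProfile(name, acts, lineage_marker_on=marker_on)


def position_profiles() -> list[CellLineProfile]:
    """Target line with low activity for all three miRNAs; off-target line
    with high/medium-high activity (strongest: miR-21-like)."""
    low = {"miR-21": 0.1, "miR-23a": 0.1, "miR-106b": 0.1}
    high = {"miR-21": 20.0, "miR-23a": 10.0, "miR-106b": 6.0}
    return [_profile(TARGET_LINE, low, True),
            _profile(OFF_LINE, high, False)]


def position_designs() -> dict[str, SensorDesign]:
    """All-3′ versus strongest-set-moved-to-5′ variants of the 3-input
    classifier."""
    all3 = SensorDesign((DesignInput("miR-21", "three_prime"),
                         DesignInput("miR-23a", "three_prime"),
                         DesignInput("miR-106b", "three_prime")),
                        label="all_three_prime")
    split = SensorDesign((DesignInput("miR-21", "five_prime"),
                          DesignInput("miR-23a", "three_prime"),
                          DesignInput("miR-106b", "three_prime")),
                         label="split_utr")
    return {"all_three_prime": all3, "split_utr": split}


def duplication_profiles() -> list[CellLineProfile]:
    """miR-21-like: slight activity in the target line, high off-target;
    miR-25-like: medium activity in both lines."""
    target = {"miR-21": 0.2, "miR-25": 1.4}
    off = {"miR-21": 20.0, "miR-25": 1.4}
    return [_profile(TARGET_LINE, target, True),
            _profile(OFF_LINE, off, False)]


def duplication_designs() -> dict[str, SensorDesign]:
    """Both sets duplicated across the UTRs versus single sets in
    separate UTRs."""
    dup = SensorDesign((DesignInput("miR-21", "five_prime"),
                        DesignInput("miR-25", "five_prime"),
                        DesignInput("miR-21", "three_prime"),
                        DesignInput("miR-25", "three_prime")),
                       label="duplicated")
    single = SensorDesign((DesignInput("miR-21", "five_prime"),
                           DesignInput("miR-25", "three_prime")),
                          label="single_sets")
    return {"duplicated": dup, "single_sets": single}


def run_coculture_design(design: SensorDesign,
                         profiles: list[CellLineProfile],
                         seed, n_cells: int = 20_000,
                         rates: RateConstants = RateConstants(),
                         noise: NoiseModel = NoiseModel(),
                         ebfp2_threshold: float = DEFAULT_EBFP2_THRESHOLD,
                         mkate2_threshold: float = DEFAULT_MKATE2_THRESHOLD,
                         roc_points: int = 60):
    """Simulate a 50:50 co-culture under Ant/Syn truth and score it.

    Returns ``(score, roc)`` at the given thresholds, with the true
    lineage taken from the simulation label of the marker-positive line.
    """
    events = simulate_coculture([(p, n_cells) for p in profiles], design,
                                rates, noise, seed)
    positive = next(p.name for p in profiles if p.lineage_marker_on)
    score = gate_and_score(events, ebfp2_threshold, mkate2_threshold,
                           positive_label=positive)
    mk = np.asarray(events["mkate2"], dtype=float)
    grid = np.logspace(np.log10(max(mk.min(), 1e-2)),
                       np.log10(mk.max()), roc_points)
    roc = roc_curve(events, ebfp2_threshold, grid, positive_label=positive)
    return score, roc
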