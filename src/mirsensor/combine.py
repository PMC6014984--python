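"""Combination rules predicting multi-input sensor output from single-input curves.

Given the per-bin output of each single-input sensor ``m_i(n)`` and of the
negative control ``m_neg(n)``, three interaction types (after the
Chou–Talalay method for mutually exclusive inhibitors) predict the
multi-input output:

* antagonistic — only the strongest input matters: per-bin minimum of the
  ``m_i``; observed for target-site sets sharing one UTR.
* additive — effects 'sum' in the Chou–Talalay sense:
  ``fu = 1 / (1 + Σ fa_i/fu_i)`` with fraction affected ``fa_i = 1 − m_i/m_neg``
  and fraction unaffected ``fu_i = 1 − fa_i``.
* synergistic — independent multiplicative contributions:
  ``m = m_neg · Π (m_i/m_neg)``; observed across the 5′ and 3′ UTRs.

The composite Ant/Syn model applies the antagonistic rule within each UTR
and then multiplies the two UTRs' fold repressions.  Per-bin fraction
affected is clamped to ``[0, 1−ε]`` so that noisy bins where a sensor
exceeds the negative control contribute zero repression and near-total
knockdown keeps the additive formula finite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

FIVE_PRIME = "five_prime"
THREE_PRIME = "three_prime"
UTR_POSITIONS = (FIVE_PRIME, THREE_PRIME)

#: clamp width for fraction affected: fa in [0, 1 - FA_EPS]
FA_EPS = 1e-6


@dataclass(frozen=True)
class SensorInput:
    """One single-input sensor curve aligned to the shared bin grid."""

    label: str
    utr_position: str
    output: np.ndarray

    def __post_init__(self) -> None:
        if self.utr_position not in UTR_POSITIONS:
            raise ValueError(
                f"utr_position must be one of {UTR_POSITIONS}, "
                f"got {self.utr_position!r}")
        out = np.asarray(self.output, dtype=float)
        object.__setattr__(self, "output", out)
        if np.any(out <= 0) or not np.all(np.isfinite(out)):
            raise ValueError(f"input {self.label!r}: outputs must be finite and > 0")


@dataclass(frozen=True)
class AlignedCurves:
    """Negative control and single-input curves on one shared bin grid."""

    grid: np.ndarray
    neg: np.ndarray
    inputs: tuple[SensorInput, ...]

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        neg = np.asarray(self.neg, dtype=float)
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "neg", neg)
        object.__setattr__(self, "inputs", tuple(self.inputs))
        if neg.size != grid.size:
            raise ValueError("neg and grid lengths differ")
        if np.any(neg <= 0) or not np.all(np.isfinite(neg)):
            raise ValueError("negative-control outputs must be finite and > 0")
        for s in self.inputs:
            if s.output.size != grid.size:
                raise ValueError(f"input {s.label!r} not aligned to grid")


@dataclass(frozen=True)
class CombinationResult:
    """Predicted multi-input output per bin under one combination rule."""

    grid: np.ndarray
    output: np.ndarray
    rule: str


def fraction_affected(m, m_neg) -> np.ndarray:
    """Knockdown fraction fa = 1 − m/m_neg, clamped into [0, 1−ε]."""
    m = np.asarray(m, dtype=float)
    m_neg = np.asarray(m_neg, dtype=float)
    if m.shape != m_neg.shape:
        raise ValueError("m and m_neg lengths differ")
    if np.any(m <= 0) or np.any(m_neg <= 0):
        raise ValueError("outputs must be > 0")
    return np.clip(1.0 - m / m_neg, 0.0, 1.0 - FA_EPS)


def _fu(s: SensorInput, curves: AlignedCurves) -> np.ndarray:
    """Clamped per-bin fraction unaffected of one input."""
    return 1.0 - fraction_affected(s.output, curves.neg)


def combine_antagonistic(curves: AlignedCurves) -> CombinationResult:
    """Per-bin minimum expression: only the strongest input represses."""
    if not curves.inputs:
        return CombinationResult(curves.grid, curves.neg.copy(), "antagonistic")
    fu = np.min([_fu(s, curves) for s in curves.inputs], axis=0)
    return CombinationResult(curves.grid, fu * curves.neg, "antagonistic")


def combine_additive(curves: AlignedCurves) -> CombinationResult:
    """Mutually exclusive Chou–Talalay sum: fu = 1/(1 + Σ fa_i/fu_i)."""
    if not curves.inputs:
        return CombinationResult(curves.grid, curves.neg.copy(), "additive")
    ratio = np.zeros_like(curves.neg)
    for s in curves.inputs:
        fu_i = _fu(s, curves)
        ratio += (1.0 - fu_i) / fu_i
    fu = 1.0 / (1.0 + ratio)
    return CombinationResult(curves.grid, fu * curves.neg, "additive")


def combine_synergistic(curves: AlignedCurves) -> CombinationResult:
    """Independent contributions: fold repressions multiply across inputs."""
    fu = np.ones_like(curves.neg)
    for s in curves.inputs:
        fu *= _fu(s, curves)
    return CombinationResult(curves.grid, fu * curves.neg, "synergistic")


def predict_ant_syn(curves: AlignedCurves) -> CombinationResult:
    """Ant/Syn model: antagonism within each UTR, synergy across UTRs.

    Per bin the fraction unaffected of each UTR is the minimum fu over its
    inputs (1 if the UTR is empty); the two UTR contributions multiply.
    """
    fu_total = np.ones_like(curves.neg)
    for utr in UTR_POSITIONS:
        members = [s for s in curves.inputs if s.utr_position == utr]
        if members:
            fu_total = fu_total * np.min([_fu(s, curves) for s in members], axis=0)
    return CombinationResult(curves.grid, fu_total * curves.neg, "ant_syn")


RULES = {
    "antagonistic": combine_antagonistic,
    "additive": combine_additive,
    "synergistic": combine_synergistic,
    "ant_syn": predict_ant_syn,
}


def combine(curves: AlignedCurves, rule: str) -> CombinationResult:
    """Apply a combination rule by name ('antagonistic', 'additive',
    'synergistic' or 'ant_syn')."""
    try:
        return RULES[rule](curves)
    except KeyError:
        raise ValueError(f"unknown combination rule {rule!r}") from None


def prediction_errors(pred, data) -> tuple[float, float]:
    """Prediction-vs-data error metrics over aligned bins.

    Returns ``(max_fold_error, mse)``: the maximum per-bin fold difference
    ``exp(max |ln(pred/data)|)`` and the mean squared error of log10
    outputs (data span decades, so errors are measured on the log scale).
    """
    p = np.asarray(getattr(pred, "output", pred), dtype=float)
    d = np.asarray(data, dtype=float)
    if p.size != d.size:
        raise ValueError("prediction and data lengths differ")
    if p.size == 0:
        raise ValueError("no overlapping bins")
    if np.any(p <= 0) or np.any(d <= 0):
        raise ValueError("outputs must be > 0")
    log_ratio = np.log(p / d)
    max_fold_error = float(np.exp(np.max(np.abs(log_ratio))))
    mse = float(np.mean((np.log10(p) - np.log10(d)) ** 2))
    return max_fold_error, mse


def align_on_shared_grid(grid_a, vals_a, grid_b, vals_b,
                         rtol: float = 1e-9):
    """Intersect two bin grids, dropping non-overlapping bins with a warning.

    Returns ``(grid, a_on_grid, b_on_grid)``.  Raises if no bins overlap.
    """
    grid_a = np.asarray(grid_a, dtype=float)
    grid_b = np.asarray(grid_b, dtype=float)
    ia, ib = [], []
    j = 0
    for i, g in enumerate(grid_a):
        while j < grid_b.size and grid_b[j] < g * (1 - rtol) - rtol:
            j += 1
        if j < grid_b.size and np.isclose(grid_b[j], g, rtol=rtol):
            ia.append(i)
            ib.append(j)
            j += 1
    if not ia:
        raise ValueError("no overlapping bins between the two curves")
    if len(ia) < grid_a.size or len(ib) < grid_b.size:
        warnings.warn("dropping bins not shared by both curves", stacklevel=2)
    ia = np.asarray(ia)
    ib = np.asarray(ib)
    return (grid_a[ia], np.asarray(vals_a, dtype=float)[ia],
            np.asarray(vals_b, dtype=float)[ib])
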