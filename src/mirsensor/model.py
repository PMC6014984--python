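"""Steady-state biochemical model of single-input miRNA sensor repression.

A sensor cell carries ``n`` plasmid copies of a two-color reporter: EBFP2
(transfection marker, unregulated) and mKate2 (output, carrying miRNA
target sites).  Both transcripts are produced at rate ``k_trs`` per plasmid
and decay nonspecifically at rate ``delta_m``.  The mKate2 transcript is
additionally bound, reversibly, by a miRNA-containing complex; the bound
species is catalytically degraded at rate ``k_cat``.  Two parameters fully
characterize a miRNA's activity against a given target-site set:

* ``M``   — effective total miRNA molecules per cell (free + bound),
* ``K_m`` — Michaelis constant ``(k_off + k_cat) / k_on``.

Under the quasi-steady-state binding relation ``complex = m * M / (K_m + m)``
the mRNA balance ``k_trs * n = delta_m * m + k_cat * complex`` becomes a
quadratic in the free mKate2 mRNA ``m``:

    delta_m * m**2 + (delta_m*K_m + k_cat*M - k_trs*n) * m - k_trs*n*K_m = 0

whose unique nonnegative root is the model output.  The model reproduces
the three regimes seen in sensor data: repressed at low ``n``, a switching
threshold, and derepression at high ``n`` where reporter mRNA saturates the
miRNA machinery.  ``M`` sets the threshold position, ``M/K_m`` the maximal
fold repression (``1 + (k_cat/delta_m) * M/K_m`` in the ``n -> 0`` limit).

A full mass-action ODE integration (:func:`ode_oracle`) is provided as an
independent numerical check of the closed form.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp


class InvalidParameterError(ValueError):
    """Raised when a model parameter violates its domain."""


class ConvergenceError(RuntimeError):
    """Raised when the ODE oracle fails to reach steady state."""


@dataclass(frozen=True)
class RateConstants:
    """Fixed kinetic parameters of the reporter system.

    Units: rates per hour; ``k_trs`` in mRNA·h⁻¹·plasmid⁻¹, translation
    rates in protein·h⁻¹·mRNA⁻¹.  Defaults correspond to an mRNA half-life
    of ~3.5 h, a protein half-life of ~23 h, and efficient catalytic
    turnover of the bound complex; all results that matter are ratios
    insensitive to the absolute scale.
    """

    k_trs: float = 2.0
    k_tln_ebfp2: float = 100.0
    k_tln_mkate2: float = 100.0
    delta_m: float = 0.2
    delta_p: float = 0.03
    k_cat: float = 1.0

    def __post_init__(self) -> None:
        for name in ("k_trs", "k_tln_ebfp2", "k_tln_mkate2",
                     "delta_m", "delta_p", "k_cat"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise InvalidParameterError(
                    f"rate constant {name!r} must be finite and > 0, got {v}")


@dataclass(frozen=True)
class Calibration:
    """Affine fluorescence calibration for one channel: F = gain·p + background."""

    gain: float = 1.0
    background: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.gain) or self.gain <= 0:
            raise InvalidParameterError(f"gain must be > 0, got {self.gain}")
        if not np.isfinite(self.background) or self.background < 0:
            raise InvalidParameterError(
                f"background must be >= 0, got {self.background}")

    def apply(self, protein):
        return self.gain * np.asarray(protein, dtype=float) + self.background


@dataclass(frozen=True)
class MiRNAActivity:
    """Fitted activity of one miRNA target-site set in one cell line."""

    mirna_id: str
    cell_line: str
    M: float
    K_m: float
    fit_diagnostics: dict | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not np.isfinite(self.M) or self.M < 0:
            raise InvalidParameterError(f"M must be finite and >= 0, got {self.M}")
        if not np.isfinite(self.K_m) or self.K_m <= 0:
            raise InvalidParameterError(
                f"K_m must be finite and > 0, got {self.K_m}")

    @property
    def activity_ratio(self) -> float:
        """M/K_m — the quantity setting maximal fold repression."""
        return self.M / self.K_m


@dataclass(frozen=True)
class SteadyState:
    """All species of the single-input model at steady state."""

    n: float
    m_free: float
    mir_free: float
    complex: float
    m_ebfp2: float
    p_ebfp2: float
    p_mkate2: float


@dataclass(frozen=True)
class PredictionCurve:
    """A model-evaluated output curve over a transfection grid."""

    grid: np.ndarray
    output: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        output = np.asarray(self.output, dtype=float)
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "output", output)
        if grid.size == 0:
            raise ValueError("empty grid")
        if grid.size != output.size:
            raise ValueError("grid and output lengths differ")
        if np.any(np.diff(grid) <= 0):
            raise ValueError("grid must be strictly ascending")
        if np.any(output < 0):
            raise ValueError("output must be nonnegative")


def free_mrna(n, activity: MiRNAActivity, rates: RateConstants):
    """Free mKate2 mRNA at steady state; vectorized over plasmid count ``n``.

    Solves the quadratic balance with a cancellation-safe root formula.
    """
    n = np.asarray(n, dtype=float)
    if np.any(n < 0) or not np.all(np.isfinite(n)):
        raise InvalidParameterError("plasmid count n must be finite and >= 0")
    a = rates.delta_m
    b = rates.delta_m * activity.K_m + rates.k_cat * activity.M - rates.k_trs * n
    c = -rates.k_trs * n * activity.K_m
    disc = np.sqrt(b * b - 4.0 * a * c)
    # positive root; avoid subtracting nearly equal numbers when b > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        m = np.where(b <= 0, (-b + disc) / (2.0 * a),
                     np.where(c == 0, 0.0, -2.0 * c / (b + disc)))
    return m if m.ndim else float(m)


def steady_state(n: float, activity: MiRNAActivity,
                 rates: RateConstants) -> SteadyState:
    """Full steady state for one cell with ``n`` plasmids.

    The EBFP2 side is unrepressed; only free mKate2 mRNA is translated.
    """
    m = free_mrna(n, activity, rates)
    bound = m * activity.M / (activity.K_m + m)
    m_ebfp2 = rates.k_trs * n / rates.delta_m
    return SteadyState(
        n=float(n),
        m_free=float(m),
        mir_free=float(activity.M - bound),
        complex=float(bound),
        m_ebfp2=float(m_ebfp2),
        p_ebfp2=float(rates.k_tln_ebfp2 * m_ebfp2 / rates.delta_p),
        p_mkate2=float(rates.k_tln_mkate2 * m / rates.delta_p),
    )


NO_ACTIVITY = MiRNAActivity("none", "any", M=0.0, K_m=1.0)


def sensor_curve(activity: MiRNAActivity, rates: RateConstants, grid,
                 calib: Calibration = Calibration(),
                 label: str | None = None) -> PredictionCurve:
    """Predicted mKate2 fluorescence over a plasmid-count grid.

    With ``M = 0`` this is the zero-activity negative-control curve.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty grid")
    m = free_mrna(grid, activity, rates)
    protein = rates.k_tln_mkate2 * m / rates.delta_p
    return PredictionCurve(grid=grid, output=calib.apply(protein),
                           label=label or activity.mirna_id)


def negative_control_curve(rates: RateConstants, grid,
                           calib: Calibration = Calibration()) -> PredictionCurve:
    """Output of the target-site-free construct (zero miRNA activity)."""
    return sensor_curve(NO_ACTIVITY, rates, grid, calib, label="negative_control")


def max_fold_repression(activity: MiRNAActivity, rates: RateConstants) -> float:
    """Maximal fold repression, the n→0 limit of (unrepressed)/(repressed) output.

    Equals ``1 + (k_cat/delta_m) * M/K_m``; dimensionless, ≥ 1.
    """
    return 1.0 + (rates.k_cat / rates.delta_m) * activity.activity_ratio


def threshold_location(curve: PredictionCurve) -> float:
    """Grid point at the middle of the switching transition.

    Operationalized as the grid value of steepest log-log slope,
    estimated by central differences on the (log n, log output) samples.
    The curvature extrema flanking the transition are equal in magnitude,
    so an |curvature|-argmax is degenerate; the slope maximum sits between
    them and is stable under depth-of-repression changes.
    """
    logn = np.log(curve.grid)
    logf = np.log(curve.output)
    d1 = np.gradient(logf, logn)
    return float(curve.grid[np.argmax(d1)])


def ode_oracle(n: float, activity: MiRNAActivity, rates: RateConstants,
               t_end: float | None = None, tol: float = 1e-10,
               k_off: float | None = None) -> SteadyState:
    """Integrate the full mass-action system to steady state.

    The closed form needs only ``K_m``; the oracle makes the binding step
    explicit with ``k_off`` (default ``k_cat``) and
    ``k_on = (k_off + k_cat)/K_m``, so the steady state must be invariant
    to the split.  Serves as an independent numerical check of
    :func:`steady_state`.
    """
    if n < 0:
        raise InvalidParameterError("n must be >= 0")
    if k_off is None:
        k_off = rates.k_cat
    k_on = (k_off + rates.k_cat) / activity.K_m

    def rhs(_t, y):
        m, mir, cplx = y
        bind = k_on * m * mir
        return [rates.k_trs * n - rates.delta_m * m - bind + k_off * cplx,
                -bind + (k_off + rates.k_cat) * cplx,
                bind - (k_off + rates.k_cat) * cplx]

    if t_end is None:
        slowest = min(rates.delta_m, rates.k_cat, k_off)
        t_end = 50.0 / slowest
    sol = solve_ivp(rhs, (0.0, t_end), [0.0, activity.M, 0.0],
                    method="LSODA", rtol=1e-10, atol=1e-12 * max(1.0, activity.M),
                    dense_output=False)
    if not sol.success:
        raise ConvergenceError(sol.message)
    m, mir, cplx = sol.y[:, -1]
    # relative distance from equilibrium: |dm/dt| compared with the decay flux
    scale = max(abs(m), rates.k_trs * n / rates.delta_m, 1e-300)
    rel = abs(rhs(sol.t[-1], sol.y[:, -1])[0]) / (rates.delta_m * scale)
    if rel > max(tol, 1e-6):
        raise ConvergenceError(
            f"steady state not reached at t_end={t_end}: relative drift {rel:.3g}")
    m_ebfp2 = rates.k_trs * n / rates.delta_m
    return SteadyState(
        n=float(n), m_free=float(m), mir_free=float(mir), complex=float(cplx),
        m_ebfp2=float(m_ebfp2),
        p_ebfp2=float(rates.k_tln_ebfp2 * m_ebfp2 / rates.delta_p),
        p_mkate2=float(rates.k_tln_mkate2 * m / rates.delta_p),
    )
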