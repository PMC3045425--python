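"""Kinetic quantification: Logan graphical analysis and the two-tissue compartment model.

The two-tissue compartment model (2TCM) describes tracer exchange between
arterial plasma (parent concentration ``Cp``) and two tissue compartments::

    dC1/dt = K1*Cp - (k2 + k3)*C1 + k4*C2
    dC2/dt = k3*C1 - k4*C2

with the measured tissue concentration ``CT = C1 + C2`` (fractional blood
volume fixed at 0).  The total distribution volume is
``VT = K1/k2 * (1 + k3/k4)``.

The solver uses the analytic bi-exponential impulse response of the model
convolved against a piecewise-linear input with an exact exponential
integrator, so it is exact for piecewise-linear ``Cp``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .io import FrameSchedule, InputFunction, ValidationError, interpolate_curve

__all__ = [
    "KineticParams",
    "LoganFit",
    "TwoTissueFit",
    "FitError",
    "two_tissue_solution",
    "one_tissue_solution",
    "logan_vt",
    "fit_two_tissue",
    "fit_delay",
    "vt_from_rates",
]


class FitError(RuntimeError):
    """A kinetic fit could not be performed."""


@dataclass(frozen=True)
class KineticParams:
    """2TCM rate constants. K1 in mL.cm-3.min-1, k2..k4 in 1/min, delay in min."""

    K1: float
    k2: float
    k3: float = 0.0
    k4: float = 0.0
    delay: float = 0.0
    vB: float = 0.0

    def __post_init__(self):
        for name in ("K1", "k2", "k3", "k4"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        if self.vB != 0.0:
            raise ValidationError("blood volume is fixed at 0 in this model")

    @property
    def vt(self) -> float:
        return vt_from_rates(self)


@dataclass(frozen=True)
class LoganFit:
    """Result of a Logan graphical fit: VT is the late-time slope."""

    vt: float
    intercept: float
    t_star: float
    n_points: int
    r_squared: float

    def __post_init__(self):
        if self.n_points < 3:
            raise ValidationError("a Logan fit needs at least 3 points")
        if not np.isfinite(self.vt):
            raise ValidationError("non-finite VT")


@dataclass
class TwoTissueFit:
    """Best 2TCM parameters plus convergence diagnostics."""

    params: KineticParams
    converged: bool
    cost: float
    fitted: np.ndarray = field(repr=False, default=None)

    @property
    def vt(self) -> float:
        return self.params.vt

    def rates_dict(self) -> dict[str, float]:
        p = self.params
        return {"K1": p.K1, "k2": p.k2, "k3": p.k3, "k4": p.k4}


# ---------------------------------------------------------------------------
# Forward model


def _exp_conv(theta: float, phi: float, t: np.ndarray, cp: np.ndarray) -> np.ndarray:
    """Convolve phi*exp(-theta*t) with a piecewise-linear cp(t), exactly.

    Recursion: y(t+h) = y(t) e^{-theta h} + phi * int_0^h e^{-theta(h-s)} cp(t+s) ds
    with cp linear on each step.
    """
    y = np.zeros_like(cp)
    h = np.diff(t)
    eth = np.exp(-theta * h)
    if theta > 1e-12:
        a = (1.0 - eth) / theta          # int e^{-theta(h-s)} ds
        b = (h - a) / theta              # int e^{-theta(h-s)} s ds
    else:
        a = h.copy()
        b = h**2 / 2.0
    m = np.diff(cp) / h
    for i in range(h.size):
        y[i + 1] = y[i] * eth[i] + phi * (cp[i] * a[i] + m[i] * b[i])
    return y


def _impulse_terms(params: KineticParams) -> list[tuple[float, float]]:
    """(theta, phi) pairs of the 2TCM impulse response K1*(phi1 e^-th1 t + ...)."""
    K1, k2, k3, k4 = params.K1, params.k2, params.k3, params.k4
    s = k2 + k3 + k4
    disc = s * s - 4.0 * k2 * k4
    disc = max(disc, 0.0)
    root = np.sqrt(disc)
    th1 = (s + root) / 2.0
    th2 = (s - root) / 2.0
    if root < 1e-10:
        # coincident eigenvalues: perturb infinitesimally for numerical stability
        th1 += 5e-9
        th2 = max(th2 - 5e-9, 0.0)
        root = th1 - th2
    phi1 = K1 * (th1 - k3 - k4) / root
    phi2 = K1 * (k3 + k4 - th2) / root
    return [(th1, phi1), (th2, phi2)]


def two_tissue_solution(
    params: KineticParams, time_grid: np.ndarray, cp_times, cp_values
) -> np.ndarray:
    """Tissue concentration C1+C2 on ``time_grid`` for a sampled input curve.

    The input is interpolated linearly onto the grid (the package contract:
    linear from (0,0) before the first sample, held after the last); a
    positive ``params.delay`` shifts the input later in time.
    """
    t = np.asarray(time_grid, dtype=float)
    if t.ndim != 1 or t.size < 2 or np.any(np.diff(t) <= 0):
        raise ValidationError("time_grid must be increasing with >= 2 points")
    if params.K1 == 0.0:
        return np.zeros_like(t)
    cp = interpolate_curve(cp_times, cp_values, t - params.delay)
    cp = np.where(t - params.delay < 0, 0.0, cp)
    out = np.zeros_like(t)
    for theta, phi in _impulse_terms(params):
        out += _exp_conv(theta, phi, t, cp)
    return out


def one_tissue_solution(K1, k2, time_grid, cp_times, cp_values, delay=0.0) -> np.ndarray:
    return two_tissue_solution(
        KineticParams(K1, k2, 0.0, 0.0, delay), time_grid, cp_times, cp_values
    )


def vt_from_rates(params: KineticParams) -> float:
    """VT = K1/k2 * (1 + k3/k4); reduces to K1/k2 when k3 = 0."""
    if params.k2 <= 0:
        raise ValidationError("VT undefined for k2 = 0")
    if params.k3 == 0:
        return params.K1 / params.k2
    if params.k4 <= 0:
        raise ValidationError("VT undefined for k3 > 0 with k4 = 0")
    return params.K1 / params.k2 * (1.0 + params.k3 / params.k4)


# ---------------------------------------------------------------------------
# Logan graphical analysis


def _cumtrapz0(t: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Cumulative trapezoid integral from t=0 (curve assumed 0 at t=0)."""
    if t[0] > 0:
        t = np.concatenate([[0.0], t])
        y = np.concatenate([[0.0], y])
        out = np.concatenate(
            [[0.0], np.cumsum(np.diff(t) * (y[1:] + y[:-1]) / 2.0)]
        )
        return out[1:]
    return np.concatenate([[0.0], np.cumsum(np.diff(t) * (y[1:] + y[:-1]) / 2.0)])


def logan_vt(
    tissue_tac: np.ndarray,
    input_function: InputFunction,
    schedule: FrameSchedule,
    t_star: float = 30.0,
) -> LoganFit:
    """Logan graphical analysis; the slope over frames past ``t_star`` is VT.

    Regresses y_i = int_0^{t_i} CT / CT(t_i) on x_i = int_0^{t_i} Cp / CT(t_i)
    at frame midpoints.  The input integral is accumulated on the input's own
    time grid and interpolated at the frame midpoints.
    """
    tac = np.asarray(tissue_tac, dtype=float)
    mid = schedule.midpoints
    if tac.size != mid.size:
        raise ValidationError("TAC length does not match schedule")
    if t_star >= schedule.scan_end:
        raise ValidationError("t_star is past the end of the scan")
    if input_function.parent_plasma is None:
        raise ValidationError("Logan analysis needs a metabolite-corrected input")

    cp_int_own = _cumtrapz0(input_function.times, input_function.parent_plasma)
    cp_int = np.interp(mid, input_function.times, cp_int_own)
    ct_int = _cumtrapz0(mid, tac)

    use = mid >= t_star
    nonzero = tac > 0
    if np.any(use & ~nonzero):
        warnings.warn("dropping frames with zero tissue activity from Logan fit")
    use &= nonzero
    if use.sum() < 3:
        raise FitError("fewer than 3 usable frames past t_star")
    x = cp_int[use] / tac[use]
    y = ct_int[use] / tac[use]
    res = stats.linregress(x, y)
    return LoganFit(
        vt=float(res.slope),
        intercept=float(res.intercept),
        t_star=float(t_star),
        n_points=int(use.sum()),
        r_squared=float(res.rvalue**2),
    )


# ---------------------------------------------------------------------------
# 2TCM nonlinear fit

_DEFAULT_INIT = (0.1, 0.1, 0.05, 0.03)
_DEFAULT_BOUNDS = ((1e-6, 1e-6, 0.0, 0.0), (2.0, 2.0, 1.0, 0.5))


def fit_two_tissue(
    tissue_tac: np.ndarray,
    input_function: InputFunction,
    schedule: FrameSchedule,
    init=None,
    bounds=None,
    n_restarts: int = 3,
    seed: int = 0,
    delay: float = 0.0,
    fine_dt: float = 0.02,
) -> TwoTissueFit:
    """Weighted nonlinear least-squares fit of the unconstrained 2TCM (vB = 0).

    Residuals are weighted by sqrt(frame duration); the fit is restarted from
    multiplicatively jittered initial values and the best converged solution
    is kept.  Non-convergence is flagged (not raised) so callers can exclude
    the region, as done when screening regional fits.
    """
    tac = np.asarray(tissue_tac, dtype=float)
    mid = schedule.midpoints
    if tac.size != mid.size:
        raise ValidationError("TAC length does not match schedule")
    if input_function.parent_plasma is None:
        raise ValidationError("2TCM fit needs a metabolite-corrected input")
    init = np.asarray(init if init is not None else _DEFAULT_INIT, dtype=float)
    lo, hi = bounds if bounds is not None else _DEFAULT_BOUNDS
    lo = np.asarray(lo, dtype=float)
    hi = np.asarray(hi, dtype=float)
    w = np.sqrt(schedule.durations)

    grid = _fine_grid(schedule, fine_dt)
    cp_t, cp_v = input_function.times, input_function.parent_plasma

    def residuals(p):
        model = two_tissue_solution(
            KineticParams(*p, delay=delay), grid, cp_t, cp_v
        )
        return w * (np.interp(mid, grid, model) - tac)

    rng = np.random.default_rng(seed)
    best = None
    for r in range(max(1, n_restarts)):
        p0 = init if r == 0 else np.clip(init * rng.lognormal(0.0, 0.4, 4), lo, hi)
        try:
            sol = optimize.least_squares(
                residuals, np.clip(p0, lo, hi), bounds=(lo, hi), xtol=1e-10, ftol=1e-10
            )
        except Exception:
            continue
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        return TwoTissueFit(KineticParams(*init), converged=False, cost=np.inf)
    params = KineticParams(*best.x, delay=delay)
    fitted = np.interp(
        mid, grid, two_tissue_solution(params, grid, cp_t, cp_v)
    )
    return TwoTissueFit(params, converged=True, cost=float(best.cost), fitted=fitted)


def _fine_grid(schedule: FrameSchedule, dt: float) -> np.ndarray:
    end = schedule.scan_end
    grid = np.arange(0.0, end + dt, dt)
    # midpoints must be representable: merge and sort
    return np.unique(np.concatenate([grid, schedule.midpoints]))


def fit_delay(
    input_function: InputFunction,
    whole_brain_tac: np.ndarray,
    schedule: FrameSchedule,
    search_half_width: float = 0.5,
    step: float = 1.0 / 60.0,
    early_window: float = 5.0,
) -> float:
    """Input-function delay via grid search (default +-30 s in 1 s steps).

    For each candidate shift a one-tissue model is fitted to the whole-brain
    TAC over the early frames (midpoint <= ``early_window`` min) and the shift
    minimizing the early-frame SSE is returned.
    """
    tac = np.asarray(whole_brain_tac, dtype=float)
    mid = schedule.midpoints
    early = mid <= early_window
    if early.sum() < 3:
        raise ValidationError("not enough early frames for delay fitting")
    cp_t = input_function.times
    cp_v = (
        input_function.parent_plasma
        if input_function.parent_plasma is not None
        else input_function.whole_blood
    )
    grid = _fine_grid(schedule, 1.0 / 120.0)
    grid = grid[grid <= early_window + 1.0]
    mid_e = mid[early]
    tac_e = tac[early]
    shifts = np.arange(-search_half_width, search_half_width + step / 2, step)

    def sse_for(shift):
        def resid(p):
            model = two_tissue_solution(
                KineticParams(p[0], p[1], 0.0, 0.0, delay=shift), grid, cp_t, cp_v
            )
            return np.interp(mid_e, grid, model) - tac_e

        p0 = np.array([0.1, 0.1])
        sol = optimize.least_squares(resid, p0, bounds=([1e-6, 1e-6], [5.0, 5.0]))
        return sol.cost

    costs = np.array([sse_for(s) for s in shifts])
    if np.ptp(costs) <= 1e-12 * max(costs.max(), 1e-300):
        warnings.warn("flat delay objective; returning 0")
        return 0.0
    return float(shifts[int(np.argmin(costs))])
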