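"""Reversible two-tissue-compartment [18F]FDG kinetics.

The tissue model is the standard pair of linear compartments

    dC1/dt = K1*Cp - (k2 + k3)*C1 + k4*C2
    dC2/dt = k3*C1 - k4*C2

driven by the metabolite-corrected arterial plasma curve Cp, with the
measured PET signal ``(1 - Vb)*(C1 + C2) + Vb*Cwb`` including a fractional
blood volume term.  The impulse response of C1+C2 is a biexponential with
exponents

    a_{1,2} = ((k2+k3+k4) -/+ sqrt((k2+k3+k4)^2 - 4*k2*k4)) / 2,

so the forward model is an analytic convolution evaluated on a fine time
grid and averaged over scan frames.

K1 is carried in mL/hg/min (1 hg of tissue == 100 mL at unit density; the
internal convolution uses K1/100 in 1/min).  The net-influx macro
parameter K1*k3/(k2+k3), combined with plasma glucose and a lumped
constant, yields CMRglc in uMol/hg/min.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .units import ML_PER_HG

__all__ = [
    "ArterialInput",
    "TimeActivityCurve",
    "TwoTissueParams",
    "KineticFit",
    "LumpedConstantTable",
    "DEFAULT_LC",
    "DEFAULT_BOUNDS",
    "DEFAULT_INIT",
    "model_tac",
    "fit_tac_nlls",
    "compute_cmrglc",
    "basis_function_fit",
    "adjust_lumped_constant",
    "glucose_adjusted_lc_table",
]

#: Lumped constant used for CMRglc when no glucose adjustment is applied.
DEFAULT_LC = 0.81

#: Fine-grid step for input interpolation and convolution, in minutes (1 s).
_DT = 1.0 / 60.0


@dataclass(frozen=True)
class ArterialInput:
    """Arterial input function sampled over the scan.

    times are minutes from injection (strictly increasing, >= 0);
    activities in kBq/mL; ``plasma_glucose`` is the clamped plasma glucose
    in mM.
    """

    times: np.ndarray
    plasma_activity: np.ndarray
    wholeblood_activity: np.ndarray
    plasma_glucose: float = 5.55

    def __post_init__(self) -> None:
        t = np.asarray(self.times, float)
        cp = np.asarray(self.plasma_activity, float)
        cwb = np.asarray(self.wholeblood_activity, float)
        if t.ndim != 1 or t.size < 2 or t[0] < 0 or np.any(np.diff(t) <= 0):
            raise ValueError("times must be 1-D, start >= 0 and strictly increase")
        if cp.shape != t.shape or cwb.shape != t.shape:
            raise ValueError("activity arrays must match times in shape")
        if np.any(cp < 0) or np.any(cwb < 0):
            raise ValueError("activities must be non-negative")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "plasma_activity", cp)
        object.__setattr__(self, "wholeblood_activity", cwb)

    def on_grid(self, t_end: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Piecewise-linear interpolation onto the 1-s working grid."""
        grid = np.arange(0.0, t_end + _DT, _DT)
        cp = np.interp(grid, self.times, self.plasma_activity, left=0.0)
        cwb = np.interp(grid, self.times, self.wholeblood_activity, left=0.0)
        return grid, cp, cwb


@dataclass(frozen=True)
class TimeActivityCurve:
    """Decay-corrected frame-mean tissue activity (kBq/mL)."""

    frame_starts: np.ndarray  # min
    frame_durations: np.ndarray  # min
    activity: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        s = np.asarray(self.frame_starts, float)
        d = np.asarray(self.frame_durations, float)
        a = np.asarray(self.activity, float)
        if s.shape != d.shape or s.shape != a.shape or s.ndim != 1:
            raise ValueError("frame arrays must be 1-D and equally shaped")
        if np.any(d <= 0):
            raise ValueError("frame durations must be > 0")
        ends = s + d
        if np.any(s[1:] < ends[:-1] - 1e-9):
            raise ValueError("frames must be ordered and non-overlapping")
        object.__setattr__(self, "frame_starts", s)
        object.__setattr__(self, "frame_durations", d)
        object.__setattr__(self, "activity", a)

    @property
    def frame_mids(self) -> np.ndarray:
        return self.frame_starts + self.frame_durations / 2.0

    @property
    def frame_ends(self) -> np.ndarray:
        return self.frame_starts + self.frame_durations


@dataclass(frozen=True)
class TwoTissueParams:
    """Rate constants of the reversible two-tissue model.

    K1 in mL/hg/min; k2, k3, k4 in 1/min; Vb unitless in [0, 1).
    """

    K1: float
    k2: float
    k3: float
    k4: float
    Vb: float

    def __post_init__(self) -> None:
        for name in ("K1", "k2", "k3", "k4", "Vb"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0):
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")
        if self.Vb >= 1.0:
            raise ValueError("Vb must be < 1")
        if self.K1 > 0 and self.k2 + self.k3 == 0:
            raise ValueError("k2 + k3 must be > 0 when K1 > 0")

    def as_array(self) -> np.ndarray:
        return np.array([self.K1, self.k2, self.k3, self.k4, self.Vb])

    @classmethod
    def from_array(cls, x: Sequence[float]) -> "TwoTissueParams":
        return cls(*[float(v) for v in x])


def _exponents(params: TwoTissueParams) -> tuple[float, float, float, float]:
    """Exponents (a1 <= a2) and weights of the biexponential response."""
    k2, k3, k4 = params.k2, params.k3, params.k4
    s = k2 + k3 + k4
    disc = s * s - 4.0 * k2 * k4
    root = math.sqrt(max(disc, 0.0))
    a1 = 0.5 * (s - root)
    a2 = 0.5 * (s + root)
    if a2 - a1 < 1e-10:
        a2 = a1 + 1e-10  # split the (measure-zero) equal-exponent case
    w1 = (k3 + k4 - a1) / (a2 - a1)
    w2 = (a2 - k3 - k4) / (a2 - a1)
    return a1, a2, w1, w2


def _exp_conv(rate: float, grid: np.ndarray, cp: np.ndarray) -> np.ndarray:
    """Exact convolution of a piecewise-linear curve with exp(-rate*t).

    Evaluates ``int_0^t cp(s) exp(-rate*(t-s)) ds`` on the uniform grid by
    the closed-form per-interval recursion, implemented as a first-order
    IIR filter; exact for the linearly interpolated input, so the forward
    model carries no quadrature error beyond the input interpolation.
    """
    from scipy.signal import lfilter

    dt = float(grid[1] - grid[0])
    c0 = cp[:-1]
    m = np.diff(cp) / dt
    if rate * dt < 1e-12:
        decay = 1.0 - rate * dt
        g1, g2 = dt, dt * dt / 2.0
    else:
        decay = math.exp(-rate * dt)
        g1 = (1.0 - decay) / rate
        g2 = (dt - g1) / rate
    u = c0 * g1 + m * g2
    z = lfilter([1.0], [1.0, -decay], u)
    return np.concatenate([[0.0], z])


def _frame_average(curve: np.ndarray, grid: np.ndarray,
                   starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    """Mean of a fine-grid curve within each frame (trapezoidal)."""
    cum = np.concatenate([[0.0], np.cumsum((curve[1:] + curve[:-1]) * 0.5 * _DT)])

    def integral(t: np.ndarray) -> np.ndarray:
        return np.interp(t, grid, cum)

    return (integral(ends) - integral(starts)) / (ends - starts)


def model_tac(params: TwoTissueParams, input_: ArterialInput,
              frame_starts: Sequence[float], frame_durations: Sequence[float],
              label: str = "") -> TimeActivityCurve:
    """Forward-model a frame-averaged tissue TAC.

    Convolves the analytic biexponential impulse response with the
    linearly interpolated plasma curve on a 1-s grid, adds the fractional
    blood signal from the whole-blood curve, and averages within frames.
    """
    starts = np.asarray(frame_starts, float)
    durations = np.asarray(frame_durations, float)
    ends = starts + durations
    t_end = float(ends[-1])
    if t_end > float(input_.times[-1]) + 1e-9:
        raise ValueError(
            f"frame scheme extends to {t_end:.3g} min but the arterial input "
            f"ends at {input_.times[-1]:.3g} min")
    grid, cp, cwb = input_.on_grid(t_end)
    tissue = _convolve(params, grid, cp)
    signal = (1.0 - params.Vb) * tissue + params.Vb * cwb
    activity = _frame_average(signal, grid, starts, ends)
    return TimeActivityCurve(starts, durations, activity, label=label)


def _convolve(params: TwoTissueParams, grid: np.ndarray,
              cp: np.ndarray) -> np.ndarray:
    """Total tissue curve C1+C2 for the given input, kBq/mL."""
    k1 = params.K1 / ML_PER_HG  # mL/hg/min -> 1/min
    a1, a2, w1, w2 = _exponents(params)
    return k1 * (w1 * _exp_conv(a1, grid, cp) + w2 * _exp_conv(a2, grid, cp))


@dataclass(frozen=True)
class KineticFit:
    """Result of a nonlinear least-squares TAC fit."""

    params: TwoTissueParams
    covariance: np.ndarray | None
    rss: float
    n_frames: int
    converged: bool
    message: str = ""
    warnings: tuple[str, ...] = field(default=())


#: Parameter bounds (K1 mL/hg/min, k2, k3, k4 1/min, Vb) for fitting.
DEFAULT_BOUNDS = (np.array([0.0, 0.0, 0.0, 0.0, 0.0]),
                  np.array([60.0, 2.0, 2.0, 0.2, 0.2]))
#: Default initial point for the fit.
DEFAULT_INIT = TwoTissueParams(K1=6.0, k2=0.3, k3=0.1, k4=0.01, Vb=0.05)


def _default_weights(tac: TimeActivityCurve) -> np.ndarray:
    # duration / activity variance proxy; epsilon guards empty early frames
    eps = max(float(np.max(tac.activity)), 1.0) * 1e-3
    w = tac.frame_durations / np.maximum(tac.activity, eps)
    return w / w.mean()


def fit_tac_nlls(tac: TimeActivityCurve, input_: ArterialInput,
                 init: TwoTissueParams = DEFAULT_INIT,
                 bounds: tuple[np.ndarray, np.ndarray] = DEFAULT_BOUNDS,
                 weights: np.ndarray | None = None,
                 weighting: str = "duration",
                 n_restarts: int = 3, seed: int = 0) -> KineticFit:
    """Fit the reversible two-tissue model to one TAC.

    Weighted nonlinear least squares within box bounds.  With the default
    ``weighting="duration"`` frames are weighted by a duration/activity
    variance proxy; ``weighting="proportional"`` assumes noise
    proportional to the signal and iterates once, re-weighting by the
    inverse squared *model-predicted* activity (weights taken from the
    prediction rather than the noisy data to avoid weight-residual
    correlation bias).  Explicit ``weights`` override both.  If the first
    solve fails to converge, up to ``n_restarts`` seeded random restarts
    within the bounds are tried and the best solution kept.
    """
    if weighting not in ("duration", "proportional"):
        raise ValueError("weighting must be 'duration' or 'proportional'")
    fit = _fit_tac_once(tac, input_, init, bounds, weights, n_restarts, seed)
    if weights is None and weighting == "proportional":
        pred = model_tac(fit.params, input_, tac.frame_starts,
                         tac.frame_durations).activity
        floor = max(float(np.max(pred)), 1e-12) * 1e-2
        w = 1.0 / np.maximum(pred, floor) ** 2
        fit = _fit_tac_once(tac, input_, fit.params, bounds,
                            w / w.mean(), n_restarts, seed)
    return fit


def _fit_tac_once(tac: TimeActivityCurve, input_: ArterialInput,
                  init: TwoTissueParams,
                  bounds: tuple[np.ndarray, np.ndarray],
                  weights: np.ndarray | None,
                  n_restarts: int, seed: int) -> KineticFit:
    if tac.activity.size < 6:
        raise ValueError("at least 6 frames are needed for 5 free parameters")
    lb, ub = bounds
    x0 = np.clip(init.as_array(), lb, ub)
    w = _default_weights(tac) if weights is None else np.asarray(weights, float)
    sw = np.sqrt(w)

    starts, durations = tac.frame_starts, tac.frame_durations
    ends = starts + durations
    grid, cp, cwb = input_.on_grid(float(ends[-1]))
    cwb_frames = _frame_average(cwb, grid, starts, ends)

    def predict(x: np.ndarray) -> np.ndarray:
        p = TwoTissueParams.from_array(np.maximum(x, 0.0))
        tissue = _convolve(p, grid, cp)
        tissue_frames = _frame_average(tissue, grid, starts, ends)
        return (1.0 - p.Vb) * tissue_frames + p.Vb * cwb_frames

    def residuals(x: np.ndarray) -> np.ndarray:
        return sw * (predict(x) - tac.activity)

    fit_warnings: list[str] = []
    best = None
    rng = np.random.default_rng(seed)
    starts_list = [x0] + [lb + rng.random(5) * (ub - lb) for _ in range(n_restarts)]
    for attempt, x_start in enumerate(starts_list):
        try:
            sol = least_squares(residuals, x_start, bounds=(lb, ub),
                                method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12)
        except Exception as exc:  # pragma: no cover - defensive
            fit_warnings.append(f"start {attempt}: {exc}")
            continue
        if best is None or sol.cost < best.cost:
            best = sol
        if attempt == 0 and sol.success:
            break
    if best is None:
        raise RuntimeError("all fit attempts failed: " + "; ".join(fit_warnings))

    dof = tac.activity.size - 5
    rss = float(np.sum(best.fun ** 2))
    cov = None
    jtj = best.jac.T @ best.jac
    rank = np.linalg.matrix_rank(jtj, tol=1e-10 * np.trace(jtj) / 5)
    if rank < 5:
        fit_warnings.append(f"rank-deficient Jacobian (rank {rank} of 5)")
    if dof > 0 and rank == 5:
        cov = np.linalg.inv(jtj) * (rss / dof)
        cov = (cov + cov.T) / 2.0
    return KineticFit(params=TwoTissueParams.from_array(best.x),
                      covariance=cov, rss=rss, n_frames=tac.activity.size,
                      converged=bool(best.success), message=best.message,
                      warnings=tuple(fit_warnings))


def compute_cmrglc(params: TwoTissueParams, plasma_glucose: float,
                   lc: float = DEFAULT_LC) -> float:
    """Cerebral metabolic rate of glucose, uMol/hg/min.

    Net-influx formulation: ``CMRglc = Gp * K1 * k3/(k2+k3) / LC`` with
    plasma glucose converted from mM to uMol/mL (numerically identical).
    """
    if lc <= 0:
        raise ValueError("lumped constant must be > 0")
    if params.k3 == 0:
        return 0.0
    if params.k2 + params.k3 == 0:
        raise ValueError("k2 + k3 must be > 0")
    gp_umol_ml = plasma_glucose  # 1 mM == 1 uMol/mL
    return gp_umol_ml * params.K1 * params.k3 / (params.k2 + params.k3) / lc


@dataclass(frozen=True)
class LumpedConstantTable:
    """Piecewise-linear lumped constant vs plasma glucose.

    An empty table means "use the fixed default" (0.81).  The glucose grid
    must be strictly increasing; queries outside the domain are clamped to
    the boundary value with a warning.
    """

    plasma_glucose: tuple[float, ...] = ()
    lc: tuple[float, ...] = ()
    default: float = DEFAULT_LC

    def __post_init__(self) -> None:
        g = np.asarray(self.plasma_glucose, float)
        v = np.asarray(self.lc, float)
        if g.size != v.size:
            raise ValueError("glucose and LC grids must have equal length")
        if g.size and np.any(np.diff(g) <= 0):
            raise ValueError("glucose grid must be strictly increasing")
        if np.any(v <= 0) or np.any(v >= 2):
            raise ValueError("LC values must lie in (0, 2)")


def glucose_adjusted_lc_table() -> LumpedConstantTable:
    """LC table embodying the rat-derived ~6% decrease at hyperglycemia.

    Anchored at the fixed LC of 0.81 for euglycemic plasma glucose (5 mM)
    and 6% lower (0.7614) at 15 mM.
    """
    return LumpedConstantTable(plasma_glucose=(5.0, 15.0), lc=(0.81, 0.7614))


def adjust_lumped_constant(table: LumpedConstantTable,
                           plasma_glucose: float) -> float:
    """Interpolate the lumped constant at a plasma glucose level (mM)."""
    if not table.plasma_glucose:
        return table.default
    g = np.asarray(table.plasma_glucose, float)
    v = np.asarray(table.lc, float)
    if plasma_glucose < g[0] or plasma_glucose > g[-1]:
        warnings.warn(
            f"plasma glucose {plasma_glucose:.3g} mM outside the LC table "
            f"domain [{g[0]:.3g}, {g[-1]:.3g}]; clamped to the boundary",
            stacklevel=2)
    return float(np.interp(plasma_glucose, g, v))


def _params_from_basis(phi1: float, phi2: float, th1: float, th2: float,
                       vb: float) -> TwoTissueParams | None:
    """Map basis coefficients back to rate constants; None if unphysical."""
    k1_per_min = phi1 + phi2
    if k1_per_min <= 0:
        return None
    # th1 < th2 are the exponents a1, a2 of the impulse response
    k3k4 = th1 + phi1 * (th2 - th1) / k1_per_min
    k2 = th1 + th2 - k3k4
    if k2 <= 0:
        return None
    k4 = th1 * th2 / k2
    k3 = k3k4 - k4
    if k3 < -1e-12 or k4 < -1e-12:
        return None
    try:
        return TwoTissueParams(K1=k1_per_min * ML_PER_HG, k2=k2,
                               k3=max(k3, 0.0), k4=max(k4, 0.0),
                               Vb=float(np.clip(vb, 0.0, 1.0 - 1e-9)))
    except ValueError:
        return None


def basis_function_fit(voxel_tacs: np.ndarray,
                       input_: ArterialInput,
                       frame_starts: Sequence[float],
                       frame_durations: Sequence[float],
                       theta_grid: np.ndarray | None = None,
                       spatial_weight: float = 0.5,
                       shape: tuple[int, int, int] | None = None,
                       vb_max: float = 0.2) -> dict[str, np.ndarray]:
    """Basis-function parametric fit of many TACs at once.

    The biexponential impulse response is linear in its two amplitudes
    once the exponents are fixed, so each basis curve ``Cp (x) exp(-th*t)``
    is precomputed on the theta grid, every ordered exponent pair plus the
    whole-blood term is solved per voxel by linear least squares, and the
    grid minimum is kept.  With ``shape`` given (voxels arranged as a 3-D
    volume) a spatial constraint follows: each voxel's exponent pair is
    shrunk toward the 3x3x3 neighbourhood median (weight
    ``spatial_weight``), snapped back to the grid, and the linear step is
    re-solved -- a smoothness prior in the spirit of hierarchical basis
    schemes.

    Returns maps (one value per voxel) of K1, k2, k3, k4, Vb, rss and a
    validity mask.
    """
    tacs = np.atleast_2d(np.asarray(voxel_tacs, float))
    n_vox, n_frames = tacs.shape
    starts = np.asarray(frame_starts, float)
    durations = np.asarray(frame_durations, float)
    if starts.size != n_frames:
        raise ValueError("voxel TACs and frame scheme disagree on frame count")
    if theta_grid is None:
        theta_grid = np.geomspace(0.005, 3.0, 24)
    theta_grid = np.sort(np.asarray(theta_grid, float))
    if theta_grid.size < 2 or np.any(theta_grid <= 0):
        raise ValueError("theta grid must hold at least two positive exponents")
    ends = starts + durations
    grid, cp, cwb = input_.on_grid(float(ends[-1]))

    # frame-averaged basis curves, one per exponent
    basis = np.empty((theta_grid.size, n_frames))
    for i, th in enumerate(theta_grid):
        basis[i] = _frame_average(_exp_conv(th, grid, cp), grid, starts, ends)
    cwb_frames = _frame_average(cwb, grid, starts, ends)

    pairs = [(i, j) for i in range(theta_grid.size)
             for j in range(i + 1, theta_grid.size)]

    def solve_pairs(tac_mat: np.ndarray, pair_list: Sequence[tuple[int, int]],
                    restrict: np.ndarray | None = None):
        """Best pair per voxel by linear LS; returns (rss, coef, pair_idx)."""
        nv = tac_mat.shape[0]
        best_rss = np.full(nv, np.inf)
        best_coef = np.zeros((nv, 3))
        best_pair = np.full(nv, -1)
        for p_idx, (i, j) in enumerate(pair_list):
            X = np.column_stack([basis[i], basis[j], cwb_frames])
            coef, _, _, _ = np.linalg.lstsq(X, tac_mat.T, rcond=None)
            resid = tac_mat.T - X @ coef
            rss = np.sum(resid ** 2, axis=0)
            # physically admissible: non-negative amplitudes, bounded blood
            ok = (coef[0] >= 0) & (coef[1] >= 0) & (coef[2] >= 0) & (coef[2] <= vb_max)
            if restrict is not None:
                ok &= restrict[:, p_idx]
            better = ok & (rss < best_rss)
            best_rss[better] = rss[better]
            best_coef[better] = coef.T[better]
            best_pair[better] = p_idx
        return best_rss, best_coef, best_pair

    rss, coef, pair_idx = solve_pairs(tacs, pairs)

    if shape is not None and spatial_weight > 0 and n_vox == int(np.prod(shape)):
        from scipy.ndimage import median_filter

        th1_map = np.where(pair_idx >= 0,
                           theta_grid[[pairs[p][0] if p >= 0 else 0 for p in pair_idx]],
                           np.nan).reshape(shape)
        th2_map = np.where(pair_idx >= 0,
                           theta_grid[[pairs[p][1] if p >= 0 else 0 for p in pair_idx]],
                           np.nan).reshape(shape)
        th1_med = median_filter(th1_map, size=3, mode="nearest")
        th2_med = median_filter(th2_map, size=3, mode="nearest")
        th1_new = (1 - spatial_weight) * th1_map + spatial_weight * th1_med
        th2_new = (1 - spatial_weight) * th2_map + spatial_weight * th2_med
        # snap the constrained exponents back to the grid and re-solve
        i_new = np.abs(theta_grid[None, :] - th1_new.reshape(-1, 1)).argmin(axis=1)
        j_new = np.abs(theta_grid[None, :] - th2_new.reshape(-1, 1)).argmin(axis=1)
        j_new = np.maximum(j_new, i_new + 1).clip(max=theta_grid.size - 1)
        i_new = np.minimum(i_new, j_new - 1)
        pair_lookup = {pq: idx for idx, pq in enumerate(pairs)}
        restrict = np.zeros((n_vox, len(pairs)), dtype=bool)
        rows = np.arange(n_vox)
        cols = np.array([pair_lookup[(int(i), int(j))]
                         for i, j in zip(i_new, j_new)])
        restrict[rows, cols] = True
        rss2, coef2, pair2 = solve_pairs(tacs, pairs, restrict=restrict)
        use = pair2 >= 0
        rss[use], coef[use], pair_idx[use] = rss2[use], coef2[use], pair2[use]

    maps = {k: np.full(n_vox, np.nan) for k in ("K1", "k2", "k3", "k4", "Vb", "rss")}
    valid = np.zeros(n_vox, dtype=bool)
    for v in range(n_vox):
        if pair_idx[v] < 0:
            continue
        i, j = pairs[pair_idx[v]]
        vb = float(coef[v, 2])
        # measured amplitudes carry the (1 - Vb) tissue fraction
        p = _params_from_basis(coef[v, 0] / (1.0 - vb), coef[v, 1] / (1.0 - vb),
                               theta_grid[i], theta_grid[j], vb)
        if p is None:
            continue
        valid[v] = True
        maps["K1"][v], maps["k2"][v] = p.K1, p.k2
        maps["k3"][v], maps["k4"][v] = p.k3, p.k4
        maps["Vb"][v] = p.Vb
        maps["rss"][v] = rss[v]
    maps["valid"] = valid
    return maps
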