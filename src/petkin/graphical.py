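"""Patlak and Logan graphical analysis and voxel-wise parametric maps.

For an irreversible tracer the Patlak transformation
``CT(t)/Cp(t)`` versus ``int_0^t Cp / Cp(t)`` becomes linear after an
equilibration time t*; the slope is the net influx rate Ki and the
intercept the initial distribution volume V.  For reversible tracers the
Logan transformation ``int_0^t CT / CT(t)`` versus ``int_0^t Cp / CT(t)``
becomes linear with slope equal to the total distribution volume Vt
(K1/k2 for a one-tissue model, K1/k2 (1 + k3/k4) for a reversible
two-tissue model).

Both methods are ordinary least squares on the transformed coordinates,
restricted to frames with midpoint time >= t*.  Voxel-wise application
yields parametric Ki/Vt maps, optionally smoothed with a separable
Gaussian (sigma = FWHM/2.355 per axis, reflect border handling).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.ndimage import gaussian_filter

from .framing import DynamicImage, TimeActivityCurve

__all__ = [
    "GraphicalFit",
    "ParametricMap",
    "patlak",
    "logan",
    "select_tstar",
    "parametric_map",
    "gaussian_smooth",
]


@dataclass(frozen=True)
class GraphicalFit:
    """Linearized-analysis result.

    ``slope`` is Ki (ml/ccm/min) for Patlak and Vt (ml/ccm) for Logan.
    ``nonlinear`` flags a maximum relative deviation of the used points
    from the regression line above 10%.
    """

    method: str
    t_star_min: float
    slope: float
    intercept: float
    r_squared: float
    n_points: int
    nonlinear: bool = False

    def __post_init__(self):
        if self.n_points < 3:
            raise ValueError("graphical fit needs at least 3 points")
        if not (0.0 <= self.r_squared <= 1.0):
            raise ValueError("R^2 must lie in [0, 1]")


def _cumint(time_min: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Zero-anchored cumulative trapezoid integral."""
    return cumulative_trapezoid(values, time_min, initial=0.0)


def _integrate_tac_to_midpoints(ct: np.ndarray, schedule) -> np.ndarray:
    """Cumulative integral of a framed TAC up to each frame midpoint.

    Frame values are treated as frame averages (the natural reading of
    count data), so each full frame contributes ``value * duration`` and
    the current frame contributes half of that up to its midpoint.  This
    keeps short early bolus frames fully weighted, which a trapezoid
    across midpoints would smear out.
    """
    dt_min = schedule.duration / 60.0
    contrib = ct * dt_min
    return np.cumsum(contrib) - 0.5 * contrib


def _ols(x: np.ndarray, y: np.ndarray):
    A = np.vstack([x, np.ones_like(x)]).T
    (slope, intercept), res, *_ = np.linalg.lstsq(A, y, rcond=None)
    yhat = slope * x + intercept
    sst = float(np.sum((y - y.mean()) ** 2))
    ssr = float(np.sum((y - yhat) ** 2))
    r2 = 1.0 if sst == 0 else max(0.0, min(1.0, 1.0 - ssr / sst))
    return float(slope), float(intercept), r2, yhat


def _graphical_coords(tac: TimeActivityCurve, cp_time_s, cp_values,
                      method: str):
    """Transformed (x, y) at frame midpoints plus the validity mask."""
    t_mid_min = tac.schedule.mid / 60.0
    cp_t_min = np.asarray(cp_time_s, float) / 60.0
    cp = np.asarray(cp_values, float)
    # integrate the input on its own (fine) grid, then read at midpoints
    icp = np.interp(t_mid_min, cp_t_min, _cumint(cp_t_min, cp))
    cp_mid = np.interp(t_mid_min, cp_t_min, cp)
    ct = tac.value
    ict = _integrate_tac_to_midpoints(ct, tac.schedule)
    if method == "patlak":
        denom = cp_mid
        x, y = icp / np.where(denom == 0, np.nan, denom), ct / np.where(
            denom == 0, np.nan, denom)
    elif method == "logan":
        denom = ct
        x, y = icp / np.where(denom == 0, np.nan, denom), ict / np.where(
            denom == 0, np.nan, denom)
    else:
        raise ValueError("method must be 'patlak' or 'logan'")
    return x, y, denom


def _fit_graphical(tac, cp_time_s, cp_values, t_star_min, method) -> GraphicalFit:
    x, y, denom = _graphical_coords(tac, cp_time_s, cp_values, method)
    sel = tac.schedule.mid / 60.0 >= t_star_min - 1e-9
    if np.count_nonzero(sel) < 3:
        raise ValueError("fewer than 3 frames after t*")
    if np.any(denom[sel] == 0) or np.any(~np.isfinite(x[sel] + y[sel])):
        what = "Cp" if method == "patlak" else "CT"
        raise ZeroDivisionError(f"{what} is zero within the fitted window")
    slope, intercept, r2, yhat = _ols(x[sel], y[sel])
    dev = _relative_deviation(y[sel], yhat)
    return GraphicalFit(method=method, t_star_min=float(t_star_min),
                        slope=slope, intercept=intercept, r_squared=r2,
                        n_points=int(np.count_nonzero(sel)),
                        nonlinear=bool(np.max(dev) > 0.10))


def _relative_deviation(y: np.ndarray, yhat: np.ndarray) -> np.ndarray:
    """Pointwise deviation of data from the regression, relative to the
    regression value (floored at 10% of its maximum to keep near-zero
    predictions from dominating)."""
    floor = 0.1 * np.max(np.abs(yhat))
    return np.abs(y - yhat) / np.maximum(np.abs(yhat), max(floor, 1e-300))


def patlak(tac: TimeActivityCurve, cp_time_s, cp_values,
           t_star_min: float = 20.0) -> GraphicalFit:
    """Patlak analysis; slope = Ki, intercept = distribution volume V."""
    cp_t_min = np.asarray(cp_time_s, float) / 60.0
    if np.trapezoid(np.asarray(cp_values, float), cp_t_min) <= 0:
        raise ValueError("input-function integral must be positive")
    return _fit_graphical(tac, cp_time_s, cp_values, t_star_min, "patlak")


def logan(tac: TimeActivityCurve, cp_time_s, cp_values,
          t_star_min: float = 10.0) -> GraphicalFit:
    """Logan analysis; slope = total distribution volume Vt."""
    return _fit_graphical(tac, cp_time_s, cp_values, t_star_min, "logan")


def select_tstar(tac: TimeActivityCurve, cp_time_s, cp_values,
                 method: str = "patlak", max_rel_dev: float = 0.10,
                 min_tail: int = 3) -> float:
    """Earliest t* (min) such that every later transformed point deviates
    less than *max_rel_dev* from the regression over the tail.

    Raises if no candidate frame satisfies the criterion (manual t*
    recommended in that case).
    """
    t_mid_min = tac.schedule.mid / 60.0
    if t_mid_min.size < 5:
        raise ValueError("need at least 5 candidate frames")
    x, y, denom = _graphical_coords(tac, cp_time_s, cp_values, method)
    for i in range(t_mid_min.size - min_tail + 1):
        xi, yi, di = x[i:], y[i:], denom[i:]
        if np.any(di == 0) or np.any(~np.isfinite(xi + yi)):
            continue
        slope, intercept, _, yhat = _ols(xi, yi)
        if np.max(np.abs(yhat)) == 0:
            continue
        if np.max(_relative_deviation(yi, yhat)) < max_rel_dev:
            return float(t_mid_min[i])
    raise RuntimeError("no t* satisfies the linearity criterion; "
                       "choose t* manually")


@dataclass
class ParametricMap:
    """3-D voxel-wise Ki or Vt map."""

    values: np.ndarray
    voxel_size: np.ndarray
    quantity: str  # "Ki" or "Vt"
    fwhm_mm: float = 0.0
    n_failed: int = 0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.voxel_size = np.asarray(self.voxel_size, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("parametric map must be 3-D")
        if self.fwhm_mm < 0:
            raise ValueError("FWHM must be non-negative")


def parametric_map(img: DynamicImage, cp_time_s, cp_values,
                   method: str = "patlak",
                   t_star_min: float = 20.0) -> ParametricMap:
    """Voxel-wise Patlak/Logan slope map.

    The regression is vectorized across voxels; voxels where the
    transformation is undefined (zero denominators, non-finite values)
    are set to NaN and counted in ``n_failed``.
    """
    sched = img.schedule
    t_mid_min = sched.mid / 60.0
    sel = t_mid_min >= t_star_min - 1e-9
    if np.count_nonzero(sel) < 3:
        raise ValueError("fewer than 3 frames after t*")
    cp_t_min = np.asarray(cp_time_s, float) / 60.0
    cp = np.asarray(cp_values, float)
    icp_mid = np.interp(t_mid_min, cp_t_min, _cumint(cp_t_min, cp))
    cp_mid = np.interp(t_mid_min, cp_t_min, cp)

    shp = img.values.shape[:3]
    ct = img.values.reshape(-1, sched.n_frames)  # (V, F)
    if method == "patlak":
        denom = np.broadcast_to(cp_mid, ct.shape)
        x = np.broadcast_to(icp_mid, ct.shape) / denom
        y = ct / denom
    elif method == "logan":
        dt_min = sched.duration / 60.0
        contrib = ct * dt_min
        ict = np.cumsum(contrib, axis=1) - 0.5 * contrib
        with np.errstate(divide="ignore", invalid="ignore"):
            x = icp_mid / ct
            y = ict / ct
    else:
        raise ValueError("method must be 'patlak' or 'logan'")

    with np.errstate(divide="ignore", invalid="ignore"):
        xs = x[:, sel]
        ys = y[:, sel]
        bad = ~np.all(np.isfinite(xs) & np.isfinite(ys), axis=1)
        xm = xs.mean(axis=1, keepdims=True)
        ym = ys.mean(axis=1, keepdims=True)
        sxx = np.sum((xs - xm) ** 2, axis=1)
        sxy = np.sum((xs - xm) * (ys - ym), axis=1)
        slope = sxy / sxx
    slope[bad | ~np.isfinite(slope)] = np.nan
    n_failed = int(np.count_nonzero(~np.isfinite(slope)))
    quantity = "Ki" if method == "patlak" else "Vt"
    return ParametricMap(slope.reshape(shp), img.voxel_size, quantity,
                         n_failed=n_failed)


def gaussian_smooth(pmap: ParametricMap, fwhm_mm: float) -> ParametricMap:
    """Separable Gaussian smoothing with sigma = FWHM/2.355 per axis (mm),
    reflect border handling.  NaN voxels are handled by normalized
    convolution (smoothing weights renormalized over valid voxels)."""
    if fwhm_mm < 0:
        raise ValueError("FWHM must be non-negative")
    if fwhm_mm == 0:
        return ParametricMap(pmap.values.copy(), pmap.voxel_size,
                             pmap.quantity, fwhm_mm=0.0,
                             n_failed=pmap.n_failed)
    sigma_vox = (fwhm_mm / 2.355) / pmap.voxel_size
    vals = pmap.values
    nanmask = ~np.isfinite(vals)
    if nanmask.any():
        filled = np.where(nanmask, 0.0, vals)
        num = gaussian_filter(filled, sigma=sigma_vox, mode="reflect")
        den = gaussian_filter((~nanmask).astype(float), sigma=sigma_vox,
                              mode="reflect")
        with np.errstate(invalid="ignore", divide="ignore"):
            out = num / den
        out[nanmask] = np.nan
    else:
        out = gaussian_filter(vals, sigma=sigma_vox, mode="reflect")
    return ParametricMap(out, pmap.voxel_size, pmap.quantity,
                         fwhm_mm=fwhm_mm, n_failed=pmap.n_failed)
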