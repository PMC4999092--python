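"""Arterial input-function (AIF) processing.

A continuously sampled whole-blood detector curve is turned into the
model-ready plasma input function(s) through a chain of corrections:

calibration -> radioactive decay -> delay -> catheter dispersion ->
plasma-to-blood ratio -> parent-fraction (metabolite) correction.

The dispersion correction is the first-order deconvolution
``Ca(t) = g(t) + tau_disp * dg/dt`` where ``g`` is the measured blood curve
and ``tau_disp`` a catheter constant (4.63 s for the 10-cm line at
200 ul/min withdrawal used as the packaged default).  Tracers that are
metabolized in vivo (FCho -> FBet) additionally need the total plasma
activity split into a parent and a metabolite input via a fitted
parent-fraction curve.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares
from scipy.signal import savgol_filter

__all__ = [
    "BloodCurve",
    "DispersionSettings",
    "RatioModel",
    "ExpSumModel",
    "ParentFractionModel",
    "InputFunctionSet",
    "F18_HALF_LIFE_S",
    "calibrate",
    "decay_correct",
    "shift_delay",
    "dispersion_correct",
    "fit_exp_sum",
    "apply_plasma_blood_ratio",
    "split_parent_metabolite",
    "default_ratio_model",
]

#: Fluorine-18 half-life in seconds (109.77 min).
F18_HALF_LIFE_S = 109.77 * 60.0


@dataclass
class BloodCurve:
    """Regularly sampled whole-blood (or plasma) activity curve.

    ``time`` in seconds, nominally 1 Hz; ``activity`` in kBq/ml (or counter
    rate before calibration).
    """

    time: np.ndarray
    activity: np.ndarray
    calibrated: bool = False
    decay_corrected: bool = False
    dispersion_corrected: bool = False

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.activity = np.asarray(self.activity, dtype=float)
        if self.time.ndim != 1 or self.time.shape != self.activity.shape:
            raise ValueError("time and activity must be equal-length 1-D arrays")
        if self.time.size < 2:
            raise ValueError("blood curve needs at least two samples")
        dt = np.diff(self.time)
        if np.any(dt <= 0):
            raise ValueError("time must be strictly increasing")
        if not np.all(np.isfinite(self.activity)):
            raise ValueError("activity must be finite")
        if (dt.max() - dt.min()) > 0.01 * dt.mean():
            raise ValueError("sampling interval must be constant within 1%")

    @property
    def dt(self) -> float:
        return float(np.mean(np.diff(self.time)))


@dataclass(frozen=True)
class DispersionSettings:
    """Catheter dispersion constant plus the geometry it came from.

    The geometry fields (catheter span, withdrawal speed, length) are stored
    as metadata only; ``tau_disp`` itself is a configured constant.
    """

    tau_disp: float = 4.63  # s
    span_v: float = 43.5
    withdrawal_speed_ul_min: float = 200.0
    catheter_length_cm: float = 10.0

    def __post_init__(self):
        if self.tau_disp < 0:
            raise ValueError("tau_disp must be non-negative")


def calibrate(raw: BloodCurve, factor: float) -> BloodCurve:
    """Scale counter rate to kBq/ml with a scalar calibration factor."""
    if factor <= 0:
        raise ValueError("calibration factor must be positive")
    return replace(raw, activity=raw.activity * factor, calibrated=True)


def decay_correct(curve, t0: float = 0.0,
                  half_life_s: float = F18_HALF_LIFE_S):
    """Correct activity back to the acquisition start time *t0*.

    Multiplies values by ``exp(+lambda (t - t0))`` with
    ``lambda = ln 2 / T_half``.  Accepts a :class:`BloodCurve` (sample
    times) or a :class:`~petkin.framing.TimeActivityCurve` (frame
    midpoints) and returns the same type.
    """
    if half_life_s <= 0:
        raise ValueError("half-life must be positive")
    lam = np.log(2.0) / half_life_s
    if isinstance(curve, BloodCurve):
        fac = np.exp(lam * (curve.time - t0))
        return replace(curve, activity=curve.activity * fac, decay_corrected=True)
    fac = np.exp(lam * (curve.time - t0))
    out = replace(curve, value=curve.value * fac)
    out.decay_corrected = True
    return out


def shift_delay(curve: BloodCurve, delta_s: float) -> BloodCurve:
    """Remove a measurement delay of *delta_s* seconds from the blood curve.

    Blood reaches the external detector *delta_s* seconds after leaving the
    artery, so the measured curve lags tissue time; the correction advances
    it: the returned curve holds ``g(t + delta_s)`` resampled on the original
    grid (edges padded by holding the first/last value).  Pass a negative
    *delta_s* to delay the curve instead.
    """
    support = curve.time[-1] - curve.time[0]
    if abs(delta_s) >= support:
        raise ValueError("delay shift exceeds the curve support")
    shifted = np.interp(curve.time + delta_s, curve.time, curve.activity,
                        left=curve.activity[0], right=curve.activity[-1])
    return replace(curve, activity=shifted)


def dispersion_correct(g: BloodCurve, settings: DispersionSettings,
                       smooth_window_s: float | None = None) -> BloodCurve:
    """First-order dispersion deconvolution ``Ca = g + tau * dg/dt``.

    The derivative uses central differences on the regular grid (one-sided
    at the ends).  For noisy detector data an optional Savitzky-Golay
    pre-smoothing (quadratic, window *smooth_window_s*) can be applied
    before differentiation.
    """
    if g.time.size < 3:
        raise ValueError("need at least 3 samples for dispersion correction")
    act = g.activity
    if smooth_window_s is not None:
        win = max(3, int(round(smooth_window_s / g.dt)) | 1)  # odd
        act = savgol_filter(act, win, polyorder=2)
    dgdt = np.gradient(act, g.time, edge_order=1)
    ca = act + settings.tau_disp * dgdt
    return replace(g, activity=ca, dispersion_corrected=True)


@dataclass(frozen=True)
class ExpSumModel:
    """Sum of up to three decaying exponentials ``sum_j A_j exp(-l_j t)``.

    Times in minutes, rates in 1/min; the conventional smooth description
    of a plasma washout tail.
    """

    amplitudes: np.ndarray
    rates: np.ndarray
    residual_norm: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "amplitudes", np.atleast_1d(
            np.asarray(self.amplitudes, dtype=float)))
        object.__setattr__(self, "rates", np.atleast_1d(
            np.asarray(self.rates, dtype=float)))
        if self.amplitudes.shape != self.rates.shape:
            raise ValueError("amplitudes and rates must have equal length")
        if np.any(self.rates < 0):
            raise ValueError("rates must be non-negative")

    def __call__(self, t_min) -> np.ndarray:
        t = np.asarray(t_min, dtype=float)
        return np.sum(self.amplitudes[:, None]
                      * np.exp(-np.outer(self.rates, t)), axis=0)


def fit_exp_sum(time_min, values, n_terms: int = 3,
                fit_start_min: float = 0.0, n_starts: int = 8,
                seed: int = 0) -> ExpSumModel:
    """Least-squares fit of a 1-3 term exponential sum to a sampled curve.

    Uses variable projection: the nonlinear search runs over log-rates only
    and the amplitudes are solved linearly at each step, which makes the
    multi-exponential problem well conditioned.  Deterministic for a given
    seed (multi-start over rate spreads).
    """
    t = np.asarray(time_min, dtype=float)
    y = np.asarray(values, dtype=float)
    sel = t >= fit_start_min
    t, y = t[sel], y[sel]
    if not 1 <= n_terms <= 3:
        raise ValueError("n_terms must be 1, 2 or 3")
    if t.size < 2 * n_terms + 1:
        raise ValueError("too few samples after fit_start for the model order")

    def amplitudes_for(rates):
        basis = np.exp(-np.outer(t, rates))
        amp, *_ = np.linalg.lstsq(basis, y, rcond=None)
        return amp, basis

    def resid(log_rates):
        amp, basis = amplitudes_for(np.exp(log_rates))
        return basis @ amp - y

    t_span = max(t[-1] - t[0], 1e-6)
    # keep rates within a physically sensible window to avoid overflow
    lo = np.log(1e-4 / t_span)
    hi = np.log(1e3 / t_span)
    rng = np.random.default_rng(seed)
    best = None
    for k in range(n_starts):
        # spread initial rates over decades bracketing 1/t_span
        base = np.geomspace(0.1 / t_span, 50.0 / t_span, n_terms)
        if k > 0:
            base = base * np.exp(rng.normal(0, 0.7, n_terms))
        x0 = np.clip(np.log(base), lo + 1e-9, hi - 1e-9)
        try:
            sol = least_squares(resid, x0, bounds=(lo, hi), method="trf",
                                xtol=1e-14, ftol=1e-14, max_nfev=2000)
        except (ValueError, np.linalg.LinAlgError):
            continue
        rn = float(np.linalg.norm(sol.fun))
        if best is None or rn < best[0]:
            best = (rn, np.exp(sol.x))
    if best is None:
        raise RuntimeError("exponential-sum fit failed on all starts")
    rn, rates = best
    scale = float(np.linalg.norm(y))
    if scale > 0 and rn / scale > 0.1:
        raise RuntimeError(
            f"exponential-sum fit did not converge (best residual norm {rn:.3g})")
    amp, _ = amplitudes_for(rates)
    order = np.argsort(-rates)
    return ExpSumModel(amp[order], rates[order], residual_norm=rn)


@dataclass(frozen=True)
class RatioModel:
    """Plasma-to-whole-blood ratio as a piecewise-linear function of time.

    Knot times in minutes; linear interpolation between knots, constant
    extrapolation beyond them.
    """

    knot_times_min: np.ndarray
    ratios: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "knot_times_min",
                           np.atleast_1d(np.asarray(self.knot_times_min, float)))
        object.__setattr__(self, "ratios",
                           np.atleast_1d(np.asarray(self.ratios, float)))
        if self.knot_times_min.shape != self.ratios.shape:
            raise ValueError("knots and ratios must have equal length")
        if np.any(np.diff(self.knot_times_min) <= 0):
            raise ValueError("knot times must be strictly increasing")
        if np.any(self.ratios <= 0):
            raise ValueError("ratios must be positive")

    def __call__(self, t_s) -> np.ndarray:
        t_min = np.asarray(t_s, dtype=float) / 60.0
        return np.interp(t_min, self.knot_times_min, self.ratios)


#: Endpoint plasma/whole-blood ratios per tracer over the acquisition.
_RATIO_DEFAULTS = {
    "FDG": ([0.0, 60.0], [1.59, 1.04]),
    "FET": ([0.0, 55.0], [1.10, 1.30]),
    "FCho": ([0.0, 20.0], [0.97, 1.03]),
}


def default_ratio_model(tracer: str) -> RatioModel:
    """Packaged plasma-to-blood ratio trajectory for FDG, FET or FCho."""
    try:
        knots, ratios = _RATIO_DEFAULTS[tracer.upper().replace("CHO", "Cho")]
    except KeyError:
        raise ValueError(f"unknown tracer {tracer!r}") from None
    return RatioModel(np.array(knots), np.array(ratios))


def apply_plasma_blood_ratio(wb: BloodCurve, ratio: RatioModel) -> BloodCurve:
    """Plasma curve ``plasma(t) = wb(t) * ratio(t)``."""
    r = ratio(wb.time)
    if np.any(r <= 0):
        raise ValueError("plasma-blood ratio must be positive on the support")
    return replace(wb, activity=wb.activity * r)


@dataclass(frozen=True)
class ParentFractionModel:
    """Parent fraction ``f(t) = a1 e^(-b1 t) + a2 e^(-b2 t) + a3``.

    Times in minutes.  The constraints ``a_j >= 0``, ``sum a_j = 1`` and
    ``b_j >= 0`` enforce ``f(0) = 1`` and ``0 <= f <= 1``.  An optional
    metabolite-fraction curve ``m(t) = m_inf (1 - e^(-kappa t))`` describes
    the rise of a labelled metabolite in plasma (FBet for FCho).
    """

    amplitudes: np.ndarray  # (a1, a2, a3); a3 is the constant term
    rates: np.ndarray       # (b1, b2) in 1/min
    metabolite_plateau: float = 0.0
    metabolite_rate: float = 0.0  # kappa, 1/min

    def __post_init__(self):
        a = np.asarray(self.amplitudes, dtype=float)
        b = np.asarray(self.rates, dtype=float)
        object.__setattr__(self, "amplitudes", a)
        object.__setattr__(self, "rates", b)
        if a.shape != (3,) or b.shape != (2,):
            raise ValueError("need 3 amplitudes and 2 rates")
        if np.any(a < -1e-12) or np.any(b < 0):
            raise ValueError("amplitudes and rates must be non-negative")
        if abs(a.sum() - 1.0) > 1e-9:
            raise ValueError("amplitudes must sum to 1 so that f(0) = 1")

    def parent_fraction(self, t_min) -> np.ndarray:
        t = np.asarray(t_min, dtype=float)
        a, b = self.amplitudes, self.rates
        return a[0] * np.exp(-b[0] * t) + a[1] * np.exp(-b[1] * t) + a[2]

    def metabolite_fraction(self, t_min) -> np.ndarray:
        t = np.asarray(t_min, dtype=float)
        return self.metabolite_plateau * (1.0 - np.exp(-self.metabolite_rate * t))

    __call__ = parent_fraction


@dataclass
class InputFunctionSet:
    """Model-ready input functions on a common time grid (seconds).

    ``cp_parent`` drives the tissue model; ``cp_metabolite`` is the second
    input of the dual-input (3C2i) topology; ``cwb`` is whole blood for the
    vascular term.
    """

    time: np.ndarray
    cp_parent: np.ndarray
    cwb: np.ndarray
    cp_metabolite: np.ndarray | None = None

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.cp_parent = np.asarray(self.cp_parent, dtype=float)
        self.cwb = np.asarray(self.cwb, dtype=float)
        n = self.time.shape
        if self.cp_parent.shape != n or self.cwb.shape != n:
            raise ValueError("all curves must share the time grid")
        if self.cp_metabolite is not None:
            self.cp_metabolite = np.asarray(self.cp_metabolite, dtype=float)
            if self.cp_metabolite.shape != n:
                raise ValueError("metabolite curve must share the time grid")


def split_parent_metabolite(plasma: BloodCurve,
                            pf: ParentFractionModel,
                            cwb: BloodCurve | None = None) -> InputFunctionSet:
    """Split total plasma activity into parent and metabolite inputs.

    ``Cp_parent = plasma * f(t)`` and ``Cp_metabolite = plasma * m(t)``;
    the modeled fractions may not exceed 1 in total.
    """
    t_min = plasma.time / 60.0
    f = pf.parent_fraction(t_min)
    if np.any(f < -1e-9) or np.any(f > 1 + 1e-9):
        raise ValueError("parent fraction must lie in [0, 1] on the support")
    m = pf.metabolite_fraction(t_min)
    if np.any(f + m > 1 + 1e-9):
        raise ValueError("parent + metabolite fractions exceed 1")
    cwb_v = plasma.activity if cwb is None else np.interp(
        plasma.time, cwb.time, cwb.activity)
    return InputFunctionSet(time=plasma.time,
                            cp_parent=plasma.activity * f,
                            cp_metabolite=plasma.activity * m,
                            cwb=cwb_v)
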