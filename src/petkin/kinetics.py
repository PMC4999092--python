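"""Compartmental kinetic models: forward simulation, fitting, selection.

Three topologies are supported, matching the model families routinely used
for FDG, FET and FCho brain PET:

``1C1i``  one tissue compartment, one input::

    dC1/dt = K1*Cp - k2*C1

``2C1i``  two tissue compartments, one input::

    dC1/dt = K1*Cp - (k2 + k3)*C1 + k4*C2
    dC2/dt = k3*C1 - k4*C2

``3C2i``  dual-input model for a metabolized tracer (parent + labelled
metabolite): the parent input drives an irreversible two-tissue branch
(K1, k2, k3) and the metabolite input an independent reversible
compartment::

    dC3/dt = K1m*Cm - k2m*C3

The model TAC is ``(1 - vB) * sum(C_tissue) + vB * Cwb``.  Because every
impulse response is a sum of exponentials, tissue curves are computed by
exact convolution of exponentials with the piecewise-linear input — no ODE
solver in the production path.

Macro-parameters follow the standard closed forms: influx
``Ki = K1*k3/(k2 + k3)``, trapping fraction ``Kp = k3/(k2 + k3)`` and
distribution volume ``Vd = K1/k2``; for FDG the glucose metabolic rate is
``MR = Ki * C_glu / LC`` with lumped constant LC.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.signal import lfilter

from .aif import InputFunctionSet
from .framing import FrameSchedule, TimeActivityCurve

__all__ = [
    "ModelSpec",
    "KineticParams",
    "GlucoseInfo",
    "MacroParams",
    "KineticFit",
    "ModelComparison",
    "expconv",
    "simulate_model",
    "fit_model",
    "macro_parameters",
    "metabolic_rate",
    "model_selection_criteria",
    "compare_models",
]

TOPOLOGIES = ("1C1i", "2C1i", "3C2i")


@dataclass(frozen=True)
class ModelSpec:
    """Model topology plus fixed parameters (e.g. ``{"k4": 0.0}``)."""

    topology: str
    fixed: dict = field(default_factory=dict)
    fit_blood_volume: bool = False

    def __post_init__(self):
        if self.topology not in TOPOLOGIES:
            raise ValueError(f"unknown topology {self.topology!r}")

    def free_parameters(self) -> list[str]:
        names = {
            "1C1i": ["K1", "k2"],
            "2C1i": ["K1", "k2", "k3", "k4"],
            "3C2i": ["K1", "k2", "k3", "K1m", "k2m"],
        }[self.topology]
        names = [n for n in names if n not in self.fixed]
        if self.fit_blood_volume:
            names.append("vB")
        return names


@dataclass
class KineticParams:
    """Micro-parameters.  K1/K1m in ml/ccm/min, rate constants in 1/min,
    vB a unitless blood-volume fraction."""

    K1: float = 0.0
    k2: float = 0.0
    k3: float = 0.0
    k4: float = 0.0
    K1m: float = 0.0
    k2m: float = 0.0
    vB: float = 0.0

    def __post_init__(self):
        for name in ("K1", "k2", "k3", "k4", "K1m", "k2m", "vB"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 <= self.vB <= 1:
            raise ValueError("vB must lie in [0, 1]")

    def as_dict(self) -> dict:
        return {n: getattr(self, n)
                for n in ("K1", "k2", "k3", "k4", "K1m", "k2m", "vB")}


@dataclass(frozen=True)
class GlucoseInfo:
    """Plasma glucose (mmol/l) and lumped constant for FDG quantification."""

    plasma_glucose_mmol_l: float = 3.44
    lumped_constant: float = 0.89

    def __post_init__(self):
        if self.plasma_glucose_mmol_l <= 0 or self.lumped_constant <= 0:
            raise ValueError("glucose level and lumped constant must be positive")


def expconv(lam: float, time_s: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Exact convolution ``y(t) = int_0^t exp(-lam (t - s)) u(s) ds`` for a
    piecewise-linear ``u`` sampled on the regular grid *time_s* (seconds).

    *lam* is in 1/min.  The per-segment update is a linear recurrence with
    constant coefficient on a regular grid, evaluated in C via ``lfilter``.
    """
    t = np.asarray(time_s, dtype=float) / 60.0  # work in minutes
    u = np.asarray(u, dtype=float)
    if t.size != u.size or t.size < 2:
        raise ValueError("time and u must be equal-length with >= 2 samples")
    dt = float(t[1] - t[0])
    x = lam * dt
    if lam < 0:
        raise ValueError("lam must be non-negative")
    if x > 1e-8:
        E = math.exp(-x)
        I1 = -math.expm1(-x) / lam          # int_0^dt e^{-lam(dt-s)} ds
        I2 = (dt - I1) / lam                # int_0^dt e^{-lam(dt-s)} s ds
    else:
        E = math.exp(-x)
        I1 = dt * (1.0 - 0.5 * x + x * x / 6.0)
        I2 = 0.5 * dt * dt * (1.0 - x / 3.0)
    slope = np.diff(u) / dt
    b = u[:-1] * I1 + slope * I2
    y = np.empty_like(u)
    y[0] = 0.0
    # y[i+1] = E*y[i] + b[i]
    y[1:] = lfilter([1.0], [1.0, -E], b)
    return y


def _tissue_response(spec: ModelSpec, p: KineticParams,
                     inputs: InputFunctionSet) -> np.ndarray:
    """Total tissue activity on the input time grid (kBq/ml)."""
    t, cp = inputs.time, inputs.cp_parent
    if spec.topology == "1C1i":
        return p.K1 * expconv(p.k2, t, cp)
    if spec.topology == "2C1i":
        return _two_tissue(p.K1, p.k2, p.k3, p.k4, t, cp)
    # 3C2i: irreversible parent branch + reversible metabolite compartment
    if inputs.cp_metabolite is None:
        raise ValueError("3C2i requires a metabolite input function")
    parent = _two_tissue(p.K1, p.k2, p.k3, 0.0, t, cp)
    metab = p.K1m * expconv(p.k2m, t, inputs.cp_metabolite)
    return parent + metab


def _two_tissue(K1, k2, k3, k4, t, cp) -> np.ndarray:
    """Two-tissue impulse response convolved with cp.

    C1 + C2 = K1/(a2 - a1) * [(k3 + k4 - a1) e^{-a1 t}
                              + (a2 - k3 - k4) e^{-a2 t}] (*) cp
    with a1,2 the roots of s^2 - (k2 + k3 + k4) s + k2 k4.
    """
    s = k2 + k3 + k4
    disc = s * s - 4.0 * k2 * k4
    sq = math.sqrt(max(disc, 0.0))
    a1 = 0.5 * (s - sq)
    a2 = 0.5 * (s + sq)
    if a2 - a1 < 1e-12:
        # degenerate equal roots: nudge apart (error O(1e-12) in rates)
        a2 = a1 + 1e-12
    c1 = (k3 + k4 - a1) / (a2 - a1)
    c2 = (a2 - k3 - k4) / (a2 - a1)
    return K1 * (c1 * expconv(a1, t, cp) + c2 * expconv(a2, t, cp))


def _sample_frames(time_s: np.ndarray, curve: np.ndarray,
                   schedule: FrameSchedule, sampling: str) -> np.ndarray:
    if sampling == "midpoint":
        return np.interp(schedule.mid, time_s, curve)
    if sampling == "average":
        out = np.empty(schedule.n_frames)
        for i, (a, b) in enumerate(zip(schedule.start, schedule.end)):
            sel = (time_s >= a - 1e-9) & (time_s <= b + 1e-9)
            if sel.sum() >= 2:
                out[i] = np.trapezoid(curve[sel], time_s[sel]) / (
                    time_s[sel][-1] - time_s[sel][0])
            else:
                out[i] = np.interp(0.5 * (a + b), time_s, curve)
        return out
    raise ValueError("sampling must be 'midpoint' or 'average'")


def simulate_model(spec: ModelSpec, params: KineticParams,
                   inputs: InputFunctionSet, schedule: FrameSchedule,
                   sampling: str = "midpoint") -> TimeActivityCurve:
    """Noiseless model TAC on the frame schedule.

    ``TAC = (1 - vB) * C_tissue + vB * Cwb`` evaluated at frame midpoints
    (default) or as frame averages.
    """
    if inputs.time[-1] + 1e-6 < schedule.mid[-1]:
        raise ValueError("input functions do not cover the frame schedule")
    tissue = _tissue_response(spec, params, inputs)
    total = (1.0 - params.vB) * tissue + params.vB * inputs.cwb
    value = _sample_frames(inputs.time, total, schedule, sampling)
    return TimeActivityCurve(schedule, value)


@dataclass(frozen=True)
class MacroParams:
    """Closed-form macro-parameters; entries are None when undefined for
    the topology."""

    Ki: float | None
    Kp: float | None
    Vd: float | None


def macro_parameters(params: KineticParams, topology: str) -> MacroParams:
    """Influx rate Ki = K1 k3/(k2 + k3), trapping fraction
    Kp = k3/(k2 + k3) and distribution volume Vd = K1/k2."""
    if topology not in TOPOLOGIES:
        raise ValueError(f"unknown topology {topology!r}")
    if params.k2 <= 0:
        raise ZeroDivisionError("Vd requires k2 > 0")
    vd = params.K1 / params.k2
    if topology == "1C1i":
        return MacroParams(Ki=None, Kp=None, Vd=vd)
    if params.k2 + params.k3 <= 0:
        raise ZeroDivisionError("Ki/Kp require k2 + k3 > 0")
    ki = params.K1 * params.k3 / (params.k2 + params.k3)
    kp = params.k3 / (params.k2 + params.k3)
    return MacroParams(Ki=ki, Kp=kp, Vd=vd)


def metabolic_rate(ki: float, glucose: GlucoseInfo) -> float:
    """Glucose metabolic rate ``MR = Ki * C_glu / LC`` in umol/ccm/min."""
    if ki < 0:
        raise ValueError("Ki must be non-negative")
    return ki * glucose.plasma_glucose_mmol_l / glucose.lumped_constant


def model_selection_criteria(y, yhat, weights, p: int):
    """Least-squares information criteria for a fitted model.

    AIC = N ln(SSR/N) + 2p,  SC (BIC) = N ln(SSR/N) + p ln N and the
    Scientist/MicroMath model selection criterion
    MSC = ln(sum w (y - ybar)^2 / sum w (y - yhat)^2) - 2p/N,
    all on the weighted residuals.  A perfect fit (SSR = 0) yields the
    sentinel (-inf, -inf, +inf) with ``perfect=True``.
    """
    y = np.asarray(y, float)
    yhat = np.asarray(yhat, float)
    w = np.ones_like(y) if weights is None else np.asarray(weights, float)
    n = y.size
    if n <= p:
        raise ValueError("need more data points than free parameters")
    ssr = float(np.sum(w * (y - yhat) ** 2))
    if ssr == 0.0:
        return {"aic": -np.inf, "sc": -np.inf, "msc": np.inf,
                "ssr": 0.0, "perfect": True}
    ybar = float(np.sum(w * y) / np.sum(w))
    sst = float(np.sum(w * (y - ybar) ** 2))
    aic = n * math.log(ssr / n) + 2 * p
    sc = n * math.log(ssr / n) + p * math.log(n)
    msc = math.log(sst / ssr) - 2.0 * p / n if sst > 0 else -np.inf
    return {"aic": aic, "sc": sc, "msc": msc, "ssr": ssr, "perfect": False}


@dataclass
class KineticFit:
    """Result of a weighted nonlinear least-squares compartment-model fit."""

    spec: ModelSpec
    params: KineticParams
    se_percent: dict
    ssr: float
    n_points: int
    n_free: int
    aic: float
    sc: float
    msc: float
    macro: MacroParams
    fitted: TimeActivityCurve
    data: np.ndarray
    weights: np.ndarray
    converged: bool = True
    perfect_fit: bool = False
    se_defined: bool = True


_DEFAULT_INIT = {"K1": 0.1, "k2": 0.1, "k3": 0.05, "k4": 0.01,
                 "K1m": 0.05, "k2m": 0.05, "vB": 0.05}
_DEFAULT_BOUNDS = {"vB": (0.0, 0.2)}
_GLOBAL_BOUNDS = (0.0, 5.0)


def fit_model(tac: TimeActivityCurve, inputs: InputFunctionSet,
              spec: ModelSpec, weights: str | np.ndarray = "frame",
              init: dict | None = None, bounds: dict | None = None,
              n_starts: int = 10, seed: int = 0,
              sampling: str = "midpoint") -> KineticFit:
    """Weighted NLLS fit of a compartment model to a TAC.

    Weights default to the frame durations (``"frame"``), matching the
    count-statistics noise model; ``"uniform"`` or an explicit array are
    also accepted.  A bounded trust-region optimizer is run from the
    default initial values plus ``n_starts - 1`` seeded log-normal
    perturbations; the best weighted SSR wins, so the result is
    deterministic for a given seed.  Percent standard errors come from the
    scaled inverse Gauss-Newton normal matrix at the solution.
    """
    y = tac.value
    sched = tac.schedule
    free = spec.free_parameters()
    n, p = y.size, len(free)
    if n <= p:
        raise ValueError(f"need more than {p} frames to fit {spec.topology}")
    if isinstance(weights, str):
        if weights == "frame":
            w = sched.duration.copy()
        elif weights == "uniform":
            w = np.ones(n)
        else:
            raise ValueError("weights must be 'frame', 'uniform' or an array")
    else:
        w = np.asarray(weights, float)
    w = w / w.mean()  # normalize so SSR scales like a plain residual sum
    sw = np.sqrt(w)

    init_full = dict(_DEFAULT_INIT)
    if init:
        init_full.update(init)
    lo = np.array([(bounds or {}).get(nm, _DEFAULT_BOUNDS.get(nm, _GLOBAL_BOUNDS))[0]
                   for nm in free])
    hi = np.array([(bounds or {}).get(nm, _DEFAULT_BOUNDS.get(nm, _GLOBAL_BOUNDS))[1]
                   for nm in free])

    fixed = {nm: float(v) for nm, v in spec.fixed.items()}

    def make_params(theta) -> KineticParams:
        kw = dict(fixed)
        kw.update({nm: float(v) for nm, v in zip(free, theta)})
        return KineticParams(**{k: v for k, v in kw.items()
                                if k in KineticParams.__dataclass_fields__})

    def model_curve(theta) -> np.ndarray:
        pset = make_params(theta)
        tissue = _tissue_response(spec, pset, inputs)
        total = (1.0 - pset.vB) * tissue + pset.vB * inputs.cwb
        return _sample_frames(inputs.time, total, sched, sampling)

    def resid(theta):
        return sw * (model_curve(theta) - y)

    x0 = np.clip([init_full[nm] for nm in free], lo + 1e-12, hi)
    rng = np.random.default_rng(seed)
    best = None
    for k in range(max(1, n_starts)):
        xk = x0 if k == 0 else np.clip(
            x0 * np.exp(rng.normal(0.0, 0.5, p)), lo + 1e-12, hi)
        try:
            sol = least_squares(resid, xk, bounds=(lo, hi), method="trf",
                                xtol=1e-12, ftol=1e-12, gtol=1e-12,
                                max_nfev=400)
        except Exception:
            continue
        ssr_k = float(np.sum(sol.fun ** 2))
        # relative tie-break keeps the default-start solution on flat ridges
        if best is None or ssr_k < best[0] * (1.0 - 1e-9) - 1e-300:
            best = (ssr_k, sol)
    if best is None:
        raise RuntimeError("all optimizer starts failed")
    ssr, sol = best
    converged = bool(sol.status > 0)
    theta = sol.x
    pset = make_params(theta)

    # all-zero data or a residual at numerical noise level leaves the
    # normal matrix scale-free: SEs are meaningless there
    scale = float(np.max(np.abs(y)))
    degenerate = scale == 0.0 or math.sqrt(ssr / n) <= 1e-10 * max(scale, 1.0)

    # standard errors from the Gauss-Newton approximation
    se = {}
    se_defined = True
    dof = n - p
    if ssr > 0 and dof > 0 and not degenerate:
        jtj = sol.jac.T @ sol.jac
        try:
            cov = np.linalg.inv(jtj) * (ssr / dof)
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(jtj) * (ssr / dof)
            se_defined = False
        sd = np.sqrt(np.clip(np.diag(cov), 0, None))
        for nm, s, v in zip(free, sd, theta):
            if abs(v) > 0:
                se[nm] = 100.0 * s / abs(v)
            else:
                se[nm] = np.inf
                se_defined = False
    else:
        se = {nm: np.inf for nm in free}
        se_defined = False

    yhat = model_curve(theta)
    crit = model_selection_criteria(y, yhat, w, p)
    try:
        macro = macro_parameters(pset, spec.topology)
    except ZeroDivisionError:
        macro = MacroParams(None, None, None)
    return KineticFit(
        spec=spec, params=pset, se_percent=se, ssr=crit["ssr"],
        n_points=n, n_free=p, aic=crit["aic"], sc=crit["sc"],
        msc=crit["msc"], macro=macro,
        fitted=TimeActivityCurve(sched, yhat), data=y.copy(), weights=w,
        converged=converged, perfect_fit=crit["perfect"] or degenerate,
        se_defined=se_defined)


@dataclass(frozen=True)
class ModelComparison:
    """Per-criterion winners and a majority consensus across fits."""

    labels: tuple
    best_aic: str
    best_sc: str
    best_msc: str
    consensus: str | None
    ties: tuple


def compare_models(fits: list[KineticFit], rtol: float = 1e-9) -> ModelComparison:
    """Rank fits of the same data: lowest AIC, lowest SC, highest MSC win;
    the consensus is the majority of the three criteria (None if fully
    split).  Ties are reported, never broken silently."""
    if len(fits) < 2:
        raise ValueError("need at least two fits to compare")
    n0 = fits[0].n_points
    if any(f.n_points != n0 for f in fits):
        raise ValueError("fits were computed on different data lengths")
    if any(not np.allclose(f.data, fits[0].data) for f in fits):
        raise ValueError("fits were computed on different data")
    labels = tuple(f.spec.topology for f in fits)

    def winner(values, largest):
        v = np.asarray(values, float)
        best = np.max(v) if largest else np.min(v)
        idx = [i for i, x in enumerate(v)
               if np.isclose(x, best, rtol=rtol, atol=1e-12) or x == best]
        return idx

    ties = []
    picks = []
    for name, vals, largest in (("aic", [f.aic for f in fits], False),
                                ("sc", [f.sc for f in fits], False),
                                ("msc", [f.msc for f in fits], True)):
        idx = winner(vals, largest)
        if len(idx) > 1:
            ties.append((name, tuple(labels[i] for i in idx)))
        picks.append(labels[idx[0]])
    counts = {lbl: picks.count(lbl) for lbl in set(picks)}
    top = max(counts.values())
    consensus = None
    if top >= 2:
        consensus = [lbl for lbl, c in counts.items() if c == top][0]
    return ModelComparison(labels=labels, best_aic=picks[0], best_sc=picks[1],
                           best_msc=picks[2], consensus=consensus,
                           ties=tuple(ties))
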