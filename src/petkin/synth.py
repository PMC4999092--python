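"""Synthetic dynamic-PET data with known ground truth.

The generators emulate a small-animal (rat) dynamic brain PET study with
continuous arterial blood sampling: a bolus-shaped arterial input function
scaled to a 37 MBq injected dose, tracer-specific plasma-to-blood ratio
trajectories, a metabolite (parent-fraction) profile for FCho, and
glioblastoma (GB) / radiation-necrosis (RN) cohorts whose micro-parameters
are drawn from published group means and standard deviations.  Everything
is a pure function of its parameters and a seed, so cohorts are
bit-reproducible.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .aif import (BloodCurve, InputFunctionSet, ParentFractionModel,
                  RatioModel, default_ratio_model, F18_HALF_LIFE_S)
from .framing import (DynamicImage, FrameSchedule, TimeActivityCurve,
                      VOIMask, build_frame_schedule)
from .kinetics import KineticParams, ModelSpec, simulate_model

__all__ = [
    "AIFModel",
    "NoiseModel",
    "GroupParameterTable",
    "SyntheticCohort",
    "generate_aif",
    "make_input_set",
    "generate_tac",
    "generate_cohort",
    "generate_phantom",
    "default_metabolite_profile",
    "default_group_table",
    "FRAMING",
]

#: Printed framing strings per tracer.
FRAMING = {
    "FDG": "12x10s/6x20s/6x1min/10x2min/6x5min",    # 60 min
    "FET": "12x10s/6x20s/6x1min/10x2min/5x5min",    # 55 min
    "FCho": "12x10s/6x20s/6x1min/2x5min",           # 20 min
}


@dataclass(frozen=True)
class AIFModel:
    """Bolus-plus-triexponential arterial whole-blood model.

    Linear rise from injection to a single peak, then a three-term
    exponential washout, continuous at the peak.  ``peak_kbq_ml`` is the
    blood peak for the reference dose; the curve scales linearly with
    ``dose_mbq``.  Washout rates in 1/min.
    """

    peak_time_s: float = 30.0
    peak_kbq_ml: float = 250.0
    dose_mbq: float = 37.0
    reference_dose_mbq: float = 37.0
    tail_fractions: tuple = (0.70, 0.25, 0.05)
    tail_rates_per_min: tuple = (4.0, 0.5, 0.01)

    def __post_init__(self):
        if self.peak_time_s <= 0 or self.peak_kbq_ml <= 0 or self.dose_mbq <= 0:
            raise ValueError("AIF parameters must be positive")
        if len(self.tail_fractions) != len(self.tail_rates_per_min):
            raise ValueError("tail fractions and rates must match in length")
        if any(f < 0 for f in self.tail_fractions) or any(
                r < 0 for r in self.tail_rates_per_min):
            raise ValueError("tail fractions and rates must be non-negative")

    def __call__(self, t_s) -> np.ndarray:
        t = np.asarray(t_s, dtype=float)
        peak = self.peak_kbq_ml * self.dose_mbq / self.reference_dose_mbq
        frac = np.asarray(self.tail_fractions, float)
        total = frac.sum()
        amps = peak * frac / (total if total > 0 else 1.0)
        rates = np.asarray(self.tail_rates_per_min, float) / 60.0  # 1/s
        rise = np.clip(t / self.peak_time_s, 0.0, 1.0) * peak
        tail = np.sum(amps[:, None]
                      * np.exp(-np.outer(rates, np.maximum(t - self.peak_time_s, 0.0))),
                      axis=0)
        return np.where(t <= self.peak_time_s, rise, tail)


def generate_aif(model: AIFModel, schedule: FrameSchedule | None = None,
                 duration_s: float | None = None,
                 dt_s: float = 1.0) -> BloodCurve:
    """Whole-blood curve sampled at *dt_s* (default 1 Hz) covering the
    schedule (or an explicit duration)."""
    if duration_s is None:
        if schedule is None:
            raise ValueError("give either a schedule or a duration")
        duration_s = schedule.total_duration
    t = np.arange(0.0, duration_s + dt_s / 2, dt_s)
    return BloodCurve(t, model(t), calibrated=True, decay_corrected=True)


def make_input_set(tracer: str, aif_blood: BloodCurve,
                   with_metabolite: bool | None = None) -> InputFunctionSet:
    """Plasma parent (and, for FCho, metabolite) inputs from a whole-blood
    curve using the packaged ratio and parent-fraction defaults."""
    tracer_key = {"FDG": "FDG", "FET": "FET", "FCHO": "FCho"}[tracer.upper()]
    ratio = default_ratio_model(tracer_key)
    plasma = aif_blood.activity * ratio(aif_blood.time)
    pf = default_metabolite_profile(tracer_key)
    t_min = aif_blood.time / 60.0
    f = pf.parent_fraction(t_min)
    if with_metabolite is None:
        with_metabolite = tracer_key == "FCho"
    cp_met = plasma * pf.metabolite_fraction(t_min) if with_metabolite else None
    return InputFunctionSet(time=aif_blood.time, cp_parent=plasma * f,
                            cwb=aif_blood.activity, cp_metabolite=cp_met)


def _fit_parent_fraction(anchors_t_min, anchors_f) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic least-squares fit of the constrained 3-exponential
    parent fraction to anchor points (weights favour t = 0 and the printed
    late point)."""
    t = np.asarray(anchors_t_min, float)
    yv = np.asarray(anchors_f, float)

    def unpack(theta):
        a1, a2 = np.clip(theta[:2], 0, 1)
        s = a1 + a2
        if s > 1:  # keep a3 = 1 - a1 - a2 >= 0
            a1, a2 = a1 / s, a2 / s
        b = np.exp(theta[2:])
        return np.array([a1, a2, 1.0 - a1 - a2]), b

    def resid(theta):
        a, b = unpack(theta)
        f = a[0] * np.exp(-b[0] * t) + a[1] * np.exp(-b[1] * t) + a[2]
        return f - yv

    sol = least_squares(resid, [0.5, 0.35, np.log(0.5), np.log(0.1)],
                        xtol=1e-14, ftol=1e-14, max_nfev=5000)
    return unpack(sol.x)


_FCHO_PARENT_15MIN = 0.172
_FCHO_METAB_15MIN = 0.293
_FCHO_PHOSPHO_15MIN = 0.028
_FCHO_METAB_PLATEAU = 0.35


def default_metabolite_profile(tracer: str) -> ParentFractionModel:
    """Packaged parent-fraction model per tracer.

    FDG and FET are metabolically stable over the scan, so their parent
    fraction is identically 1 (no metabolite correction).  For FCho the
    parent fraction decays from 1 at injection to 17.2% at 15 min while the
    labelled oxidation product (FBet) rises to 29.3% at 15 min; the
    phospho-FCho plasma fraction stays at or below 2.8% and is not modeled
    as an input.
    """
    key = tracer.upper()
    if key in ("FDG", "FET"):
        return ParentFractionModel(np.array([0.0, 0.0, 1.0]),
                                   np.array([0.0, 0.0]))
    if key != "FCHO":
        raise ValueError(f"unknown tracer {tracer!r}")
    # anchor shape: printed values at 0 and 15 min; intermediate anchors
    # are the package's interpolation choice for a rapidly oxidized tracer
    anchors_t = [0.0, 1.0, 5.0, 15.0, 20.0]
    anchors_f = [1.0, 0.90, 0.45, _FCHO_PARENT_15MIN, 0.14]
    a, b = _fit_parent_fraction(anchors_t, anchors_f)
    kappa = -np.log(1.0 - _FCHO_METAB_15MIN / _FCHO_METAB_PLATEAU) / 15.0
    return ParentFractionModel(a, b, metabolite_plateau=_FCHO_METAB_PLATEAU,
                               metabolite_rate=float(kappa))


@dataclass(frozen=True)
class NoiseModel:
    """Frame-count PET noise: ``sigma_i^2 = alpha * C(t_i) *
    exp(lambda_decay * t_i) / dt_i`` with C in kBq/ml, t in s.

    ``alpha`` (kBq s/ml) sets the overall level; the default gives a TAC
    coefficient of variation of roughly 5% at mid-acquisition for the FDG
    settings.  ``alpha = 0`` disables noise.
    """

    alpha: float = 7.0
    decay_constant_per_s: float = np.log(2.0) / F18_HALF_LIFE_S

    def __post_init__(self):
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")

    def sigma(self, tac_values, schedule: FrameSchedule) -> np.ndarray:
        c = np.clip(np.asarray(tac_values, float), 0.0, None)
        var = (self.alpha * c
               * np.exp(self.decay_constant_per_s * schedule.mid)
               / schedule.duration)
        return np.sqrt(var)


def generate_tac(params: KineticParams, spec: ModelSpec,
                 inputs: InputFunctionSet, schedule: FrameSchedule,
                 noise: NoiseModel | None = None,
                 rng: np.random.Generator | int | None = None
                 ) -> TimeActivityCurve:
    """Noiseless model TAC plus seeded Gaussian frame noise."""
    tac = simulate_model(spec, params, inputs, schedule)
    if noise is None or noise.alpha == 0:
        return tac
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    sigma = noise.sigma(tac.value, schedule)
    noisy = tac.value + rng.normal(0.0, 1.0, tac.value.size) * sigma
    return TimeActivityCurve(schedule, noisy)


@dataclass(frozen=True)
class GroupParameterTable:
    """Mean and SD of each micro-parameter per group, plus the topology
    the tracer is analysed with."""

    tracer: str
    topology: str
    groups: dict  # group -> {param: (mean, sd)}

    def __post_init__(self):
        for g, entry in self.groups.items():
            for p, (m, s) in entry.items():
                if m < 0 or s < 0:
                    raise ValueError(f"negative mean/SD for {g}:{p}")


#: Published group-level micro-parameters (mean, SD).  SDs not printed for
#: a parameter are set to 20% of the mean, a typical between-animal spread.
_GROUP_TABLES = {
    "FDG": GroupParameterTable("FDG", "2C1i", {
        "GB": {"K1": (0.16, 0.032), "k2": (0.19, 0.04), "k3": (0.07, 0.03)},
        "RN": {"K1": (0.17, 0.034), "k2": (0.28, 0.03), "k3": (0.04, 0.01)},
    }),
    "FET": GroupParameterTable("FET", "1C1i", {
        "GB": {"K1": (0.06, 0.01), "k2": (0.05, 0.01)},
        "RN": {"K1": (0.02, 0.01), "k2": (0.05, 0.01)},
    }),
    "FCho": GroupParameterTable("FCho", "1C1i", {
        "GB": {"K1": (0.11, 0.03), "k2": (0.05, 0.02)},
        "RN": {"K1": (0.10, 0.02), "k2": (0.07, 0.01)},
    }),
}


def default_group_table(tracer: str) -> GroupParameterTable:
    key = {"FDG": "FDG", "FET": "FET", "FCHO": "FCho"}.get(tracer.upper())
    if key is None:
        raise ValueError(f"unknown tracer {tracer!r}")
    return _GROUP_TABLES[key]


@dataclass
class SyntheticCohort:
    """Generated animals: TACs plus the ground-truth parameters."""

    tracer: str
    spec: ModelSpec
    schedule: FrameSchedule
    inputs: InputFunctionSet
    tacs: list
    truth: list          # list of KineticParams
    group: list          # group label per animal
    seed: int


def _truncated_normal(mean, sd, size, rng) -> np.ndarray:
    """Normal(mean, sd) truncated at zero via rejection sampling."""
    if sd == 0:
        return np.full(size, mean, dtype=float)
    x = rng.normal(mean, sd, size)
    bad = x < 0
    while bad.any():
        x[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = x < 0
    return x


def generate_cohort(table: GroupParameterTable, n_per_group: dict,
                    seed: int = 0, noise: NoiseModel | None = None,
                    aif: AIFModel | None = None) -> SyntheticCohort:
    """Draw per-animal truth from truncated normals and generate TACs.

    *n_per_group* maps group label -> number of animals (e.g.
    ``{"GB": 6, "RN": 5}``).  Bit-reproducible from (table, n, seed).
    """
    if any(n < 1 for n in n_per_group.values()):
        raise ValueError("each group needs at least one animal")
    schedule = build_frame_schedule(FRAMING[table.tracer])
    aif = aif or AIFModel()
    blood = generate_aif(aif, schedule)
    inputs = make_input_set(table.tracer, blood)
    fixed = {"k4": 0.0} if table.topology == "2C1i" else {}
    spec = ModelSpec(table.topology, fixed=fixed)
    rng = np.random.default_rng(seed)
    tacs, truth, labels = [], [], []
    for group in sorted(n_per_group):
        n = n_per_group[group]
        entry = table.groups[group]
        draws = {p: _truncated_normal(m, s, n, rng)
                 for p, (m, s) in entry.items()}
        for i in range(n):
            params = KineticParams(**{p: float(draws[p][i]) for p in draws})
            tac = generate_tac(params, spec, inputs, schedule, noise, rng)
            tacs.append(tac)
            truth.append(params)
            labels.append(group)
    return SyntheticCohort(tracer=table.tracer, spec=spec, schedule=schedule,
                           inputs=inputs, tacs=tacs, truth=truth,
                           group=labels, seed=seed)


def generate_phantom(dims: tuple, regions: dict, inputs: InputFunctionSet,
                     schedule: FrameSchedule, spec: ModelSpec | None = None,
                     noise: NoiseModel | None = None,
                     seed: int = 0) -> tuple[DynamicImage, dict]:
    """4D phantom: every voxel of a region carries that region's TAC.

    *regions* maps label -> (boolean mask of shape *dims*, KineticParams).
    Regions must be disjoint and non-empty; voxels outside all regions are
    zero.  Returns the image and a dict label -> VOIMask.
    """
    if not regions:
        raise ValueError("empty region map")
    spec = spec or ModelSpec("2C1i", fixed={"k4": 0.0})
    occupancy = np.zeros(dims, dtype=int)
    masks = {}
    for label, (mask, _) in regions.items():
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != tuple(dims):
            raise ValueError(f"region {label!r} mask shape mismatch")
        if not mask.any():
            raise ValueError(f"region {label!r} is empty")
        occupancy += mask
        masks[label] = VOIMask.from_bool(mask)
    if occupancy.max() > 1:
        raise ValueError("regions overlap")
    n_frames = schedule.n_frames
    values = np.zeros((*dims, n_frames))
    rng = np.random.default_rng(seed)
    for label, (mask, params) in regions.items():
        tac = generate_tac(params, spec, inputs, schedule, noise, rng)
        values[np.asarray(mask, bool), :] = tac.value
    img = DynamicImage(values, np.array([1.0, 1.0, 1.0]), schedule)
    return img, masks
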