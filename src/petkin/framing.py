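"""Frame schedules, dynamic images, VOI extraction and SUV/LNR measures.

Dynamic PET protocols are conventionally written as compact framing strings
such as ``"12x10s/6x20s/6x1min/10x2min/6x5min"`` (twelve 10-second frames,
six 20-second frames, ...).  This module expands those strings into explicit
frame schedules, extracts region time-activity curves (TACs) from 4D images,
and computes the semi-quantitative uptake measures used for lesion reporting:
the standardized uptake value (SUV) and the lesion-to-normal-tissue ratio
(LNR) against a reference region.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, replace

import nibabel as nib
import numpy as np

__all__ = [
    "FrameSchedule",
    "DynamicImage",
    "VOIMask",
    "TimeActivityCurve",
    "SUVReport",
    "build_frame_schedule",
    "format_frame_schedule",
    "cubic_voi",
    "extract_voi_tac",
    "compute_suv",
    "compute_lnr",
]

_TOKEN_RE = re.compile(r"^(\d+)x(\d+(?:\.\d+)?)(s|min)$")
_UNIT_S = {"s": 1.0, "min": 60.0}


class FrameScheduleError(ValueError):
    """Malformed framing string or inconsistent frame timing."""


@dataclass(frozen=True)
class FrameSchedule:
    """Contiguous, non-overlapping acquisition frames.

    Parameters
    ----------
    start : ndarray
        Frame start times in seconds; ``start[0]`` must be 0.
    duration : ndarray
        Frame durations in seconds, all positive.
    """

    start: np.ndarray
    duration: np.ndarray

    def __post_init__(self):
        start = np.asarray(self.start, dtype=float)
        duration = np.asarray(self.duration, dtype=float)
        object.__setattr__(self, "start", start)
        object.__setattr__(self, "duration", duration)
        if start.ndim != 1 or start.shape != duration.shape or start.size == 0:
            raise FrameScheduleError("start/duration must be equal-length 1-D arrays")
        if start[0] != 0.0:
            raise FrameScheduleError("first frame must start at t = 0")
        if np.any(duration <= 0):
            raise FrameScheduleError("frame durations must be positive")
        if not np.allclose(start[1:], start[:-1] + duration[:-1], rtol=0, atol=1e-9):
            raise FrameScheduleError("frames must be contiguous and non-overlapping")

    @property
    def n_frames(self) -> int:
        return self.start.size

    @property
    def end(self) -> np.ndarray:
        """Frame end times in seconds."""
        return self.start + self.duration

    @property
    def mid(self) -> np.ndarray:
        """Frame midpoint times in seconds (the reference time used for
        model evaluation throughout the package)."""
        return self.start + 0.5 * self.duration

    @property
    def total_duration(self) -> float:
        """Total acquisition length in seconds."""
        return float(self.end[-1])

    def __len__(self) -> int:
        return self.n_frames


def build_frame_schedule(spec: str) -> FrameSchedule:
    """Expand a compact framing string into a :class:`FrameSchedule`.

    The grammar is ``count x duration unit`` with unit ``s`` or ``min``,
    groups separated by ``/``; e.g. ``"12x10s/6x20s/6x1min/10x2min/6x5min"``
    expands to 40 contiguous frames totalling 3600 s.
    """
    if not isinstance(spec, str) or not spec.strip():
        raise FrameScheduleError("empty framing string")
    durations = []
    for token in spec.strip().split("/"):
        m = _TOKEN_RE.match(token.strip())
        if m is None:
            raise FrameScheduleError(f"malformed framing token {token!r}")
        count = int(m.group(1))
        dur = float(m.group(2)) * _UNIT_S[m.group(3)]
        if count == 0:
            raise FrameScheduleError(f"zero frame count in token {token!r}")
        if dur == 0:
            raise FrameScheduleError(f"zero frame duration in token {token!r}")
        durations.extend([dur] * count)
    duration = np.array(durations)
    start = np.concatenate([[0.0], np.cumsum(duration)[:-1]])
    return FrameSchedule(start, duration)


def format_frame_schedule(schedule: FrameSchedule) -> str:
    """Compact framing string for *schedule* (inverse of
    :func:`build_frame_schedule` whenever durations are exact in s or min)."""
    groups: list[tuple[int, float]] = []
    for d in schedule.duration:
        if groups and groups[-1][1] == d:
            groups[-1] = (groups[-1][0] + 1, d)
        else:
            groups.append((1, float(d)))
    tokens = []
    for count, d in groups:
        if d >= 60 and (d / 60) == int(d / 60):
            tokens.append(f"{count}x{int(d / 60)}min")
        else:
            tokens.append(f"{count}x{d:g}s")
    return "/".join(tokens)


@dataclass
class TimeActivityCurve:
    """Activity concentration per frame for one region or voxel.

    ``value`` is in kBq/ml unless the curve has been normalized to SUV.
    """

    schedule: FrameSchedule
    value: np.ndarray
    statistic: str = "mean"  # "mean" or "max" over the VOI
    decay_corrected: bool = True

    def __post_init__(self):
        self.value = np.asarray(self.value, dtype=float)
        if self.value.shape != (self.schedule.n_frames,):
            raise ValueError("TAC length must equal the number of frames")
        if not np.all(np.isfinite(self.value)):
            raise ValueError("TAC values must be finite")
        if self.statistic not in ("mean", "max"):
            raise ValueError("statistic must be 'mean' or 'max'")

    @property
    def time(self) -> np.ndarray:
        """Frame midpoints in seconds."""
        return self.schedule.mid


@dataclass
class DynamicImage:
    """4D dynamic PET image (x, y, z, frame) in kBq/ml."""

    values: np.ndarray
    voxel_size: np.ndarray  # mm per axis
    schedule: FrameSchedule

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.voxel_size = np.asarray(self.voxel_size, dtype=float)
        if self.values.ndim != 4:
            raise ValueError("dynamic image must be 4-D")
        if self.values.shape[3] != self.schedule.n_frames:
            raise ValueError("frame axis must match the schedule length")
        if self.voxel_size.shape != (3,) or np.any(self.voxel_size <= 0):
            raise ValueError("voxel_size must be three positive numbers (mm)")

    @classmethod
    def from_nifti(cls, path, schedule: FrameSchedule) -> "DynamicImage":
        img = nib.load(str(path))
        zooms = img.header.get_zooms()[:3]
        return cls(np.asanyarray(img.dataobj), np.array(zooms), schedule)

    def to_nifti(self, path) -> None:
        affine = np.diag([*self.voxel_size, 1.0])
        nib.save(nib.Nifti1Image(self.values.astype(np.float32), affine), str(path))


@dataclass
class VOIMask:
    """Volume of interest as an explicit voxel-index set."""

    indices: np.ndarray  # (n, 3) integer voxel indices
    voxel_size: np.ndarray | None = None

    def __post_init__(self):
        self.indices = np.atleast_2d(np.asarray(self.indices, dtype=int))
        if self.indices.size == 0:
            raise ValueError("VOI mask is empty")
        if self.indices.shape[1] != 3:
            raise ValueError("indices must be (n, 3)")

    @classmethod
    def from_bool(cls, mask: np.ndarray, voxel_size=None) -> "VOIMask":
        return cls(np.argwhere(np.asarray(mask, dtype=bool)), voxel_size)

    def check_bounds(self, shape) -> None:
        shape = np.asarray(shape[:3])
        if np.any(self.indices < 0) or np.any(self.indices >= shape):
            raise IndexError("VOI mask indices fall outside the image grid")


def cubic_voi(center: tuple[int, int, int], edge_mm: float,
              voxel_size) -> VOIMask:
    """Cubic VOI of nominal edge length *edge_mm* (e.g. the 3x3x3 mm
    contralateral reference region), snapped to the nearest odd voxel count
    per axis and centred on *center* (voxel indices)."""
    voxel_size = np.asarray(voxel_size, dtype=float)
    counts = np.maximum(1, np.rint(edge_mm / voxel_size).astype(int))
    counts += (counts + 1) % 2  # odd counts so the cube is centred
    half = counts // 2
    ranges = [np.arange(c - h, c + h + 1) for c, h in zip(center, half)]
    grid = np.stack(np.meshgrid(*ranges, indexing="ij"), axis=-1).reshape(-1, 3)
    return VOIMask(grid, voxel_size)


def extract_voi_tac(img: DynamicImage, voi: VOIMask,
                    statistic: str = "mean") -> TimeActivityCurve:
    """Per-frame mean (or max) activity over the VOI voxels."""
    if statistic not in ("mean", "max"):
        raise ValueError("statistic must be 'mean' or 'max'")
    voi.check_bounds(img.values.shape)
    i, j, k = voi.indices.T
    block = img.values[i, j, k, :]  # (n_voxels, n_frames)
    value = block.mean(axis=0) if statistic == "mean" else block.max(axis=0)
    return TimeActivityCurve(img.schedule, value, statistic=statistic)


def compute_suv(tac: TimeActivityCurve, injected_dose_kbq: float,
                body_weight_g: float) -> TimeActivityCurve:
    """Body-weight SUV curve: ``SUV = C * weight / dose``.

    With C in kBq/ml, dose in kBq and weight in g, the result is unitless
    (g/ml, assuming unit tissue density).
    """
    if injected_dose_kbq <= 0:
        raise ValueError("injected dose must be positive")
    if body_weight_g <= 0:
        raise ValueError("body weight must be positive")
    suv = tac.value * body_weight_g / injected_dose_kbq
    return replace(tac, value=suv)


@dataclass(frozen=True)
class SUVReport:
    """Window-averaged SUV and lesion-to-normal ratios."""

    suv_mean: float
    suv_max: float
    lnr_mean: float
    lnr_max: float
    window_min: float

    def __post_init__(self):
        if not (self.suv_max >= self.suv_mean >= 0):
            raise ValueError("require suv_max >= suv_mean >= 0")
        if self.lnr_mean < 0 or self.lnr_max < 0:
            raise ValueError("LNRs must be non-negative")


def _window_average(tac: TimeActivityCurve, window_min: float) -> float:
    """Duration-weighted average over frames whose midpoint lies in the
    closed window covering the last *window_min* minutes of the acquisition."""
    t_end = tac.schedule.total_duration
    lo = t_end - window_min * 60.0
    sel = tac.schedule.mid >= lo - 1e-9
    if not np.any(sel):
        raise ValueError("averaging window contains no frames")
    w = tac.schedule.duration[sel]
    return float(np.sum(tac.value[sel] * w) / np.sum(w))


def compute_lnr(lesion_mean: TimeActivityCurve,
                lesion_max: TimeActivityCurve | None,
                reference_mean: TimeActivityCurve,
                window_min: float) -> SUVReport:
    """Lesion-to-normal-tissue ratios over a late uptake window.

    ``LNR_mean = SUVmean(lesion) / SUVmean(reference)`` and
    ``LNR_max = SUVmax(lesion) / SUVmean(reference)``, each averaged over the
    last *window_min* minutes (e.g. 20 min for FDG/FET, 10 min for FCho).
    *lesion_max* is the spatial-max TAC of the lesion VOI; if omitted, the
    report's max entries fall back to the temporal max of *lesion_mean*
    within the window.
    """
    if reference_mean.statistic != "mean":
        raise ValueError("reference curve must use the 'mean' statistic")
    if window_min * 60.0 > lesion_mean.schedule.total_duration + 1e-9:
        raise ValueError("window exceeds the acquisition length")
    ref = _window_average(reference_mean, window_min)
    if ref == 0:
        raise ZeroDivisionError("reference SUVmean is zero in the window")
    les_mean = _window_average(lesion_mean, window_min)
    if lesion_max is not None:
        if lesion_max.statistic != "max":
            raise ValueError("lesion_max curve must use the 'max' statistic")
        les_max = _window_average(lesion_max, window_min)
    else:
        t_end = lesion_mean.schedule.total_duration
        sel = lesion_mean.schedule.mid >= t_end - window_min * 60.0 - 1e-9
        les_max = float(np.max(lesion_mean.value[sel]))
    return SUVReport(suv_mean=les_mean, suv_max=les_max,
                     lnr_mean=les_mean / ref, lnr_max=les_max / ref,
                     window_min=window_min)
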