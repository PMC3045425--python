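"""Core I/O: dynamic-image / blood-table formats and the shared curve-interpolation contract.

Conventions used throughout the package:

* times are minutes post injection,
* activity concentrations are decay-corrected kBq/mL,
* 4D dynamic volumes are NIfTI-1 with a JSON sidecar carrying
  ``FrameStart`` / ``FrameDuration`` arrays in seconds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "FrameSchedule",
    "DynamicImage",
    "LabelMap",
    "BloodSeries",
    "InputFunction",
    "ValidationError",
    "FormatError",
    "load_dynamic_image",
    "save_dynamic_image",
    "load_blood_table",
    "save_curve_table",
    "load_curve_table",
    "interpolate_curve",
]

PROVENANCE_TAGS = (
    "arterial",
    "chen",
    "mourik",
    "naganawa",
    "su",
    "parker",
    "backes",
    "croteau",
)


class ValidationError(ValueError):
    """Input data violates a structural invariant."""


class FormatError(ValueError):
    """On-disk data does not match the expected format."""


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional")
    if arr.size == 0:
        raise ValidationError(f"{name} must be non-empty")
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} contains non-finite values")
    return arr


@dataclass(frozen=True)
class FrameSchedule:
    """Timing of a dynamic acquisition, in minutes.

    The default clinical schedule is 6 x 30 s, 3 x 60 s, 2 x 120 s and
    16 x 300 s (27 frames, 90 min analyzed span).
    """

    start_times: np.ndarray
    durations: np.ndarray

    def __post_init__(self):
        starts = _as_float_array(self.start_times, "start_times")
        durs = _as_float_array(self.durations, "durations")
        if starts.size != durs.size:
            raise ValidationError("start_times and durations differ in length")
        if np.any(np.diff(starts) <= 0):
            raise ValidationError("frame start times must be strictly increasing")
        if np.any(durs <= 0):
            raise ValidationError("frame durations must be positive")
        if np.any(starts[:-1] + durs[:-1] > starts[1:] + 1e-9):
            raise ValidationError("frames overlap")
        object.__setattr__(self, "start_times", starts)
        object.__setattr__(self, "durations", durs)

    @property
    def n_frames(self) -> int:
        return self.start_times.size

    @property
    def midpoints(self) -> np.ndarray:
        return self.start_times + self.durations / 2.0

    @property
    def end_times(self) -> np.ndarray:
        return self.start_times + self.durations

    @property
    def scan_end(self) -> float:
        return float(self.end_times[-1])

    @classmethod
    def from_block_lengths(cls, blocks: list[tuple[int, float]]) -> "FrameSchedule":
        """Build a schedule from ``[(count, duration_min), ...]`` blocks."""
        durs = np.concatenate([np.full(n, d, dtype=float) for n, d in blocks])
        starts = np.concatenate([[0.0], np.cumsum(durs)[:-1]])
        return cls(starts, durs)

    @classmethod
    def clinical_default(cls) -> "FrameSchedule":
        """6 x 30 s, 3 x 60 s, 2 x 120 s, 16 x 300 s: the 90-min analyzed span."""
        return cls.from_block_lengths([(6, 0.5), (3, 1.0), (2, 2.0), (16, 5.0)])


@dataclass
class DynamicImage:
    """4D dynamic PET volume (decay-corrected kBq/mL) with its frame schedule."""

    voxels: np.ndarray
    voxel_size: np.ndarray  # mm per axis
    schedule: FrameSchedule

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 4:
            raise ValidationError("voxels must be a 4D array (x, y, z, frame)")
        if self.voxels.shape[3] != self.schedule.n_frames:
            raise FormatError(
                f"image has {self.voxels.shape[3]} frames but schedule lists "
                f"{self.schedule.n_frames}"
            )
        if not np.all(np.isfinite(self.voxels)):
            raise ValidationError("image contains non-finite voxels")
        self.voxel_size = np.asarray(self.voxel_size, dtype=float).reshape(3)
        if np.any(self.voxel_size <= 0):
            raise ValidationError("voxel_size must be positive")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.voxels.shape

    def frame(self, i: int) -> np.ndarray:
        return self.voxels[..., i]

    def roi_tac(self, mask: np.ndarray) -> np.ndarray:
        """Mean time-activity curve over a boolean mask."""
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise ValidationError("empty ROI mask")
        return self.voxels[mask, :].mean(axis=0)


@dataclass
class LabelMap:
    """3D integer label volume with a label-id -> region-name map."""

    labels: np.ndarray
    names: dict[int, str]
    voxel_size: np.ndarray = field(default_factory=lambda: np.ones(3))

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValidationError("labels must be a 3D volume")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValidationError("labels must be integer-valued")
        self.voxel_size = np.asarray(self.voxel_size, dtype=float).reshape(3)
        present = set(np.unique(self.labels).tolist()) - {0}
        missing = present - set(self.names)
        if missing:
            raise ValidationError(f"label ids without names: {sorted(missing)}")

    def mask(self, name: str) -> np.ndarray:
        ids = [k for k, v in self.names.items() if v == name]
        if not ids:
            raise KeyError(f"no label named {name!r}")
        return np.isin(self.labels, ids)

    @property
    def region_names(self) -> list[str]:
        return [self.names[k] for k in sorted(self.names)]


@dataclass
class BloodSeries:
    """Discrete arterial samples: whole blood, total plasma and parent fraction."""

    times: np.ndarray
    whole_blood: np.ndarray
    plasma: np.ndarray
    parent_fraction: np.ndarray

    def __post_init__(self):
        self.times = _as_float_array(self.times, "times")
        self.whole_blood = _as_float_array(self.whole_blood, "whole_blood")
        self.plasma = _as_float_array(self.plasma, "plasma")
        self.parent_fraction = _as_float_array(self.parent_fraction, "parent_fraction")
        n = self.times.size
        for name in ("whole_blood", "plasma", "parent_fraction"):
            if getattr(self, name).size != n:
                raise ValidationError(f"{name} length does not match times")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError("sample times must be strictly increasing")
        if np.any(self.whole_blood < 0) or np.any(self.plasma < 0):
            raise ValidationError("activities must be non-negative")
        if np.any(self.parent_fraction < 0) or np.any(self.parent_fraction > 1):
            raise ValidationError("parent_fraction must lie in [0, 1]")

    def whole_blood_at(self, t) -> np.ndarray:
        return interpolate_curve(self.times, self.whole_blood, np.atleast_1d(t))


@dataclass
class InputFunction:
    """Continuous input curve: whole blood and, once metabolite-corrected, parent plasma."""

    times: np.ndarray
    whole_blood: np.ndarray
    parent_plasma: np.ndarray | None = None
    provenance: str = "arterial"

    def __post_init__(self):
        self.times = _as_float_array(self.times, "times")
        self.whole_blood = _as_float_array(self.whole_blood, "whole_blood")
        if self.whole_blood.size != self.times.size:
            raise ValidationError("whole_blood length does not match times")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError("times must be strictly increasing")
        if np.any(self.whole_blood < -1e-9):
            raise ValidationError("whole_blood must be non-negative")
        self.whole_blood = np.maximum(self.whole_blood, 0.0)
        if self.parent_plasma is not None:
            pp = _as_float_array(self.parent_plasma, "parent_plasma")
            if pp.size != self.times.size:
                raise ValidationError("parent_plasma length does not match times")
            if np.any(pp < -1e-9):
                raise ValidationError("parent_plasma must be non-negative")
            self.parent_plasma = np.maximum(pp, 0.0)
        if self.provenance not in PROVENANCE_TAGS:
            raise ValidationError(f"unknown provenance tag {self.provenance!r}")

    def whole_blood_at(self, t) -> np.ndarray:
        return interpolate_curve(self.times, self.whole_blood, np.atleast_1d(t))

    def parent_plasma_at(self, t) -> np.ndarray:
        if self.parent_plasma is None:
            raise ValidationError("input function has no parent_plasma curve")
        return interpolate_curve(self.times, self.parent_plasma, np.atleast_1d(t))


# ---------------------------------------------------------------------------
# NIfTI + sidecar round trip


def save_dynamic_image(image: DynamicImage, path, sidecar_path) -> None:
    """Write a 4D NIfTI plus a JSON timing sidecar (seconds, BIDS-like keys)."""
    affine = np.diag(list(image.voxel_size) + [1.0])
    nib.save(nib.Nifti1Image(image.voxels.astype(np.float64), affine), str(path))
    sidecar = {
        "FrameStart": (image.schedule.start_times * 60.0).tolist(),
        "FrameDuration": (image.schedule.durations * 60.0).tolist(),
        "Units": "kBq/mL",
    }
    Path(sidecar_path).write_text(json.dumps(sidecar, indent=1))


def load_dynamic_image(path, sidecar_path) -> DynamicImage:
    """Load a 4D NIfTI and its JSON timing sidecar into a validated DynamicImage."""
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    if data.ndim != 4:
        raise FormatError(f"{path} is {data.ndim}D; expected a 4D dynamic image")
    meta = json.loads(Path(sidecar_path).read_text())
    try:
        starts = np.asarray(meta["FrameStart"], dtype=float) / 60.0
        durs = np.asarray(meta["FrameDuration"], dtype=float) / 60.0
    except KeyError as exc:
        raise FormatError(f"sidecar missing key: {exc}") from exc
    schedule = FrameSchedule(starts, durs)
    if schedule.n_frames != data.shape[3]:
        raise FormatError(
            f"sidecar lists {schedule.n_frames} frames but image has {data.shape[3]}"
        )
    voxel_size = np.asarray(img.header.get_zooms()[:3], dtype=float)
    return DynamicImage(data, voxel_size, schedule)


def save_label_map(label_map: LabelMap, path, names_path) -> None:
    affine = np.diag(list(label_map.voxel_size) + [1.0])
    nib.save(nib.Nifti1Image(label_map.labels.astype(np.int16), affine), str(path))
    Path(names_path).write_text(
        json.dumps({str(k): v for k, v in label_map.names.items()}, indent=1)
    )


def load_label_map(path, names_path) -> LabelMap:
    img = nib.load(str(path))
    labels = np.asarray(img.dataobj).astype(np.int32)
    names = {int(k): v for k, v in json.loads(Path(names_path).read_text()).items()}
    voxel_size = np.asarray(img.header.get_zooms()[:3], dtype=float)
    return LabelMap(labels, names, voxel_size)


# ---------------------------------------------------------------------------
# CSV tables

_BLOOD_COLUMNS = ["time_min", "whole_blood_kBq_ml", "plasma_kBq_ml", "parent_fraction"]


def load_blood_table(path) -> BloodSeries:
    """Read an arterial sample table (CSV with '#' comments)."""
    df = pd.read_csv(path, comment="#")
    missing = [c for c in _BLOOD_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"blood table missing columns: {missing}")
    return BloodSeries(
        df["time_min"].to_numpy(),
        df["whole_blood_kBq_ml"].to_numpy(),
        df["plasma_kBq_ml"].to_numpy(),
        df["parent_fraction"].to_numpy(),
    )


def save_blood_table(series: BloodSeries, path) -> None:
    df = pd.DataFrame(
        {
            "time_min": series.times,
            "whole_blood_kBq_ml": series.whole_blood,
            "plasma_kBq_ml": series.plasma,
            "parent_fraction": series.parent_fraction,
        }
    )
    df.to_csv(path, index=False)


def save_curve_table(input_function: InputFunction, path) -> None:
    """Write an input-function curve as CSV, provenance in a header comment."""
    data = {"time_min": input_function.times, "whole_blood_kBq_ml": input_function.whole_blood}
    if input_function.parent_plasma is not None:
        data["parent_plasma_kBq_ml"] = input_function.parent_plasma
    with open(path, "w") as fh:
        fh.write(f"# provenance: {input_function.provenance}\n")
        pd.DataFrame(data).to_csv(fh, index=False)


def load_curve_table(path) -> InputFunction:
    provenance = "arterial"
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# provenance:"):
            provenance = first.split(":", 1)[1].strip()
    df = pd.read_csv(path, comment="#")
    if df.empty:
        raise FormatError("empty curve table")
    return InputFunction(
        df["time_min"].to_numpy(),
        df["whole_blood_kBq_ml"].to_numpy(),
        df["parent_plasma_kBq_ml"].to_numpy() if "parent_plasma_kBq_ml" in df else None,
        provenance=provenance,
    )


# ---------------------------------------------------------------------------
# Interpolation contract


def interpolate_curve(times, values, query_times, mode: str = "linear") -> np.ndarray:
    """Linear interpolation with the package-wide extrapolation contract.

    Before the first sample the curve rises linearly from (0, 0); after the
    last sample the final value is held.  ``mode='frame_start'`` accepts a
    FrameSchedule as ``query_times`` and evaluates at frame start times (the
    convention used for metabolite correction).
    """
    times = _as_float_array(times, "times")
    values = _as_float_array(values, "values")
    if times.size != values.size:
        raise ValidationError("times and values differ in length")
    if np.any(np.diff(times) <= 0):
        raise ValidationError("times must be strictly increasing")
    if mode == "frame_start":
        if not isinstance(query_times, FrameSchedule):
            raise ValidationError("mode='frame_start' expects a FrameSchedule")
        query = query_times.start_times
    elif mode == "linear":
        query = np.asarray(query_times, dtype=float)
    else:
        raise ValidationError(f"unknown interpolation mode {mode!r}")

    out = np.interp(query, times, values)
    # left extrapolation: linear from (0, 0) to the first sample
    before = query < times[0]
    if np.any(before):
        t0 = times[0]
        if t0 > 0:
            out = np.where(before, values[0] * np.clip(query, 0.0, None) / t0, out)
        else:
            out = np.where(before, values[0], out)
    return out
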