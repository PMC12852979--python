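"""Domain containers and on-disk formats.

Every other module consumes and produces the types defined here:
:class:`TensileTest` for mechanical traces, :class:`CTVolume` for calibrated
attenuation grids, and :class:`StudyTable` for the paired control/damaged
study design.  Traces travel as delimited text (CSV/TSV), volumes as
multipage TIFF or NIfTI-1 stacks, reports as CSV + JSON.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger(__name__)

#: unit scale factors into the canonical (s, mm, N) system
_TIME_UNITS = {"s": 1.0, "ms": 1e-3, "min": 60.0}
_LENGTH_UNITS = {"mm": 1.0, "m": 1e3, "um": 1e-3}
_FORCE_UNITS = {"N": 1.0, "mN": 1e-3, "kN": 1e3}

GROUPS = ("control", "damaged")
AGENTS = ("iodixanol", "Ta2O5-cNP", "none")

#: nominal immersion timepoints (hours) per contrast agent
AGENT_TIMEPOINTS_H = {
    "iodixanol": (0.75, 1.5, 3.0, 5.0, 8.0, 22.0),
    "Ta2O5-cNP": (3.0, 8.0, 22.0, 46.0, 72.0),
}


class ValidationError(ValueError):
    """A domain invariant was violated while constructing an object."""


@dataclass(frozen=True)
class Geometry:
    """Dumbbell sample geometry.

    ``clamp_length_mm`` is the zero-load clamp-to-clamp distance, determined
    on the device by applying a 0.05 MPa tensile preload.
    """

    width_mm: float
    thickness_mm: float
    clamp_length_mm: float

    def __post_init__(self) -> None:
        for name in ("width_mm", "thickness_mm", "clamp_length_mm"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValidationError(f"geometry: {name} must be > 0, got {v!r}")


@dataclass(frozen=True)
class Segment:
    """A labeled half-open time interval ``[t0, t1)`` of the test protocol."""

    label: str
    t0: float
    t1: float

    def __post_init__(self) -> None:
        if not self.t1 > self.t0:
            raise ValidationError(f"segment {self.label!r}: t1 must exceed t0")


# protocol segment labels; post-damage repeats carry a "post_" prefix
SEGMENT_LABELS = (
    "preconditioning",
    "rezero",
    "ramp8",
    "hold8",
    "sinusoid@0.1",
    "sinusoid@0.5",
    "sinusoid@1",
    "sinusoid@2",
    "ramp16",
    "hold2s",
    "return",
    "post_ramp8",
    "post_hold8",
    "post_sinusoid@0.1",
    "post_sinusoid@0.5",
    "post_sinusoid@1",
    "post_sinusoid@2",
)

#: segments that only a damaged-group test may (and must) contain
DAMAGE_SEGMENTS = ("ramp16", "hold2s", "return", "post_ramp8", "post_hold8")


@dataclass
class TensileTest:
    """A raw mechanical trace with protocol annotations.

    ``time`` is seconds (strictly increasing), ``displacement`` mm relative to
    the zero-load clamp-to-clamp length, ``force`` N.
    """

    time: np.ndarray
    displacement: np.ndarray
    force: np.ndarray
    segments: list[Segment]
    geometry: Geometry
    sample_id: str
    group: str

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.displacement = np.asarray(self.displacement, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if not (self.time.shape == self.displacement.shape == self.force.shape):
            raise ValidationError("trace arrays must share one shape")
        dt = np.diff(self.time)
        if dt.size and not np.all(dt > 0):
            bad = int(np.argmin(dt > 0)) + 1
            raise ValidationError(f"time not strictly increasing at row {bad}")
        if self.group not in GROUPS:
            raise ValidationError(f"group must be one of {GROUPS}, got {self.group!r}")
        self._check_segments()

    def _check_segments(self) -> None:
        segs = sorted(self.segments, key=lambda s: s.t0)
        for a, b in zip(segs, segs[1:]):
            if b.t0 < a.t1 - 1e-12:
                raise ValidationError(f"segments {a.label!r} and {b.label!r} overlap")
        if segs:
            # segments are half-open [t0, t1); the final t1 may exceed the last
            # sample by up to one sampling interval
            dt = float(np.median(np.diff(self.time))) if self.time.size > 1 else 0.0
            t_lo, t_hi = self.time[0], self.time[-1]
            if segs[0].t0 < t_lo - 1e-9 or segs[-1].t1 > t_hi + dt + 1e-9:
                raise ValidationError("segments extend beyond the recorded time range")
        labels = {s.label for s in self.segments}
        has_damage = any(lbl in labels for lbl in DAMAGE_SEGMENTS)
        if self.group == "damaged" and self.segments and not has_damage:
            raise ValidationError("damaged-group test lacks overstrain segments")
        if self.group == "control" and has_damage:
            raise ValidationError("control-group test contains overstrain segments")

    def segment(self, label: str) -> Segment:
        for s in self.segments:
            if s.label == label:
                return s
        raise KeyError(f"no segment labeled {label!r}")

    def segment_slice(self, label: str) -> slice:
        """Index slice of the samples inside segment ``label`` (t1 exclusive)."""
        s = self.segment(label)
        i0 = int(np.searchsorted(self.time, s.t0 - 1e-12, side="left"))
        i1 = int(np.searchsorted(self.time, s.t1 - 1e-12, side="left"))
        return slice(i0, i1)

    @property
    def length(self) -> np.ndarray:
        """Clamp-to-clamp length in mm at every sample."""
        return self.geometry.clamp_length_mm + self.displacement


@dataclass
class CTVolume:
    """A 3D attenuation grid, axis order (z, y, x) with z the fascicle axis."""

    intensities: np.ndarray
    voxel_size_um: float = 16.99
    calibrated: bool = False
    water_roi: np.ndarray | None = None
    air_roi: np.ndarray | None = None
    timepoint_h: float | None = None
    agent: str = "none"
    bath_hu: float | None = None
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float32)
        if self.intensities.ndim != 3:
            raise ValidationError("intensities must be a 3D grid")
        if not self.voxel_size_um > 0:
            raise ValidationError("voxel_size_um must be > 0")
        if self.agent not in AGENTS:
            raise ValidationError(f"agent must be one of {AGENTS}")
        for name in ("water_roi", "air_roi"):
            roi = getattr(self, name)
            if roi is not None:
                roi = np.asarray(roi, dtype=bool)
                if roi.shape != self.intensities.shape:
                    raise ValidationError(f"{name} shape differs from the grid")
                setattr(self, name, roi)
        if self.calibrated and self.water_roi is not None and self.water_roi.any():
            m = float(self.intensities[self.water_roi].mean())
            if not -15.0 <= m <= 15.0:
                raise ValidationError(
                    f"calibrated volume has water ROI mean {m:.1f} HU outside [-15, 15]"
                )

    def roi_mean(self, roi: np.ndarray) -> float:
        roi = np.asarray(roi, dtype=bool)
        if not roi.any():
            raise ValidationError("empty ROI")
        return float(self.intensities[roi].mean())


@dataclass
class StudyRow:
    """One subsample: a ligament x group x agent cell of the design."""

    ligament_id: str
    group: str
    agent: str
    trace_path: str | None = None
    volume_paths: tuple[str, ...] = ()
    excluded: bool = False


@dataclass
class StudyTable:
    """Paired control/damaged study design with optional attached objects.

    ``traces`` maps (ligament_id, group) to a TensileTest; ``volumes`` maps
    (ligament_id, group, agent) to an ordered volume series (native first);
    ``truth`` carries generator ground truth when the cohort is synthetic.
    """

    rows: list[StudyRow] = field(default_factory=list)
    traces: dict = field(default_factory=dict)
    volumes: dict = field(default_factory=dict)
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        by_lig: dict[str, set[str]] = {}
        for r in self.rows:
            by_lig.setdefault(r.ligament_id, set()).add(r.group)
        for lig, groups in by_lig.items():
            complete = groups == set(GROUPS)
            if not complete:
                for r in self.rows:
                    if r.ligament_id == lig and not r.excluded:
                        raise ValidationError(
                            f"ligament {lig!r} has an incomplete pair and is not excluded"
                        )

    @property
    def ligament_ids(self) -> list[str]:
        seen: list[str] = []
        for r in self.rows:
            if r.ligament_id not in seen:
                seen.append(r.ligament_id)
        return seen


# ---------------------------------------------------------------------------
# tensile traces
# ---------------------------------------------------------------------------

def read_tensile_trace(
    path: str | Path,
    geometry: Geometry | Mapping[str, float],
    segment_map: Mapping[str, tuple[float, float]] | Sequence[Segment],
    *,
    sample_id: str = "",
    group: str = "control",
    units: Mapping[str, str] | None = None,
) -> TensileTest:
    """Read a delimited mechanical trace into a validated :class:`TensileTest`.

    The file must have a header with columns ``time``, ``displacement`` and
    ``force`` (comma- or tab-delimited).  ``units`` maps those column names to
    source units (defaults ``s``/``mm``/``N``); any conversion applied is
    logged with source and target unit.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python")
    df.columns = [c.strip().lower() for c in df.columns]
    missing = {"time", "displacement", "force"} - set(df.columns)
    if missing:
        raise ValidationError(f"{path.name}: missing column(s) {sorted(missing)}")

    units = dict(units or {})
    scales = {
        "time": _TIME_UNITS[units.get("time", "s")],
        "displacement": _LENGTH_UNITS[units.get("displacement", "mm")],
        "force": _FORCE_UNITS[units.get("force", "N")],
    }
    for col, scale in scales.items():
        if scale != 1.0:
            logger.info(
                "converting %s from %s to canonical unit (x%g)", col, units[col], scale
            )
    time = df["time"].to_numpy(dtype=float) * scales["time"]
    dt = np.diff(time)
    if np.any(dt <= 0):
        bad = int(np.argmax(dt <= 0)) + 1
        raise ValidationError(f"{path.name}: time non-monotone at row {bad}")

    if isinstance(geometry, Mapping):
        geometry = Geometry(**geometry)
    if isinstance(segment_map, Mapping):
        segments = [Segment(lbl, t0, t1) for lbl, (t0, t1) in segment_map.items()]
    else:
        segments = list(segment_map)
    return TensileTest(
        time=time,
        displacement=df["displacement"].to_numpy(dtype=float) * scales["displacement"],
        force=df["force"].to_numpy(dtype=float) * scales["force"],
        segments=segments,
        geometry=geometry,
        sample_id=sample_id,
        group=group,
    )


def write_tensile_trace(test: TensileTest, path: str | Path) -> Path:
    """Write the trace as CSV plus a JSON sidecar with geometry and segments."""
    path = Path(path)
    df = pd.DataFrame(
        {"time": test.time, "displacement": test.displacement, "force": test.force}
    )
    df.to_csv(path, index=False, float_format="%.17g")
    sidecar = {
        "sample_id": test.sample_id,
        "group": test.group,
        "geometry": {
            "width_mm": test.geometry.width_mm,
            "thickness_mm": test.geometry.thickness_mm,
            "clamp_length_mm": test.geometry.clamp_length_mm,
        },
        "segments": {s.label: [s.t0, s.t1] for s in test.segments},
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    return path


def read_tensile_trace_with_sidecar(path: str | Path) -> TensileTest:
    """Read a trace written by :func:`write_tensile_trace`."""
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    return read_tensile_trace(
        path,
        Geometry(**meta["geometry"]),
        {lbl: tuple(t) for lbl, t in meta["segments"].items()},
        sample_id=meta["sample_id"],
        group=meta["group"],
    )


# ---------------------------------------------------------------------------
# CT volumes
# ---------------------------------------------------------------------------

def _roi_from_spec(spec, shape) -> np.ndarray | None:
    """Accept a boolean mask or a {'z': [a,b], 'y': [a,b], 'x': [a,b]} box."""
    if spec is None:
        return None
    if isinstance(spec, np.ndarray):
        return spec.astype(bool)
    mask = np.zeros(shape, dtype=bool)
    z, y, x = (tuple(spec[k]) for k in ("z", "y", "x"))
    mask[z[0]:z[1], y[0]:y[1], x[0]:x[1]] = True
    return mask


def read_volume(path: str | Path) -> np.ndarray:
    """Read a multipage TIFF or NIfTI-1 stack as a (z, y, x) float32 grid."""
    path = Path(path)
    if path.suffix in {".nii", ".gz"} or path.name.endswith(".nii.gz"):
        img = nib.load(str(path))
        # NIfTI stores (x, y, z); transpose into our (z, y, x) convention
        return np.ascontiguousarray(np.asanyarray(img.dataobj).T.astype(np.float32))
    return tifffile.imread(str(path)).astype(np.float32)


def write_volume(volume: CTVolume | np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    data = volume.intensities if isinstance(volume, CTVolume) else np.asarray(volume)
    data = data.astype(np.float32)
    if path.suffix in {".nii", ".gz"} or path.name.endswith(".nii.gz"):
        nib.save(nib.Nifti1Image(data.T, affine=np.eye(4)), str(path))
    else:
        tifffile.imwrite(str(path), data, photometric="minisblack")
    return path


def read_volume_series(
    paths: Sequence[str | Path],
    metadata: Sequence[Mapping] | Mapping,
) -> list[CTVolume]:
    """Read an immersion time series of volumes, sorted native-first.

    ``metadata`` is one mapping per path (or one shared mapping) supplying
    ``timepoint_h`` (None/absent for the native scan), ``agent``,
    ``voxel_size_um``, ``bath_hu`` and optional ``water_roi``/``air_roi``
    (boolean masks or index boxes).
    """
    if isinstance(metadata, Mapping):
        metadata = [metadata] * len(paths)
    if len(metadata) != len(paths):
        raise ValidationError("one metadata mapping required per path")
    volumes: list[CTVolume] = []
    shapes = []
    for path, meta in zip(paths, metadata):
        grid = read_volume(path)
        shapes.append(grid.shape)
        volumes.append(
            CTVolume(
                intensities=grid,
                voxel_size_um=float(meta.get("voxel_size_um", 16.99)),
                calibrated=bool(meta.get("calibrated", False)),
                water_roi=_roi_from_spec(meta.get("water_roi"), grid.shape),
                air_roi=_roi_from_spec(meta.get("air_roi"), grid.shape),
                timepoint_h=meta.get("timepoint_h"),
                agent=meta.get("agent", "none"),
                bath_hu=meta.get("bath_hu"),
                sample_id=meta.get("sample_id", ""),
            )
        )
    if len(set(shapes)) > 1:
        raise ValidationError(f"grid shapes differ across timepoints: {shapes}")
    volumes.sort(key=lambda v: (-np.inf if v.timepoint_h is None else v.timepoint_h))
    return volumes


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

def write_report(results: pd.DataFrame | Sequence[Mapping], out_path: str | Path) -> Path:
    """Write a results table (one row per subsample per parameter) plus a JSON
    summary; column order and row order are deterministic so identical results
    produce byte-identical files."""
    out_path = Path(out_path)
    df = pd.DataFrame(results)
    if df.empty:
        df = pd.DataFrame(columns=["sample_id", "group", "parameter", "value"])
    df = df.reindex(columns=sorted(df.columns))
    sort_cols = [c for c in ("sample_id", "group", "agent", "parameter") if c in df.columns]
    if sort_cols:
        df = df.sort_values(sort_cols, kind="mergesort").reset_index(drop=True)
    df.to_csv(out_path, index=False, float_format="%.10g")
    summary = {
        "n_rows": int(len(df)),
        "columns": list(df.columns),
    }
    if "parameter" in df.columns and "value" in df.columns and len(df):
        grouped = df.groupby("parameter")["value"].agg(["mean", "std", "count"])
        summary["parameters"] = {
            str(k): {
                "mean": None if pd.isna(v["mean"]) else float(v["mean"]),
                "sd": None if pd.isna(v["std"]) else float(v["std"]),
                "n": int(v["count"]),
            }
            for k, v in grouped.iterrows()
        }
    out_path.with_suffix(".summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True)
    )
    return out_path


__all__ = [
    "AGENT_TIMEPOINTS_H",
    "AGENTS",
    "CTVolume",
    "DAMAGE_SEGMENTS",
    "Geometry",
    "GROUPS",
    "Segment",
    "SEGMENT_LABELS",
    "StudyRow",
    "StudyTable",
    "TensileTest",
    "ValidationError",
    "read_tensile_trace",
    "read_tensile_trace_with_sidecar",
    "read_volume",
    "read_volume_series",
    "write_report",
    "write_tensile_trace",
    "write_volume",
]
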