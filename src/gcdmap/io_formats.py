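"""File formats, configuration and run logging.

Images travel as NIfTI-1 (optionally gzipped), cohort manifests and metric
tables as TSV, configuration as YAML.  Voxel coordinates are 0-based array
indices throughout; world coordinates exist only through the affine.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("gcdmap")

GROUP_LABELS = ("substate_A", "substate_B")


class ImageReadError(ValueError):
    """Raised when a file cannot be interpreted as the expected image."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ImageVolume:
    """A 3D or 4D real-valued image with its voxel-to-world transform.

    Parameters
    ----------
    data
        3D (mask/map) or 4D (time series, time last) array.
    affine
        4x4 invertible voxel-to-world transform.
    tr_seconds
        Sampling interval of the time axis; required for 4D data.
    """

    data: np.ndarray
    affine: np.ndarray
    tr_seconds: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim not in (3, 4):
            raise ValueError(f"expected 3D or 4D data, got {self.data.ndim}D")
        if any(s <= 0 for s in self.data.shape):
            raise ValueError("all dimensions must be positive")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine must be invertible")
        if self.data.ndim == 4:
            if self.tr_seconds is None or not self.tr_seconds > 0:
                raise ValueError(
                    "4D volume requires tr_seconds > 0; supply the sampling "
                    "interval via config if the header lacks it"
                )

    @property
    def voxel_size_mm(self) -> tuple[float, float, float]:
        scales = np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))
        return tuple(float(s) for s in scales)

    @property
    def n_timepoints(self) -> int:
        if self.data.ndim != 4:
            raise ValueError("not a 4D volume")
        return self.data.shape[3]


@dataclass
class MotionParams:
    """Six rigid-body parameters per retained timepoint."""

    translations_mm: np.ndarray  # T x 3
    rotations_rad: np.ndarray  # T x 3

    def __post_init__(self) -> None:
        self.translations_mm = np.atleast_2d(np.asarray(self.translations_mm, dtype=float))
        self.rotations_rad = np.atleast_2d(np.asarray(self.rotations_rad, dtype=float))
        if self.translations_mm.shape[1] != 3 or self.rotations_rad.shape[1] != 3:
            raise ValueError("motion parameters must have 3 translation and 3 rotation columns")
        if self.translations_mm.shape[0] != self.rotations_rad.shape[0]:
            raise ValueError("translation and rotation row counts differ")

    @property
    def n_timepoints(self) -> int:
        return self.translations_mm.shape[0]

    def as_matrix(self) -> np.ndarray:
        return np.hstack([self.translations_mm, self.rotations_rad])


MANIFEST_COLUMNS = [
    "subject_id",
    "group_label",
    "image_path",
    "motion_path",
    "age",
    "sex",
    "duration",
]


@dataclass
class CohortManifest:
    """Subject table binding images, motion files, labels and covariates."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in MANIFEST_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"manifest missing columns: {missing}")
        ids = self.table["subject_id"]
        if ids.duplicated().any():
            raise ValueError("subject_ids must be unique")
        bad = set(self.table["group_label"]) - set(GROUP_LABELS)
        if bad:
            raise ValueError(f"unknown group labels {bad}; expected {GROUP_LABELS}")

    def __len__(self) -> int:
        return len(self.table)

    def __iter__(self) -> Iterator[pd.Series]:
        return (row for _, row in self.table.iterrows())

    @property
    def labels(self) -> np.ndarray:
        return self.table["group_label"].to_numpy()

    def require_both_groups(self) -> None:
        present = set(self.table["group_label"])
        if present != set(GROUP_LABELS):
            raise ValueError(f"classification needs both groups; found {sorted(present)}")


# ---------------------------------------------------------------------------
# image I/O
# ---------------------------------------------------------------------------


def read_image(path: str | Path, tr_seconds: float | None = None) -> ImageVolume:
    """Read a NIfTI-1 file into an :class:`ImageVolume`.

    The TR is taken from the header's fourth zoom (seconds); a 4D file whose
    header carries no usable TR is a hard error unless ``tr_seconds`` is
    given explicitly.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types for bad payloads
        raise ImageReadError(f"{path} is not a readable NIfTI-1 file: {exc}") from exc
    data = np.asanyarray(img.dataobj).astype(np.float64)
    if data.ndim == 4:
        if tr_seconds is None:
            zooms = img.header.get_zooms()
            header_tr = float(zooms[3]) if len(zooms) > 3 else 0.0
            units = img.header.get_xyzt_units()[1]
            if units == "msec":
                header_tr /= 1000.0
            elif units == "usec":
                header_tr /= 1e6
            if header_tr <= 0:
                raise ImageReadError(
                    f"{path}: 4D image with zero/absent TR in header; "
                    "supply tr_seconds via config"
                )
            tr_seconds = header_tr
        return ImageVolume(data, img.affine, tr_seconds=tr_seconds)
    return ImageVolume(data, img.affine)


def write_image(volume: ImageVolume, path: str | Path) -> Path:
    """Write an :class:`ImageVolume` as NIfTI-1 (32-bit float payload)."""
    path = Path(path)
    img = nib.Nifti1Image(volume.data.astype(np.float32), volume.affine)
    if volume.data.ndim == 4:
        zooms = list(img.header.get_zooms())
        zooms[3] = volume.tr_seconds
        img.header.set_zooms(zooms)
        img.header.set_xyzt_units("mm", "sec")
    else:
        img.header.set_xyzt_units("mm")
    nib.save(img, str(path))
    return path


def read_motion_params(
    path: str | Path,
    degrees: bool = False,
    n_timepoints: int | None = None,
) -> MotionParams:
    """Read a 6-column whitespace-delimited motion-parameter file.

    Columns 1-3 are translations (mm), 4-6 rotations (radians, or degrees
    when ``degrees`` is set).  ``n_timepoints`` enforces agreement with the
    retained volume count.
    """
    path = Path(path)
    try:
        mat = np.loadtxt(str(path), ndmin=2)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric motion parameter rows: {exc}") from exc
    if mat.shape[1] != 6:
        raise ValueError(f"{path}: expected 6 columns, found {mat.shape[1]}")
    if n_timepoints is not None and mat.shape[0] != n_timepoints:
        raise ValueError(
            f"{path}: {mat.shape[0]} motion rows vs {n_timepoints} image timepoints"
        )
    rot = mat[:, 3:6]
    if degrees:
        rot = np.deg2rad(rot)
    return MotionParams(mat[:, 0:3], rot)


def write_motion_params(motion: MotionParams, path: str | Path) -> Path:
    path = Path(path)
    np.savetxt(str(path), motion.as_matrix(), fmt="%.8f")
    return path


# ---------------------------------------------------------------------------
# manifests, tables, config
# ---------------------------------------------------------------------------


def read_manifest(path: str | Path) -> CohortManifest:
    table = pd.read_csv(path, sep="\t")
    return CohortManifest(table)


def write_manifest(manifest: CohortManifest, path: str | Path) -> Path:
    path = Path(path)
    manifest.table.to_csv(path, sep="\t", index=False)
    return path


GCD_METRICS = ("inflow", "outflow", "totalflow", "intflow")


def write_gcd_maps(maps, mask: ImageVolume, out_prefix: str | Path) -> list[Path]:
    """Write one 3D NIfTI per GCD metric; NaN outside the mask.

    Filenames embed the metric name: ``<prefix>_<metric>.nii.gz``.
    """
    out_prefix = Path(out_prefix)
    mask_bool = mask.data.astype(bool)
    written = []
    for metric in GCD_METRICS:
        vol = np.full(mask_bool.shape, np.nan)
        values = getattr(maps, _METRIC_ATTR[metric])
        idx = tuple(maps.voxel_index.T)
        vol[idx] = values
        p = out_prefix.parent / f"{out_prefix.name}_{metric}.nii.gz"
        write_image(ImageVolume(vol, mask.affine), p)
        written.append(p)
    return written


_METRIC_ATTR = {
    "inflow": "inflow",
    "outflow": "outflow",
    "totalflow": "total_flow",
    "intflow": "int_flow",
}


def read_gcd_maps(out_prefix: str | Path, alpha: float = 0.05, lag_order: int = 1):
    """Re-read the four metric files written by :func:`write_gcd_maps`."""
    from .gcd_core import GcdMaps  # local import to avoid a cycle

    out_prefix = Path(out_prefix)
    arrays = {}
    for metric in GCD_METRICS:
        p = out_prefix.parent / f"{out_prefix.name}_{metric}.nii.gz"
        arrays[metric] = read_image(p)
    inflow_vol = arrays["inflow"].data
    voxel_index = np.argwhere(np.isfinite(inflow_vol))
    idx = tuple(voxel_index.T)
    return GcdMaps(
        inflow=arrays["inflow"].data[idx],
        outflow=arrays["outflow"].data[idx],
        voxel_index=voxel_index,
        alpha=alpha,
        lag_order=lag_order,
    )


def load_config(path: str | Path | None) -> dict:
    if path is None:
        return {}
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config file must contain a YAML mapping")
    return cfg


def config_hash(cfg: dict) -> str:
    payload = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


# ---------------------------------------------------------------------------
# run logging
# ---------------------------------------------------------------------------


class RunLog:
    """Plain-text run log recording config hash, seed and per-stage timings."""

    def __init__(self, log_path: str | Path | None, cfg: dict, seed: int | None):
        self.path = Path(log_path) if log_path else None
        self._t0: dict[str, float] = {}
        self._lines: list[str] = []
        self.record(f"config_hash={config_hash(cfg)} seed={seed}")

    def record(self, line: str) -> None:
        stamp = time.strftime("%Y-%m-%dT%H:%M:%S")
        entry = f"{stamp} {line}"
        self._lines.append(entry)
        logger.info(line)
        if self.path:
            with open(self.path, "a") as fh:
                fh.write(entry + "\n")

    def start(self, stage: str) -> None:
        self._t0[stage] = time.perf_counter()

    def stop(self, stage: str) -> float:
        dt = time.perf_counter() - self._t0.pop(stage)
        self.record(f"stage={stage} seconds={dt:.3f}")
        return dt
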