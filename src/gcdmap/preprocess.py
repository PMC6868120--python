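"""Temporal preprocessing ahead of causality estimation.

The chain, in fixed order: discard initial volumes -> framewise-displacement
scrubbing with linear interpolation -> nuisance regression (Friston-24 motion
expansion plus global signal) -> linear detrend -> zero-phase band-pass.
Spatial steps (registration, smoothing) are out of scope; the input is a 4D
volume already on a common grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .io_formats import ImageVolume, MotionParams

logger = logging.getLogger("gcdmap")

DEFAULT_N_DISCARD = 10
DEFAULT_FD_THRESHOLD_MM = 0.5
DEFAULT_HEAD_RADIUS_MM = 50.0
DEFAULT_BAND_HZ = (0.01, 0.1)


@dataclass
class VoxelSeries:
    """Masked 4D data as a voxels x timepoints matrix.

    ``voxel_index`` holds the 0-based grid coordinate of each row;
    ``censored_frames`` the timepoints whose values were replaced by
    interpolation during scrubbing.
    """

    matrix: np.ndarray  # V x T
    voxel_index: np.ndarray  # V x 3 int
    tr_seconds: float
    censored_frames: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=np.float64))
        self.voxel_index = np.asarray(self.voxel_index, dtype=np.intp).reshape(-1, 3)
        if self.voxel_index.shape[0] != self.matrix.shape[0]:
            raise ValueError("voxel_index rows must match matrix rows")
        if not self.tr_seconds > 0:
            raise ValueError("tr_seconds must be positive")
        if not np.isfinite(self.matrix).all():
            raise ValueError("voxel series must contain no missing values")

    @property
    def n_voxels(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.matrix.shape[1]

    def replace(self, matrix: np.ndarray, censored: frozenset[int] | None = None) -> "VoxelSeries":
        return VoxelSeries(
            matrix,
            self.voxel_index,
            self.tr_seconds,
            self.censored_frames if censored is None else censored,
        )


@dataclass
class FdSeries:
    """Per-timepoint framewise displacement with the censoring threshold."""

    fd_mm: np.ndarray
    threshold_mm: float = DEFAULT_FD_THRESHOLD_MM

    def __post_init__(self) -> None:
        self.fd_mm = np.asarray(self.fd_mm, dtype=np.float64).ravel()
        if (self.fd_mm < 0).any():
            raise ValueError("framewise displacement must be nonnegative")

    @property
    def censored(self) -> np.ndarray:
        return self.fd_mm > self.threshold_mm


def extract_voxel_series(volume: ImageVolume, mask: ImageVolume) -> VoxelSeries:
    """Pull in-mask voxels from a 4D volume into a voxels x timepoints matrix."""
    if volume.data.ndim != 4:
        raise ValueError("need a 4D volume")
    if mask.data.shape != volume.data.shape[:3]:
        raise ValueError("mask geometry does not match volume")
    mask_bool = mask.data.astype(bool)
    voxel_index = np.argwhere(mask_bool)
    matrix = volume.data[mask_bool, :]
    return VoxelSeries(matrix, voxel_index, volume.tr_seconds)


def series_to_volume(series: VoxelSeries, grid_shape: tuple[int, int, int],
                     affine: np.ndarray) -> ImageVolume:
    """Scatter a voxel series back onto its grid (NaN outside the mask)."""
    data = np.full(grid_shape + (series.n_timepoints,), np.nan)
    data[tuple(series.voxel_index.T)] = series.matrix
    return ImageVolume(data, affine, tr_seconds=series.tr_seconds)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def discard_initial_volumes(volume: ImageVolume, n_discard: int = DEFAULT_N_DISCARD) -> ImageVolume:
    """Drop the first ``n_discard`` timepoints (scanner equilibration)."""
    if volume.data.ndim != 4:
        raise ValueError("need a 4D volume")
    if n_discard < 0:
        raise ValueError("n_discard must be nonnegative")
    if n_discard >= volume.n_timepoints:
        raise ValueError(
            f"cannot discard {n_discard} of {volume.n_timepoints} timepoints"
        )
    return ImageVolume(volume.data[..., n_discard:], volume.affine, tr_seconds=volume.tr_seconds)


def compute_fd(motion: MotionParams,
               head_radius_mm: float = DEFAULT_HEAD_RADIUS_MM,
               threshold_mm: float = DEFAULT_FD_THRESHOLD_MM) -> FdSeries:
    """Framewise displacement as the sum of absolute backward differences.

    Rotations are converted to arc length at ``head_radius_mm`` (default
    50 mm); the first frame is 0 by convention.
    """
    if motion.n_timepoints < 2:
        raise ValueError("framewise displacement needs at least 2 timepoints")
    d_trans = np.abs(np.diff(motion.translations_mm, axis=0)).sum(axis=1)
    d_rot = np.abs(head_radius_mm * np.diff(motion.rotations_rad, axis=0)).sum(axis=1)
    fd = np.concatenate([[0.0], d_trans + d_rot])
    return FdSeries(fd, threshold_mm)


def scrub_interpolate(series: VoxelSeries, fd: FdSeries) -> VoxelSeries:
    """Replace high-motion frames by per-voxel linear interpolation.

    Frames with FD above the threshold are replaced by linear interpolation
    between the nearest uncensored neighbours; censored frames at either end
    take the nearest uncensored value.  Uncensored frames are never touched.
    """
    if fd.fd_mm.shape[0] != series.n_timepoints:
        raise ValueError("FD length must equal timepoint count")
    bad = fd.censored
    if not bad.any():
        return series.replace(series.matrix.copy(), frozenset())
    if bad.all():
        raise ValueError("all frames exceed the FD threshold; nothing to interpolate from")
    t = np.arange(series.n_timepoints)
    good = ~bad
    out = series.matrix.copy()
    # np.interp clamps outside the support, giving nearest-value extension
    out[:, bad] = np.apply_along_axis(
        lambda row: np.interp(t[bad], t[good], row[good]), 1, series.matrix
    )
    return series.replace(out, frozenset(np.flatnonzero(bad).tolist()))


def build_friston24(motion: MotionParams) -> np.ndarray:
    """Friston-24 motion expansion: params, one-frame lag, and both squared.

    Columns 0-5 are the six rigid-body parameters, 6-11 the same lagged by
    one frame (first row zero-padded), 12-23 the squares of both blocks.
    """
    if motion.n_timepoints < 2:
        raise ValueError("need at least 2 timepoints")
    p = motion.as_matrix()
    lagged = np.vstack([np.zeros((1, 6)), p[:-1]])
    return np.hstack([p, lagged, p ** 2, lagged ** 2])


def regress_nuisance(series: VoxelSeries, regressors: np.ndarray | None) -> VoxelSeries:
    """Replace each voxel series by its OLS residual against the regressors.

    An intercept is always included.  Collinear regressor columns are
    dropped with a logged warning (pivoted-QR rank detection), so the
    residuals are orthogonal to every retained regressor.
    """
    T = series.n_timepoints
    if regressors is None or np.size(regressors) == 0:
        design = np.ones((T, 1))
    else:
        regressors = np.atleast_2d(np.asarray(regressors, dtype=float))
        if regressors.shape[0] != T:
            raise ValueError("regressor rows must equal timepoint count")
        design = np.column_stack([np.ones(T), regressors])
        design = _drop_collinear(design)
    q, _ = np.linalg.qr(design)
    resid = series.matrix - (series.matrix @ q) @ q.T
    return series.replace(resid)


def _drop_collinear(design: np.ndarray, rtol: float = 1e-10) -> np.ndarray:
    from scipy.linalg import qr

    _, r, piv = qr(design, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    keep_rank = int((diag > rtol * diag.max()).sum())
    if keep_rank < design.shape[1]:
        dropped = sorted(piv[keep_rank:].tolist())
        logger.warning("dropping %d collinear nuisance column(s): %s",
                       len(dropped), dropped)
        design = design[:, sorted(piv[:keep_rank].tolist())]
    return design


def detrend_linear(series: VoxelSeries) -> VoxelSeries:
    """Remove each voxel's least-squares line (mean and slope)."""
    return series.replace(sps.detrend(series.matrix, axis=1, type="linear"))


def bandpass(series: VoxelSeries,
             low_hz: float = DEFAULT_BAND_HZ[0],
             high_hz: float = DEFAULT_BAND_HZ[1],
             order: int = 4) -> VoxelSeries:
    """Zero-phase Butterworth band-pass (forward-backward filtering).

    Zero phase matters here: a causal filter would shift energy across lags
    and bias the autoregressive causality estimates.
    """
    nyquist = 0.5 / series.tr_seconds
    if not (0 <= low_hz < high_hz):
        raise ValueError("need 0 <= low_hz < high_hz")
    if high_hz >= nyquist:
        raise ValueError(f"high_hz={high_hz} must be below Nyquist={nyquist}")
    if low_hz > 0:
        sos = sps.butter(order, [low_hz, high_hz], btype="bandpass", fs=1.0 / series.tr_seconds,
                         output="sos")
    else:
        sos = sps.butter(order, high_hz, btype="lowpass", fs=1.0 / series.tr_seconds,
                         output="sos")
    out = sps.sosfiltfilt(sos, series.matrix, axis=1)
    return series.replace(np.ascontiguousarray(out))


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------


def preprocess_subject(
    volume: ImageVolume,
    mask: ImageVolume,
    motion: MotionParams,
    n_discard: int = DEFAULT_N_DISCARD,
    fd_threshold_mm: float = DEFAULT_FD_THRESHOLD_MM,
    head_radius_mm: float = DEFAULT_HEAD_RADIUS_MM,
    band_hz: tuple[float, float] | None = DEFAULT_BAND_HZ,
    global_signal: bool = True,
) -> tuple[VoxelSeries, dict]:
    """Run the full temporal chain on one subject.

    Motion rows must match the retained timepoint count (after discard).
    Returns the cleaned series and a small report (FD values, censored
    frames).
    """
    vol = discard_initial_volumes(volume, n_discard) if n_discard else volume
    if motion.n_timepoints != vol.n_timepoints:
        raise ValueError(
            f"{motion.n_timepoints} motion rows vs {vol.n_timepoints} retained volumes"
        )
    series = extract_voxel_series(vol, mask)
    fd = compute_fd(motion, head_radius_mm, fd_threshold_mm)
    series = scrub_interpolate(series, fd)
    regressors = [build_friston24(motion)]
    if global_signal:
        regressors.append(series.matrix.mean(axis=0)[:, None])
    series = regress_nuisance(series, np.hstack(regressors))
    series = detrend_linear(series)
    if band_hz is not None:
        series = bandpass(series, band_hz[0], band_hz[1])
    report = {
        "fd_mm": fd.fd_mm,
        "censored_frames": sorted(series.censored_frames),
        "n_timepoints": series.n_timepoints,
    }
    return series, report
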