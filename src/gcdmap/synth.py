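"""Synthetic two-group VAR cohorts with planted directed structure.

The generator is the exact generative counterpart of the estimator's model:
each in-mask voxel follows a first-order vector autoregression

    x_t = s o x_{t-1} + A x_{t-1} + drift_t + eps_t,   eps_t ~ N(0, noise_sd^2)

with per-voxel self-coefficients s, a directed coupling matrix A (A[target,
source]), low-frequency drift and Gaussian innovations.  Group B receives an
additive change on designated coupling edges (the planted group effect), and
every subject gets small random coupling jitter.  Motion traces with
occasional framewise-displacement spikes above the scrubbing threshold and
Table-style demographics (age, sex, duration) accompany each subject, so the
whole pipeline — preprocessing, density mapping, classification — runs
end-to-end without real data.

All randomness flows from one integer seed; subject i uses seed + i.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .gcd_core import GcdMaps, compute_gcd_maps
from .io_formats import (CohortManifest, ImageVolume, MotionParams,
                         write_image, write_manifest, write_motion_params)
from .preprocess import VoxelSeries, extract_voxel_series, preprocess_subject

logger = logging.getLogger("gcdmap")

DEFAULT_GRID = (8, 8, 8)
DEFAULT_T = 240  # the acquisition's 250 volumes minus the 10 discarded
DEFAULT_TR = 2.0
DEFAULT_SELF_COEFF = 0.6  # lag-1 autocorrelation of BOLD-like series at TR 2 s;
# keeps the VAR signal inside the 0.01-0.1 Hz analysis band
DEFAULT_NOISE_SD = 1.0
DEFAULT_DRIFT_AMPLITUDE = 1.0
DEFAULT_BASE_COUPLING = 0.1
DEFAULT_GROUP_EFFECT = 0.5
DEFAULT_JITTER_SD = 0.05
BURN_IN = 100


@dataclass
class NetworkSpec:
    """Generative VAR(1) network on a voxel grid."""

    grid_shape: tuple[int, int, int]
    mask: np.ndarray  # boolean grid
    adjacency: np.ndarray  # V x V, [target, source]
    self_coeff: np.ndarray  # V
    noise_sd: float = DEFAULT_NOISE_SD
    drift_amplitude: float = DEFAULT_DRIFT_AMPLITUDE
    tr_seconds: float = DEFAULT_TR
    n_timepoints: int = DEFAULT_T

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.adjacency = np.asarray(self.adjacency, dtype=np.float64)
        self.self_coeff = np.asarray(self.self_coeff, dtype=np.float64).ravel()
        V = int(self.mask.sum())
        if self.adjacency.shape != (V, V):
            raise ValueError("adjacency must be V x V over in-mask voxels")
        if self.self_coeff.shape[0] != V:
            raise ValueError("one self coefficient per in-mask voxel")
        if not self.noise_sd > 0:
            raise ValueError("noise_sd must be positive")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def companion(self) -> np.ndarray:
        return np.diag(self.self_coeff) + self.adjacency

    @property
    def spectral_radius(self) -> float:
        return float(np.max(np.abs(np.linalg.eigvals(self.companion))))

    def check_stationary(self) -> None:
        rho = self.spectral_radius
        if rho >= 1.0:
            raise ValueError(f"non-stationary network: spectral radius {rho:.3f} >= 1")


@dataclass
class GroundTruth:
    """Planted structure against which estimated maps are scored."""

    true_outflow: np.ndarray  # out-degree-weighted coupling per voxel
    true_inflow: np.ndarray
    hub_voxels: list[int]
    sink_voxels: list[int]
    group_difference_voxels: list[int]

    def to_json(self) -> str:
        return json.dumps({
            "true_outflow": self.true_outflow.tolist(),
            "true_inflow": self.true_inflow.tolist(),
            "hub_voxels": self.hub_voxels,
            "sink_voxels": self.sink_voxels,
            "group_difference_voxels": self.group_difference_voxels,
        })


def ball_mask(grid_shape: tuple[int, int, int] = DEFAULT_GRID,
              radius: float | None = None) -> np.ndarray:
    """Spherical mask centred on the grid (~200 voxels on the 8x8x8 default)."""
    if radius is None:
        radius = 0.47 * min(grid_shape)
    centre = (np.asarray(grid_shape) - 1) / 2.0
    coords = np.indices(grid_shape).reshape(3, -1).T
    inside = ((coords - centre) ** 2).sum(axis=1) <= radius ** 2
    return inside.reshape(grid_shape)


def ground_truth_from_spec(spec: NetworkSpec,
                           group_edges: list[tuple[int, int]] | None = None) -> GroundTruth:
    A = spec.adjacency
    out_w = np.abs(A).sum(axis=0)  # influence each source exerts
    in_w = np.abs(A).sum(axis=1)
    hubs = np.flatnonzero(out_w > in_w + 1e-12)
    sinks = np.flatnonzero(in_w > out_w + 1e-12)
    diff = sorted({v for e in (group_edges or []) for v in e})
    return GroundTruth(out_w, in_w, hubs.tolist(), sinks.tolist(), diff)


def make_network_spec(
    grid_shape: tuple[int, int, int] = DEFAULT_GRID,
    n_timepoints: int = DEFAULT_T,
    tr_seconds: float = DEFAULT_TR,
    self_coeff: float = DEFAULT_SELF_COEFF,
    noise_sd: float = DEFAULT_NOISE_SD,
    drift_amplitude: float = DEFAULT_DRIFT_AMPLITUDE,
    edges: list[tuple[int, int, float]] | None = None,
    mask: np.ndarray | None = None,
) -> NetworkSpec:
    """Build a spec from an edge list of (source, target, weight) triples."""
    mask = ball_mask(grid_shape) if mask is None else np.asarray(mask, dtype=bool)
    V = int(mask.sum())
    A = np.zeros((V, V))
    for src, tgt, w in edges or []:
        A[tgt, src] = w
    spec = NetworkSpec(grid_shape, mask, A, np.full(V, self_coeff),
                       noise_sd=noise_sd, drift_amplitude=drift_amplitude,
                       tr_seconds=tr_seconds, n_timepoints=n_timepoints)
    spec.check_stationary()
    return spec


def planted_hub_edges(n_voxels: int, n_hubs: int = 2, targets_per_hub: int = 5,
                      seed: int = 0) -> list[tuple[int, int]]:
    """Choose hub->target edges (10 by default) spread over the mask.

    On masks too small for the requested layout the per-hub target count is
    reduced to fit (with a logged warning).
    """
    if n_voxels < 2 * n_hubs:
        raise ValueError(f"mask of {n_voxels} voxels cannot host {n_hubs} hubs")
    if n_hubs * (targets_per_hub + 1) > n_voxels:
        targets_per_hub = max(1, (n_voxels - n_hubs) // n_hubs)
        logger.warning("mask too small for requested hub layout; using %d targets/hub",
                       targets_per_hub)
    rng = np.random.default_rng(seed)
    picks = rng.choice(n_voxels, size=n_hubs * (targets_per_hub + 1), replace=False)
    hubs, rest = picks[:n_hubs], picks[n_hubs:]
    edges = []
    for h_i, hub in enumerate(hubs):
        for t in rest[h_i * targets_per_hub:(h_i + 1) * targets_per_hub]:
            edges.append((int(hub), int(t)))
    return edges


def simulate_var_subject(spec: NetworkSpec, seed: int,
                         ground_truth: GroundTruth | None = None
                         ) -> tuple[ImageVolume, GroundTruth]:
    """One subject's 4D volume from the VAR(1) model (burn-in discarded)."""
    spec.check_stationary()
    rng = np.random.default_rng(seed)
    V, T = spec.n_voxels, spec.n_timepoints
    C = spec.companion
    total = T + BURN_IN
    noise = rng.normal(0.0, spec.noise_sd, size=(total, V))
    x = np.zeros(V)
    out = np.empty((total, V))
    for t in range(total):
        x = C @ x + noise[t]
        out[t] = x
    series = out[BURN_IN:]
    if spec.drift_amplitude > 0:
        tt = np.arange(T) * spec.tr_seconds
        phase = rng.uniform(0, 2 * np.pi, size=V)
        slope = rng.uniform(-1, 1, size=V)
        drift = (np.cos(2 * np.pi * 0.005 * tt[:, None] + phase)
                 + slope * (tt[:, None] / tt[-1] - 0.5))
        series = series + spec.drift_amplitude * drift
    data = np.zeros(spec.grid_shape + (T,))
    data[spec.mask] = series.T
    volume = ImageVolume(data, np.eye(4) * np.diag([3.0, 3.0, 3.0, 1.0]),
                         tr_seconds=spec.tr_seconds)
    if ground_truth is None:
        ground_truth = ground_truth_from_spec(spec)
    return volume, ground_truth


def simulate_motion(n_timepoints: int, seed: int, n_spikes: int = 3,
                    walk_sd_mm: float = 0.01, spike_mm: float = 0.7) -> MotionParams:
    """Random-walk motion with occasional one-frame spikes exceeding 0.5 mm FD."""
    rng = np.random.default_rng(seed)
    trans = np.cumsum(rng.normal(0, walk_sd_mm, size=(n_timepoints, 3)), axis=0)
    rot = np.cumsum(rng.normal(0, walk_sd_mm / 50.0, size=(n_timepoints, 3)), axis=0)
    if n_spikes > 0:
        frames = rng.choice(np.arange(5, n_timepoints - 5), size=n_spikes, replace=False)
        for f in frames:
            axis = rng.integers(0, 3)
            trans[f, axis] += spike_mm * rng.choice([-1.0, 1.0])
    return MotionParams(trans, rot)


@dataclass
class SyntheticSubject:
    subject_id: str
    group_label: str
    volume: ImageVolume
    motion: MotionParams
    age: float
    sex: str
    duration: float


@dataclass
class SyntheticCohort:
    subjects: list[SyntheticSubject]
    mask: ImageVolume
    ground_truth: GroundTruth
    spec_a: NetworkSpec
    spec_b: NetworkSpec

    @property
    def labels(self) -> np.ndarray:
        return np.array([s.group_label for s in self.subjects])

    def manifest(self, image_paths=None, motion_paths=None) -> CohortManifest:
        rows = []
        for i, s in enumerate(self.subjects):
            rows.append({
                "subject_id": s.subject_id,
                "group_label": s.group_label,
                "image_path": "" if image_paths is None else str(image_paths[i]),
                "motion_path": "" if motion_paths is None else str(motion_paths[i]),
                "age": s.age,
                "sex": s.sex,
                "duration": s.duration,
            })
        return CohortManifest(pd.DataFrame(rows))


def simulate_cohort(
    n_per_group: int = 21,
    group_effect: float = DEFAULT_GROUP_EFFECT,
    base_coupling: float = DEFAULT_BASE_COUPLING,
    n_hubs: int = 2,
    targets_per_hub: int = 5,
    subject_jitter_sd: float = DEFAULT_JITTER_SD,
    seed: int = 0,
    spec: NetworkSpec | None = None,
    out_dir: str | Path | None = None,
) -> SyntheticCohort:
    """Two-group cohort with a planted coupling difference on 10 edges.

    Group substate_A carries ``base_coupling`` on the planted edges, group
    substate_B ``base_coupling + group_effect`` (the IED-like group).  Every
    subject's nonzero couplings are jittered with sd
    ``subject_jitter_sd``.  When ``out_dir`` is given, images, motion files,
    a manifest TSV and a ground-truth JSON are written there.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    base = spec if spec is not None else make_network_spec()
    edges = planted_hub_edges(base.n_voxels, n_hubs, targets_per_hub, seed=seed)
    A_a = base.adjacency.copy()
    A_b = base.adjacency.copy()
    for src, tgt in edges:
        A_a[tgt, src] += base_coupling
        A_b[tgt, src] += base_coupling + group_effect
    spec_a = replace(base, adjacency=A_a)
    spec_b = replace(base, adjacency=A_b)
    spec_b.check_stationary()
    truth = ground_truth_from_spec(spec_b, group_edges=edges)

    rng = np.random.default_rng(seed)
    subjects: list[SyntheticSubject] = []
    demo = {
        "substate_A": {"age": (9.19, 2.02), "duration": (24.66, 23.1)},
        "substate_B": {"age": (8.14, 1.88), "duration": (16.12, 16.16)},
    }
    for i in range(2 * n_per_group):
        group = "substate_A" if i < n_per_group else "substate_B"
        gspec = spec_a if group == "substate_A" else spec_b
        subj_seed = seed + i
        jitter_rng = np.random.default_rng(subj_seed)
        A = gspec.adjacency.copy()
        nz = A != 0
        A[nz] += jitter_rng.normal(0, subject_jitter_sd, size=int(nz.sum()))
        sspec = replace(gspec, adjacency=A)
        sspec.check_stationary()
        volume, _ = simulate_var_subject(sspec, subj_seed, ground_truth=truth)
        motion = simulate_motion(gspec.n_timepoints, seed=subj_seed + 10_000)
        mu_age, sd_age = demo[group]["age"]
        mu_dur, sd_dur = demo[group]["duration"]
        subjects.append(SyntheticSubject(
            subject_id=f"sub-{i:03d}",
            group_label=group,
            volume=volume,
            motion=motion,
            age=float(np.round(rng.normal(mu_age, sd_age), 1)),
            sex="M" if rng.random() < 0.5 else "F",
            duration=float(np.round(max(1.0, rng.normal(mu_dur, sd_dur)), 1)),
        ))
    mask_vol = ImageVolume(base.mask.astype(float), np.eye(4) * np.diag([3.0, 3.0, 3.0, 1.0]))
    cohort = SyntheticCohort(subjects, mask_vol, truth, spec_a, spec_b)
    if out_dir is not None:
        _write_cohort(cohort, Path(out_dir))
    return cohort


def _write_cohort(cohort: SyntheticCohort, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    write_image(cohort.mask, out_dir / "mask.nii.gz")
    image_paths, motion_paths = [], []
    for s in cohort.subjects:
        ip = out_dir / f"{s.subject_id}_bold.nii.gz"
        mp = out_dir / f"{s.subject_id}_motion.txt"
        write_image(s.volume, ip)
        write_motion_params(s.motion, mp)
        image_paths.append(ip)
        motion_paths.append(mp)
    write_manifest(cohort.manifest(image_paths, motion_paths), out_dir / "manifest.tsv")
    (out_dir / "ground_truth.json").write_text(cohort.ground_truth.to_json())


def cohort_metric_arrays(
    cohort: SyntheticCohort,
    order: int = 1,
    alpha: float = 0.05,
    residual_measure: str = "sd",
    preprocess: bool = True,
    n_discard: int = 0,
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Run preprocessing + GCD mapping in memory for every subject.

    Returns ({metric: subjects x voxels}, labels); the simulated series are
    already post-discard length, so no volumes are dropped by default.
    """
    maps: list[GcdMaps] = []
    for s in cohort.subjects:
        if preprocess:
            series, _ = preprocess_subject(s.volume, cohort.mask, s.motion,
                                           n_discard=n_discard)
        else:
            series = extract_voxel_series(s.volume, cohort.mask)
        maps.append(compute_gcd_maps(series, order=order, alpha=alpha,
                                     residual_measure=residual_measure))
    arrays = {
        "inflow": np.vstack([m.inflow for m in maps]),
        "outflow": np.vstack([m.outflow for m in maps]),
        "totalflow": np.vstack([m.total_flow for m in maps]),
        "intflow": np.vstack([m.int_flow for m in maps]),
    }
    return arrays, cohort.labels
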