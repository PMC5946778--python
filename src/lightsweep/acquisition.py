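"""Optical forward model: swept light sheet + swept detection plane.

Volume scanning mode drives the light sheet and the detection focal plane
with synchronized sine waves and locks the camera exposure to exactly one
scan period, so each frame is an average intensity projection of one full Z
sweep — a fast-volume XYT stack with an effective sheet thickness equal to
the sweep depth.  Single-plane and stage-stepped structural modes share the
same rendering core.

Axial profiles are Gaussian: excitation weight exp(-(z - sheet_z)^2 / 2*sigma_s^2)
times detection weight exp(-(z - focus_z)^2 / 2*sigma_d^2).  A sheet/focus
mismatch additionally blurs the image laterally at ``defocus_blur_rate`` µm
of blur sigma per µm of mismatch.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable

import numpy as np
import tifffile
from scipy.ndimage import gaussian_filter

from .errors import ConfigError, DataError
from .phantom import Box, FluorescenceField

__all__ = [
    "ScanWaveform",
    "OpticsModel",
    "CameraModel",
    "ImagingGrid",
    "FrameStack",
    "StaticField",
    "z_position",
    "render_subframe",
    "acquire_volume_scan",
    "acquire_single_plane",
    "acquire_structural_stack",
    "time_averaged_excitation",
    "support_width",
]


# ---------------------------------------------------------------------------
# parameter sets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScanWaveform:
    """Sine drive for the light sheet or the detection focal plane.

    z(t) = center_z + amplitude * sin(2*pi*frequency*t + phase).
    ``amplitude`` is half the peak-to-peak sweep; ``phase`` houses the
    sheet/lens phase difference P compensating the tunable lens's lag.
    """

    frequency: float            # Hz
    amplitude: float            # µm
    center_z: float = 0.0       # µm
    phase: float = 0.0          # rad

    def __post_init__(self) -> None:
        if self.frequency <= 0:
            raise ConfigError(f"frequency must be > 0, got {self.frequency}")
        if self.amplitude < 0:
            raise ConfigError(f"amplitude must be >= 0, got {self.amplitude}")

    @property
    def period(self) -> float:
        return 1.0 / self.frequency

    def z_position(self, t):
        t = np.asarray(t, dtype=float)
        z = self.center_z + self.amplitude * np.sin(2.0 * np.pi * self.frequency * t + self.phase)
        return float(z) if z.ndim == 0 else z

    def with_lag(self, lag_s: float) -> "ScanWaveform":
        """Waveform delayed by ``lag_s`` (models the tunable lens response lag)."""
        return replace(self, phase=self.phase - 2.0 * np.pi * self.frequency * lag_s)


def z_position(waveform: ScanWaveform, t):
    """Axial position of a scan waveform at time ``t`` (s)."""
    return waveform.z_position(t)


@dataclass(frozen=True)
class OpticsModel:
    """Gaussian-profile optics of the simulated microscope.

    Defaults are plausible for a 0.8 NA detection / 0.3 NA illumination
    water-dipping pair, chosen so that single-plane mode visibly truncates a
    phantom meandering over tens of µm in Z; they are model parameters, not
    measured point-spread functions.
    """

    sheet_thickness_sigma: float = 2.0       # µm, axial excitation sigma
    dof_sigma: float = 1.5                   # µm, axial detection sigma
    lateral_blur_sigma_in_focus: float = 0.4  # µm
    defocus_blur_rate: float = 0.25          # µm lateral sigma per µm defocus
    pixel_size: float = 0.4                  # µm in sample space

    def __post_init__(self) -> None:
        for name in ("sheet_thickness_sigma", "dof_sigma",
                     "lateral_blur_sigma_in_focus", "pixel_size"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        if self.defocus_blur_rate < 0:
            raise ConfigError("defocus_blur_rate must be >= 0")


@dataclass(frozen=True)
class CameraModel:
    """Camera and sampling parameters.

    ``photon_scale`` converts rendered intensity to expected photon counts
    for shot noise; ``None`` disables noise entirely and yields float frames.
    ``offset`` is the sensor bias level added to every frame (sCMOS cameras
    sit on a non-zero baseline; it matters when normalising image statistics).
    ``substeps_per_exposure`` is the number of sweep positions averaged per
    exposure (the numeric analogue of continuous integration).
    """

    exposure_ms: float = 20.0
    frame_shape: tuple[int, int] = (128, 128)   # (rows, cols)
    photon_scale: float | None = 30.0           # photons per intensity unit
    read_noise_sigma: float = 2.0               # counts
    offset: float = 0.0                         # bias level, counts
    substeps_per_exposure: int = 32

    def __post_init__(self) -> None:
        if self.exposure_ms <= 0:
            raise ConfigError(f"exposure_ms must be > 0, got {self.exposure_ms}")
        if self.substeps_per_exposure < 8:
            raise ConfigError("substeps_per_exposure must be >= 8")
        if self.photon_scale is not None and self.photon_scale <= 0:
            raise ConfigError("photon_scale must be > 0 or None")
        if self.read_noise_sigma < 0:
            raise ConfigError("read_noise_sigma must be >= 0")

    @property
    def exposure_s(self) -> float:
        return self.exposure_ms / 1000.0

    def noiseless(self) -> "CameraModel":
        return replace(self, photon_scale=None, read_noise_sigma=0.0)


@dataclass(frozen=True)
class ImagingGrid:
    """Sample-space grid: pixel-center x/y coordinates and a z quadrature grid."""

    x: np.ndarray               # (nx,) µm, pixel centers (columns)
    y: np.ndarray               # (ny,) µm, pixel centers (rows)
    z: np.ndarray               # (nz,) µm, axial quadrature nodes
    pixel_size: float
    dz: float

    def __post_init__(self) -> None:
        if len(self.x) == 0 or len(self.y) == 0 or len(self.z) == 0:
            raise ConfigError("ImagingGrid axes must be non-empty")

    @property
    def frame_shape(self) -> tuple[int, int]:
        return (len(self.y), len(self.x))

    def cache_key(self) -> tuple:
        return (
            len(self.x), len(self.y), len(self.z),
            float(self.x[0]), float(self.y[0]), float(self.z[0]),
            self.pixel_size, self.dz,
        )

    @classmethod
    def from_bounds(
        cls,
        bounds: Box,
        optics: OpticsModel,
        frame_shape: tuple[int, int],
        dz: float = 0.5,
        z_pad: float = 6.0,
    ) -> "ImagingGrid":
        """Grid centered on the bounds, sized by the camera frame."""
        ny, nx = frame_shape
        cx = 0.5 * (bounds.lo[0] + bounds.hi[0])
        cy = 0.5 * (bounds.lo[1] + bounds.hi[1])
        x = cx + (np.arange(nx) - (nx - 1) / 2.0) * optics.pixel_size
        y = cy + (np.arange(ny) - (ny - 1) / 2.0) * optics.pixel_size
        z = np.arange(bounds.lo[2] - z_pad, bounds.hi[2] + z_pad + dz / 2.0, dz)
        return cls(x=x, y=y, z=z, pixel_size=optics.pixel_size, dz=dz)


# ---------------------------------------------------------------------------
# voxel samplers
# ---------------------------------------------------------------------------

@dataclass
class SparseVoxels:
    """Sparse voxelisation of a dendrite field: only tube voxels are stored."""

    field: FluorescenceField
    shape: tuple[int, int, int]      # (nz, ny, nx)
    dz: float
    iz: np.ndarray                   # (n,) z-slice index per voxel
    pix: np.ndarray                  # (n,) flattened row*nx+col index
    occupancy: np.ndarray            # (n,) partial-volume fraction
    arclength: np.ndarray            # (n,) nearest-centerline arclength, µm

    _arc_grid: np.ndarray = field(init=False, repr=False)
    _arc_idx: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        # dF/F is evaluated on a coarse arclength grid and gathered per voxel
        ds = 0.5
        total = self.field.phantom.total_length
        self._arc_grid = np.arange(0.0, total + ds, ds)
        self._arc_idx = np.clip(
            np.round(self.arclength / ds).astype(np.intp), 0, len(self._arc_grid) - 1
        )

    def subframe(self, wz: np.ndarray, t: float, channel: str) -> np.ndarray:
        nz, ny, nx = self.shape
        if channel == "structural":
            dens = self.field.phantom.structural_density
            vals = self.occupancy * dens
        elif channel == "indicator":
            dff = self.field.dff_along(self._arc_grid, t)
            vals = self.occupancy * self.field.phantom.indicator_baseline * (
                1.0 + dff[self._arc_idx]
            )
        else:
            raise DataError(f"unknown channel {channel!r}")
        img = np.bincount(self.pix, weights=vals * wz[self.iz], minlength=ny * nx)
        return img.reshape(ny, nx) * self.dz


@dataclass
class DenseVoxels:
    """Dense voxelisation of a time-invariant field (beads, uniform slabs)."""

    volume: np.ndarray               # (nz, ny, nx)
    dz: float

    def subframe(self, wz: np.ndarray, t: float, channel: str) -> np.ndarray:
        return np.tensordot(wz, self.volume, axes=(0, 0)) * self.dz


class StaticField:
    """Time-invariant emission field defined by a callable density(x, y, z).

    Both channels return the same density.  Used for beads, slabs and other
    simple test objects.
    """

    def __init__(self, density: Callable[[np.ndarray, np.ndarray, np.ndarray], np.ndarray],
                 bounds: Box):
        self._density = density
        self.bounds = bounds
        self._vox_cache: dict = {}

    def evaluate(self, x, y, z, t: float = 0.0, channel: str = "indicator"):
        x, y, z = np.broadcast_arrays(
            np.asarray(x, float), np.asarray(y, float), np.asarray(z, float)
        )
        return self._density(x, y, z)

    def voxelize(self, grid: ImagingGrid) -> DenseVoxels:
        key = grid.cache_key()
        if key not in self._vox_cache:
            zz, yy, xx = np.meshgrid(grid.z, grid.y, grid.x, indexing="ij")
            self._vox_cache[key] = DenseVoxels(
                volume=np.asarray(self._density(xx, yy, zz), dtype=float), dz=grid.dz
            )
        return self._vox_cache[key]


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _axial_weights(z: np.ndarray, optics: OpticsModel,
                   sheet_z: float, focus_z: float) -> np.ndarray:
    exc = np.exp(-0.5 * ((z - sheet_z) / optics.sheet_thickness_sigma) ** 2)
    det = np.exp(-0.5 * ((z - focus_z) / optics.dof_sigma) ** 2)
    return exc * det


def render_subframe(
    field,
    optics: OpticsModel,
    sheet_z: float,
    focus_z: float,
    grid: ImagingGrid,
    t: float = 0.0,
    channel: str = "indicator",
) -> np.ndarray:
    """Noiseless instantaneous image for given sheet and focus positions.

    Pixel value = integral over z of density * excitation * detection weight
    (midpoint rule on ``grid.z``), followed by a lateral Gaussian blur whose
    sigma grows with the sheet/focus mismatch.
    """
    vox = field.voxelize(grid)
    wz = _axial_weights(grid.z, optics, sheet_z, focus_z)
    img = vox.subframe(wz, t, channel)
    sigma_um = (
        optics.lateral_blur_sigma_in_focus
        + optics.defocus_blur_rate * abs(sheet_z - focus_z)
    )
    return gaussian_filter(img, sigma=sigma_um / optics.pixel_size)


# ---------------------------------------------------------------------------
# frame stacks and noise
# ---------------------------------------------------------------------------

@dataclass
class FrameStack:
    """XYT (or Z for structural mode) stack of camera frames plus metadata."""

    data: np.ndarray                 # (T, rows, cols)
    frame_interval_ms: float
    mode: str                        # volume_scan | single_plane | structural_z
    metadata: dict

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def times(self) -> np.ndarray:
        """Frame mid-exposure times, s."""
        dt = self.frame_interval_ms / 1000.0
        return (np.arange(self.n_frames) + 0.5) * dt

    def save(self, path) -> None:
        """Write a multi-page TIFF plus a JSON metadata sidecar."""
        path = Path(path)
        data = self.data
        if np.issubdtype(data.dtype, np.integer):
            data = data.astype(np.uint16)
        else:
            data = data.astype(np.float32)
        tifffile.imwrite(path, data, photometric="minisblack")
        sidecar = {
            "frame_interval_ms": self.frame_interval_ms,
            "mode": self.mode,
            "metadata": self.metadata,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, path) -> "FrameStack":
        path = Path(path)
        data = tifffile.imread(path)
        if data.ndim == 2:
            data = data[None]
        sidecar_path = path.with_suffix(".json")
        if sidecar_path.exists():
            sidecar = json.loads(sidecar_path.read_text())
        else:
            raise DataError(f"metadata sidecar not found: {sidecar_path}")
        return cls(
            data=data,
            frame_interval_ms=float(sidecar["frame_interval_ms"]),
            mode=str(sidecar["mode"]),
            metadata=sidecar.get("metadata", {}),
        )


def _apply_noise(frames: np.ndarray, camera: CameraModel,
                 rng: np.random.Generator) -> np.ndarray:
    """Shot noise on photons, then bias offset and Gaussian read noise,
    rounded and clipped.  ``photon_scale=None`` returns float frames with the
    bias applied but no noise."""
    if camera.photon_scale is None:
        return frames + camera.offset if camera.offset else frames
    counts = rng.poisson(camera.photon_scale * frames).astype(float)
    counts += camera.offset
    if camera.read_noise_sigma > 0:
        counts += rng.normal(0.0, camera.read_noise_sigma, size=counts.shape)
    counts = np.clip(np.rint(counts), 0, 65535)
    return counts.astype(np.uint16)


def _default_grid(field, optics: OpticsModel, camera: CameraModel,
                  grid: ImagingGrid | None) -> ImagingGrid:
    if grid is not None:
        return grid
    return ImagingGrid.from_bounds(field.bounds, optics, camera.frame_shape)


def _substep_times(frame_index: int, exposure: float, k: int) -> np.ndarray:
    return (frame_index + (np.arange(k) + 0.5) / k) * exposure


# ---------------------------------------------------------------------------
# acquisition modes
# ---------------------------------------------------------------------------

def acquire_volume_scan(
    field,
    sheet_wf: ScanWaveform,
    focus_wf: ScanWaveform,
    optics: OpticsModel,
    camera: CameraModel,
    duration: float,
    seed: int | None = None,
    grid: ImagingGrid | None = None,
    channel: str = "indicator",
) -> FrameStack:
    """Fast volume scan: one full sine sweep integrated per camera exposure.

    The exposure must equal the waveform period (one complete Z scan per
    frame); each frame is the mean of ``substeps_per_exposure`` instantaneous
    renders at midpoint times across the exposure.
    """
    period = sheet_wf.period
    if abs(camera.exposure_s - period) > 1e-6 * period:
        raise ConfigError(
            f"exposure_ms ({camera.exposure_ms}) must equal one waveform period "
            f"({period * 1000.0} ms) for volume scanning"
        )
    if abs(focus_wf.frequency - sheet_wf.frequency) > 1e-9 * sheet_wf.frequency:
        raise ConfigError("sheet and focus waveforms must share a frequency")
    grid = _default_grid(field, optics, camera, grid)
    exposure = camera.exposure_s
    n_frames = int(math.floor(duration / exposure + 1e-9))
    k = camera.substeps_per_exposure
    frames = np.empty((n_frames, *grid.frame_shape))
    for i in range(n_frames):
        acc = np.zeros(grid.frame_shape)
        for t in _substep_times(i, exposure, k):
            acc += render_subframe(
                field, optics, sheet_wf.z_position(t), focus_wf.z_position(t),
                grid, t=t, channel=channel,
            )
        frames[i] = acc / k
    rng = np.random.default_rng(seed)
    data = _apply_noise(frames, camera, rng)
    return FrameStack(
        data=data,
        frame_interval_ms=camera.exposure_ms,
        mode="volume_scan",
        metadata={
            "pixel_size_um": optics.pixel_size,
            "sheet_waveform": vars(sheet_wf).copy(),
            "focus_waveform": vars(focus_wf).copy(),
            "channel": channel,
            "seed": seed,
            "grid_origin_um": [float(grid.x[0]), float(grid.y[0])],
        },
    )


def acquire_single_plane(
    field,
    plane_z: float,
    optics: OpticsModel,
    camera: CameraModel,
    duration: float,
    seed: int | None = None,
    grid: ImagingGrid | None = None,
    channel: str = "indicator",
) -> FrameStack:
    """Single-plane XYT acquisition: static sheet and focus at ``plane_z``."""
    grid = _default_grid(field, optics, camera, grid)
    exposure = camera.exposure_s
    n_frames = int(math.floor(duration / exposure + 1e-9))
    k = camera.substeps_per_exposure
    frames = np.empty((n_frames, *grid.frame_shape))
    for i in range(n_frames):
        acc = np.zeros(grid.frame_shape)
        for t in _substep_times(i, exposure, k):
            acc += render_subframe(field, optics, plane_z, plane_z, grid,
                                   t=t, channel=channel)
        frames[i] = acc / k
    rng = np.random.default_rng(seed)
    data = _apply_noise(frames, camera, rng)
    return FrameStack(
        data=data,
        frame_interval_ms=camera.exposure_ms,
        mode="single_plane",
        metadata={
            "pixel_size_um": optics.pixel_size,
            "plane_z_um": plane_z,
            "channel": channel,
            "seed": seed,
            "grid_origin_um": [float(grid.x[0]), float(grid.y[0])],
        },
    )


def acquire_structural_stack(
    field,
    z_start: float,
    z_step: float,
    n_steps: int,
    optics: OpticsModel,
    camera: CameraModel,
    seed: int | None = None,
    grid: ImagingGrid | None = None,
    channel: str = "structural",
) -> FrameStack:
    """Stage-stepped structural Z stack: one frame per plane z_start + i*z_step."""
    if n_steps < 1:
        raise ConfigError(f"n_steps must be >= 1, got {n_steps}")
    grid = _default_grid(field, optics, camera, grid)
    z_planes = z_start + np.arange(n_steps) * z_step
    frames = np.empty((n_steps, *grid.frame_shape))
    for i, z in enumerate(z_planes):
        frames[i] = render_subframe(field, optics, z, z, grid, t=0.0, channel=channel)
    rng = np.random.default_rng(seed)
    data = _apply_noise(frames, camera, rng)
    return FrameStack(
        data=data,
        frame_interval_ms=camera.exposure_ms,
        mode="structural_z",
        metadata={
            "pixel_size_um": optics.pixel_size,
            "z_start_um": z_start,
            "z_step_um": z_step,
            "n_steps": n_steps,
            "depth_um": float(n_steps * z_step),
            "channel": channel,
            "seed": seed,
            "grid_origin_um": [float(grid.x[0]), float(grid.y[0])],
        },
    )


# ---------------------------------------------------------------------------
# effective sheet profile
# ---------------------------------------------------------------------------

def time_averaged_excitation(
    waveform: ScanWaveform,
    sheet_sigma: float,
    z_grid: np.ndarray,
    n_substeps: int = 256,
) -> np.ndarray:
    """Excitation weight averaged over one full sweep period on ``z_grid``.

    This is the effective axial illumination profile of the volume-scan mode:
    a thin Gaussian sheet swept sinusoidally spreads its time-averaged weight
    over the whole peak-to-peak sweep depth.
    """
    if sheet_sigma <= 0:
        raise ConfigError("sheet_sigma must be > 0")
    t = (np.arange(n_substeps) + 0.5) / n_substeps * waveform.period
    sheet_z = waveform.z_position(t)                       # (k,)
    prof = np.exp(
        -0.5 * ((z_grid[None, :] - sheet_z[:, None]) / sheet_sigma) ** 2
    ).mean(axis=0)
    return prof


def support_width(profile: np.ndarray, z_grid: np.ndarray,
                  threshold_fraction: float = 0.05) -> float:
    """Width of the region where ``profile`` exceeds a fraction of its peak."""
    above = profile >= threshold_fraction * profile.max()
    if not above.any():
        return 0.0
    z = z_grid[above]
    return float(z.max() - z.min())
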