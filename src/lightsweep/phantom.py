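"""Synthetic dendrite phantoms with ground-truth Ca2+ transients.

A phantom stands in for a dye-filled neuron in a brain slice: a meandering
tube around a smoothed random-walk centerline, carrying two fluorophores —
a structural dye of constant brightness and a Ca2+ indicator whose emission
follows baseline * (1 + dF/F).  Transient events are parameterised by the
rise/decay kernel b*t*exp(-c*t); their amplitude attenuates exponentially
and their onset is delayed linearly with arclength distance from the origin.

All lengths are in micrometres, times in seconds, fluorescence densities in
arbitrary units per µm^3.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import ConfigError, DataError

__all__ = [
    "Box",
    "CalciumEvent",
    "DendriteConfig",
    "DendritePhantom",
    "FluorescenceField",
    "event_kernel",
    "unit_peak_kernel",
    "make_dendrite",
    "place_events",
    "evaluate_field",
    "event_truth_at_arclength",
]

CHANNELS = ("structural", "indicator")


# ---------------------------------------------------------------------------
# temporal kernel
# ---------------------------------------------------------------------------

def event_kernel(t_since_onset, b: float, c: float):
    """Rise/decay transient kernel b*t*exp(-c*t) for t >= 0, 0 before onset.

    The kernel peaks at t = 1/c with value b/(c*e).  ``t_since_onset`` may be
    a scalar or array; the return matches its shape.
    """
    if c <= 0:
        raise ConfigError(f"rise_decay_c must be > 0, got {c}")
    t = np.asarray(t_since_onset, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]
    out[pos] = b * tp * np.exp(-c * tp)
    if np.ndim(t_since_onset) == 0:
        return float(out)
    return out


def unit_peak_kernel(t_since_onset, c: float):
    """Kernel normalised to unit peak: (c*e)*t*exp(-c*t)."""
    return event_kernel(t_since_onset, c * math.e, c)


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Box:
    """Axis-aligned 3D bounding box, µm."""

    lo: tuple[float, float, float]
    hi: tuple[float, float, float]

    def __post_init__(self) -> None:
        if any(h < l for l, h in zip(self.lo, self.hi)):
            raise ConfigError(f"bounds: hi must be >= lo, got lo={self.lo} hi={self.hi}")

    def contains(self, points: np.ndarray, atol: float = 1e-9) -> np.ndarray:
        pts = np.atleast_2d(points)
        lo = np.asarray(self.lo) - atol
        hi = np.asarray(self.hi) + atol
        return np.all((pts >= lo) & (pts <= hi), axis=1)

    @property
    def extent(self) -> np.ndarray:
        return np.asarray(self.hi) - np.asarray(self.lo)

    def to_dict(self) -> dict:
        return {"lo": list(self.lo), "hi": list(self.hi)}

    @classmethod
    def from_dict(cls, d: dict) -> "Box":
        return cls(lo=tuple(d["lo"]), hi=tuple(d["hi"]))


def _catmull_rom(points: np.ndarray, samples_per_segment: int) -> np.ndarray:
    """Uniform Catmull-Rom spline through control points, endpoints clamped."""
    p = np.vstack([points[0], points, points[-1]])
    t = np.linspace(0.0, 1.0, samples_per_segment, endpoint=False)[:, None]
    segs = []
    for i in range(len(points) - 1):
        p0, p1, p2, p3 = p[i], p[i + 1], p[i + 2], p[i + 3]
        segs.append(
            0.5
            * (
                2 * p1
                + (-p0 + p2) * t
                + (2 * p0 - 5 * p1 + 4 * p2 - p3) * t**2
                + (-p0 + 3 * p1 - 3 * p2 + p3) * t**3
            )
        )
    segs.append(points[-1][None])
    return np.vstack(segs)


@dataclass
class DendritePhantom:
    """Tube of fluorescent dye around an ordered 3D centerline polyline.

    ``structural_density`` is the emission density of the structural dye
    (time-invariant); ``indicator_baseline`` is the resting indicator
    emission density F0.
    """

    centerline: np.ndarray          # (N, 3) µm
    radius: float                   # µm (scalar tube radius)
    structural_density: float       # a.u. / µm^3
    indicator_baseline: float       # a.u. / µm^3
    bounds: Box

    _arclength: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.centerline = np.asarray(self.centerline, dtype=float)
        if self.centerline.ndim != 2 or self.centerline.shape[1] != 3:
            raise ConfigError("centerline must be an (N, 3) array")
        if self.radius <= 0:
            raise ConfigError(f"radius must be > 0, got {self.radius}")
        if self.structural_density < 0 or self.indicator_baseline < 0:
            raise ConfigError("dye densities must be non-negative")
        seg = np.linalg.norm(np.diff(self.centerline, axis=0), axis=1)
        self._arclength = np.concatenate([[0.0], np.cumsum(seg)])
        if self._arclength[-1] <= 0:
            raise ConfigError("centerline arclength must be > 0")
        if not self.bounds.contains(self.centerline).all():
            raise ConfigError("centerline must lie inside bounds")

    @property
    def arclength(self) -> np.ndarray:
        """Cumulative arclength at each centerline vertex, µm."""
        return self._arclength

    @property
    def total_length(self) -> float:
        return float(self._arclength[-1])

    @property
    def z_span(self) -> float:
        return float(np.ptp(self.centerline[:, 2]))

    def point_at(self, s) -> np.ndarray:
        """Interpolate centerline position(s) at arclength ``s``."""
        s = np.clip(np.asarray(s, dtype=float), 0.0, self.total_length)
        return np.stack(
            [np.interp(s, self._arclength, self.centerline[:, i]) for i in range(3)],
            axis=-1,
        )

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "centerline": self.centerline.tolist(),
            "radius": self.radius,
            "structural_density": self.structural_density,
            "indicator_baseline": self.indicator_baseline,
            "bounds": self.bounds.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DendritePhantom":
        return cls(
            centerline=np.asarray(d["centerline"], dtype=float),
            radius=float(d["radius"]),
            structural_density=float(d["structural_density"]),
            indicator_baseline=float(d["indicator_baseline"]),
            bounds=Box.from_dict(d["bounds"]),
        )


@dataclass(frozen=True)
class DendriteConfig:
    """Geometry parameters for :func:`make_dendrite`.

    ``length`` is the approximate path length of the random walk before
    smoothing; ``z_span`` the full peak-to-peak Z extent of the centerline
    (set larger than the sweep depth when probing volume coverage);
    ``smoothness`` the control-point spacing of the walk (larger = straighter).
    """

    length: float = 120.0
    z_span: float = 20.0
    radius: float = 1.0
    smoothness: float = 10.0
    turn_sigma: float = 0.55          # rad of heading change per control step
    z_center: float = 0.0
    margin: float = 4.0               # bounds padding beyond tube, µm
    structural_density: float = 8.0
    indicator_baseline: float = 6.0
    vertex_spacing: float = 0.5       # µm resampling of the smoothed polyline


def make_dendrite(config: DendriteConfig, seed: int) -> DendritePhantom:
    """Generate a meandering dendrite phantom, deterministic for fixed seed.

    The centerline is a Catmull-Rom-smoothed 2D random walk whose Z profile
    is an independent smoothed walk rescaled to exactly ``config.z_span``.
    """
    if config.length <= 0:
        raise ConfigError(f"length must be > 0, got {config.length}")
    if config.radius <= 0:
        raise ConfigError(f"radius must be > 0, got {config.radius}")
    if config.z_span < 0:
        raise ConfigError(f"z_span must be >= 0, got {config.z_span}")
    if config.smoothness <= 0:
        raise ConfigError(f"smoothness must be > 0, got {config.smoothness}")

    rng = np.random.default_rng(seed)
    n_ctrl = max(int(round(config.length / config.smoothness)), 3) + 1

    theta = rng.uniform(0.0, 2.0 * np.pi) + np.concatenate(
        [[0.0], np.cumsum(rng.normal(0.0, config.turn_sigma, n_ctrl - 1))]
    )
    step = config.length / (n_ctrl - 1)
    xy = np.zeros((n_ctrl, 2))
    xy[1:] = np.cumsum(step * np.stack([np.cos(theta[:-1]), np.sin(theta[:-1])], axis=1), axis=0)
    xy -= 0.5 * (xy.min(axis=0) + xy.max(axis=0))

    z = np.cumsum(rng.normal(0.0, 1.0, n_ctrl))
    ctrl = np.column_stack([xy, z])

    per_seg = max(int(math.ceil(config.smoothness / config.vertex_spacing)), 2)
    line = _catmull_rom(ctrl, per_seg)

    # rescale Z of the final polyline so the realised span is exact
    zp = line[:, 2]
    if config.z_span == 0 or np.ptp(zp) == 0:
        line[:, 2] = config.z_center
    else:
        line[:, 2] = (zp - zp.min()) / np.ptp(zp) * config.z_span
        line[:, 2] += config.z_center - config.z_span / 2.0

    pad = config.radius + config.margin
    bounds = Box(lo=tuple(line.min(axis=0) - pad), hi=tuple(line.max(axis=0) + pad))
    return DendritePhantom(
        centerline=line,
        radius=config.radius,
        structural_density=config.structural_density,
        indicator_baseline=config.indicator_baseline,
        bounds=bounds,
    )


# ---------------------------------------------------------------------------
# events
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CalciumEvent:
    """Ground-truth Ca2+ transient.

    ``peak_dff`` is the dF/F peak at the origin; at arclength distance d the
    amplitude is peak_dff * exp(-d / spread_length) and the onset is delayed
    by propagation_delay * d.  ``rise_decay_b`` is derived from the peak via
    peak = b/(c*e) unless supplied, in which case consistency is enforced.
    """

    origin_arclength: float          # µm along centerline
    onset_time: float                # s
    peak_dff: float                  # dimensionless dF/F at origin
    rise_decay_c: float              # 1/s
    spread_length: float             # µm
    propagation_delay: float = 0.0   # s per µm
    rise_decay_b: float | None = None  # dF/F / s

    def __post_init__(self) -> None:
        if self.peak_dff < 0:
            raise ConfigError(f"peak_dff must be >= 0, got {self.peak_dff}")
        if self.rise_decay_c <= 0:
            raise ConfigError(f"rise_decay_c must be > 0, got {self.rise_decay_c}")
        if self.spread_length <= 0:
            raise ConfigError(f"spread_length must be > 0, got {self.spread_length}")
        if self.propagation_delay < 0:
            raise ConfigError("propagation_delay must be >= 0")
        b_expected = self.peak_dff * self.rise_decay_c * math.e
        if self.rise_decay_b is None:
            object.__setattr__(self, "rise_decay_b", b_expected)
        elif not math.isclose(self.rise_decay_b, b_expected, rel_tol=1e-6, abs_tol=1e-12):
            raise ConfigError(
                "rise_decay_b inconsistent with peak_dff: kernel max b/(c*e) "
                f"= {self.rise_decay_b / (self.rise_decay_c * math.e):.6g} "
                f"but peak_dff = {self.peak_dff:.6g}"
            )

    @property
    def time_to_peak(self) -> float:
        return 1.0 / self.rise_decay_c

    def amplitude_at(self, s: float) -> float:
        """Peak dF/F at arclength position ``s``."""
        return self.peak_dff * math.exp(-abs(s - self.origin_arclength) / self.spread_length)

    def onset_at(self, s: float) -> float:
        """Onset time at arclength position ``s`` (propagation delay applied)."""
        return self.onset_time + self.propagation_delay * abs(s - self.origin_arclength)

    def to_dict(self) -> dict:
        return {
            "origin_arclength": self.origin_arclength,
            "onset_time": self.onset_time,
            "peak_dff": self.peak_dff,
            "rise_decay_b": self.rise_decay_b,
            "rise_decay_c": self.rise_decay_c,
            "spread_length": self.spread_length,
            "propagation_delay": self.propagation_delay,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalciumEvent":
        return cls(
            origin_arclength=float(d["origin_arclength"]),
            onset_time=float(d["onset_time"]),
            peak_dff=float(d["peak_dff"]),
            rise_decay_c=float(d["rise_decay_c"]),
            spread_length=float(d["spread_length"]),
            propagation_delay=float(d.get("propagation_delay", 0.0)),
            rise_decay_b=float(d["rise_decay_b"]) if d.get("rise_decay_b") is not None else None,
        )


def place_events(
    phantom: DendritePhantom,
    specs: Sequence[CalciumEvent] | None = None,
    *,
    rate: float | None = None,
    duration: float = 10.0,
    seed: int | None = None,
    peak_range: tuple[float, float] = (0.3, 1.2),
    c_range: tuple[float, float] = (4.0, 10.0),
    spread_length: float = 6.0,
    propagation_delay: float = 0.005,
) -> list[CalciumEvent]:
    """Place ground-truth events on a phantom.

    Either pass explicit ``specs`` (validated and returned in onset order) or
    a Poisson ``rate`` in events/s over ``duration``: origins are uniform on
    the arclength domain, onsets uniform in time, peaks and rise rates drawn
    uniformly from the stated ranges.
    """
    total = phantom.total_length
    if specs is not None:
        for ev in specs:
            if not (0.0 <= ev.origin_arclength <= total):
                raise ConfigError(
                    f"event origin {ev.origin_arclength} outside arclength "
                    f"domain [0, {total:.3g}]"
                )
        return sorted(specs, key=lambda e: e.onset_time)
    if rate is None or rate < 0:
        raise ConfigError(f"rate must be >= 0, got {rate}")
    if duration <= 0:
        raise ConfigError(f"duration must be > 0, got {duration}")
    rng = np.random.default_rng(seed)
    n = int(rng.poisson(rate * duration))
    events = [
        CalciumEvent(
            origin_arclength=float(rng.uniform(0.0, total)),
            onset_time=float(rng.uniform(0.0, duration)),
            peak_dff=float(rng.uniform(*peak_range)),
            rise_decay_c=float(rng.uniform(*c_range)),
            spread_length=spread_length,
            propagation_delay=propagation_delay,
        )
        for _ in range(n)
    ]
    return sorted(events, key=lambda e: e.onset_time)


def event_truth_at_arclength(events: Sequence[CalciumEvent], s: float) -> list[dict]:
    """Expected transients at arclength ``s``: onset, amplitude, time-to-peak.

    The reference for matching detected events at an ROI against ground truth.
    """
    return [
        {
            "onset_time": ev.onset_at(s),
            "amplitude": ev.amplitude_at(s),
            "time_to_peak": ev.time_to_peak,
        }
        for ev in events
    ]


# ---------------------------------------------------------------------------
# fluorescence field
# ---------------------------------------------------------------------------

class FluorescenceField:
    """Two-channel emission-density field of a phantom plus its events.

    The structural channel is time-invariant; the indicator channel equals
    baseline * (1 + dF/F(s, t)) inside the tube, where s is the arclength of
    the nearest centerline point.  Overlapping events sum linearly in dF/F.
    """

    def __init__(self, phantom: DendritePhantom, events: Sequence[CalciumEvent] = ()):
        self.phantom = phantom
        self.events = list(events)
        # dense centerline samples used for nearest-point queries
        ds = min(0.25, phantom.radius / 2.0)
        n = max(int(math.ceil(phantom.total_length / ds)) + 1, 2)
        self._query_s = np.linspace(0.0, phantom.total_length, n)
        self._query_pts = phantom.point_at(self._query_s)
        self._tree = cKDTree(self._query_pts)
        self._vox_cache: dict = {}

    @property
    def bounds(self) -> Box:
        return self.phantom.bounds

    def dff_along(self, s, t):
        """Total dF/F at arclength position(s) ``s`` and time ``t``.

        ``s`` and ``t`` broadcast against each other.
        """
        s = np.asarray(s, dtype=float)
        total = np.zeros(np.broadcast_shapes(s.shape, np.shape(t)))
        for ev in self.events:
            d = np.abs(s - ev.origin_arclength)
            amp = ev.peak_dff * np.exp(-d / ev.spread_length)
            tt = np.asarray(t) - ev.onset_time - ev.propagation_delay * d
            total = total + amp * unit_peak_kernel(tt, ev.rise_decay_c)
        return total

    def nearest_arclength(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Distance to the centerline and arclength of the nearest point."""
        dist, idx = self._tree.query(np.atleast_2d(points))
        return dist, self._query_s[idx]

    def evaluate(self, x, y, z, t: float, channel: str):
        """Emission density at point(s) (x, y, z) and time ``t``.

        Hard tube edge: exactly zero for points farther than the radius from
        the centerline.
        """
        if channel not in CHANNELS:
            raise DataError(f"unknown channel {channel!r}; expected one of {CHANNELS}")
        x, y, z = np.broadcast_arrays(
            np.asarray(x, float), np.asarray(y, float), np.asarray(z, float)
        )
        pts = np.column_stack([x.ravel(), y.ravel(), z.ravel()])
        dist, s = self.nearest_arclength(pts)
        inside = dist <= self.phantom.radius
        out = np.zeros(pts.shape[0])
        if channel == "structural":
            out[inside] = self.phantom.structural_density
        else:
            dff = self.dff_along(s[inside], t)
            if np.any(dff < -1.0):
                raise DataError("indicator dF/F fell below -1; event set invalid")
            out[inside] = self.phantom.indicator_baseline * (1.0 + dff)
        out = out.reshape(x.shape)
        return float(out) if out.ndim == 0 else out

    # -- voxelisation (used by the acquisition forward model) ---------------

    def voxelize(self, grid):
        """Sparse voxel representation on an :class:`~lightsweep.acquisition.ImagingGrid`.

        Voxels overlapping the tube get a partial-volume occupancy in [0, 1]
        (linear anti-aliased edge one voxel wide); each voxel stores the
        arclength of its nearest centerline point for dF/F lookup.
        """
        key = grid.cache_key()
        if key in self._vox_cache:
            return self._vox_cache[key]
        from .acquisition import SparseVoxels  # local import avoids a cycle

        zz, yy, xx = np.meshgrid(grid.z, grid.y, grid.x, indexing="ij")
        pts = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
        dist, s = self.nearest_arclength(pts)
        edge = max(grid.pixel_size, grid.dz)  # anti-alias width
        occ = np.clip((self.phantom.radius + 0.5 * edge - dist) / edge, 0.0, 1.0)
        keep = occ > 0
        nz, ny, nx = len(grid.z), len(grid.y), len(grid.x)
        iz, iy, ix = np.unravel_index(np.nonzero(keep)[0], (nz, ny, nx))
        vox = SparseVoxels(
            field=self,
            shape=(nz, ny, nx),
            dz=grid.dz,
            iz=iz.astype(np.intp),
            pix=(iy * nx + ix).astype(np.intp),
            occupancy=occ[keep],
            arclength=s[keep],
        )
        self._vox_cache[key] = vox
        return vox


def evaluate_field(
    phantom: DendritePhantom,
    events: Sequence[CalciumEvent],
    x, y, z, t: float,
    channel: str,
):
    """Convenience wrapper: emission density of (phantom, events) at a point."""
    return FluorescenceField(phantom, events).evaluate(x, y, z, t, channel)


# ---------------------------------------------------------------------------
# ground-truth I/O
# ---------------------------------------------------------------------------

EVENT_CSV_COLUMNS = [
    "event_id", "origin_um", "onset_s", "peak_dff", "b", "c",
    "spread_um", "delay_s_per_um",
]


def save_ground_truth(path, phantom: DendritePhantom, events: Sequence[CalciumEvent]) -> None:
    """Serialise phantom geometry and the event table to a JSON file."""
    payload = {
        "phantom": phantom.to_dict(),
        "events": [ev.to_dict() for ev in events],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_ground_truth(path) -> tuple[DendritePhantom, list[CalciumEvent]]:
    d = json.loads(Path(path).read_text())
    phantom = DendritePhantom.from_dict(d["phantom"])
    events = [CalciumEvent.from_dict(e) for e in d["events"]]
    return phantom, events


def events_to_csv(path, events: Sequence[CalciumEvent]) -> None:
    """Export the event table as CSV."""
    rows = [
        {
            "event_id": i,
            "origin_um": ev.origin_arclength,
            "onset_s": ev.onset_time,
            "peak_dff": ev.peak_dff,
            "b": ev.rise_decay_b,
            "c": ev.rise_decay_c,
            "spread_um": ev.spread_length,
            "delay_s_per_um": ev.propagation_delay,
        }
        for i, ev in enumerate(events)
    ]
    pd.DataFrame(rows, columns=EVENT_CSV_COLUMNS).to_csv(path, index=False)
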