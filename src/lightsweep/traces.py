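"""ROI time courses and dF/F conversion with background-decay correction.

The workflow mirrors standard slice calcium-imaging practice: mean ROI
intensity per frame, an exponential decay p + q*exp(-r*t) fitted to a large
background ROI (photobleaching plus ambient floor), subtraction of that
model from every ROI trace, and normalisation by a baseline-window F0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from skimage.draw import polygon2mask

from .acquisition import FrameStack, ImagingGrid
from .errors import ConfigError, DataError
from .phantom import DendritePhantom

__all__ = [
    "Roi",
    "RoiTrace",
    "BackgroundFit",
    "extract_trace",
    "fit_background",
    "compute_dff",
    "load_rois",
    "save_rois",
    "traces_to_csv",
    "traces_from_csv",
    "dendrite_rois",
    "coverage_fraction",
]


# ---------------------------------------------------------------------------
# ROIs
# ---------------------------------------------------------------------------

@dataclass
class Roi:
    """A labelled set of pixels; rows/cols are 0-based, origin top-left."""

    label: str
    pixels: np.ndarray               # (n, 2) int array of (row, col)
    is_background: bool = False

    def __post_init__(self) -> None:
        self.pixels = np.atleast_2d(np.asarray(self.pixels, dtype=int))
        if self.pixels.size == 0:
            raise DataError(f"ROI {self.label!r}: empty pixel mask")

    @classmethod
    def from_polygon(cls, label: str, vertices, frame_shape: tuple[int, int],
                     is_background: bool = False) -> "Roi":
        """Rasterise a polygon given as (row, col) vertices."""
        mask = polygon2mask(frame_shape, np.asarray(vertices, dtype=float))
        pixels = np.argwhere(mask)
        if pixels.size == 0:
            raise DataError(f"ROI {label!r}: polygon rasterised to zero pixels")
        return cls(label=label, pixels=pixels, is_background=is_background)

    @classmethod
    def box(cls, label: str, row: int, col: int, half: int = 1,
            frame_shape: tuple[int, int] | None = None,
            is_background: bool = False) -> "Roi":
        """Square ROI of side 2*half+1 centered on (row, col)."""
        rows = np.arange(row - half, row + half + 1)
        cols = np.arange(col - half, col + half + 1)
        rr, cc = np.meshgrid(rows, cols, indexing="ij")
        pixels = np.column_stack([rr.ravel(), cc.ravel()])
        if frame_shape is not None:
            keep = (
                (pixels[:, 0] >= 0) & (pixels[:, 0] < frame_shape[0])
                & (pixels[:, 1] >= 0) & (pixels[:, 1] < frame_shape[1])
            )
            pixels = pixels[keep]
            if pixels.size == 0:
                raise DataError(f"ROI {label!r}: box entirely outside frame")
        return cls(label=label, pixels=pixels, is_background=is_background)


def load_rois(path, frame_shape: tuple[int, int]) -> list[Roi]:
    """Read ROIs from a JSON file of labelled polygons (or explicit pixels).

    Expected layout::

        {"rois": [{"label": "a", "polygon": [[r, c], ...], "background": false},
                  {"label": "bg", "pixels": [[r, c], ...], "background": true}]}
    """
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise DataError(f"malformed ROI JSON {path}: line {exc.lineno}: {exc.msg}") from exc
    if "rois" not in doc:
        raise DataError(f"ROI JSON {path} missing top-level 'rois' list")
    rois = []
    for i, entry in enumerate(doc["rois"]):
        label = entry.get("label", f"roi_{i}")
        bg = bool(entry.get("background", False))
        if "polygon" in entry:
            rois.append(Roi.from_polygon(label, entry["polygon"], frame_shape,
                                         is_background=bg))
        elif "pixels" in entry:
            rois.append(Roi(label=label, pixels=np.asarray(entry["pixels"]),
                            is_background=bg))
        else:
            raise DataError(f"ROI {label!r}: needs 'polygon' or 'pixels'")
    return rois


def save_rois(path, rois: Sequence[Roi], extra: dict | None = None) -> None:
    doc = {"rois": [
        {"label": r.label, "pixels": r.pixels.tolist(), "background": r.is_background}
        for r in rois
    ]}
    if extra:
        doc.update(extra)
    Path(path).write_text(json.dumps(doc))


# ---------------------------------------------------------------------------
# traces
# ---------------------------------------------------------------------------

@dataclass
class RoiTrace:
    """Mean-intensity time course of one ROI, optionally with dF/F."""

    label: str
    time: np.ndarray                 # s, frame mid-exposure times
    raw: np.ndarray                  # mean counts per frame
    dff: np.ndarray | None = None
    baseline_f0: float | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.raw = np.asarray(self.raw, dtype=float)
        if self.time.shape != self.raw.shape:
            raise DataError("time and raw must have equal length")
        if len(self.time) > 1:
            dt = np.diff(self.time)
            if np.any(dt <= 0):
                raise DataError("time must be strictly increasing")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0]) if len(self.time) > 1 else 0.0


def extract_trace(stack: FrameStack, roi: Roi) -> RoiTrace:
    """Mean pixel value inside the ROI at every frame."""
    t, ny, nx = stack.data.shape
    rows, cols = roi.pixels[:, 0], roi.pixels[:, 1]
    if rows.min() < 0 or cols.min() < 0 or rows.max() >= ny or cols.max() >= nx:
        raise DataError(
            f"ROI {roi.label!r} outside frame bounds {(ny, nx)}"
        )
    raw = stack.data[:, rows, cols].mean(axis=1).astype(float)
    return RoiTrace(label=roi.label, time=stack.times, raw=raw)


# ---------------------------------------------------------------------------
# background model
# ---------------------------------------------------------------------------

@dataclass
class BackgroundFit:
    """Exponential background model p + q*exp(-r*t)."""

    offset: float                    # p, counts
    amplitude: float                 # q, counts
    rate: float                      # r, 1/s
    residual_rms: float
    converged: bool = True

    def predict(self, t):
        return self.offset + self.amplitude * np.exp(-self.rate * np.asarray(t, float))

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps({
            "offset": self.offset, "amplitude": self.amplitude, "rate": self.rate,
            "residual_rms": self.residual_rms, "converged": self.converged,
        }, indent=1))


def _model(t, p, q, r):
    return p + q * np.exp(-r * t)


def fit_background(background_trace: RoiTrace) -> BackgroundFit:
    """Nonlinear least-squares fit of p + q*exp(-r*t) to a background trace.

    A constant trace short-circuits to (p=mean, q=0, r=0).  If the nonlinear
    fit fails to converge, a log-linear fallback is used and the result is
    flagged ``converged=False``.
    """
    t = background_trace.time
    y = background_trace.raw
    if len(y) < 10:
        raise DataError("background fit needs at least 10 samples")
    if np.ptp(y) == 0:
        return BackgroundFit(offset=float(y[0]), amplitude=0.0, rate=0.0,
                             residual_rms=0.0)
    # fit in units of the trace mean so the result is exactly equivariant
    # under global intensity rescaling
    scale = float(np.abs(y).mean())
    ys = y / scale
    p0_off = float(np.percentile(ys, 5))
    q0 = float(ys[0] - p0_off)
    span = float(t[-1] - t[0])
    p0 = (p0_off, q0 if q0 != 0 else float(np.ptp(ys)), 1.0 / max(span / 3.0, 1e-6))
    try:
        popt, _ = curve_fit(
            _model, t, ys, p0=p0,
            bounds=([-np.inf, -np.inf, 0.0], [np.inf, np.inf, np.inf]),
            maxfev=20000, xtol=1e-14, ftol=1e-14, gtol=1e-14,
        )
        resid = y - scale * _model(t, *popt)
        return BackgroundFit(
            offset=float(scale * popt[0]), amplitude=float(scale * popt[1]),
            rate=float(popt[2]),
            residual_rms=float(np.sqrt(np.mean(resid**2))),
        )
    except (RuntimeError, ValueError):
        # log-linear fallback: ln(y - floor) ~ ln(q) - r*t
        floor = float(y.min()) - 1e-9
        w = np.log(np.clip(y - floor, 1e-12, None))
        slope, intercept = np.polyfit(t, w, 1)
        fit = BackgroundFit(
            offset=floor, amplitude=float(np.exp(intercept)),
            rate=float(max(-slope, 0.0)), residual_rms=float("nan"),
            converged=False,
        )
        resid = y - fit.predict(t)
        fit.residual_rms = float(np.sqrt(np.mean(resid**2)))
        return fit


def compute_dff(
    raw_trace: RoiTrace,
    background_fit: BackgroundFit | None = None,
    f0_window: float | tuple[float, float] = 1.0,
    mode: str = "subtract",
) -> RoiTrace:
    """Convert a raw trace to dF/F after background-decay correction.

    ``mode='subtract'`` (default) removes the fitted background model from
    the raw trace; ``mode='divide'`` divides out the fitted decay normalised
    to t=0.  F0 is the mean of the corrected trace over ``f0_window`` —
    either a duration from the start (float, seconds) or an explicit
    (t_start, t_stop) pair.
    """
    t = raw_trace.time
    if background_fit is None:
        corrected = raw_trace.raw.copy()
    elif mode == "subtract":
        corrected = raw_trace.raw - background_fit.predict(t)
    elif mode == "divide":
        decay = background_fit.predict(t) / background_fit.predict(0.0)
        corrected = raw_trace.raw / decay
    else:
        raise ConfigError(f"unknown dF/F mode {mode!r}")
    if isinstance(f0_window, tuple):
        w0, w1 = f0_window
    else:
        w0, w1 = float(t[0]), float(t[0]) + float(f0_window)
    if w1 > t[-1] + raw_trace.dt:
        raise ConfigError("f0_window extends beyond the trace duration")
    sel = (t >= w0) & (t < w1)
    if not sel.any():
        raise ConfigError("f0_window contains no samples")
    f0 = float(corrected[sel].mean())
    if f0 <= 0:
        raise DataError(
            f"ROI {raw_trace.label!r}: baseline F0 <= 0 after background "
            "subtraction; ROI indistinguishable from background"
        )
    return RoiTrace(
        label=raw_trace.label, time=t, raw=raw_trace.raw,
        dff=(corrected - f0) / f0, baseline_f0=f0,
    )


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def traces_to_csv(path, traces: Sequence[RoiTrace]) -> None:
    """Tidy CSV: one row per (roi, frame)."""
    frames = []
    for tr in traces:
        frames.append(pd.DataFrame({
            "roi_label": tr.label,
            "frame": np.arange(len(tr.time)),
            "time_s": tr.time,
            "raw": tr.raw,
            "dff": tr.dff if tr.dff is not None else np.nan,
        }))
    # %.17g guarantees float64 round-trips bit-exactly
    pd.concat(frames, ignore_index=True).to_csv(path, index=False,
                                                float_format="%.17g")


def traces_from_csv(path) -> list[RoiTrace]:
    df = pd.read_csv(path, float_precision="round_trip")
    out = []
    for label, g in df.groupby("roi_label", sort=False):
        dff = g["dff"].to_numpy()
        out.append(RoiTrace(
            label=str(label), time=g["time_s"].to_numpy(), raw=g["raw"].to_numpy(),
            dff=None if np.isnan(dff).all() else dff,
        ))
    return out


# ---------------------------------------------------------------------------
# dendrite coverage
# ---------------------------------------------------------------------------

def dendrite_rois(
    phantom: DendritePhantom,
    grid: ImagingGrid,
    spacing: float = 2.0,
    half: int = 1,
) -> list[tuple[float, Roi]]:
    """Square ROIs centered on the projected centerline every ``spacing`` µm.

    Returns (arclength, Roi) pairs; positions projecting outside the frame
    are dropped.
    """
    out = []
    ny, nx = grid.frame_shape
    for s in np.arange(spacing / 2.0, phantom.total_length, spacing):
        x, y, _ = phantom.point_at(s)
        col = int(round((x - grid.x[0]) / grid.pixel_size))
        row = int(round((y - grid.y[0]) / grid.pixel_size))
        if not (half <= row < ny - half and half <= col < nx - half):
            continue
        out.append((float(s), Roi.box(f"s{s:07.2f}", row, col, half=half)))
    return out


def coverage_fraction(
    stack: FrameStack,
    phantom: DendritePhantom,
    grid: ImagingGrid,
    snr_threshold: float = 3.0,
    spacing: float = 2.0,
) -> float:
    """Fraction of dendrite arclength with a usable ROI trace.

    For each ROI along the projected centerline, signal is its mean raw
    intensity above the stack-wide background floor (median pixel value) and
    noise is the frame-to-frame noise estimated from first differences.  The
    fraction of ROIs with signal/noise above ``snr_threshold`` measures how
    much of the meandering dendrite an acquisition mode keeps in focus.
    """
    rois = dendrite_rois(phantom, grid, spacing=spacing)
    if not rois:
        raise DataError("no dendrite ROIs fall inside the frame")
    floor = float(np.median(stack.data))
    n_ok = 0
    for _, roi in rois:
        tr = extract_trace(stack, roi)
        signal = tr.raw.mean() - floor
        noise = float(np.std(np.diff(tr.raw)) / np.sqrt(2.0))
        if noise <= 0:
            noise = 1e-12
        if signal / noise > snr_threshold:
            n_ok += 1
    return n_ok / len(rois)
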