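"""Thick-line brightness profiles along the modular band and phase analysis.

Reproduces, automated, the plot-profile workflow used on this material: a
thick sampling contour (default thickness 100 px) is laid through the layer 2
modules in ventral-to-dorsal order, the same contour is applied to every
channel of a section, and the paired profiles are compared. The degree to
which two channels' waveforms are in or out of phase is quantified as the
Pearson correlation of the linearly detrended profiles at zero lag:
r > 0 means in-phase, r < 0 out-of-phase (one channel's troughs align with
the other's peaks).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.signal import detrend
from skimage.measure import regionprops

from .errors import ConfigError, ConstantProfileError, ContourClippedWarning
from .image import MultiChannelImage

__all__ = [
    "SamplingContour",
    "ProfilePair",
    "build_sampling_contour",
    "sample_profile",
    "phase_concordance",
    "cross_correlogram",
    "profile_pair",
]


@dataclass(frozen=True)
class SamplingContour:
    """An ordered polyline with a sampling thickness.

    ``vertices`` is an (N, 2) float array of (row, col) pixel coordinates,
    N >= 2; ``thickness`` is the width (in pixels) of the band averaged at
    each arclength step.
    """

    vertices: np.ndarray
    thickness: int = 100

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=np.float64)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 2:
            raise ConfigError("contour needs an (N>=2, 2) vertex array")
        if self.thickness < 1:
            raise ConfigError("thickness must be >= 1")
        object.__setattr__(self, "vertices", v)

    @property
    def length(self) -> float:
        d = np.diff(self.vertices, axis=0)
        return float(np.hypot(d[:, 0], d[:, 1]).sum())


@dataclass
class ProfilePair:
    """Paired brightness profiles of two channels along one contour."""

    positions: np.ndarray     # arclength, px
    channel_a: str
    channel_b: str
    values_a: np.ndarray
    values_b: np.ndarray
    r: float                  # zero-lag phase concordance

    def __post_init__(self) -> None:
        n = len(self.positions)
        if len(self.values_a) != n or len(self.values_b) != n:
            raise ConfigError("profile series lengths differ")


def build_sampling_contour(
    modules: np.ndarray, thickness: int = 100
) -> SamplingContour:
    """Polyline through module centroids, ordered ventral to dorsal.

    Centroids are sorted by increasing column index (the default
    ventral-to-dorsal mapping) and the polyline is extended by half the mean
    inter-centroid spacing at each end so terminal modules are fully
    encompassed. A single module yields a horizontal segment through its
    centroid spanning the module's bounding box.
    """
    modules = np.asarray(modules)
    props = regionprops(modules.astype(np.int32))
    if not props:
        raise ConfigError("cannot build a sampling contour from 0 modules")
    if len(props) == 1:
        p = props[0]
        r = p.centroid[0]
        _, c0, _, c1 = p.bbox
        verts = np.array([[r, float(c0)], [r, float(c1 - 1)]])
        return SamplingContour(vertices=verts, thickness=thickness)

    cents = np.array([p.centroid for p in props])
    cents = cents[np.argsort(cents[:, 1])]
    spacing = np.hypot(*np.diff(cents, axis=0).T)
    half = float(spacing.mean()) / 2.0
    first_dir = (cents[0] - cents[1]) / spacing[0]
    last_dir = (cents[-1] - cents[-2]) / spacing[-1]
    # clamp the end extensions to the modules' bounding box so the contour
    # never runs off the modular field into signal-free territory
    rows, cols = np.nonzero(modules)
    lo = np.array([rows.min(), cols.min()], dtype=float)
    hi = np.array([rows.max(), cols.max()], dtype=float)
    head = np.clip(cents[0] + half * first_dir, lo, hi)
    tail = np.clip(cents[-1] + half * last_dir, lo, hi)
    verts = np.vstack([head, cents, tail])
    return SamplingContour(vertices=verts, thickness=thickness)


def _arc_samples(contour: SamplingContour) -> Tuple[np.ndarray, np.ndarray]:
    """Resample the polyline at unit arclength; return centres and unit tangents."""
    v = contour.vertices
    seg = np.diff(v, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    total = cum[-1]
    if total <= 0:
        raise ConfigError("contour has zero length")
    s = np.arange(0.0, total + 1e-9, 1.0)
    rows = np.interp(s, cum, v[:, 0])
    cols = np.interp(s, cum, v[:, 1])
    centres = np.stack([rows, cols], axis=1)
    if len(s) > 1:
        tangents = np.gradient(centres, axis=0)
        norms = np.hypot(tangents[:, 0], tangents[:, 1])
        norms[norms == 0] = 1.0
        tangents /= norms[:, None]
    else:
        tangents = np.array([[0.0, 1.0]])
    return centres, tangents


def sample_profile(channel: np.ndarray, contour: SamplingContour) -> np.ndarray:
    """Mean intensity across the thick line at each unit arclength step.

    At each step, ``thickness`` points spaced 1 px along the perpendicular
    of the local tangent (centred on the contour) are read by bilinear
    interpolation and averaged. Sample points falling outside the image are
    clipped to the border with a :class:`ContourClippedWarning`.
    """
    channel = np.asarray(channel, dtype=np.float64)
    if channel.ndim != 2:
        raise ConfigError("channel must be a 2-D raster")
    centres, tangents = _arc_samples(contour)
    normals = np.stack([-tangents[:, 1], tangents[:, 0]], axis=1)
    t = contour.thickness
    offsets = np.arange(t, dtype=np.float64) - (t - 1) / 2.0
    rows = centres[:, 0:1] + offsets[None, :] * normals[:, 0:1]
    cols = centres[:, 1:2] + offsets[None, :] * normals[:, 1:2]
    h, w = channel.shape
    if rows.min() < 0 or rows.max() > h - 1 or cols.min() < 0 or cols.max() > w - 1:
        warnings.warn(
            "thickened contour exits the image; samples clipped to the border",
            ContourClippedWarning,
        )
    samples = map_coordinates(
        channel, [rows.ravel(), cols.ravel()], order=1, mode="nearest"
    ).reshape(rows.shape)
    return samples.mean(axis=1)


def arclength_positions(contour: SamplingContour) -> np.ndarray:
    """The arclength grid (px) used by :func:`sample_profile`."""
    centres, _ = _arc_samples(contour)
    return np.arange(len(centres), dtype=np.float64)


def _detrended(series: np.ndarray) -> np.ndarray:
    x = np.asarray(series, dtype=np.float64)
    if x.ndim != 1 or x.size < 8:
        raise ConfigError("profile series must be 1-D with length >= 8")
    return detrend(x, type="linear")


def phase_concordance(a: np.ndarray, b: np.ndarray) -> float:
    """Zero-lag Pearson correlation of the linearly detrended series.

    Negative values indicate out-of-phase (anti-aligned) waveforms, positive
    values in-phase ones. Identical (or exactly negated) detrended series
    return exactly +1 (-1). Raises :class:`ConstantProfileError` when either
    series is constant after detrending.
    """
    da, db = _detrended(a), _detrended(b)
    if len(da) != len(db):
        raise ConfigError("series lengths differ")
    sa, sb = float(np.std(da)), float(np.std(db))
    if sa < 1e-12 or sb < 1e-12:
        raise ConstantProfileError(
            "a profile is constant after detrending; phase undefined"
        )
    if np.array_equal(da, db):
        return 1.0
    if np.array_equal(da, -db):
        return -1.0
    r = float(np.corrcoef(da, db)[0, 1])
    return float(np.clip(r, -1.0, 1.0))


def cross_correlogram(
    a: np.ndarray, b: np.ndarray, max_lag: Optional[int] = None
) -> Tuple[np.ndarray, np.ndarray]:
    """Diagnostic lag sweep: Pearson r of the detrended series at each lag.

    A positive lag k means ``b`` trails ``a`` by k arclength steps (so
    ``b = roll(a, k)`` peaks at +k). Lags with fewer than 8 overlapping
    samples are excluded.
    """
    da, db = _detrended(a), _detrended(b)
    if len(da) != len(db):
        raise ConfigError("series lengths differ")
    n = len(da)
    if max_lag is None:
        max_lag = n // 4
    max_lag = min(max_lag, n - 8)
    lags = np.arange(-max_lag, max_lag + 1)
    rs = np.empty(lags.shape, dtype=np.float64)
    for i, lag in enumerate(lags):
        if lag >= 0:
            xa, xb = da[: n - lag], db[lag:]
        else:
            xa, xb = da[-lag:], db[: n + lag]
        if np.std(xa) < 1e-12 or np.std(xb) < 1e-12:
            rs[i] = np.nan
        else:
            rs[i] = np.corrcoef(xa, xb)[0, 1]
    return lags, rs


def profile_pair(
    image: MultiChannelImage,
    channel_a: str,
    channel_b: str,
    contour: SamplingContour,
) -> ProfilePair:
    """Sample both channels along one identical contour and score their phase."""
    va = sample_profile(image[channel_a], contour)
    vb = sample_profile(image[channel_b], contour)
    return ProfilePair(
        positions=np.arange(len(va), dtype=np.float64),
        channel_a=channel_a,
        channel_b=channel_b,
        values_a=va,
        values_b=vb,
        r=phase_concordance(va, vb),
    )
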