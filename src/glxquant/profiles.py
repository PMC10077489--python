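"""Capillary-loop contour extraction and perpendicular profile sampling.

The membrane-channel ridge of a preselected capillary loop is traced,
smoothed with a periodic spline, and profile lines are placed perpendicular
to the local tangent, oriented from the lumen (inside) to the abluminal
side (outside).  Both channels are then sampled along each line with
sub-pixel bilinear interpolation.

Coordinate convention: continuous micrometre coordinates ``(x, y)`` with
``x`` running along columns and ``y`` along rows; the centre of pixel
``(row, col)`` sits at ``((col + 0.5) * pixel_size, (row + 0.5) * pixel_size)``.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from matplotlib.path import Path as _MplPath
from scipy import interpolate, ndimage
from skimage import filters, measure, morphology
from skimage.segmentation import flood

log = logging.getLogger(__name__)

DEFAULT_LINE_LENGTH_UM = 2.0
DEFAULT_LINE_STEP_UM = 0.05
DEFAULT_N_LINES = 200

__all__ = [
    "ChannelImagePair",
    "LoopContour",
    "ProfileLine",
    "IntensityProfile",
    "ContourError",
    "ProfileError",
    "extract_contour",
    "place_lines_auto",
    "place_lines_manual",
    "sample_profile",
    "save_overlay",
]


class ContourError(RuntimeError):
    """Raised when no usable membrane ridge can be traced."""


class ProfileError(RuntimeError):
    """Raised when a profile line cannot be sampled."""


@dataclass(frozen=True)
class ChannelImagePair:
    """Two co-registered single-plane channels with a physical pixel size.

    ``glx`` is the glycocalyx-lectin channel, ``membrane`` the cell-membrane
    channel; ``pixel_size`` is in micrometre per pixel.
    """

    glx: np.ndarray
    membrane: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        glx = np.asarray(self.glx, dtype=float)
        mem = np.asarray(self.membrane, dtype=float)
        if glx.ndim != 2 or mem.ndim != 2:
            raise ValueError("channels must be 2D intensity grids")
        if glx.shape != mem.shape:
            raise ValueError(
                f"channel shapes differ: {glx.shape} vs {mem.shape}"
            )
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be > 0")
        if glx.min() < 0 or mem.min() < 0:
            raise ValueError("intensities must be non-negative")
        object.__setattr__(self, "glx", glx)
        object.__setattr__(self, "membrane", mem)

    @property
    def shape(self) -> tuple[int, int]:
        return self.glx.shape

    @property
    def extent_um(self) -> tuple[float, float]:
        """(width, height) of the field of view in micrometres."""
        nrows, ncols = self.shape
        return ncols * self.pixel_size, nrows * self.pixel_size


@dataclass(frozen=True)
class LoopContour:
    """Ordered sub-pixel trace of the membrane ridge of one capillary loop."""

    points: np.ndarray  # (n, 2) xy in um, ordered around the loop
    closed: bool
    interior_point: np.ndarray  # (2,) xy in um, a point in the lumen

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 8:
            raise ValueError("contour needs >= 8 (x, y) points")
        interior = np.asarray(self.interior_point, dtype=float).reshape(2)
        if self.closed:
            poly = _MplPath(pts)
            if not poly.contains_point(interior):
                raise ValueError("interior_point does not lie inside the contour")
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "interior_point", interior)

    def perimeter(self) -> float:
        pts = self.points
        closed = np.vstack([pts, pts[:1]]) if self.closed else pts
        return float(np.sum(np.hypot(*np.diff(closed, axis=0).T)))

    def mean_radius(self) -> float:
        c = self.points.mean(axis=0)
        return float(np.mean(np.hypot(*(self.points - c).T)))


@dataclass(frozen=True)
class ProfileLine:
    """Oriented sampling segment running lumen (start) -> abluminal (end)."""

    start: np.ndarray
    end: np.ndarray
    step: float = DEFAULT_LINE_STEP_UM
    line_id: str | None = None

    def __post_init__(self) -> None:
        start = np.asarray(self.start, dtype=float).reshape(2)
        end = np.asarray(self.end, dtype=float).reshape(2)
        if not np.hypot(*(end - start)) > 0:
            raise ValueError("profile line has zero length")
        if not self.step > 0:
            raise ValueError("step must be > 0")
        object.__setattr__(self, "start", start)
        object.__setattr__(self, "end", end)

    @property
    def length(self) -> float:
        return float(np.hypot(*(self.end - self.start)))

    @property
    def direction(self) -> np.ndarray:
        return (self.end - self.start) / self.length

    def sample_distances(self) -> np.ndarray:
        n = int(np.floor(self.length / self.step + 1e-9)) + 1
        return np.arange(n) * self.step


@dataclass(frozen=True)
class IntensityProfile:
    """Per-channel intensities sampled at uniform offsets along one line."""

    distances: np.ndarray
    glx_values: np.ndarray
    membrane_values: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.distances, dtype=float)
        g = np.asarray(self.glx_values, dtype=float)
        m = np.asarray(self.membrane_values, dtype=float)
        if not (d.shape == g.shape == m.shape) or d.ndim != 1:
            raise ValueError("distances and value vectors must share length")
        dd = np.diff(d)
        if d.size >= 2 and (np.any(dd <= 0) or not np.allclose(dd, dd[0])):
            raise ValueError("distances must be strictly increasing and uniform")
        object.__setattr__(self, "distances", d)
        object.__setattr__(self, "glx_values", g)
        object.__setattr__(self, "membrane_values", m)


def extract_contour(
    images: ChannelImagePair,
    seed_point,
    smooth_sigma_um: float = 0.1,
    threshold: float | None = None,
    n_points: int = 2048,
) -> LoopContour:
    """Trace the membrane-channel ridge enclosing *seed_point*.

    The membrane channel is Gaussian-smoothed and thresholded (Otsu unless
    *threshold* is given), the ring component surrounding the seed is
    skeletonised, and the skeleton is smoothed with a periodic spline.

    Raises :class:`ContourError` when no closed ridge surrounds the seed or
    the ridge touches the image border.
    """
    seed = np.asarray(seed_point, dtype=float).reshape(2)
    ps = images.pixel_size
    nrows, ncols = images.shape
    col = int(seed[0] / ps)
    row = int(seed[1] / ps)
    if not (0 <= row < nrows and 0 <= col < ncols):
        raise ValueError(f"seed point {tuple(seed)} um lies outside the image")

    smoothed = ndimage.gaussian_filter(images.membrane, smooth_sigma_um / ps)
    if np.ptp(smoothed) == 0:
        raise ContourError("no closed ridge found: membrane channel is constant")
    thr = filters.threshold_otsu(smoothed) if threshold is None else threshold
    mask = smoothed > thr
    if mask[row, col]:
        raise ContourError("seed point lies on the membrane ridge, not in the lumen")

    # lumen = connected below-threshold region around the seed; if it leaks
    # to the border there is no closed ridge
    lumen = flood(mask, (row, col), connectivity=1)
    if lumen[0, :].any() or lumen[-1, :].any() or lumen[:, 0].any() or lumen[:, -1].any():
        raise ContourError("no closed ridge found around the seed point")

    labels = measure.label(mask, connectivity=2)
    touching = np.unique(labels[ndimage.binary_dilation(lumen) & mask])
    touching = touching[touching > 0]
    if touching.size == 0:
        raise ContourError("no closed ridge found around the seed point")
    ring = np.isin(labels, touching)
    if ring[0, :].any() or ring[-1, :].any() or ring[:, 0].any() or ring[:, -1].any():
        raise ContourError("membrane ridge touches the image border")

    skel = morphology.skeletonize(ring)
    rows, cols = np.nonzero(skel)
    if rows.size < 8:
        raise ContourError("ridge skeleton too short to form a contour")
    xs = (cols + 0.5) * ps
    ys = (rows + 0.5) * ps
    order = np.argsort(np.arctan2(ys - seed[1], xs - seed[0]))
    xs, ys = xs[order], ys[order]

    # periodic smoothing spline over the angle-ordered skeleton; smoothing
    # absorbs the half-pixel quantisation of the skeleton
    smooth = xs.size * (0.5 * ps) ** 2
    tck, _ = interpolate.splprep([xs, ys], s=smooth, per=True, quiet=2)
    u = np.linspace(0.0, 1.0, 512, endpoint=False)
    cx, cy = interpolate.splev(u, tck)
    dx, dy = interpolate.splev(u, tck, der=1)

    # refine onto the intensity ridge: parabolic sub-pixel maximum of the
    # smoothed membrane channel along each local normal
    tnorm = np.hypot(dx, dy)
    nx, ny = -dy / tnorm, dx / tnorm
    offs = np.arange(-3.0, 3.01, 0.25) * ps
    px = cx[:, None] + offs[None, :] * nx[:, None]
    py = cy[:, None] + offs[None, :] * ny[:, None]
    vals = ndimage.map_coordinates(
        smoothed, [py.ravel() / ps - 0.5, px.ravel() / ps - 0.5],
        order=3, mode="nearest",
    ).reshape(px.shape)
    imax = np.clip(np.argmax(vals, axis=1), 1, offs.size - 2)
    rows512 = np.arange(u.size)
    y0, y1, y2 = vals[rows512, imax - 1], vals[rows512, imax], vals[rows512, imax + 1]
    denom = y0 - 2 * y1 + y2
    delta = np.where(denom != 0, 0.5 * (y0 - y2) / denom, 0.0) * (offs[1] - offs[0])
    doff = offs[imax] + delta
    rx, ry = cx + doff * nx, cy + doff * ny

    tck2, _ = interpolate.splprep(
        [rx, ry], s=rx.size * (0.1 * ps) ** 2, per=True, quiet=2
    )
    u2 = np.linspace(0.0, 1.0, n_points, endpoint=False)
    fx, fy = interpolate.splev(u2, tck2)
    return LoopContour(np.column_stack([fx, fy]), closed=True, interior_point=seed)


def place_lines_auto(
    contour: LoopContour,
    n_lines: int = DEFAULT_N_LINES,
    length: float = DEFAULT_LINE_LENGTH_UM,
    step: float = DEFAULT_LINE_STEP_UM,
) -> list[ProfileLine]:
    """Place *n_lines* lines at equal arc-length spacing along *contour*.

    Each line is perpendicular to the local contour tangent, centred on the
    contour, and oriented inside -> outside.
    """
    if n_lines < 1:
        raise ValueError("n_lines must be >= 1")
    n_samples = int(np.floor(length / step + 1e-9)) + 1
    if n_samples < 8:
        raise ValueError(
            f"length/step yields only {n_samples} samples; >= 8 required"
        )

    pts = contour.points
    closed = np.vstack([pts, pts[:1]])
    seg = np.diff(closed, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    total = cum[-1]
    targets = (np.arange(n_lines) + 0.5) * total / n_lines

    idx = np.clip(np.searchsorted(cum, targets, side="right") - 1, 0, len(seg) - 1)
    frac = (targets - cum[idx]) / seglen[idx]
    anchors = closed[idx] + frac[:, None] * seg[idx]
    tangents = seg[idx] / seglen[idx][:, None]
    normals = np.column_stack([-tangents[:, 1], tangents[:, 0]])
    outward = np.sign(
        np.einsum("ij,ij->i", normals, anchors - contour.interior_point)
    )
    outward[outward == 0] = 1.0
    normals *= outward[:, None]

    half = length / 2.0
    return [
        ProfileLine(a - half * n, a + half * n, step=step, line_id=f"auto_{i:04d}")
        for i, (a, n) in enumerate(zip(anchors, normals))
    ]


def place_lines_manual(
    roi_lines,
    step: float = DEFAULT_LINE_STEP_UM,
) -> list[ProfileLine]:
    """Convert manually drawn ``(start, end)`` segments to profile lines.

    The stated orientation is preserved: no reorientation is applied, so the
    annotator is responsible for drawing inside -> outside.
    """
    lines: list[ProfileLine] = []
    for i, (start, end) in enumerate(roi_lines):
        start = np.asarray(start, dtype=float)
        end = np.asarray(end, dtype=float)
        if not np.hypot(*(end - start)) > 0:
            raise ValueError(f"ROI segment {i} has zero length")
        lines.append(ProfileLine(start, end, step=step, line_id=f"manual_{i:04d}"))
    if not lines:
        log.warning("place_lines_manual received an empty ROI list")
    return lines


def sample_profile(images: ChannelImagePair, line: ProfileLine) -> IntensityProfile:
    """Sample both channels along *line* with bilinear sub-pixel interpolation."""
    d = line.sample_distances()
    pos = line.start + d[:, None] * line.direction
    width, height = images.extent_um
    if (
        pos[:, 0].min() < 0
        or pos[:, 1].min() < 0
        or pos[:, 0].max() > width
        or pos[:, 1].max() > height
    ):
        raise ProfileError(
            f"profile line {line.line_id or tuple(line.start)} exits the image bounds"
        )
    ps = images.pixel_size
    coords = np.vstack([pos[:, 1] / ps - 0.5, pos[:, 0] / ps - 0.5])
    glx = ndimage.map_coordinates(images.glx, coords, order=1, mode="nearest")
    mem = ndimage.map_coordinates(images.membrane, coords, order=1, mode="nearest")
    return IntensityProfile(distances=d, glx_values=glx, membrane_values=mem)


def save_overlay(images: ChannelImagePair, contour, lines, path) -> None:
    """Write a PNG overlay of the membrane channel, contour, and lines."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    width, height = images.extent_um
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(
        images.membrane,
        cmap="gray",
        extent=(0, width, height, 0),
        interpolation="nearest",
    )
    if contour is not None:
        pts = np.vstack([contour.points, contour.points[:1]])
        ax.plot(pts[:, 0], pts[:, 1], "-", color="cyan", lw=1)
    for ln in lines or []:
        ax.plot(
            [ln.start[0], ln.end[0]], [ln.start[1], ln.end[1]],
            "-", color="yellow", lw=0.3, alpha=0.6,
        )
    ax.set_xlabel("x (um)")
    ax.set_ylabel("y (um)")
    fig.savefig(path, dpi=150)
    plt.close(fig)
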