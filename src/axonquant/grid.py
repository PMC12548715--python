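"""Systematic ROI sampling: square windows, region assignment, intensity profiles.

Montaged sections are sampled with square windows (default 89.51 um side)
placed at fixed intervals (default 100 um) along x and y. Each window is
assigned to one of three anatomical compartments — the medial mediodorsal
nucleus (MDm), the MDm-PVT transition zone, or the PVT core — by majority
vote over a region label map, and carries measurements (mean fluorescence
per channel, axon density) used for the gradient and correlation analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "RoiWindow",
    "RoiGrid",
    "LineProfile",
    "build_grid",
    "assign_regions",
    "roi_mean_intensity",
    "line_profile",
]

REGIONS = ("MDm", "transition", "core")
EXCLUDED = "excluded"


@dataclass
class RoiWindow:
    """One square sampling window; origin is the (y, x) corner in um."""

    origin_um: tuple[float, float]
    side_um: float
    region: str = ""
    included: bool = True
    measurements: dict = field(default_factory=dict)


@dataclass
class RoiGrid:
    windows: list[RoiWindow]
    spacing_um: float
    window_um: float
    pixel_size_um: float = 1.0

    @property
    def included(self) -> list[RoiWindow]:
        return [w for w in self.windows if w.included]


@dataclass
class LineProfile:
    """Mean intensity along a polyline, averaged across a perpendicular band."""

    distance_um: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.distance_um, dtype=float)
        if d.size and not np.all(np.diff(d) > 0):
            raise ValueError("profile distances must be strictly increasing")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("profile intensities must be finite")


def build_grid(
    image_extent_um: tuple[float, float],
    spacing_um: float = 100.0,
    window_um: float = 89.51,
    origin_um: tuple[float, float] = (0.0, 0.0),
    pixel_size_um: float = 1.0,
) -> RoiGrid:
    """Deterministic tiling of square windows from an origin corner.

    Window corners sit at ``origin + k * spacing`` along y and x; windows
    extending beyond the image extent are kept in the list but marked
    excluded, so the tiling itself never depends on the image content.
    """
    if spacing_um <= 0 or window_um <= 0:
        raise ValueError("spacing and window side must be strictly positive")
    ey, ex = image_extent_um
    oy, ox = origin_um
    windows = []
    y = oy
    while y < ey:
        x = ox
        while x < ex:
            inside = (y >= 0 and x >= 0 and y + window_um <= ey and x + window_um <= ex)
            windows.append(
                RoiWindow((y, x), window_um, region="" if inside else EXCLUDED,
                          included=inside)
            )
            x += spacing_um
        y += spacing_um
    return RoiGrid(windows, spacing_um, window_um, pixel_size_um)


def _window_slices(window: RoiWindow, pixel_size_um: float, shape) -> tuple[slice, slice]:
    y0 = int(round(window.origin_um[0] / pixel_size_um))
    x0 = int(round(window.origin_um[1] / pixel_size_um))
    n = int(round(window.side_um / pixel_size_um))
    y1, x1 = min(y0 + n, shape[0]), min(x0 + n, shape[1])
    return slice(y0, y1), slice(x0, x1)


def assign_regions(grid: RoiGrid, label_map: np.ndarray) -> RoiGrid:
    """Label each included window by the majority region of its pixels.

    ``label_map`` is a 2D array of strings over {"MDm", "transition",
    "core", "none"} covering the image at ``grid.pixel_size_um``. Windows
    whose majority label is "none", or with an exact tie for the majority,
    are excluded — mirroring the practice of omitting anatomically ambiguous
    squares rather than forcing a call.
    """
    if label_map is None:
        raise ValueError("a region label map is required")
    label_map = np.asarray(label_map)
    for w in grid.windows:
        if not w.included:
            continue
        sy, sx = _window_slices(w, grid.pixel_size_um, label_map.shape)
        patch = label_map[sy, sx]
        if patch.size == 0:
            w.included, w.region = False, EXCLUDED
            continue
        names, counts = np.unique(patch, return_counts=True)
        order = np.argsort(counts)[::-1]
        top = names[order[0]]
        tie = counts.size > 1 and counts[order[0]] == counts[order[1]]
        if top not in REGIONS or tie:
            w.included, w.region = False, EXCLUDED
        else:
            w.region = str(top)
    return grid


def roi_mean_intensity(image: np.ndarray, window: RoiWindow, pixel_size_um: float = 1.0) -> float:
    """Arithmetic mean of pixel intensities inside the window (raw AU, no
    background subtraction)."""
    if not window.included:
        raise ValueError("window is excluded from analysis")
    sy, sx = _window_slices(window, pixel_size_um, image.shape)
    patch = np.asarray(image, dtype=float)[sy, sx]
    if patch.size == 0:
        raise ValueError("window covers no pixels")
    return float(patch.mean())


def measure_grid(
    grid: RoiGrid, images: dict[str, np.ndarray], pixel_size_um: float | None = None
) -> RoiGrid:
    """Record per-window mean intensity for every named channel image."""
    ps = grid.pixel_size_um if pixel_size_um is None else pixel_size_um
    for w in grid.included:
        for channel, image in images.items():
            w.measurements[f"mean_{channel}"] = roi_mean_intensity(image, w, ps)
    return grid


def label_map_from_polygons(
    polygons: dict[str, np.ndarray],
    shape: tuple[int, int],
    pixel_size_um: float = 1.0,
) -> np.ndarray:
    """Rasterize named closed polygons (vertices in um, (y, x) order) into a
    string label map; pixels outside every polygon get "none". Later entries
    overwrite earlier ones where polygons overlap."""
    yy, xx = np.meshgrid(
        (np.arange(shape[0]) + 0.5) * pixel_size_um,
        (np.arange(shape[1]) + 0.5) * pixel_size_um,
        indexing="ij",
    )
    labels = np.full(shape, "none", dtype="<U16")
    for name, verts in polygons.items():
        verts = np.asarray(verts, dtype=float).reshape(-1, 2)
        inside = np.zeros(shape, dtype=bool)
        n = len(verts)
        for i in range(n):  # crossing-number point-in-polygon, vectorized per edge
            y1, x1 = verts[i]
            y2, x2 = verts[(i + 1) % n]
            if y1 == y2:
                continue
            cond = (yy >= min(y1, y2)) & (yy < max(y1, y2))
            x_at = x1 + (yy - y1) * (x2 - x1) / (y2 - y1)
            inside ^= cond & (xx < x_at)
        labels[inside] = name
    return labels


def line_profile(
    image: np.ndarray,
    polyline_um: np.ndarray,
    band_width_um: float,
    step_um: float,
    pixel_size_um: float = 1.0,
) -> LineProfile:
    """Mean intensity at arc-length steps along a polyline.

    At every step the intensity is averaged over a band of
    ``band_width_um`` perpendicular to the local direction (bilinear
    interpolation at sub-pixel sample points). A band of one pixel or less
    degenerates to nearest-line sampling.
    """
    polyline = np.asarray(polyline_um, dtype=float).reshape(-1, 2)  # (y, x) um
    seg = np.linalg.norm(np.diff(polyline, axis=0), axis=1)
    total = float(seg.sum())
    if total <= 0:
        raise ValueError("polyline has zero length")
    if step_um <= 0 or band_width_um <= 0:
        raise ValueError("step and band width must be positive")
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    distances = np.arange(0.0, total + 1e-9, step_um)
    # positions and unit tangents at each sample distance
    pos = np.column_stack([np.interp(distances, arc, polyline[:, k]) for k in range(2)])
    tangents = np.empty_like(pos)
    seg_dirs = np.diff(polyline, axis=0) / seg[:, None]
    idx = np.clip(np.searchsorted(arc, distances, side="right") - 1, 0, len(seg) - 1)
    tangents = seg_dirs[idx]
    normals = np.column_stack([-tangents[:, 1], tangents[:, 0]])

    n_band = max(int(np.ceil(band_width_um / pixel_size_um)), 1)
    offsets = (
        np.linspace(-band_width_um / 2, band_width_um / 2, n_band)
        if n_band > 1
        else np.array([0.0])
    )
    img = np.asarray(image, dtype=float)
    samples = pos[:, None, :] + offsets[None, :, None] * normals[:, None, :]
    coords = samples.reshape(-1, 2).T / pixel_size_um  # pixel units, (y, x)
    values = ndimage.map_coordinates(img, coords, order=1, mode="nearest")
    intensity = values.reshape(len(distances), -1).mean(axis=1)
    return LineProfile(distances, intensity)
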