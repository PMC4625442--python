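"""Time-lapse microcolony image analysis.

Implements the imaging chain for early biofilm movies: flat-field estimation
from the first-timepoint position grid, grid stitching, local-variance colony
segmentation, contour extraction, algebraic circle fits, centre tracking,
fluorescent-patch segmentation inside colony ROIs, radius-normalized polar
coordinates, and clone assignment on the pooled unit disk.

Coordinate convention: rasters are ``(row, col)``, 0-based, pixel centres at
integers.  Analysis coordinates are ``x = col`` (rightward) and ``y`` upward,
i.e. ``y = -(row - cy)`` about a colony centre — angles are measured from the
+x axis, counterclockwise.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

__all__ = [
    "IlluminationField",
    "ColonyTrack",
    "FluorescentPatch",
    "NormalizedCoordinates",
    "estimate_illumination",
    "local_variance",
    "stitch_grid",
    "segment_colonies",
    "extract_contour",
    "fit_circle",
    "track_colonies",
    "segment_fluorescence",
    "normalize_coordinates",
    "assign_clones",
]

_CROSS = ndimage.generate_binary_structure(2, 1)  # 3x3 cross


@dataclass
class IlluminationField:
    """Multiplicative illumination field, normalized to mean 1."""

    raster: np.ndarray
    normalization: float

    def correct(self, image: np.ndarray) -> np.ndarray:
        return np.asarray(image, float) / self.raster


@dataclass
class ColonyTrack:
    """Per-frame circle of one tracked microcolony.

    ``valid`` flags form a prefix: once a colony has grown into another, the
    remainder of the track is invalid for clone analysis.
    """

    track_id: int
    frames: List[int] = field(default_factory=list)
    centers: List[Tuple[float, float]] = field(default_factory=list)  # (x, y) px
    radii: List[float] = field(default_factory=list)
    valid: List[bool] = field(default_factory=list)

    def circle_at(self, frame: int) -> Tuple[float, float, float]:
        i = self.frames.index(frame)
        return (*self.centers[i], self.radii[i])

    @property
    def n_valid(self) -> int:
        return int(np.sum(self.valid))


@dataclass
class FluorescentPatch:
    """Connected set of background-corrected fluorescent pixels in one frame."""

    frame: int
    coords: np.ndarray  # (n, 2) raster (row, col)
    intensities: np.ndarray  # background-corrected, > 0
    colony_id: int = 0


@dataclass
class NormalizedCoordinates:
    """Radius-normalized polar coordinates of pixels about a colony circle."""

    r_norm: np.ndarray  # r / R, >= 0
    theta: np.ndarray  # [0, 2π)
    frame: Optional[int] = None


# ---------------------------------------------------------------------------
# Illumination and stitching
# ---------------------------------------------------------------------------

def estimate_illumination(
    images: np.ndarray, smoothing_scale: float = 25.0
) -> IlluminationField:
    """Flat-field from first-timepoint images of all stage positions.

    At the start of the experiment only single cells are present, so the
    normalized, smoothed, pixelwise average over positions shows nothing but
    the illumination.  Correction of an image is division by the field.
    """
    stack = np.asarray(images, float)
    if stack.ndim != 3:
        raise ValueError("expected a (positions, rows, cols) stack")
    if stack.shape[0] < 10:
        warnings.warn(
            f"only {stack.shape[0]} positions; illumination estimate may retain "
            "cell content",
            stacklevel=2,
        )
    mean_img = stack.mean(axis=0)
    if not np.any(mean_img):
        raise ValueError("all-zero images: cannot estimate illumination")
    smoothed = ndimage.gaussian_filter(mean_img, smoothing_scale)
    norm = float(smoothed.mean())
    return IlluminationField(raster=smoothed / norm, normalization=norm)


def stitch_grid(
    tiles: Sequence[np.ndarray], metadata: Dict[str, object]
) -> np.ndarray:
    """Place per-position tiles on their stated regular grid.

    ``metadata`` must provide ``grid_shape`` (rows, cols of positions),
    ``tile_shape``, and optionally ``overlap`` (px, linear blending in the
    shared band) and ``order`` (only ``"row-major"`` is supported).
    """
    gr, gc = metadata["grid_shape"]
    tr, tc = metadata["tile_shape"]
    overlap = int(metadata.get("overlap", 0))
    if metadata.get("order", "row-major") != "row-major":
        raise ValueError("only row-major tile order is supported")
    n_expected = gr * gc
    if len(tiles) != n_expected:
        missing = n_expected - len(tiles)
        raise ValueError(f"missing {missing} tile(s): expected {n_expected}, got {len(tiles)}")
    for i, t in enumerate(tiles):
        if t.shape != (tr, tc):
            raise ValueError(f"tile {i} has shape {t.shape}, expected {(tr, tc)}")
    step_r, step_c = tr - overlap, tc - overlap
    if step_r <= 0 or step_c <= 0:
        raise ValueError("overlap must be smaller than the tile size")
    out_r = step_r * (gr - 1) + tr
    out_c = step_c * (gc - 1) + tc
    acc = np.zeros((out_r, out_c))
    wsum = np.zeros((out_r, out_c))
    wr = _tile_weight(tr, overlap)
    wc = _tile_weight(tc, overlap)
    w = wr[:, None] * wc[None, :]
    for i, tile in enumerate(tiles):
        r, c = divmod(i, gc)
        r0, c0 = r * step_r, c * step_c
        acc[r0 : r0 + tr, c0 : c0 + tc] += tile * w
        wsum[r0 : r0 + tr, c0 : c0 + tc] += w
    return acc / wsum


def _tile_weight(n: int, overlap: int) -> np.ndarray:
    w = np.ones(n)
    if overlap > 0:
        ramp = np.linspace(1.0 / (overlap + 1), 1.0 - 1.0 / (overlap + 1), overlap)
        w[:overlap] = ramp
        w[-overlap:] = ramp[::-1]
    return w


# ---------------------------------------------------------------------------
# Colony segmentation
# ---------------------------------------------------------------------------

def local_variance(image: np.ndarray, window: int = 5) -> np.ndarray:
    """Local intensity variance in ``window × window`` neighbourhoods."""
    img = np.asarray(image, float)
    mean = ndimage.uniform_filter(img, window)
    mean_sq = ndimage.uniform_filter(img * img, window)
    return np.maximum(mean_sq - mean * mean, 0.0)


def segment_colonies(
    image: np.ndarray,
    window: int = 5,
    threshold: Optional[float] = None,
    morph_iterations: int = 3,
) -> np.ndarray:
    """Label growing microcolonies by their high local intensity variance.

    Colonies show strong pixel-to-pixel contrast (dark and bright cell bodies)
    while empty agar is smooth, so thresholding the 5×5 local-variance image
    (Otsu by default, or a fixed ``threshold``) marks colony area.  The binary
    image is dilated to connect the segmentation, eroded the same number of
    times to shrink the contour back onto the cells at the front, and
    hole-filled; connected components are labeled.
    """
    img = np.asarray(image, float)
    if img.max() > 0 and np.mean(img >= img.max()) > 0.25:
        warnings.warn("image appears saturated; variance segmentation may fail", stacklevel=2)
    var = local_variance(img, window)
    if threshold is None:
        if np.ptp(var) == 0:
            return np.zeros(img.shape, dtype=int)
        threshold = threshold_otsu(var)
    binary = var > threshold
    if not binary.any():
        return np.zeros(img.shape, dtype=int)
    if morph_iterations > 0:
        binary = ndimage.binary_dilation(binary, _CROSS, iterations=morph_iterations)
        binary = ndimage.binary_erosion(binary, _CROSS, iterations=morph_iterations)
    binary = ndimage.binary_fill_holes(binary)
    labels, _ = ndimage.label(binary, _CROSS)
    return labels


def extract_contour(mask: np.ndarray) -> Dict[int, np.ndarray]:
    """Contour pixels per label: pixels removed by one further binary erosion."""
    labels = np.asarray(mask)
    out: Dict[int, np.ndarray] = {}
    for lab in np.unique(labels):
        if lab == 0:
            continue
        m = labels == lab
        contour = m & ~ndimage.binary_erosion(m, _CROSS, border_value=0)
        out[int(lab)] = np.argwhere(contour)
    return out


def fit_circle(points: np.ndarray) -> Tuple[float, float, float, float]:
    """Algebraic (Kåsa) least-squares circle through raster points.

    ``points`` is an ``(n, 2)`` array of ``(row, col)`` pixels.  Returns
    ``(cx, cy, radius, rms_residual)`` with the centre in ``(x=col, y=row)``
    pixel units.  Exact on noise-free circles; raises on fewer than three
    points or collinear input.
    """
    pts = np.asarray(points, float)
    if pts.ndim != 2 or pts.shape[0] < 3:
        raise ValueError("need at least 3 points for a circle fit")
    y = pts[:, 0]
    x = pts[:, 1]
    A = np.column_stack([2.0 * x, 2.0 * y, np.ones_like(x)])
    b = x * x + y * y
    sol, residuals, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < 3:
        raise ValueError("collinear points: circle is undetermined")
    cx, cy, c = sol
    r2 = c + cx * cx + cy * cy
    if r2 <= 0:
        raise ValueError("degenerate circle fit")
    radius = math.sqrt(r2)
    rms = float(np.sqrt(np.mean((np.hypot(x - cx, y - cy) - radius) ** 2)))
    return float(cx), float(cy), radius, rms


# ---------------------------------------------------------------------------
# Tracking
# ---------------------------------------------------------------------------

def track_colonies(
    circles_per_frame: Sequence[Sequence[Tuple[float, float, float]]],
    overlap_margin: float = 3.0,
) -> List[ColonyTrack]:
    """Link per-frame colony circles into tracks and flag merged colonies.

    Frame-to-frame linking is nearest-centre with a displacement gate of
    ``max(5 px, 0.5·R)``; ambiguities resolve by smallest displacement, ties
    by smallest radius change.  A track is invalidated from the first frame
    in which its circle overlaps another circle (centre distance below
    ``R1 + R2 + overlap_margin``) and stays invalid thereafter.
    """
    tracks: List[ColonyTrack] = []
    active: Dict[int, Tuple[float, float, float]] = {}  # track_id -> last circle
    next_id = 0
    for f, circles in enumerate(circles_per_frame):
        circles = list(circles)
        assignments: Dict[int, int] = {}  # circle index -> track id
        # candidate links sorted by (displacement, radius change): greedy resolution
        candidates = []
        for ci, (x, y, r) in enumerate(circles):
            for tid, (px, py, pr) in active.items():
                d = math.hypot(x - px, y - py)
                if d < max(5.0, 0.5 * pr):
                    candidates.append((d, abs(r - pr), ci, tid))
        used_tracks: set = set()
        for d, dr, ci, tid in sorted(candidates):
            if ci in assignments or tid in used_tracks:
                continue
            assignments[ci] = tid
            used_tracks.add(tid)
        # overlap invalidation applies to this frame's circles
        overlapping = set()
        for i in range(len(circles)):
            for j in range(i + 1, len(circles)):
                xi, yi, ri = circles[i]
                xj, yj, rj = circles[j]
                if math.hypot(xi - xj, yi - yj) < ri + rj + overlap_margin:
                    overlapping.update((i, j))
        new_active: Dict[int, Tuple[float, float, float]] = {}
        for ci, (x, y, r) in enumerate(circles):
            tid = assignments.get(ci)
            if tid is None:
                tid = next_id
                next_id += 1
                tracks.append(ColonyTrack(track_id=tid))
            tr = tracks[tid]
            prev_valid = tr.valid[-1] if tr.valid else True
            tr.frames.append(f)
            tr.centers.append((x, y))
            tr.radii.append(r)
            tr.valid.append(prev_valid and ci not in overlapping)
            new_active[tid] = (x, y, r)
        active = new_active
    return tracks


# ---------------------------------------------------------------------------
# Fluorescence
# ---------------------------------------------------------------------------

def segment_fluorescence(
    fluorescence: np.ndarray,
    roi_circle: Tuple[float, float, float],
    frame: int = 0,
    kernel: int = 11,
    sigma: float = 1.5,
    threshold: Optional[float] = None,
    mad_factor: float = 5.0,
    colony_id: int = 0,
    roi_pad: float = 1.1,
    min_area: int = 4,
) -> List[FluorescentPatch]:
    """Segment patches of fluorescent bacteria inside one colony ROI.

    The image is convolved with a ``kernel × kernel`` Gaussian (σ in px); the
    local intensity background of the ROI — the median of ROI pixels below the
    ROI's 75th percentile, robust to the bright patch itself — is subtracted,
    and pixels above ``mad_factor`` × MAD of the background residuals (or a
    fixed ``threshold``) form connected patches; components smaller than
    ``min_area`` pixels are discarded as noise specks.  Intensities returned
    are background-corrected smoothed values.
    """
    img = np.asarray(fluorescence, float)
    cx, cy, R = roi_circle
    nrows, ncols = img.shape
    if not (0 <= cx < ncols and 0 <= cy < nrows):
        raise ValueError("ROI centre lies outside the image")
    rad = R * roi_pad
    rr = np.arange(nrows)[:, None] - cy
    cc = np.arange(ncols)[None, :] - cx
    roi = (rr * rr + cc * cc) <= rad * rad
    if not roi.any():
        raise ValueError("ROI does not intersect the image")

    trunc = (kernel - 1) / 2.0 / sigma  # Gaussian support limited to the stated kernel
    smoothed = ndimage.gaussian_filter(img, sigma, truncate=trunc)

    vals = smoothed[roi]
    low = vals[vals <= np.percentile(vals, 75)]
    background = float(np.median(low))
    corrected = smoothed - background
    if threshold is None:
        resid = low - background
        mad = float(np.median(np.abs(resid))) * 1.4826
        threshold = mad_factor * mad
    fg = (corrected > threshold) & roi
    if not fg.any():
        return []
    labels, n = ndimage.label(fg, _CROSS)
    patches = []
    for lab in range(1, n + 1):
        coords = np.argwhere(labels == lab)
        if len(coords) < min_area:
            continue
        inten = corrected[coords[:, 0], coords[:, 1]]
        patches.append(
            FluorescentPatch(frame=frame, coords=coords, intensities=inten, colony_id=colony_id)
        )
    return patches


def normalize_coordinates(
    coords: np.ndarray, circle: Tuple[float, float, float], frame: Optional[int] = None
) -> NormalizedCoordinates:
    """Radius-normalized polar coordinates of raster pixels about a circle.

    ``coords`` are ``(row, col)`` pixels; the circle is ``(cx, cy, R)`` in
    pixel units.  The raster row axis points down, so ``y = -(row - cy)``
    (documented y-flip) makes θ counterclockwise from the +x axis.  Pixels at
    the exact centre get θ = 0.
    """
    cx, cy, R = circle
    if R <= 0:
        raise ValueError("circle radius must be positive")
    pts = np.asarray(coords, float).reshape(-1, 2)
    x = pts[:, 1] - cx
    y = -(pts[:, 0] - cy)
    r = np.hypot(x, y)
    theta = np.where(r > 0, np.mod(np.arctan2(y, x), 2.0 * math.pi), 0.0)
    return NormalizedCoordinates(r_norm=r / R, theta=theta, frame=frame)


def assign_clones(
    coords_per_frame: Sequence[NormalizedCoordinates],
    mode: str = "auto",
    n_bins: int = 64,
    min_occupancy: int = 1,
    polygons: Optional[Sequence[np.ndarray]] = None,
) -> List[np.ndarray]:
    """Group fluorescent pixels into clones on the pooled unit disk.

    Because clones co-expand with the colony, their radius-normalized
    coordinates are stationary, so pooling all frames onto the unit circle
    separates clones spatially.  ``mode="auto"`` bins the pooled ``(x, y)``
    onto an ``n_bins × n_bins`` grid over [-1, 1]², thresholds occupancy,
    takes connected components as clones, and assigns every pixel by its
    bin's component (-1 = unassigned).  ``mode="manual"`` assigns by
    point-in-polygon against user-supplied unit-disk polygons.

    Returns one integer label array per frame.
    """
    xs, ys, frame_sizes = [], [], []
    for nc in coords_per_frame:
        xs.append(nc.r_norm * np.cos(nc.theta))
        ys.append(nc.r_norm * np.sin(nc.theta))
        frame_sizes.append(len(nc.r_norm))
    if sum(frame_sizes) == 0:
        return [np.empty(0, dtype=int) for _ in coords_per_frame]
    x_all = np.concatenate(xs)
    y_all = np.concatenate(ys)

    if mode == "manual":
        if not polygons:
            raise ValueError("manual mode requires polygons")
        from matplotlib.path import Path

        labels_all = np.full(x_all.size, -1, dtype=int)
        pts = np.column_stack([x_all, y_all])
        for li, poly in enumerate(polygons):
            inside = Path(poly).contains_points(pts)
            labels_all[inside & (labels_all == -1)] = li
    elif mode == "auto":
        edges = np.linspace(-1.0, 1.0, n_bins + 1)
        bx = np.clip(np.searchsorted(edges, x_all, side="right") - 1, 0, n_bins - 1)
        by = np.clip(np.searchsorted(edges, y_all, side="right") - 1, 0, n_bins - 1)
        occ = np.zeros((n_bins, n_bins), dtype=int)
        np.add.at(occ, (by, bx), 1)
        binary = occ >= min_occupancy
        # one dilation bridges single-bin gaps before labeling components
        comp, _ = ndimage.label(ndimage.binary_dilation(binary, _CROSS), _CROSS)
        comp[~binary] = 0
        labels_all = comp[by, bx] - 1
    else:
        raise ValueError(f"unknown clone-assignment mode {mode!r}")

    out = []
    pos = 0
    for nsize in frame_sizes:
        out.append(labels_all[pos : pos + nsize])
        pos += nsize
    return out
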