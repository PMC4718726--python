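"""Membrane detection inside a patch pipette and circle fitting of the dome.

The detector sweeps intensity line scans *parallel to the pipette walls*
(i.e. along the pipette axis), one scan per lateral offset between the two
walls.  Each scan is smoothed with a centred rolling mean (default window 9
samples), the global intensity minimum located, and the position refined to
subpixel precision by parabolic interpolation.  The resulting point cloud is
fit with a least-squares circle (algebraic initialisation followed by
geometric, orthogonal-distance refinement) to obtain the dome radius R.

Coordinates: image origin top-left, x rightward (columns), y downward (rows),
positions in micrometres after pixel-size scaling, 0-based pixel indexing.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage, optimize
from skimage.transform import hough_line, hough_line_peaks

from .mechanics import FLAT_CURVATURE


class DetectionError(RuntimeError):
    """Membrane detection failed (no usable scan lines / too few points)."""


class WallEstimationError(RuntimeError):
    """Fewer than two pipette-wall line features could be located."""


@dataclass(frozen=True)
class Line:
    """Infinite line in um coordinates: a point on it and a unit direction."""

    point: np.ndarray
    direction: np.ndarray

    def __post_init__(self):
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if n == 0:
            raise ValueError("direction must be non-zero")
        object.__setattr__(self, "point", np.asarray(self.point, dtype=float))
        object.__setattr__(self, "direction", d / n)

    def normal(self) -> np.ndarray:
        dx, dy = self.direction
        return np.array([-dy, dx])

    def signed_distance(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        return (pts - self.point) @ self.normal()

    def angle_deg(self) -> float:
        """Orientation in degrees in [0, 180)."""
        ang = np.degrees(np.arctan2(self.direction[1], self.direction[0]))
        return float(ang % 180.0)


@dataclass
class PatchImage:
    """2-D grayscale intensity grid with physical pixel size (um/pixel)."""

    intensities: np.ndarray
    pixel_size: float
    wall_lines: Optional[tuple[Line, Line]] = None

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 2 or self.intensities.size == 0:
            raise ValueError("intensities must be a nonempty 2-D array")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self):
        return self.intensities.shape

    @property
    def extent_um(self) -> tuple[float, float]:
        """(width, height) of the field of view in um."""
        rows, cols = self.intensities.shape
        return cols * self.pixel_size, rows * self.pixel_size


@dataclass
class MembraneProfile:
    """Ordered subpixel membrane positions from the line-scan detector."""

    points: np.ndarray              # (n, 2) positions in um (x, y)
    intensities: np.ndarray         # intensity at each detected minimum
    scan_axis: np.ndarray           # unit vector along the scan direction
    tip_direction: Optional[np.ndarray] = None  # unit vector toward the tip

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.scan_axis = np.asarray(self.scan_axis, dtype=float)
        if len(self.points) < 3:
            raise ValueError("a membrane profile needs at least 3 points")

    def __len__(self):
        return len(self.points)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"x_um": self.points[:, 0],
                             "y_um": self.points[:, 1],
                             "intensity": self.intensities})


@dataclass(frozen=True)
class CircleFit:
    """Least-squares circle through a membrane profile.

    ``radius`` is um; a flat membrane is reported with ``radius = inf`` and
    ``signed_curvature = 0`` rather than an arbitrarily huge radius.  Sign
    convention: positive curvature = convex dome (bulging toward the pipette
    tip, as at rest and under negative pressure), negative = concave.
    """

    center: tuple[float, float]
    radius: float
    rms_residual: float
    n_points: int
    signed_curvature: float
    converged: bool = True

    def __post_init__(self):
        if self.rms_residual < 0:
            raise ValueError("rms_residual must be non-negative")
        if np.isfinite(self.radius):
            if self.radius <= 0:
                raise ValueError("radius must be positive")
            if not np.isclose(abs(self.signed_curvature), 1.0 / self.radius):
                raise ValueError("|signed_curvature| must equal 1/radius")
        elif self.signed_curvature != 0.0:
            raise ValueError("flat fits must have zero curvature")

    @property
    def flat(self) -> bool:
        return not np.isfinite(self.radius)

    def to_dict(self) -> dict:
        return {"cx_um": self.center[0], "cy_um": self.center[1],
                "radius_um": self.radius, "rms_um": self.rms_residual,
                "n_points": self.n_points,
                "curvature_sign": int(np.sign(self.signed_curvature)),
                "signed_curvature_per_um": self.signed_curvature,
                "converged": self.converged}


# ---------------------------------------------------------------------------
# wall estimation
# ---------------------------------------------------------------------------

def estimate_walls(image: PatchImage, *, min_angle_sep_deg: float = 2.0,
                   theta_step_deg: float = 0.1) -> tuple[Line, Line]:
    """Locate the two pipette walls as the two dominant dark line features.

    A straight-line Hough transform is run on the thresholded dark features;
    the two strongest sufficiently separated peaks are returned as lines in
    um coordinates.  Raises :class:`WallEstimationError` when fewer than two
    line features are present (e.g. a featureless image).
    """
    img = image.intensities
    rng_int = float(img.max() - img.min())
    if rng_int <= 0:
        raise WallEstimationError("image has no intensity contrast")
    dark = (img.max() - img) / rng_int
    mask = dark > 0.5

    n_theta = int(round(180.0 / theta_step_deg))
    thetas = np.linspace(-np.pi / 2, np.pi / 2, n_theta, endpoint=False)
    hspace, angles, dists = hough_line(mask, theta=thetas)
    # a genuine line must collect far more votes than a random line through
    # the mask at its overall density would
    density = float(mask.mean())
    chance_votes = density * float(np.hypot(*img.shape))
    min_votes = int(max(20, 0.25 * min(img.shape), 2.0 * chance_votes))
    accums, peak_angles, peak_dists = hough_line_peaks(
        hspace, angles, dists, num_peaks=4, threshold=min_votes,
        min_distance=9, min_angle=max(3, int(min_angle_sep_deg / theta_step_deg)))

    lines: list[Line] = []
    for _, theta, rho in sorted(zip(accums, peak_angles, peak_dists),
                                key=lambda t: t[0], reverse=True):
        cand = Line(point=np.array([np.cos(theta), np.sin(theta)]) * rho * image.pixel_size,
                    direction=np.array([-np.sin(theta), np.cos(theta)]))
        if any(_angle_between(cand, ln) < min_angle_sep_deg for ln in lines):
            continue
        lines.append(cand)
        if len(lines) == 2:
            break
    if len(lines) < 2:
        raise WallEstimationError(
            f"found {len(lines)} wall line feature(s); need 2")
    return lines[0], lines[1]


def _angle_between(a: Line, b: Line) -> float:
    diff = abs(a.angle_deg() - b.angle_deg())
    return min(diff, 180.0 - diff)


def pipette_axis(walls: tuple[Line, Line]) -> Line:
    """Bisector of the two wall lines: the pipette axis."""
    w1, w2 = walls
    d1, d2 = w1.direction, w2.direction
    if d1 @ d2 < 0:
        d2 = -d2
    bisector = d1 + d2
    # anchor the axis midway between the walls
    mid = (w1.point + w2.point) / 2.0
    return Line(point=mid, direction=bisector)


# ---------------------------------------------------------------------------
# membrane detection
# ---------------------------------------------------------------------------

def _rolling_mean(values: np.ndarray, window: int) -> np.ndarray:
    """Centred rolling mean with the window truncated at the ends."""
    if window <= 1:
        return values.astype(float)
    kernel = np.ones(window)
    sums = np.convolve(values, kernel, mode="same")
    counts = np.convolve(np.ones_like(values, dtype=float), kernel, mode="same")
    return sums / counts


def _parabolic_refine(values: np.ndarray, idx: int) -> float:
    """Subpixel offset of a minimum from the 3 samples around ``idx``."""
    if idx <= 0 or idx >= len(values) - 1:
        return 0.0
    y0, y1, y2 = values[idx - 1], values[idx], values[idx + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom <= 0:
        return 0.0
    delta = 0.5 * (y0 - y2) / denom
    return float(np.clip(delta, -0.5, 0.5))


def detect_membrane(image: PatchImage, *, window: int = 9,
                    wall_margin: float = 8.0,
                    min_prominence: float = 0.3,
                    subpixel: bool = True) -> MembraneProfile:
    """Detect the membrane as per-scan-line intensity minima.

    Line scans run parallel to the pipette walls (along the pipette axis),
    one per lateral offset; only samples lying between the two walls with at
    least ``wall_margin`` pixels of clearance are considered.  Each scan is
    smoothed with a centred rolling mean of ``window`` samples, the global
    minimum located (ties broken toward the pipette tip), and optionally
    refined to subpixel position by parabolic interpolation.

    ``min_prominence`` is the required intensity dip on a scan line as a
    fraction of the image dynamic range; lines without a sufficiently deep
    minimum (e.g. beyond the membrane contact points) are skipped.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    walls = image.wall_lines or estimate_walls(image)
    axis = pipette_axis(walls)
    u = axis.direction
    v = axis.normal()

    rows, cols = image.shape
    px = image.pixel_size
    width_um, height_um = image.extent_um
    center = np.array([width_um, height_um]) / 2.0
    half_span = 0.75 * max(width_um, height_um)

    s_coords = np.arange(-half_span, half_span, px)
    o_coords = np.arange(-half_span, half_span, px)
    # sample positions p = center + s*u + o*v  on a rotated grid
    S, O = np.meshgrid(s_coords, o_coords, indexing="ij")
    X = center[0] + S * u[0] + O * v[0]
    Y = center[1] + S * u[1] + O * v[1]

    in_field = (X >= 0) & (X <= width_um - px) & (Y >= 0) & (Y <= height_um - px)
    pts = np.stack([X.ravel(), Y.ravel()], axis=1)
    margin_um = wall_margin * px
    interior = np.ones(len(pts), dtype=bool)
    for wall in walls:
        d = wall.signed_distance(pts)
        sign = np.sign(wall.signed_distance(center[None, :])[0]) or 1.0
        interior &= (d * sign) >= margin_um
    valid = in_field & interior.reshape(S.shape)

    intens = ndimage.map_coordinates(image.intensities,
                                     [Y.ravel() / px, X.ravel() / px],
                                     order=1, mode="nearest").reshape(S.shape)

    # orient +s away from the tip: interior width must grow with s
    widths = valid.sum(axis=1).astype(float)
    nz = np.nonzero(widths > 0)[0]
    if len(nz) == 0:
        raise DetectionError("no scan samples between the walls")
    tip_first = widths[nz[: max(1, len(nz) // 4)]].mean() \
        <= widths[nz[-max(1, len(nz) // 4):]].mean()
    # with +s away from the tip, the first occurrence of a tied minimum along
    # ascending s is the one nearest the tip
    s_order = np.arange(len(s_coords)) if tip_first \
        else np.arange(len(s_coords))[::-1]

    contrast = float(image.intensities.max() - image.intensities.min())
    if contrast <= 0:
        raise DetectionError("image has no intensity contrast")
    threshold = min_prominence * contrast

    points, minima = [], []
    for j in range(len(o_coords)):
        col_valid = valid[s_order, j]
        if col_valid.sum() < max(window, 5):
            continue
        idxs = np.nonzero(col_valid)[0]
        # use the longest contiguous run of valid samples
        splits = np.split(idxs, np.nonzero(np.diff(idxs) > 1)[0] + 1)
        run = max(splits, key=len)
        if len(run) < max(window, 5):
            continue
        line = intens[s_order[run], j]
        smooth = _rolling_mean(line, window)
        if smooth.max() - smooth.min() < threshold:
            continue
        k = int(np.argmin(smooth))
        frac = _parabolic_refine(smooth, k) if subpixel else 0.0
        s_idx = s_order[run[k]]
        s_val = s_coords[s_idx]
        step = s_coords[s_order[run[min(k + 1, len(run) - 1)]]] - s_val \
            if len(run) > 1 else px
        s_val = s_val + frac * step
        o_val = o_coords[j]
        points.append(center + s_val * u + o_val * v)
        minima.append(smooth[k])

    if points:
        # the wall shadow biases minima close to the contact points: exclude
        # detected points inside twice the scan clearance
        pts_arr = np.array(points)
        keep = np.ones(len(pts_arr), dtype=bool)
        for wall in walls:
            keep &= np.abs(wall.signed_distance(pts_arr)) >= 2.0 * margin_um
        points = [p for p, k in zip(points, keep) if k]
        minima = [m for m, k in zip(minima, keep) if k]

    if len(points) < 3:
        raise DetectionError(
            f"only {len(points)} membrane points detected; need >= 3")
    tip_dir = -u if tip_first else u
    return MembraneProfile(points=np.array(points),
                           intensities=np.array(minima),
                           scan_axis=u, tip_direction=tip_dir)


# ---------------------------------------------------------------------------
# circle fitting
# ---------------------------------------------------------------------------

def _algebraic_circle(pts: np.ndarray) -> tuple[np.ndarray, float]:
    """Kasa algebraic least-squares circle (linear solve)."""
    x, y = pts[:, 0], pts[:, 1]
    A = np.column_stack([2 * x, 2 * y, np.ones_like(x)])
    b = x ** 2 + y ** 2
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    cx, cy, c = sol
    radius = float(np.sqrt(max(c + cx ** 2 + cy ** 2, 0.0)))
    return np.array([cx, cy]), radius


def fit_circle(profile, *, tip_direction: Optional[Sequence[float]] = None,
               flat_curvature: float = FLAT_CURVATURE) -> CircleFit:
    """Orthogonal-distance least-squares circle through the profile points.

    Minimises ``sum_i (||p_i - center|| - radius)^2``: an algebraic (Kasa)
    initialisation is refined geometrically over the centre (the optimal
    radius for a fixed centre is the mean point-to-centre distance).
    Collinear or nearly flat profiles are reported as flat
    (``radius = inf``, curvature 0).  ``tip_direction`` (um coordinates unit
    vector toward the pipette tip) fixes the curvature sign: positive when
    the dome bulges toward the tip.
    """
    if isinstance(profile, MembraneProfile):
        pts = profile.points
        if tip_direction is None and profile.tip_direction is not None:
            tip_direction = profile.tip_direction
    else:
        pts = np.asarray(profile, dtype=float).reshape(-1, 2)
    n = len(pts)
    if n < 3:
        raise ValueError("circle fit needs at least 3 points")

    centered = pts - pts.mean(axis=0)
    svals = np.linalg.svd(centered, compute_uv=False)
    scale = float(svals[0])
    if scale == 0 or svals[1] / scale < 1e-9:
        return _flat_fit(n)

    center0, _ = _algebraic_circle(pts)

    def residuals(c):
        d = np.linalg.norm(pts - c, axis=1)
        return d - d.mean()

    converged = True
    try:
        sol = optimize.least_squares(residuals, center0, method="lm",
                                     xtol=1e-15, ftol=1e-15, gtol=1e-15)
        center = sol.x
        if not sol.success:
            raise RuntimeError(sol.message)
    except Exception:  # pragma: no cover - fallback path
        warnings.warn("geometric circle refinement did not converge; "
                      "falling back to algebraic fit", RuntimeWarning)
        center, _ = _algebraic_circle(pts)
        converged = False

    dists = np.linalg.norm(pts - center, axis=1)
    radius = float(dists.mean())
    rms = float(np.sqrt(np.mean((dists - radius) ** 2)))
    if radius <= 0 or 1.0 / radius < flat_curvature:
        return _flat_fit(n, rms=rms)

    sign = 1.0
    if tip_direction is not None:
        tip = np.asarray(tip_direction, dtype=float)
        # convex: centre lies on the opposite side of the arc from the tip
        sign = 1.0 if (center - pts.mean(axis=0)) @ tip <= 0 else -1.0
    return CircleFit(center=(float(center[0]), float(center[1])),
                     radius=radius, rms_residual=rms, n_points=n,
                     signed_curvature=sign / radius, converged=converged)


def _flat_fit(n: int, rms: float = 0.0) -> CircleFit:
    return CircleFit(center=(np.nan, np.nan), radius=np.inf,
                     rms_residual=rms, n_points=n, signed_curvature=0.0)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_patch_image(path, *, pixel_size: Optional[float] = None,
                     page: int = 0) -> PatchImage:
    """Read a grayscale TIFF (optionally multi-page) into a PatchImage.

    Pixel size is taken from ``pixel_size`` or from a ``<stem>.json`` sidecar
    with a ``pixel_size_um`` field (and optional ``wall_lines``).
    """
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim == 3:
        data = data[page]
    walls = None
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        pixel_size = pixel_size or meta.get("pixel_size_um")
        if "wall_lines" in meta:
            walls = tuple(Line(point=np.array(w["point"]),
                               direction=np.array(w["direction"]))
                          for w in meta["wall_lines"])
    if pixel_size is None:
        raise ValueError("pixel_size not given and no sidecar JSON found")
    return PatchImage(intensities=np.asarray(data, dtype=float),
                      pixel_size=float(pixel_size), wall_lines=walls)


def write_patch_image(path, image: PatchImage, ground_truth: Optional[dict] = None):
    """Write a PatchImage as float32 TIFF plus a JSON sidecar with metadata."""
    path = Path(path)
    tifffile.imwrite(path, image.intensities.astype(np.float32))
    meta: dict = {"pixel_size_um": image.pixel_size}
    if image.wall_lines is not None:
        meta["wall_lines"] = [{"point": list(map(float, ln.point)),
                               "direction": list(map(float, ln.direction))}
                              for ln in image.wall_lines]
    if ground_truth:
        meta["ground_truth"] = ground_truth
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))
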