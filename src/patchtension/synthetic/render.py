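"""Rendering of geometric pipette/membrane phantom images.

These are not optical simulations: walls and membrane are dark Gaussian
ridges over a bright background, which is sufficient to exercise the
line-scan detector and circle fit with exactly known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..imaging import Line, PatchImage
from .params import PipetteGeometry


class GeometryError(ValueError):
    """Requested membrane arc does not fit in the field of view."""


@dataclass
class RenderedPatch:
    """A rendered phantom plus its ground truth."""

    image: PatchImage
    arc_points: np.ndarray          # (n, 2) true arc coordinates, um
    center: np.ndarray | None       # true circle centre, um (None if flat)
    radius: float                   # true unsigned radius, um (inf if flat)
    signed_curvature: float         # +convex / -concave / 0 flat, 1/um
    axis: Line                      # true pipette axis (unit dir toward interior)
    walls: tuple[Line, Line]

    def ground_truth_dict(self) -> dict:
        return {"radius_um": self.radius,
                "signed_curvature_per_um": self.signed_curvature,
                "center_um": None if self.center is None
                else [float(self.center[0]), float(self.center[1])],
                "axis_angle_deg": self.axis.angle_deg()}


def render_patch_image(geometry: PipetteGeometry, radius_um: float, *,
                       image_shape: tuple[int, int] = (420, 420),
                       noise_sd: float = 0.0, seed: int = 0,
                       contact_fraction: float = 0.85,
                       background: float = 0.95,
                       membrane_darkness: float = 0.75,
                       wall_sigma_px: float = 2.0,
                       membrane_sigma_px: float = 3.0) -> RenderedPatch:
    """Render two converging dark walls and a dark membrane arc.

    ``radius_um`` is the *signed* dome radius: positive = convex (bulging
    toward the tip), negative = concave, 0 or inf = flat chord.  The arc
    meets the walls at a chord of half-width ``contact_fraction * |R|``
    (clamped to the pipette opening and the field).  Raises
    :class:`GeometryError` when the arc cannot fit in the field of view.
    """
    rows, cols = image_shape
    px = geometry.pixel_size
    width_um, height_um = cols * px, rows * px
    field = min(width_um, height_um)
    center_f = np.array([width_um, height_um]) / 2.0

    flat = radius_um == 0 or not np.isfinite(radius_um)
    r_abs = abs(float(radius_um)) if not flat else np.inf
    if not flat and r_abs < geometry.tip_inner_radius:
        raise GeometryError("|radius| must be at least tip_inner_radius")
    if geometry.tip_inner_radius > 0.40 * field:
        raise GeometryError("pipette opening is wider than the field of view")

    # half-width of the membrane/wall contact chord
    if flat:
        half_w = min(1.25 * geometry.tip_inner_radius, 0.40 * field)
    else:
        half_w = min(contact_fraction * r_abs, 0.40 * field)
        half_w = max(half_w, min(geometry.tip_inner_radius, 0.40 * field))
    if half_w > 0.45 * field or (not flat and half_w > r_abs):
        raise GeometryError("membrane contact chord does not fit in the field")

    theta = np.radians(geometry.axis_angle)
    u = np.array([np.cos(theta), np.sin(theta)])   # +u: away from the tip
    v = np.array([-np.sin(theta), np.cos(theta)])

    # contact chord centred in the field; virtual wall apex lies at -u
    tan_half = np.tan(np.radians(geometry.half_angle))
    s_m = half_w / tan_half                          # apex -> chord distance
    apex = center_f - s_m * u
    wall_dirs = []
    for sgn in (+1.0, -1.0):
        phi = np.radians(geometry.axis_angle + sgn * geometry.half_angle)
        wall_dirs.append(np.array([np.cos(phi), np.sin(phi)]))
    walls = (Line(point=apex, direction=wall_dirs[0]),
             Line(point=apex, direction=wall_dirs[1]))
    contacts = np.array([center_f + half_w * v, center_f - half_w * v])

    yy, xx = np.meshgrid(np.arange(rows) * px, np.arange(cols) * px,
                         indexing="ij")
    pts = np.stack([xx, yy], axis=-1)

    img = np.full((rows, cols), background)
    for wall in walls:
        d = (pts - wall.point) @ wall.normal()
        img -= geometry.wall_darkness * background * \
            np.exp(-d ** 2 / (2 * (wall_sigma_px * px) ** 2))

    if flat:
        chord = Line(point=center_f, direction=v)
        d_arc = (pts - chord.point) @ chord.normal()
        along = (pts - chord.point) @ chord.direction
        in_span = np.abs(along) <= half_w
        arc_center, sig_curv = None, 0.0
        t = np.linspace(-half_w, half_w, 200)
        arc_points = center_f[None, :] + t[:, None] * v[None, :]
    else:
        sag = np.sqrt(r_abs ** 2 - half_w ** 2)
        convex = radius_um > 0
        # convex: circle centre deeper inside the pipette (+u side), the arc
        # bulges toward the tip; concave: mirrored
        arc_center = center_f + (sag if convex else -sag) * u
        sig_curv = (1.0 if convex else -1.0) / r_abs
        dome_tip = arc_center - (r_abs if convex else -r_abs) * u
        for p in np.vstack([contacts, dome_tip]):
            if not (0.2 < p[0] < width_um - 0.2 and 0.2 < p[1] < height_um - 0.2):
                raise GeometryError("membrane arc extends outside the field")
        rel = pts - arc_center
        d_arc = np.linalg.norm(rel, axis=-1) - r_abs
        # restrict the ridge to the arc between the two wall contacts
        axial = -(rel @ u) if convex else (rel @ u)
        in_span = axial >= sag - 1e-9
        half_ang = np.arcsin(half_w / r_abs)
        ang = np.linspace(-half_ang, half_ang, 200)
        sgn = -1.0 if convex else 1.0
        arc_points = arc_center[None, :] \
            + sgn * r_abs * np.cos(ang)[:, None] * u[None, :] \
            + r_abs * np.sin(ang)[:, None] * v[None, :]

    ridge = membrane_darkness * background * \
        np.exp(-d_arc ** 2 / (2 * (membrane_sigma_px * px) ** 2))
    img -= np.where(in_span, ridge, 0.0)

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sd, size=img.shape)

    axis = Line(point=apex, direction=u)
    image = PatchImage(intensities=img, pixel_size=px, wall_lines=walls)
    return RenderedPatch(image=image, arc_points=arc_points,
                         center=arc_center, radius=r_abs,
                         signed_curvature=sig_curv, axis=axis, walls=walls)
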