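"""Conversion of patch geometry and applied pressure to lateral membrane tension.

The lateral tension ``T`` carried by a spherical membrane cap of radius ``R``
under a pressure difference ``dp`` follows Laplace's law ``T = R * dp / 2``.
Tension is reported as a magnitude (in mN/m): a membrane curved either way by
the same |dp| carries the same tension, while the *sign* of the deformation is
tracked separately as a signed curvature (1/um).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Exact-to-six-digits conversion factor between mmHg and Pascal.
MMHG_TO_PA: float = 133.322

#: Tension in mN/m produced by 1 um of radius at 1 mmHg:
#: R[m] * dp[Pa] / 2 -> mN/m  ==  1e-6 * 133.322 / 2 * 1e3.
TENSION_PER_UM_MMHG: float = MMHG_TO_PA * 1e-3 / 2.0

#: Curvature magnitudes below this (1/um) are treated as a flat membrane.
FLAT_CURVATURE: float = 1e-3


class FlatMembrane(float):
    """Sentinel radius for a flat membrane (infinite radius of curvature)."""

    def __new__(cls):
        return super().__new__(cls, np.inf)


def laplace_tension(radius_um, delta_p_mmhg, *, flat: bool = False):
    """Lateral tension (mN/m) from dome radius (um) and applied pressure (mmHg).

    ``T = R * |dp| / 2`` with unit conversion via 133.322 Pa/mmHg.  The
    absolute value of the pressure is used: tension is a symmetrical
    (sign-free) quantity, unlike curvature.  A flat membrane (``flat=True``
    or a non-finite radius) carries zero tension by convention.

    Accepts scalars or numpy arrays (broadcast).
    """
    radius = np.asarray(radius_um, dtype=float)
    dp = np.asarray(delta_p_mmhg, dtype=float)
    if flat:
        return np.zeros(np.broadcast(radius, dp).shape)[()] if radius.ndim or dp.ndim else 0.0
    if np.any(radius <= 0):
        raise ValueError("radius must be positive (or pass flat=True)")
    tension = np.where(np.isfinite(radius),
                       radius * np.abs(dp) * TENSION_PER_UM_MMHG, 0.0)
    return float(tension) if tension.ndim == 0 else tension


def inverse_radius(circle) -> float:
    """Signed curvature (1/um) of a fitted circle; 0 for a flat membrane.

    Accepts any object with ``signed_curvature`` (preferred) or ``radius``
    attributes, e.g. :class:`patchtension.imaging.CircleFit`.
    """
    curv = getattr(circle, "signed_curvature", None)
    if curv is not None:
        return 0.0 if abs(curv) < FLAT_CURVATURE else float(curv)
    radius = float(getattr(circle, "radius"))
    if not np.isfinite(radius):
        return 0.0
    return 1.0 / radius


@dataclass(frozen=True)
class TensionMeasurement:
    """One (radius, pressure) pair resolved into tension and curvature."""

    radius_um: float
    delta_p_mmhg: float
    tension_mn_per_m: float
    curvature_per_um: float

    def __post_init__(self):
        if self.tension_mn_per_m < 0:
            raise ValueError("tension must be non-negative")


def measure_tension(radius_um: float, delta_p_mmhg: float, *,
                    flat: bool = False, convex: bool = True) -> TensionMeasurement:
    """Bundle Laplace tension with the matching signed curvature."""
    tension = laplace_tension(radius_um, delta_p_mmhg, flat=flat)
    if flat or not np.isfinite(radius_um):
        curv = 0.0
    else:
        curv = (1.0 if convex else -1.0) / radius_um
        if abs(curv) < FLAT_CURVATURE:
            curv = 0.0
    return TensionMeasurement(radius_um=float(radius_um),
                              delta_p_mmhg=float(delta_p_mmhg),
                              tension_mn_per_m=float(tension),
                              curvature_per_um=curv)


def tension_table(circles: pd.DataFrame, pressures: pd.DataFrame,
                  *, on=("cell_id", "sweep_id"),
                  include_flat: bool = True) -> pd.DataFrame:
    """Join per-sweep circle fits with applied pressures into a tension table.

    ``circles`` needs columns ``radius_um`` (may be inf for flat) and the join
    keys; ``pressures`` needs ``dp_mmHg`` and the join keys.  Flat rows get
    tension 0 and are kept unless ``include_flat=False``.
    """
    merged = circles.merge(pressures, on=list(on), how="inner")
    radius = merged["radius_um"].to_numpy(dtype=float)
    dp = merged["dp_mmHg"].to_numpy(dtype=float)
    flat_mask = ~np.isfinite(radius) | (radius <= 0)
    tension = np.zeros_like(dp)
    ok = ~flat_mask
    tension[ok] = laplace_tension(radius[ok], dp[ok])
    out = merged.copy()
    out["tension_mN_per_m"] = tension
    out["flat"] = flat_mask
    if not include_flat:
        out = out.loc[~flat_mask].reset_index(drop=True)
    return out
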