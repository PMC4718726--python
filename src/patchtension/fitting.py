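"""Sigmoid and exponential fitting pipeline for pooled current responses.

The workflow mirrors the analysis the data types are built for: per-cell
Boltzmann fits of current-pressure series, normalization of each response to
the fitted plateau (or to the per-patch maximum), pooling and fixed-width
binning of normalized current against tension (1 mN/m) or inverse radius
(0.05 1/um), a per-bin-SD-weighted Boltzmann fit of the binned means, and a
saturating-exponential fit of recovery time courses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

logger = logging.getLogger(__name__)

TENSION_BIN_WIDTH = 1.0          # mN/m
INVERSE_RADIUS_BIN_WIDTH = 0.05  # 1/um


class FitError(RuntimeError):
    """Nonlinear fit failed to converge."""


class DegenerateDataError(ValueError):
    """Input data cannot constrain the fit (e.g. all responses equal)."""


def boltzmann(x, i_max, x50, k):
    """``I = I_max / (1 + exp(-(x - x50)/k))``."""
    return i_max / (1.0 + np.exp(-(np.asarray(x, dtype=float) - x50) / k))


@dataclass(frozen=True)
class BoltzmannFit:
    """Fitted Boltzmann parameters with standard errors.

    ``domain`` records the stimulus axis ("pressure" in mmHg or "tension"
    in mN/m) so that midpoints in different units are never mixed.
    """

    I_max: float
    X50: float
    k: float
    se_I_max: float
    se_X50: float
    se_k: float
    n_points: int
    domain: str
    weighted: bool = False

    def __post_init__(self):
        if self.k <= 0:
            raise ValueError("slope factor k must be positive")
        if self.I_max <= 0:
            raise ValueError("I_max must be positive")
        if self.domain not in ("pressure", "tension"):
            raise ValueError("domain must be 'pressure' or 'tension'")

    def __call__(self, x):
        return boltzmann(x, self.I_max, self.X50, self.k)

    def to_dict(self) -> dict:
        return {"I_max": self.I_max, "X50": self.X50, "k": self.k,
                "se_I_max": self.se_I_max, "se_X50": self.se_X50,
                "se_k": self.se_k, "n_points": self.n_points,
                "domain": self.domain, "weighted": self.weighted}


@dataclass(frozen=True)
class RecoveryFit:
    """Saturating exponential ``I(t) = I_max - A exp(-(t - t0)/tau)``."""

    I_max: float
    A: float
    t0: float
    tau: float
    se_I_max: float
    se_A: float
    se_tau: float
    n_points: int
    t0_fixed: bool = True

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("tau must be positive")

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        return self.I_max - self.A * np.exp(-(t - self.t0) / self.tau)

    def to_dict(self) -> dict:
        return {"I_max": self.I_max, "A": self.A, "t0": self.t0,
                "tau": self.tau, "se_I_max": self.se_I_max,
                "se_A": self.se_A, "se_tau": self.se_tau,
                "n_points": self.n_points, "t0_fixed": self.t0_fixed}


@dataclass
class BinnedHistogram:
    """Fixed-width bins of normalized current against a stimulus."""

    bin_edges: np.ndarray     # (n_bins + 1,), contiguous, anchored at 0
    mean: np.ndarray
    sd: np.ndarray
    sem: np.ndarray
    n: np.ndarray
    stimulus: str = "tension"

    @property
    def centers(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2.0

    def __len__(self):
        return len(self.mean)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"bin_left": self.bin_edges[:-1],
                             "bin_right": self.bin_edges[1:],
                             "bin_center": self.centers,
                             "mean": self.mean, "sd": self.sd,
                             "sem": self.sem, "n": self.n})


# ---------------------------------------------------------------------------
# Boltzmann fitting
# ---------------------------------------------------------------------------

def _boltzmann_p0(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    i_max0 = float(np.max(y))
    half = i_max0 / 2.0
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    above = np.nonzero(ys >= half)[0]
    if len(above) and above[0] > 0:
        j = above[0]
        x0, x1, y0, y1 = xs[j - 1], xs[j], ys[j - 1], ys[j]
        x50_0 = x0 + (half - y0) * (x1 - x0) / (y1 - y0) if y1 != y0 else x1
    else:
        x50_0 = float(np.median(xs))
    k0 = max((xs[-1] - xs[0]) / 10.0, 1e-6)
    return i_max0, float(x50_0), k0


def fit_boltzmann(x, y, *, sd: Optional[Sequence[float]] = None,
                  domain: str = "tension") -> BoltzmannFit:
    """Weighted nonlinear least squares of the Boltzmann activation curve.

    ``sd`` supplies per-point standard deviations used as weights (larger
    SD = smaller weight).  Initialisation: I_max from the data maximum, X50
    from the interpolated half-maximum crossing, k from a tenth of the x
    range.  I_max is bounded in (0, 2*max(y)] and k > 0.  Standard errors
    come from the covariance of the fit.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 4:
        raise ValueError("need at least 4 points for a Boltzmann fit")
    if np.ptp(y) == 0:
        raise DegenerateDataError("all responses are identical")
    sigma = None
    if sd is not None:
        sigma = np.asarray(sd, dtype=float)
        if np.any(sigma <= 0):
            raise ValueError("weights (SDs) must be strictly positive")

    p0 = _boltzmann_p0(x, y)
    bounds = ([1e-12, -np.inf, 1e-9], [2.0 * max(np.max(y), 1e-12), np.inf, np.inf])
    p0 = tuple(np.clip(p0, bounds[0], bounds[1]))
    try:
        popt, pcov = optimize.curve_fit(
            boltzmann, x, y, p0=p0, sigma=sigma, bounds=bounds,
            maxfev=20000, xtol=1e-13, ftol=1e-13)
    except (RuntimeError, optimize.OptimizeWarning) as exc:
        raise FitError(f"Boltzmann fit did not converge: {exc}") from exc
    ses = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
    return BoltzmannFit(I_max=float(popt[0]), X50=float(popt[1]),
                        k=float(popt[2]), se_I_max=float(ses[0]),
                        se_X50=float(ses[1]), se_k=float(ses[2]),
                        n_points=len(x), domain=domain,
                        weighted=sigma is not None)


# ---------------------------------------------------------------------------
# normalization / pooling
# ---------------------------------------------------------------------------

def normalize_responses(responses: pd.DataFrame, *, mode: str = "plateau",
                        cell_col: str = "cell_id", x_col: str = "dp_mmHg",
                        y_col: str = "peak_pA",
                        domain: str = "pressure") -> tuple[pd.DataFrame, dict]:
    """Normalize per-cell responses to the fitted plateau or the maximum.

    mode "plateau": each cell's (|x|, peak) series is fit with an unweighted
    Boltzmann and responses are divided by its fitted I_max; cells whose fit
    fails are excluded with a logged warning.  mode "max": responses are
    divided by that cell's maximal response (the maximum maps to 1.0).

    Returns the table with a ``norm_current`` column plus a dict of per-cell
    fits (mode "plateau") or maxima (mode "max").
    """
    if mode not in ("plateau", "max"):
        raise ValueError("mode must be 'plateau' or 'max'")
    pieces, info = [], {}
    for cell, grp in responses.groupby(cell_col, sort=True):
        y = grp[y_col].to_numpy(dtype=float)
        if mode == "max":
            denom = float(np.max(y))
            if denom <= 0:
                logger.warning("cell %s dropped: non-positive maximum", cell)
                continue
            info[cell] = denom
        else:
            x = np.abs(grp[x_col].to_numpy(dtype=float))
            try:
                cell_fit = fit_boltzmann(x, y, domain=domain)
            except (FitError, DegenerateDataError, ValueError) as exc:
                logger.warning("cell %s dropped: per-cell fit failed (%s)",
                               cell, exc)
                continue
            denom = cell_fit.I_max
            info[cell] = cell_fit
        out = grp.copy()
        out["norm_current"] = y / denom
        pieces.append(out)
    if not pieces:
        raise DegenerateDataError("no cell yielded a usable normalization")
    return pd.concat(pieces, ignore_index=True), info


def pool_and_bin(x, y, *, bin_width: float = TENSION_BIN_WIDTH,
                 stimulus: str = "tension") -> BinnedHistogram:
    """Pool normalized responses into left-closed bins anchored at 0.

    Empty bins are dropped.  Bins holding a single response keep their mean
    but have their SD replaced by the global median SD of multi-response
    bins, so they can still enter an SD-weighted fit.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0:
        raise ValueError("need at least one response")
    idx = np.floor(x / bin_width).astype(int)
    means, sds, ns, lefts = [], [], [], []
    for i in np.unique(idx):
        sel = idx == i
        vals = y[sel]
        lefts.append(i * bin_width)
        means.append(vals.mean())
        ns.append(sel.sum())
        sds.append(vals.std(ddof=1) if len(vals) > 1 else np.nan)
    means, sds, ns = np.array(means), np.array(sds), np.array(ns)
    lefts = np.array(lefts)
    multi = ns > 1
    if multi.any():
        fill = float(np.nanmedian(sds[multi]))
    else:
        fill = 1.0
    fill = max(fill, 1e-12)
    sds = np.where(np.isnan(sds) | (sds <= 0), fill, sds)
    sem = sds / np.sqrt(ns)
    edges = np.append(lefts, lefts[-1] + bin_width)
    return BinnedHistogram(bin_edges=edges, mean=means, sd=sds, sem=sem,
                          n=ns, stimulus=stimulus)


def fit_tension_curve(hist: BinnedHistogram) -> BoltzmannFit:
    """SD-weighted Boltzmann fit of bin centers vs bin means."""
    if len(hist) < 4:
        raise ValueError("need at least 4 populated bins")
    return fit_boltzmann(hist.centers, hist.mean, sd=hist.sd,
                         domain="tension")


# ---------------------------------------------------------------------------
# recovery fitting
# ---------------------------------------------------------------------------

def _recovery_model(t, i_max, a, tau, t0):
    return i_max - a * np.exp(-(t - t0) / tau)


def fit_recovery(durations, peaks, *, t0: Optional[float] = None,
                 free_t0: bool = False) -> RecoveryFit:
    """Fit ``I(t) = I_max - A exp(-(t - t0)/tau)`` to recovery data.

    ``t0`` is fixed at the shortest tested duration by default (the printed
    form of this model is degenerate in (A, t0); fixing t0 removes the
    degeneracy).  ``free_t0=True`` fits it as a fourth parameter.
    Monotonically decreasing data indicate a sign/convention problem and
    raise :class:`DegenerateDataError`.
    """
    t = np.asarray(durations, dtype=float)
    y = np.asarray(peaks, dtype=float)
    if len(np.unique(t)) < 4:
        raise ValueError("need at least 4 distinct durations")
    slope = np.polyfit(t, y, 1)[0]
    if slope < 0:
        raise DegenerateDataError("peaks decrease with duration; "
                                  "check normalization/sign conventions")
    if t0 is None:
        t0 = float(np.min(t))

    i_max0 = float(np.max(y))
    a0 = max(i_max0 - float(np.min(y)), 1e-6)
    tau0 = max((np.max(t) - np.min(t)) / 3.0, 1e-3)
    try:
        if free_t0:
            popt, pcov = optimize.curve_fit(
                _recovery_model, t, y, p0=(i_max0, a0, tau0, t0),
                bounds=([1e-12, 1e-12, 1e-9, -np.inf],
                        [np.inf, np.inf, np.inf, np.inf]),
                maxfev=20000, xtol=1e-13, ftol=1e-13)
            i_max, a, tau, t0_fit = popt
        else:
            def model(t, i_max, a, tau):
                return _recovery_model(t, i_max, a, tau, t0)

            popt, pcov = optimize.curve_fit(
                model, t, y, p0=(i_max0, a0, tau0),
                bounds=([1e-12, 1e-12, 1e-9], [np.inf, np.inf, np.inf]),
                maxfev=20000, xtol=1e-13, ftol=1e-13)
            i_max, a, tau = popt
            t0_fit = t0
    except RuntimeError as exc:
        raise FitError(f"recovery fit did not converge: {exc}") from exc
    ses = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
    return RecoveryFit(I_max=float(i_max), A=float(a), t0=float(t0_fit),
                       tau=float(tau), se_I_max=float(ses[0]),
                       se_A=float(ses[1]), se_tau=float(ses[2]),
                       n_points=len(t), t0_fixed=not free_t0)


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def bootstrap_ci(x, y, fit_func, param: str, *, n_boot: int = 1000,
                 alpha: float = 0.05, seed: int = 0) -> tuple[float, float]:
    """Seeded percentile bootstrap CI for one parameter of a paired fit.

    ``fit_func(x, y)`` must return an object exposing ``param`` as an
    attribute.  Resamples pairs with replacement; failed refits are skipped.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    stats = []
    for _ in range(n_boot):
        idx = rng.integers(0, len(x), size=len(x))
        try:
            stats.append(getattr(fit_func(x[idx], y[idx]), param))
        except Exception:
            continue
    if len(stats) < n_boot // 2:
        raise FitError("bootstrap failed for most resamples")
    lo, hi = np.percentile(stats, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)
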