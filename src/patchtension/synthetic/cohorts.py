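"""Cohort-level generators: per-response tables with known ground truth.

Each generator uses a :class:`numpy.random.SeedSequence` split per cell so
that identical configs are bit-reproducible and per-cell subsets do not
depend on the other cells.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from ..mechanics import laplace_tension
from .params import ChannelParams, MembraneModel, SimulationConfig


#: Generative (T50, k) pairs in mN/m per recording condition, the per-cell
#: counts and response totals of the bundled demonstration cohorts, and the
#: normalization mode each condition's analysis uses.
CONDITIONS: dict[str, dict] = {
    "cell_attached": dict(T50=2.7, k=0.8, n_cells=15, n_responses=218,
                          normalization="plateau"),
    "inside_out": dict(T50=4.7, k=1.2, n_cells=10, n_responses=123,
                       normalization="plateau"),
    "prepulse_0": dict(T50=2.2, k=0.8, n_cells=11, n_responses=121,
                       normalization="max"),
    "prepulse_5": dict(T50=1.4, k=0.7, n_cells=11, n_responses=121,
                       normalization="max"),
    "prepulse_10": dict(T50=1.8, k=1.1, n_cells=11, n_responses=121,
                        normalization="max"),
}

#: Test-pressure grid (mmHg): 0 to -50 in 5 mmHg increments.
DEFAULT_PRESSURES: tuple[float, ...] = tuple(float(-5 * i) for i in range(11))


def boltzmann(x, i_max, x50, k):
    return i_max / (1.0 + np.exp(-(np.asarray(x, dtype=float) - x50) / k))


def config_for_condition(condition: str, seed: int = 0,
                         **overrides) -> SimulationConfig:
    """A SimulationConfig matching a named condition's generative parameters."""
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}; "
                         f"choose from {sorted(CONDITIONS)}")
    preset = CONDITIONS[condition]
    channel = ChannelParams(T50_true=preset["T50"], k_true=preset["k"])
    cfg = SimulationConfig(seed=seed, n_cells=preset["n_cells"],
                           n_responses=preset["n_responses"], channel=channel)
    for key, value in overrides.items():
        setattr(cfg, key, value)
    return cfg


def simulate_response_set(config: SimulationConfig,
                          condition: str = "cell_attached",
                          *, pressures=DEFAULT_PRESSURES) -> pd.DataFrame:
    """Per-response table for a synthetic cohort.

    For every response: the true dome radius comes from the membrane
    curvature-pressure map (with a per-cell pipette-opening radius, since
    pipette size varies from patch to patch), true tension from Laplace's
    law, the mean peak from the generative tension Boltzmann with per-cell
    heterogeneity, plus additive current noise; the *measured* radius adds
    ``noise_radius``.

    Columns: cell_id, sweep_id, dp_mmHg, radius_um (measured),
    radius_true_um, tension_true_mN_m, peak_pA, plus per-cell ground truth
    (T50_cell, I_max_cell).
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    preset = CONDITIONS[condition]
    channel = config.channel
    t50, k = channel.T50_true, channel.k_true
    if (t50, k) == (ChannelParams.T50_true, ChannelParams.k_true) and \
            (preset["T50"], preset["k"]) != (t50, k):
        # config left at defaults: adopt the condition's generative pair
        channel = replace(channel, T50_true=preset["T50"], k_true=preset["k"])
        t50, k = channel.T50_true, channel.k_true

    counts = config.responses_by_cell()
    streams = np.random.SeedSequence(config.seed).spawn(config.n_cells)
    rows = []
    for i, (count, stream) in enumerate(zip(counts, streams)):
        rng = np.random.default_rng(stream)
        t50_cell = t50 + rng.normal(0.0, config.cell_heterogeneity * t50)
        imax_cell = channel.I_max_true * \
            rng.lognormal(0.0, config.cell_heterogeneity)
        r_min_cell = config.membrane.r_min * \
            (1.0 + rng.uniform(-config.tip_radius_spread,
                               config.tip_radius_spread))
        membrane_cell = replace(config.membrane, r_min=r_min_cell)

        dps = np.tile(pressures, int(np.ceil(count / len(pressures))))[:count]
        for j, dp in enumerate(dps):
            r_true = float(membrane_cell.radius(dp))
            flat = not np.isfinite(r_true)
            t_true = 0.0 if flat else float(laplace_tension(r_true, dp))
            mean_peak = float(boltzmann(t_true, imax_cell, t50_cell, k))
            peak = mean_peak + rng.normal(0.0, config.noise_current)
            r_meas = np.inf if flat else \
                r_true + rng.normal(0.0, config.noise_radius)
            rows.append(dict(cell_id=f"cell{i:03d}", sweep_id=j,
                             dp_mmHg=float(dp), radius_um=r_meas,
                             radius_true_um=r_true,
                             tension_true_mN_m=t_true, peak_pA=peak,
                             T50_cell=t50_cell, I_max_cell=imax_cell))
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class RecoveryModel:
    """Saturating-exponential growth of the off-response with prepulse time:
    ``I(t) = I_max - A * exp(-(t - t0) / tau)``."""

    I_max: float = 0.82
    A: float = 0.49
    tau: float = 2.4
    t0: float = 0.3

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        return self.I_max - self.A * np.exp(-(t - self.t0) / self.tau)


def recovery_durations(t_min: float = 0.3, t_max: float = 10.0,
                       factor: float = 0.75) -> np.ndarray:
    """Prepulse durations spanning [t_min, t_max], spaced by 1/factor."""
    durations = [t_min]
    while durations[-1] / factor < t_max * (1 + 1e-9):
        durations.append(durations[-1] / factor)
    return np.array(durations)


def simulate_recovery_peaks(*, n_patches: int = 11,
                            durations: np.ndarray | None = None,
                            model: RecoveryModel = RecoveryModel(),
                            noise_sd: float = 0.05,
                            peak_scale_pA: float = 300.0,
                            seed: int = 0) -> pd.DataFrame:
    """Off-response peak vs prepulse duration for a set of patches.

    Peaks are drawn from the saturating-exponential recovery model (scaled
    to pA with per-patch scale heterogeneity) plus Gaussian noise of
    fractional SD ``noise_sd``.

    Columns: patch_id, duration_s, peak_pA.
    """
    if durations is None:
        durations = recovery_durations()
    streams = np.random.SeedSequence(seed).spawn(n_patches)
    rows = []
    for i, stream in enumerate(streams):
        rng = np.random.default_rng(stream)
        scale = peak_scale_pA * rng.lognormal(0.0, 0.2)
        values = model(durations) + rng.normal(0.0, noise_sd,
                                               size=len(durations))
        for t, v in zip(durations, values):
            rows.append(dict(patch_id=f"patch{i:03d}", duration_s=float(t),
                             peak_pA=float(v * scale)))
    return pd.DataFrame(rows)


def simulate_pressure_cells(*, n_cells: int = 15, p50_mean: float = -16.7,
                            p50_sd: float = 2.8 * np.sqrt(15.0),
                            k_mmhg: float = 5.0,
                            i_max_pA: float = 400.0,
                            pressures=DEFAULT_PRESSURES,
                            noise_current: float = 8.0,
                            heterogeneity: float = 0.1,
                            seed: int = 0) -> pd.DataFrame:
    """Negative-pressure step series with per-cell Boltzmann midpoints.

    Each cell's half-activation pressure is spread normal around
    ``p50_mean`` with SD ``p50_sd`` (the population SD implied by a
    standard error of 2.8 mmHg over 15 cells), realised as shuffled
    stratified normal quantiles so the cohort mean is pinned at the
    population mean rather than at the luck of 15 draws; midpoints are
    clipped to at most -1 mmHg (every cell is activated by suction).
    Currents follow a Boltzmann in |pressure| plus additive noise.

    Columns: cell_id, dp_mmHg, peak_pA, P50_cell.
    """
    from scipy import stats

    streams = np.random.SeedSequence(seed).spawn(n_cells)
    z = stats.norm.ppf((np.arange(n_cells) + 0.5) / n_cells)
    np.random.default_rng(seed).shuffle(z)
    p50_cells = np.minimum(p50_mean + p50_sd * z, -1.0)
    rows = []
    for i, stream in enumerate(streams):
        rng = np.random.default_rng(stream)
        p50_cell = p50_cells[i]
        imax_cell = i_max_pA * rng.lognormal(0.0, heterogeneity)
        for j, dp in enumerate(pressures):
            mean_peak = boltzmann(abs(dp), imax_cell, abs(p50_cell), k_mmhg)
            rows.append(dict(cell_id=f"cell{i:03d}", sweep_id=j,
                             dp_mmHg=float(dp),
                             peak_pA=float(mean_peak
                                           + rng.normal(0, noise_current)),
                             P50_cell=float(p50_cell)))
    return pd.DataFrame(rows)
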