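"""Parameter types for the synthetic-data generators."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

from ..mechanics import FLAT_CURVATURE, TENSION_PER_UM_MMHG


@dataclass
class PipetteGeometry:
    """Geometry of the rendered pipette phantom.

    half_angle        taper of the walls away from the axis, degrees
    tip_inner_radius  inner radius of the tip opening, um
    axis_angle        pipette axis relative to image rows, degrees (~15 in
                      the experimental arrangement)
    wall_darkness     depth of the dark wall ridges (fraction of background)
    pixel_size        um per pixel (default 1/61.5)
    """

    half_angle: float = 12.0
    tip_inner_radius: float = 2.4
    axis_angle: float = 15.0
    wall_darkness: float = 0.85
    pixel_size: float = 1.0 / 61.5

    def __post_init__(self):
        if self.half_angle <= 0:
            raise ValueError("half_angle must be positive")
        if self.tip_inner_radius <= 0:
            raise ValueError("tip_inner_radius must be positive")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")


@dataclass
class MembraneModel:
    """Curvature-pressure map of the membrane dome.

    Signed curvature is linear in applied pressure,
    ``c(dp) = c_rest * (1 - dp / dp_flat)`` with ``c_rest = 1/R_rest``:
    convex (positive) at rest, flattening to zero at ``dp_flat`` (around
    +5 to +6 mmHg) and inverting beyond.  The curvature magnitude is capped
    at ``1/r_min`` (the dome cannot be tighter than the pipette opening),
    so the radius is pinned at ``r_min`` for strong suction and tension then
    grows linearly with |dp|.
    """

    R_rest: float = 3.0
    dp_flat: float = 5.0
    r_min: float = 2.4
    convex_at_rest: bool = True

    def __post_init__(self):
        if self.R_rest <= 0:
            raise ValueError("R_rest must be positive")
        if self.dp_flat <= 0:
            raise ValueError("dp_flat must be positive")
        if self.r_min <= 0:
            raise ValueError("r_min must be positive")

    def curvature(self, dp_mmhg):
        """Signed curvature (1/um) at applied pressure dp (mmHg)."""
        dp = np.asarray(dp_mmhg, dtype=float)
        c = (1.0 / self.R_rest) * (1.0 - dp / self.dp_flat)
        c_max = 1.0 / self.r_min
        return np.clip(c, -c_max, c_max)[()] if c.ndim == 0 else np.clip(c, -c_max, c_max)

    def radius(self, dp_mmhg):
        """Unsigned dome radius (um); inf where the membrane is flat."""
        c = np.abs(np.asarray(self.curvature(dp_mmhg), dtype=float))
        with np.errstate(divide="ignore"):
            r = np.where(c < FLAT_CURVATURE, np.inf, 1.0 / np.maximum(c, 1e-300))
        return float(r) if r.ndim == 0 else r

    def tension(self, dp_mmhg):
        """Laplace tension (mN/m) of the dome at applied pressure dp."""
        dp = np.asarray(dp_mmhg, dtype=float)
        r = np.asarray(self.radius(dp_mmhg), dtype=float)
        t = np.where(np.isfinite(r), r * np.abs(dp) * TENSION_PER_UM_MMHG, 0.0)
        return float(t) if t.ndim == 0 else t


@dataclass
class ChannelParams:
    """Gating parameters of the simulated mechanosensitive channel.

    Activation is an instantaneous Boltzmann in tension (midpoint
    ``T50_true``, slope ``k_true``); a slow availability variable relaxes
    with time constant ``tau_inact`` (tens of ms) when open probability is
    high and ``tau_rec`` (seconds) when tension is near zero.  ``T_rest`` is
    the resting tension at dp = 0 (order 0.5-4 mN/m in gigaseal patches).
    """

    T50_true: float = 2.7
    k_true: float = 0.8
    I_max_true: float = 400.0
    tau_inact: float = 30e-3
    tau_rec: float = 2.4
    T_rest: float = 2.0

    def __post_init__(self):
        for name in ("T50_true", "k_true", "I_max_true", "tau_inact",
                     "tau_rec", "T_rest"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.tau_rec <= self.tau_inact:
            raise ValueError("tau_rec must be much larger than tau_inact")

    def open_probability(self, tension):
        t = np.asarray(tension, dtype=float)
        p = 1.0 / (1.0 + np.exp(-(t - self.T50_true) / self.k_true))
        return float(p) if p.ndim == 0 else p


@dataclass
class PressureProtocol:
    """Ordered pressure steps: (amplitude mmHg, duration ms)."""

    steps: Sequence[tuple[float, float]]
    inter_sweep_interval: float = 10.0
    sample_rate: float = 5000.0

    def __post_init__(self):
        self.steps = [(float(a), float(d)) for a, d in self.steps]
        if not self.steps:
            raise ValueError("protocol must contain at least one step")
        if any(d <= 0 for _, d in self.steps):
            raise ValueError("step durations must be positive")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def total_duration_s(self) -> float:
        return sum(d for _, d in self.steps) / 1000.0

    def pressure_series(self) -> np.ndarray:
        """Per-sample pressure trace (mmHg) at the protocol sample rate."""
        chunks = []
        for amp, dur_ms in self.steps:
            n = int(round(dur_ms / 1000.0 * self.sample_rate))
            chunks.append(np.full(max(n, 1), amp))
        return np.concatenate(chunks)


def step_protocol(amplitude: float, duration_ms: float, *,
                  pre_ms: float = 200.0, post_ms: float = 500.0,
                  sample_rate: float = 5000.0) -> PressureProtocol:
    """Baseline / test step / release protocol."""
    return PressureProtocol(steps=[(0.0, pre_ms), (amplitude, duration_ms),
                                   (0.0, post_ms)], sample_rate=sample_rate)


def prepulse_protocol(prepulse_mmhg: float, prepulse_s: float, *,
                      pre_ms: float = 200.0, post_ms: float = 700.0,
                      sample_rate: float = 5000.0) -> PressureProtocol:
    """Conditioning prepulse followed by release back to 0 mmHg."""
    return PressureProtocol(steps=[(0.0, pre_ms),
                                   (prepulse_mmhg, prepulse_s * 1000.0),
                                   (0.0, post_ms)], sample_rate=sample_rate)


@dataclass
class SimulationConfig:
    """Full configuration of a synthetic cohort.

    The seed is split deterministically (``numpy.random.SeedSequence``)
    per cell, so an identical config yields bit-identical output and
    per-cell subsets are reproducible.
    """

    seed: int = 0
    n_cells: int = 15
    responses_per_cell: int = 15
    n_responses: Optional[int] = None  # total; overrides responses_per_cell
    geometry: PipetteGeometry = field(default_factory=PipetteGeometry)
    membrane: MembraneModel = field(default_factory=MembraneModel)
    channel: ChannelParams = field(default_factory=ChannelParams)
    noise_current: float = 8.0        # pA, additive per peak / per sample
    noise_radius: float = 0.05        # um, per radius measurement
    cell_heterogeneity: float = 0.08  # fractional SD on T50_true / I_max_true
    tip_radius_spread: float = 0.30   # fractional half-range of per-cell r_min

    def __post_init__(self):
        for name in ("noise_current", "noise_radius", "cell_heterogeneity",
                     "tip_radius_spread"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")

    def total_responses(self) -> int:
        if self.n_responses is not None:
            return int(self.n_responses)
        return self.n_cells * self.responses_per_cell

    def responses_by_cell(self) -> list[int]:
        """Distribute the total response count as evenly as possible."""
        total = self.total_responses()
        base, extra = divmod(total, self.n_cells)
        return [base + (1 if i < extra else 0) for i in range(self.n_cells)]

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if isinstance(d.get("geometry"), dict):
            d["geometry"] = PipetteGeometry(**d["geometry"])
        if isinstance(d.get("membrane"), dict):
            d["membrane"] = MembraneModel(**d["membrane"])
        if isinstance(d.get("channel"), dict):
            d["channel"] = ChannelParams(**d["channel"])
        return cls(**d)
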