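"""Ensemble current-trace simulation with a two-variable gating model.

Open probability follows the tension Boltzmann instantaneously; a slow
availability variable a(t) relaxes toward a steady state that decreases
with open probability, fast under high tension (tau_inact) and slowly when
tension is near zero (tau_rec).  The current is ``-I_max * p_o(t) * a(t)``
(negative = inward at negative holding potential) plus optional noise.
"""

from __future__ import annotations

import numpy as np

from ..ephys import SweepRecord
from ..mechanics import FLAT_CURVATURE
from .params import ChannelParams, MembraneModel, PressureProtocol


class SolverError(RuntimeError):
    """The availability integration step is invalid or unstable."""


def gating_tension(dp_mmhg, membrane: MembraneModel,
                   channel: ChannelParams):
    """Tension (mN/m) driving the gating model at applied pressure dp.

    The Laplace tension of the (curvature-capped) dome, with a resting-
    tension floor that scales with relative curvature: at dp = 0 the patch
    carries ``T_rest`` even though the applied pressure is zero, and the
    floor vanishes together with the curvature at ``dp_flat``.  This floor
    is a modelling stand-in; the behaviour of dome tension between dp = 0
    and the flattening pressure is not constrained by measurements.
    """
    dp = np.asarray(dp_mmhg, dtype=float)
    t_lap = np.asarray(membrane.tension(dp), dtype=float)
    rel_curv = np.abs(np.asarray(membrane.curvature(dp), dtype=float)) \
        * membrane.R_rest
    rel_curv = np.where(rel_curv < FLAT_CURVATURE * membrane.R_rest,
                        0.0, rel_curv)
    t = np.maximum(t_lap, channel.T_rest * rel_curv)
    return float(t) if t.ndim == 0 else t


def availability_steady_state(p_open):
    """Fraction of channels available at steady state: 1 - p_open."""
    return 1.0 - np.asarray(p_open, dtype=float)


def availability_tau(p_open, channel: ChannelParams):
    """Relaxation time constant: tau_rec near rest, tau_inact when driven."""
    p = np.asarray(p_open, dtype=float)
    return channel.tau_rec + (channel.tau_inact - channel.tau_rec) * p


def simulate_trace(protocol: PressureProtocol, channel: ChannelParams,
                   membrane: MembraneModel, *, seed: int = 0,
                   noise_current: float = 0.0,
                   cell_id: str = "sim", sweep_id: int = 0,
                   configuration: str = "cell_attached",
                   initial_availability: float | None = None) -> SweepRecord:
    """Integrate the gating model over a pressure protocol.

    Availability starts at its steady state for the resting tension unless
    ``initial_availability`` is given.  Integration uses the exact
    per-sample exponential update of the linear relaxation, which is
    unconditionally stable; invalid sampling raises :class:`SolverError`.
    """
    if not np.isfinite(protocol.sample_rate) or protocol.sample_rate <= 0:
        raise SolverError("invalid sample rate")
    pressure = protocol.pressure_series()
    dt = 1.0 / protocol.sample_rate

    tension = gating_tension(pressure, membrane, channel)
    if np.any(~np.isfinite(tension)):
        raise SolverError("non-finite tension in protocol")
    p_open = channel.open_probability(tension)
    a_inf = availability_steady_state(p_open)
    tau = availability_tau(p_open, channel)
    decay = 1.0 - np.exp(-dt / tau)

    if initial_availability is None:
        p_rest = channel.open_probability(channel.T_rest)
        a = float(availability_steady_state(p_rest))
    else:
        a = float(initial_availability)

    avail = np.empty_like(p_open)
    for i in range(len(p_open)):
        a = a + (a_inf[i] - a) * decay[i]
        avail[i] = a

    current = -channel.I_max_true * p_open * avail
    if noise_current > 0:
        rng = np.random.default_rng(seed)
        current = current + rng.normal(0.0, noise_current, size=current.shape)

    # step window: span of the largest-|amplitude| step
    t0 = 0.0
    best = None
    for amp, dur_ms in protocol.steps:
        t1 = t0 + dur_ms / 1000.0
        if amp != 0.0 and (best is None or abs(amp) > abs(best[0])):
            best = (amp, t0, t1)
        t0 = t1
    if best is None:  # all-zero protocol: second half, leaving a baseline
        total = len(pressure) * dt
        window = (total / 2.0, total)
    else:
        window = (best[1], best[2])

    prepulse = None
    positives = [(amp, dur_ms / 1000.0) for amp, dur_ms in protocol.steps
                 if amp > 0]
    if positives:
        prepulse = max(positives, key=lambda t: t[1])

    return SweepRecord(cell_id=cell_id, sweep_id=sweep_id,
                       configuration=configuration,
                       trace_pA=current, pressure_mmHg=pressure,
                       sample_rate=protocol.sample_rate,
                       step_window=window, prepulse=prepulse)
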