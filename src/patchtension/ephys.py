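"""Current-sweep processing: baseline subtraction, peak measurement, QC.

Traces follow the recording convention of inward current at negative holding
potential: the stimulated current is negative-going.  Peak amplitudes are
reported as non-negative magnitudes after baseline subtraction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import optimize


class WindowError(ValueError):
    """A measurement window falls outside the trace."""


class QCInputError(ValueError):
    """A required QC field is missing."""


CONFIGURATIONS = ("cell_attached", "inside_out", "outside_out")


@dataclass
class SweepRecord:
    """One pressure sweep: current trace plus aligned pressure series."""

    cell_id: str
    sweep_id: int
    configuration: str
    trace_pA: np.ndarray
    pressure_mmHg: np.ndarray
    sample_rate: float
    step_window: tuple[float, float]           # (start, end) seconds
    prepulse: Optional[tuple[float, float]] = None  # (mmHg, duration s)

    def __post_init__(self):
        self.trace_pA = np.asarray(self.trace_pA, dtype=float)
        self.pressure_mmHg = np.asarray(self.pressure_mmHg, dtype=float)
        if self.trace_pA.shape != self.pressure_mmHg.shape:
            raise ValueError("trace and pressure series must have equal length")
        if self.configuration not in CONFIGURATIONS:
            raise ValueError(f"unknown configuration {self.configuration!r}")
        start, end = self.step_window
        if not (0 <= start < end <= self.duration_s + 1e-9):
            raise ValueError("step_window must lie within the trace span")

    @property
    def duration_s(self) -> float:
        return len(self.trace_pA) / self.sample_rate

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(len(self.trace_pA)) / self.sample_rate

    def slice(self, window: tuple[float, float]) -> np.ndarray:
        i0 = int(round(window[0] * self.sample_rate))
        i1 = int(round(window[1] * self.sample_rate))
        if i0 < 0 or i1 > len(self.trace_pA) or i0 >= i1:
            raise WindowError(f"window {window} outside trace "
                              f"of {self.duration_s:.3f} s")
        return self.trace_pA[i0:i1]


@dataclass(frozen=True)
class PeakMeasurement:
    """Baseline and on/off peak magnitudes for one sweep."""

    baseline: float
    peak_on: float
    peak_off: float
    decay_tau_ms: Optional[float] = None

    def __post_init__(self):
        if not np.isfinite(self.baseline):
            raise ValueError("baseline must be finite")
        if self.peak_on < 0 or self.peak_off < 0:
            raise ValueError("peaks are non-negative magnitudes")


@dataclass(frozen=True)
class PatchQC:
    seal_resistance_GOhm: float
    max_abs_current_pA: float
    passed: bool
    reason: str = ""


def measure_peaks(sweep: SweepRecord, *,
                  baseline_window: Optional[tuple[float, float]] = None,
                  off_window_s: float = 0.5,
                  inward_negative: bool = True,
                  fit_decay: bool = False,
                  decay_prominence_pA: float = 10.0) -> PeakMeasurement:
    """Measure baseline-subtracted on- and off-response peak magnitudes.

    baseline = mean current over ``baseline_window`` (default: from the trace
    start to the step onset); peak_on = largest inward excursion from
    baseline during the step window; peak_off = the same over a window of
    ``off_window_s`` seconds after the step ends (clipped to the trace).
    ``fit_decay`` optionally fits a single exponential from the on-peak to
    the step end and reports its time constant in ms.
    """
    step_start, step_end = sweep.step_window
    if baseline_window is None:
        baseline_window = (0.0, step_start)
    if baseline_window[1] > step_start + 1e-9:
        raise WindowError("baseline window must precede the step window")
    if np.any(~np.isfinite(sweep.trace_pA)):
        raise ValueError("trace contains non-finite samples")

    baseline = float(np.mean(sweep.slice(baseline_window)))
    sign = -1.0 if inward_negative else 1.0
    response = sign * (sweep.trace_pA - baseline)  # inward excursion, >= 0-ish

    step = sweep.slice(sweep.step_window)
    peak_on = float(max(np.max(sign * (step - baseline)), 0.0))

    off_end = min(step_end + off_window_s, sweep.duration_s)
    if off_end > step_end:
        off = sweep.slice((step_end, off_end))
        peak_off = float(max(np.max(sign * (off - baseline)), 0.0))
    else:
        peak_off = 0.0

    decay_tau_ms = None
    if fit_decay and peak_on >= decay_prominence_pA:
        i0 = int(round(step_start * sweep.sample_rate))
        i1 = int(round(step_end * sweep.sample_rate))
        seg = response[i0:i1]
        k = int(np.argmax(seg))
        tail = seg[k:]
        if len(tail) >= 10:
            t = np.arange(len(tail)) / sweep.sample_rate

            def model(t, amp, tau, offset):
                return amp * np.exp(-t / tau) + offset

            try:
                popt, _ = optimize.curve_fit(
                    model, t, tail,
                    p0=(tail[0] - tail[-1], max(t[-1] / 3.0, 1e-4), tail[-1]),
                    bounds=([0, 1e-6, -np.inf], [np.inf, np.inf, np.inf]),
                    maxfev=10000)
                decay_tau_ms = float(popt[1] * 1000.0)
            except RuntimeError:
                decay_tau_ms = None

    return PeakMeasurement(baseline=baseline, peak_on=peak_on,
                           peak_off=peak_off, decay_tau_ms=decay_tau_ms)


def apply_qc(*, seal_resistance_GOhm: Optional[float] = None,
             max_abs_current_pA: Optional[float] = None,
             configuration: str = "cell_attached",
             negative_pressure: bool = True,
             min_seal_GOhm: float = 1.0,
             min_current_primary_pA: float = 50.0,
             min_current_other_pA: float = 20.0) -> PatchQC:
    """Patch-level quality control.

    A patch passes when seal resistance is at least ``min_seal_GOhm`` (1 GOhm)
    and the maximal pressure-induced current reaches the configuration
    threshold: 50 pA for cell-attached and inside-out patches under negative
    pressure, 20 pA for all other configurations.
    """
    if seal_resistance_GOhm is None or max_abs_current_pA is None:
        raise QCInputError("seal_resistance_GOhm and max_abs_current_pA "
                           "are required")
    if configuration not in CONFIGURATIONS:
        raise QCInputError(f"unknown configuration {configuration!r}")

    primary = configuration in ("cell_attached", "inside_out") and negative_pressure
    current_threshold = min_current_primary_pA if primary else min_current_other_pA

    reasons = []
    if seal_resistance_GOhm < min_seal_GOhm:
        reasons.append("seal")
    if max_abs_current_pA < current_threshold:
        reasons.append("current")
    return PatchQC(seal_resistance_GOhm=float(seal_resistance_GOhm),
                   max_abs_current_pA=float(max_abs_current_pA),
                   passed=not reasons, reason=",".join(reasons))
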