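"""End-to-end orchestration: simulate -> tension -> normalize -> bin -> fit.

Every run is driven by a serializable config whose SHA-256 hash is embedded
in the outputs, and all randomness flows from a single seed, so reruns with
the same config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import fitting, imaging, mechanics
from .fitting import BinnedHistogram, BoltzmannFit, RecoveryFit
from .synthetic import cohorts, render
from .synthetic.params import SimulationConfig

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Run configuration is inconsistent or incomplete."""


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    condition: str = "cell_attached"
    simulate: bool = True
    responses_path: Optional[str] = None   # used when simulate=False
    out_dir: str = "runs/out"
    seed: int = 0
    bin_width: float = fitting.TENSION_BIN_WIDTH
    normalization: str = "plateau"
    include_flat: bool = True
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def __post_init__(self):
        if self.condition not in cohorts.CONDITIONS:
            raise ConfigError(f"unknown condition {self.condition!r}")
        if not self.simulate and not self.responses_path:
            raise ConfigError("simulation disabled but no responses_path given")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if isinstance(d.get("simulation"), dict):
            d["simulation"] = SimulationConfig.from_dict(d["simulation"])
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml
            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls.from_dict(data)

    def config_hash(self) -> str:
        """Hash of the analysis-relevant config (output paths excluded)."""
        d = self.to_dict()
        d.pop("out_dir", None)
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """Summary of one pipeline run."""

    config_hash: str
    n_cells: int
    n_responses: int
    n_cells_used: int
    fit: dict
    histogram_bins: int
    ground_truth: dict = field(default_factory=dict)
    recovered_vs_true: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)  # path -> sha256

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def compute_tensions(responses: pd.DataFrame, *,
                     radius_col: str = "radius_um",
                     include_flat: bool = True) -> pd.DataFrame:
    """Add a ``tension_mN_m`` column from measured radius and pressure."""
    out = responses.copy()
    radius = out[radius_col].to_numpy(dtype=float)
    dp = out["dp_mmHg"].to_numpy(dtype=float)
    flat = ~np.isfinite(radius) | (radius <= 0)
    tension = np.zeros_like(dp)
    tension[~flat] = mechanics.laplace_tension(radius[~flat], dp[~flat])
    out["tension_mN_m"] = tension
    out["flat"] = flat
    if not include_flat:
        out = out.loc[~flat].reset_index(drop=True)
    return out


def analyze_tension_cohort(responses: pd.DataFrame, *,
                           bin_width: float = fitting.TENSION_BIN_WIDTH,
                           normalization: str = "plateau",
                           include_flat: bool = True,
                           radius_col: str = "radius_um"):
    """Full tension analysis of a per-response table.

    Steps: Laplace tension from measured radii, per-cell normalization
    (fitted plateau or per-patch maximum), pooling into ``bin_width`` bins,
    SD-weighted Boltzmann fit of the binned means.

    Returns ``(fit, histogram, normalized_table, per_cell_info)``.
    """
    with_t = compute_tensions(responses, radius_col=radius_col,
                              include_flat=include_flat)
    normed, cell_info = fitting.normalize_responses(
        with_t, mode=normalization)
    hist = fitting.pool_and_bin(normed["tension_mN_m"],
                                normed["norm_current"],
                                bin_width=bin_width)
    fit = fitting.fit_tension_curve(hist)
    return fit, hist, normed, cell_info


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the configured stages and write all artifacts to out_dir."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if config.simulate:
        sim = dataclasses.replace(config.simulation, seed=config.seed)
        if sim.n_responses is None:
            preset = cohorts.CONDITIONS[config.condition]
            sim = dataclasses.replace(sim, n_cells=preset["n_cells"],
                                      n_responses=preset["n_responses"])
        responses = cohorts.simulate_response_set(sim, config.condition)
        logger.info("simulated %d responses over %d cells",
                    len(responses), responses["cell_id"].nunique())
    else:
        path = Path(config.responses_path)
        if not path.exists():
            raise ConfigError(f"responses file not found: {path}")
        responses = pd.read_csv(path)
        logger.info("loaded %d responses from %s", len(responses), path)

    try:
        fit, hist, normed, cell_info = analyze_tension_cohort(
            responses, bin_width=config.bin_width,
            normalization=config.normalization,
            include_flat=config.include_flat)
    except Exception as exc:
        raise RuntimeError(
            f"analysis stage failed for condition {config.condition!r} "
            f"({len(responses)} responses): {exc}") from exc

    ground_truth, deltas = {}, {}
    if "T50_cell" in responses.columns:
        gen = cohorts.CONDITIONS[config.condition]
        ground_truth = {"T50": gen["T50"], "k": gen["k"]}
        deltas = {"T50": fit.X50 - gen["T50"], "k": fit.k - gen["k"]}

    paths = {
        "responses.csv": responses,
        "binned.csv": hist.to_frame(),
        "normalized.csv": normed,
    }
    outputs = {}
    for name, frame in paths.items():
        p = out_dir / name
        frame.to_csv(p, index=False, float_format="%.10g")
        outputs[name] = _sha256(p)
    fit_payload = {"fit": fit.to_dict(), "config_hash": config.config_hash(),
                   "normalization": config.normalization,
                   "bin_width": config.bin_width}
    fit_path = out_dir / "fit.json"
    fit_path.write_text(json.dumps(fit_payload, indent=2, sort_keys=True))
    outputs["fit.json"] = _sha256(fit_path)

    report = RunReport(config_hash=config.config_hash(),
                       n_cells=responses["cell_id"].nunique(),
                       n_responses=len(responses),
                       n_cells_used=len(cell_info),
                       fit=fit.to_dict(), histogram_bins=len(hist),
                       ground_truth=ground_truth,
                       recovered_vs_true=deltas, outputs=outputs)
    (out_dir / "report.json").write_text(
        json.dumps(report.to_dict(), indent=2, sort_keys=True))
    return report


# ---------------------------------------------------------------------------
# canned recovery experiments (parameter-recovery harness)
# ---------------------------------------------------------------------------

def recover_condition(condition: str, *, seed: int = 0, **overrides) -> dict:
    """Simulate a named condition and run the tension pipeline on it."""
    cfg = cohorts.config_for_condition(condition, seed=seed, **overrides)
    responses = cohorts.simulate_response_set(cfg, condition)
    normalization = cohorts.CONDITIONS[condition]["normalization"]
    fit, hist, normed, cell_info = analyze_tension_cohort(
        responses, normalization=normalization)
    gen = cohorts.CONDITIONS[condition]
    return {"condition": condition, "generative": {"T50": gen["T50"],
                                                   "k": gen["k"]},
            "fit": fit, "histogram": hist, "responses": responses,
            "n_cells_used": len(cell_info)}


def recover_recovery_tau(*, seed: int = 0, n_patches: int = 11,
                         noise_sd: float = 0.05) -> dict:
    """Simulate recovery peaks and fit the mean normalized time course."""
    model = cohorts.RecoveryModel()
    table = cohorts.simulate_recovery_peaks(n_patches=n_patches,
                                            noise_sd=noise_sd, seed=seed)
    normed, _ = fitting.normalize_responses(table, mode="max",
                                            cell_col="patch_id",
                                            y_col="peak_pA")
    mean = normed.groupby("duration_s", sort=True)["norm_current"] \
                 .mean().reset_index()
    fit = fitting.fit_recovery(mean["duration_s"], mean["norm_current"])
    return {"generative": {"I_max": model.I_max, "A": model.A,
                           "tau": model.tau, "t0": model.t0},
            "fit": fit, "table": table}


def recover_pressure_midpoint(*, seed: int = 0, n_cells: int = 15) -> dict:
    """Per-cell pressure-domain Boltzmann fits; returns the mean midpoint."""
    table = cohorts.simulate_pressure_cells(n_cells=n_cells, seed=seed)
    p50s = []
    for cell, grp in table.groupby("cell_id", sort=True):
        fit = fitting.fit_boltzmann(np.abs(grp["dp_mmHg"]), grp["peak_pA"],
                                    domain="pressure")
        p50s.append(-fit.X50)  # negative-pressure branch
    p50s = np.array(p50s)
    return {"generative_mean_P50": -16.7, "mean_P50": float(p50s.mean()),
            "se_P50": float(p50s.std(ddof=1) / np.sqrt(len(p50s))),
            "per_cell_P50": p50s, "table": table}


def measure_phantom_radius(radius_um: float = 2.87, *, seed: int = 0,
                           noise_sd: float = 0.01,
                           use_true_walls: bool = False) -> dict:
    """Render a phantom, re-detect the membrane, and fit its radius."""
    geometry = cohorts.SimulationConfig().geometry
    rendered = render.render_patch_image(geometry, radius_um,
                                         noise_sd=noise_sd, seed=seed)
    image = rendered.image
    if not use_true_walls:
        image = imaging.PatchImage(intensities=image.intensities,
                                   pixel_size=image.pixel_size)
    profile = imaging.detect_membrane(image, window=9)
    fit = imaging.fit_circle(profile)
    return {"radius_true": radius_um, "radius_fit": fit.radius,
            "fit": fit, "profile": profile, "rendered": rendered}


def run_reference_suite(out_dir, *, seed: int = 0) -> dict:
    """Run the canned parameter-recovery suite and write a summary table.

    Covers the five tension-curve conditions at their standard cohort
    sizes, the recovery time-course fit, the per-cell pressure midpoints,
    and the phantom-imaging round trip; the summary compares each recovered
    parameter with its generative value.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []

    for i, condition in enumerate(sorted(cohorts.CONDITIONS)):
        res = recover_condition(condition, seed=seed + i)
        fit: BoltzmannFit = res["fit"]
        rows.append(dict(experiment=condition, parameter="T50",
                         recovered=fit.X50, se=fit.se_X50,
                         generative=res["generative"]["T50"]))
        rows.append(dict(experiment=condition, parameter="k",
                         recovered=fit.k, se=fit.se_k,
                         generative=res["generative"]["k"]))

    rec = recover_recovery_tau(seed=seed + 10)
    rows.append(dict(experiment="recovery", parameter="tau",
                     recovered=rec["fit"].tau, se=rec["fit"].se_tau,
                     generative=rec["generative"]["tau"]))

    pres = recover_pressure_midpoint(seed=seed + 11)
    rows.append(dict(experiment="pressure_cell_attached", parameter="P50",
                     recovered=pres["mean_P50"], se=pres["se_P50"],
                     generative=pres["generative_mean_P50"]))

    phantom = measure_phantom_radius(seed=seed + 12)
    rows.append(dict(experiment="phantom_imaging", parameter="radius_um",
                     recovered=phantom["radius_fit"], se=np.nan,
                     generative=phantom["radius_true"]))

    table = pd.DataFrame(rows)
    table["delta"] = table["recovered"] - table["generative"]
    path = out_dir / "reference_suite.csv"
    table.to_csv(path, index=False, float_format="%.6g")
    summary = {"seed": seed, "n_experiments": len(table),
               "outputs": {"reference_suite.csv": _sha256(path)}}
    (out_dir / "reference_suite.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True))
    return {"table": table, "summary": summary}
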