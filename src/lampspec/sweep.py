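"""Sensitivity-analysis harness: default run plus single-parameter sweeps.

Each condition perturbs exactly one acquisition parameter away from the
defaults (noise level, temperature step, lowest temperature, filament
temperature error, spectral step, channel count), simulates noisy
acquisitions of a spectrum panel, reconstructs, and tabulates both
error metrics.  Conditions are replicated over independent noise draws
so that ordering comparisons between conditions are statistically
stable; seeds are split per (condition, spectrum, replicate) from one
master seed, making every cell independently reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .detector import channel_sensitivity, default_qe, make_bands
from .forward_model import (
    NoiseModel,
    TemperaturePerturbation,
    assemble_system,
    perturb_illumination,
    simulate_signals,
)
from .metrics import DEFAULT_RRMSE_FLOOR, compare
from .radiometry import (
    BulbFilter,
    build_illumination_matrix,
    make_grid,
    make_temperature_sequence,
)
from .reconstruction import (
    RegularizationConfig,
    augment,
    default_weights,
    solve_reflectance,
)
from .spectra import ReflectanceSpectrum
from .synthetic_spectra import default_panel_families, generate

__all__ = ["RunConfig", "SweepResult", "sensitivity_conditions", "run_default", "run_sensitivity"]


@dataclass(frozen=True)
class RunConfig:
    """One simulation configuration; the defaults are the baseline protocol.

    ``weights=None`` applies the 1/SNR rule (``k2 = 1/snr``,
    ``k1 = k2 * 1e-4``) so that conditions which change the SNR also
    change the regularization, as in the baseline protocol.
    """

    grid_start: float = 400.0
    grid_stop: float = 700.0
    grid_step: float = 10.0
    t_min: float = 2450.0
    t_max: float = 3400.0
    delta_t: float = 50.0
    p: int = 3
    snr: float = 100.0
    temp_error_sd: float = 0.0
    noise_convention: str = "per-signal"
    smoothing_operator: str = "printed-tridiagonal"
    weights: tuple[float, float] | None = None
    rrmse_floor: float = DEFAULT_RRMSE_FLOOR
    replicates: int = 20
    master_seed: int = 0
    panel_seed: int = 0

    def grid(self):
        return make_grid(self.grid_start, self.grid_stop, self.grid_step)

    def temperatures(self):
        return make_temperature_sequence(self.t_min, self.t_max, self.delta_t)

    def regularization(self) -> RegularizationConfig:
        if self.weights is not None:
            return RegularizationConfig(*self.weights, smoothing_operator=self.smoothing_operator)
        return default_weights(self.snr, smoothing_operator=self.smoothing_operator)

    def replace(self, **overrides) -> "RunConfig":
        return dataclasses.replace(self, **overrides)


@dataclass(frozen=True)
class SweepResult:
    """Tidy per-(condition, spectrum, replicate) metrics plus table views."""

    records: pd.DataFrame
    conditions: tuple[str, ...]

    def mean_table(self, metric: str = "rmse", as_percent: bool = True) -> pd.DataFrame:
        """Spectra-by-conditions table of replicate means."""
        table = self.records.pivot_table(
            index="spectrum", columns="condition", values=metric, sort=False
        )[list(self.conditions)]
        return 100.0 * table if as_percent else table

    def condition_means(self, metric: str = "rmse", as_percent: bool = True) -> pd.Series:
        """Per-condition ensemble mean: average over spectra, then replicates."""
        per_rep = self.records.groupby(["condition", "replicate"], sort=False)[metric].mean()
        out = per_rep.groupby("condition", sort=False).mean()[list(self.conditions)]
        return 100.0 * out if as_percent else out

    def condition_spread(self, metric: str = "rmse", as_percent: bool = True) -> pd.Series:
        """Replicate-to-replicate standard deviation of the panel mean."""
        per_rep = self.records.groupby(["condition", "replicate"], sort=False)[metric].mean()
        out = per_rep.groupby("condition", sort=False).std()[list(self.conditions)]
        return 100.0 * out if as_percent else out


def sensitivity_conditions(config: RunConfig) -> list[tuple[str, RunConfig]]:
    """The default condition plus the ten single-parameter perturbations."""
    return [
        ("default", config),
        ("snr=1000", config.replace(snr=1000.0)),
        ("snr=10", config.replace(snr=10.0)),
        ("delta_t=10K", config.replace(delta_t=10.0)),
        ("delta_t=100K", config.replace(delta_t=100.0)),
        ("t_min=1950K", config.replace(t_min=1950.0)),
        ("t_min=2950K", config.replace(t_min=2950.0)),
        ("temp_error=10K", config.replace(temp_error_sd=10.0)),
        ("step=5nm", config.replace(grid_step=5.0)),
        ("step=20nm", config.replace(grid_step=20.0)),
        ("p=6", config.replace(p=6)),
    ]


def _panel_for(config: RunConfig, grid, panel):
    """Evaluate the panel on ``grid``: regenerate families, or interpolate
    user-supplied spectra measured on a different grid."""
    if panel is None:
        return [generate(f, grid) for f in default_panel_families(config.panel_seed)]
    out = []
    for spec in panel:
        if spec.grid == grid:
            out.append(spec)
        else:
            values = np.interp(grid.points, spec.grid.points, spec.values)
            out.append(ReflectanceSpectrum(grid=grid, values=values, name=spec.name))
    return out


def _run_condition(
    name: str,
    cfg: RunConfig,
    cond_index: int,
    master_seed: int,
    panel,
    bulb_filter: BulbFilter | None,
) -> list[dict]:
    grid = cfg.grid()
    temps = cfg.temperatures()
    illum = build_illumination_matrix(grid, temps, bulb_filter)
    qe = default_qe()
    bands = make_bands(cfg.grid_start, cfg.grid_stop, cfg.p)
    sens = [channel_sensitivity(qe, band, grid) for band in bands]
    system = assemble_system(illum, sens)
    reg = cfg.regularization()
    noise = NoiseModel(snr=cfg.snr, convention=cfg.noise_convention)
    spectra = _panel_for(cfg, grid, panel)

    records = []
    for spec_index, spec in enumerate(spectra):
        for rep in range(cfg.replicates):
            noise_rng = np.random.default_rng(
                np.random.SeedSequence(master_seed, spawn_key=(cond_index, spec_index, rep))
            )
            if cfg.temp_error_sd > 0:
                pert_rng = np.random.default_rng(
                    np.random.SeedSequence(master_seed, spawn_key=(cond_index, spec_index, rep, 1))
                )
                sim_illum = perturb_illumination(
                    illum, TemperaturePerturbation(cfg.temp_error_sd), rng=pert_rng
                )
                sim_system = assemble_system(sim_illum, sens)
            else:
                sim_system = system
            signals = simulate_signals(sim_system, spec, noise, rng=noise_rng)
            # reconstruction always uses the nominal system
            estimate = solve_reflectance(augment(system, signals, reg))
            report = compare(estimate, spec, floor=cfg.rrmse_floor)
            records.append(
                {
                    "condition": name,
                    "spectrum": spec.name or f"spectrum_{spec_index + 1}",
                    "replicate": rep,
                    "rmse": report.rmse,
                    "rrmse": report.rrmse,
                    "n_used": report.n_used,
                }
            )
    return records


def run_default(
    config: RunConfig | None = None,
    panel=None,
    bulb_filter: BulbFilter | None = None,
) -> SweepResult:
    """Simulate and reconstruct the panel under one configuration."""
    config = config or RunConfig()
    records = _run_condition("default", config, 0, config.master_seed, panel, bulb_filter)
    return SweepResult(records=pd.DataFrame(records), conditions=("default",))


def run_sensitivity(
    config: RunConfig | None = None,
    panel=None,
    bulb_filter: BulbFilter | None = None,
) -> SweepResult:
    """Run the full battery: baseline plus the ten perturbed conditions."""
    config = config or RunConfig()
    conditions = sensitivity_conditions(config)
    records: list[dict] = []
    for cond_index, (name, cfg) in enumerate(conditions):
        records.extend(
            _run_condition(name, cfg, cond_index, config.master_seed, panel, bulb_filter)
        )
    return SweepResult(
        records=pd.DataFrame(records), conditions=tuple(name for name, _ in conditions)
    )
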