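"""End-to-end runs: configuration, orchestration, outputs.

A run wires the stages together: load the injector table for the chosen
compound and driving pressure, build the calibrated jet, advance parcels
with drag, dispersion and TAB breakup, collect outlet crossings at the
measuring plane, and reduce the final analysis window (by default the
last 0.01 s of a 0.06 s transient, once the aerosol cone is developed)
to the cumulative mass curve Y_dg and the headline Da/MMAD/GSD summary.
Every artifact is a pure function of (configuration, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .breakup import TABConstants
from .flow_field import JetFlowConfig
from .injection import load_injection_table
from .lagrangian import SimulationResult, simulate
from .metrics import (
    AerosolSummary,
    SizeDistribution,
    cumulative_mass_distribution,
    geometric_to_aerodynamic,
    summarize,
)
from .particles import get_compound

__all__ = ["RunConfig", "RunResult", "run", "ydg_curve", "compare_distributions"]

_DEFAULT_DOMAIN = {"PFD": 0.060, "FC75": 0.052}


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one aerosol-transport run.

    Defaults mirror the study conditions: outlet plane at 60 mm (PFD) or
    52 mm (FC75) from the catheter tip, 1e-4 s time-steps, 500 parcels
    per step, 0.06 s of physical time with the final 0.01 s analyzed.
    """

    compound: str = "PFD"
    pressure: int = 4
    domain_length: float | None = None  # m; None -> compound default
    dt: float = 1.0e-4
    parcels_per_step: int = 500
    duration: float = 0.06
    analysis_window: float = 0.01
    seed: int = 0
    output_dir: str | None = None
    breakup_enabled: bool = True
    turbulence_enabled: bool = True
    injection_x: float = 0.002
    injection_line_length: float = 1.0e-4
    jet_overrides: dict = field(default_factory=dict)
    tab_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.duration <= 0:
            raise ValueError("dt and duration must be positive")
        if not 0 < self.analysis_window <= self.duration:
            raise ValueError("analysis_window must lie within the duration")

    @property
    def resolved_domain_length(self) -> float:
        if self.domain_length is not None:
            return self.domain_length
        return _DEFAULT_DOMAIN[self.compound.upper()]

    def jet_config(self) -> JetFlowConfig:
        return JetFlowConfig.for_pressure(
            self.pressure,
            domain_length=self.resolved_domain_length,
            **self.jet_overrides,
        )

    def tab_constants(self) -> TABConstants:
        return TABConstants(**self.tab_overrides)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Load a config from a YAML (or JSON) mapping."""
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ValueError("config file must contain a mapping")
        return cls(**data)


@dataclass
class RunResult:
    """Bundle of one run's outputs."""

    config: RunConfig
    sim: SimulationResult
    summary: AerosolSummary | None  # None if nothing reached the outlet
    ydg: pd.DataFrame  # columns diameter_um, cum_mass_fraction
    mass_balance_ratio: float  # outlet flux over injected flux, window-avg
    outlet_mass_flow: float  # kg/s over the analysis window
    injected_mass_flow: float  # kg/s


def ydg_curve(diameters_um, masses, n_points: int = 200) -> pd.DataFrame:
    """Cumulative mass distribution over droplet size as a table."""
    dist = SizeDistribution.from_particles(diameters_um, masses, n_bins=n_points)
    d, frac = cumulative_mass_distribution(dist)
    return pd.DataFrame({"diameter_um": d, "cum_mass_fraction": frac})


def run(config: RunConfig) -> RunResult:
    """Execute a full aerosol-transport run.

    Stages: injection -> transport -> breakup -> outlet collection ->
    metrics; optionally writes outlet records, the Y_dg curve, the
    summary and a mass-balance report under ``config.output_dir``.
    """
    table = load_injection_table(config.compound, config.pressure)
    props = get_compound(config.compound)
    jet = config.jet_config()
    sim = simulate(
        jet,
        table,
        config.duration,
        dt=config.dt,
        parcels_per_step=config.parcels_per_step,
        seed=config.seed,
        breakup_enabled=config.breakup_enabled,
        turbulence_enabled=config.turbulence_enabled,
        tab_constants=config.tab_constants(),
        props=props,
        injection_x=config.injection_x,
        injection_line_length=config.injection_line_length,
    )

    t0 = config.duration - config.analysis_window
    window = sim.outlet[sim.outlet["time_s"] >= t0]
    injected_flow = table.total_mass_flow
    outlet_flow = float(window["mass_kg"].sum()) / config.analysis_window
    ratio = outlet_flow / injected_flow if injected_flow > 0 else float("nan")

    if len(window):
        dg = window["diameter_um"].to_numpy()
        m = window["mass_kg"].to_numpy()
        da = geometric_to_aerodynamic(dg, props.liquid_density / 1000.0)
        summary = summarize(da, masses=m, counts=window["droplet_count"].to_numpy())
        ydg = ydg_curve(dg, m)
    else:
        summary = None
        ydg = pd.DataFrame(columns=["diameter_um", "cum_mass_fraction"])

    result = RunResult(
        config=config,
        sim=sim,
        summary=summary,
        ydg=ydg,
        mass_balance_ratio=ratio,
        outlet_mass_flow=outlet_flow,
        injected_mass_flow=injected_flow,
    )
    if config.output_dir is not None:
        _write_outputs(result)
    return result


def _write_outputs(result: RunResult) -> None:
    out = Path(result.config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.sim.outlet.to_csv(out / "outlet_records.csv", index=False)
    result.ydg.to_csv(out / "ydg_curve.csv", index=False)
    report = {
        "mass_balance_ratio": result.mass_balance_ratio,
        "outlet_mass_flow_kg_s": result.outlet_mass_flow,
        "injected_mass_flow_kg_s": result.injected_mass_flow,
        "injected_mass_kg": result.sim.injected_mass,
        "outlet_mass_kg": result.sim.outlet_mass,
        "lost_upstream_mass_kg": result.sim.lost_upstream_mass,
        "lost_side_mass_kg": result.sim.lost_side_mass,
        "active_mass_end_kg": result.sim.active_mass_end,
        "max_weber": result.sim.max_weber,
        "momentum_to_gas_kg_m_s": result.sim.momentum_to_gas,
        "n_breakup_events": result.sim.n_breakup_events,
    }
    with open(out / "mass_balance.json", "w") as fh:
        json.dump(report, fh, indent=2)
    if result.summary is not None:
        with open(out / "summary.json", "w") as fh:
            json.dump(
                {
                    "Da_um": result.summary.Da,
                    "MMAD_um": result.summary.MMAD,
                    "GSD": result.summary.GSD,
                    "heterodisperse": result.summary.heterodisperse,
                },
                fh,
                indent=2,
            )
    with open(out / "run.log", "w") as fh:
        fh.write(f"seed={result.config.seed}\n")
        fh.write(f"config_hash={result.config.config_hash()}\n")
        fh.write(json.dumps(dataclasses.asdict(result.config), default=str) + "\n")


def _as_curve(curve):
    if isinstance(curve, pd.DataFrame):
        d = curve["diameter_um"].to_numpy(dtype=float)
        f = curve["cum_mass_fraction"].to_numpy(dtype=float)
    else:
        d, f = (np.asarray(a, dtype=float) for a in curve)
    if np.any(np.diff(f) < -1e-12) or f[-1] > 1 + 1e-9 or not np.isclose(f[-1], 1.0, atol=1e-6):
        raise ValueError("curve must be a normalized non-decreasing CDF ending at 1")
    return d, f


def compare_distributions(simulated, reference, cut_points_um=(3.0, 5.0, 10.0)) -> dict:
    """Deviation metrics between two cumulative mass curves.

    Returns the maximum absolute deviation over the union grid and, for
    each cut diameter, the difference in the mass fraction carried by
    particles above it (simulated minus reference).
    """
    d_s, f_s = _as_curve(simulated)
    d_r, f_r = _as_curve(reference)
    grid = np.union1d(d_s, d_r)
    fs = np.interp(grid, d_s, f_s, left=0.0, right=1.0)
    fr = np.interp(grid, d_r, f_r, left=0.0, right=1.0)
    out = {"max_abs_deviation": float(np.max(np.abs(fs - fr)))}
    for c in cut_points_um:
        above_s = 1.0 - float(np.interp(c, d_s, f_s, left=0.0, right=1.0))
        above_r = 1.0 - float(np.interp(c, d_r, f_r, left=0.0, right=1.0))
        out[f"mass_fraction_above_{c:g}um_diff"] = above_s - above_r
    return out
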