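"""Discrete-phase source: the ten-injector tables and parcel emission.

The experimentally measured droplet population at the injection plane is
discretized into ten injectors spread uniformly along an injection line
(length = the central-lumen radius) 2 mm downstream of the catheter tip.
Each injector carries a geometric diameter and a liquid mass flow; the
packaged tables reproduce the measured initial conditions for both
compounds (PFD, FC75) at both driving pressures (4, 5 bar) verbatim, and
an arbitrary aerodynamic-sizer histogram can be rebinned onto any number
of injectors mass-conservatively.

Emission is exactly mass-balanced every time-step: parcels are allocated
to injectors proportionally to mass flow (largest-remainder rounding,
with every active injector guaranteed at least one parcel), and droplet
counts per parcel are chosen so the emitted mass equals
``total_mass_flow * dt`` identically.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .particles import CompoundProperties, Parcel, get_compound

__all__ = [
    "InjectionSpec",
    "InjectionTable",
    "load_injection_table",
    "rebin_aps_to_injections",
    "allocate_parcels",
    "emit_parcel_arrays",
    "emit_parcels",
]


@dataclass(frozen=True)
class InjectionSpec:
    """One injector: droplet geometric diameter and liquid mass flow."""

    Dg_um: float  # geometric diameter, micrometres
    mass_flow: float  # kg/s

    def __post_init__(self) -> None:
        if self.Dg_um <= 0:
            raise ValueError("geometric diameter must be positive")
        if self.mass_flow < 0:
            raise ValueError("mass flow must be non-negative")

    @property
    def diameter_m(self) -> float:
        return self.Dg_um * 1e-6


@dataclass(frozen=True)
class InjectionTable:
    """A set of injectors for one compound / driving-pressure case."""

    compound: str
    pressure: int  # bar
    specs: tuple[InjectionSpec, ...]

    @property
    def total_mass_flow(self) -> float:
        """Sum of the per-injector mass flows [kg/s]."""
        return float(sum(s.mass_flow for s in self.specs))

    @property
    def diameters_m(self) -> np.ndarray:
        return np.array([s.diameter_m for s in self.specs])

    @property
    def mass_flows(self) -> np.ndarray:
        return np.array([s.mass_flow for s in self.specs])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "injection_index": np.arange(1, len(self.specs) + 1),
                "Dg_um": [s.Dg_um for s in self.specs],
                "mass_flow_kg_s": [s.mass_flow for s in self.specs],
            }
        )


_VALID_CASES = {("PFD", 4), ("PFD", 5), ("FC75", 4), ("FC75", 5)}


def load_injection_table(compound: str, pressure: int) -> InjectionTable:
    """Load the packaged measured injector table for one case.

    ``compound`` is ``"PFD"`` or ``"FC75"``; ``pressure`` is 4 or 5 bar.
    """
    key = (str(compound).upper(), int(pressure))
    if key not in _VALID_CASES:
        raise ValueError(
            f"no injection table for {compound!r} at {pressure} bar; "
            f"valid options: {sorted(_VALID_CASES)}"
        )
    fname = f"injectors_{key[0].lower()}_{key[1]}bar.csv"
    with resources.files("aerocath").joinpath("data", fname).open("r") as fh:
        df = pd.read_csv(fh)
    specs = tuple(
        InjectionSpec(float(row.Dg_um), float(row.mass_flow_kg_s))
        for row in df.itertuples()
    )
    return InjectionTable(compound=key[0], pressure=key[1], specs=specs)


def rebin_aps_to_injections(
    aps_sample,
    n_injections: int,
    *,
    compound: str = "PFD",
    pressure: int = 4,
    total_mass_flow: float | None = None,
) -> InjectionTable:
    """Rebin a sizer histogram onto ``n_injections`` injectors.

    ``aps_sample`` is anything with ``bin_edges`` (µm, ascending) and
    ``mass_per_bin`` attributes.  Mass is redistributed in log-diameter
    with exact conservation: each source bin's mass is split across the
    target bins in proportion to log-overlap.  The representative
    diameter of a target bin is the mass-weighted geometric mean of the
    contributing source-bin centers.  If ``total_mass_flow`` is given the
    injector flows are scaled to sum to it; otherwise the histogram
    masses are used as flows directly.
    """
    edges = np.asarray(aps_sample.bin_edges, dtype=float)
    mass = np.asarray(aps_sample.mass_per_bin, dtype=float)
    if mass.sum() <= 0:
        raise ValueError("sample has no mass")
    if n_injections < 1:
        raise ValueError("n_injections must be at least 1")

    occupied = np.nonzero(mass > 0)[0]
    lo, hi = edges[0], edges[-1]
    tgt = np.exp(np.linspace(np.log(lo), np.log(hi), n_injections + 1))

    log_src_lo, log_src_hi = np.log(edges[:-1]), np.log(edges[1:])
    log_tgt_lo, log_tgt_hi = np.log(tgt[:-1]), np.log(tgt[1:])
    src_w = log_src_hi - log_src_lo

    tgt_mass = np.zeros(n_injections)
    tgt_logd = np.zeros(n_injections)  # mass-weighted sum of log-diameters
    for j in range(n_injections):
        ov_lo = np.maximum(log_src_lo, log_tgt_lo[j])
        ov_hi = np.minimum(log_src_hi, log_tgt_hi[j])
        frac = np.clip(ov_hi - ov_lo, 0.0, None) / src_w
        if j == n_injections - 1:  # closed upper edge
            frac[occupied[-1]] = max(frac[occupied[-1]], (log_src_hi[occupied[-1]] - np.maximum(log_src_lo[occupied[-1]], log_tgt_lo[j])) / src_w[occupied[-1]])
        m = frac * mass
        tgt_mass[j] = m.sum()
        center = 0.5 * (np.clip(ov_lo, log_src_lo, log_src_hi) + np.clip(ov_hi, log_src_lo, log_src_hi))
        tgt_logd[j] = float(np.sum(m * center))

    # Exact conservation: rescale for floating drift.
    tgt_mass *= mass.sum() / tgt_mass.sum()

    keep = tgt_mass > 0
    rep_d = np.exp(tgt_logd[keep] / tgt_mass[keep])
    flows = tgt_mass[keep]
    if total_mass_flow is not None:
        flows = flows / flows.sum() * total_mass_flow
    specs = tuple(InjectionSpec(float(d), float(f)) for d, f in zip(rep_d, flows))
    return InjectionTable(compound=str(compound).upper(), pressure=int(pressure), specs=specs)


def allocate_parcels(mass_flows: np.ndarray, parcels_per_step: int) -> np.ndarray:
    """Allocate parcels to injectors proportionally to mass flow.

    Every injector with positive flow receives at least one parcel; the
    remainder is distributed by largest-remainder rounding of the
    proportional quotas.
    """
    flows = np.asarray(mass_flows, dtype=float)
    active = flows > 0
    n_active = int(active.sum())
    if parcels_per_step < n_active:
        raise ValueError(
            f"parcels_per_step ({parcels_per_step}) must be at least the "
            f"number of active injectors ({n_active})"
        )
    alloc = np.zeros(len(flows), dtype=int)
    alloc[active] = 1
    rest = parcels_per_step - n_active
    if rest > 0 and n_active > 0:
        quota = rest * flows / flows.sum()
        base = np.floor(quota).astype(int)
        base[~active] = 0
        short = rest - base.sum()
        rem = np.where(active, quota - np.floor(quota), -1.0)
        order = np.argsort(-rem, kind="stable")
        base[order[:short]] += 1
        alloc += base
    return alloc


def emit_parcel_arrays(
    table: InjectionTable,
    parcels_per_step: int,
    dt: float,
    rng: np.random.Generator,
    jet=None,
    *,
    injection_x: float = 0.002,
    line_length: float = 1.0e-4,
    props: CompoundProperties | None = None,
):
    """Emit one time-step's parcels as arrays ``(pos, vel, diameter, count)``.

    Parcels sit on the injection plane ``x = injection_x`` at radii drawn
    uniformly along the injection line (random azimuth), moving with the
    local gas velocity.  Per-injector emitted mass is exactly
    ``mass_flow * dt``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if props is None:
        props = get_compound(table.compound)
    flows = table.mass_flows
    diams = table.diameters_m
    alloc = allocate_parcels(flows, parcels_per_step)

    idx = np.repeat(np.arange(len(flows)), alloc)
    n = len(idx)
    d = diams[idx]
    parcel_mass = (flows * dt / np.maximum(alloc, 1))[idx]
    count = parcel_mass / props.droplet_mass(d)

    r = rng.uniform(0.0, line_length, size=n)
    phi = rng.uniform(0.0, 2.0 * np.pi, size=n)
    pos = np.empty((n, 3))
    pos[:, 0] = injection_x
    pos[:, 1] = r * np.cos(phi)
    pos[:, 2] = r * np.sin(phi)

    vel = np.zeros((n, 3))
    if jet is not None:
        from .flow_field import sample_flow_arrays

        u_ax, u_rad, _, _ = sample_flow_arrays(np.full(n, injection_x), r, jet)
        vel[:, 0] = u_ax
        with np.errstate(invalid="ignore"):
            inv_r = np.where(r > 0, 1.0 / np.where(r > 0, r, 1.0), 0.0)
        vel[:, 1] = u_rad * pos[:, 1] * inv_r
        vel[:, 2] = u_rad * pos[:, 2] * inv_r
    return pos, vel, d, count


def emit_parcels(
    table: InjectionTable,
    parcels_per_step: int,
    dt: float,
    rng: np.random.Generator,
    jet=None,
    *,
    injection_x: float = 0.002,
    line_length: float = 1.0e-4,
    props: CompoundProperties | None = None,
) -> list[Parcel]:
    """Emit one time-step's parcels as :class:`Parcel` objects."""
    pos, vel, d, count = emit_parcel_arrays(
        table, parcels_per_step, dt, rng, jet,
        injection_x=injection_x, line_length=line_length, props=props,
    )
    return [
        Parcel(pos[i], vel[i], float(d[i]), float(count[i]), table.compound)
        for i in range(len(d))
    ]
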