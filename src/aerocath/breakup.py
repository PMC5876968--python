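"""Taylor-analogy secondary breakup (TAB).

A distorting droplet is modelled as a forced, damped spring-mass system
in its fundamental oscillation mode: aerodynamic pressure forces the
distortion, surface tension restores it, liquid viscosity damps it.  In
the normalized distortion variable ``y`` (surface displacement over
``C_b r``) the dynamics are

    y'' = (C_F/C_b) rho_g u^2 / (rho_l r^2)
        - (C_k sigma / (rho_l r^3)) y
        - (C_d mu_l / (rho_l r^2)) y'

Because the forcing is piecewise-constant over a time-step, the update
uses the exact solution of the oscillator (underdamped, overdamped and
undamped branches), not numerical integration.  When ``y`` exceeds the
critical value 1 the parent droplet is replaced by child droplets whose
Sauter mean diameter follows the TAB surface/oscillation energy balance
and whose sizes are drawn from a Rosin-Rammler distribution truncated at
the parent diameter.  Breakup conserves liquid mass exactly.

The model is a low-Weber-number one; the driving group is the Weber
number ``We = rho_g u_rel^2 Dp / sigma``, and simulations track its
maximum as a validity diagnostic (the regime of interest stays below
We = 100).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gamma as _gamma

from .particles import CompoundProperties, Parcel

__all__ = [
    "TABConstants",
    "weber_number",
    "tab_update_arrays",
    "advance_distortion",
    "child_sauter_diameter",
    "sample_child_diameters",
    "breakup",
]


@dataclass(frozen=True)
class TABConstants:
    """Canonical TAB model constants plus child-sizing controls.

    ``C_b, C_k, C_d, C_F`` and the energy-balance factor ``K_energy`` are
    the standard values of the original formulation; ``child_spread_q``
    is the Rosin-Rammler exponent for child sizes and ``max_children``
    caps the number of child parcels created per breakup event.
    """

    C_b: float = 0.5
    C_k: float = 8.0
    C_d: float = 5.0
    C_F: float = 1.0 / 3.0
    K_energy: float = 10.0 / 3.0
    child_spread_q: float = 3.5
    critical_y: float = 1.0
    max_children: int = 10

    def __post_init__(self) -> None:
        for name in ("C_b", "C_k", "C_d", "C_F", "K_energy", "child_spread_q"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def weber_number(gas_density, u_rel, Dp, surface_tension):
    """Droplet Weber number ``We = rho_g u_rel^2 Dp / sigma``."""
    sigma = np.asarray(surface_tension, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("surface tension must be positive")
    Dp = np.asarray(Dp, dtype=float)
    if np.any(Dp <= 0):
        raise ValueError("droplet diameter must be positive")
    we = np.asarray(gas_density, dtype=float) * np.asarray(u_rel, dtype=float) ** 2 * Dp / sigma
    return float(we) if we.ndim == 0 else we


def tab_update_arrays(
    y,
    ydot,
    u_rel,
    diameter,
    gas_density,
    props: CompoundProperties,
    consts: TABConstants,
    dt: float,
):
    """Advance distortion state over ``dt`` by the exact oscillator solution.

    All arguments broadcast; returns ``(y_new, ydot_new)``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    y = np.asarray(y, dtype=float)
    ydot = np.asarray(ydot, dtype=float)
    u_rel = np.asarray(u_rel, dtype=float)
    r = np.asarray(diameter, dtype=float) / 2.0
    rho_l = props.liquid_density

    omega0_sq = consts.C_k * props.surface_tension / (rho_l * r**3)
    inv_td = consts.C_d * props.liquid_viscosity / (2.0 * rho_l * r**2)
    # Steady-state distortion under the current forcing.
    y_eq = (
        consts.C_F
        / (consts.C_b * consts.C_k)
        * np.asarray(gas_density, dtype=float)
        * u_rel**2
        * r
        / props.surface_tension
    )

    disc = omega0_sq - inv_td**2
    A = y - y_eq
    decay = np.exp(-inv_td * dt)

    # Underdamped branch (trig) and overdamped branch (hyperbolic) share
    # the same algebra with omega -> i*nu; evaluate both where valid.
    omega = np.sqrt(np.maximum(disc, 0.0))
    nu = np.sqrt(np.maximum(-disc, 0.0))
    under = disc > 0

    with np.errstate(invalid="ignore", divide="ignore"):
        B_u = np.where(omega > 0, (ydot + A * inv_td) / np.where(omega > 0, omega, 1.0), 0.0)
        c, s = np.cos(omega * dt), np.sin(omega * dt)
        y_u = y_eq + decay * (A * c + B_u * s)
        yd_u = decay * ((-A * inv_td + B_u * omega) * c + (-B_u * inv_td - A * omega) * s)

        # Overdamped branch in stable exponential form: both rates are
        # non-positive, so neither exponential can overflow.
        lam_p = -inv_td + nu
        lam_m = -inv_td - nu
        C_p = np.where(nu > 0, (ydot - lam_m * A) / np.where(nu > 0, 2.0 * nu, 1.0), 0.0)
        C_m = A - C_p
        e_p, e_m = np.exp(lam_p * dt), np.exp(lam_m * dt)
        y_o = y_eq + C_p * e_p + C_m * e_m
        yd_o = C_p * lam_p * e_p + C_m * lam_m * e_m

    # Critically damped limit (measure-zero): linear-in-t exact solution.
    crit = disc == 0
    if np.any(crit):
        y_c = y_eq + decay * (A + (ydot + A * inv_td) * dt)
        yd_c = decay * (ydot - (ydot + A * inv_td) * inv_td * dt)
        y_o = np.where(crit, y_c, y_o)
        yd_o = np.where(crit, yd_c, yd_o)

    y_new = np.where(under, y_u, y_o)
    ydot_new = np.where(under, yd_u, yd_o)
    return y_new, ydot_new


def advance_distortion(
    parcel: Parcel,
    flow,
    props: CompoundProperties,
    consts: TABConstants,
    dt: float,
) -> Parcel:
    """Advance a single parcel's TAB state against the local gas flow.

    The relative speed is taken from the mean flow sample; breakup is
    indicated by the returned parcel having ``tab_y`` above the critical
    value.
    """
    gas_vel = np.array([flow.axial_velocity, flow.radial_velocity, 0.0])
    # Parcel radial direction maps the axisymmetric sample into 3-D.
    rr = parcel.radial_position
    if rr > 0:
        e_r = np.array([0.0, parcel.position[1] / rr, parcel.position[2] / rr])
        gas3 = np.array([flow.axial_velocity, 0.0, 0.0]) + flow.radial_velocity * e_r
    else:
        gas3 = np.array([flow.axial_velocity, 0.0, 0.0])
    u_rel = float(np.linalg.norm(parcel.velocity - gas3))
    y, ydot = tab_update_arrays(
        parcel.tab_y,
        parcel.tab_ydot,
        u_rel,
        parcel.diameter,
        flow.gas_density,
        props,
        consts,
        dt,
    )
    return Parcel(
        position=parcel.position.copy(),
        velocity=parcel.velocity.copy(),
        diameter=parcel.diameter,
        droplets_per_parcel=parcel.droplets_per_parcel,
        compound=parcel.compound,
        tab_y=float(y),
        tab_ydot=float(ydot),
        active=parcel.active,
    )


def child_sauter_diameter(
    diameter,
    tab_y,
    tab_ydot,
    props: CompoundProperties,
    consts: TABConstants,
):
    """Sauter mean diameter of child droplets from the TAB energy balance.

    r_parent / r32 = 1 + 8 K y^2 / 20
                   + rho_l r^3 ydot^2 / sigma * (6 K - 5) / 120
    """
    r = np.asarray(diameter, dtype=float) / 2.0
    K = consts.K_energy
    ratio = (
        1.0
        + 8.0 * K * np.asarray(tab_y, dtype=float) ** 2 / 20.0
        + props.liquid_density
        * r**3
        * np.asarray(tab_ydot, dtype=float) ** 2
        / props.surface_tension
        * (6.0 * K - 5.0)
        / 120.0
    )
    return 2.0 * r / ratio


def rosin_rammler_cdf(d, scale, q):
    """Mass-fraction CDF of the Rosin-Rammler law, ``1 - exp(-(d/X)^q)``."""
    d = np.asarray(d, dtype=float)
    return 1.0 - np.exp(-((d / scale) ** q))


def _rr_scale_from_sauter(d32, q):
    # For a Rosin-Rammler mass distribution, d32 = X / Gamma(1 - 1/q).
    return np.asarray(d32, dtype=float) * _gamma(1.0 - 1.0 / q)


def sample_child_diameters(
    n: int,
    d32: float,
    parent_diameter: float,
    q: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw child diameters from a Rosin-Rammler mass distribution.

    Inverse-CDF sampling truncated at the parent diameter so every child
    is strictly smaller than its parent.
    """
    scale = float(_rr_scale_from_sauter(d32, q))
    u_max = float(rosin_rammler_cdf(parent_diameter, scale, q))
    u = rng.uniform(0.0, u_max, size=n)
    d = scale * (-np.log1p(-u)) ** (1.0 / q)
    # Guard the open upper end against floating round-up.
    return np.minimum(d, np.nextafter(parent_diameter, 0.0))


def breakup(
    parent: Parcel,
    props: CompoundProperties,
    consts: TABConstants,
    rng: np.random.Generator,
) -> list[Parcel]:
    """Replace a critically distorted parent parcel with child parcels.

    Each child parcel receives an equal share of the parent's liquid
    mass; its droplet count is set from its own sampled diameter so the
    total child mass equals the parent mass to machine precision.  Child
    distortion state is reset to rest.
    """
    if parent.tab_y <= consts.critical_y:
        raise ValueError("parcel is not flagged for breakup (tab_y <= critical)")
    d32 = float(
        child_sauter_diameter(parent.diameter, parent.tab_y, parent.tab_ydot, props, consts)
    )
    n = int(np.clip(round((parent.diameter / d32) ** 3), 2, consts.max_children))
    diam = sample_child_diameters(n, d32, parent.diameter, consts.child_spread_q, rng)
    parent_mass = parent.mass(props)
    share = parent_mass / n
    counts = share / props.droplet_mass(diam)
    return [
        Parcel(
            position=parent.position.copy(),
            velocity=parent.velocity.copy(),
            diameter=float(diam[i]),
            droplets_per_parcel=float(counts[i]),
            compound=parent.compound,
            tab_y=0.0,
            tab_ydot=0.0,
        )
        for i in range(n)
    ]
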