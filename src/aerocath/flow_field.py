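"""Surrogate continuous phase: a calibrated axisymmetric turbulent round jet.

The carrier air flow is not solved here.  The catheter discharges a
high-speed annular air jet; downstream of the tip it behaves like a
turbulent round jet, for which the self-similar description is standard:
a potential core of constant centerline velocity followed by 1/x decay,
a Gaussian radial profile with linear spreading, and the radial velocity
required by continuity (outward motion near the axis, entrainment inflow
far from it).  The free parameter — the core velocity — is calibrated so
the centerline value at the droplet-injection plane (x = 2 mm) equals the
measured injector-plane velocity: 247 m/s at 4 bar and 293 m/s at 5 bar
of driving pressure.

Turbulence quantities feed the stochastic droplet dispersion model:
turbulent kinetic energy ``k`` from a local-intensity profile and the
dissipation rate from ``epsilon = C_mu^(1/2) k^(3/2) / l_eps`` with the
dissipation length ``l_eps = 0.07 L`` (L = width of the annular air ring,
the duct dimension of the fully developed feed flow) and C_mu = 0.09.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "JetFlowConfig",
    "FlowSample",
    "dissipation_length_scale",
    "turbulent_dissipation",
    "sample_flow",
    "sample_flow_arrays",
]

#: (injector-plane centerline velocity m/s, air mass flow kg/s) per driving
#: pressure in bar.
_PRESSURE_PRESETS = {
    4: (247.0, 1.1344e-5),
    5: (293.0, 1.14766e-5),
}


@dataclass(frozen=True)
class JetFlowConfig:
    """Configuration of the surrogate jet.

    Parameters
    ----------
    driving_pressure : int
        Compressed-air driving pressure in bar; presets exist for 4 and 5.
    injector_plane_velocity : float
        Centerline axial velocity at the calibration plane [m/s].
    air_mass_flow : float
        Air mass flow through the annular ring [kg/s]; bookkeeping value,
        the kinematics are set by the calibrated velocity.
    annulus_width_L : float
        Width of the equivalent annular air ring [m]; only the
        dissipation length scale depends on it.  The catheter lumen
        geometry is not publicly specified, so this is a free parameter.
    core_length : float
        Potential-core length [m]; centerline velocity is constant up to
        here, then decays as 1/x.
    spreading_sigma : float
        Gaussian half-width growth rate d(sigma)/dx; 0.075 reproduces the
        classic round-jet half-velocity spreading rate r_1/2 ~ 0.09 x.
    calibration_x : float
        Axial position of the injector plane used for calibration [m].
    turbulence_intensity : float
        Local turbulence intensity u'/u used to build k.
    """

    driving_pressure: int = 4
    injector_plane_velocity: float = 247.0  # m/s
    air_mass_flow: float = 1.1344e-5  # kg/s
    annulus_width_L: float = 1.0e-4  # m
    gas_density: float = 1.204  # kg/m^3, air at 20 C
    gas_viscosity: float = 1.81e-5  # Pa s
    C_mu: float = 0.09
    turbulence_intensity: float = 0.10
    domain_length: float = 0.060  # m
    core_length: float = 0.002  # m
    spreading_sigma: float = 0.075
    calibration_x: float = 0.002  # m

    def __post_init__(self) -> None:
        for name in (
            "injector_plane_velocity",
            "air_mass_flow",
            "annulus_width_L",
            "gas_density",
            "gas_viscosity",
            "C_mu",
            "turbulence_intensity",
            "domain_length",
            "core_length",
            "spreading_sigma",
            "calibration_x",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def for_pressure(cls, pressure: int, **overrides) -> "JetFlowConfig":
        """Build a config from the 4 or 5 bar preset, with overrides."""
        try:
            v, mdot = _PRESSURE_PRESETS[int(pressure)]
        except (KeyError, ValueError):
            raise ValueError(
                f"no preset for driving pressure {pressure!r}; "
                f"valid options: {sorted(_PRESSURE_PRESETS)}"
            ) from None
        cfg = cls(
            driving_pressure=int(pressure),
            injector_plane_velocity=v,
            air_mass_flow=mdot,
        )
        return replace(cfg, **overrides) if overrides else cfg

    @property
    def core_velocity(self) -> float:
        """Centerline velocity in the potential core, from calibration."""
        if self.core_length >= self.calibration_x:
            return self.injector_plane_velocity
        return self.injector_plane_velocity * self.calibration_x / self.core_length

    @property
    def l_eps(self) -> float:
        return dissipation_length_scale(self.annulus_width_L)


@dataclass(frozen=True)
class FlowSample:
    """Local gas state seen by a droplet."""

    axial_velocity: float  # m/s
    radial_velocity: float  # m/s
    k: float  # m^2/s^2
    epsilon: float  # m^2/s^3
    gas_density: float  # kg/m^3

    def __post_init__(self) -> None:
        if self.k < 0 or self.epsilon < 0:
            raise ValueError("k and epsilon must be non-negative")
        if self.gas_density <= 0:
            raise ValueError("gas_density must be positive")


def dissipation_length_scale(annulus_width_L: float) -> float:
    """Dissipation length scale of the fully developed annular feed flow.

    ``l_eps = 0.07 L`` with L the width of the air ring.
    """
    if annulus_width_L <= 0:
        raise ValueError("annulus width must be positive")
    return 0.07 * annulus_width_L


def turbulent_dissipation(k, l_eps: float, C_mu: float = 0.09):
    """Turbulent dissipation rate from k and the dissipation length.

    ``epsilon = C_mu^(1/2) k^(3/2) / l_eps``.
    """
    k = np.asarray(k, dtype=float)
    if np.any(k < 0):
        raise ValueError("k must be non-negative")
    if l_eps <= 0:
        raise ValueError("l_eps must be positive")
    eps = np.sqrt(C_mu) * k**1.5 / l_eps
    return float(eps) if eps.ndim == 0 else eps


def _centerline(x, cfg: JetFlowConfig):
    u0 = cfg.core_velocity
    xc = cfg.core_length
    return np.where(x <= xc, u0, u0 * xc / np.maximum(x, xc))


def sample_flow_arrays(x, r, cfg: JetFlowConfig):
    """Vectorized field lookup.

    Returns ``(axial_velocity, radial_velocity, k, epsilon)`` arrays for
    axial positions ``x`` and radial distances ``r`` (any broadcastable
    shapes).  Raises for coordinates outside the axisymmetric domain.
    """
    x = np.asarray(x, dtype=float)
    r = np.asarray(r, dtype=float)
    if np.any(x < 0) or np.any(x > cfg.domain_length):
        raise ValueError("axial coordinate outside [0, domain_length]")
    if np.any(r < 0):
        raise ValueError("radial coordinate must be non-negative")

    uc = _centerline(x, cfg)
    sigma = cfg.spreading_sigma * np.maximum(x, cfg.core_length)
    eta = r / sigma
    gauss = np.exp(-0.5 * eta**2)
    u_ax = uc * gauss

    # Radial velocity from continuity for the Gaussian self-similar jet:
    # v = -uc * (S/eta) * [1 - (1 + eta^2) exp(-eta^2/2)], with the small-eta
    # limit v -> +uc * S * eta / 2 (outward near the axis, entrainment
    # inflow at large eta).  Zero inside the potential core, where the
    # centerline velocity and width are constant.
    S = cfg.spreading_sigma
    small = eta < 1e-4
    eta_safe = np.where(small, 1.0, eta)
    v_sim = -uc * (S / eta_safe) * (1.0 - (1.0 + eta**2) * gauss)
    v_sim = np.where(small, 0.5 * uc * S * eta, v_sim)
    u_rad = np.where(x <= cfg.core_length, 0.0, v_sim)

    k = 1.5 * (cfg.turbulence_intensity * u_ax) ** 2
    eps = np.sqrt(cfg.C_mu) * k**1.5 / cfg.l_eps
    return u_ax, u_rad, k, eps


def sample_flow(x: float, r: float, cfg: JetFlowConfig) -> FlowSample:
    """Gas state at axial position ``x`` and radial distance ``r``."""
    u_ax, u_rad, k, eps = sample_flow_arrays(x, r, cfg)
    return FlowSample(
        axial_velocity=float(u_ax),
        radial_velocity=float(u_rad),
        k=float(k),
        epsilon=float(eps),
        gas_density=cfg.gas_density,
    )
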