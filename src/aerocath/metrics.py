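"""Aerosol sizing statistics.

Conventions follow aerodynamic particle sizing practice:

* aerodynamic diameter ``Da`` — diameter of a unit-density sphere with
  the particle's settling velocity; related to the geometric (physical)
  diameter by ``Dg = Da sqrt(rho_0 / rho)`` with ``rho_0 = 1 g/cm^3``;
* MMAD — diameter below which half of the aerosol *mass* lies, read off
  the cumulative mass curve with log-linear interpolation;
* GSD — ``sqrt(d_84.1 / d_15.9)`` on mass-weighted quantile diameters
  (for an exactly lognormal aerosol this equals ``exp(sd of ln d)``);
  a GSD above 1.25 marks a heterodisperse aerosol;
* aerosolization rate — liquid volume aerosolized per minute, from the
  liquid-chamber mass loss over a pulse;
* the sizer classifies particles into four events: (1) below 0.5 µm,
  (2) in the 0.5-20 µm measuring range, (3) coincident (two particles in
  the beams at once), (4) above 20 µm.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

__all__ = [
    "SizeDistribution",
    "AerosolSummary",
    "aerodynamic_to_geometric",
    "geometric_to_aerodynamic",
    "cumulative_mass_distribution",
    "quantile_diameter",
    "mass_quantile_from_particles",
    "mmad",
    "gsd",
    "HETERODISPERSE_GSD",
    "aerosolization_rate",
    "EventCounts",
    "classify_aps_events",
]

#: GSD above this marks particles of appreciably different sizes.
HETERODISPERSE_GSD = 1.25


@dataclass(frozen=True)
class SizeDistribution:
    """Mass binned over diameter.

    ``bin_edges`` are in µm, strictly ascending, length ``n_bins + 1``;
    ``mass_per_bin`` may be absolute (kg) or normalized fractions.
    """

    bin_edges: np.ndarray
    mass_per_bin: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "bin_edges", np.asarray(self.bin_edges, dtype=float))
        object.__setattr__(self, "mass_per_bin", np.asarray(self.mass_per_bin, dtype=float))
        if len(self.bin_edges) != len(self.mass_per_bin) + 1:
            raise ValueError("need len(bin_edges) == len(mass_per_bin) + 1")
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if np.any(self.mass_per_bin < 0):
            raise ValueError("bin masses must be non-negative")

    @classmethod
    def from_particles(
        cls,
        diameters_um,
        masses,
        n_bins: int = 52,
        limits: tuple[float, float] | None = None,
    ) -> "SizeDistribution":
        """Bin particle masses into logarithmically spaced bins."""
        d = np.asarray(diameters_um, dtype=float)
        m = np.asarray(masses, dtype=float)
        if limits is None:
            lo, hi = d.min(), d.max()
            if lo == hi:
                lo, hi = lo * 0.999, hi * 1.001
        else:
            lo, hi = limits
        edges = np.exp(np.linspace(np.log(lo), np.log(hi), n_bins + 1))
        mass, _ = np.histogram(np.clip(d, lo, hi), bins=edges, weights=m)
        return cls(edges, mass)

    @property
    def total_mass(self) -> float:
        return float(self.mass_per_bin.sum())


@dataclass(frozen=True)
class AerosolSummary:
    """Headline statistics of one aerosol sample."""

    Da: float  # mean aerodynamic diameter, µm
    MMAD: float  # mass median aerodynamic diameter, µm
    GSD: float

    @property
    def heterodisperse(self) -> bool:
        return self.GSD > HETERODISPERSE_GSD


def aerodynamic_to_geometric(Da, liquid_density: float, unit_density: float = 1.0):
    """Geometric diameter from aerodynamic: ``Dg = Da sqrt(rho_0/rho)``.

    Densities in g/cm^3 (any unit, only the ratio matters).
    """
    if liquid_density <= 0 or unit_density <= 0:
        raise ValueError("densities must be positive")
    out = np.asarray(Da, dtype=float) * np.sqrt(unit_density / liquid_density)
    return float(out) if out.ndim == 0 else out


def geometric_to_aerodynamic(Dg, liquid_density: float, unit_density: float = 1.0):
    """Inverse of :func:`aerodynamic_to_geometric`."""
    if liquid_density <= 0 or unit_density <= 0:
        raise ValueError("densities must be positive")
    out = np.asarray(Dg, dtype=float) * np.sqrt(liquid_density / unit_density)
    return float(out) if out.ndim == 0 else out


def cumulative_mass_distribution(dist: SizeDistribution):
    """Normalized cumulative mass curve ``Y(d)``.

    Returns ``(diameters, fraction)`` arrays over the bin edges; the
    curve rises from 0 to 1 and is evaluated between edges by
    interpolation (linear in log-diameter, matching :func:`mmad`).
    """
    total = dist.total_mass
    if total <= 0:
        raise ValueError("total mass must be positive")
    frac = np.concatenate([[0.0], np.cumsum(dist.mass_per_bin)]) / total
    return dist.bin_edges.copy(), frac


def quantile_diameter(dist: SizeDistribution, q: float) -> float:
    """Diameter at cumulative mass fraction ``q``, log-linear in d."""
    if not 0 < q < 1:
        raise ValueError("q must lie in (0, 1)")
    edges, frac = cumulative_mass_distribution(dist)
    return float(np.exp(np.interp(q, frac, np.log(edges))))


def mass_quantile_from_particles(diameters_um, masses, q: float) -> float:
    """Mass-weighted quantile diameter of an unbinned particle set.

    Log-linear interpolation between adjacent distinct sample diameters;
    degenerate (monodisperse) sets return their common diameter exactly.
    """
    if not 0 < q < 1:
        raise ValueError("q must lie in (0, 1)")
    d = np.asarray(diameters_um, dtype=float)
    m = np.asarray(masses, dtype=float)
    total = m.sum()
    if total <= 0:
        raise ValueError("total mass must be positive")
    order = np.argsort(d, kind="stable")
    d, m = d[order], m[order]
    # Midpoint (unbiased) convention: each point mass sits at the centre
    # of its own cumulative step.
    cum = (np.cumsum(m) - 0.5 * m) / total
    if d[0] == d[-1]:
        return float(d[0])
    return float(np.exp(np.interp(q, cum, np.log(d))))


def mmad(dist_or_diameters, masses=None) -> float:
    """Mass median aerodynamic diameter [µm].

    Accepts a :class:`SizeDistribution` or ``(diameters, masses)``
    particle arrays.
    """
    if masses is None:
        return quantile_diameter(dist_or_diameters, 0.5)
    return mass_quantile_from_particles(dist_or_diameters, masses, 0.5)


def gsd(dist_or_diameters, masses=None) -> float:
    """Geometric standard deviation ``sqrt(d_84.1 / d_15.9)`` (mass-weighted)."""
    if masses is None:
        d84 = quantile_diameter(dist_or_diameters, 0.841)
        d16 = quantile_diameter(dist_or_diameters, 0.159)
    else:
        d84 = mass_quantile_from_particles(dist_or_diameters, masses, 0.841)
        d16 = mass_quantile_from_particles(dist_or_diameters, masses, 0.159)
    return float(np.sqrt(d84 / d16))


def summarize(aerodynamic_diameters_um, masses, counts=None) -> AerosolSummary:
    """Build an :class:`AerosolSummary` from per-particle data.

    ``Da`` is the count-weighted mean aerodynamic diameter (the sizer's
    sample mean); MMAD and GSD are mass-weighted.
    """
    d = np.asarray(aerodynamic_diameters_um, dtype=float)
    w = np.ones_like(d) if counts is None else np.asarray(counts, dtype=float)
    da = float(np.average(d, weights=w))
    return AerosolSummary(
        Da=da,
        MMAD=mmad(d, masses),
        GSD=gsd(d, masses),
    )


def aerosolization_rate(
    mass_before_g: float,
    mass_after_g: float,
    pulse_duration_min: float,
    liquid_density_g_ml: float,
) -> float:
    """Aerosolized liquid volume per unit time [mL/min].

    ``AR = (m_before - m_after) / (t_pulse * rho)`` from the liquid
    chamber mass before/after an aerosolization pulse.
    """
    if pulse_duration_min <= 0:
        raise ValueError("pulse duration must be positive")
    if liquid_density_g_ml <= 0:
        raise ValueError("density must be positive")
    dm = mass_before_g - mass_after_g
    if dm < 0:
        raise ValueError("mass gain during a pulse signals a measurement problem")
    return dm / (pulse_duration_min * liquid_density_g_ml)


class EventCounts(NamedTuple):
    """Four-way classification of sizer detections."""

    event1: int  # d < 0.5 µm
    event2: int  # 0.5 µm <= d <= 20 µm
    event3: int  # coincident detections
    event4: int  # d > 20 µm


def classify_aps_events(diameters_um, coincidence_flags=None) -> EventCounts:
    """Partition particles into the sizer's four events.

    Coincidence takes precedence; every particle lands in exactly one
    event.
    """
    d = np.asarray(diameters_um, dtype=float)
    if np.any(d < 0):
        raise ValueError("diameters must be non-negative")
    if coincidence_flags is None:
        coin = np.zeros(d.shape, dtype=bool)
    else:
        coin = np.asarray(coincidence_flags, dtype=bool)
    e3 = int(coin.sum())
    rest = d[~coin]
    e1 = int(np.sum(rest < 0.5))
    e2 = int(np.sum((rest >= 0.5) & (rest <= 20.0)))
    e4 = int(np.sum(rest > 20.0))
    return EventCounts(e1, e2, e3, e4)
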