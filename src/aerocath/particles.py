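"""Shared discrete-phase containers.

A *parcel* is the unit of the Lagrangian discretization: a computational
particle standing for ``droplets_per_parcel`` identical physical droplets
(same diameter, velocity and distortion state).  The scalar
:class:`Parcel` dataclass is the public, per-droplet-group view used in
the API and tests; :class:`ParcelArray` is the struct-of-arrays store the
simulator advances in bulk.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CompoundProperties", "Parcel", "ParcelArray", "PFD", "FC75"]


@dataclass(frozen=True)
class CompoundProperties:
    """Bulk liquid properties of the aerosolized compound.

    Densities follow the perfluorocarbon datasheet values used throughout
    (PFD 1950 kg/m^3, FC75 1780 kg/m^3).  Surface tension and liquid
    viscosity are externally sourced defaults (perfluorocarbons are low
    surface-tension liquids, sigma ~ 0.015-0.019 N/m) and are plain
    config values, overridable per run.
    """

    name: str
    liquid_density: float  # kg/m^3
    surface_tension: float  # N/m
    liquid_viscosity: float  # Pa s

    def __post_init__(self) -> None:
        if self.liquid_density <= 0:
            raise ValueError("liquid_density must be positive")
        if self.surface_tension <= 0:
            raise ValueError("surface_tension must be positive")
        if self.liquid_viscosity < 0:
            raise ValueError("liquid_viscosity must be non-negative")

    def droplet_mass(self, diameter: float | np.ndarray) -> float | np.ndarray:
        """Mass of a single spherical droplet of the given diameter [kg]."""
        return self.liquid_density * np.pi / 6.0 * np.asarray(diameter) ** 3


#: Perfluorodecalin.  Surface tension / viscosity are literature-style
#: defaults for perfluorocarbon liquids, not fitted quantities.
PFD = CompoundProperties(
    name="PFD", liquid_density=1950.0, surface_tension=0.019, liquid_viscosity=5.1e-3
)

#: FC75 (perfluoro-2-butyltetrahydrofuran).
FC75 = CompoundProperties(
    name="FC75", liquid_density=1780.0, surface_tension=0.015, liquid_viscosity=1.4e-3
)

_COMPOUNDS = {"PFD": PFD, "FC75": FC75}


def get_compound(name: str) -> CompoundProperties:
    try:
        return _COMPOUNDS[name.upper()]
    except KeyError:
        raise ValueError(
            f"unknown compound {name!r}; valid options: {sorted(_COMPOUNDS)}"
        ) from None


@dataclass
class Parcel:
    """One droplet group: position/velocity in 3-D Cartesian coordinates
    (x axial, measured downstream from the catheter tip), physical droplet
    diameter, droplet count and TAB distortion state.
    """

    position: np.ndarray  # m, shape (3,)
    velocity: np.ndarray  # m/s, shape (3,)
    diameter: float  # m
    droplets_per_parcel: float  # real-valued count > 0
    compound: str = "PFD"
    tab_y: float = 0.0
    tab_ydot: float = 0.0  # 1/s
    active: bool = True

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.velocity = np.asarray(self.velocity, dtype=float)
        if self.diameter <= 0:
            raise ValueError("diameter must be positive")
        if self.droplets_per_parcel <= 0:
            raise ValueError("droplets_per_parcel must be positive")

    @property
    def radial_position(self) -> float:
        return float(np.hypot(self.position[1], self.position[2]))

    def mass(self, props: CompoundProperties) -> float:
        """Total liquid mass carried by the parcel [kg]."""
        return float(self.droplets_per_parcel * props.droplet_mass(self.diameter))


class ParcelArray:
    """Struct-of-arrays parcel store with amortized append.

    All per-parcel state lives in flat numpy arrays so a single time-step
    is a handful of vectorized operations regardless of population size.
    """

    _FIELDS = ("pos", "vel", "eddy_vel")  # (n, 3) float arrays
    _SCALARS = ("diameter", "count", "tab_y", "tab_ydot", "eddy_time")

    def __init__(self, capacity: int = 1024):
        self._n = 0
        self.pos = np.zeros((capacity, 3))
        self.vel = np.zeros((capacity, 3))
        self.eddy_vel = np.zeros((capacity, 3))
        self.diameter = np.zeros(capacity)
        self.count = np.zeros(capacity)
        self.tab_y = np.zeros(capacity)
        self.tab_ydot = np.zeros(capacity)
        self.eddy_time = np.zeros(capacity)
        self.active = np.zeros(capacity, dtype=bool)

    def __len__(self) -> int:
        return self._n

    def _grow(self, need: int) -> None:
        cap = len(self.diameter)
        if self._n + need <= cap:
            return
        new = max(2 * cap, self._n + need)
        for name in self._FIELDS:
            arr = getattr(self, name)
            out = np.zeros((new, 3))
            out[: self._n] = arr[: self._n]
            setattr(self, name, out)
        for name in self._SCALARS:
            arr = getattr(self, name)
            out = np.zeros(new)
            out[: self._n] = arr[: self._n]
            setattr(self, name, out)
        out = np.zeros(new, dtype=bool)
        out[: self._n] = self.active[: self._n]
        self.active = out

    def append(
        self,
        pos: np.ndarray,
        vel: np.ndarray,
        diameter: np.ndarray,
        count: np.ndarray,
        tab_y: np.ndarray | None = None,
        tab_ydot: np.ndarray | None = None,
    ) -> None:
        m = len(diameter)
        if m == 0:
            return
        self._grow(m)
        s = slice(self._n, self._n + m)
        self.pos[s] = pos
        self.vel[s] = vel
        self.diameter[s] = diameter
        self.count[s] = count
        self.tab_y[s] = 0.0 if tab_y is None else tab_y
        self.tab_ydot[s] = 0.0 if tab_ydot is None else tab_ydot
        self.eddy_vel[s] = 0.0
        self.eddy_time[s] = 0.0
        self.active[s] = True
        self._n += m

    def compact(self) -> None:
        """Drop inactive rows, keeping order of the survivors."""
        keep = self.active[: self._n]
        k = int(keep.sum())
        for name in self._FIELDS:
            arr = getattr(self, name)
            arr[:k] = arr[: self._n][keep]
        for name in self._SCALARS:
            arr = getattr(self, name)
            arr[:k] = arr[: self._n][keep]
        self.active[:k] = True
        self.active[k : self._n] = False
        self._n = k

    @property
    def radial(self) -> np.ndarray:
        p = self.pos[: self._n]
        return np.hypot(p[:, 1], p[:, 2])
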