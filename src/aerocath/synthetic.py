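"""Synthetic study inputs.

Everything the pipeline consumes can be generated here with the
statistical structure the analysis assumes, so every stage is testable
without instrument data:

* sizer-like samples — heterodisperse aerosols are lognormal in mass
  (MMAD and GSD are the lognormal's sufficient parameters), drawn as
  number-weighted diameters via the Hatch-Choate relation, classified
  into the instrument's four events and binned into 52 logarithmic
  intervals over the 0.5-20 µm measuring range (the instrument's exact
  proprietary bin edges are replaced by log-uniform ones);
* the packaged measured injector tables for both compounds and both
  driving pressures;
* mesh-convergence series ``v(h) = v0 + C h^p`` for exercising the
  verification toolkit.

Every generator is a pure function of its spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gci import MeshLevel
from .injection import InjectionTable, load_injection_table
from .metrics import AerosolSummary, EventCounts, classify_aps_events, summarize

__all__ = [
    "SyntheticAerosolSpec",
    "APSSample",
    "generate_aps_sample",
    "write_aps_csv",
    "read_aps_csv",
    "measured_injection_tables",
    "generate_mesh_series",
]

N_INSTRUMENT_BINS = 52
INSTRUMENT_RANGE_UM = (0.5, 20.0)


@dataclass(frozen=True)
class SyntheticAerosolSpec:
    """Parameters of one synthetic heterodisperse aerosol sample."""

    mass_median_diameter: float  # µm (aerodynamic)
    sigma_g: float  # geometric standard deviation, >= 1
    n_particles: int
    instrument_range: tuple[float, float] = INSTRUMENT_RANGE_UM
    coincidence_fraction: float = 0.0
    sample_time_s: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mass_median_diameter <= 0:
            raise ValueError("mass_median_diameter must be positive")
        if self.sigma_g < 1:
            raise ValueError("sigma_g must be at least 1")
        if self.n_particles <= 0:
            raise ValueError("n_particles must be positive")
        if not 0 <= self.coincidence_fraction < 1:
            raise ValueError("coincidence_fraction must lie in [0, 1)")


@dataclass(frozen=True)
class APSSample:
    """A 52-interval sizer histogram plus the four event counts.

    ``mass_per_bin`` is the liquid mass represented by the in-range,
    non-coincident particles of each bin (arbitrary consistent units).
    When produced by the generator the raw in-range diameters are kept
    in memory for exact (unbinned) statistics.
    """

    bin_edges: np.ndarray  # µm, length 53
    counts: np.ndarray  # in-range particle counts per bin
    mass_per_bin: np.ndarray
    events: EventCounts
    sample_time_s: float = 10.0
    raw_diameters_um: np.ndarray | None = field(default=None, repr=False)

    def summary(self) -> AerosolSummary:
        """Da/MMAD/GSD of the in-range particles.

        Uses the raw diameters when available (exact), otherwise the
        binned histogram with bin-center mass weighting.
        """
        if self.raw_diameters_um is not None and len(self.raw_diameters_um):
            d = self.raw_diameters_um
            return summarize(d, masses=d**3)
        centers = np.sqrt(self.bin_edges[:-1] * self.bin_edges[1:])
        keep = self.counts > 0
        return summarize(centers[keep], masses=self.mass_per_bin[keep],
                         counts=self.counts[keep])


def generate_aps_sample(spec: SyntheticAerosolSpec) -> APSSample:
    """Draw one synthetic sizer sample.

    Aerodynamic diameters are lognormal with mass-median
    ``spec.mass_median_diameter`` and geometric standard deviation
    ``spec.sigma_g``; by Hatch-Choate the corresponding count-median is
    ``MMAD exp(-3 ln^2 sigma_g)``.  A fraction of detections is flagged
    as coincident; the rest are classified by diameter, and the in-range
    ones binned into 52 logarithmic intervals.
    """
    rng = np.random.default_rng(spec.seed)
    ln_sg = np.log(spec.sigma_g)
    cmd = spec.mass_median_diameter * np.exp(-3.0 * ln_sg**2)
    d = np.exp(rng.normal(np.log(cmd), ln_sg, size=spec.n_particles))
    coin = rng.random(spec.n_particles) < spec.coincidence_fraction
    events = classify_aps_events(d, coin)

    lo, hi = spec.instrument_range
    in_range = ~coin & (d >= lo) & (d <= hi)
    d_in = d[in_range]
    edges = np.exp(np.linspace(np.log(lo), np.log(hi), N_INSTRUMENT_BINS + 1))
    counts, _ = np.histogram(d_in, bins=edges)
    mass, _ = np.histogram(d_in, bins=edges, weights=np.pi / 6.0 * d_in**3)
    return APSSample(
        bin_edges=edges,
        counts=counts.astype(float),
        mass_per_bin=mass,
        events=events,
        sample_time_s=spec.sample_time_s,
        raw_diameters_um=d_in,
    )


def write_aps_csv(sample: APSSample, path) -> None:
    """Write a sample in the plain-text sizer dialect.

    Two comment header lines (sample time; four event counts) followed by
    52 rows of ``bin_lower_um,bin_upper_um,particle_count``.
    """
    e = sample.events
    with open(path, "w") as fh:
        fh.write(f"# sample_time_s={sample.sample_time_s:g}\n")
        fh.write(
            f"# event1={e.event1},event2={e.event2},event3={e.event3},event4={e.event4}\n"
        )
        fh.write("bin_lower_um,bin_upper_um,particle_count\n")
        for lo, hi, c in zip(sample.bin_edges[:-1], sample.bin_edges[1:], sample.counts):
            fh.write(f"{lo:.6g},{hi:.6g},{c:g}\n")


def read_aps_csv(path) -> APSSample:
    """Read a sample written by :func:`write_aps_csv`.

    Per-bin mass is reconstructed from counts at the bin geometric
    centers (raw diameters are not serialized).
    """
    with open(path) as fh:
        line1 = fh.readline().strip()
        line2 = fh.readline().strip()
        df = pd.read_csv(fh)
    sample_time = float(line1.split("=")[1])
    ev = dict(kv.split("=") for kv in line2.lstrip("# ").split(","))
    events = EventCounts(*(int(ev[f"event{i}"]) for i in (1, 2, 3, 4)))
    edges = np.concatenate([df["bin_lower_um"].to_numpy(), [df["bin_upper_um"].iloc[-1]]])
    counts = df["particle_count"].to_numpy(dtype=float)
    centers = np.sqrt(edges[:-1] * edges[1:])
    mass = counts * np.pi / 6.0 * centers**3
    return APSSample(
        bin_edges=edges,
        counts=counts,
        mass_per_bin=mass,
        events=events,
        sample_time_s=sample_time,
    )


def measured_injection_tables() -> dict[tuple[str, int], InjectionTable]:
    """The four packaged measured injector tables, keyed by case."""
    return {
        (c, p): load_injection_table(c, p)
        for c in ("PFD", "FC75")
        for p in (4, 5)
    }


def generate_mesh_series(
    v0: float,
    C: float,
    p: float,
    r: float = 2.0,
    n_levels: int = 3,
    noise_sd: float = 0.0,
    seed: int | None = None,
    h_fine: float = 1.0,
    cells_fine: int = 400_000,
) -> list[MeshLevel]:
    """Construct a mesh-convergence series ``v_i = v0 + C h_i^p``.

    Spacings grow geometrically with ratio ``r`` from the finest level;
    optional Gaussian noise emulates iterative-convergence scatter.
    Cell counts scale as ``h^-2`` (axisymmetric 2-D meshes).
    """
    if r <= 1:
        raise ValueError("refinement ratio must exceed 1")
    if n_levels < 3:
        raise ValueError("need at least three levels")
    rng = np.random.default_rng(seed)
    levels = []
    for i in range(n_levels):
        h = h_fine * r**i
        v = v0 + C * h**p
        if noise_sd > 0:
            v += rng.normal(0.0, noise_sd)
        levels.append(
            MeshLevel(
                label=f"M{i + 1}",
                cell_count=max(1, int(round(cells_fine / r ** (2 * i)))),
                observable_value=float(v),
                representative_size_h=h,
            )
        )
    return levels
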