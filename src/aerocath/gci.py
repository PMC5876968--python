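"""Solution verification: observed order, Richardson extrapolation, GCI.

Given a monitored observable on three systematically refined meshes
(fine v1, medium v2, coarse v3; refinement ratio r), the toolkit
computes the observed order of accuracy

    p = ln((v3 - v2) / (v2 - v1)) / ln(r),

the Richardson-extrapolated zero-spacing value

    v_h=0 = v1 + (v1 - v2) / (r^p - 1),

per-level discretization errors relative to the extrapolated value, and
the Grid Convergence Index of each mesh pair

    GCI = Fs |v_a - v_b| / |v_ref| / (r^p - 1) * 100   [%]

with safety factor Fs = 1.25 for a three-grid study.  Each pair is
normalized by its coarser-grid solution (``v_ref`` = v2 for GCI12, v3
for GCI23); the asymptotic-range check is the ratio
``GCI23 / (r^p GCI12)``, which approaches 1 when both pairs sit in the
asymptotic convergence range.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

__all__ = [
    "MeshLevel",
    "GCIReport",
    "observed_order",
    "richardson_extrapolate",
    "gci",
    "asymptotic_ratio",
    "per_level_errors",
    "grid_convergence_report",
]


@dataclass(frozen=True)
class MeshLevel:
    """One mesh of the refinement study and its monitored value."""

    label: str
    cell_count: int
    observable_value: float
    representative_size_h: float | None = None

    def __post_init__(self) -> None:
        if self.cell_count <= 0:
            raise ValueError("cell_count must be positive")


@dataclass(frozen=True)
class GCIReport:
    """Full three-mesh verification result."""

    refinement_ratio_r: float
    observed_order_p: float
    extrapolated_value: float
    per_level_error_pct: tuple[float, float, float]  # fine, medium, coarse
    gci_12: float  # %
    gci_23: float  # %
    asymptotic_ratio: float
    safety_factor_Fs: float
    normalization: str = "coarser-of-pair"

    @property
    def in_asymptotic_range(self) -> bool:
        return abs(self.asymptotic_ratio - 1.0) < 0.1

    def to_json(self, **kwargs) -> str:
        return json.dumps(asdict(self), **kwargs)

    def format_text(self) -> str:
        e1, e2, e3 = self.per_level_error_pct
        return (
            f"refinement ratio r        : {self.refinement_ratio_r:g}\n"
            f"observed order p          : {self.observed_order_p:.4f}\n"
            f"extrapolated value (h=0)  : {self.extrapolated_value:.4f}\n"
            f"per-level errors [%]      : {e1:.2f} / {e2:.2f} / {e3:.2f}\n"
            f"GCI12 [%]                 : {self.gci_12:.2f}\n"
            f"GCI23 [%]                 : {self.gci_23:.2f}\n"
            f"asymptotic ratio          : {self.asymptotic_ratio:.2f}\n"
            f"safety factor Fs          : {self.safety_factor_Fs:g}\n"
        )


def observed_order(v1: float, v2: float, v3: float, r: float = 2.0) -> float:
    """Observed order of accuracy from three monotonically converging values.

    ``v1`` fine, ``v2`` medium, ``v3`` coarse.
    """
    if r <= 1:
        raise ValueError("refinement ratio must exceed 1")
    d21 = v2 - v1
    d32 = v3 - v2
    if d21 == 0 or d32 == 0:
        raise ValueError("converged pair: successive solutions are identical")
    ratio = d32 / d21
    if ratio <= 0:
        raise ValueError("oscillatory convergence: successive differences change sign")
    return math.log(ratio) / math.log(r)


def richardson_extrapolate(v1: float, v2: float, r: float, p: float) -> float:
    """Zero-spacing estimate ``v1 + (v1 - v2)/(r^p - 1)``."""
    if r <= 1:
        raise ValueError("refinement ratio must exceed 1")
    if v1 == v2:
        return v1
    if p <= 0:
        raise ValueError("order of accuracy must be positive")
    return v1 + (v1 - v2) / (r**p - 1.0)


def gci(v_fine: float, v_coarse: float, r: float, p: float, Fs: float = 1.25) -> float:
    """Grid Convergence Index of one mesh pair, in percent.

    Normalized by the coarser solution of the pair.
    """
    if r <= 1:
        raise ValueError("refinement ratio must exceed 1")
    if p <= 0:
        raise ValueError("order of accuracy must be positive")
    if Fs <= 0:
        raise ValueError("safety factor must be positive")
    if v_coarse == 0:
        raise ValueError("cannot normalize by a zero solution value")
    return Fs * abs(v_fine - v_coarse) / abs(v_coarse) / (r**p - 1.0) * 100.0


def asymptotic_ratio(gci23: float, gci12: float, r: float, p: float) -> float:
    """Asymptotic-range check ``GCI23 / (r^p GCI12)``; ~1 in range."""
    if gci12 == 0:
        raise ValueError("GCI12 must be nonzero")
    return gci23 / (r**p * gci12)


def per_level_errors(values, extrapolated: float) -> list[float]:
    """Percent deviation of each mesh-level value from the extrapolated one."""
    if extrapolated == 0:
        raise ValueError("extrapolated value must be nonzero")
    return [100.0 * abs(v - extrapolated) / abs(extrapolated) for v in values]


def grid_convergence_report(
    levels: list[MeshLevel] | tuple[float, float, float],
    r: float = 2.0,
    Fs: float = 1.25,
) -> GCIReport:
    """End-to-end three-mesh verification.

    ``levels`` may be three :class:`MeshLevel` (any order; sorted to
    fine-to-coarse by cell count) or a plain ``(v1, v2, v3)`` triple
    already ordered fine to coarse.
    """
    if len(levels) != 3:
        raise ValueError("exactly three mesh levels are required")
    if isinstance(levels[0], MeshLevel):
        lv = sorted(levels, key=lambda m: -m.cell_count)
        v1, v2, v3 = (m.observable_value for m in lv)
    else:
        v1, v2, v3 = map(float, levels)
    p = observed_order(v1, v2, v3, r)
    v0 = richardson_extrapolate(v1, v2, r, p)
    errs = per_level_errors((v1, v2, v3), v0)
    g12 = gci(v1, v2, r, p, Fs)
    g23 = gci(v2, v3, r, p, Fs)
    return GCIReport(
        refinement_ratio_r=r,
        observed_order_p=p,
        extrapolated_value=v0,
        per_level_error_pct=tuple(errs),
        gci_12=g12,
        gci_23=g23,
        asymptotic_ratio=asymptotic_ratio(g23, g12, r, p),
        safety_factor_Fs=Fs,
    )
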