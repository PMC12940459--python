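"""DVH construction, dose-volume metrics, constraint checking and the
gamma index.

Dose-volume histograms are the evaluation currency of treatment planning:
the differential DVH bins a structure's voxel doses by dose, the cumulative
DVH gives the volume receiving at least each dose level.  From the
cumulative curve come the standard point metrics (D_x%, V_dose), the
homogeneity index HI = (D2% - D98%) / D50%, and pass/fail reports against
protocol dose-volume constraints.  Constraints may be checked on the
physical dose axis or after an EQD2 transform of the dose axis.

The gamma index compares two dose grids point by point, combining a dose
difference criterion (fraction of the global reference maximum) with a
distance-to-agreement (DTA) search; a point passes when gamma <= 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

from .radbio import DoseDistribution, FractionationScheme, eqd2

__all__ = [
    "DifferentialDVH",
    "CumulativeDVH",
    "ClinicalConstraint",
    "GammaCriteria",
    "build_dvh",
    "cumulative",
    "dose_at_volume",
    "volume_at_dose",
    "homogeneity_index",
    "eqd2_dvh",
    "evaluate_constraints",
    "gamma_pass_rate",
]


@dataclass(frozen=True)
class DifferentialDVH:
    """Binned dose-volume histogram: volume (cm^3) per dose bin."""

    bin_edges: np.ndarray  # length n+1, increasing, Gy
    bin_volume: np.ndarray  # length n, cm^3
    structure_name: str = ""

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        vol = np.asarray(self.bin_volume, dtype=float)
        if edges.ndim != 1 or vol.ndim != 1 or edges.size != vol.size + 1:
            raise ValueError("bin_edges must have one more entry than bin_volume")
        if np.any(np.diff(edges) <= 0):
            raise ValueError("bin_edges must be strictly increasing")
        if np.any(vol < 0):
            raise ValueError("bin volumes must be non-negative")
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "bin_volume", vol)

    @property
    def total_volume(self) -> float:
        return float(self.bin_volume.sum())

    def as_distribution(self, scheme: FractionationScheme) -> DoseDistribution:
        """View the DVH as a dose distribution whose voxels are bins
        (bin-center dose), dropping empty bins."""
        centers = 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])
        keep = self.bin_volume > 0
        return DoseDistribution(centers[keep], self.bin_volume[keep], scheme)


@dataclass(frozen=True)
class CumulativeDVH:
    """Volume receiving at least each dose level; non-increasing in dose."""

    dose: np.ndarray  # Gy, increasing, starts at 0
    volume: np.ndarray  # cm^3, non-increasing, volume[0] = total volume
    structure_name: str = ""

    @property
    def total_volume(self) -> float:
        return float(self.volume[0])

    def as_table(self) -> pd.DataFrame:
        """Cumulative curve with both absolute and relative volume columns."""
        return pd.DataFrame(
            {
                "dose_gy": self.dose,
                "volume_cm3": self.volume,
                "volume_pct": 100.0 * self.volume / self.total_volume,
            }
        )


def build_dvh(
    dist: DoseDistribution, bin_width: float = 0.05, structure_name: str = ""
) -> DifferentialDVH:
    """Bin a voxel dose distribution into a differential DVH.

    Bins span [0, max dose + bin_width); total volume is conserved exactly.
    """
    if not bin_width > 0:
        raise ValueError("bin_width must be positive")
    top = float(dist.voxel_dose.max()) + bin_width
    n_bins = int(np.ceil(top / bin_width))
    edges = np.arange(n_bins + 1) * bin_width
    vol, _ = np.histogram(dist.voxel_dose, bins=edges, weights=dist.voxel_volume)
    return DifferentialDVH(edges, vol, structure_name or "")


def cumulative(dvh: DifferentialDVH) -> CumulativeDVH:
    """Cumulative DVH on the differential bin edges.

    The curve value at edge j is the volume of all bins at or above j, so
    it starts at the total volume and is non-increasing.
    """
    cum = np.concatenate([np.cumsum(dvh.bin_volume[::-1])[::-1], [0.0]])
    return CumulativeDVH(dvh.bin_edges.copy(), cum, dvh.structure_name)


def dose_at_volume(cdvh: CumulativeDVH, volume_pct: float) -> float:
    """D_x%: the dose covering at least x% of the structure volume.

    Linear interpolation on the cumulative curve; x is relative volume in
    percent, strictly inside (0, 100).
    """
    if not 0.0 < volume_pct < 100.0:
        raise ValueError(f"volume percentage must be in (0, 100), got {volume_pct!r}")
    target = volume_pct / 100.0 * cdvh.total_volume
    vol = cdvh.volume
    dose = cdvh.dose
    # volume is non-increasing in dose -> reverse for np.interp
    return float(np.interp(target, vol[::-1], dose[::-1]))


def volume_at_dose(
    cdvh: CumulativeDVH, dose_gy: float, relative: bool = True
) -> float:
    """V_dose: volume receiving at least ``dose_gy``, in % or cm^3."""
    if dose_gy < 0:
        raise ValueError("dose must be non-negative")
    v = float(np.interp(dose_gy, cdvh.dose, cdvh.volume))
    return 100.0 * v / cdvh.total_volume if relative else v


def homogeneity_index(cdvh: CumulativeDVH) -> float:
    """HI = (D2% - D98%) / D50%; zero for a perfectly uniform dose."""
    d50 = dose_at_volume(cdvh, 50.0)
    if d50 <= 0:
        raise ValueError("median dose is zero; homogeneity index undefined")
    return (dose_at_volume(cdvh, 2.0) - dose_at_volume(cdvh, 98.0)) / d50


def eqd2_dvh(
    dvh: DifferentialDVH, scheme: FractionationScheme, alpha_beta: float
) -> DifferentialDVH:
    """Transform the DVH dose axis from physical total dose to EQD2."""
    edges = np.asarray(eqd2(dvh.bin_edges, scheme, alpha_beta))
    return DifferentialDVH(edges, dvh.bin_volume.copy(), dvh.structure_name)


# ---------------------------------------------------------------------------
# Clinical constraints
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClinicalConstraint:
    """One protocol dose-volume requirement.

    kind is one of ``V_at_dose`` (volume receiving >= dose_gy), ``D_at_volume``
    (dose covering volume_pct of the structure) or ``D_max``; ``op`` is the
    comparison (``le`` or ``ge``) against ``limit`` expressed in ``unit``
    (``pct``, ``cm3`` or ``Gy``).
    """

    structure: str
    kind: str
    op: str
    limit: float
    unit: str
    dose_gy: float | None = None
    volume_pct: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in {"V_at_dose", "D_at_volume", "D_max"}:
            raise ValueError(f"unknown constraint kind {self.kind!r}")
        if self.op not in {"le", "ge"}:
            raise ValueError(f"unknown comparison {self.op!r}")
        if self.unit not in {"pct", "cm3", "Gy"}:
            raise ValueError(f"unknown unit {self.unit!r}")
        if self.kind == "V_at_dose" and self.dose_gy is None:
            raise ValueError("V_at_dose constraint needs dose_gy")
        if self.kind == "D_at_volume" and self.volume_pct is None:
            raise ValueError("D_at_volume constraint needs volume_pct")
        if self.unit == "pct" and not 0 <= self.limit <= 100:
            raise ValueError("percentage limit outside [0, 100]")
        if self.limit < 0:
            raise ValueError("limit must be non-negative")

    def measure(self, cdvh: CumulativeDVH) -> float:
        if self.kind == "V_at_dose":
            return volume_at_dose(cdvh, self.dose_gy, relative=(self.unit == "pct"))
        if self.kind == "D_at_volume":
            return dose_at_volume(cdvh, self.volume_pct)
        # D_max: highest dose with non-zero volume on the curve
        nz = cdvh.volume > 0
        return float(cdvh.dose[nz][-1]) if np.any(nz) else 0.0

    def passes(self, measured: float) -> bool:
        return measured <= self.limit if self.op == "le" else measured >= self.limit


class MissingStructureError(KeyError):
    """A constraint references a structure with no DVH."""


def evaluate_constraints(
    dvhs: Mapping[str, DifferentialDVH],
    constraints: Sequence[ClinicalConstraint],
) -> pd.DataFrame:
    """Check every constraint against the per-structure DVHs.

    Returns a table with one row per constraint: structure, kind, the
    measured value, the limit, and pass/fail.  Raises
    :class:`MissingStructureError` when a referenced structure is absent.
    """
    missing = {c.structure for c in constraints} - set(dvhs)
    if missing:
        raise MissingStructureError(
            f"no DVH for structure(s): {', '.join(sorted(missing))}"
        )
    rows = []
    for c in constraints:
        cdvh = cumulative(dvhs[c.structure])
        measured = c.measure(cdvh)
        rows.append(
            {
                "structure": c.structure,
                "kind": c.kind,
                "dose_gy": c.dose_gy,
                "volume_pct": c.volume_pct,
                "op": c.op,
                "limit": c.limit,
                "unit": c.unit,
                "measured": measured,
                "passed": c.passes(measured),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Gamma index
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GammaCriteria:
    """Gamma comparison criteria (global normalization).

    dose_tolerance is a fraction of the reference maximum (0.03 = 3%),
    dta the distance-to-agreement in mm, low_dose_threshold the fraction of
    the reference maximum below which evaluated points are excluded, and
    pass_requirement the pass-rate fraction deemed equivalent.
    """

    dose_tolerance: float = 0.03
    dta_mm: float = 2.0
    low_dose_threshold: float = 0.10
    pass_requirement: float = 0.95
    search_radius_factor: float = 3.0
    search_step_mm: float = 0.4

    def __post_init__(self) -> None:
        for name in ("dose_tolerance", "low_dose_threshold", "pass_requirement"):
            if not 0.0 < getattr(self, name) < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")
        if not self.dta_mm > 0:
            raise ValueError("dta_mm must be positive")


def gamma_pass_rate(
    reference: np.ndarray,
    evaluated: np.ndarray,
    spacing_mm: Sequence[float],
    criteria: GammaCriteria = GammaCriteria(),
) -> float:
    """Percentage of evaluated grid points with gamma <= 1.

    Both dose grids share one coordinate frame with the given voxel spacing
    (mm per axis).  Dose differences are normalized to the reference
    maximum (global normalization); evaluated points below the low-dose
    threshold are excluded.  For each remaining point the minimum of
    sqrt((dD/tol)^2 + (dr/DTA)^2) is searched over reference positions
    within ``search_radius_factor * DTA``, sampling the tri-linearly
    interpolated reference on a sub-voxel step grid.
    """
    ref = np.asarray(reference, dtype=float)
    ev = np.asarray(evaluated, dtype=float)
    if ref.shape != ev.shape:
        raise ValueError(f"grid shapes differ: {ref.shape} vs {ev.shape}")
    spacing = np.asarray(spacing_mm, dtype=float)
    if spacing.size != ref.ndim or np.any(spacing <= 0):
        raise ValueError("spacing must give a positive length per grid axis")

    ref_max = float(ref.max())
    if ref_max <= 0:
        raise ValueError("reference maximum dose must be positive")
    dose_tol = criteria.dose_tolerance * ref_max

    mask = ev >= criteria.low_dose_threshold * ref_max
    if not np.any(mask):
        raise ValueError("no evaluated points above the low-dose threshold")
    pts_idx = np.argwhere(mask)
    pts_mm = pts_idx * spacing  # physical coordinates of evaluated points
    ev_dose = ev[mask]

    axes = [np.arange(n) * s for n, s in zip(ref.shape, spacing)]
    interp = RegularGridInterpolator(
        axes, ref, bounds_error=False, fill_value=np.nan
    )

    radius = criteria.search_radius_factor * criteria.dta_mm
    offsets = _search_offsets(ref.ndim, radius, criteria.search_step_mm)

    gamma_sq = np.full(ev_dose.shape, np.inf)
    for off in offsets:
        dist_sq = float(np.sum(off**2)) / criteria.dta_mm**2
        # offsets are sorted by distance: once the distance term alone
        # exceeds every current gamma^2, no later offset can improve any point
        if dist_sq >= float(np.max(gamma_sq)):
            break
        ref_dose = interp(pts_mm + off)
        valid = ~np.isnan(ref_dose)
        if not np.any(valid):
            continue
        dd_sq = ((ev_dose[valid] - ref_dose[valid]) / dose_tol) ** 2
        cand = dd_sq + dist_sq
        np.minimum.at(gamma_sq, np.nonzero(valid)[0], cand)

    passed = np.sqrt(gamma_sq) <= 1.0 + 1e-12
    return 100.0 * float(passed.mean())


def _search_offsets(ndim: int, radius: float, step: float) -> np.ndarray:
    """Offsets (mm) on a regular grid within a ball of the given radius,
    sorted by distance so the zero-offset dose check comes first."""
    n = int(np.floor(radius / step))
    one = np.arange(-n, n + 1) * step
    grids = np.meshgrid(*([one] * ndim), indexing="ij")
    pts = np.stack([g.ravel() for g in grids], axis=1)
    d2 = np.sum(pts**2, axis=1)
    keep = d2 <= radius**2 + 1e-9
    pts, d2 = pts[keep], d2[keep]
    return pts[np.argsort(d2)]
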