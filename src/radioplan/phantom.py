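"""Seeded synthetic pelvic phantom and beamlet influence-matrix generator.

The phantom is a voxel grid carrying boolean masks for the three target
volumes — the imaging-defined gross tumor (``gtv_union``) inside the
prostate gland, the remaining gland (``prostate_minus``) and the 3 mm
extracapsular margin shell (``ctv_minus``) — plus up to seven organs at
risk placed with pelvic topology (rectum posterior, bladder
superior-anterior, femoral heads lateral, small bowel superior, penile
bulb inferior, sigmoid colon superior-posterior).  Structures are built as
noise-perturbed nested ellipsoids whose realized volumes match the request
to within half a voxel, emulating the cohort's published structure-volume
statistics.

The beamlet generator lays equi-angular parallel pencil-beam arrays around
the gland and computes a dose-influence matrix on the union of all
structure voxels: exponential depth attenuation along the beam axis with a
Gaussian lateral profile per beamlet.  It is a deliberately simple,
water-equivalent surrogate for a clinical dose engine — linear in the
beamlet weights, deterministic, and fast enough to sit inside a stochastic
outer optimization loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Mapping, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .datasets import cohort_fixture  # re-exported: the phantom module owns it
from .datasets import OAR_STRUCTURES, TARGET_STRUCTURES

__all__ = [
    "PhantomConfig",
    "Phantom",
    "BeamletMatrix",
    "generate_phantom",
    "generate_beamlets",
    "small_phantom_config",
    "cohort_fixture",
]

#: Published cohort ranges the generator enforces for its requests.
PROSTATE_VOLUME_RANGE = (23.59, 60.26)  # cm^3
GTV_FRACTION_RANGE = (0.0367, 0.3914)

_DEFAULT_OAR_VOLUMES = {
    "bladder": 25.0,
    "rectum": 18.0,
    "sigmoid_colon": 8.0,
    "small_bowel": 12.0,
    "penile_bulb": 3.0,
    "femoral_head_left": 12.0,
    "femoral_head_right": 12.0,
}

# Placement relative to the gland center, in mm (x lateral, y
# anterior(-)/posterior(+), z inferior(-)/superior(+)), with per-axis
# ellipsoid shape ratios.
_OAR_LAYOUT = {
    "rectum": ((0.0, 30.0, 0.0), (1.0, 0.8, 1.8)),
    "bladder": ((0.0, -28.0, 15.0), (1.2, 1.0, 0.8)),
    "sigmoid_colon": ((0.0, 25.0, 22.0), (1.0, 0.9, 1.4)),
    "small_bowel": ((0.0, -8.0, 27.0), (1.4, 1.0, 0.7)),
    "penile_bulb": ((0.0, 5.0, -26.0), (1.0, 1.0, 1.0)),
    "femoral_head_left": ((-38.0, 0.0, 0.0), (0.8, 1.0, 1.4)),
    "femoral_head_right": ((38.0, 0.0, 0.0), (0.8, 1.0, 1.4)),
}


class ConfigurationError(ValueError):
    """Phantom or beamlet request outside the supported envelope."""


@dataclass(frozen=True)
class PhantomConfig:
    """Volume targets and geometry for one synthetic phantom.

    Volumes in cm^3; the prostate volume and GTV fraction must lie within
    the cohort's published ranges.  ``noise_amplitude`` scales the smooth
    random boundary perturbation (0 gives clean ellipsoids).
    """

    prostate_volume_cm3: float = 41.0
    gtv_fraction: float = 0.118
    ctv_margin_mm: float = 3.0
    oar_volumes: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_OAR_VOLUMES)
    )
    grid_shape: Tuple[int, int, int] = (40, 40, 24)
    voxel_size_mm: float = 2.5
    noise_amplitude: float = 0.06

    def __post_init__(self) -> None:
        lo, hi = PROSTATE_VOLUME_RANGE
        if not lo <= self.prostate_volume_cm3 <= hi:
            raise ConfigurationError(
                f"prostate volume {self.prostate_volume_cm3} cm^3 outside the "
                f"supported cohort range [{lo}, {hi}]"
            )
        flo, fhi = GTV_FRACTION_RANGE
        if not flo <= self.gtv_fraction <= fhi:
            raise ConfigurationError(
                f"GTV fraction {self.gtv_fraction} outside the supported "
                f"cohort range [{flo}, {fhi}]"
            )
        unknown = set(self.oar_volumes) - set(OAR_STRUCTURES)
        if unknown:
            raise ConfigurationError(f"unknown OAR(s): {sorted(unknown)}")
        if self.voxel_size_mm <= 0 or any(n < 4 for n in self.grid_shape):
            raise ConfigurationError("degenerate grid")


def small_phantom_config(**overrides) -> PhantomConfig:
    """Coarse desk-scale preset (5 mm voxels on the same physical extent),
    suitable for fast end-to-end runs."""
    base = PhantomConfig(grid_shape=(20, 20, 12), voxel_size_mm=5.0)
    return replace(base, **overrides) if overrides else base


@dataclass(frozen=True)
class Phantom:
    """Voxelised anatomy: grid geometry plus per-structure boolean masks."""

    grid_shape: Tuple[int, int, int]
    voxel_size_mm: float
    structure_masks: Dict[str, np.ndarray]

    @property
    def voxel_volume_cm3(self) -> float:
        return (self.voxel_size_mm / 10.0) ** 3

    @property
    def volumes(self) -> Dict[str, float]:
        """Realized structure volumes in cm^3 (mask count x voxel volume)."""
        return {
            name: float(mask.sum()) * self.voxel_volume_cm3
            for name, mask in self.structure_masks.items()
        }

    @property
    def target_names(self) -> Tuple[str, ...]:
        return tuple(n for n in TARGET_STRUCTURES if n in self.structure_masks)

    @property
    def oar_names(self) -> Tuple[str, ...]:
        return tuple(n for n in OAR_STRUCTURES if n in self.structure_masks)

    def voxel_coords_mm(self, mask: np.ndarray | None = None) -> np.ndarray:
        """Physical voxel-center coordinates (mm, grid-centered)."""
        idx = np.argwhere(mask if mask is not None else np.ones(self.grid_shape, bool))
        center = (np.asarray(self.grid_shape) - 1) / 2.0
        return (idx - center) * self.voxel_size_mm

    def volumes_table(self):
        import pandas as pd

        return pd.DataFrame(
            sorted(self.volumes.items()), columns=["structure", "volume_cm3"]
        )


def _take_nearest(
    allowed: np.ndarray, fieldvals: np.ndarray, count: int
) -> np.ndarray:
    """Boolean mask of the ``count`` allowed voxels with the smallest field
    value (a perturbed ellipsoidal distance)."""
    mask = np.zeros(fieldvals.shape, dtype=bool)
    flat_allowed = np.flatnonzero(allowed)
    if count > flat_allowed.size:
        raise ConfigurationError(
            f"structure of {count} voxels does not fit in the remaining grid"
        )
    order = np.argsort(fieldvals.ravel()[flat_allowed], kind="stable")
    mask.ravel()[flat_allowed[order[:count]]] = True
    return mask


def generate_phantom(config: PhantomConfig = PhantomConfig(), seed: int = 0) -> Phantom:
    """Generate a seeded synthetic pelvic phantom.

    Deterministic for a fixed ``(config, seed)``; every structure's
    realized volume matches its request to within half a voxel.
    """
    rng = np.random.default_rng(seed)
    shape = config.grid_shape
    vox = config.voxel_size_mm
    vox_cm3 = (vox / 10.0) ** 3

    center = (np.asarray(shape) - 1) / 2.0
    ii = np.indices(shape).astype(float)
    coords = (ii - center.reshape(3, 1, 1, 1)) * vox  # mm, grid-centered

    def noise_field() -> np.ndarray:
        raw = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=1.5)
        sd = raw.std() or 1.0
        return raw / sd

    def ellipsoid_field(center_mm, ratios) -> np.ndarray:
        rel = [
            (coords[k] - center_mm[k]) / ratios[k] for k in range(3)
        ]
        r = np.sqrt(rel[0] ** 2 + rel[1] ** 2 + rel[2] ** 2)
        # perturb the boundary: noise scaled to a fraction of the local radius
        return r * (1.0 + config.noise_amplitude * noise_field())

    masks: Dict[str, np.ndarray] = {}

    # prostate gland, then the GTV nested inside it
    n_prostate = int(round(config.prostate_volume_cm3 / vox_cm3))
    gland_field = ellipsoid_field((0.0, 0.0, 0.0), (1.0, 0.9, 0.85))
    gland = _take_nearest(np.ones(shape, bool), gland_field, n_prostate)

    gland_r_mm = (3.0 * config.prostate_volume_cm3 * 1000.0 / (4.0 * np.pi)) ** (1 / 3)
    gtv_center = np.array([0.35, -0.25, 0.1]) * gland_r_mm
    n_gtv = max(1, int(round(config.gtv_fraction * n_prostate)))
    gtv_field = ellipsoid_field(gtv_center, (1.0, 1.0, 0.9))
    masks["gtv_union"] = _take_nearest(gland, gtv_field, n_gtv)
    masks["prostate_minus"] = gland & ~masks["gtv_union"]

    # extracapsular shell: isotropic dilation of the gland minus the gland
    r_vox = max(1, int(round(config.ctv_margin_mm / vox)))
    ball = _ball_structuring_element(r_vox)
    dilated = ndimage.binary_dilation(gland, structure=ball)
    masks["ctv_minus"] = dilated & ~gland

    tv_union = gland | masks["ctv_minus"]
    assigned = tv_union.copy()
    for name, volume in config.oar_volumes.items():
        offset, ratios = _OAR_LAYOUT[name]
        n_vox = max(1, int(round(volume / vox_cm3)))
        fieldvals = ellipsoid_field(offset, ratios)
        mask = _take_nearest(~assigned, fieldvals, n_vox)
        masks[name] = mask
        assigned |= mask

    return Phantom(grid_shape=shape, voxel_size_mm=vox, structure_masks=masks)


def _ball_structuring_element(radius_vox: int) -> np.ndarray:
    n = 2 * radius_vox + 1
    idx = np.indices((n, n, n)) - radius_vox
    return (idx**2).sum(axis=0) <= radius_vox**2 + 1e-9


# ---------------------------------------------------------------------------
# Beamlet influence matrix
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BeamletMatrix:
    """Dose-influence mapping: Gy per unit beamlet weight on ROI voxels.

    ``matrix`` has shape (n_beamlets, n_roi_voxels); ``structure_rows``
    indexes the ROI axis per structure; ``adjacency`` lists beamlet pairs
    that are lateral neighbours within one beam (used by the smoothing
    penalty of the dose engine).
    """

    matrix: np.ndarray
    roi_coords_mm: np.ndarray
    roi_flat_indices: np.ndarray  # flat voxel indices into the phantom grid
    grid_shape: Tuple[int, int, int]
    structure_rows: Dict[str, np.ndarray]
    roi_volume_cm3: float
    beam_angles_deg: np.ndarray
    beam_of_beamlet: np.ndarray
    beamlet_width_mm: float
    adjacency: np.ndarray  # (n_pairs, 2)
    beamlet_offsets_mm: np.ndarray  # (n_beamlets, 2): (lateral, axial-z)

    @property
    def n_beamlets(self) -> int:
        return self.matrix.shape[0]

    def dose(self, weights: np.ndarray) -> np.ndarray:
        """Total ROI dose for the given non-negative beamlet weights."""
        w = np.asarray(weights, dtype=float)
        if w.shape != (self.n_beamlets,):
            raise ValueError(f"expected {self.n_beamlets} weights, got {w.shape}")
        return w @ self.matrix

    def structure_dose(self, weights: np.ndarray) -> Dict[str, np.ndarray]:
        d = self.dose(weights)
        return {name: d[rows] for name, rows in self.structure_rows.items()}

    def dose_grid(self, weights: np.ndarray) -> np.ndarray:
        """Total dose embedded back into the phantom grid (zeros outside
        the ROI)."""
        grid = np.zeros(int(np.prod(self.grid_shape)))
        grid[self.roi_flat_indices] = self.dose(weights)
        return grid.reshape(self.grid_shape)

    def axis_profile(self, beamlet: int) -> Tuple[np.ndarray, np.ndarray]:
        """(depth, dose-per-unit-weight) along a voxel column parallel to
        one beamlet's axis.

        Picks the most populated column of ROI voxels sharing one lateral
        offset from the beamlet axis (within the beamlet width), so the
        returned profile isolates the depth dependence of the kernel.
        """
        angle = np.deg2rad(self.beam_angles_deg[self.beam_of_beamlet[beamlet]])
        u = np.array([np.cos(angle), np.sin(angle), 0.0])
        lat = np.array([-np.sin(angle), np.cos(angle), 0.0])
        off_l, off_z = self.beamlet_offsets_mm[beamlet]
        dl = self.roi_coords_mm @ lat - off_l
        dz = self.roi_coords_mm[:, 2] - off_z
        near = (np.abs(dl) < self.beamlet_width_mm) & (
            np.abs(dz) < self.beamlet_width_mm
        )
        idx = np.flatnonzero(near & (self.matrix[beamlet] > 0))
        if idx.size == 0:
            return np.array([]), np.array([])
        # group by quantized lateral offset; keep the densest column
        keys = [
            (round(float(dl[i]), 3), round(float(dz[i]), 3)) for i in idx
        ]
        from collections import Counter

        best_key, _ = Counter(keys).most_common(1)[0]
        col = idx[[k == best_key for k in keys]]
        depth = self.roi_coords_mm[col] @ u
        order = np.argsort(depth)
        return depth[order], self.matrix[beamlet, col][order]


def generate_beamlets(
    phantom: Phantom,
    n_beams: int = 8,
    beamlet_width_mm: float = 10.0,
    attenuation_coeff: float = 0.005,
    margin_mm: float = 8.0,
    lateral_sigma_factor: float = 0.55,
) -> BeamletMatrix:
    """Equi-angular parallel pencil-beam influence matrix over the union of
    all structure voxels.

    Each beam is a 2-D array of beamlets (in-plane lateral x longitudinal)
    sized to cover the target volumes plus ``margin_mm``.  The per-voxel
    kernel is exp(-mu * depth) * Gaussian(lateral offset); each beamlet is
    normalized to unit peak dose within the ROI, so weights are expressed
    directly in Gy at the beamlet peak.
    """
    if n_beams < 2:
        raise ConfigurationError("need at least 2 beams")
    if beamlet_width_mm <= 0:
        raise ConfigurationError("beamlet width must be positive")
    if attenuation_coeff < 0:
        raise ConfigurationError("attenuation coefficient must be non-negative")

    roi_mask = np.zeros(phantom.grid_shape, dtype=bool)
    for m in phantom.structure_masks.values():
        roi_mask |= m
    roi_idx = np.argwhere(roi_mask)
    coords = phantom.voxel_coords_mm(roi_mask)  # (n_roi, 3)

    flat_roi = np.flatnonzero(roi_mask.ravel())
    pos_in_roi = {v: i for i, v in enumerate(flat_roi)}
    structure_rows = {
        name: np.array(
            [pos_in_roi[v] for v in np.flatnonzero(mask.ravel())], dtype=int
        )
        for name, mask in phantom.structure_masks.items()
    }

    tv_rows = np.concatenate(
        [structure_rows[n] for n in phantom.target_names]
    )
    tv_coords = coords[tv_rows]

    # grid physical half-extent, for the entry-plane depth reference
    half_extent = (np.asarray(phantom.grid_shape) - 1) / 2.0 * phantom.voxel_size_mm

    angles = np.arange(n_beams) * (360.0 / n_beams)
    sigma = lateral_sigma_factor * beamlet_width_mm

    z_lo = tv_coords[:, 2].min() - margin_mm
    z_hi = tv_coords[:, 2].max() + margin_mm
    z_offsets = _cover(z_lo, z_hi, beamlet_width_mm)

    rows = []
    beam_of = []
    offsets = []
    adjacency = []
    for b, ang in enumerate(angles):
        a = np.deg2rad(ang)
        u = np.array([np.cos(a), np.sin(a), 0.0])
        lat = np.array([-np.sin(a), np.cos(a), 0.0])
        l_proj = tv_coords @ lat
        l_offsets = _cover(l_proj.min() - margin_mm, l_proj.max() + margin_mm,
                           beamlet_width_mm)
        # depth from the grid entry plane along u
        corners = np.array(
            [[sx * half_extent[0], sy * half_extent[1], sz * half_extent[2]]
             for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)]
        )
        d_entry = float((corners @ u).min())
        depth = coords @ u - d_entry
        atten = np.exp(-attenuation_coeff * depth)
        dl_all = coords @ lat
        base = len(rows)
        grid_pos = {}
        for iz, oz in enumerate(z_offsets):
            gz = np.exp(-((coords[:, 2] - oz) ** 2) / (2 * sigma**2))
            for il, ol in enumerate(l_offsets):
                gl = np.exp(-((dl_all - ol) ** 2) / (2 * sigma**2))
                kernel = atten * gz * gl
                peak = kernel.max()
                if peak <= 0:
                    continue
                kernel = kernel / peak
                kernel[kernel < 1e-4] = 0.0
                grid_pos[(iz, il)] = len(rows)
                rows.append(kernel)
                beam_of.append(b)
                offsets.append((ol, oz))
        for (iz, il), k in grid_pos.items():
            for nb in ((iz + 1, il), (iz, il + 1)):
                if nb in grid_pos:
                    adjacency.append((k, grid_pos[nb]))

    matrix = np.asarray(rows)
    tv_cov = matrix[:, tv_rows].sum(axis=0)
    if np.any(tv_cov <= 0):
        raise ConfigurationError("some target voxels unreachable by any beamlet")

    return BeamletMatrix(
        matrix=matrix,
        roi_coords_mm=coords,
        roi_flat_indices=flat_roi,
        grid_shape=phantom.grid_shape,
        structure_rows=structure_rows,
        roi_volume_cm3=phantom.voxel_volume_cm3,
        beam_angles_deg=angles,
        beam_of_beamlet=np.asarray(beam_of, dtype=int),
        beamlet_width_mm=beamlet_width_mm,
        adjacency=np.asarray(adjacency, dtype=int).reshape(-1, 2),
        beamlet_offsets_mm=np.asarray(offsets, dtype=float),
    )


def _cover(lo: float, hi: float, step: float) -> np.ndarray:
    """Centers of a symmetric step-grid covering [lo, hi]."""
    mid = 0.5 * (lo + hi)
    n = max(1, int(np.ceil((hi - lo) / step)))
    return mid + (np.arange(n) - (n - 1) / 2.0) * step
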