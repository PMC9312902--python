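"""Synthetic CT-like volumes with per-structure labels and a calibration phantom.

The rasterizer stands in for a clinical MDCT acquisition plus segmentation: it
voxelizes a :class:`~spinefe.geometry.SpineGeometry` onto an anisotropic HU
grid (1 mm in-plane, 3 mm slices by default, emulating clinical-routine
resolution), adds a two-insert calibration phantom (bone-equivalent 200 mg/mL
and water-equivalent 0 mg/mL) beneath the subject, and writes an aligned
integer label mask for every vertebra, the annulus, the nucleus and the
phantom inserts.

The trabecular HU mean is chosen by *inverting* the densitometric chain
(BMD_QCT -> BMD_MDCT -> HU via the phantom inserts placed in the same volume),
so downstream phantom-calibrated densitometry recovers the requested
BMD_QCT-L1-3 target exactly in the noiseless case.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import CTSynthesisError, ValidationError
from .geometry import SpineGeometry

# Label codes shared across the package.
LABEL_BACKGROUND = 0
LABEL_VERTEBRA = {"L1": 1, "L2": 2, "L3": 3, "L4": 4, "L5": 5}
LABEL_ANNULUS = 6
LABEL_NUCLEUS = 7
LABEL_PHANTOM_BONE = 8
LABEL_PHANTOM_WATER = 9

LABEL_NAMES = {
    0: "background", 1: "L1", 2: "L2", 3: "L3", 4: "L4", 5: "L5",
    6: "annulus", 7: "nucleus", 8: "phantom_bone", 9: "phantom_water",
}


@dataclass
class CTVolume:
    """A HU scalar grid with voxel spacing (mm) and world origin (mm).

    ``data[i, j, k]`` is the HU value of the voxel whose centre sits at
    ``origin + (i, j, k) * spacing`` in the package frame (x anterior,
    y left, z superior).
    """

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float32)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if np.any(self.spacing <= 0):
            raise ValidationError(f"voxel spacing must be > 0, got {self.spacing}")
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("HU grid contains non-finite values")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Continuous (fractional) voxel indices for world coordinates."""
        return (np.atleast_2d(points) - self.origin) / self.spacing


@dataclass
class LabelMask:
    """Integer region labels aligned voxel-for-voxel with a CTVolume."""

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.int16)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def voxels(self, label: int) -> np.ndarray:
        return np.argwhere(self.data == label)

    def count(self, label: int) -> int:
        return int(np.count_nonzero(self.data == label))


@dataclass(frozen=True)
class CTConfig:
    """Acquisition / phantom parameters of the synthetic scanner."""

    in_plane: float = 1.0  # mm, isotropic x-y spacing
    slice_thickness: float = 3.0  # mm, z spacing
    margin: float = 6.0  # mm of padding around the anatomy
    air_hu: float = -1000.0
    shell_hu: float = 1200.0  # cortical shell, fixed high
    annulus_hu: float = 80.0
    nucleus_hu: float = 40.0
    insert_hu_bone: float = 400.0  # 200 mg/mL insert
    insert_hu_water: float = 0.0  # 0 mg/mL insert
    ha_bone: float = 200.0  # mg/mL
    ha_water: float = 0.0  # mg/mL
    qct_slope: float = 0.69  # BMD_QCT = slope * BMD_MDCT + intercept
    qct_intercept: float = -11.0  # mg/mL
    soft_tissue_hu: float = 40.0  # paraspinal soft-tissue envelope
    soft_tissue_margin: float = 5.0  # mm of soft tissue around the anatomy
    phantom_radius: float = 6.0  # mm
    phantom_length: float = 44.0  # mm, cylinder axis along y
    phantom_offset: float = 16.0  # mm below the posterior body wall
    noise_on_inserts: bool = True

    def __post_init__(self):
        for name in ("in_plane", "slice_thickness", "phantom_radius"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"CTConfig.{name} must be > 0")


def invert_bmd_to_hu(target_bmd_qct: float, cfg: CTConfig) -> float:
    """Mean trabecular HU whose calibrated densitometry equals the target.

    Runs the densitometric chain backwards: BMD_QCT -> BMD_MDCT through the
    linear QCT cross-calibration, then BMD_MDCT -> HU through the two-point
    phantom line defined by the insert HU values placed in the volume.
    """
    bmd_mdct = (target_bmd_qct - cfg.qct_intercept) / cfg.qct_slope
    slope = cfg.ha_bone / (cfg.insert_hu_bone - cfg.insert_hu_water)
    return cfg.insert_hu_water + bmd_mdct / slope


def rasterize_ct(
    geom: SpineGeometry,
    target_bmd_qct: float,
    noise_sd: float = 30.0,
    seed: int = 0,
    config: CTConfig | None = None,
) -> tuple[CTVolume, LabelMask]:
    """Voxelize a spine geometry into an HU volume and a label mask.

    Parameters
    ----------
    geom : SpineGeometry
        The parametric anatomy to scan.
    target_bmd_qct : float
        Requested subject-level BMD_QCT-L1-3 in mg/mL; all five trabecular
        compartments share the corresponding mean HU.
    noise_sd : float
        Gaussian HU noise s.d. added to trabecular voxels (and, by default,
        the phantom inserts).
    seed : int
        Seed for the noise generator; the output is deterministic given
        (geom, target, noise_sd, seed, config).
    """
    cfg = config or CTConfig()
    if not (20.0 < target_bmd_qct < 250.0):
        raise ValidationError(
            f"target_bmd_qct = {target_bmd_qct} outside supported range (20, 250)"
        )
    min_semi = min(min(v.a_ap, v.a_ml) for v in geom.vertebrae)
    if 2.0 * min_semi < 2.0 * cfg.in_plane:
        raise CTSynthesisError(
            "in-plane voxel spacing too coarse: fewer than 2 voxels across "
            f"the smallest vertebral body ({2 * min_semi:.1f} mm wide at "
            f"{cfg.in_plane:.1f} mm spacing)"
        )

    mu = invert_bmd_to_hu(target_bmd_qct, cfg)
    rng = np.random.default_rng(seed)

    # Grid bounds covering anatomy plus phantom.
    a_max = max(v.a_ap for v in geom.vertebrae)
    b_max = max(v.a_ml for v in geom.vertebrae)
    x_phantom = -(a_max + cfg.phantom_offset)
    x_lo = x_phantom - cfg.phantom_radius - cfg.margin
    x_hi = a_max + cfg.margin
    y_hi = max(b_max, 0.5 * cfg.phantom_length) + cfg.margin
    z_lo = geom.z_bottom - cfg.margin
    z_hi = geom.z_top + cfg.margin

    dx = dy = cfg.in_plane
    dz = cfg.slice_thickness
    nx = int(np.ceil((x_hi - x_lo) / dx))
    ny = int(np.ceil(2 * y_hi / dy))
    nz = int(np.ceil((z_hi - z_lo) / dz))
    origin = np.array([x_lo + 0.5 * dx, -y_hi + 0.5 * dy, z_lo + 0.5 * dz])
    spacing = np.array([dx, dy, dz])

    xs = origin[0] + dx * np.arange(nx)
    ys = origin[1] + dy * np.arange(ny)
    zs = origin[2] + dz * np.arange(nz)
    X, Y = np.meshgrid(xs, ys, indexing="ij")

    hu = np.full((nx, ny, nz), cfg.air_hu, dtype=np.float32)
    lab = np.zeros((nx, ny, nz), dtype=np.int16)

    # Phantom: two cylinders (axis along y) below the posterior body wall,
    # separated along z - mirrors a reference phantom lying in the scanner
    # mat beneath a supine subject.
    z_span = geom.z_top - geom.z_bottom
    z_bone = geom.z_bottom + 0.3 * z_span
    z_water = geom.z_bottom + 0.7 * z_span
    half_len = 0.5 * cfg.phantom_length
    for z_c, label, ins_hu in (
        (z_bone, LABEL_PHANTOM_BONE, cfg.insert_hu_bone),
        (z_water, LABEL_PHANTOM_WATER, cfg.insert_hu_water),
    ):
        for k, z in enumerate(zs):
            r2 = (X - x_phantom) ** 2 + (z - z_c) ** 2
            inside = (r2 <= cfg.phantom_radius**2) & (np.abs(Y) <= half_len)
            hu[:, :, k][inside] = ins_hu
            lab[:, :, k][inside] = label

    # Anatomy, slice by slice.  The cortical shell is a thin ring on the
    # body wall; bony endplates are not modelled separately (see methods).
    trab_mask = np.zeros((nx, ny, nz), dtype=bool)
    for k, z in enumerate(zs):
        seg = geom.segment_at(z)
        # paraspinal soft-tissue envelope: a real scan embeds the spine in
        # muscle/fat, so the bone boundary must never mix with air
        m = cfg.soft_tissue_margin
        if m > 0 and geom.z_bottom - m <= z <= geom.z_top + m:
            z_c = float(np.clip(z, geom.z_bottom, geom.z_top - 1e-9))
            ab = geom.semi_axes_at(z_c)
            if ab is not None:
                a_env, b_env = ab[0] + m, ab[1] + m
                env = ((X / a_env) ** 2 + (Y / b_env) ** 2 <= 1.0) & (
                    lab[:, :, k] == LABEL_BACKGROUND
                )
                hu[:, :, k][env] = cfg.soft_tissue_hu
        if seg is None:
            continue
        kind, obj = seg
        if kind == "vertebra":
            a, b = obj.a_ap, obj.a_ml
            t = obj.shell_thickness
            outer = (X / a) ** 2 + (Y / b) ** 2 <= 1.0
            inner = (X / max(a - t, 1e-6)) ** 2 + (Y / max(b - t, 1e-6)) ** 2 <= 1.0
            shell = outer & ~inner
            trab = outer & inner
            sl_hu = hu[:, :, k]
            sl_hu[shell] = cfg.shell_hu
            sl_hu[trab] = mu
            trab_mask[:, :, k] = trab
            lab[:, :, k][outer] = LABEL_VERTEBRA[obj.level]
        else:  # disc
            a, b = obj.semi_axes_at(z)
            fr = np.sqrt(obj.nucleus_fraction)
            outer = (X / a) ** 2 + (Y / b) ** 2 <= 1.0
            nucleus = (X / (fr * a)) ** 2 + (Y / (fr * b)) ** 2 <= 1.0
            sl_hu = hu[:, :, k]
            sl_hu[outer & ~nucleus] = cfg.annulus_hu
            sl_hu[outer & nucleus] = cfg.nucleus_hu
            sl_lab = lab[:, :, k]
            sl_lab[outer & ~nucleus] = LABEL_ANNULUS
            sl_lab[outer & nucleus] = LABEL_NUCLEUS

    if noise_sd > 0:
        noisy = trab_mask.copy()
        if cfg.noise_on_inserts:
            noisy |= np.isin(lab, [LABEL_PHANTOM_BONE, LABEL_PHANTOM_WATER])
        hu[noisy] += rng.normal(0.0, noise_sd, size=int(noisy.sum())).astype(
            np.float32
        )

    vol = CTVolume(data=hu, spacing=spacing, origin=origin)
    mask = LabelMask(data=lab, spacing=spacing, origin=origin)
    for level, code in LABEL_VERTEBRA.items():
        if mask.count(code) == 0:
            raise CTSynthesisError(f"vertebra {level} rasterized to zero voxels")
    return vol, mask
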