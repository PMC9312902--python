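"""HU-driven material mapping for vertebral bone, plus disc constants.

Bone follows the densitometric power-law chain

    rho_app [kg/m^3] = 47 + 1.122 * HU          (HU clamped at 0)
    rho_ash           = 0.6 * rho_app
    Ez [MPa]          = 4730 * rho_app^1.56     (rho_app in g/cm^3)
    Ex = Ey = 0.333 Ez;  Gxy = 0.121 Ez;  Gxz = Gyz = 0.157 Ez
    nu_xy = 0.381;  nu_xz = nu_yz = 0.104
    sigma_max [MPa]   = 137 * rho_ash^1.88  (rho_ash < 0.317 g/cm^3)
                      = 114 * rho_ash^1.72  (rho_ash > 0.317 g/cm^3)
    eps_AB            = -0.00315 + 0.0728 * rho_ash   (clamped >= 1e-6)
    sigma_min [MPa]   = 65.1 * rho_ash^1.93

Densities are stored in kg/m^3 but every power law evaluates with the density
expressed in g/cm^3, which is the unit system in which the literature
coefficients (4730, 137, 114, 65.1) produce megapascals.  The bone fabric is
transversely isotropic with the symmetry (z) axis along the global spine
axial direction.  Discs are linear elastic and isotropic: annulus E = 25 MPa,
nucleus E = 1 MPa, both with nu = 0.49.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .ct import CTVolume
from .errors import MaterialError

# Fixed anisotropy ratios of vertebral bone.
EX_RATIO = 0.333
GXY_RATIO = 0.121
GXZ_RATIO = 0.157
NU_XY = 0.381
NU_XZ = 0.104

SIGMA_BREAK = 0.317  # g/cm^3, strength-law branch point
EPS_AB_FLOOR = 1e-6

#: Region codes on mesh elements (shared with ct label codes 6/7 for discs).
REGION_BONE = 1
REGION_ANNULUS = 6
REGION_NUCLEUS = 7

DISC_CONSTANTS = {
    REGION_ANNULUS: {"E": 25.0, "nu": 0.49, "density_ton_mm3": 1.20e-9},
    REGION_NUCLEUS: {"E": 1.0, "nu": 0.49, "density_ton_mm3": 1.00e-9},
}


def apparent_density(hu, hu_floor: float = 0.0):
    """rho_app in kg/m^3 from HU; HU below ``hu_floor`` is clamped.

    The clamp guards against partial-volume voxels with negative HU inside
    the bone label, which would otherwise map to a non-physical density.
    """
    hu = np.maximum(np.asarray(hu, dtype=float), hu_floor)
    return 47.0 + 1.122 * hu


def ash_density(rho_app):
    """rho_ash = 0.6 * rho_app (kg/m^3 in, kg/m^3 out)."""
    rho_app = np.asarray(rho_app, dtype=float)
    if np.any(rho_app < 0):
        raise MaterialError("apparent density must be >= 0")
    return 0.6 * rho_app


def elastic_constants(rho_app):
    """Transversely isotropic elastic constants from rho_app (kg/m^3).

    Returns a dict with Ez, Ex, Ey, Gxy, Gxz, Gyz (MPa) and the Poisson
    ratios; every modulus is an exact fixed ratio of Ez.
    """
    rho_app = np.asarray(rho_app, dtype=float)
    if np.any(rho_app <= 0):
        raise MaterialError("apparent density must be > 0 for the modulus law")
    rho_g = rho_app / 1000.0  # kg/m^3 -> g/cm^3
    ez = 4730.0 * rho_g**1.56
    return {
        "Ez": ez,
        "Ex": EX_RATIO * ez,
        "Ey": EX_RATIO * ez,
        "Gxy": GXY_RATIO * ez,
        "Gxz": GXZ_RATIO * ez,
        "Gyz": GXZ_RATIO * ez,
        "nu_xy": np.full_like(ez, NU_XY),
        "nu_xz": np.full_like(ez, NU_XZ),
        "nu_yz": np.full_like(ez, NU_XZ),
    }


def strength_limits(rho_ash):
    """(sigma_max, eps_AB, sigma_min) from rho_ash (kg/m^3).

    sigma_max is the piecewise maximum-principal-stress limit; sigma_min is
    returned as a positive magnitude for the minimum-principal (compressive)
    limit; eps_AB is the plastic strain, clamped at a small positive floor
    because the linear law goes negative below 0.0433 g/cm^3.
    """
    rho_ash = np.asarray(rho_ash, dtype=float)
    if np.any(rho_ash <= 0):
        raise MaterialError("ash density must be > 0 for the strength laws")
    r = rho_ash / 1000.0  # g/cm^3
    sigma_max = np.where(r < SIGMA_BREAK, 137.0 * r**1.88, 114.0 * r**1.72)
    eps_ab = np.maximum(-0.00315 + 0.0728 * r, EPS_AB_FLOOR)
    sigma_min = 65.1 * r**1.93
    return sigma_max, eps_ab, sigma_min


def transverse_isotropic_compliance_unit() -> np.ndarray:
    """Compliance matrix (Voigt: xx yy zz yz xz xy) for Ez = 1 MPa.

    Because every modulus is a fixed multiple of Ez, the whole compliance
    scales as 1/Ez; the stiffness of any bone element is Ez times the
    inverse of this matrix.
    """
    ex = EX_RATIO
    s = np.zeros((6, 6))
    s[0, 0] = s[1, 1] = 1.0 / ex
    s[2, 2] = 1.0
    s[0, 1] = s[1, 0] = -NU_XY / ex
    # nu_xz: transverse strain in z under in-plane load
    s[0, 2] = s[2, 0] = -NU_XZ / ex
    s[1, 2] = s[2, 1] = -NU_XZ / ex
    s[3, 3] = 1.0 / GXZ_RATIO  # yz
    s[4, 4] = 1.0 / GXZ_RATIO  # xz
    s[5, 5] = 1.0 / GXY_RATIO  # xy
    return s


_C_UNIT_BONE = np.linalg.inv(transverse_isotropic_compliance_unit())


def isotropic_stiffness(E: float, nu: float) -> np.ndarray:
    """Isotropic elasticity matrix (Voigt, engineering shear strains)."""
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    c = np.zeros((6, 6))
    c[:3, :3] = lam
    c[np.diag_indices(3)] = lam + 2 * mu
    c[3, 3] = c[4, 4] = c[5, 5] = mu
    return c


@dataclass
class MaterialCard:
    """Per-element material state for a tetrahedral mesh.

    Bone elements carry the full densitometric chain (HU, densities, Ez,
    strength limits, plastic strain); disc elements carry the constant
    annulus/nucleus properties and have NaN densities.
    """

    region: np.ndarray  # element region code
    hu: np.ndarray
    rho_app: np.ndarray  # kg/m^3 (NaN for discs)
    rho_ash: np.ndarray
    Ez: np.ndarray  # MPa; for discs this is the isotropic E
    sigma_max: np.ndarray  # MPa (inf for discs: discs do not damage)
    sigma_min: np.ndarray  # MPa, positive magnitude
    eps_ab: np.ndarray
    #: explicit per-element elasticity matrices; overrides the bone/disc
    #: constitutive rules when set (verification fixtures, custom materials)
    C_override: np.ndarray | None = None

    @property
    def n_elements(self) -> int:
        return self.region.size

    @property
    def is_bone(self) -> np.ndarray:
        return self.region == REGION_BONE

    def elasticity(self) -> np.ndarray:
        """(n_elements, 6, 6) elasticity matrices in the global frame.

        The bone symmetry axis coincides with the global z (spine axial)
        direction, so no per-element rotation is needed.
        """
        n = self.n_elements
        if self.C_override is not None:
            C = np.asarray(self.C_override, dtype=float)
            if C.shape == (6, 6):
                C = np.broadcast_to(C, (n, 6, 6)).copy()
            return C
        C = np.empty((n, 6, 6))
        bone = self.is_bone
        C[bone] = self.Ez[bone, None, None] * _C_UNIT_BONE
        for code, props in DISC_CONSTANTS.items():
            sel = self.region == code
            if sel.any():
                C[sel] = isotropic_stiffness(props["E"], props["nu"])
        other = ~bone & ~np.isin(self.region, list(DISC_CONSTANTS))
        if other.any():
            raise MaterialError(
                f"elements with unknown region codes: {np.unique(self.region[other])}"
            )
        return C

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "region": self.region, "hu": self.hu, "rho_app": self.rho_app,
            "rho_ash": self.rho_ash, "Ez": self.Ez,
            "sigma_max": self.sigma_max, "sigma_min": self.sigma_min,
            "eps_ab": self.eps_ab,
        })


def bone_card_from_hu(hu: np.ndarray) -> dict[str, np.ndarray]:
    """Evaluate the full bone chain for an HU array (clamped at 0)."""
    rho_app = apparent_density(hu)
    rho_ash = ash_density(rho_app)
    elastic = elastic_constants(rho_app)
    sigma_max, eps_ab, sigma_min = strength_limits(rho_ash)
    return {
        "rho_app": rho_app, "rho_ash": rho_ash, "Ez": elastic["Ez"],
        "sigma_max": sigma_max, "sigma_min": sigma_min, "eps_ab": eps_ab,
    }


def _sample_hu(vol: CTVolume, points: np.ndarray) -> np.ndarray:
    """Trilinear HU interpolation at world points (mm)."""
    idx = vol.world_to_index(points).T  # (3, n)
    lo = idx.min(axis=1)
    hi = (np.asarray(vol.shape)[:, None] - 1 - idx).min(axis=1)
    if lo.min() < -0.5 or hi.min() < -0.5:
        bad = np.argmax(
            np.any((idx < -0.5) | (idx > np.asarray(vol.shape)[:, None] - 0.5), axis=0)
        )
        raise MaterialError(f"element {bad}: sample point outside the CT volume")
    # points within half a voxel of the border are clamped onto it
    return ndimage.map_coordinates(
        vol.data.astype(float), np.clip(idx, 0, np.asarray(vol.shape)[:, None] - 1),
        order=1, mode="nearest",
    )


def mask_guided_hu(vol: CTVolume, mask) -> CTVolume:
    """HU volume with every non-bone voxel replaced by its nearest bone HU.

    Material mapping samples element HU by interpolation; near the endplates
    and the body wall that interpolation would mix trabecular bone with disc,
    soft tissue or air (partial volume), mapping spuriously weak endplate
    layers.  Restricting the sample support to the segmented bone (the
    mask-guided practice of CT material-mapping pipelines) removes that
    artifact.
    """
    from scipy import ndimage as ndi

    bone_vox = np.isin(mask.data, list(range(1, 6)))  # L1..L5 labels
    if not bone_vox.any():
        raise MaterialError("mask contains no vertebra labels")
    idx = ndi.distance_transform_edt(
        ~bone_vox, sampling=vol.spacing, return_distances=False,
        return_indices=True,
    )
    filled = vol.data[tuple(idx)]
    return CTVolume(data=filled, spacing=vol.spacing, origin=vol.origin)


def map_materials(mesh, vol: CTVolume, mode: str = "centroid",
                  mask=None) -> MaterialCard:
    """Assign a material card to every element of a tetrahedral mesh.

    Bone elements sample HU from the volume - at the element centroid by
    default, or averaged over the four vertices plus centroid with
    ``mode='volume'`` (a cheap volume-integration variant).  When a label
    mask is given, bone sampling is restricted to bone-labeled voxels (see
    :func:`mask_guided_hu`).  Annulus and nucleus elements always receive
    the constant disc properties regardless of the underlying HU.
    """
    if mode not in ("centroid", "volume"):
        raise MaterialError(f"unknown HU sampling mode {mode!r}")
    region = np.where(
        np.isin(mesh.region, (REGION_ANNULUS, REGION_NUCLEUS)),
        mesh.region, REGION_BONE,
    )
    n = region.size
    coords = mesh.nodes[mesh.elems]  # (n, 4, 3)
    centroids = coords.mean(axis=1)

    hu = np.zeros(n)
    bone = region == REGION_BONE
    if bone.any():
        bone_vol = mask_guided_hu(vol, mask) if mask is not None else vol
        if mode == "centroid":
            hu_bone = _sample_hu(bone_vol, centroids[bone])
        else:
            pts = np.concatenate(
                [coords[bone].reshape(-1, 3), centroids[bone]], axis=0
            )
            samples = _sample_hu(bone_vol, pts)
            nb = int(bone.sum())
            hu_bone = 0.5 * samples[: 4 * nb].reshape(nb, 4).mean(axis=1) + \
                0.5 * samples[4 * nb:]
        hu[bone] = np.maximum(hu_bone, 0.0)

    rho_app = np.full(n, np.nan)
    rho_ash = np.full(n, np.nan)
    Ez = np.empty(n)
    sigma_max = np.full(n, np.inf)
    sigma_min = np.full(n, np.inf)
    eps_ab = np.full(n, np.nan)

    if bone.any():
        chain = bone_card_from_hu(hu[bone])
        rho_app[bone] = chain["rho_app"]
        rho_ash[bone] = chain["rho_ash"]
        Ez[bone] = chain["Ez"]
        sigma_max[bone] = chain["sigma_max"]
        sigma_min[bone] = chain["sigma_min"]
        eps_ab[bone] = chain["eps_ab"]
    for code, props in DISC_CONSTANTS.items():
        sel = region == code
        Ez[sel] = props["E"]

    return MaterialCard(
        region=region, hu=hu, rho_app=rho_app, rho_ash=rho_ash, Ez=Ez,
        sigma_max=sigma_max, sigma_min=sigma_min, eps_ab=eps_ab,
    )
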