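"""Parametric lumbar spine geometry (L1-L5) with discs and ligament anchors.

The model is a stand-in for patient anatomy: five vertebral bodies with an
elliptical cross-section and a thin cortical shell, four intervertebral discs
(annulus fibrosus + nucleus pulposus, the nucleus holding 30 % of the disc
cross-sectional area), and simplified posterior-element landmarks that carry
the attachment points of the seven spinal ligaments (ALL, PLL, LF, ISL, SSL,
ITL, FCL).

Coordinate frame (used everywhere in the package): millimetres, right-handed,
+z axial (superior), +x anterior, +y left.  z = 0 is the inferior endplate of
L5; levels are stacked bottom-up so L1 sits on top.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError, ValidationError

LEVELS = ("L1", "L2", "L3", "L4", "L5")
MOTION_SEGMENTS = (("L1", "L2"), ("L2", "L3"), ("L3", "L4"), ("L4", "L5"))

# Ligament material constants: Young's modulus (MPa), Poisson ratio,
# circular cross-sectional area (mm^2), number of parallel cables per
# spanned segment, density (ton/mm^3).
LIGAMENT_TABLE: dict[str, dict[str, float]] = {
    "ALL": {"E": 55.77, "nu": 0.4, "area": 32.4, "count": 3, "density": 1e-9},
    "PLL": {"E": 54.43, "nu": 0.4, "area": 5.2, "count": 3, "density": 1e-9},
    "LF": {"E": 3.25, "nu": 0.4, "area": 84.2, "count": 3, "density": 1e-9},
    "ISL": {"E": 2.23, "nu": 0.4, "area": 35.1, "count": 4, "density": 1e-9},
    "SSL": {"E": 12.80, "nu": 0.4, "area": 25.2, "count": 2, "density": 1e-9},
    "ITL": {"E": 11.50, "nu": 0.4, "area": 12.0, "count": 4, "density": 1e-9},
    "FCL": {"E": 8.69, "nu": 0.4, "area": 43.8, "count": 6, "density": 1e-9},
}

LIGAMENT_TYPES = tuple(LIGAMENT_TABLE)

#: Valid ranges for anthropometric parameters (desk-scale model, see docs).
PARAM_BOUNDS: dict[str, tuple[float, float]] = {
    "body_ap": (4.0, 30.0),
    "body_ml": (5.0, 35.0),
    "body_height": (8.0, 40.0),
    "disc_height": (2.0, 15.0),
    "shell_thickness": (0.2, 3.0),
    "nucleus_fraction": (0.05, 0.60),
    "level_gradient": (0.0, 0.10),
    "jitter": (0.0, 0.10),
    "posterior_scale": (0.3, 3.0),
}


@dataclass(frozen=True)
class AnthropometricParams:
    """Anthropometry of the synthetic lumbar spine.

    Defaults describe the package's desk-scale reference subject; they were
    calibrated once so that the coarse-mesh healthy-cohort failure loads fall
    inside the experimental plausibility range (see docs/methods.md).

    Parameters
    ----------
    body_ap, body_ml : float
        Anterior-posterior / medio-lateral semi-axes of the L1 vertebral body
        cross-section (mm).  More caudal levels grow by ``level_gradient``.
    body_height : float
        Vertebral body height (mm).
    disc_height : float
        Intervertebral disc height (mm).
    shell_thickness : float
        Cortical shell thickness (mm), applied on the ring and endplates.
    nucleus_fraction : float
        Nucleus cross-sectional area as a fraction of the whole disc area.
    level_gradient : float
        Relative per-level caudal growth of the body semi-axes.
    jitter : float
        Relative s.d. of the seeded per-level random size perturbation.
    posterior_scale : float
        Scales all posterior-element landmark offsets.
    """

    body_ap: float = 13.9
    body_ml: float = 17.8
    body_height: float = 18.0
    disc_height: float = 6.0
    shell_thickness: float = 0.4
    nucleus_fraction: float = 0.30
    level_gradient: float = 0.02
    jitter: float = 0.03
    posterior_scale: float = 1.0

    def __post_init__(self):
        for name, (lo, hi) in PARAM_BOUNDS.items():
            value = getattr(self, name)
            if not np.isfinite(value) or not (lo <= value <= hi):
                raise ValidationError(
                    f"parameter '{name}' = {value!r} outside physiologic "
                    f"bounds [{lo}, {hi}]"
                )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AnthropometricParams":
        return cls(**d)


def ellipse_polygon(a: float, b: float, n: int = 128) -> np.ndarray:
    """Closed polygon (n, 2) approximating an ellipse with semi-axes a, b."""
    t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    return np.column_stack([a * np.cos(t), b * np.sin(t)])


def polygon_area(poly: np.ndarray) -> float:
    """Shoelace area of a closed polygon given as (n, 2) vertices."""
    x, y = poly[:, 0], poly[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


@dataclass(frozen=True)
class VertebraGeometry:
    """One vertebral body plus simplified posterior-element landmarks."""

    level: str
    a_ap: float
    a_ml: float
    height: float
    shell_thickness: float
    z_inferior: float
    posterior_scale: float = 1.0

    @property
    def z_superior(self) -> float:
        return self.z_inferior + self.height

    @property
    def z_center(self) -> float:
        return self.z_inferior + 0.5 * self.height

    @property
    def cross_section_area(self) -> float:
        return np.pi * self.a_ap * self.a_ml

    def outline(self, n: int = 128) -> np.ndarray:
        return ellipse_polygon(self.a_ap, self.a_ml, n)

    @property
    def landmarks(self) -> dict[str, np.ndarray]:
        """Posterior-element landmark points (mm, global frame).

        The posterior elements are not meshed as solids; these points only
        define where ligament cables anchor and where the facet patches sit.
        """
        a, s = self.a_ap, self.posterior_scale
        zc, zi, zs = self.z_center, self.z_inferior, self.z_superior
        pts = {
            "posterior_wall": (-a, 0.0, zc),
            "pedicle_l": (-(a + 2.0 * s), 0.45 * self.a_ml, zc),
            "pedicle_r": (-(a + 2.0 * s), -0.45 * self.a_ml, zc),
            "transverse_l": (-(a + 4.0 * s), self.a_ml + 8.0 * s, zc),
            "transverse_r": (-(a + 4.0 * s), -(self.a_ml + 8.0 * s), zc),
            "lamina_l": (-(a + 7.0 * s), 3.5 * s, zc),
            "lamina_c": (-(a + 7.0 * s), 0.0, zc),
            "lamina_r": (-(a + 7.0 * s), -3.5 * s, zc),
            "spinous": (-(a + 14.0 * s), 0.0, zc - 0.2 * self.height),
            "facet_sup_l": (-(a + 5.0 * s), 0.55 * self.a_ml, zs - 1.0),
            "facet_sup_r": (-(a + 5.0 * s), -0.55 * self.a_ml, zs - 1.0),
            "facet_inf_l": (-(a + 5.0 * s), 0.55 * self.a_ml, zi + 1.0),
            "facet_inf_r": (-(a + 5.0 * s), -0.55 * self.a_ml, zi + 1.0),
        }
        return {k: np.asarray(v, dtype=float) for k, v in pts.items()}


@dataclass(frozen=True)
class DiscGeometry:
    """One intervertebral disc between two adjacent vertebrae.

    The cross-section tapers linearly from the superior endplate outline of
    the lower vertebra to the inferior endplate outline of the upper vertebra,
    so an extruded mesh is conforming at both interfaces.  The nucleus outline
    is the outer outline scaled by sqrt(nucleus_fraction) about the section
    centroid, which makes the nucleus/disc area ratio exact by construction.
    """

    gap: int  # 0 = L1-L2 ... 3 = L4-L5
    upper_level: str
    lower_level: str
    z_inferior: float
    height: float
    a_ap_inf: float
    a_ml_inf: float
    a_ap_sup: float
    a_ml_sup: float
    nucleus_fraction: float = 0.30

    @property
    def z_superior(self) -> float:
        return self.z_inferior + self.height

    def semi_axes_at(self, z: float) -> tuple[float, float]:
        t = np.clip((z - self.z_inferior) / self.height, 0.0, 1.0)
        return (
            (1 - t) * self.a_ap_inf + t * self.a_ap_sup,
            (1 - t) * self.a_ml_inf + t * self.a_ml_sup,
        )

    def annulus_outline(self, z: float | None = None, n: int = 128) -> np.ndarray:
        if z is None:
            z = self.z_inferior + 0.5 * self.height
        a, b = self.semi_axes_at(z)
        return ellipse_polygon(a, b, n)

    def nucleus_outline(self, z: float | None = None, n: int = 128) -> np.ndarray:
        return np.sqrt(self.nucleus_fraction) * self.annulus_outline(z, n)

    def disc_area(self, z: float | None = None) -> float:
        if z is None:
            z = self.z_inferior + 0.5 * self.height
        a, b = self.semi_axes_at(z)
        return np.pi * a * b

    def nucleus_area(self, z: float | None = None) -> float:
        return self.nucleus_fraction * self.disc_area(z)


@dataclass
class SpineGeometry:
    """Full L1-L5 geometry: 5 vertebral bodies, 4 discs, axial direction."""

    vertebrae: list[VertebraGeometry]  # ordered L1 (top) .. L5 (bottom)
    discs: list[DiscGeometry]  # ordered L1-L2 .. L4-L5
    params: AnthropometricParams
    seed: int = 0
    axial: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    def __post_init__(self):
        self.validate()

    @property
    def z_bottom(self) -> float:
        return self.vertebrae[-1].z_inferior

    @property
    def z_top(self) -> float:
        return self.vertebrae[0].z_superior

    @property
    def total_height(self) -> float:
        return self.z_top - self.z_bottom

    def vertebra(self, level: str) -> VertebraGeometry:
        for v in self.vertebrae:
            if v.level == level:
                return v
        raise GeometryError(f"unknown vertebral level {level!r}")

    def segment_at(self, z: float):
        """Classify an axial station: ('vertebra', obj) | ('disc', obj) | None."""
        for v in self.vertebrae:
            if v.z_inferior <= z < v.z_superior:
                return ("vertebra", v)
        for d in self.discs:
            if d.z_inferior <= z < d.z_superior:
                return ("disc", d)
        return None

    def semi_axes_at(self, z: float) -> tuple[float, float] | None:
        seg = self.segment_at(z)
        if seg is None:
            return None
        kind, obj = seg
        if kind == "vertebra":
            return (obj.a_ap, obj.a_ml)
        return obj.semi_axes_at(z)

    def validate(self) -> None:
        if len(self.vertebrae) != 5 or len(self.discs) != 4:
            raise GeometryError(
                f"expected 5 vertebrae and 4 discs, got "
                f"{len(self.vertebrae)} / {len(self.discs)}"
            )
        for v in self.vertebrae:
            for name in ("a_ap", "a_ml", "height", "shell_thickness"):
                if getattr(v, name) <= 0:
                    raise GeometryError(f"{v.level}.{name} must be > 0")
            if v.shell_thickness >= 0.5 * min(v.a_ap, v.a_ml):
                raise GeometryError(
                    f"{v.level}: cortical shell thicker than trabecular core"
                )
        for d in self.discs:
            if d.height <= 0:
                raise GeometryError(f"disc {d.upper_level}-{d.lower_level}: height <= 0")
            ratio = polygon_area(d.nucleus_outline()) / polygon_area(d.annulus_outline())
            if abs(ratio - d.nucleus_fraction) > 0.005:
                raise GeometryError(
                    f"disc {d.upper_level}-{d.lower_level}: nucleus/disc area "
                    f"ratio {ratio:.4f} deviates from {d.nucleus_fraction}"
                )
            # nucleus strictly inside annulus
            if np.sqrt(d.nucleus_fraction) >= 1.0:
                raise GeometryError("nucleus outline not inside annulus outline")

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "seed": self.seed,
            "axial": self.axial.tolist(),
            "vertebrae": [
                {k: getattr(v, k) for k in (
                    "level", "a_ap", "a_ml", "height", "shell_thickness",
                    "z_inferior", "posterior_scale")}
                for v in self.vertebrae
            ],
            "discs": [
                {k: getattr(d, k) for k in (
                    "gap", "upper_level", "lower_level", "z_inferior", "height",
                    "a_ap_inf", "a_ml_inf", "a_ap_sup", "a_ml_sup",
                    "nucleus_fraction")}
                for d in self.discs
            ],
        }

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "SpineGeometry":
        return cls(
            vertebrae=[VertebraGeometry(**v) for v in d["vertebrae"]],
            discs=[DiscGeometry(**x) for x in d["discs"]],
            params=AnthropometricParams.from_dict(d["params"]),
            seed=d.get("seed", 0),
            axial=np.asarray(d.get("axial", [0.0, 0.0, 1.0])),
        )

    @classmethod
    def load_json(cls, path) -> "SpineGeometry":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def build_spine_geometry(
    params: AnthropometricParams | None = None,
    seed: int = 0,
    nucleus_fraction: float | None = None,
) -> SpineGeometry:
    """Construct a seeded synthetic L1-L5 geometry.

    The per-level dimensions are the anthropometric defaults scaled by a
    caudal growth gradient and a small seeded jitter (clipped at 2.5 sigma),
    so distinct seeds give distinct but bounded subjects and the same seed
    reproduces the geometry bit-for-bit.
    """
    params = params or AnthropometricParams()
    if nucleus_fraction is not None:
        params = dataclasses.replace(params, nucleus_fraction=nucleus_fraction)
    rng = np.random.default_rng(seed)

    def jittered(base: float) -> float:
        g = np.clip(rng.standard_normal(), -2.5, 2.5)
        return base * (1.0 + params.jitter * g)

    vertebrae: list[VertebraGeometry] = []
    disc_heights: list[float] = []
    for i, level in enumerate(LEVELS):
        grow = 1.0 + params.level_gradient * i
        vertebrae.append(
            VertebraGeometry(
                level=level,
                a_ap=jittered(params.body_ap * grow),
                a_ml=jittered(params.body_ml * grow),
                height=jittered(params.body_height),
                shell_thickness=params.shell_thickness,
                z_inferior=0.0,  # assigned after stacking
                posterior_scale=params.posterior_scale,
            )
        )
        if i < 4:
            disc_heights.append(jittered(params.disc_height))

    # Stack bottom-up: L5 inferior endplate at z = 0.
    z = 0.0
    stacked: list[VertebraGeometry] = []
    discs: list[DiscGeometry] = []
    for i in range(4, -1, -1):
        v = dataclasses.replace(vertebrae[i], z_inferior=z)
        stacked.append(v)
        z = v.z_superior
        if i > 0:
            upper = vertebrae[i - 1]
            discs.append(
                DiscGeometry(
                    gap=i - 1,
                    upper_level=upper.level,
                    lower_level=v.level,
                    z_inferior=z,
                    height=disc_heights[i - 1],
                    a_ap_inf=v.a_ap,
                    a_ml_inf=v.a_ml,
                    a_ap_sup=upper.a_ap,
                    a_ml_sup=upper.a_ml,
                    nucleus_fraction=params.nucleus_fraction,
                )
            )
            z += disc_heights[i - 1]

    stacked.reverse()  # L1 first
    discs.reverse()  # L1-L2 first
    return SpineGeometry(vertebrae=stacked, discs=discs, params=params, seed=seed)


@dataclass(frozen=True)
class LigamentCable:
    """A single tension-only wire element spanning one motion segment."""

    ltype: str
    E: float  # MPa
    nu: float
    area: float  # mm^2
    p_upper: np.ndarray  # attachment on the upper vertebra (mm)
    p_lower: np.ndarray  # attachment on the lower vertebra (mm)
    gap: int
    upper_level: str
    lower_level: str

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.p_upper - self.p_lower))

    @property
    def stiffness(self) -> float:
        """Axial stiffness EA/L in N/mm."""
        return self.E * self.area / self.length


@dataclass
class LigamentSet:
    """All ligament cables of one spine, with the material constants."""

    cables: list[LigamentCable]

    def __len__(self) -> int:
        return len(self.cables)

    def count_by_type(self, gap: int | None = None) -> dict[str, int]:
        out = {t: 0 for t in LIGAMENT_TYPES}
        for c in self.cables:
            if gap is None or c.gap == gap:
                out[c.ltype] += 1
        return out

    def validate(self) -> None:
        expected = {t: int(LIGAMENT_TABLE[t]["count"]) for t in LIGAMENT_TYPES}
        for gap in range(4):
            got = self.count_by_type(gap)
            if got != expected:
                raise GeometryError(
                    f"segment {gap}: ligament counts {got} != table {expected}"
                )
        for c in self.cables:
            if c.length <= 1e-9:
                raise GeometryError(
                    f"zero-length {c.ltype} cable at segment {c.gap}"
                )


def _on_ellipse(v: VertebraGeometry, theta: float, z: float) -> np.ndarray:
    return np.array([v.a_ap * np.cos(theta), v.a_ml * np.sin(theta), z])


def place_ligaments(geom: SpineGeometry) -> LigamentSet:
    """Anchor the seven ligament types on every motion segment.

    ALL runs on the anterior body wall, PLL on the posterior body wall, LF
    between laminae, ISL along the interspinous line, SSL between spinous
    tips, ITL between transverse-process tips and FCL across the facet
    patches.  Cable counts per segment follow the ligament table exactly.
    """
    cables: list[LigamentCable] = []
    inset = 1.0  # mm below/above the endplates adjacent to the disc

    for gap, (up_level, low_level) in enumerate(MOTION_SEGMENTS):
        up = geom.vertebra(up_level)
        low = geom.vertebra(low_level)
        z_u = up.z_inferior + inset
        z_l = low.z_superior - inset
        lm_u, lm_l = up.landmarks, low.landmarks

        def add(ltype: str, pu: np.ndarray, pl: np.ndarray):
            props = LIGAMENT_TABLE[ltype]
            cable = LigamentCable(
                ltype=ltype, E=props["E"], nu=props["nu"], area=props["area"],
                p_upper=np.asarray(pu, float), p_lower=np.asarray(pl, float),
                gap=gap, upper_level=up_level, lower_level=low_level,
            )
            if cable.length <= 1e-9:
                raise GeometryError(
                    f"coincident attachment points for {ltype} at segment "
                    f"{up_level}-{low_level}"
                )
            cables.append(cable)

        # ALL: three cables fanned over the anterior wall
        for th in (-0.45, 0.0, 0.45):
            add("ALL", _on_ellipse(up, th, z_u), _on_ellipse(low, th, z_l))
        # PLL: three cables on the posterior wall
        for th in (np.pi - 0.35, np.pi, np.pi + 0.35):
            add("PLL", _on_ellipse(up, th, z_u), _on_ellipse(low, th, z_l))
        # LF: between laminae (left, centre, right)
        for name in ("lamina_l", "lamina_c", "lamina_r"):
            if name not in lm_u or name not in lm_l:
                raise GeometryError(f"missing landmark {name!r}")
            pu, pl = lm_u[name].copy(), lm_l[name].copy()
            pu[2], pl[2] = z_u, z_l
            add("LF", pu, pl)
        # ISL: four cables along the lamina->spinous-tip line
        for frac in (0.2, 0.45, 0.7, 0.95):
            pu = (1 - frac) * lm_u["lamina_c"] + frac * lm_u["spinous"]
            pl = (1 - frac) * lm_l["lamina_c"] + frac * lm_l["spinous"]
            pu, pl = pu.copy(), pl.copy()
            pu[2], pl[2] = z_u, z_l
            add("ISL", pu, pl)
        # SSL: two cables between the spinous tips
        for dy in (1.0, -1.0):
            pu = lm_u["spinous"] + np.array([0.0, dy, 0.0])
            pl = lm_l["spinous"] + np.array([0.0, dy, 0.0])
            add("SSL", pu, pl)
        # ITL: two cables per transverse process
        for side in ("transverse_l", "transverse_r"):
            for dy in (1.0, -1.0):
                pu = lm_u[side] + np.array([0.0, dy, 0.0])
                pl = lm_l[side] + np.array([0.0, dy, 0.0])
                add("ITL", pu, pl)
        # FCL: three cables per facet joint (left and right)
        for side in ("l", "r"):
            fu = lm_u[f"facet_inf_{side}"]
            fl = lm_l[f"facet_sup_{side}"]
            for dy in (-1.5, 0.0, 1.5):
                add("FCL", fu + np.array([0.0, dy, 0.0]),
                    fl + np.array([0.0, dy, 0.0]))

    lset = LigamentSet(cables=cables)
    lset.validate()
    return lset
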