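"""Load-case drivers: compression to failure and pure-moment range of motion.

Failure is modelled as quasi-brittle element damage: at every displacement
increment the linear system is solved, element principal stresses are
recovered, and bone elements whose maximum principal stress exceeds the
tensile limit or whose minimum principal stress exceeds the compressive limit
(in magnitude) lose their stiffness (scaled by a knock-down factor).  The
inner loop repeats until no new element fails at that increment; the peak of
the resulting load-displacement curve is the failure load (FL).

Because the solver is linear and the compression case is driven purely by a
prescribed master displacement, the solution for a fixed damage state scales
linearly with the imposed displacement; the driver exploits this and only
refactorizes when the damage state or the active ligament set changes.

Range of motion applies a pure moment (default 7.5 N*m) about the motion
axis to the superior master point; the reported angle is the master-point
rotation in degrees.  Damage is disabled for ROM (kinematics only).
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np

from .config import RunConfig
from .ct import CTVolume, LabelMask, LABEL_VERTEBRA, LABEL_ANNULUS, LABEL_NUCLEUS
from .densitometry import SubjectBMD, subject_bmd
from .errors import FENonConvergenceError, PipelineError, ValidationError
from .fe import FEModel, FEOperator, principal_stresses
from .geometry import (
    AnthropometricParams,
    DiscGeometry,
    SpineGeometry,
    VertebraGeometry,
    build_spine_geometry,
    place_ligaments,
)
from .materials import map_materials
from .meshing import snap_ligaments, tetrahedralize

logger = logging.getLogger(__name__)

#: Moment axis (unit generalized moment direction) per motion.
MOTION_AXES = {
    "flexion": np.array([0.0, 1.0, 0.0]),
    "extension": np.array([0.0, -1.0, 0.0]),
    "lateral_bending": np.array([1.0, 0.0, 0.0]),
    "twisting": np.array([0.0, 0.0, 1.0]),
}


@dataclass
class LoadDisplacementCurve:
    """Axial compression record; FL is the peak of the force array."""

    displacement: np.ndarray  # mm, starts at 0
    force: np.ndarray  # N, starts at 0
    fl: float  # N
    failure_displacement: float  # mm
    no_peak: bool  # True when the force never peaked within the ramp
    n_damaged: int

    def __post_init__(self):
        assert len(self.displacement) == len(self.force)


@dataclass
class MomentAngleCurve:
    """Pure-moment record; ROM is the angle at the peak moment."""

    motion: str
    moment: np.ndarray  # N*m, 0 -> peak
    angle: np.ndarray  # degrees
    rom: float  # degrees at peak moment


def simulate_compression_failure(
    model: FEModel,
    max_disp: float,
    n_steps: int = 40,
    knockdown: float = 0.01,
    operator: FEOperator | None = None,
    max_damage_iters: int = 60,
    stop_fraction: float = 0.7,
) -> LoadDisplacementCurve:
    """Displacement-controlled axial compression with element damage.

    The ramp terminates at the first structural collapse: once the
    equilibrium force has dropped below ``stop_fraction`` of the running
    peak, a vertebral section has failed and the failure load is bracketed -
    with a quasi-brittle knock-down, riding the ramp further only crushes
    the already-failed section (and, under displacement control through the
    compliant discs, produces spurious secondary peaks).  Set
    ``stop_fraction=0`` to ramp to ``max_disp`` unconditionally.
    """
    if max_disp <= 0:
        raise ValidationError(f"max_disp must be > 0, got {max_disp}")
    if n_steps < 10:
        raise ValidationError(f"n_steps must be >= 10, got {n_steps}")
    if not model.couple_superior:
        raise ValidationError("compression driver needs a coupled superior surface")

    op = operator or FEOperator(model)
    card = model.card
    damageable = card.is_bone & (
        np.isfinite(card.sigma_max) | np.isfinite(card.sigma_min)
    )
    if knockdown >= 1.0:  # knock-down of 1 leaves stiffness intact: disabled
        damageable &= False
    damage = np.ones(op.Ke0.shape[0])
    nc = len(op.cables)
    active = np.ones(nc, dtype=bool)

    m0 = op.master_q0
    pres_idx = m0 + np.arange(6)  # all six master dofs driven
    pattern = np.array([0.0, 0.0, -1.0, 0.0, 0.0, 0.0])  # unit axial push

    deltas = np.linspace(0.0, max_disp, n_steps + 1)[1:]
    forces = [0.0]
    disps = [0.0]

    state_dirty = True
    collapsed = False
    peak_seen = 0.0
    for delta in deltas:
        for _ in range(max_damage_iters):
            if state_dirty:
                use_damage = damage if (damage < 1).any() else None
                K = op.assemble(damage=use_damage, active_cables=active if nc else None)
                fac = op.factorize(K, pres_idx)
                full_pres = np.zeros(len(fac.pres))
                # master dofs are the last six prescribed entries
                order = np.argsort(fac.pres)
                pres_sorted = fac.pres[order]
                vals = np.zeros(len(fac.pres))
                for i, dof in enumerate(pres_idx):
                    vals[np.searchsorted(pres_sorted, dof)] = pattern[i]
                full_pres[order] = vals
                q_hat, react_hat = fac.solve(full_pres, None)
                u_hat = op.expand(q_hat)
                _, stress_hat = op.element_stress_strain(u_hat, damage)
                prin_hat = principal_stresses(stress_hat)
                elong_hat = op.cable_elongations(u_hat)
                fz_pos = int(np.flatnonzero(fac.pres == m0 + 2)[0])
                fz_hat = react_hat[fz_pos]
                state_dirty = False

            changed = False
            if nc and model.tension_only:
                new_active = elong_hat > 1e-14
                if not np.array_equal(new_active, active):
                    active = new_active
                    changed = True
            over_tension = delta * prin_hat[:, 0] > card.sigma_max
            over_compress = delta * prin_hat[:, 2] < -card.sigma_min
            fresh = damageable & (damage >= 1.0) & (over_tension | over_compress)
            if fresh.any():
                damage[fresh] = knockdown
                changed = True
            if not changed:
                break
            state_dirty = True
            # collapse guard: once the equilibrium force at this increment
            # has fallen well below the running peak, the failure load is
            # already bracketed and the remaining cascade only crushes the
            # failed section - stop iterating it to convergence.
            f_now = float(-fz_hat * delta)
            peak_seen = max(peak_seen, f_now)
            if stop_fraction > 0 and f_now < stop_fraction * peak_seen:
                collapsed = True
                break
        else:
            logger.warning(
                "damage iteration cap (%d) reached at delta=%.3f mm",
                max_damage_iters, delta,
            )
        disps.append(float(delta))
        forces.append(float(-fz_hat * delta))  # compressive reaction, N
        peak_seen = max(peak_seen, forces[-1])
        if collapsed or (
            stop_fraction > 0
            and forces[-1] < stop_fraction * peak_seen
            and int(np.argmax(forces)) < len(forces) - 1
        ):
            logger.debug(
                "post-peak stop at delta=%.3f mm (F=%.0f N, peak=%.0f N)",
                delta, forces[-1], peak_seen,
            )
            break

    forces = np.asarray(forces)
    disps = np.asarray(disps)
    i_peak = int(np.argmax(forces))
    no_peak = i_peak == len(forces) - 1
    if no_peak:
        logger.warning("no force peak within the ramp; FL taken at last step")
    return LoadDisplacementCurve(
        displacement=disps,
        force=forces,
        fl=float(forces[i_peak]),
        failure_displacement=float(disps[i_peak]),
        no_peak=no_peak,
        n_damaged=int((damage < 1).sum()),
    )


def simulate_rom(
    model: FEModel,
    motion: str,
    peak_moment: float = 7.5,
    n_steps: int = 8,
    operator: FEOperator | None = None,
    max_tension_iters: int = 20,
) -> MomentAngleCurve:
    """Pure moment about the motion axis; angle from the master rotation.

    With a fixed active ligament set the model is linear, and because cable
    strain signs are invariant along a proportional load path the active set
    found at the peak moment holds for the whole ramp; the curve is therefore
    exactly linear through the origin.
    """
    if motion not in MOTION_AXES:
        raise ValidationError(
            f"unknown motion {motion!r}; valid: {sorted(MOTION_AXES)}"
        )
    if peak_moment <= 0:
        raise ValidationError("peak_moment must be > 0")
    op = operator or FEOperator(model)
    axis = MOTION_AXES[motion]
    force = np.zeros(6)
    force[3:] = axis * peak_moment * 1000.0  # N*m -> N*mm

    nc = len(op.cables)
    active = np.ones(nc, dtype=bool)
    seen: list[bytes] = []
    for _ in range(max(1, max_tension_iters)):
        K = op.assemble(active_cables=active if nc else None)
        fac = op.factorize(K, np.empty(0, dtype=int))
        f = np.zeros(op.nq)
        f[op.master_q0: op.master_q0 + 6] = force
        q, _ = fac.solve(None, f)
        if not (model.tension_only and nc):
            break
        elong = op.cable_elongations(op.expand(q))
        new_active = elong > 1e-14
        if np.array_equal(new_active, active):
            break
        key = new_active.tobytes()
        if key in seen:
            raise FENonConvergenceError(
                f"tension-only iteration oscillates during {motion}"
            )
        seen.append(key)
        active = new_active
    else:
        raise FENonConvergenceError(
            f"tension-only iteration did not settle during {motion}"
        )

    theta = q[op.master_q0 + 3: op.master_q0 + 6]
    angle_peak = float(np.degrees(abs(np.dot(theta, axis))))
    moments = np.linspace(0.0, peak_moment, n_steps + 1)
    angles = angle_peak * moments / peak_moment
    return MomentAngleCurve(
        motion=motion, moment=moments, angle=angles, rom=angle_peak
    )


# ---------------------------------------------------------------------------
# full per-subject pipeline
# ---------------------------------------------------------------------------

@dataclass
class SubjectRecord:
    """One row of the cohort table plus provenance and raw curves."""

    subject_id: str
    bmd_qct_l1_3: float
    cohort: str
    fl: float
    failure_displacement: float
    theta_f: float
    theta_e: float
    theta_l: float
    theta_t: float
    bmd: SubjectBMD | None = field(default=None, repr=False)
    compression: LoadDisplacementCurve | None = field(default=None, repr=False)
    rom_curves: dict[str, MomentAngleCurve] = field(default_factory=dict, repr=False)
    provenance: dict = field(default_factory=dict, repr=False)

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "bmd_qct_l1_3": self.bmd_qct_l1_3,
            "cohort": self.cohort,
            "fl": self.fl,
            "failure_displacement": self.failure_displacement,
            "theta_f": self.theta_f,
            "theta_e": self.theta_e,
            "theta_l": self.theta_l,
            "theta_t": self.theta_t,
            "provenance": self.provenance,
        }


_MOTION_FIELD = {
    "flexion": "theta_f",
    "extension": "theta_e",
    "lateral_bending": "theta_l",
    "twisting": "theta_t",
}


def geometry_from_mask(
    vol: CTVolume, mask: LabelMask, params: AnthropometricParams | None = None
) -> SpineGeometry:
    """Reconstruct the parametric spine model from a segmentation mask.

    This is the model-generation stage of the pipeline: each vertebral body
    becomes an elliptical solid fitted to the axial extent and mid-height
    footprint of its label; discs fill the gaps between adjacent bodies, and
    the nucleus fraction is measured from the annulus/nucleus label areas.
    Sub-voxel features (the cortical shell thickness) fall back to the
    anthropometric defaults.
    """
    params = params or AnthropometricParams()
    dz = vol.spacing[2]
    verts: list[VertebraGeometry] = []
    for level in ("L1", "L2", "L3", "L4", "L5"):
        idx = np.argwhere(mask.data == LABEL_VERTEBRA[level])
        if idx.size == 0:
            raise PipelineError("geometry", f"vertebra label {level} is empty")
        z_lo = vol.origin[2] + idx[:, 2].min() * dz - 0.5 * dz
        z_hi = vol.origin[2] + idx[:, 2].max() * dz + 0.5 * dz
        k_mid = int(round(0.5 * (idx[:, 2].min() + idx[:, 2].max())))
        slab = idx[np.abs(idx[:, 2] - k_mid) <= 1]
        a_ap = 0.5 * (slab[:, 0].max() - slab[:, 0].min() + 1) * vol.spacing[0]
        a_ml = 0.5 * (slab[:, 1].max() - slab[:, 1].min() + 1) * vol.spacing[1]
        verts.append(
            VertebraGeometry(
                level=level, a_ap=float(a_ap), a_ml=float(a_ml),
                height=float(z_hi - z_lo),
                shell_thickness=params.shell_thickness,
                z_inferior=float(z_lo),
                posterior_scale=params.posterior_scale,
            )
        )

    n_nuc = (mask.data == LABEL_NUCLEUS).sum()
    n_ann = (mask.data == LABEL_ANNULUS).sum()
    frac = float(n_nuc / max(n_nuc + n_ann, 1))
    frac = min(max(frac, 0.05), 0.60)

    discs: list[DiscGeometry] = []
    for gap in range(4):
        upper, lower = verts[gap], verts[gap + 1]
        height = upper.z_inferior - lower.z_superior
        if height <= 0:
            raise PipelineError(
                "geometry",
                f"no disc space between {upper.level} and {lower.level}",
            )
        discs.append(
            DiscGeometry(
                gap=gap, upper_level=upper.level, lower_level=lower.level,
                z_inferior=lower.z_superior, height=float(height),
                a_ap_inf=lower.a_ap, a_ml_inf=lower.a_ml,
                a_ap_sup=upper.a_ap, a_ml_sup=upper.a_ml,
                nucleus_fraction=frac,
            )
        )
    import dataclasses as _dc

    params = _dc.replace(params, nucleus_fraction=frac)
    return SpineGeometry(vertebrae=verts, discs=discs, params=params)


def synthesize_subject(
    target_bmd_qct: float,
    geometry_seed: int = 0,
    noise_seed: int | None = None,
    config: RunConfig | None = None,
) -> tuple[SpineGeometry, CTVolume, LabelMask]:
    """Generate one synthetic subject (geometry + calibrated CT + mask)."""
    from .ct import rasterize_ct

    cfg = config or RunConfig()
    geom = build_spine_geometry(cfg.anthropometry, seed=geometry_seed)
    vol, mask = rasterize_ct(
        geom, target_bmd_qct, noise_sd=cfg.noise_sd,
        seed=cfg.seed if noise_seed is None else noise_seed, config=cfg.ct,
    )
    return geom, vol, mask


def build_fe_model(
    geom: SpineGeometry, vol: CTVolume, config: RunConfig | None = None,
    mask: LabelMask | None = None,
) -> FEModel:
    """Mesh + materials + snapped ligaments -> ready-to-solve FE model.

    When the label mask is available, bone HU sampling is mask-guided so
    partial-volume mixing with discs/soft tissue does not map spuriously
    weak endplate layers.
    """
    cfg = config or RunConfig()
    mesh = tetrahedralize(geom, cfg.edge_vert, cfg.edge_ivd)
    snap_ligaments(mesh, place_ligaments(geom))
    card = map_materials(mesh, vol, mode=cfg.hu_sampling, mask=mask)
    return FEModel(mesh=mesh, card=card, cables=mesh.cables,
                   tension_only=cfg.tension_only)


def run_subject(
    vol: CTVolume,
    mask: LabelMask,
    config: RunConfig | None = None,
    subject_id: str = "subject",
    geometry: SpineGeometry | None = None,
    compression: bool = True,
    keep_curves: bool = True,
) -> SubjectRecord:
    """Execute the full pipeline on one subject and collect all outcomes.

    Stages: densitometry -> geometry (from the mask unless given) -> mesh &
    ligaments -> material mapping -> FE assembly -> compression to failure ->
    pure-moment ROM for the configured motions.  Any stage failure aborts
    with the stage name; stage wall times and the config hash are logged in
    the record's provenance.
    """
    cfg = config or RunConfig()
    prov: dict = {"config_digest": cfg.digest(), "stages": {}}

    def timed(stage, fn, *args, **kwargs):
        t0 = time.perf_counter()
        try:
            out = fn(*args, **kwargs)
        except PipelineError:
            raise
        except Exception as err:
            raise PipelineError(stage, str(err)) from err
        prov["stages"][stage] = round(time.perf_counter() - t0, 4)
        return out

    bmd = timed("densitometry", subject_bmd, vol, mask,
                erosion_mm=cfg.roi_erosion_mm)
    geom = geometry or timed("geometry", geometry_from_mask, vol, mask,
                             cfg.anthropometry)
    model = timed("fe_model", build_fe_model, geom, vol, cfg, mask)
    op = timed("fe_assembly", FEOperator, model)
    prov["n_nodes"] = model.mesh.n_nodes
    prov["n_elements"] = model.mesh.n_elements

    fl = fail_disp = float("nan")
    curve = None
    if compression:
        max_disp = cfg.max_disp or cfg.max_disp_fraction * geom.total_height
        curve = timed(
            "compression", simulate_compression_failure, model,
            max_disp=max_disp, n_steps=cfg.n_steps_compression,
            knockdown=cfg.knockdown, operator=op,
        )
        fl, fail_disp = curve.fl, curve.failure_displacement
        prov["no_peak"] = curve.no_peak

    angles = {v: float("nan") for v in _MOTION_FIELD.values()}
    rom_curves: dict[str, MomentAngleCurve] = {}
    for motion in cfg.motions:
        mc = timed(f"rom_{motion}", simulate_rom, model, motion,
                   peak_moment=cfg.peak_moment, n_steps=cfg.n_steps_rom,
                   operator=op)
        rom_curves[motion] = mc
        angles[_MOTION_FIELD[motion]] = mc.rom

    return SubjectRecord(
        subject_id=subject_id,
        bmd_qct_l1_3=bmd.bmd_qct_l1_3,
        cohort=bmd.cohort,
        fl=fl,
        failure_displacement=fail_disp,
        **angles,
        bmd=bmd,
        compression=curve if keep_curves else None,
        rom_curves=rom_curves if keep_curves else {},
        provenance=prov,
    )


@dataclass
class ConvergenceResult:
    """Mesh-sensitivity ladder outcome."""

    edges: list[float]
    edge_ivd: list[float]
    n_elements: list[int]
    fl: list[float]
    tolerance: float
    converged_edge: float | None

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "edge_vert": self.edges, "edge_ivd": self.edge_ivd,
            "n_elements": self.n_elements, "fl": self.fl,
        })


def convergence_study(
    subject,
    edge_lengths,
    tolerance: float = 0.05,
    config: RunConfig | None = None,
) -> ConvergenceResult:
    """Failure-load mesh-sensitivity analysis over a descending edge ladder.

    ``subject`` is a (geometry, volume) or (geometry, volume, mask) tuple
    (or any object exposing ``.geometry``, ``.volume`` and optionally
    ``.mask``); each vertebral edge length is paired with half that value
    for the discs.  Reports the first edge length at which the relative FL
    change from the previous (coarser) rung drops below ``tolerance``;
    non-convergence is reported, not raised.
    """
    import dataclasses as _dc

    edges = [float(e) for e in edge_lengths]
    if len(edges) < 2:
        raise ValidationError("convergence study needs at least two edge lengths")
    if any(b >= a for a, b in zip(edges, edges[1:])):
        raise ValidationError("edge lengths must be strictly descending")
    mask = None
    if hasattr(subject, "geometry") and hasattr(subject, "volume"):
        geom, vol = subject.geometry, subject.volume
        mask = getattr(subject, "mask", None)
    elif len(subject) == 3:
        geom, vol, mask = subject
    else:
        geom, vol = subject
    cfg = config or RunConfig()

    fls, counts, ivds = [], [], []
    for e in edges:
        e_ivd = min(max(e / 2.0, 0.25), 3.0)
        c = _dc.replace(cfg, edge_vert=e, edge_ivd=e_ivd)
        model = build_fe_model(geom, vol, c, mask)
        max_disp = c.max_disp or c.max_disp_fraction * geom.total_height
        curve = simulate_compression_failure(
            model, max_disp=max_disp, n_steps=c.n_steps_compression,
            knockdown=c.knockdown,
        )
        fls.append(curve.fl)
        counts.append(model.mesh.n_elements)
        ivds.append(e_ivd)

    converged = None
    for i in range(1, len(edges)):
        if abs(fls[i] - fls[i - 1]) / max(abs(fls[i - 1]), 1e-12) < tolerance:
            converged = edges[i]
            break
    if converged is None:
        logger.warning(
            "FL did not converge within %.0f%% over edges %s",
            100 * tolerance, edges,
        )
    return ConvergenceResult(
        edges=edges, edge_ivd=ivds, n_elements=counts, fl=fls,
        tolerance=tolerance, converged_edge=converged,
    )
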