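"""Compression-to-failure and ROM drivers, full pipeline, convergence."""

import dataclasses

import numpy as np
import pytest

from spinefe.config import RunConfig
from spinefe.errors import ValidationError
from spinefe.fe import FEModel, FEOperator
from spinefe.materials import isotropic_stiffness
from spinefe.meshing import structured_box_mesh
from spinefe.simulate import (
    convergence_study,
    geometry_from_mask,
    run_subject,
    simulate_compression_failure,
    simulate_rom,
)

from test_fe import iso_card


class TestCompression:
    def test_linear_without_damage(self, tiny_model):
        """Knock-down factor 1 disables damage: force affine in displacement
        with R^2 = 1 to machine precision."""
        curve = simulate_compression_failure(
            tiny_model, max_disp=0.5, n_steps=10, knockdown=1.0
        )
        assert curve.displacement[0] == 0.0 and curve.force[0] == 0.0
        slope = np.polyfit(curve.displacement, curve.force, 1)
        resid = curve.force - np.polyval(slope, curve.displacement)
        ss = 1 - resid @ resid / max((curve.force - curve.force.mean()) @
                                     (curve.force - curve.force.mean()), 1e-30)
        assert ss == pytest.approx(1.0, abs=1e-12)
        assert curve.no_peak  # monotone ramp: FL flagged at the last step

    def test_uniform_block_limit_load(self):
        """Homogeneous block: FL within 10% of strength times area."""
        E, nu, smin, a, L = 1000.0, 0.0, 5.0, 10.0, 20.0
        mesh = structured_box_mesh((a, a, L), (3, 3, 6))
        card = iso_card(mesh, E=E, nu=nu, sigma_min=smin)
        model = FEModel(mesh=mesh, card=card)
        eps_fail = smin / E
        curve = simulate_compression_failure(
            model, max_disp=2.5 * eps_fail * L, n_steps=40
        )
        assert not curve.no_peak
        assert curve.fl == pytest.approx(smin * a * a, rel=0.10)

    def test_validation(self, tiny_model):
        with pytest.raises(ValidationError):
            simulate_compression_failure(tiny_model, max_disp=-1.0)
        with pytest.raises(ValidationError):
            simulate_compression_failure(tiny_model, max_disp=1.0, n_steps=5)


@pytest.fixture(scope="module")
def op(tiny_model):
    return FEOperator(tiny_model)


class TestROM:
    def test_curves_through_origin_and_monotone(self, tiny_model, op):
        for motion in ("flexion", "extension", "lateral_bending", "twisting"):
            mc = simulate_rom(tiny_model, motion, operator=op, n_steps=6)
            assert mc.moment[0] == 0.0 and mc.angle[0] == 0.0
            assert np.all(np.diff(mc.angle) >= 0)
            assert mc.moment[-1] == pytest.approx(7.5)
            assert np.isfinite(mc.rom) and mc.rom > 0
            # angle at the full moment dominates the half-moment angle
            half = mc.angle[np.searchsorted(mc.moment, 3.75)]
            assert mc.rom >= half

    def test_small_moment_limit(self, tiny_model, op):
        tiny = simulate_rom(tiny_model, "flexion", peak_moment=1e-6, operator=op)
        assert tiny.rom < 1e-4

    def test_removing_ligaments_increases_rom(self, tiny_model, op):
        with_lig = simulate_rom(tiny_model, "flexion", operator=op).rom
        free = FEModel(mesh=tiny_model.mesh, card=tiny_model.card, cables=[])
        without = simulate_rom(free, "flexion").rom
        assert without > with_lig

    def test_unknown_motion(self, tiny_model, op):
        with pytest.raises(ValidationError, match="motion"):
            simulate_rom(tiny_model, "sideways", operator=op)


class TestPipeline:
    def test_run_subject_complete_and_deterministic(self, tiny_subject,
                                                    tiny_config):
        _, vol, mask = tiny_subject
        cfg = dataclasses.replace(tiny_config, n_steps_compression=15)
        r1 = run_subject(vol, mask, cfg, subject_id="s1")
        assert r1.cohort == "healthy"
        assert np.isfinite(r1.fl) and r1.fl > 0
        assert np.isfinite(r1.theta_f) and np.isfinite(r1.theta_t)
        assert r1.provenance["stages"]
        r2 = run_subject(vol, mask, cfg, subject_id="s1")
        assert r2.fl == r1.fl
        assert r2.bmd_qct_l1_3 == r1.bmd_qct_l1_3
        assert r2.theta_f == r1.theta_f

    def test_geometry_reconstruction_close_to_truth(self, tiny_subject):
        geom, vol, mask = tiny_subject
        rec = geometry_from_mask(vol, mask)
        for v_true, v_rec in zip(geom.vertebrae, rec.vertebrae):
            assert v_rec.a_ap == pytest.approx(v_true.a_ap, abs=1.5)
            assert v_rec.a_ml == pytest.approx(v_true.a_ml, abs=1.5)
            assert v_rec.height == pytest.approx(
                v_true.height, abs=vol.spacing[2]
            )
        assert rec.params.nucleus_fraction == pytest.approx(0.30, abs=0.05)


class TestConvergence:
    def test_ladder(self, tiny_subject, tiny_config):
        geom, vol, mask = tiny_subject
        cfg = dataclasses.replace(tiny_config, n_steps_compression=12)
        res = convergence_study((geom, vol, mask), [4.0, 3.0],
                                tolerance=1.0, config=cfg)
        assert res.n_elements[1] > res.n_elements[0]
        # degenerate 100% tolerance declares the first refinement converged
        assert res.converged_edge == 3.0
        frame = res.to_frame()
        assert list(frame.columns) == ["edge_vert", "edge_ivd", "n_elements",
                                       "fl"]

    def test_single_edge_rejected(self, tiny_subject):
        geom, vol, mask = tiny_subject
        with pytest.raises(ValidationError):
            convergence_study((geom, vol, mask), [3.0])

    def test_non_descending_rejected(self, tiny_subject):
        geom, vol, mask = tiny_subject
        with pytest.raises(ValidationError):
            convergence_study((geom, vol, mask), [3.0, 3.0])
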