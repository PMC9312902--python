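"""Density, modulus and strength mapping laws."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spinefe.ct import CTVolume
from spinefe.errors import MaterialError
from spinefe.materials import (
    EPS_AB_FLOOR,
    MaterialCard,
    REGION_NUCLEUS,
    apparent_density,
    ash_density,
    bone_card_from_hu,
    elastic_constants,
    isotropic_stiffness,
    map_materials,
    strength_limits,
    transverse_isotropic_compliance_unit,
)
from spinefe.meshing import structured_box_mesh


class TestDensityLaws:
    @pytest.mark.parametrize("hu,expected", [
        (0.0, 47.0), (850.0, 1000.7), (-100.0, 47.0),
    ])
    def test_apparent_density(self, hu, expected):
        assert apparent_density(hu) == pytest.approx(expected)

    @pytest.mark.parametrize("rho,expected", [(1000.0, 600.0), (47.0, 28.2),
                                              (0.0, 0.0)])
    def test_ash_density(self, rho, expected):
        assert ash_density(rho) == pytest.approx(expected)

    def test_negative_density_rejected(self):
        with pytest.raises(MaterialError):
            ash_density(-1.0)


class TestElasticity:
    def test_unit_base_case(self):
        # 1 g/cm^3 apparent density -> Ez = 4730 MPa exactly
        assert elastic_constants(1000.0)["Ez"] == pytest.approx(4730.0, abs=0.0)

    def test_half_density(self):
        ez = elastic_constants(500.0)["Ez"]
        assert ez == pytest.approx(1604.1, rel=1e-3)

    @settings(max_examples=30, deadline=None)
    @given(rho=st.floats(50.0, 2000.0))
    def test_fixed_ratios(self, rho):
        c = elastic_constants(rho)
        assert c["Gxz"] / c["Ez"] == pytest.approx(0.157, abs=1e-12)
        assert c["Gxy"] / c["Ez"] == pytest.approx(0.121, abs=1e-12)
        assert c["Ex"] / c["Ez"] == pytest.approx(0.333, abs=1e-12)

    def test_nonpositive_density_rejected(self):
        with pytest.raises(MaterialError):
            elastic_constants(0.0)

    def test_unit_compliance_positive_definite(self):
        S = transverse_isotropic_compliance_unit()
        assert np.all(np.linalg.eigvalsh(S) > 0)
        assert np.allclose(S, S.T)


class TestStrength:
    def test_branch_continuity_at_breakpoint(self):
        lo = 137.0 * 0.317**1.88
        hi = 114.0 * 0.317**1.72
        assert abs(lo - hi) / hi < 1e-3
        smax, _, _ = strength_limits(317.0)
        assert smax == pytest.approx(lo, rel=1e-9) or smax == pytest.approx(
            hi, rel=1e-9
        )

    def test_eps_ab_clamped(self):
        # the linear plastic-strain law turns negative below 43.3 kg/m^3 ash
        _, eps, _ = strength_limits(40.0)
        assert eps == EPS_AB_FLOOR

    def test_sigma_min_base_case(self):
        _, _, smin = strength_limits(1000.0)
        assert smin == pytest.approx(65.1)

    def test_monotone_in_hu(self):
        hu = np.linspace(1.0, 1500.0, 200)
        chain = bone_card_from_hu(hu)
        for key in ("Ez", "sigma_max", "sigma_min"):
            assert np.all(np.diff(chain[key]) > 0), key


class TestMapMaterials:
    def _vol(self, value, lo=(-5, -5, -5), size=40.0, n=9):
        data = np.full((n, n, n), float(value), dtype=np.float32)
        sp = size / n
        return CTVolume(data=data, spacing=[sp] * 3,
                        origin=np.asarray(lo) + sp / 2)

    def test_homogeneous_volume_identical_cards(self):
        mesh = structured_box_mesh((10, 10, 10), (2, 2, 2))
        card = map_materials(mesh, self._vol(850.0))
        assert np.allclose(card.hu, 850.0)
        assert np.unique(card.Ez).size == 1
        chain = bone_card_from_hu(np.array([850.0]))
        assert card.Ez[0] == pytest.approx(chain["Ez"][0])
        assert card.sigma_max[0] == pytest.approx(chain["sigma_max"][0])

    def test_nucleus_ignores_hu(self):
        mesh = structured_box_mesh((10, 10, 10), (2, 2, 2),
                                   region_code=REGION_NUCLEUS)
        card = map_materials(mesh, self._vol(1400.0))
        C = card.elasticity()
        expected = isotropic_stiffness(1.0, 0.49)
        assert np.allclose(C[0], expected)
        assert np.isinf(card.sigma_max).all()  # discs never damage

    def test_higher_hu_strictly_stiffer(self):
        mesh = structured_box_mesh((10, 10, 10), (2, 2, 2))
        lo = map_materials(mesh, self._vol(300.0))
        hi = map_materials(mesh, self._vol(400.0))
        assert np.all(hi.Ez > lo.Ez)

    def test_centroid_outside_volume(self):
        mesh = structured_box_mesh((10, 10, 10), (2, 2, 2))
        small = self._vol(100.0, lo=(0, 0, 0), size=5.0)
        with pytest.raises(MaterialError, match="outside"):
            map_materials(mesh, small)

    def test_negative_hu_clamped(self):
        mesh = structured_box_mesh((10, 10, 10), (2, 2, 2))
        card = map_materials(mesh, self._vol(-400.0))
        assert np.allclose(card.hu, 0.0)
        assert np.allclose(card.rho_app, 47.0)

    def test_positive_definite_for_generated_cards(self, tiny_model):
        C = tiny_model.card.elasticity()
        eig = np.linalg.eigvalsh(C)
        assert eig.min() > 0
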