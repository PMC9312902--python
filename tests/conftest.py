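"""Shared fixtures: a miniature spine keeps the unit tests fast; the
acceptance tests build the full-size reference subjects themselves."""

import dataclasses

import numpy as np
import pytest

from spinefe.config import RunConfig
from spinefe.geometry import AnthropometricParams, build_spine_geometry, place_ligaments
from spinefe.ct import rasterize_ct
from spinefe.meshing import snap_ligaments, tetrahedralize
from spinefe.materials import map_materials
from spinefe.fe import FEModel


#: Small anthropometry for fast unit tests (not the study conditions).
TINY = AnthropometricParams(
    body_ap=8.0, body_ml=10.0, body_height=12.0, disc_height=4.0,
    shell_thickness=0.4,
)


@pytest.fixture(scope="session")
def tiny_config():
    return dataclasses.replace(
        RunConfig(), anthropometry=TINY, n_steps_compression=20,
        motions=("flexion", "twisting"),
    )


@pytest.fixture(scope="session")
def tiny_geometry():
    return build_spine_geometry(TINY, seed=1)


@pytest.fixture(scope="session")
def tiny_subject(tiny_geometry):
    """(geometry, noiseless CT volume, label mask) at BMD_QCT-L1-3 = 100."""
    vol, mask = rasterize_ct(tiny_geometry, 100.0, noise_sd=0.0, seed=1)
    return tiny_geometry, vol, mask


@pytest.fixture(scope="session")
def tiny_mesh(tiny_geometry):
    mesh = tetrahedralize(tiny_geometry, 3.0, 1.5)
    snap_ligaments(mesh, place_ligaments(tiny_geometry))
    return mesh


@pytest.fixture(scope="session")
def tiny_model(tiny_subject, tiny_mesh):
    geom, vol, mask = tiny_subject
    card = map_materials(tiny_mesh, vol, mask=mask)
    return FEModel(mesh=tiny_mesh, card=card, cables=tiny_mesh.cables)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
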