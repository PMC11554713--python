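"""Shared fixtures: coarse meshes and solved states reused across tests."""

import numpy as np
import pytest

from lnflow.params import (default_params, derive_exchange_coefficients,
                           EffectiveTransport)
from lnflow.geometry import NodeGeometry, build_node_mesh
from lnflow.macro import solve_coupled


@pytest.fixture(scope="session")
def blocks():
    """(fluid, micro, exchange-template, bc) with Table defaults."""
    return default_params()


@pytest.fixture(scope="session")
def transport():
    return EffectiveTransport()


@pytest.fixture(scope="session")
def sphere_geom():
    return NodeGeometry(shape="sphere")


@pytest.fixture(scope="session")
def oblate_geom():
    return NodeGeometry(shape="oblate")


@pytest.fixture(scope="session")
def sphere_mesh_coarse(sphere_geom):
    return build_node_mesh(sphere_geom, "coarse")


@pytest.fixture(scope="session")
def sphere_mesh_medium(sphere_geom):
    return build_node_mesh(sphere_geom, "medium")


@pytest.fixture(scope="session")
def sphere_exchange(blocks, sphere_geom):
    _, _, ex0, _ = blocks
    return derive_exchange_coefficients(ex0, sphere_geom.lc_volume())


@pytest.fixture(scope="session")
def coarse_solution(blocks, transport, sphere_mesh_coarse, sphere_exchange):
    """Default-parameter coupled solve on the coarse sphere mesh."""
    fluid, _, _, bc = blocks
    return solve_coupled(sphere_mesh_coarse, fluid, sphere_exchange,
                         transport, bc)
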