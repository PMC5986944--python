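"""Shared fixtures: coarse reduced-heart models for fast property tests."""

import numpy as np
import pytest

from cardiomech.materials import (
    ActiveParams,
    HUMAN_SHEAR_PARAMS,
    PassiveParams,
)
from cardiomech.ventricle import VentricleGeometry, VentricleModel, build_geometry
from cardiomech.circulation import CirculationParams, CoupledHeart


@pytest.fixture(scope="session")
def shear_params() -> PassiveParams:
    """The human-shear-calibrated passive parameter set."""
    return HUMAN_SHEAR_PARAMS


@pytest.fixture(scope="session")
def lv_geometry() -> VentricleGeometry:
    return build_geometry()


@pytest.fixture(scope="session")
def coarse_lv_geometry() -> VentricleGeometry:
    """Low-order quadrature LV for fast coupled-simulation tests."""
    return build_geometry(n_transmural=3, n_longitudinal=4)


@pytest.fixture(scope="session")
def coarse_rv_geometry() -> VentricleGeometry:
    return build_geometry(
        a_endo=14.0, c_endo=42.0, a_epi=19.0, c_epi=47.0, z_base=10.0,
        n_transmural=3, n_longitudinal=4,
    )


@pytest.fixture()
def coarse_heart(coarse_lv_geometry, coarse_rv_geometry):
    """Coupled heart at desk-test scale (coarse quadrature, soft wall)."""
    passive = HUMAN_SHEAR_PARAMS.scaled(0.098, 0.1635)
    active = ActiveParams(Tmax=85.0, n_s=0.07)
    lv = VentricleModel(coarse_lv_geometry, passive, active)
    rv = VentricleModel(coarse_rv_geometry, passive, active)
    return CoupledHeart(lv, rv, CirculationParams(kappa_p=8.0, dt=2.0))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20180529)
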