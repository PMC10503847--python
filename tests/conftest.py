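import math

import numpy as np
import pytest

from vesselwall.data_io import RingGeometry
from vesselwall.synth import FiberFieldSpec, VesselModel, find_force_invariant_stretch


@pytest.fixture(scope="session")
def default_model() -> VesselModel:
    return VesselModel()


@pytest.fixture(scope="session")
def lam_star(default_model) -> float:
    """Force-invariant axial stretch of the default vessel (dense search)."""
    return find_force_invariant_stretch(default_model)


@pytest.fixture(scope="session")
def default_ring(default_model) -> RingGeometry:
    return RingGeometry(
        math.pi * default_model.D_i, math.pi * default_model.D_o
    )


@pytest.fixture
def straight_line_image() -> np.ndarray:
    """One bright horizontal line, 80 px long, on a dark background."""
    img = np.zeros((64, 128))
    img[32, 20:100] = 200.0
    return img


def grating_spec(angle_deg: float, seed: int = 1, **kw) -> FiberFieldSpec:
    """Straight parallel fibers at a fixed angle (an orientation 'grating')."""
    defaults = dict(
        n_fibers=15,
        amplitude=0.0,
        mixture_means=(angle_deg,),
        mixture_kappas=(1e9,),
        mixture_weights=(1.0,),
        seed=seed,
    )
    defaults.update(kw)
    return FiberFieldSpec(**defaults)
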