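import numpy as np
import pytest

from hepacomet.model import DamageScenario
from hepacomet.presets import agent_preset, landmark_scenarios
from hepacomet.quant import Window
from hepacomet.synth import ArrayGeometry, CometSpec, render_field


@pytest.fixture(scope="session")
def geometry():
    return ArrayGeometry()


@pytest.fixture(scope="session")
def landmarks():
    return landmark_scenarios()


@pytest.fixture(scope="session")
def uv_preset():
    return agent_preset("uv_c")


@pytest.fixture
def single_comet_window(geometry):
    """Factory: render one isolated comet and hand back its analysis window.

    The window replicates the pipeline layout (one pitch transverse,
    0.35/0.75 pitches behind/ahead of the head).
    """

    def _make(tail_frac, budget=2.0e5, background=0.0, noise="none", rng=None, seed=None):
        spec = CometSpec(
            row=0, col=0, cy=150.0, cx=120.0, budget=budget, tail_frac=tail_frac
        )
        fld, manifest = render_field(
            [spec], geometry, shape=(300, 420), background=background,
            noise=noise, rng=rng, seed=seed,
        )
        p = geometry.pitch_px
        y0, y1 = int(150 - p / 2), int(150 + p / 2)
        x0, x1 = int(120 - 0.35 * p), int(120 + 0.75 * p)
        win = Window(
            image=np.asarray(fld.image, dtype=float)[y0:y1, x0:x1],
            origin=(y0, x0),
            node=(150.0, 120.0),
            node_index=(0, 0),
            expected_head=120 - x0,
        )
        return win, fld, manifest

    return _make
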