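import numpy as np
import pytest

from loopalign import LoopScene, VirtualBeamline, default_config


@pytest.fixture
def config():
    return default_config()


@pytest.fixture
def bl(config):
    return VirtualBeamline(config)


def make_config(**overrides):
    """Default config with nested overrides, e.g. make_config(
    simulator={'mount_capture_range_mm': 0.0})."""
    cfg = default_config()
    data = cfg.model_dump()
    for key, sub in overrides.items():
        if isinstance(sub, dict):
            data[key].update(sub)
        else:
            data[key] = sub
    return type(cfg).model_validate(data)


@pytest.fixture
def exact_bl():
    """Beamline with zero mount error: the scene's tip_offset is exact."""
    return VirtualBeamline(make_config(simulator={"mount_capture_range_mm": 0.0}))


def mount(bl, scene=None, seed=0, **scene_kwargs):
    scene = scene or LoopScene(**scene_kwargs)
    bl.mount_sample(scene, np.random.default_rng(seed))
    return scene


def angle_error_deg(a, b, period=180.0):
    d = (a - b) % period
    return min(d, period - d)
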