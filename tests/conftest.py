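import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from zotrad.features import FeatureConfig, generate_catalogue
from zotrad.phantom import PhantomSpec, generate_phantom
from zotrad.zot import ZotConfig, detect_zot

settings.register_profile(
    "deterministic", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def demo_case():
    """One textured two-phase phantom with its manual mask."""
    spec = PhantomSpec(seed=7)
    arterial, venous, mask = generate_phantom(spec)
    return spec, arterial, venous, mask


@pytest.fixture(scope="session")
def demo_zot(demo_case):
    """Refined masks + ZOT regions for both phases of the demo phantom."""
    _, arterial, venous, mask = demo_case
    cfg = ZotConfig()
    out = {}
    for phase, img in (("arterial", arterial), ("venous", venous)):
        refined, zot, report = detect_zot(img, mask, cfg)
        out[phase] = (refined, zot, report)
    return out


@pytest.fixture(scope="session")
def demo_catalogue(demo_case, demo_zot):
    """Full 654-entry feature catalogue of the demo phantom."""
    _, arterial, venous, _ = demo_case
    images = {"arterial": arterial, "venous": venous}
    tmasks = {p: demo_zot[p][0] for p in images}
    zmasks = {p: demo_zot[p][1].support for p in images}
    return generate_catalogue(images, tmasks, zmasks, FeatureConfig(),
                              subject_id="demo", label=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
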