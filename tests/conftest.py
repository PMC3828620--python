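import hypothesis
import numpy as np
import pytest

import dendrochem as dc

hypothesis.settings.register_profile(
    "ci", derandomize=True, max_examples=50, deadline=None
)
hypothesis.settings.load_profile("ci")


@pytest.fixture
def simple_cable():
    """One 100 µm cable, diam 1 µm, 10 segments, full cross-section region."""
    morph = dc.Morphology()
    sec = morph.create_section("cable", L=100.0, diam=1.0, nseg=10)
    region = dc.Region([sec], nrn_region="i", name="cyt")
    return morph, sec, region


@pytest.fixture
def y_morphology():
    """A stem with two daughters attached at its 1-end."""
    morph = dc.Morphology()
    stem = morph.create_section("stem", L=50.0, diam=2.0, nseg=5)
    a = morph.create_section("a", L=30.0, diam=1.0, nseg=3)
    b = morph.create_section("b", L=40.0, diam=1.0, nseg=4)
    morph.connect(a, stem, parent_x=1)
    morph.connect(b, stem, parent_x=1)
    return morph


def diffusing_model(morph, d=1.0, initial=1.0, name="s"):
    region = dc.Region(morph.sections, name="all")
    sp = dc.Species(region, d=d, name=name, initial=initial)
    model = dc.Model(species=[sp])
    model.initialize()
    return model, sp, region


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)
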