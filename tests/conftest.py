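import pytest

from ribocollide import CollisionGeometry, VelocityModel


@pytest.fixture
def geometry() -> CollisionGeometry:
    return CollisionGeometry(footprint_codons=10)


@pytest.fixture
def vmodel() -> VelocityModel:
    return VelocityModel(mean_velocity=5.6, sd_velocity=2.5)
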