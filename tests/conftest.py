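import pytest

from chromdomain.io import FeatureMap


@pytest.fixture
def ring_map() -> FeatureMap:
    """A small chromatin ring with a central gene feature and a cut site
    placed opposite it, like a 5S ring linearized to center the gene."""
    return FeatureMap(
        ring_length=2500,
        features={"gene": (1190, 1310)},
        cut_site=0,
    )
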