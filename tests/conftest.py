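import numpy as np
import pytest

from retveins.phantom import fixture_suite
from retveins.pipeline import PipelineConfig, segment_stages

BATTERY_SEEDS = (1, 2, 3)
FIXTURE_NAMES = ("clean", "bias", "noise", "capillary", "lesion")


@pytest.fixture(scope="session")
def battery_runs():
    """Full-pipeline stage dicts for the 5-fixture battery × 3 seeds.

    Computed once per session; keyed by (seed, fixture name) with values
    ``(phantom, stages)``.  Ablated final masks are derivable from the
    cached stages (no elongation: postprocess(cleaned); no post-processing:
    the elongated mask), so the ablation tests reuse this cache.
    """
    cfg = PipelineConfig()
    runs = {}
    for seed in BATTERY_SEEDS:
        for phantom, name in zip(fixture_suite(seed), FIXTURE_NAMES):
            runs[(seed, name)] = (phantom, segment_stages(phantom.image, cfg))
    return runs


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
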