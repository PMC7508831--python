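import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from diplobench.align import (
    extract_variants,
    merge_diploid,
    piecewise_align,
)
from diplobench.simulate import (
    DivergentConfig,
    SimConfig,
    simulate_reads,
    simulate_truth,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def mild_config():
    """A 200 kb locus whose divergent segment stays below the 5%
    alignability threshold, so the whole locus is callable."""
    return SimConfig(
        seed=11,
        divergent_region=DivergentConfig(length=20_000, divergence=0.04),
    )


@pytest.fixture(scope="session")
def truth_mild(mild_config):
    return simulate_truth(mild_config)


@pytest.fixture(scope="session")
def reads_mild(mild_config, truth_mild):
    return simulate_reads(truth_mild, mild_config)


@pytest.fixture(scope="session")
def callset_mild(truth_mild):
    """Diploid callset from aligning both truth haplotigs back to the
    reference (assembler consumed as ground truth)."""
    per_hap = []
    for h in (1, 2):
        hap = truth_mild.hap(h)
        blocks, _ = piecewise_align(
            hap, truth_mild.reference, chrom=truth_mild.chrom
        )
        per_hap.append(
            extract_variants(
                blocks, truth_mild.reference, hap, chrom=truth_mild.chrom
            )
        )
    return merge_diploid(per_hap[0], per_hap[1])


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
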