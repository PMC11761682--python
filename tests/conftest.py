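import numpy as np
import pytest

from vnarmine.config import PipelineConfig
from vnarmine.simulate import GeneratorConfig


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def pipeline_config():
    return PipelineConfig()


@pytest.fixture
def small_generator_config():
    """Scaled-down study conditions for fast unit tests."""
    return GeneratorConfig(
        n_background_lineages=60,
        n_target_specific_lineages=2,
        n_shared_lineages=2,
        target_lineage_n_variants=31,
        target_lineage_seed_count=400,
        rng_seed=7,
    )


def write_fastq_file(path, records):
    with open(path, "w") as fh:
        for rid, seq, qual in records:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")
    return path
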