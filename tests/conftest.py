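import numpy as np
import pytest

from comodnet.gem import GEM
from comodnet.simulate import ModuleSpec, SynthConfig, generate_gem


@pytest.fixture
def tiny_gem() -> GEM:
    """5 transcripts x 4 samples with one missing cell."""
    rng = np.random.default_rng(7)
    values = rng.uniform(1.0, 16.0, size=(5, 4))
    values[2, 1] = np.nan
    return GEM(
        transcript_ids=[f"T{i}" for i in range(5)],
        sample_ids=[f"S{j}" for j in range(4)],
        values=values,
    )


@pytest.fixture(scope="session")
def small_synth():
    """A fast two-condition fixture with one planted module (for pipeline and
    CLI tests; the full default fixture is exercised in the acceptance suite)."""
    cfg = SynthConfig(
        conditions=[("CA", 40), ("CB", 40)],
        modules=[ModuleSpec(6, ("CA",))],
        background_genes=20,
        noise_sd=1.0,
        missing_rate=0.02,
        seed=11,
    )
    gem, truth, ann = generate_gem(cfg)
    return cfg, gem, truth, ann
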