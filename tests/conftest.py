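import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import indelpoly as ip
from indelpoly import coalescent as co

settings.register_profile(
    "ci", derandomize=True, max_examples=40,
    suppress_health_check=[HealthCheck.too_slow], deadline=None,
)
settings.load_profile("ci")


def random_alignment(rng, n, L, missing=0.0, locus_id="rand"):
    """Random ACGT alignment with optional sprinkled gaps/Ns."""
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    mat = bases[rng.integers(0, 4, size=(n, L))]
    if missing:
        mask = rng.random((n, L)) < missing
        mat = mat.copy()
        mat[mask] = np.where(rng.random((n, L)) < 0.5, ord("-"), ord("N"))[mask]
    return ip.Alignment(locus_id, tuple(f"s{i:02d}" for i in range(n)), mat)


@pytest.fixture(scope="session")
def null96():
    """Shared 96-sample neutral null at the survey's theta (10k replicates)."""
    cfg = co.NullModelConfig(n=96, theta=4.0, replicates=10000, seed=11)
    return co.build_null_distribution(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260924)
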