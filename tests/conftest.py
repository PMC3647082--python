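import sys
from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings

sys.path.insert(0, str(Path(__file__).parent))  # for the _oracles helper

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from comigratlas import (  # noqa: E402
    NoiseParams,
    generate_proteome,
    proteome_index,
    simulate_peptide_table,
)
from comigratlas.synthetic_data import default_complex_specs  # noqa: E402


@pytest.fixture(scope="session")
def bench_dataset():
    """One deterministic 5-complex benchmark dataset shared across tests."""
    seed = 11
    proteome = generate_proteome(30, (80, 300), seed=seed)
    specs = default_complex_specs(proteome, seed=seed)
    noise = NoiseParams(background_rate=0.0, seed=seed)
    table = simulate_peptide_table(proteome, specs, noise, 60)
    return {
        "proteome": proteome,
        "index": proteome_index(proteome),
        "specs": specs,
        "noise": noise,
        "table": table,
        "n_slices": 60,
    }
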