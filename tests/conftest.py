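import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for reference_impl

from condensate_profiler.design import granule_ip_design
from condensate_profiler.synthetic_data import (
    ProteomeSimSpec,
    NoiseSpec,
    generate_quant_dataset,
)


@pytest.fixture(scope="session")
def design():
    return granule_ip_design()


@pytest.fixture(scope="session")
def default_dataset(design):
    """The default synthetic fractionation dataset (seeded)."""
    return generate_quant_dataset(design=design, seed=1)


@pytest.fixture(scope="session")
def clean_dataset(design):
    """Noise-free dataset without missingness (exact-template identity)."""
    spec = ProteomeSimSpec(noise=NoiseSpec(sd=0.0), target_missing_rate=None)
    return generate_quant_dataset(design=design, spec=spec, seed=5)
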