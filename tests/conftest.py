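import pytest
from hypothesis import settings

from barcodetree import BarcodeRecord, LabelCodec

settings.register_profile("repeatable", derandomize=True)
settings.load_profile("repeatable")
from barcodetree.simulate import SimConfig, default_sim_codec, simulate_dataset


@pytest.fixture
def codec() -> LabelCodec:
    return default_sim_codec()


@pytest.fixture
def toy_records() -> list[BarcodeRecord]:
    """Three records, two sharing a haplotype across countries."""
    seq_a = "ACGT" * 160
    seq_b = "ACGT" * 159 + "ACGA"
    return [
        BarcodeRecord(
            "r1", seq_a, species_name="Agrypnia obsoleta", country="Finland"
        ),
        BarcodeRecord(
            "r2", seq_a, species_name="Agrypnia obsoleta", country="Canada",
            region="Ontario",
        ),
        BarcodeRecord(
            "r3", seq_b, species_name="Agrypnia obsoleta", country="Finland"
        ),
    ]


@pytest.fixture(scope="session")
def small_dataset():
    """Default-regime synthetic dataset shared across read-only tests."""
    return simulate_dataset(SimConfig(n_species=8, seed=11))
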