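import pytest

from ltrmir import ScanConfig, make_records, scan_records


@pytest.fixture(scope="session")
def small_dataset():
    """Six synthetic LTR genomes with planted cassettes plus ground truth."""
    return make_records(6, 1.0, rng_seed=11)


@pytest.fixture(scope="session")
def small_scan(small_dataset):
    """Default-config scan results for the small fixture set."""
    records, truth = small_dataset
    return scan_records(records, ScanConfig()), truth
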