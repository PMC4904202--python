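import pytest

from ulvahydro import datasets


@pytest.fixture(scope="session")
def runs():
    """The packaged 16-run screen table (mean/sd outcome summaries)."""
    return datasets.load_hydrolysis_runs()


@pytest.fixture(scope="session")
def design(runs):
    return datasets.hydrolysis_design(runs)


@pytest.fixture(scope="session")
def snr_reference():
    """Published per-run S/N values for the six outcomes."""
    return datasets.load_snr_reference()
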