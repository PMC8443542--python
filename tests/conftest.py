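import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from barcodekit.records import (  # noqa: E402
    Source,
    TotalTable,
    harmonize_record,
)


@pytest.fixture
def bold_row():
    return {
        "processid": "ABC123",
        "organism": "Neotamias minimus",
        "marker": "COI-5P",
        "seq": "ACGTACGT",
    }


@pytest.fixture
def small_table(bold_row):
    """Three harmonized records: clean, no_seq, and multiply flagged."""
    r1 = harmonize_record(bold_row, Source.BOLD)
    r2 = harmonize_record(
        {**bold_row, "processid": "ABC124", "seq": ""}, Source.BOLD
    )
    r3 = harmonize_record(
        {
            "accession": "MK000001",
            "organism": "Neotamias sp. 3",
            "gene": "CYTB",
            "sequence": "ACGT",
        },
        Source.NCBI,
    )
    return TotalTable(records=[r1, r2, r3])
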