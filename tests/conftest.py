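import datetime as dt

import pytest

from evoclock.sequence_io import Dataset, SampleMetadata, SequenceRecord


@pytest.fixture
def small_dataset() -> Dataset:
    """Reference plus four dated samples, one per week, with simple metadata."""
    ref = SequenceRecord(id="ref", sequence="ACGT" * 25)
    samples = []
    for i in range(4):
        seq = SequenceRecord(id=f"s{i}", sequence="ACGT" * 25)
        meta = SampleMetadata(
            id=f"s{i}",
            collection_date=dt.date(2021, 1, 1) + dt.timedelta(days=7 * i),
            extra={"country": "UK" if i % 2 == 0 else "USA"},
        )
        samples.append((seq, meta))
    return Dataset(reference=ref, samples=samples)


def write_lines(path, text: str) -> str:
    path.write_text(text)
    return str(path)
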