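import pytest

from bonechron import (
    BoneRecord,
    BurialClass,
    OccurrenceRecord,
    Source,
)


@pytest.fixture
def bone_records():
    """Six bones, two burial classes, three regions, cold-to-warm MATs."""
    mk = BoneRecord
    return [
        mk("b1", "svalbard", "caribou", 1800.0, 60.0, -6.0, BurialClass.NEVER_BURIED),
        mk("b2", "svalbard", "caribou", 1200.0, 40.0, -6.0, BurialClass.POTENTIALLY_NEVER_BURIED),
        mk("b3", "ellesmere", "caribou", 2100.0, 80.0, -18.0, BurialClass.NEVER_BURIED),
        mk("b4", "ellesmere", "muskox", 3600.0, 90.0, -18.0, BurialClass.POTENTIALLY_NEVER_BURIED),
        mk("b5", "yellowstone", "elk", 160.0, 30.0, 2.0, BurialClass.NEVER_BURIED),
        mk("b6", "antarctica", "seal", 5100.0, 120.0, -12.0, BurialClass.NEVER_BURIED),
    ]


@pytest.fixture
def occurrence_records():
    """A small mixed fossil/eDNA series for one region."""
    mk = OccurrenceRecord
    return [
        mk("f1", "siberia", Source.FOSSIL, 14000.0, 200.0),
        mk("f2", "siberia", Source.FOSSIL, 13000.0, 150.0),
        mk("f3", "siberia", Source.FOSSIL, 12100.0, 180.0),
        mk("f4", "siberia", Source.FOSSIL, 11000.0, 120.0),
        mk("e1", "siberia", Source.EDNA, 10500.0, 300.0),
        mk("e2", "siberia", Source.EDNA, 8600.0, 250.0),
    ]
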