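import pytest

from phonealign.types import LabeledSegment, PhoneInventory, default_inventory


@pytest.fixture(scope="session")
def inventory() -> PhoneInventory:
    return default_inventory()


def seg(label: str, start: float, end: float) -> LabeledSegment:
    return LabeledSegment(label=label, start=start, end=end)
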