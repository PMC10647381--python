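import struct
import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module


@pytest.fixture
def rng():
    return np.random.default_rng(20231)


def write_mit_annotations(path: Path, samples, codes) -> None:
    """Encode beats in the MIT annotation format (test helper).

    Uses plain (code, delta) words for gaps under 1024 samples and a
    SKIP(59) pseudo-annotation for longer gaps.
    """
    data = bytearray()
    prev = 0
    for s, code in zip(samples, codes):
        delta = s - prev
        if delta > 1023:
            data += struct.pack("<H", 59 << 10)
            data += struct.pack("<HH", (delta >> 16) & 0xFFFF, delta & 0xFFFF)
            delta = 0
        data += struct.pack("<H", (code << 10) | delta)
        prev = s
    data += struct.pack("<H", 0)  # end of annotations
    path.write_bytes(bytes(data))


@pytest.fixture
def mit_writer():
    return write_mit_annotations
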