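"""Deterministic seed derivation.

All randomness in the package flows from one master seed through named
substreams, so results are reproducible and independent of scheduling
(worker count, candidate evaluation order).
"""

from __future__ import annotations

import zlib

import numpy as np


def derive_seed(*parts: int | str) -> int:
    """Derive a 32-bit seed from a master seed plus context labels.

    Parts may be integers (seeds, iteration counters, feature indices) or
    strings (substream names); strings are hashed with CRC-32 so the same
    labels always map to the same stream.
    """
    ints = []
    for p in parts:
        if isinstance(p, str):
            ints.append(zlib.crc32(p.encode("utf-8")))
        else:
            ints.append(int(p) & 0xFFFFFFFF)
    return int(np.random.SeedSequence(ints).generate_state(1)[0])
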