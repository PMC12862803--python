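"""Shared helpers: named, reproducible random substreams."""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, name: str) -> np.random.Generator:
    """Independent generator derived from a master seed and a stream name.

    All randomness in the package flows from one master seed through named
    substreams, so changing e.g. the fold split leaves subsampling intact.
    """
    key = zlib.crc32(name.encode("utf-8")) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, key]))
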