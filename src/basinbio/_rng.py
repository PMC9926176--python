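"""Named random streams fanned out from one master seed.

Each pipeline stage draws from its own labelled stream so stages can be
rerun independently yet reproducibly from a single master seed.
"""

from __future__ import annotations

import zlib

import numpy as np


def seed_stream(master_seed: int, label: str) -> np.random.Generator:
    """Deterministic per-label generator derived from the master seed."""
    key = zlib.crc32(label.encode("utf8"))
    return np.random.default_rng(np.random.SeedSequence(int(master_seed), spawn_key=(key,)))
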