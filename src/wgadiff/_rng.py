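"""Seed-stream derivation.

All randomness flows from one master seed.  Each pipeline stage draws from a
child stream derived from (master_seed, stage label), so a stage can be
reproduced in isolation and adding a stage never perturbs the others.
"""

from __future__ import annotations

import zlib

import numpy as np

_MOD = 2**31


def derive_seed(master_seed: int, label: str) -> int:
    """Deterministic child seed (< 2**31) for a labeled stage."""
    ss = np.random.SeedSequence([int(master_seed) % _MOD, zlib.crc32(label.encode())])
    return int(ss.generate_state(1)[0] % _MOD)


def child_rng(master_seed: int, label: str) -> np.random.Generator:
    return np.random.default_rng(derive_seed(master_seed, label))
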