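"""Deterministic seed derivation: every stochastic stage gets its seed from the
global seed plus a stage tag, so one integer in the run manifest reproduces a
whole experiment."""

from __future__ import annotations

import hashlib

import numpy as np

_MOD = 2**31 - 1


def derive_seed(master: int, tag: str) -> int:
    """Stable sub-seed in [0, 2^31-1) from a master seed and a stage tag."""
    digest = hashlib.sha256(f"{int(master)}:{tag}".encode()).digest()
    return int.from_bytes(digest[:8], "big") % _MOD


def rng_for(master: int, tag: str) -> np.random.Generator:
    return np.random.default_rng(derive_seed(master, tag))
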