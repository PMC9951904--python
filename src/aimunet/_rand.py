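"""Counter-based random streams keyed by (seed, tokens).

Philox keys derived from a SHA-256 of the key tuple give order-independent,
parallel-safe reproducibility: the stream for any (patient, slice) can be
reconstructed in isolation.
"""

from __future__ import annotations

import hashlib

import numpy as np


def keyed_rng(seed: int, *tokens) -> np.random.Generator:
    digest = hashlib.sha256(repr((seed, tokens)).encode()).digest()
    key = np.frombuffer(digest[:16], dtype=np.uint64)  # Philox4x64 takes a 2-word key
    return np.random.Generator(np.random.Philox(key=key))
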