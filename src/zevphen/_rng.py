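"""Named random substreams derived from one global seed.

Every stochastic stage draws from its own substream so that adding or
reordering stages never perturbs the randomness seen by the others.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["substream", "child_seed"]


def child_seed(seed: int, name: str) -> int:
    """Derive a stable 31-bit child seed from (seed, stage name)."""
    digest = hashlib.sha256(f"{seed}:{name}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator seeded deterministically for stage ``name``."""
    return np.random.default_rng(child_seed(seed, name))
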