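"""Seed plumbing: one global seed, named per-stage substreams."""

from __future__ import annotations

import hashlib

import numpy as np


def substream_seed(seed: int, name: str) -> int:
    """Derive a deterministic 31-bit child seed from (seed, stage name)."""
    digest = hashlib.sha256(f"{int(seed)}:{name}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def substream(seed: int, name: str) -> np.random.Generator:
    """A named random substream of the global seed.

    Every stochastic stage draws from one of these; no stage uses an
    unseeded source, so a run is fully determined by the global seed.
    """
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) % (2**31), substream_seed(seed, name)])
    )
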