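"""Deterministic per-stage random substreams from a single global seed."""

from __future__ import annotations

import hashlib

import numpy as np


def substream(seed: int, tag: str) -> np.random.Generator:
    """Generator for a named stage, reproducible given (seed, tag).

    The tag is hashed so that adding a stage never perturbs the streams of
    existing stages.
    """
    digest = hashlib.sha256(tag.encode()).digest()
    tag_int = int.from_bytes(digest[:8], "little")
    return np.random.default_rng(np.random.SeedSequence([int(seed), tag_int]))
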