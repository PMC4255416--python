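"""Named random streams derived from one global seed.

Every stochastic stage pulls its own generator from :func:`stream` so that
modules can be exercised independently while the whole pipeline stays
reproducible under a single integer seed.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["stream"]


def _name_key(name: str) -> int:
    digest = hashlib.blake2s(name.encode("utf-8"), digest_size=4).digest()
    return int.from_bytes(digest, "little") % (2**31)


def stream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator keyed by (seed, name); stable across processes."""
    return np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), _name_key(name)]))
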