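"""Named, reproducible random streams.

All stochastic stages derive their generator from a root integer seed plus a
tuple of string labels, so that independent stages never share a stream and
the whole pipeline is reproducible from a single seed.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["derive_rng", "derive_seed"]


def _label_key(labels: tuple[str, ...]) -> list[int]:
    digest = hashlib.sha256("/".join(labels).encode()).digest()
    # four 32-bit words are plenty of spawn-key entropy
    return [int.from_bytes(digest[i : i + 4], "little") for i in range(0, 16, 4)]


def derive_rng(seed: int, *labels: str) -> np.random.Generator:
    """Return a Generator for stream `labels` under root `seed`."""
    if labels:
        ss = np.random.SeedSequence(entropy=int(seed), spawn_key=_label_key(labels))
    else:
        ss = np.random.SeedSequence(entropy=int(seed))
    return np.random.default_rng(ss)


def derive_seed(seed: int, *labels: str) -> int:
    """A 31-bit integer sub-seed for stream `labels` under root `seed`."""
    return int(derive_rng(seed, *labels).integers(0, 2**31 - 1))
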