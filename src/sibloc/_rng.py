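"""Named, independent random streams derived from a single root seed.

Every stochastic stage of the pipeline (geography, cohort, kernels, each
Monte Carlo repetition, ...) draws from its own `numpy` Generator, keyed by a
string path. Streams are independent by construction (SeedSequence spawn
keys) and bit-reproducible for a given root seed.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stream"]


def _key(name: str) -> int:
    # stable 32-bit key from the stream name; crc32 keeps keys < 2**32
    return zlib.crc32(name.encode("utf-8"))


def stream(seed: int, *names: str) -> np.random.Generator:
    """Return an independent Generator for the stream named by ``names``.

    Parameters
    ----------
    seed
        Root seed of the run.
    *names
        Hierarchical stream name, e.g. ``stream(seed, "cohort", "moves")``.
    """
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=tuple(_key(n) for n in names))
    return np.random.default_rng(ss)
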