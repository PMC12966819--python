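"""Deterministic seed fan-out.

One master seed drives every stage of a run.  Stage and model seeds are
derived by hashing the master seed together with string tokens through
``numpy.random.SeedSequence``, so stages are statistically independent yet
individually reproducible, and adding a stage never perturbs the seeds of
existing ones.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["derive_seed", "derive_rng"]


def derive_seed(master_seed: int, *tokens) -> int:
    """Derive a child seed (< 2**31) from a master seed and labelling tokens."""
    keys = [zlib.crc32(str(t).encode("utf-8")) for t in tokens]
    ss = np.random.SeedSequence([int(master_seed) & 0xFFFFFFFF, *keys])
    return int(ss.generate_state(1)[0] % (2**31))


def derive_rng(master_seed: int, *tokens) -> np.random.Generator:
    """A fresh Generator seeded from :func:`derive_seed`."""
    return np.random.default_rng(derive_seed(master_seed, *tokens))
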