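"""Deterministic seed derivation.

One master seed fans out to every stochastic operation through a stable
label-based scheme, so adding an experiment never perturbs another's
randomness and every report can record the exact integer it used.
"""

from __future__ import annotations

import zlib

import numpy as np


def child_seed(master: int, *labels) -> int:
    """A child seed (< 2**31) derived from a master seed and labels."""
    keys = [int(master) % (2**31)]
    for lab in labels:
        if isinstance(lab, (int, np.integer)):
            keys.append(int(lab) % (2**31))
        else:
            keys.append(zlib.crc32(str(lab).encode()) % (2**31))
    return int(np.random.SeedSequence(keys).generate_state(1)[0] % (2**31))


def child_rng(master: int, *labels) -> np.random.Generator:
    return np.random.default_rng(child_seed(master, *labels))
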