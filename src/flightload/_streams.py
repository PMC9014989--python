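"""Deterministic RNG stream derivation.

Every stochastic stage draws from its own child stream of a single root seed,
keyed by a stable tuple, so that adding or reordering one stage never perturbs
the draws of another (stream isolation).
"""

from __future__ import annotations

import numpy as np

# Fixed stage words; appending new stages keeps existing streams stable.
STAGE_BEHAVIOR = 1
STAGE_RR = 2
STAGE_FNIRS = 3
STAGE_TLX = 4


def rng_from(root_seed: int, *key: int) -> np.random.Generator:
    """Generator for the child stream of ``root_seed`` identified by ``key``."""
    ss = np.random.SeedSequence(entropy=int(root_seed), spawn_key=tuple(int(k) for k in key))
    return np.random.Generator(np.random.PCG64(ss))


def child_seed(root_seed: int, *key: int) -> int:
    """A plain integer seed (< 2**31) for the child stream ``key``."""
    ss = np.random.SeedSequence(entropy=int(root_seed), spawn_key=tuple(int(k) for k in key))
    return int(ss.generate_state(1)[0] % (2**31))
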