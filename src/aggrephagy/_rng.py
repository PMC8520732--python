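"""Deterministic child-stream seeding.

One master seed per simulation; every aggregate and every stochastic
sub-operation draws from its own child stream, so adding an aggregate or
reordering operations does not reshuffle the randomness of the others.
"""

from __future__ import annotations

import numpy as np

# Stable operation codes used as spawn keys; never renumber.
OP_MARKERS = 1
OP_MOTION = 2
OP_SHOT_NOISE = 3
OP_READ_NOISE = 4
OP_SCRIPTS = 5
OP_FACS = 6


def child_rng(master_seed: int, *key: int) -> np.random.Generator:
    """Return a Generator for the child stream identified by ``key``.

    ``key`` is typically ``(op_code,)`` or ``(op_code, aggregate_id)``.
    """
    if not (0 <= int(master_seed) < 2**31):
        raise ValueError(f"master seed must be in [0, 2^31), got {master_seed}")
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=tuple(int(k) for k in key))
    return np.random.default_rng(ss)
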