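"""Deterministic seed fan-out.

A single master seed is split into per-stage / per-run seeds through
``numpy.random.SeedSequence`` keyed on a path of integers, so every stage
is independently re-runnable with the same stream.
"""

from __future__ import annotations

import numpy as np


def split_seed(master: int, *path: int) -> int:
    """A 31-bit child seed of ``master`` for the given integer path."""
    ss = np.random.SeedSequence(entropy=int(master), spawn_key=tuple(int(p) for p in path))
    return int(ss.generate_state(1)[0] % (2**31))
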