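"""Seed-substream derivation.

Every stochastic stage derives its generator from one user-facing integer
seed plus a stable string label, so stages can be rerun in isolation and
still reproduce a full-pipeline run bit for bit.  The label is hashed with
CRC32, which is stable across platforms and Python versions (unlike
``hash``).
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "spawn_seed"]


def substream(seed: int, *labels: str) -> np.random.Generator:
    """Return a Generator for stage ``labels`` of run ``seed``.

    ``substream(7, "simulate", "pig")`` is independent of
    ``substream(7, "simulate", "mouse")`` and reproducible across calls.
    """
    entropy = [int(seed)] + [zlib.crc32(lbl.encode()) for lbl in labels]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def spawn_seed(seed: int, *labels: str) -> int:
    """Derive a plain integer sub-seed (< 2**31) for APIs that want one."""
    entropy = [int(seed)] + [zlib.crc32(lbl.encode()) for lbl in labels]
    return int(np.random.SeedSequence(entropy).generate_state(1)[0] % (2**31))
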