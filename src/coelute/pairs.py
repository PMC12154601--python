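"""Canonical unordered orthogroup pairs.

A pair key is a 2-tuple of distinct ID strings in lexicographic order, so
``(a, b)`` and ``(b, a)`` hash and compare identically everywhere in the
pipeline.
"""

from __future__ import annotations

from itertools import combinations
from typing import Iterable

from .errors import ParameterError

PairKey = tuple[str, str]

__all__ = ["PairKey", "pair_key", "all_pairs", "cocomplex_pairs"]


def pair_key(a: str, b: str) -> PairKey:
    if a == b:
        raise ParameterError(f"self-pair not allowed: {a!r}")
    return (a, b) if a < b else (b, a)


def all_pairs(ids: Iterable[str]) -> set[PairKey]:
    """All C(n, 2) unordered pairs over a set of IDs."""
    return set(combinations(sorted(set(ids)), 2))


def cocomplex_pairs(complexes: Iterable[Iterable[str]]) -> set[PairKey]:
    """Union of within-complex member pairs; duplicates across complexes collapse."""
    out: set[PairKey] = set()
    for members in complexes:
        out |= all_pairs(members)
    return out
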