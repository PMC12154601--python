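"""Leakage-free labeled pairs from curated complex definitions.

Complexes act as internal standards: within-complex pairs are positive
labels, pairs of complex-annotated proteins never found together in any
complex are negative candidates.  Because one protein can sit in several
complexes, complexes sharing members are grouped into connected components
and train/test splits are made group-exclusive, so no test pair shares
complex context with a training pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.model_selection import GroupShuffleSplit

from ._rng import spawn_seed, substream
from .errors import ParameterError, ParseError
from .pairs import PairKey, all_pairs, cocomplex_pairs

__all__ = [
    "ComplexSet",
    "GoldStandard",
    "read_complexes",
    "filter_complex_size",
    "group_complexes",
    "make_labels",
    "split_train_test",
    "stratify_positives",
    "negative_cap",
]


@dataclass(frozen=True)
class ComplexSet:
    """Named complexes, each a set of >= 2 member IDs."""

    complexes: dict[str, frozenset[str]]

    def __post_init__(self):
        for name, members in self.complexes.items():
            if len(members) < 2:
                raise ParameterError(f"complex {name!r} has < 2 members")

    def members(self) -> set[str]:
        return set().union(*self.complexes.values()) if self.complexes else set()

    def pairs(self) -> set[PairKey]:
        return cocomplex_pairs(self.complexes.values())

    def __len__(self):
        return len(self.complexes)


@dataclass
class GoldStandard:
    """Labeled pair table: id1, id2, label (1/0), group, and after
    splitting a fold column and train/test role per fold."""

    table: pd.DataFrame
    neg_ratio: float = 3.0

    @property
    def positives(self) -> set[PairKey]:
        pos = self.table[self.table.label == 1]
        return set(zip(pos.id1, pos.id2))

    @property
    def negatives(self) -> set[PairKey]:
        neg = self.table[self.table.label == 0]
        return set(zip(neg.id1, neg.id2))

    def fold_roles(self, fold: int) -> pd.Series:
        col = f"role_fold{fold}"
        if col not in self.table:
            raise ParameterError(f"no split for fold {fold}")
        return self.table[col]


def read_complexes(path: str | Path, has_names: str | bool = "auto") -> ComplexSet:
    """One complex per line, tab-separated members, optional leading name.

    With ``has_names="auto"`` a leading name column is inferred when the
    first fields are unique line-to-line and never reappear as members.
    """
    path = Path(path)
    lines = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.rstrip("\n").split("\t")
            fields = [f for f in fields if f]
            if not fields:
                continue
            if len(fields) < 2:
                raise ParseError(f"{path.name}:{lineno}: fewer than 2 fields")
            lines.append(fields)
    if has_names == "auto":
        firsts = [f[0] for f in lines]
        rest = {m for f in lines for m in f[1:]}
        has_names = len(set(firsts)) == len(firsts) and not (set(firsts) & rest)
    complexes = {}
    for i, fields in enumerate(lines):
        name = fields[0] if has_names else f"complex{i + 1:04d}"
        members = fields[1:] if has_names else fields
        complexes[name] = frozenset(members)
    return ComplexSet(complexes)


def filter_complex_size(complexes: ComplexSet, max_size: int = 30) -> ComplexSet:
    """Drop complexes with more than ``max_size`` members (size == max_size
    is retained)."""
    return ComplexSet({n: m for n, m in complexes.complexes.items()
                       if len(m) <= max_size})


def group_complexes(complexes: ComplexSet) -> dict[str, str]:
    """Group label per complex: connected components of the graph joining
    complexes that share at least one member."""
    if not complexes.complexes:
        raise ParameterError("empty complex set")
    g = nx.Graph()
    g.add_nodes_from(complexes.complexes)
    by_member: dict[str, list[str]] = {}
    for name, members in complexes.complexes.items():
        for m in members:
            by_member.setdefault(m, []).append(name)
    for names in by_member.values():
        for other in names[1:]:
            g.add_edge(names[0], other)
    labels: dict[str, str] = {}
    for i, comp in enumerate(
        sorted(nx.connected_components(g), key=lambda c: sorted(c)[0])
    ):
        for name in comp:
            labels[name] = f"g{i:04d}"
    return labels


def negative_cap(n_positives: int, n_candidates: int | float,
                 neg_ratio: float = 3.0) -> int:
    """Number of negative labels under the class-imbalance cap:
    min(neg_ratio x positives, available candidates)."""
    if n_positives < 0 or n_candidates < 0:
        raise ParameterError("counts must be non-negative")
    return int(min(neg_ratio * n_positives, n_candidates))


def make_labels(
    complexes: ComplexSet,
    observed: set[str],
    neg_ratio: float = 3.0,
    seed: int = 0,
    exclude: ComplexSet | None = None,
) -> GoldStandard:
    """Label pairs from size-filtered complexes restricted to observed IDs.

    Positives: all within-complex pairs with both members observed.
    Negative candidates: pairs of observed complex-annotated proteins that
    never co-occur in ANY complex of ``exclude`` (default: the unfiltered
    set, so members of removed giant complexes are never mislabeled
    negative).  Negatives are drawn uniformly without replacement up to
    ``neg_ratio`` times the positive count.  Each pair carries the group of
    its complexes' connected component; negatives inherit the
    lexicographically smallest of their members' component labels.
    """
    if not observed:
        raise ParameterError("observed orthogroup set is empty")
    exclude = exclude or complexes
    groups = group_complexes(complexes)

    member_group: dict[str, str] = {}
    for name, members in complexes.complexes.items():
        for m in members:
            g = groups[name]
            if m not in member_group or g < member_group[m]:
                member_group[m] = g

    positives = {p for p in complexes.pairs()
                 if p[0] in observed and p[1] in observed}
    if not positives:
        raise ParameterError("zero positive pairs among observed orthogroups")

    annotated = sorted(complexes.members() & observed)
    forbidden = exclude.pairs() | complexes.pairs()
    candidates = sorted(all_pairs(annotated) - forbidden)

    n_neg = negative_cap(len(positives), len(candidates), neg_ratio)
    rng = substream(seed, "negatives")
    chosen_idx = rng.choice(len(candidates), size=n_neg, replace=False)
    negatives = [candidates[i] for i in sorted(chosen_idx)]

    rows = []
    for a, b in sorted(positives):
        rows.append((a, b, 1, min(member_group[a], member_group[b])))
    for a, b in negatives:
        rows.append((a, b, 0, min(member_group[a], member_group[b])))
    table = pd.DataFrame(rows, columns=["id1", "id2", "label", "group"])
    return GoldStandard(table, neg_ratio=neg_ratio)


def split_train_test(
    gold: GoldStandard,
    train_frac: float = 0.75,
    n_splits: int = 5,
    seed: int = 0,
) -> GoldStandard:
    """Group-exclusive random train/test splits (GroupShuffleSplit
    semantics): per fold, no group appears on both sides."""
    table = gold.table.copy()
    groups = table["group"].to_numpy()
    if len(np.unique(groups)) < 2:
        raise ParameterError("need >= 2 groups to split")
    gss = GroupShuffleSplit(n_splits=n_splits, train_size=train_frac,
                            random_state=spawn_seed(seed, "split"))
    for fold, (tr, te) in enumerate(gss.split(table, groups=groups)):
        role = np.full(len(table), "", dtype=object)
        role[tr] = "train"
        role[te] = "test"
        table[f"role_fold{fold}"] = role
    return GoldStandard(table, neg_ratio=gold.neg_ratio)


def stratify_positives(
    gold: GoldStandard, per_group_cap: int = 100, seed: int = 0
) -> GoldStandard:
    """Cap each group's positive pairs by uniform subsampling, then re-cap
    negatives to keep the configured negative:positive ratio."""
    table = gold.table
    rng = substream(seed, "stratify")
    keep = np.ones(len(table), dtype=bool)
    pos = table[table.label == 1]
    for g, idx in pos.groupby("group").groups.items():
        if len(idx) > per_group_cap:
            drop = rng.choice(np.asarray(idx), size=len(idx) - per_group_cap,
                              replace=False)
            keep[table.index.get_indexer(drop)] = False
    n_pos = int((table.label == 1)[keep].sum())
    neg_idx = np.asarray(table.index[(table.label == 0) & keep])
    n_neg_target = negative_cap(n_pos, len(neg_idx), gold.neg_ratio)
    if len(neg_idx) > n_neg_target:
        drop = rng.choice(neg_idx, size=len(neg_idx) - n_neg_target,
                          replace=False)
        keep[table.index.get_indexer(drop)] = False
    out = table[keep].reset_index(drop=True)
    return GoldStandard(out, neg_ratio=gold.neg_ratio)


def write_labels_tsv(gold: GoldStandard, path: str | Path) -> None:
    gold.table.to_csv(path, sep="\t", index=False)
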