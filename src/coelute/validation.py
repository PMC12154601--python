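"""Validation statistics for a scored interaction network.

Four independent lines of evidence:

* **Bin-wise external enrichment** — the score range is divided into 10
  decile bins plus a terminal exact-1.0 bin; within each bin the ratio
  A/B compares how strongly the bin's pairs capture externally positive
  pairs (A) versus externally negative pairs (B), with the tested-pair
  universe rebuilt on the proteins shared between the bin and the external
  assay.  All-by-all assays test every C(n, 2) pair; bait-prey assays test
  |B||P| − n_bp − C(n_bp, 2) pairs where n_bp = |B ∩ P|.
* **Cross-dataset elution correlation** — high-scoring pairs should
  co-elute in an independent fractionation experiment.
* **Seed propagation (guilt by association)** — each node i is ranked by
  s_i = Σ_{j in seed, j ≠ i} w_ij and AUROC measures how well seed members
  rank above the rest; a same-size random-seed null should center on 0.5.
* **Ontology mapping** — term annotations inherit orthogroups along the
  ontology DAG and redundant terms are deduplicated before use as seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, rankdata

from ._rng import substream
from .elution import ElutionMatrix
from .errors import ParameterError
from .features import pearson_feature
from .pairs import PairKey, all_pairs, pair_key

__all__ = [
    "ExternalEvidence",
    "ScoreBin",
    "EnrichmentResult",
    "count_tested_pairs",
    "tested_pair_count_bait_prey",
    "bin_scores",
    "enrichment_from_sets",
    "enrichment_score",
    "enrichment_report",
    "cross_dataset_correlation",
    "OntologyMapping",
    "propagate_annotations",
    "seed_score",
    "auroc",
    "SeedEvaluation",
    "evaluate_seed_set",
    "random_seed_null",
    "read_evidence_tsv",
    "read_annotations_tsv",
]


# --- external evidence -----------------------------------------------------

@dataclass(frozen=True)
class ExternalEvidence:
    """An independent interaction dataset with its tested-pair universe.

    ``all_by_all`` assays declare a single protein universe; ``bait_prey``
    assays declare bait and prey sets whose products are the tested pairs.
    """

    kind: str  # "all_by_all" | "bait_prey"
    positives: frozenset[PairKey]
    universe: frozenset[str]
    baits: frozenset[str] | None = None
    preys: frozenset[str] | None = None

    def __post_init__(self):
        if self.kind not in ("all_by_all", "bait_prey"):
            raise ParameterError(f"unknown evidence kind {self.kind!r}")
        if self.kind == "bait_prey" and (self.baits is None or self.preys is None):
            raise ParameterError("bait_prey evidence requires bait and prey sets")

    def singles(self) -> frozenset[str]:
        if self.kind == "bait_prey":
            return frozenset(self.baits | self.preys)
        return self.universe


def tested_pair_count_bait_prey(baits: set[str], preys: set[str]) -> int:
    """Closed-form count of unordered bait-prey pairs {b, p}, b != p:
    |B||P| − n_bp − C(n_bp, 2), with n_bp = |B ∩ P|."""
    n_bp = len(set(baits) & set(preys))
    return len(baits) * len(preys) - n_bp - n_bp * (n_bp - 1) // 2


def count_tested_pairs(ev: ExternalEvidence) -> tuple[set[PairKey], int]:
    """Enumerate the tested-pair universe and its size.

    The bait-prey size is cross-checked against the closed form; a mismatch
    would indicate a construction bug, so it is asserted.
    """
    if not ev.singles():
        raise ParameterError("empty evidence universe")
    if ev.kind == "all_by_all":
        pairs = all_pairs(ev.universe)
        return pairs, len(pairs)
    pairs = {pair_key(b, p) for b in ev.baits for p in ev.preys if b != p}
    count = tested_pair_count_bait_prey(ev.baits, ev.preys)
    assert count == len(pairs)
    return pairs, count


# --- score bins ------------------------------------------------------------

@dataclass
class ScoreBin:
    """One score bin: half-open decile [0.1(x−1), 0.1x), or the terminal
    exact-1.0 bin that captures the classifier's maximal score."""

    index: int
    lo: float
    hi: float
    closed_hi: bool
    members: set[PairKey] = field(default_factory=set)

    @property
    def interval(self) -> str:
        right = "]" if self.closed_hi else ")"
        return f"[{self.lo:.1f}, {self.hi:.1f}{right}"


def bin_scores(scores: pd.Series, scheme: str = "paper") -> list[ScoreBin]:
    """Assign every scored pair to exactly one bin.

    ``paper`` scheme: ten decile bins with half-open right edges plus a
    terminal [1.0, 1.0] bin for exact-1.0 scores.  ``merged_top`` closes
    the tenth bin at 1.0 instead (no terminal bin).
    """
    vals = scores.to_numpy(dtype=float)
    if ((vals < 0) | (vals > 1)).any():
        raise ParameterError("scores outside [0, 1]")
    if scheme == "paper":
        bins = [ScoreBin(x, 0.1 * (x - 1), 0.1 * x, False) for x in range(1, 11)]
        bins.append(ScoreBin(11, 1.0, 1.0, True))
    elif scheme == "merged_top":
        bins = [ScoreBin(x, 0.1 * (x - 1), 0.1 * x, x == 10) for x in range(1, 11)]
    else:
        raise ParameterError(f"unknown bin scheme {scheme!r}")

    edges = np.array([b.lo for b in bins[1:]] + [np.inf])
    which = np.searchsorted(edges, vals, side="right")
    if scheme == "paper":
        which = np.where(vals == 1.0, len(bins) - 1, np.minimum(which, 9))
    else:
        which = np.minimum(which, 9)
    for key, b_idx in zip(scores.index, which):
        bins[int(b_idx)].members.add(tuple(key))
    return bins


# --- enrichment ------------------------------------------------------------

@dataclass
class EnrichmentResult:
    """A/B enrichment with every intermediate set, for auditability."""

    enrichment: float | None
    flag: str  # "ok" | "infinite" | "undefined"
    a: float | None
    b: float | None
    cfms_pos: set[PairKey]
    cfms_single: set[str]
    cfms_all: set[PairKey]
    e_single: set[str]
    e_single_cfms: set[str]
    e_all: set[PairKey]
    e_pos: set[PairKey]
    e_neg: set[PairKey]


def enrichment_from_sets(cfms_pos: set[PairKey], cfms_all: set[PairKey],
                         e_pos: set[PairKey], e_neg: set[PairKey],
                         **extras) -> EnrichmentResult:
    """Core A/B arithmetic given the four pair sets.

    A = |CFMS+ ∩ E+| / |CFMSall ∩ E+| and B = |CFMS+ ∩ E−| / |CFMSall ∩ E−|.
    B = 0 flags the result "infinite"; an empty A denominator flags it
    "undefined" (the bin carries no usable external signal).
    """
    denom_a = len(cfms_all & e_pos)
    denom_b = len(cfms_all & e_neg)
    kw = dict(cfms_pos=cfms_pos, cfms_all=cfms_all, e_pos=e_pos, e_neg=e_neg)
    kw.update({k: extras.get(k, set()) for k in
               ("cfms_single", "e_single", "e_single_cfms", "e_all")})
    if denom_a == 0:
        return EnrichmentResult(None, "undefined", None, None, **kw)
    a = len(cfms_pos & e_pos) / denom_a
    if denom_b == 0:
        return EnrichmentResult(None, "infinite", a, None, **kw)
    b = len(cfms_pos & e_neg) / denom_b
    if b == 0:
        return EnrichmentResult(None, "infinite", a, 0.0, **kw)
    return EnrichmentResult(a / b, "ok", a, b, **kw)


def enrichment_score(bin_pairs: set[PairKey],
                     evidence: ExternalEvidence) -> EnrichmentResult:
    """Bin-level enrichment of external evidence.

    The external universe is restricted to proteins appearing in the bin's
    CF-MS pairs, the tested-pair universe is rebuilt on that intersection,
    and split into externally positive and negative pairs.
    """
    if not bin_pairs:
        raise ParameterError("empty bin")
    cfms_pos = set(bin_pairs)
    cfms_single = {p for pr in cfms_pos for p in pr}
    cfms_all = all_pairs(cfms_single)
    e_single = set(evidence.singles())
    e_single_cfms = e_single & cfms_single
    if evidence.kind == "all_by_all":
        e_all = all_pairs(e_single_cfms)
    else:
        b = evidence.baits & e_single_cfms
        p = evidence.preys & e_single_cfms
        e_all = {pair_key(x, y) for x in b for y in p if x != y}
    e_pos = e_all & set(evidence.positives)
    e_neg = e_all - e_pos
    return enrichment_from_sets(
        cfms_pos, cfms_all, e_pos, e_neg,
        cfms_single=cfms_single, e_single=e_single,
        e_single_cfms=e_single_cfms, e_all=e_all,
    )


def enrichment_report(scores: pd.Series, evidence: ExternalEvidence,
                      scheme: str = "paper") -> pd.DataFrame:
    """Per-bin enrichment table over all score bins with members."""
    rows = []
    for b in bin_scores(scores, scheme=scheme):
        if not b.members:
            continue
        res = enrichment_score(b.members, evidence)
        rows.append({
            "bin": b.index, "interval": b.interval,
            "n_cfms_pos": len(res.cfms_pos), "n_e_all": len(res.e_all),
            "n_e_pos": len(res.e_pos), "A": res.a, "B": res.b,
            "enrichment": res.enrichment, "flag": res.flag,
        })
    return pd.DataFrame(rows)


# --- cross-dataset correlation ---------------------------------------------

@dataclass
class CrossDatasetResult:
    observed_r: np.ndarray
    random_r: np.ndarray
    median_observed: float
    median_random: float | None
    p_value: float | None


def cross_dataset_correlation(
    pairs: set[PairKey], external: ElutionMatrix,
    n_random: int = 1000, seed: int = 0,
) -> CrossDatasetResult:
    """Pearson r of high-confidence pairs in an independent elution matrix,
    against r of random orthogroup pairs from the same matrix.

    Returns both distributions, their medians, and a one-sided
    Mann-Whitney U p-value for observed > random.
    """
    idx = set(external.data.index)
    mappable = sorted(p for p in pairs if p[0] in idx and p[1] in idx)
    if not mappable:
        raise ParameterError("no high-score pair maps into the external matrix")
    vals = external.data

    def r_of(a, b):
        return pearson_feature(vals.loc[a].to_numpy(), vals.loc[b].to_numpy())

    observed = np.array([r_of(a, b) for a, b in mappable])
    rng = substream(seed, "crossdataset")
    ids = np.array(sorted(idx))
    rand = []
    for _ in range(n_random):
        a, b = rng.choice(ids, size=2, replace=False)
        rand.append(r_of(a, b))
    random_r = np.array(rand)
    if n_random:
        p = float(mannwhitneyu(observed, random_r, alternative="greater").pvalue)
        med_r = float(np.median(random_r))
    else:
        p, med_r = None, None
    return CrossDatasetResult(observed, random_r,
                              float(np.median(observed)), med_r, p)


# --- ontology mapping ------------------------------------------------------

@dataclass
class OntologyMapping:
    """Post-inheritance term annotations with redundancy removed."""

    term_to_ogs: dict[str, frozenset[str]]
    edges: list[tuple[str, str]]  # child -> parent
    removed: set[str]
    max_jaccard: dict[str, float]
    high_overlap: dict[str, bool]


def _jaccard(a: set, b: set) -> float:
    u = len(a | b)
    return len(a & b) / u if u else 0.0


def propagate_annotations(
    term_to_ogs: dict[str, set[str]],
    edges: list[tuple[str, str]],
    training_complexes: list[set[str]] | None = None,
    jaccard_threshold: float = 0.5,
    direction: str = "ancestor_to_child",
) -> OntologyMapping:
    """Inherit annotations along the ontology DAG and deduplicate terms.

    Default direction copies ancestors' orthogroups down into descendant
    terms; ``child_to_ancestor`` implements the conventional true-path
    rule instead.  After inheritance: (i) when an ancestor and a descendant
    carry identical sets, only the ancestor is kept; (ii) when several
    remaining terms with identical sets share a common ancestor on the kept
    list, those terms are removed.  Each kept term is annotated with its
    maximum Jaccard index against the training complex sets.
    """
    g = nx.DiGraph()
    g.add_nodes_from(term_to_ogs)
    for child, parent in edges:
        g.add_edge(child, parent)  # edge points child -> parent
    if not nx.is_directed_acyclic_graph(g):
        raise ParameterError("ontology edges contain a cycle")

    ancestors = {t: nx.descendants(g, t) for t in g}  # all terms above t

    full: dict[str, set[str]] = {}
    for t in g:
        base = set(term_to_ogs.get(t, set()))
        if direction == "ancestor_to_child":
            for anc in ancestors[t]:
                base |= term_to_ogs.get(anc, set())
        elif direction == "child_to_ancestor":
            for desc in nx.ancestors(g, t):  # terms below t
                base |= term_to_ogs.get(desc, set())
        else:
            raise ParameterError(f"unknown direction {direction!r}")
        full[t] = base

    removed: set[str] = set()
    # rule (i): ancestor/descendant with identical sets -> drop descendant
    for t in g:
        for anc in ancestors[t]:
            if full[t] == full[anc]:
                removed.add(t)
                break
    # rule (ii): identical-set groups sharing a kept common ancestor
    kept = [t for t in g if t not in removed]
    by_set: dict[frozenset, list[str]] = {}
    for t in kept:
        by_set.setdefault(frozenset(full[t]), []).append(t)
    for group in by_set.values():
        if len(group) < 2:
            continue
        common = set.intersection(*(ancestors[t] for t in group))
        if any(a not in removed for a in common):
            removed.update(group)

    final = {t: frozenset(full[t]) for t in g if t not in removed}
    complexes = [set(c) for c in (training_complexes or [])]
    max_j = {
        t: max((_jaccard(set(s), c) for c in complexes), default=0.0)
        for t, s in final.items()
    }
    high = {t: j >= jaccard_threshold for t, j in max_j.items()}
    return OntologyMapping(final, list(edges), removed, max_j, high)


# --- seed propagation & AUROC ----------------------------------------------

def seed_score(network, seed_set: set[str],
               missing: str = "error") -> pd.Series:
    """Guilt-by-association score s_i = Σ_{j in seed, j ≠ i} w_ij for every
    network node.  Seed members are scored by the *other* seeds (no
    self-link).  ``missing`` controls seeds absent from the network:
    "error" raises, "drop" ignores them with the remainder used.
    """
    nodes = network.node_index
    absent = set(seed_set) - set(nodes)
    if absent:
        if missing == "error":
            raise ParameterError(f"seed(s) not in network: {sorted(absent)[:5]}")
        seed_set = set(seed_set) - absent
    if not seed_set:
        raise ParameterError("empty seed set after filtering")
    adj = network.adjacency()
    cols = [nodes.get_loc(s) for s in seed_set]
    s = adj[:, cols].sum(axis=1)
    return pd.Series(np.asarray(s).ravel(), index=nodes, name="s_i")


def auroc(scores: pd.Series | np.ndarray, positives: set[str] | np.ndarray) -> float:
    """Tie-aware AUROC of a ranking, via the rank-sum identity.

    Equivalent to averaging the ROC over all orderings of tied scores:
    AUROC = (R⁺ − n⁺(n⁺ + 1) / 2) / (n⁺ n⁻) with R⁺ the summed mid-ranks
    of the positives.
    """
    if isinstance(scores, pd.Series):
        labels = np.array([i in positives for i in scores.index])
        vals = scores.to_numpy(dtype=float)
    else:
        vals = np.asarray(scores, dtype=float)
        labels = np.asarray(positives, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ParameterError("AUROC requires both positives and negatives")
    r = rankdata(vals)  # average ranks over ties
    r_pos = r[labels].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


@dataclass
class SeedEvaluation:
    seed_set: frozenset[str]
    scores: pd.Series
    auroc: float


def evaluate_seed_set(network, seed_set: set[str],
                      min_annotation_size: int = 5,
                      missing: str = "error") -> SeedEvaluation:
    """Rank all nodes by s_i and score the ranking with seed members as
    positives.  Seed sets smaller than ``min_annotation_size`` (after
    restriction to the network) are rejected, mirroring the requirement of
    at least five in-network orthogroups per annotation."""
    in_net = set(seed_set) & set(network.node_index)
    if len(in_net) < min_annotation_size:
        raise ParameterError(
            f"seed set has {len(in_net)} in-network members; "
            f"need >= {min_annotation_size}"
        )
    s = seed_score(network, seed_set, missing=missing)
    return SeedEvaluation(frozenset(in_net), s, auroc(s, in_net))


def random_seed_null(network, seed_set_size: int, n_reps: int = 1000,
                     min_annotation_size: int = 5, seed: int = 0) -> np.ndarray:
    """Null AUROC distribution from uniformly drawn same-size seed sets."""
    if seed_set_size < min_annotation_size:
        raise ParameterError(
            f"seed_set_size {seed_set_size} < minimum {min_annotation_size}"
        )
    nodes = np.array(network.node_index)
    if seed_set_size > len(nodes):
        raise ParameterError("seed set larger than the network")
    rng = substream(seed, "random_seed_null")
    adj = np.asarray(network.adjacency())
    out = np.empty(n_reps)
    for k in range(n_reps):
        pick = rng.choice(len(nodes), size=seed_set_size, replace=False)
        s = adj[:, pick].sum(axis=1)
        labels = np.zeros(len(nodes), dtype=bool)
        labels[pick] = True
        out[k] = auroc(s, labels)
    return out


# --- readers ---------------------------------------------------------------

def read_evidence_tsv(pair_path, kind: str = "all_by_all",
                      bait_path=None, prey_path=None,
                      universe=None) -> ExternalEvidence:
    """Positive-pair TSV plus optional bait/prey list files.

    Without an explicit universe, the all-by-all universe defaults to the
    proteins seen in the positive pairs.
    """
    df = pd.read_csv(pair_path, sep="\t", header=None, names=["id1", "id2"],
                     dtype=str)
    positives = frozenset(pair_key(a, b) for a, b in zip(df.id1, df.id2))
    baits = preys = None
    if kind == "bait_prey":
        baits = frozenset(pd.read_csv(bait_path, header=None)[0].astype(str))
        preys = frozenset(pd.read_csv(prey_path, header=None)[0].astype(str))
        universe = baits | preys
    elif universe is None:
        universe = {p for pr in positives for p in pr}
    return ExternalEvidence(kind, positives, frozenset(universe), baits, preys)


def read_annotations_tsv(term_path, edge_path):
    terms_df = pd.read_csv(term_path, sep="\t", header=None,
                           names=["term", "orthogroup"], dtype=str)
    terms: dict[str, set[str]] = {}
    for t, og in zip(terms_df.term, terms_df.orthogroup):
        terms.setdefault(t, set()).add(og)
    edges_df = pd.read_csv(edge_path, sep="\t", header=None,
                           names=["child", "parent"], dtype=str)
    return terms, list(zip(edges_df.child, edges_df.parent))
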