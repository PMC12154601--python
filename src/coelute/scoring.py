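"""Supervised interaction scoring.

An extremely-randomized-trees ensemble is trained on gold-standard labeled
pairs with group-exclusive cross-validation, then scores every observed
pair with its positive-class probability (the CF-MS score in [0, 1]).  A
precision-recall sweep on fully withheld labeled pairs calibrates a score
threshold at a target false discovery rate (FDR = 1 − precision), and the
pairs at or above the threshold form the weighted interaction network.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import ExtraTreesClassifier
from sklearn.metrics import average_precision_score
from sklearn.model_selection import GroupKFold

from ._rng import spawn_seed
from .errors import ParameterError, UncalibratableError
from .goldstd import GoldStandard

__all__ = [
    "TrainedScorer",
    "PRCurve",
    "ScoredNetwork",
    "select_features",
    "train_scorer",
    "score_pairs",
    "precision_recall_curve",
    "select_threshold",
    "build_network",
]


def _training_rows(table: pd.DataFrame, gold: GoldStandard,
                   fold: int | None) -> pd.DataFrame:
    sub = gold.table
    if fold is not None:
        sub = sub[sub[f"role_fold{fold}"] == "train"]
    keys = pd.MultiIndex.from_arrays([sub.id1, sub.id2])
    present = keys.isin(table.index)
    if not present.all():
        missing = keys[~present][:3].tolist()
        raise ParameterError(f"labeled pairs absent from feature table: {missing}")
    return sub


def select_features(
    table: pd.DataFrame, gold: GoldStandard, top_k: int = 100,
    seed: int = 0, fold: int | None = 0, n_estimators: int = 256,
) -> list[str]:
    """Rank feature columns by impurity importance of an
    extremely-randomized-trees fit on TRAINING pairs only; return the top k.
    """
    if top_k <= 0:
        raise ParameterError("top_k must be positive")
    if top_k > table.shape[1]:
        raise ParameterError(
            f"top_k={top_k} exceeds {table.shape[1]} feature columns"
        )
    sub = _training_rows(table, gold, fold)
    x = table.loc[pd.MultiIndex.from_arrays([sub.id1, sub.id2])]
    ranker = ExtraTreesClassifier(
        n_estimators=n_estimators, random_state=spawn_seed(seed, "select"),
        n_jobs=1,
    )
    ranker.fit(x.to_numpy(), sub.label.to_numpy())
    order = np.argsort(ranker.feature_importances_)[::-1]
    return [table.columns[i] for i in order[:top_k]]


@dataclass
class TrainedScorer:
    """Fitted ensemble plus its training provenance.

    ``oof_scores`` holds the out-of-fold score of every training pair
    (each pair scored by the CV model that did not see its group), the
    pool used to calibrate the score threshold without touching the
    withheld test split."""

    model: ExtraTreesClassifier
    features: list[str]
    cv_average_precision: list[float]
    n_folds: int
    seed: int
    oof_scores: pd.Series | None = None
    oof_labels: np.ndarray | None = None

    def save_metadata(self, path: str | Path) -> None:
        meta = {
            "features": self.features,
            "cv_average_precision": self.cv_average_precision,
            "n_folds": self.n_folds,
            "seed": self.seed,
            "n_estimators": self.model.n_estimators,
        }
        Path(path).write_text(json.dumps(meta, indent=2))


def train_scorer(
    table: pd.DataFrame, gold: GoldStandard, features: list[str],
    n_folds: int = 5, seed: int = 0, fold: int | None = 0,
    n_estimators: int = 256,
) -> TrainedScorer:
    """Fit the tree ensemble on training pairs with group-exclusive
    internal cross-validation (average precision per CV fold reported),
    then refit on all training pairs."""
    missing = [f for f in features if f not in table.columns]
    if missing:
        raise ParameterError(f"features absent from table: {missing[:5]}")
    sub = _training_rows(table, gold, fold)
    x = table.loc[pd.MultiIndex.from_arrays([sub.id1, sub.id2]), features]
    y = sub.label.to_numpy()
    groups = sub.group.to_numpy()

    def new_model():
        return ExtraTreesClassifier(
            n_estimators=n_estimators,
            random_state=spawn_seed(seed, "train"), n_jobs=1,
        )

    cv_scores: list[float] = []
    oof = np.full(len(y), np.nan)
    n_groups = len(np.unique(groups))
    gkf = GroupKFold(n_splits=min(n_folds, n_groups))
    for k, (tr, te) in enumerate(gkf.split(x, y, groups=groups)):
        if len(np.unique(y[tr])) < 2:
            raise ParameterError(f"CV fold {k} has single-class training labels")
        if len(np.unique(y[te])) < 2:
            raise ParameterError(f"CV fold {k} has single-class test labels")
        m = new_model().fit(x.to_numpy()[tr], y[tr])
        p = m.predict_proba(x.to_numpy()[te])[:, 1]
        oof[te] = p
        cv_scores.append(float(average_precision_score(y[te], p)))

    final = new_model().fit(x.to_numpy(), y)
    oof_scores = pd.Series(oof, index=x.index, name="oof_score")
    return TrainedScorer(final, list(features), cv_scores, n_folds, seed,
                         oof_scores, y.copy())


def score_pairs(scorer: TrainedScorer, table: pd.DataFrame) -> pd.Series:
    """CF-MS score (positive-class probability) for every pair in the
    feature table, labeled or not."""
    missing = [f for f in scorer.features if f not in table.columns]
    if missing:
        raise ParameterError(f"missing feature column(s): {missing[:5]}")
    x = table[scorer.features].to_numpy()
    pos_col = list(scorer.model.classes_).index(1)
    p = scorer.model.predict_proba(x)[:, pos_col]
    return pd.Series(p, index=table.index, name="cfms_score")


@dataclass
class PRCurve:
    """Cumulative precision/recall/FDR over descending score thresholds.

    Tied scores collapse to a single threshold step, so precision never
    oscillates within a tie block."""

    thresholds: np.ndarray  # descending unique scores
    tp: np.ndarray  # cumulative true positives at each threshold
    n_at: np.ndarray  # cumulative pairs at each threshold
    n_pos: int
    n_neg: int

    @property
    def precision(self) -> np.ndarray:
        return self.tp / self.n_at

    @property
    def recall(self) -> np.ndarray:
        return self.tp / self.n_pos

    @property
    def fdr(self) -> np.ndarray:
        return 1.0 - self.precision

    def fdr_estimate(self, smoothing: str = "none",
                     confidence: float = 0.90) -> np.ndarray:
        """Cumulative FDR under three estimators.

        ``none``: the plain ratio FP / n.  ``laplace``: add-one smoothing
        (FP + 1) / (n + 2), a mild guard against threshold overshoot on
        sparse calibration sets.  ``jeffreys``: the one-sided upper
        ``confidence`` bound of the Jeffreys Beta(FP + 1/2, TP + 1/2)
        posterior — calibrating against this bound *controls* the FDR at
        the target rather than merely matching it in expectation.  All
        three converge to the plain ratio as n grows."""
        fp = self.n_at - self.tp
        if smoothing == "none":
            return self.fdr
        if smoothing == "laplace":
            return (fp + 1.0) / (self.n_at + 2.0)
        if smoothing == "jeffreys":
            from scipy.stats import beta

            return beta.ppf(confidence, fp + 0.5, self.tp + 0.5)
        raise ParameterError(f"unknown smoothing {smoothing!r}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "threshold": self.thresholds, "precision": self.precision,
            "recall": self.recall, "fdr": self.fdr,
        })


def precision_recall_curve(scores: pd.Series | np.ndarray,
                           labels: np.ndarray) -> PRCurve:
    """Threshold sweep at each unique score (descending) on withheld pairs."""
    vals = scores.to_numpy() if isinstance(scores, pd.Series) else np.asarray(scores)
    labels = np.asarray(labels).astype(int)
    if vals.shape != labels.shape:
        raise ParameterError("scores and labels differ in length")
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0:
        raise ParameterError("no positive labels in the test set")
    order = np.argsort(-vals, kind="stable")
    v = vals[order]
    l = labels[order]
    tp = np.cumsum(l)
    n_at = np.arange(1, len(l) + 1)
    # keep the LAST index of each tie block: cumulative counts at threshold
    uniq_last = np.nonzero(np.diff(np.append(v, -np.inf)))[0]
    return PRCurve(v[uniq_last], tp[uniq_last].astype(float),
                   n_at[uniq_last].astype(float), n_pos, n_neg)


def select_threshold(curve: PRCurve, target_fdr: float = 0.08,
                     smoothing: str = "none") -> float:
    """Smallest score threshold whose cumulative FDR is <= the target.

    With ``smoothing="laplace"`` the smoothed estimate of
    :meth:`PRCurve.fdr_estimate` is compared to the target instead of the
    plain ratio.  Raises :class:`UncalibratableError` (carrying the best
    achievable FDR) when no threshold qualifies."""
    if curve.thresholds.size == 0:
        raise ParameterError("empty PR curve")
    est = curve.fdr_estimate(smoothing)
    ok = est <= target_fdr
    if not ok.any():
        raise UncalibratableError(target_fdr, float(est.min()))
    return float(curve.thresholds[np.nonzero(ok)[0][-1]])


@dataclass
class ScoredNetwork:
    """Thresholded CF-MS score network: edges with weight = score."""

    edges: pd.DataFrame  # columns id1, id2, weight
    threshold: float
    _adj: np.ndarray | None = field(default=None, repr=False, compare=False)

    @property
    def node_index(self) -> pd.Index:
        return pd.Index(sorted(set(self.edges.id1) | set(self.edges.id2)))

    @property
    def n_nodes(self) -> int:
        return len(self.node_index)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def adjacency(self) -> np.ndarray:
        """Dense symmetric weight matrix over node_index order."""
        if self._adj is None:
            nodes = self.node_index
            loc = {n: i for i, n in enumerate(nodes)}
            a = np.zeros((len(nodes), len(nodes)))
            for r in self.edges.itertuples(index=False):
                i, j = loc[r.id1], loc[r.id2]
                a[i, j] = a[j, i] = r.weight
            self._adj = a
        return self._adj

    def to_igraph(self):
        import igraph as ig

        nodes = list(self.node_index)
        loc = {n: i for i, n in enumerate(nodes)}
        g = ig.Graph(
            n=len(nodes),
            edges=[(loc[r.id1], loc[r.id2])
                   for r in self.edges.itertuples(index=False)],
        )
        g.vs["name"] = nodes
        g.es["weight"] = self.edges.weight.tolist()
        return g

    def write_tsv(self, path: str | Path) -> None:
        self.edges.to_csv(path, sep="\t", index=False)


def build_network(scores: pd.Series, threshold: float) -> ScoredNetwork:
    """Retain pairs scoring at or above the threshold; isolated orthogroups
    (no retained edge) are excluded by construction."""
    if not 0 <= threshold <= 1:
        raise ParameterError("threshold must lie in [0, 1]")
    sel = scores[scores >= threshold]
    edges = pd.DataFrame({
        "id1": [k[0] for k in sel.index],
        "id2": [k[1] for k in sel.index],
        "weight": sel.to_numpy(),
    })
    return ScoredNetwork(edges, threshold)
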