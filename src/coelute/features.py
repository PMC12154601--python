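"""Co-elution similarity features.

Four measures per elution matrix — Pearson's r, Spearman's rho, inverted/
normalized Euclidean distance, and Bray-Curtis similarity — each computed
on Poisson-noise-augmented count profiles and averaged over noise
replicates.  Columns are named ``<matrix>__<measure>``; rows are canonical
unordered orthogroup pairs.

Correlation measures are location/scale invariant so profiles enter as raw
counts (plus noise); Euclidean distances are inverted and rescaled by the
largest pairwise distance within the same matrix so that identical profiles
score 1 and the most dissimilar observed pair scores 0.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

from ._rng import substream
from .elution import ElutionMatrix
from .errors import ParameterError
from .pairs import pair_key

__all__ = [
    "MEASURES",
    "add_poisson_noise",
    "pearson_feature",
    "spearman_feature",
    "euclidean_similarity",
    "braycurtis_similarity",
    "build_feature_table",
    "write_feature_table",
    "read_feature_table",
]

MEASURES = ("pearson", "spearman", "euclidean", "braycurtis")


def add_poisson_noise(values: np.ndarray, lam: float, eps: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Return ``values + eps * Poisson(lam)`` drawn i.i.d. per cell."""
    if lam < 0 or eps < 0:
        raise ParameterError("noise lam and eps must be >= 0")
    values = np.asarray(values, dtype=float)
    if lam == 0 or eps == 0:
        return values.copy()
    return values + eps * rng.poisson(lam, size=values.shape)


def _check_lengths(u, v):
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ParameterError(f"length mismatch: {u.shape} vs {v.shape}")
    if u.size < 2:
        raise ParameterError("profiles must have length >= 2")
    return u, v


def pearson_feature(u, v, fill: float = 0.0) -> float:
    """Product-moment correlation; zero-variance input returns ``fill``."""
    u, v = _check_lengths(u, v)
    if u.std() == 0 or v.std() == 0:
        return fill
    return float(np.corrcoef(u, v)[0, 1])


def spearman_feature(u, v, fill: float = 0.0) -> float:
    """Pearson correlation of tie-averaged ranks."""
    u, v = _check_lengths(u, v)
    return pearson_feature(rankdata(u), rankdata(v), fill=fill)


def euclidean_similarity(matrix: np.ndarray) -> np.ndarray:
    """All-pairs inverted Euclidean similarity within one matrix.

    ``s(u, v) = 1 - d(u, v) / d_max`` with ``d_max`` the largest pairwise
    distance among the matrix's rows; identical profiles score 1 and the
    farthest pair scores 0.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape[0] < 2:
        raise ParameterError("euclidean_similarity needs >= 2 rows")
    d = pdist(matrix, metric="euclidean")
    d_max = d.max()
    if d_max == 0:
        return np.ones((matrix.shape[0],) * 2)
    return 1.0 - squareform(d) / d_max


def braycurtis_similarity(u, v, fill: float = 0.0) -> float:
    """``1 - sum|u - v| / sum(u + v)`` on non-negative profiles."""
    u, v = _check_lengths(u, v)
    if (u < 0).any() or (v < 0).any():
        raise ParameterError("Bray-Curtis requires non-negative entries")
    denom = (u + v).sum()
    if denom == 0:
        return fill
    return float(1.0 - np.abs(u - v).sum() / denom)


def _pairwise_measures(values: np.ndarray, fill: float) -> dict[str, np.ndarray]:
    """n x n similarity matrices for all four measures on one (noise-added)
    matrix.  Vectorized: correlations via matrix products on standardized /
    ranked rows, distances via scipy pdist."""
    n = values.shape[0]

    def corr(x):
        sd = x.std(axis=1)
        ok = sd > 0
        xc = x - x.mean(axis=1, keepdims=True)
        norm = np.sqrt((xc ** 2).sum(axis=1))
        norm[~ok] = 1.0
        xn = xc / norm[:, None]
        c = xn @ xn.T
        c[~ok, :] = fill
        c[:, ~ok] = fill
        return np.clip(c, -1.0, 1.0)

    ranks = np.apply_along_axis(rankdata, 1, values)
    out = {"pearson": corr(values), "spearman": corr(ranks)}

    out["euclidean"] = euclidean_similarity(values) if n >= 2 else np.ones((n, n))

    if n >= 2:
        with np.errstate(invalid="ignore", divide="ignore"):
            d_bc = pdist(values, metric="braycurtis")
        bc = 1.0 - squareform(np.where(np.isnan(d_bc), 1.0 - fill, d_bc))
        np.fill_diagonal(bc, 1.0)
    else:
        bc = np.ones((n, n))
    out["braycurtis"] = bc
    return out


def build_feature_table(
    matrices: dict[str, ElutionMatrix],
    noise_lam: float = 1.0,
    noise_eps: float = 0.1,
    noise_reps: int = 3,
    seed: int = 0,
    fill: float = 0.0,
) -> pd.DataFrame:
    """Assemble the all-by-all pair feature table.

    Rows: every unordered pair of orthogroups observed (non-zero row) in at
    least one matrix, as a (id1, id2) MultiIndex in canonical order.
    Columns: ``<matrix>__<measure>`` for each matrix and measure, averaged
    over ``noise_reps`` Poisson-noise replicates.  Pairs with a member
    absent or all-zero in a matrix get ``fill`` in that matrix's columns.
    """
    if not matrices:
        raise ParameterError("build_feature_table requires >= 1 matrix")
    observed: dict[str, dict[str, np.ndarray]] = {}
    for name, m in matrices.items():
        tot = m.row_totals()
        present = tot[tot > 0].index
        observed[name] = m.data.loc[present]

    universe = sorted(set().union(*(set(df.index) for df in observed.values())))
    if len(universe) < 2:
        raise ParameterError("need >= 2 observed orthogroups")
    idx_of = {og: i for i, og in enumerate(universe)}
    n = len(universe)
    iu = np.triu_indices(n, k=1)

    cols = {}
    for name in matrices:
        df = observed[name]
        rows = [idx_of[og] for og in df.index]
        vals = df.to_numpy(dtype=float)
        acc = {meas: np.zeros((len(rows),) * 2) for meas in MEASURES}
        for r in range(noise_reps):
            rng = substream(seed, "noise", name, str(r))
            noisy = add_poisson_noise(vals, noise_lam, noise_eps, rng)
            per = _pairwise_measures(noisy, fill)
            for meas in MEASURES:
                acc[meas] += per[meas]
        for meas in MEASURES:
            full = np.full((n, n), fill, dtype=float)
            sub = acc[meas] / noise_reps
            full[np.ix_(rows, rows)] = sub
            cols[f"{name}__{meas}"] = full[iu]

    index = pd.MultiIndex.from_arrays(
        [np.array(universe)[iu[0]], np.array(universe)[iu[1]]],
        names=["id1", "id2"],
    )
    return pd.DataFrame(cols, index=index)


def write_feature_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t")


def read_feature_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    bad = df.apply(lambda r: not (r["id1"] < r["id2"]), axis=1)
    if bad.any():
        raise ParameterError("pair keys not in canonical (id1 < id2) order")
    return df.set_index(["id1", "id2"])


def pair_features(table: pd.DataFrame, a: str, b: str) -> pd.Series:
    """Feature vector of one unordered pair."""
    return table.loc[pair_key(a, b)]
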