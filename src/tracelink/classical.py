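"""Classical neighborhood link predictors adapted to out-link information.

Retrograde tracing observes only the in-rows of injected targets, which means
the only information available *for every ordered pair* (u, v) is the set of
out-links of u and v into the injected set I.  The five classical predictors
(common neighbors, preferential attachment, Adamic-Adar, resource allocation,
Jaccard) are therefore reformulated over out-neighborhoods.  Writing
``w(z, x)`` for the weight of the out-link x -> z (matrix entry ``w[z, x]``,
z an injected target) and ``S(z) = sum_x w(x, z)`` for the observed
out-strength of z:

    CN2(u, v) = 1/2 * sum_{z in I} [w(z,u) + w(z,v)]
    PA2(u, v) = mean_{z in Go(u)} w(z,u) * mean_{z in Go(v)} w(z,v)
    AA2(u, v) = 1/2 * sum_{z in I} [w(z,u) + w(z,v)] / log S(z)
    RA2(u, v) =       sum_{z in I} [w(z,u) + w(z,v)] / S(z)
    JA2(u, v) = sum_{z in I} min(w(z,u), w(z,v)) / sum_{z in I} max(w(z,u), w(z,v))

where Go(x) = {z in I : w(z, x) > 0} is the out-neighborhood of x within the
training targets.  All five scores are symmetric in (u, v); JA2 lies in [0, 1].
Path-based predictors (Katz, PageRank, shortest path) are excluded: no paths
exist into non-injected areas.
"""

from __future__ import annotations

import numpy as np

from .errors import EmptyTrainingSet, UnknownMethod

CLASSICAL_METHODS = ("CN2", "PA2", "AA2", "RA2", "JA2")


def _check(w_rows: np.ndarray, method: str) -> np.ndarray:
    if method not in CLASSICAL_METHODS:
        raise UnknownMethod(f"unknown classical method {method!r}; choose from {CLASSICAL_METHODS}")
    w_rows = np.asarray(w_rows, dtype=float)
    if w_rows.ndim != 2 or w_rows.shape[0] == 0:
        raise EmptyTrainingSet("classical scores need at least one training target row")
    return w_rows


def _pa_factor(col: np.ndarray, x_in_train: bool, gamma_includes_self: bool) -> float:
    # |Go(x)|, optionally counting x itself as a (zero-weight) member
    deg = int((col > 0).sum())
    if gamma_includes_self and x_in_train:
        deg += 1
    return float(col.sum() / deg) if deg > 0 else 0.0


def classical_score(
    method: str,
    u: int,
    v: int,
    w_rows: np.ndarray,
    train_targets: np.ndarray,
    *,
    gamma_includes_self: bool = False,
) -> float:
    """Score the ordered pair (u, v) with one classical predictor.

    Parameters
    ----------
    u, v
        Global column indices of the pair's endpoints (u != v).
    w_rows
        Training-view weight matrix, shape (|I_train|, N): row r holds the
        in-row of training target ``train_targets[r]``.
    train_targets
        Global indices of the training targets, aligned with ``w_rows`` rows.
    gamma_includes_self
        Whether the out-neighborhood of x counts x itself (as a zero-weight
        member) when x is a training target; affects PA2 only.
    """
    w_rows = _check(w_rows, method)
    if u == v:
        raise ValueError("self-pairs (u, u) are not scored")
    train_targets = np.asarray(train_targets, dtype=int)
    cu = w_rows[:, u]
    cv = w_rows[:, v]

    if method == "CN2":
        return float(0.5 * (cu.sum() + cv.sum()))
    if method == "PA2":
        return _pa_factor(cu, u in train_targets, gamma_includes_self) * _pa_factor(
            cv, v in train_targets, gamma_includes_self
        )
    if method == "JA2":
        denom = np.maximum(cu, cv).sum()
        return float(np.minimum(cu, cv).sum() / denom) if denom > 0 else 0.0

    # AA2 / RA2 share the per-z out-strength S(z) over training rows
    strength = w_rows[:, train_targets].sum(axis=0)  # S(z) for z in I_train
    both = cu + cv
    if method == "RA2":
        ok = strength > 0
        return float((both[ok] / strength[ok]).sum())
    # AA2: skip log-denominators <= 0 (S(z) <= 1), mirroring Adamic-Adar's
    # degree >= 2 convention; natural log (base only rescales ranks)
    ok = strength > 1
    return float(0.5 * (both[ok] / np.log(strength[ok])).sum())


def classical_score_all(
    method: str,
    pairs: np.ndarray,
    w_rows: np.ndarray,
    train_targets: np.ndarray,
    *,
    gamma_includes_self: bool = False,
) -> np.ndarray:
    """Vectorized scores for an array of ordered pairs, shape (n_pairs, 2).

    Agrees elementwise with :func:`classical_score`.
    """
    w_rows = _check(w_rows, method)
    pairs = np.asarray(pairs, dtype=int).reshape(-1, 2)
    if pairs.shape[0] == 0:
        return np.zeros(0)
    train_targets = np.asarray(train_targets, dtype=int)
    U, V = pairs[:, 0], pairs[:, 1]
    CU = w_rows[:, U]  # (T_train, n_pairs)
    CV = w_rows[:, V]

    if method == "CN2":
        return 0.5 * (CU.sum(axis=0) + CV.sum(axis=0))
    if method == "PA2":
        col_sum = w_rows.sum(axis=0)
        deg = (w_rows > 0).sum(axis=0).astype(float)
        if gamma_includes_self:
            deg = deg.copy()
            deg[train_targets] += 1
        with np.errstate(invalid="ignore", divide="ignore"):
            factor = np.where(deg > 0, col_sum / np.maximum(deg, 1), 0.0)
        return factor[U] * factor[V]
    if method == "JA2":
        num = np.minimum(CU, CV).sum(axis=0)
        den = np.maximum(CU, CV).sum(axis=0)
        return np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)

    strength = w_rows[:, train_targets].sum(axis=0)
    both = CU + CV
    if method == "RA2":
        ok = strength > 0
        return (both[ok] / strength[ok, None]).sum(axis=0)
    ok = strength > 1
    return 0.5 * (both[ok] / np.log(strength[ok])[:, None]).sum(axis=0)


def scores_to_frame(pairs, scores, method, atlas):
    """Long-format table (source, target, method, score) for export."""
    import pandas as pd

    names = atlas.area_names
    return pd.DataFrame(
        {
            "source": [names[u] for u, _ in pairs],
            "target": [names[v] for _, v in pairs],
            "method": method,
            "score": np.asarray(scores, dtype=float),
        }
    )
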