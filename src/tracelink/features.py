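"""Feature vectors for machine-learning link prediction.

Each ordered pair (u, v) — u the source, v the target of the directed link to
be predicted — gets a fixed-length vector computed *identically for all pairs*
from out-link information into the training targets I_train only.  With A the
transformed weight matrix (A(i, x) = weight of the out-link x -> i), D the
scaled distance feature matrix and d(x) the out-degree of x into I_train, the
available feature functions are:

==========================  =================================================  ==========
id                          definition                                         length
==========================  =================================================  ==========
weighted_common_neighbors   sum_i [A(i,u) + A(i,v)]                            1
degree_plus_distance        {d(u), d(v), D(u,v)}                               3
adjacency                   {A(i,u) > 0, A(i,v) > 0 | i in I}                  2|I|
outdistance_source          {D(i,u) | i in I}                                  |I|
outdistance_target          {D(i,v) | i in I}                                  |I|
outdistance                 {D(i,u), D(i,v) | i in I}                          2|I|
fln                         {A(i,u), A(i,v) | i in I}                          2|I|
fln_plus_distance           fln  U  {D(u,v)}                                   2|I| + 1
==========================  =================================================  ==========

Per-target entries are interleaved (A(i,u), A(i,v)) with i ascending in global
area order, so learners see a fixed convention.  Entries indexed by i = u or
i = v are masked to 0: when v is itself a training target, A(v, u) *is* the
pair's label, and leaving it in place would leak ground truth into training
features and give test-time features different semantics.  Degrees and the
weighted-common-neighbor sum exclude the masked rows for the same reason.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datasets import DistanceFeatures, WeightMatrix
from .errors import EmptyTrainingSet, LabelUnavailable, NonFiniteFeature, UnknownMethod

FEATURE_SPECS = (
    "weighted_common_neighbors",
    "degree_plus_distance",
    "adjacency",
    "outdistance_source",
    "outdistance_target",
    "outdistance",
    "fln",
    "fln_plus_distance",
)


def feature_length(spec: str, n_train: int) -> int:
    """Expected feature-vector length given |I_train|."""
    if spec == "weighted_common_neighbors":
        return 1
    if spec == "degree_plus_distance":
        return 3
    if spec in ("adjacency", "outdistance", "fln"):
        return 2 * n_train
    if spec in ("outdistance_source", "outdistance_target"):
        return n_train
    if spec == "fln_plus_distance":
        return 2 * n_train + 1
    raise UnknownMethod(f"unknown feature spec {spec!r}; choose from {FEATURE_SPECS}")


@dataclass(frozen=True)
class DesignMatrix:
    """Pairs, their feature matrix, and (optionally) ground-truth labels."""

    pairs: np.ndarray  # (n_pairs, 2) global indices (source u, target v)
    X: np.ndarray  # (n_pairs, n_features)
    y: np.ndarray | None  # binary {0,1} or real weights; None for unlabeled
    spec: str
    kind: str | None  # "binary" | "weight" | None

    def __post_init__(self) -> None:
        if self.X.shape[0] != self.pairs.shape[0]:
            raise NonFiniteFeature("row count differs from pair count")
        if self.pairs.size and np.any(self.pairs[:, 0] == self.pairs[:, 1]):
            raise ValueError("self-pairs (u, u) are not allowed in a design matrix")
        if self.X.size and not np.all(np.isfinite(self.X)):
            raise NonFiniteFeature("design matrix contains non-finite entries")

    @property
    def n_pairs(self) -> int:
        return int(self.pairs.shape[0])


def _prepare_view(wm: WeightMatrix, train_targets) -> tuple[np.ndarray, np.ndarray]:
    """Training rows sorted by global area index, with their global indices."""
    train_targets = np.asarray(train_targets, dtype=int)
    if train_targets.size == 0:
        raise EmptyTrainingSet("no training targets")
    order = np.argsort(train_targets)
    train_targets = train_targets[order]
    injected = wm.atlas.injected_indices
    row_of = {g: r for r, g in enumerate(injected)}
    try:
        rows = [row_of[g] for g in train_targets]
    except KeyError as e:
        raise LabelUnavailable(f"area index {e.args[0]} is not an injected target") from None
    return wm.w[rows, :], train_targets


def _pair_features(
    spec: str,
    U: np.ndarray,
    V: np.ndarray,
    w_rows: np.ndarray,
    train_targets: np.ndarray,
    dfeat: np.ndarray,
) -> np.ndarray:
    n_pairs, n_train = U.shape[0], train_targets.shape[0]
    # mask[i, p]: training target i is an endpoint of pair p
    mask = (train_targets[:, None] == U[None, :]) | (train_targets[:, None] == V[None, :])

    def masked_w(cols: np.ndarray) -> np.ndarray:
        out = w_rows[:, cols]
        return np.where(mask, 0.0, out)

    def masked_d(cols: np.ndarray) -> np.ndarray:
        out = dfeat[train_targets][:, cols]
        return np.where(mask, 0.0, out)

    if spec == "weighted_common_neighbors":
        return (masked_w(U) + masked_w(V)).sum(axis=0)[:, None]
    if spec == "degree_plus_distance":
        du = (masked_w(U) > 0).sum(axis=0)
        dv = (masked_w(V) > 0).sum(axis=0)
        return np.column_stack([du, dv, dfeat[U, V]])
    if spec == "adjacency":
        X = np.empty((n_pairs, 2 * n_train))
        X[:, 0::2] = (masked_w(U) > 0).T
        X[:, 1::2] = (masked_w(V) > 0).T
        return X
    if spec == "outdistance_source":
        return masked_d(U).T
    if spec == "outdistance_target":
        return masked_d(V).T
    if spec == "outdistance":
        X = np.empty((n_pairs, 2 * n_train))
        X[:, 0::2] = masked_d(U).T
        X[:, 1::2] = masked_d(V).T
        return X
    if spec in ("fln", "fln_plus_distance"):
        X = np.empty((n_pairs, 2 * n_train + (spec == "fln_plus_distance")))
        X[:, 0 : 2 * n_train : 2] = masked_w(U).T
        X[:, 1 : 2 * n_train : 2] = masked_w(V).T
        if spec == "fln_plus_distance":
            X[:, -1] = dfeat[U, V]
        return X
    raise UnknownMethod(f"unknown feature spec {spec!r}")


def build_feature_vector(
    spec: str,
    u: int,
    v: int,
    wm: WeightMatrix,
    train_targets,
    dfeat: DistanceFeatures,
) -> np.ndarray:
    """Feature vector for a single ordered pair (u, v), u != v."""
    if u == v:
        raise ValueError("self-pairs (u, u) have no features")
    w_rows, tt = _prepare_view(wm, train_targets)
    return _pair_features(
        spec, np.array([u]), np.array([v]), w_rows, tt, dfeat.dfeat
    )[0]


def build_design_matrix(
    spec: str,
    pairs,
    wm: WeightMatrix,
    train_targets,
    dfeat: DistanceFeatures,
    ground_truth_kind: str | None = None,
) -> DesignMatrix:
    """Design matrix for a list of ordered pairs.

    Features are computed from training-target rows only; labels (when
    requested) are read from each pair's *own* target row, which must be
    observed.  ``ground_truth_kind``: "binary" (y = 1 iff the link exists),
    "weight" (y = transformed weight), or None for unlabeled prediction pairs.
    """
    pairs = np.asarray(pairs, dtype=int).reshape(-1, 2)
    w_rows, tt = _prepare_view(wm, train_targets)
    n_train = tt.shape[0]
    if pairs.shape[0] == 0:
        X = np.zeros((0, feature_length(spec, n_train)))
        y = np.zeros(0) if ground_truth_kind else None
        return DesignMatrix(pairs=pairs, X=X, y=y, spec=spec, kind=ground_truth_kind)

    X = _pair_features(spec, pairs[:, 0], pairs[:, 1], w_rows, tt, dfeat.dfeat)

    y = None
    if ground_truth_kind is not None:
        if ground_truth_kind not in ("binary", "weight"):
            raise UnknownMethod(f"unknown ground_truth_kind {ground_truth_kind!r}")
        injected = wm.atlas.injected_indices
        row_of = {g: r for r, g in enumerate(injected)}
        y = np.empty(pairs.shape[0])
        for p, (u, v) in enumerate(pairs):
            if v not in row_of:
                raise LabelUnavailable(
                    f"target {wm.atlas.area_names[v]!r} has no observed row"
                )
            wt = wm.w[row_of[v], u]
            y[p] = (wt > 0) if ground_truth_kind == "binary" else wt
        if ground_truth_kind == "binary":
            y = y.astype(int)
    return DesignMatrix(pairs=pairs, X=X, y=y, spec=spec, kind=ground_truth_kind)


def design_matrix_to_frame(dm: DesignMatrix, atlas):
    """Audit export: pairs + features + label as a DataFrame."""
    import pandas as pd

    names = atlas.area_names
    df = pd.DataFrame(dm.X, columns=[f"f{i}" for i in range(dm.X.shape[1])])
    df.insert(0, "target", [names[v] for _, v in dm.pairs])
    df.insert(0, "source", [names[u] for u, _ in dm.pairs])
    if dm.y is not None:
        df["label"] = dm.y
    return df
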