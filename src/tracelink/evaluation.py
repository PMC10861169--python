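"""Row-wise cross-validation and all predictability analyses.

Injections observe whole rows of the connectivity matrix, so cross-validation
splits *target areas* (rows), never individual pairs: the injected set I is
randomly permuted, split into k near-equal folds, and each fold's rows are
predicted from models trained (or classical scores computed) on the remaining
rows only.  The whole scheme is repeated R times with fresh permutations and
all metrics are averaged over repetitions.

Binary performance is measured by ROC curves and their area (AUC), plus the
accuracy at the numerically determined max-accuracy threshold of each
repetition's ROC.  Weighted performance is measured by the mean absolute
error MAE = |w_pred - w_true| and the relative MAE; for nonlink pairs the
relative error substitutes the experimental lower cutoff w_cut = 0.9 (the
weight of the lowest statistically acceptable FLN, 8e-7) for the ground
truth.  Further analyses localize predictability: per-link and per-region
error matrices, error-vs-weight and error-vs-distance profiles, residual
diagnostics for regressors, and a leave-one-out scaling analysis of internal
error versus the number of injected areas available for training.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve

from . import learners
from .classical import CLASSICAL_METHODS, classical_score_all
from .datasets import (
    W_CUT,
    TracingDataset,
    WeightClassSpec,
    WeightMatrix,
    scale_distances,
    transform_weights,
)
from .errors import (
    BadFoldCount,
    BadSubsetSize,
    DensityWarning,
    EmptyClass,
    SingleClassLabels,
    SparseBinWarning,
)
from .features import build_design_matrix
from .learners import PredictorConfig

#: Table-style weight strata for MAE/RMAE reporting (strict inequalities,
#: unlike the inclusive binary weight classes).
RMAE_STRATA = (
    "weak",
    "weak_medium",
    "medium_strong",
    "strong",
    "all_links",
    "nonlinks",
    "both",
)


def derive_seed(base: int, *streams: int) -> int:
    """Deterministically expand one seed into per-stage seeds (< 2^31)."""
    mask = (1 << 64) - 1
    h = (int(base) * 0x9E3779B97F4A7C15) & mask
    for s in streams:
        h = ((h ^ (int(s) + 1)) * 0xBF58476D1CE4E5B9) & mask
    return h % (2**31)


# ---------------------------------------------------------------------------
# Fold plans


@dataclass(frozen=True)
class FoldPlan:
    """Randomized assignment of injected targets to k folds, repeated R times.

    ``assignment[r, i]`` is the fold index of injected row i in repetition r.
    """

    k: int
    R: int
    seed: int
    assignment: np.ndarray  # (R, T) int fold labels

    @property
    def T(self) -> int:
        return self.assignment.shape[1]

    def folds(self, rep: int):
        """Yield (test_rows, train_rows) index arrays for one repetition."""
        labels = self.assignment[rep]
        for f in range(self.k):
            test = np.flatnonzero(labels == f)
            train = np.flatnonzero(labels != f)
            yield test, train


def make_fold_plan(T: int, k: int = 3, R: int = 100, seed: int = 0) -> FoldPlan:
    """Balanced randomized k-fold plan over T injected targets, R repetitions."""
    if not 2 <= k <= T:
        raise BadFoldCount(f"need 2 <= k <= T, got k={k}, T={T}")
    rng = np.random.default_rng(seed)
    assignment = np.empty((R, T), dtype=int)
    base = np.concatenate([np.full(len(chunk), f) for f, chunk in
                           enumerate(np.array_split(np.arange(T), k))])
    for r in range(R):
        perm = rng.permutation(T)
        assignment[r, perm] = base
    return FoldPlan(k=k, R=R, seed=seed, assignment=assignment)


# ---------------------------------------------------------------------------
# ROC / AUC


def roc_points(y_true: np.ndarray, scores: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """ROC curve (FPR, TPR, thresholds) by threshold sweep over unique scores.

    Points are returned with FPR ascending; endpoints are exactly (0,0) and
    (1,1).
    """
    fpr, tpr, thr = _sk_roc_curve(y_true, scores, drop_intermediate=False)
    return fpr, tpr, thr


def auc_trapezoid(y_true: np.ndarray, scores: np.ndarray) -> float:
    """Area under the ROC curve by trapezoidal integration."""
    fpr, tpr, _ = roc_points(y_true, scores)
    return float(np.trapezoid(tpr, fpr))


def max_accuracy_threshold(y_true: np.ndarray, scores: np.ndarray) -> tuple[float, float]:
    """Score threshold maximizing ACC = (TP+TN)/n, and that accuracy."""
    y_true = np.asarray(y_true)
    fpr, tpr, thr = roc_points(y_true, scores)
    P = int((y_true == 1).sum())
    N = int((y_true == 0).sum())
    acc = (tpr * P + (1.0 - fpr) * N) / (P + N)
    i = int(np.argmax(acc))
    t = thr[i]
    if np.isinf(t):  # sklearn's sentinel above the max score
        t = float(scores.max())
    return float(t), float(acc[i])


# ---------------------------------------------------------------------------
# Prediction containers


@dataclass
class PairPrediction:
    """Per-pair ground truth and per-repetition predictions.

    For binary runs ``per_rep`` holds continuous scores and ``per_rep_binary``
    the thresholded 0/1 predictions of each repetition; ``mean_pred`` averages
    the binary predictions (so error = |y_true - <y_pred>| is in [0, 1]).
    For weighted runs ``per_rep`` holds predicted weights and ``mean_pred``
    their average.
    """

    pairs: np.ndarray  # (n, 2) global (source u, target v)
    y_true: np.ndarray  # {0,1} or weights
    per_rep: np.ndarray  # (R, n)
    mean_pred: np.ndarray  # (n,)
    mode: str  # "binary" | "weighted"
    per_rep_binary: np.ndarray | None = None


@dataclass
class EvaluationReport:
    """Aggregated cross-validation performance."""

    mode: str
    auc_mean: float | None = None
    auc_sd: float | None = None
    auc_per_rep: np.ndarray | None = None
    threshold_mean: float | None = None
    acc_mean: float | None = None
    roc: tuple[np.ndarray, np.ndarray] | None = None  # pooled (FPR, TPR)
    mae_rmae: pd.DataFrame | None = None
    extras: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Candidate pairs and the CV engine


def candidate_pairs(ds: TracingDataset) -> np.ndarray:
    """All ordered pairs (u, v) with v injected and u != v — every pair with
    an observed ground-truth value."""
    inj = ds.atlas.injected_indices
    N = ds.n_areas
    pairs = []
    for v in inj:
        us = np.delete(np.arange(N), v)
        pairs.append(np.column_stack([us, np.full(N - 1, v)]))
    return np.vstack(pairs)


def _density_guard(y: np.ndarray) -> None:
    nonlink_frac = float((y == 0).mean())
    if nonlink_frac < 0.05:
        warnings.warn(
            f"only {nonlink_frac:.1%} nonlinks: binary prediction is strongly biased "
            "on ultra-dense networks (cf. the 97%-dense mouse data)",
            DensityWarning,
            stacklevel=3,
        )


def _predict_fold(
    predictor,
    feature_spec: str,
    wm: WeightMatrix,
    dfeat,
    train_targets: np.ndarray,
    train_pairs: np.ndarray,
    test_pairs: np.ndarray,
    mode: str,
    seed: int,
) -> np.ndarray:
    """Scores/weights for test pairs from training-row information only."""
    if isinstance(predictor, str):
        if predictor not in CLASSICAL_METHODS:
            raise KeyError(f"unknown predictor {predictor!r}")
        row_of = {g: r for r, g in enumerate(wm.atlas.injected_indices)}
        w_rows = wm.w[[row_of[g] for g in np.sort(train_targets)], :]
        return classical_score_all(predictor, test_pairs, w_rows, np.sort(train_targets))
    config: PredictorConfig = predictor
    config = PredictorConfig(
        algorithm=config.algorithm,
        mode="classifier" if mode == "binary" else "regressor",
        hyperparameters=config.hyperparameters,
        seed=seed,
    )
    kind = "binary" if mode == "binary" else "weight"
    dm_train = build_design_matrix(feature_spec, train_pairs, wm, train_targets, dfeat, kind)
    dm_test = build_design_matrix(feature_spec, test_pairs, wm, train_targets, dfeat, None)
    handle = learners.fit(config, dm_train)
    return learners.predict(handle, dm_test)


def _run_cv(
    ds: TracingDataset,
    predictor,
    plan: FoldPlan,
    mode: str,
    feature_spec: str = "fln_plus_distance",
    pair_mask: np.ndarray | None = None,
    train_pair_mask: np.ndarray | None = None,
) -> PairPrediction:
    """Shared CV loop.  ``pair_mask``/``train_pair_mask`` restrict which
    candidate pairs are scored / used as training examples (None = all)."""
    wm = transform_weights(ds)
    dfeat = scale_distances(ds)
    inj = ds.atlas.injected_indices
    all_pairs = candidate_pairs(ds)
    n = all_pairs.shape[0]
    if pair_mask is None:
        pair_mask = np.ones(n, dtype=bool)
    if train_pair_mask is None:
        train_pair_mask = np.ones(n, dtype=bool)

    row_of = {g: r for r, g in enumerate(inj)}
    w_true = np.array([wm.w[row_of[v], u] for u, v in all_pairs])
    y = w_true if mode == "weighted" else (w_true > 0).astype(int)

    target_of_pair = all_pairs[:, 1]
    per_rep = np.full((plan.R, n), np.nan)
    base_seed = predictor.seed if isinstance(predictor, PredictorConfig) else 0
    for r in range(plan.R):
        for f, (test_rows, train_rows) in enumerate(plan.folds(r)):
            train_targets = inj[train_rows]
            test_targets = set(inj[test_rows].tolist())
            in_test = np.isin(target_of_pair, list(test_targets))
            in_train = np.isin(target_of_pair, train_targets)
            tr_sel = in_train & train_pair_mask
            te_sel = in_test & pair_mask
            if not te_sel.any():
                continue
            scores = _predict_fold(
                predictor,
                feature_spec,
                wm,
                dfeat,
                train_targets,
                all_pairs[tr_sel],
                all_pairs[te_sel],
                mode,
                derive_seed(base_seed, plan.seed, r, f),
            )
            per_rep[r, te_sel] = scores

    keep = pair_mask
    pairs = all_pairs[keep]
    per_rep = per_rep[:, keep]
    y = y[keep]
    if mode == "binary":
        return PairPrediction(
            pairs=pairs, y_true=y, per_rep=per_rep, mean_pred=np.nanmean(per_rep, axis=0),
            mode="binary",
        )
    return PairPrediction(
        pairs=pairs, y_true=y, per_rep=per_rep, mean_pred=np.nanmean(per_rep, axis=0),
        mode="weighted",
    )


def _binary_report(preds: PairPrediction) -> EvaluationReport:
    R = preds.per_rep.shape[0]
    aucs, thrs, accs = [], [], []
    binary = np.zeros_like(preds.per_rep)
    for r in range(R):
        s = preds.per_rep[r]
        ok = ~np.isnan(s)
        if np.unique(preds.y_true[ok]).size < 2:
            binary[r, :] = np.nan  # degenerate repetition carries no signal
            continue
        aucs.append(auc_trapezoid(preds.y_true[ok], s[ok]))
        t, a = max_accuracy_threshold(preds.y_true[ok], s[ok])
        thrs.append(t)
        accs.append(a)
        binary[r, ok] = (s[ok] >= t).astype(float)
        binary[r, ~ok] = np.nan
    if not aucs:
        raise SingleClassLabels("test pairs contain a single class in every repetition")
    preds.per_rep_binary = binary
    preds.mean_pred = np.nanmean(binary, axis=0)
    mean_scores = np.nanmean(preds.per_rep, axis=0)
    fpr, tpr, _ = roc_points(preds.y_true, mean_scores)
    return EvaluationReport(
        mode="binary",
        auc_mean=float(np.mean(aucs)),
        auc_sd=float(np.std(aucs)),
        auc_per_rep=np.array(aucs),
        threshold_mean=float(np.mean(thrs)),
        acc_mean=float(np.mean(accs)),
        roc=(fpr, tpr),
    )


def cross_validate_binary(
    ds: TracingDataset,
    predictor,
    plan: FoldPlan | None = None,
    *,
    feature_spec: str = "fln_plus_distance",
    k: int = 3,
    R: int = 100,
    seed: int = 0,
) -> tuple[PairPrediction, EvaluationReport]:
    """Binary link-prediction CV.

    ``predictor`` is either a classical method id ("CN2", "PA2", "AA2",
    "RA2", "JA2") or a :class:`~tracelink.learners.PredictorConfig`.
    """
    plan = plan or make_fold_plan(ds.n_injected, k=k, R=R, seed=seed)
    wm = transform_weights(ds)
    _density_guard((candidate_labels(wm) > 0).astype(int))
    preds = _run_cv(ds, predictor, plan, "binary", feature_spec)
    return preds, _binary_report(preds)


def candidate_labels(wm: WeightMatrix) -> np.ndarray:
    """Ground-truth weights for all candidate pairs, in candidate order."""
    inj = wm.atlas.injected_indices
    N = len(wm.atlas.area_names)
    out = []
    for r, v in enumerate(inj):
        row = np.delete(wm.w[r], v)
        out.append(row)
    return np.concatenate(out)


# ---------------------------------------------------------------------------
# Weighted CV and MAE/RMAE


def pair_rmae(
    w_true: np.ndarray,
    w_pred: np.ndarray,
    *,
    w_cut: float = W_CUT,
    nonlink_rmae: str = "substitute",
) -> np.ndarray:
    """Per-pair relative absolute error.

    Links (w_true > w_cut): |w_pred - w_true| / w_true.  Nonlinks: the ground
    truth is replaced by the cutoff weight w_cut ("substitute",
    |w_pred - w_cut| / w_cut); "denominator_only" keeps the raw numerator
    |w_pred - w_true| and divides by w_cut.
    """
    w_true = np.asarray(w_true, dtype=float)
    w_pred = np.asarray(w_pred, dtype=float)
    link = w_true > w_cut
    out = np.empty_like(w_true)
    out[link] = np.abs(w_pred[link] - w_true[link]) / w_true[link]
    if nonlink_rmae == "substitute":
        out[~link] = np.abs(w_pred[~link] - w_cut) / w_cut
    elif nonlink_rmae == "denominator_only":
        out[~link] = np.abs(w_pred[~link] - w_true[~link]) / w_cut
    else:
        raise KeyError(f"unknown nonlink_rmae mode {nonlink_rmae!r}")
    return out


def mae_rmae_table(
    w_true: np.ndarray,
    w_pred: np.ndarray,
    *,
    w_cut: float = W_CUT,
    nonlink_rmae: str = "substitute",
) -> pd.DataFrame:
    """MAE and RMAE by weight stratum (weak, weak&medium, medium&strong,
    strong, all links, nonlinks, both)."""
    w_true = np.asarray(w_true, dtype=float)
    w_pred = np.asarray(w_pred, dtype=float)
    abs_err = np.abs(w_pred - w_true)
    rel_err = pair_rmae(w_true, w_pred, w_cut=w_cut, nonlink_rmae=nonlink_rmae)
    strata = {
        "weak": (w_true > w_cut) & (w_true < 3),
        "weak_medium": (w_true > w_cut) & (w_true < 5),
        "medium_strong": w_true > 3,
        "strong": w_true > 5,
        "all_links": w_true > w_cut,
        "nonlinks": w_true <= w_cut,
        "both": np.ones_like(w_true, dtype=bool),
    }
    rows = []
    for name, m in strata.items():
        rows.append(
            {
                "stratum": name,
                "n": int(m.sum()),
                "MAE": float(abs_err[m].mean()) if m.any() else np.nan,
                "RMAE": float(rel_err[m].mean()) if m.any() else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("stratum")


def cross_validate_weighted(
    ds: TracingDataset,
    predictor: PredictorConfig,
    plan: FoldPlan | None = None,
    *,
    feature_spec: str = "fln_plus_distance",
    k: int = 3,
    R: int = 100,
    seed: int = 0,
    w_cut: float = W_CUT,
    nonlink_rmae: str = "substitute",
) -> tuple[PairPrediction, EvaluationReport]:
    """Weighted link-prediction CV with MAE/RMAE reporting by weight stratum."""
    plan = plan or make_fold_plan(ds.n_injected, k=k, R=R, seed=seed)
    preds = _run_cv(ds, predictor, plan, "weighted", feature_spec)
    table = mae_rmae_table(preds.y_true, preds.mean_pred, w_cut=w_cut, nonlink_rmae=nonlink_rmae)
    report = EvaluationReport(mode="weighted", mae_rmae=table)
    return preds, report


# ---------------------------------------------------------------------------
# Weight-class-restricted binary CV


def class_restricted_cv(
    ds: TracingDataset,
    class_id: str,
    predictor,
    plan: FoldPlan | None = None,
    *,
    mode: str = "within_class",
    feature_spec: str = "fln_plus_distance",
    k: int = 3,
    R: int = 20,
    seed: int = 0,
    class_spec: WeightClassSpec | None = None,
):
    """Binary predictability restricted to one weight class.

    ``within_class``: candidate positives are the links of the class,
    negatives the nonlinks; out-of-class links are removed from both training
    labels and scoring.  Returns (PairPrediction, EvaluationReport).

    ``train_class_predict_all``: training labels restricted as above but all
    pairs are scored; returns a dict {true class or "nonlink-vs-link" group:
    EvaluationReport} decomposing predictions by ground-truth class.
    """
    spec = class_spec or WeightClassSpec()
    wm = transform_weights(ds)
    w_all = candidate_labels(wm)
    in_class = spec.mask(class_id, w_all)
    nonlink = w_all == 0
    if not in_class.any():
        raise EmptyClass(f"no links in class {class_id!r}")
    keep = in_class | nonlink
    if in_class.all() or not nonlink.any():
        raise SingleClassLabels("class restriction leaves a single label class")
    plan = plan or make_fold_plan(ds.n_injected, k=k, R=R, seed=seed)

    if mode == "within_class":
        preds = _run_cv(ds, predictor, plan, "binary", feature_spec,
                        pair_mask=keep, train_pair_mask=keep)
        return preds, _binary_report(preds)
    if mode != "train_class_predict_all":
        raise KeyError(f"unknown mode {mode!r}")

    preds = _run_cv(ds, predictor, plan, "binary", feature_spec,
                    pair_mask=None, train_pair_mask=keep)
    out: dict[str, EvaluationReport] = {}
    for cid in spec.class_ids:
        if not spec.mask(cid, w_all).any():
            continue  # class absent from this dataset
        grp = spec.mask(cid, w_all) | nonlink
        sub = PairPrediction(
            pairs=preds.pairs[grp],
            y_true=preds.y_true[grp],
            per_rep=preds.per_rep[:, grp],
            mean_pred=preds.mean_pred[grp],
            mode="binary",
        )
        out[cid] = _binary_report(sub)
    return preds, out


# ---------------------------------------------------------------------------
# Error localization


def error_matrix(preds: PairPrediction, atlas) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-link error matrix (targets x sources) and its region x region mean.

    Binary: error = |y_true - <y_pred>| with <y_pred> the averaged thresholded
    predictions.  Weighted: per-pair relative error (nonlinks against w_cut).
    Self-pairs are absent by construction; unobserved cells are NaN and
    excluded from regional averages.
    """
    names = atlas.area_names
    inj = list(atlas.injected)
    err = pair_errors(preds)
    M = pd.DataFrame(np.nan, index=inj, columns=list(names))
    for (u, v), e in zip(preds.pairs, err):
        M.loc[names[v], names[u]] = e

    regions = list(atlas.regions)
    R = pd.DataFrame(np.nan, index=regions, columns=regions)
    tgt_region = np.array([atlas.region_of[t] for t in inj])
    src_region = np.array([atlas.region_of[s] for s in names])
    vals = M.to_numpy()
    for rt in regions:
        for rs in regions:
            block = vals[np.ix_(tgt_region == rt, src_region == rs)]
            if np.isfinite(block).any():
                R.loc[rt, rs] = float(np.nanmean(block))
    return M, R


def pair_errors(preds: PairPrediction) -> np.ndarray:
    """Per-pair scalar error: |y_true - <y_pred>| (binary) or relative error
    (weighted, nonlinks against w_cut)."""
    if preds.mode == "binary":
        return np.abs(preds.y_true - preds.mean_pred)
    return pair_rmae(preds.y_true, preds.mean_pred)


def error_profiles(
    errors: np.ndarray,
    x: np.ndarray,
    *,
    n_bins: int = 20,
    min_points: int = 3,
) -> pd.DataFrame:
    """Mean +/- sd of errors in equal-width bins of x (weight or distance).

    Bins with fewer than ``min_points`` points are flagged ``sparse`` and a
    warning is emitted.
    """
    errors = np.asarray(errors, dtype=float)
    x = np.asarray(x, dtype=float)
    edges = np.linspace(x.min(), x.max(), n_bins + 1)
    idx = np.clip(np.digitize(x, edges[1:-1]), 0, n_bins - 1)
    rows = []
    n_sparse = 0
    for b in range(n_bins):
        m = idx == b
        n = int(m.sum())
        sparse = 0 < n < min_points
        n_sparse += sparse
        rows.append(
            {
                "bin_lo": edges[b],
                "bin_hi": edges[b + 1],
                "n": n,
                "mean": float(errors[m].mean()) if n else np.nan,
                "sd": float(errors[m].std()) if n else np.nan,
                "sparse": bool(sparse),
            }
        )
    if n_sparse:
        warnings.warn(f"{n_sparse} profile bins hold fewer than {min_points} points",
                      SparseBinWarning, stacklevel=2)
    return pd.DataFrame(rows)


def residual_diagnostics(
    w_pred: np.ndarray, w_true: np.ndarray, *, featureless_cutoff: float = 0.1
) -> dict:
    """Residual structure statistics for a weight regressor.

    Residuals r = w_pred - w_true should form a featureless scatter against
    the predictions once all learnable signal is extracted: near-zero mean
    and no rank correlation of r (bias trend) or |r| (heteroscedasticity)
    with w_pred.
    """
    w_pred = np.asarray(w_pred, dtype=float)
    r = w_pred - np.asarray(w_true, dtype=float)
    if r.size < 3 or np.allclose(r, r[0]) or np.allclose(w_pred, w_pred[0]):
        rho_r = rho_abs = 0.0
    else:
        rho_r = float(stats.spearmanr(w_pred, r).statistic)
        rho_abs = float(stats.spearmanr(w_pred, np.abs(r)).statistic)
        rho_r = 0.0 if np.isnan(rho_r) else rho_r
        rho_abs = 0.0 if np.isnan(rho_abs) else rho_abs
    return {
        "residuals": r,
        "mean_residual": float(r.mean()) if r.size else 0.0,
        "rank_corr_residual": rho_r,
        "rank_corr_abs_residual": rho_abs,
        "featureless": bool(
            max(abs(rho_r), abs(rho_abs)) < featureless_cutoff
        ),
    }


# ---------------------------------------------------------------------------
# Leave-one-out scaling analysis


def internal_error_scaling(
    ds: TracingDataset,
    m_values,
    *,
    n_rep: int = 500,
    predictor: PredictorConfig | None = None,
    feature_spec: str = "fln_plus_distance",
    seed: int = 0,
    w_cut: float = W_CUT,
) -> pd.DataFrame:
    """Internal RMAE versus training-set size m, by weight stratum.

    For each m: draw a random subset M of m injected targets; leave each
    member out in turn and predict its out-links *restricted to source areas
    within M* from the remaining m - 1 rows; average the per-stratum relative
    errors over members and over ``n_rep`` subset draws.
    """
    predictor = predictor or PredictorConfig(algorithm="GB", mode="regressor")
    wm = transform_weights(ds)
    dfeat = scale_distances(ds)
    inj = ds.atlas.injected_indices
    T = len(inj)
    row_of = {g: r for r, g in enumerate(inj)}
    rng = np.random.default_rng(seed)
    records = []
    for m in m_values:
        if not 2 <= m <= T:
            raise BadSubsetSize(f"need 2 <= m <= T={T}, got m={m}")
        sums: dict[str, list[float]] = {s: [] for s in RMAE_STRATA}
        for rep in range(n_rep):
            subset = rng.choice(T, size=m, replace=False)
            for leave in subset:
                train_rows = np.array([r for r in subset if r != leave])
                train_targets = inj[train_rows]
                v = inj[leave]
                sources = np.array([inj[r] for r in subset if inj[r] != v])
                if sources.size == 0:
                    continue
                test_pairs = np.column_stack([sources, np.full(sources.size, v)])
                train_pairs = []
                for tr in train_rows:
                    t = inj[tr]
                    us = np.array([inj[r] for r in subset if inj[r] != t])
                    train_pairs.append(np.column_stack([us, np.full(us.size, t)]))
                train_pairs = np.vstack(train_pairs)
                w_pred = _predict_fold(
                    predictor, feature_spec, wm, dfeat, train_targets,
                    train_pairs, test_pairs, "weighted",
                    derive_seed(predictor.seed, seed, m, rep, int(leave)),
                )
                w_true = np.array([wm.w[row_of[v], u] for u in sources])
                tab = mae_rmae_table(w_true, w_pred, w_cut=w_cut)
                for s in RMAE_STRATA:
                    if tab.loc[s, "n"] > 0:
                        sums[s].append(float(tab.loc[s, "RMAE"]))
        rec = {"m": m}
        for s in RMAE_STRATA:
            rec[s] = float(np.mean(sums[s])) if sums[s] else np.nan
        records.append(rec)
    return pd.DataFrame(records).set_index("m")
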