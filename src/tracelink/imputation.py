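"""Imputation of the full interareal network (FIN) from partial injections.

Once cross-validation has established that the observed rows carry
significant predictability, a regressor trained on *all* observed rows can
predict the weights of every pair whose target was never injected, producing
samples of the complete N x N weighted network (91 x 91 macaque-scale,
47 x 47 mouse-scale).  Observed entries are copied through untouched;
imputed entries carry the raw regressor output plus a [0, 7]-clipped
reporting channel.  Repeating the fit with different seeds yields a sample
spread per imputed entry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datasets import TracingDataset, scale_distances, transform_weights
from .errors import PredictabilityGateFailed
from .evaluation import cross_validate_binary, derive_seed, make_fold_plan
from .features import build_design_matrix
from .learners import PredictorConfig, fit, predict


@dataclass(frozen=True)
class FinSample:
    """One imputed full-network sample.

    ``w`` holds observed weights where the mask says "observed" and raw
    regressor outputs elsewhere (diagonal 0); ``w_clipped`` clips imputed
    entries into the empirical [0, 7] weight range.
    """

    w: np.ndarray  # (N, N), raw channel
    w_clipped: np.ndarray  # (N, N), reporting channel
    observed: np.ndarray  # (N, N) bool, True = measured entry
    config: PredictorConfig
    seed: int


def impute_fin(
    ds: TracingDataset,
    config: PredictorConfig | None = None,
    *,
    feature_spec: str = "fln_plus_distance",
    n_samples: int = 1,
    seed: int = 0,
    gate_auc: float | None = None,
    gate_R: int = 5,
) -> list[FinSample]:
    """Train on all observed rows and predict every unobserved entry.

    ``gate_auc``: when set, a quick binary CV is run first and imputation is
    refused (PredictabilityGateFailed) if its mean AUC does not exceed the
    gate — imputation is only meaningful on data with demonstrated
    predictability.
    """
    config = config or PredictorConfig(algorithm="GB", mode="regressor")
    if gate_auc is not None:
        clf = PredictorConfig(algorithm=config.algorithm
                              if config.algorithm != "NBA" else "GB",
                              mode="classifier",
                              hyperparameters=config.hyperparameters,
                              seed=derive_seed(seed, 9))
        _, rep = cross_validate_binary(
            ds, clf, make_fold_plan(ds.n_injected, k=3, R=gate_R,
                                    seed=derive_seed(seed, 7)),
            feature_spec=feature_spec,
        )
        if rep.auc_mean <= gate_auc:
            raise PredictabilityGateFailed(
                f"cross-validated AUC {rep.auc_mean:.3f} <= gate {gate_auc}"
            )

    wm = transform_weights(ds)
    dfeat = scale_distances(ds)
    atlas = ds.atlas
    N = atlas.n_areas
    inj = atlas.injected_indices
    inj_set = set(inj.tolist())
    row_of = {g: r for r, g in enumerate(inj)}

    train_pairs = np.array(
        [(u, v) for v in inj for u in range(N) if u != v], dtype=int
    )
    missing_targets = [v for v in range(N) if v not in inj_set]
    test_pairs = np.array(
        [(u, v) for v in missing_targets for u in range(N) if u != v], dtype=int
    ).reshape(-1, 2)

    observed = np.zeros((N, N), dtype=bool)
    base = np.zeros((N, N))
    for v in inj:
        cols = np.ones(N, dtype=bool)
        cols[v] = False
        observed[v, cols] = True
        base[v] = np.where(cols, wm.w[row_of[v]], 0.0)

    dm_train = build_design_matrix(feature_spec, train_pairs, wm, inj, dfeat, "weight")
    dm_test = build_design_matrix(feature_spec, test_pairs, wm, inj, dfeat, None)

    samples: list[FinSample] = []
    for s in range(n_samples):
        cfg = PredictorConfig(
            algorithm=config.algorithm,
            mode="regressor",
            hyperparameters=config.hyperparameters,
            seed=derive_seed(seed, s),
        )
        handle = fit(cfg, dm_train)
        pred = predict(handle, dm_test)
        w = base.copy()
        for (u, v), p in zip(test_pairs, pred):
            w[v, u] = p
        np.fill_diagonal(w, 0.0)
        w_clipped = w.copy()
        imput = ~observed & ~np.eye(N, dtype=bool)
        w_clipped[imput] = np.clip(w_clipped[imput], 0.0, 7.0)
        samples.append(
            FinSample(w=w, w_clipped=w_clipped, observed=observed, config=cfg,
                      seed=derive_seed(seed, s))
        )
    return samples


def summarize_fin_samples(samples: list[FinSample]) -> dict[str, np.ndarray]:
    """Per-entry mean and sd over samples, plus the observed mask."""
    if not samples:
        raise ValueError("need at least one sample")
    stack = np.stack([s.w for s in samples])
    sd = stack.std(axis=0)
    sd[np.all(stack == stack[:1], axis=0)] = 0.0  # bitwise-equal entries spread exactly 0
    return {
        "mean": stack.mean(axis=0),
        "sd": sd,
        "observed": samples[0].observed.copy(),
    }
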