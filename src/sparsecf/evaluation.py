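"""Masking cross-validation across sparsity levels, with per-user scoring.

The harness turns a dense (or at least observed) rating matrix into a
sparse recovery problem: at each sparsity level a random fraction of the
observed cells is masked out, every algorithm is trained on the remaining
cells and asked to predict the masked ones, and errors are scored per user.
The split at a given (sparsity, iteration) is shared by all algorithms and
dilation settings, so comparisons are paired.

Scores are the RMSE of predictions against the held-out truths, divided by
the rating-scale range (normalized error in [0, 1] for scale-bounded
predictors), plus the per-user Pearson correlation between predictions and
truths. Aggregation is deliberately user-first: normalized error is
averaged over iterations within each user, then across users, which
respects user-level clustering instead of pooling all ratings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import ObservationSplit, RatingsMatrix, mask_random
from .dilation import DilationKernel, dilate
from .models import (
    ImputationError,
    knn_fit,
    knn_predict,
    mean_predict,
    mice_predict,
    nnmf_mult_fit,
    nnmf_predict,
    nnmf_sgd_fit,
)

__all__ = [
    "rmse",
    "normalized_error",
    "per_user_correlation",
    "EvaluationTable",
    "cross_validate",
    "make_algorithm",
    "BUILTIN_ALGORITHMS",
]

DEFAULT_SPARSITY_LEVELS = tuple(round(0.1 * k, 1) for k in range(1, 10))


def rmse(predictions: Sequence[float], truths: Sequence[float]) -> float:
    """Root mean squared error between two equal-length vectors."""
    p = np.asarray(predictions, dtype=float)
    t = np.asarray(truths, dtype=float)
    if p.shape != t.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {t.shape}")
    if p.size == 0:
        raise ValueError("empty input")
    if not (np.all(np.isfinite(p)) and np.all(np.isfinite(t))):
        raise ValueError("non-finite values")
    return float(np.sqrt(np.mean((p - t) ** 2)))


def normalized_error(rmse_value: float, r_min: float, r_max: float) -> float:
    """RMSE divided by the rating range: 0 is perfect, 1 is maximal error."""
    if not r_max > r_min:
        raise ValueError(f"degenerate range ({r_min}, {r_max})")
    if rmse_value < 0:
        raise ValueError("rmse must be non-negative")
    return float(rmse_value) / (float(r_max) - float(r_min))


def per_user_correlation(
    predictions: Sequence[float], truths: Sequence[float], by_user: Sequence
) -> dict:
    """Pearson correlation of predictions vs truths, separately per user.

    A user with fewer than two cells, or a constant prediction or truth
    vector, gets NaN (undefined) and is excluded from any average taken
    over the returned values.
    """
    p = np.asarray(predictions, dtype=float)
    t = np.asarray(truths, dtype=float)
    users = np.asarray(by_user)
    if not (p.shape == t.shape == users.shape):
        raise ValueError("length mismatch")
    out = {}
    for user in pd.unique(users):
        sel = users == user
        pu, tu = p[sel], t[sel]
        if pu.size < 2 or pu.std() == 0.0 or tu.std() == 0.0:
            out[user] = np.nan
        else:
            out[user] = float(np.corrcoef(pu, tu)[0, 1])
    return out


# -- algorithm adapters --------------------------------------------------

# An algorithm is a callable (train: RatingsMatrix, cells, seed: int) ->
# array of predicted values aligned with `cells`.
Algorithm = Callable[[RatingsMatrix, np.ndarray, int], np.ndarray]


def make_algorithm(name: str, **params) -> Algorithm:
    """Build a harness-ready adapter for one of the built-in predictors.

    ``params`` are forwarded to the underlying fit/predict call (e.g. ``k``
    and ``metric`` for knn, ``f``/``gamma``/``lambdas``/``tol``/``max_iter``
    for nnmf_sgd).
    """
    if name == "mean":
        def run(train, cells, seed):
            return mean_predict(train, cells).values
    elif name == "knn":
        def run(train, cells, seed):
            fit = knn_fit(train, **params)
            return knn_predict(fit, cells).values
    elif name == "nnmf_sgd":
        def run(train, cells, seed):
            fit = nnmf_sgd_fit(train, seed=seed, **params)
            return nnmf_predict(fit, cells).values
    elif name == "nnmf_mult":
        def run(train, cells, seed):
            fit = nnmf_mult_fit(train, seed=seed, **params)
            return nnmf_predict(fit, cells).values
    elif name == "mice":
        def run(train, cells, seed):
            return mice_predict(train, cells, seed=seed, **params).values
    else:
        raise ValueError(f"unknown algorithm {name!r}")
    run.__name__ = name
    return run


BUILTIN_ALGORITHMS = ("mean", "knn", "nnmf_sgd", "nnmf_mult", "mice")


@dataclass
class EvaluationTable:
    """Long-form per-(algorithm, dilation, sparsity, iteration, user) scores.

    ``records`` has columns algorithm, dilation_width_s, sparsity_level,
    iteration, user, n_test_cells, rmse, normalized_error,
    pred_truth_correlation. ``failures`` lists runs that raised, with the
    diagnostic preserved.
    """

    records: pd.DataFrame
    failures: pd.DataFrame

    def aggregate(self, ci: bool = True, n_boot: int = 1000, seed: int = 0) -> pd.DataFrame:
        """Mean normalized error per (algorithm, dilation, sparsity).

        Per-user means over iterations first, then the mean across users,
        with an optional seeded bootstrap (over users) 95% CI.
        """
        group_cols = ["algorithm", "dilation_width_s", "sparsity_level"]
        rows = []
        rng = np.random.default_rng(seed)
        for key, grp in self.records.groupby(group_cols, dropna=False):
            per_user = grp.groupby("user")["normalized_error"].mean().to_numpy()
            row = dict(zip(group_cols, key))
            row["n_users"] = per_user.size
            row["normalized_error"] = float(per_user.mean())
            if ci and per_user.size > 1:
                boots = np.empty(n_boot)
                for b in range(n_boot):
                    boots[b] = rng.choice(per_user, size=per_user.size, replace=True).mean()
                row["ci_low"], row["ci_high"] = np.percentile(boots, [2.5, 97.5])
            else:
                row["ci_low"] = row["ci_high"] = np.nan
            rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)


def _split_seed(base_seed: int, sparsity_idx: int, iteration: int) -> int:
    ss = np.random.SeedSequence([int(base_seed), sparsity_idx, iteration])
    return int(ss.generate_state(1)[0] % (2**31))


def cross_validate(
    matrix: RatingsMatrix,
    algorithms: Mapping[str, Algorithm],
    sparsity_levels: Iterable[float] = DEFAULT_SPARSITY_LEVELS,
    n_iterations: int = 10,
    dilation_widths_s: Iterable[float | None] = (None,),
    base_seed: int = 0,
) -> EvaluationTable:
    """Run the full masking sweep and score every algorithm per user.

    For each (sparsity, iteration) one seeded random split is drawn and
    shared across all algorithms and dilation widths. Dilation (when a
    width is given) is applied to the training side only, after masking.
    Each algorithm predicts all test cells from the (possibly dilated)
    training matrix; per-user RMSE over that user's test cells is
    normalized by the declared scale range (observed data range when no
    scale is declared). A run that raises is recorded as a failure, not
    silently dropped.
    """
    if not algorithms:
        raise ValueError("at least one algorithm is required")
    sparsity_levels = list(sparsity_levels)
    dilation_widths_s = list(dilation_widths_s)
    r_min, r_max = matrix.value_range()
    records: list[dict] = []
    failures: list[dict] = []
    model_seed_root = np.random.SeedSequence([int(base_seed), 987654321])
    for s_idx, sparsity in enumerate(sparsity_levels):
        for iteration in range(n_iterations):
            split = mask_random(matrix, sparsity, _split_seed(base_seed, s_idx, iteration))
            cells = split.test_cells()
            truths = matrix.values[cells[:, 0], cells[:, 1]]
            users = cells[:, 0]
            base_train = split.train_matrix(matrix)
            for width in dilation_widths_s:
                if width is None:
                    train = base_train
                else:
                    train = dilate(matrix, split.train_mask, DilationKernel(width))
                for alg_idx, (name, algorithm) in enumerate(algorithms.items()):
                    seed = int(
                        np.random.SeedSequence(
                            [int(base_seed), s_idx, iteration, alg_idx]
                        ).generate_state(1)[0]
                        % (2**31)
                    )
                    try:
                        preds = np.asarray(algorithm(train, cells, seed), dtype=float)
                    except Exception as exc:
                        failures.append(
                            {
                                "algorithm": name,
                                "dilation_width_s": width,
                                "sparsity_level": sparsity,
                                "iteration": iteration,
                                "error": f"{type(exc).__name__}: {exc}",
                            }
                        )
                        continue
                    if preds.shape != truths.shape:
                        raise ValueError(
                            f"algorithm {name!r} returned {preds.shape} predictions "
                            f"for {truths.shape} test cells"
                        )
                    corr = per_user_correlation(preds, truths, users)
                    for user in np.unique(users):
                        sel = users == user
                        user_rmse = rmse(preds[sel], truths[sel])
                        records.append(
                            {
                                "algorithm": name,
                                "dilation_width_s": width,
                                "sparsity_level": sparsity,
                                "iteration": iteration,
                                "user": matrix.user_ids[int(user)],
                                "n_test_cells": int(sel.sum()),
                                "rmse": user_rmse,
                                "normalized_error": normalized_error(user_rmse, r_min, r_max),
                                "pred_truth_correlation": corr[user],
                            }
                        )
    rec_cols = [
        "algorithm", "dilation_width_s", "sparsity_level", "iteration", "user",
        "n_test_cells", "rmse", "normalized_error", "pred_truth_correlation",
    ]
    fail_cols = ["algorithm", "dilation_width_s", "sparsity_level", "iteration", "error"]
    return EvaluationTable(
        pd.DataFrame(records, columns=rec_cols),
        pd.DataFrame(failures, columns=fail_cols),
    )
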