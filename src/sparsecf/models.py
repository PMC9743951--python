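"""Predictors for unobserved cells of a sparse user x item rating matrix.

Four predictors plus one imputation comparator:

* mean baseline -- the item's mean over observed training ratings;
* user-based KNN -- similarity-weighted mean over the top-k positively
  similar neighbors who rated the item;
* NNMF trained by stochastic gradient descent (SGD) with global-mean,
  user-bias and item-bias terms, non-negative factors, fit on observed
  cells only;
* NNMF trained by the classic multiplicative update rule, which requires a
  dense matrix and therefore zero-fills missing cells (kept as a documented
  weak comparator);
* MICE -- multivariate imputation by chained equations with a per-item
  linear regression, the standard missing-data comparator.

All predictors share a fallback cascade for cells they cannot reach with
their own rule: the item mean over observed training ratings, then the
global training mean. Collaborative-filtering predictions are never clipped
to the rating scale; MICE output is clipped to the observed training range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from sklearn.linear_model import LinearRegression

from .core import RatingsMatrix
from .similarity import SimilarityMatrix, pairwise_similarity

__all__ = [
    "Prediction",
    "Predictions",
    "KNNFit",
    "NNMFFit",
    "ImputationError",
    "mean_predict",
    "knn_fit",
    "knn_predict",
    "nnmf_sgd_fit",
    "nnmf_mult_fit",
    "mult_update",
    "nnmf_predict",
    "mice_impute",
    "mice_predict",
]

MODEL = "model"
ITEM_MEAN_FALLBACK = "item_mean_fallback"
GLOBAL_MEAN_FALLBACK = "global_mean_fallback"


@dataclass
class Prediction:
    """A single predicted cell and the rule that produced it."""

    user: int
    item: int
    value: float
    method_used: str


class Predictions(list):
    """List of :class:`Prediction` with array/table convenience views."""

    @property
    def values(self) -> np.ndarray:
        return np.array([p.value for p in self], dtype=float)

    @property
    def methods(self) -> list[str]:
        return [p.method_used for p in self]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [(p.user, p.item, p.value, p.method_used) for p in self],
            columns=["user", "item", "prediction", "method_used"],
        )


def _as_cells(cells) -> np.ndarray:
    cells = np.asarray(cells, dtype=int)
    if cells.ndim != 2 or cells.shape[1] != 2:
        raise ValueError("cells must be an (n, 2) array of (user, item) indices")
    return cells


def _check_cells(cells: np.ndarray, n_users: int, n_items: int) -> None:
    if cells.size == 0:
        return
    if cells[:, 0].min() < 0 or cells[:, 0].max() >= n_users:
        raise KeyError("user index out of range")
    if cells[:, 1].min() < 0 or cells[:, 1].max() >= n_items:
        raise KeyError("item index out of range")


def _column_stats(train: RatingsMatrix) -> tuple[np.ndarray, float]:
    obs = np.isfinite(train.values)
    # per-column mean of the compressed observed values: bit-identical to
    # np.mean on the same values, which downstream exactness checks rely on
    col_means = np.array(
        [
            np.mean(train.values[obs[:, j], j]) if obs[:, j].any() else np.nan
            for j in range(train.n_items)
        ]
    )
    global_mean = float(np.mean(train.values[obs]))
    return col_means, global_mean


# -- mean baseline ------------------------------------------------------


def mean_predict(train: RatingsMatrix, cells) -> Predictions:
    """Predict each cell as the item's mean over observed training ratings.

    An item with no observed training rating falls back to the global
    training mean and is flagged ``global_mean_fallback``.
    """
    cells = _as_cells(cells)
    _check_cells(cells, train.n_users, train.n_items)
    col_means, global_mean = _column_stats(train)
    out = Predictions()
    for u, i in cells:
        if np.isfinite(col_means[i]):
            out.append(Prediction(int(u), int(i), float(col_means[i]), MODEL))
        else:
            out.append(Prediction(int(u), int(i), global_mean, GLOBAL_MEAN_FALLBACK))
    return out


# -- user-based KNN ------------------------------------------------------


@dataclass
class KNNFit:
    """Train matrix plus the user-similarity structure for neighbor lookup."""

    train: RatingsMatrix
    similarity: SimilarityMatrix
    k: int

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")


def knn_fit(
    train: RatingsMatrix, k: int = 10, metric: str = "pearson", min_overlap: int = 2
) -> KNNFit:
    """Compute the user-similarity matrix on the training data."""
    sim = pairwise_similarity(train, metric=metric, min_overlap=min_overlap)
    return KNNFit(train, sim, k)


def knn_predict(fit: KNNFit, cells) -> Predictions:
    """Similarity-weighted neighbor mean, with the fallback cascade.

    For a cell (u, i) the candidate neighbors are the users with a defined,
    strictly positive similarity to u who have an observed training rating
    for item i. The top-k candidates by similarity (ties broken by user
    order) contribute; the prediction is sum(r_v * sim_uv) / sum(sim_uv).
    With no candidates the item mean is used; with an empty item, the
    global training mean. Predictions are not clipped to the rating scale.
    """
    cells = _as_cells(cells)
    train = fit.train
    _check_cells(cells, train.n_users, train.n_items)
    col_means, global_mean = _column_stats(train)
    obs = np.isfinite(train.values)
    sim = fit.similarity.values
    out = Predictions()
    for u, i in cells:
        s = sim[u].copy()
        s[u] = np.nan  # a user is never their own neighbor
        candidates = np.where(np.isfinite(s) & (s > 0) & obs[:, i])[0]
        if candidates.size:
            # stable sort on -similarity keeps user order on ties
            top = candidates[np.argsort(-s[candidates], kind="stable")][: fit.k]
            weights = s[top]
            ratings = train.values[top, i]
            value = float(np.dot(ratings, weights) / weights.sum())
            out.append(Prediction(int(u), int(i), value, MODEL))
        elif np.isfinite(col_means[i]):
            out.append(Prediction(int(u), int(i), float(col_means[i]), ITEM_MEAN_FALLBACK))
        else:
            out.append(Prediction(int(u), int(i), global_mean, GLOBAL_MEAN_FALLBACK))
    return out


# -- NNMF ----------------------------------------------------------------


@dataclass
class NNMFFit:
    """A fitted non-negative factor model with bias terms.

    Predictions are mu + b_u + b_i + p_u . q_i where p_u is a row of W and
    q_i a column of H; W and H stay elementwise non-negative throughout
    training. For the multiplicative variant the bias vectors are zero and
    ``mu`` holds the additive shift that made the training data
    non-negative (0 when no shift was needed).
    """

    mu: float
    b_u: np.ndarray
    b_i: np.ndarray
    W: np.ndarray
    H: np.ndarray
    gamma: float
    lambdas: tuple[float, float, float, float]
    f: int
    history: list[float]
    seed: int
    converged: bool
    algorithm: str = "sgd"


@njit(cache=True)
def _sgd_epoch(rows, cols, vals, order, mu, b_u, b_i, W, H, gamma, lbu, lbi, lpu, lqi):
    """One pass over the observed cells in the given order.

    Per cell: one prediction error e, then bias and factor updates all
    computed from that same e and the pre-update parameter values (the
    standard simultaneous SGD step), projecting each factor coordinate
    onto [0, inf) immediately after its update.
    """
    f = W.shape[1]
    for t in range(order.shape[0]):
        idx = order[t]
        u = rows[idx]
        i = cols[idx]
        pred = mu + b_u[u] + b_i[i]
        for k in range(f):
            pred += W[u, k] * H[k, i]
        e = vals[idx] - pred
        b_i[i] += gamma * (e - lbi * b_i[i])
        b_u[u] += gamma * (e - lbu * b_u[u])
        for k in range(f):
            q_old = H[k, i]
            p_old = W[u, k]
            q_new = q_old + gamma * (e * p_old - lqi * q_old)
            if q_new < 0.0:
                q_new = 0.0
            p_new = p_old + gamma * (e * q_old - lpu * p_old)
            if p_new < 0.0:
                p_new = 0.0
            H[k, i] = q_new
            W[u, k] = p_new


@njit(cache=True)
def _train_mse(rows, cols, vals, mu, b_u, b_i, W, H):
    f = W.shape[1]
    total = 0.0
    for t in range(rows.shape[0]):
        u = rows[t]
        i = cols[t]
        pred = mu + b_u[u] + b_i[i]
        for k in range(f):
            pred += W[u, k] * H[k, i]
        d = vals[t] - pred
        total += d * d
    return total / rows.shape[0]


def nnmf_sgd_fit(
    train: RatingsMatrix,
    f: int | str = "auto",
    gamma: float = 0.001,
    lambdas: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0),
    tol: float = 1e-6,
    max_iter: int = 1000,
    seed: int = 0,
) -> NNMFFit:
    """Fit the biased non-negative factor model by SGD on observed cells.

    mu is the training mean; biases start at zero; W and H start as
    |N(0, 1)| / f (seeded), so initial predictions sit near mu. Every
    iteration shuffles the observed cells (seeded) and applies the
    per-cell updates; training stops when the change in mean squared
    training error is at most ``tol`` or after ``max_iter`` iterations.

    Parameters
    ----------
    f
        Number of latent factors; ``"auto"`` uses min(n_users, n_items).
    lambdas
        L2 penalties (lambda_bu, lambda_bi, lambda_pu, lambda_qi); the
        default disables regularization.
    """
    if gamma < 0:
        raise ValueError("gamma must be non-negative (0 leaves parameters at initialization)")
    obs = np.isfinite(train.values)
    rows, cols = np.nonzero(obs)
    if rows.size == 0:
        raise ValueError("no observed training ratings")
    if f == "auto":
        f = min(train.n_users, train.n_items)
    f = int(f)
    if f < 1:
        raise ValueError("f must be >= 1")
    lbu, lbi, lpu, lqi = (float(x) for x in lambdas)
    vals = train.values[rows, cols]
    rows = rows.astype(np.int64)
    cols = cols.astype(np.int64)
    mu = float(vals.mean())
    rng = np.random.default_rng(seed)
    W = np.abs(rng.standard_normal((train.n_users, f))) / f
    H = np.abs(rng.standard_normal((f, train.n_items))) / f
    b_u = np.zeros(train.n_users)
    b_i = np.zeros(train.n_items)
    history: list[float] = []
    converged = False
    prev = np.inf
    for _ in range(int(max_iter)):
        order = rng.permutation(rows.size).astype(np.int64)
        _sgd_epoch(rows, cols, vals, order, mu, b_u, b_i, W, H, gamma, lbu, lbi, lpu, lqi)
        mse = float(_train_mse(rows, cols, vals, mu, b_u, b_i, W, H))
        if not np.isfinite(mse):
            raise FloatingPointError(
                "training error became non-finite; the learning rate is "
                f"likely too large (gamma={gamma})"
            )
        history.append(mse)
        if np.isfinite(prev) and abs(prev - mse) <= tol:
            converged = True
            break
        prev = mse
    return NNMFFit(mu, b_u, b_i, W, H, gamma, (lbu, lbi, lpu, lqi), f, history, seed, converged, "sgd")


def nnmf_predict(fit: NNMFFit, cells) -> Predictions:
    """Predict mu + b_u + b_i + p_u . q_i for each requested cell, unclipped."""
    cells = _as_cells(cells)
    _check_cells(cells, fit.W.shape[0], fit.H.shape[1])
    out = Predictions()
    for u, i in cells:
        value = fit.mu + fit.b_u[u] + fit.b_i[i] + float(fit.W[u] @ fit.H[:, i])
        out.append(Prediction(int(u), int(i), float(value), MODEL))
    return out


def mult_update(V: np.ndarray, W: np.ndarray, H: np.ndarray, eps: float = 1e-12):
    """One round of the classic multiplicative updates for V ~ WH.

    Both factors are rescaled by ratios that equal one at an exact
    factorization, so an exact (W, H) is a fixed point. ``eps`` guards the
    denominators.
    """
    H = H * ((W.T @ V) / (W.T @ W @ H + eps))
    W = W * ((V @ H.T) / (W @ H @ H.T + eps))
    return W, H


def nnmf_mult_fit(
    train: RatingsMatrix,
    f: int | str = "auto",
    tol: float = 1e-6,
    max_iter: int = 1000,
    seed: int = 0,
) -> NNMFFit:
    """Fit plain NNMF by the multiplicative update rule on a zero-filled matrix.

    The multiplicative rule needs a dense non-negative matrix, so missing
    cells are filled with zero before factorization -- the known weakness of
    this variant on sparse data, kept as a comparator. Training data with
    negative values are shifted by the declared scale minimum (the shift is
    added back at prediction time via ``mu``); negative values without a
    declared scale are rejected. No bias terms are fit.
    """
    obs = np.isfinite(train.values)
    vals = train.values[obs]
    shift = 0.0
    if vals.min() < 0:
        if train.scale is None:
            raise ValueError(
                "negative ratings require a declared scale to define the "
                "non-negativity shift"
            )
        shift = float(train.scale[0])
    V = np.where(obs, train.values - shift, 0.0)
    if f == "auto":
        f = min(train.n_users, train.n_items)
    f = int(f)
    if f < 1:
        raise ValueError("f must be >= 1")
    rng = np.random.default_rng(seed)
    W = np.abs(rng.standard_normal((train.n_users, f))) / f
    H = np.abs(rng.standard_normal((f, train.n_items))) / f
    history: list[float] = []
    converged = False
    prev = np.inf
    for _ in range(int(max_iter)):
        W, H = mult_update(V, W, H)
        mse = float(np.mean((V - W @ H) ** 2))
        history.append(mse)
        if np.isfinite(prev) and abs(prev - mse) <= tol:
            converged = True
            break
        prev = mse
    return NNMFFit(
        shift, np.zeros(train.n_users), np.zeros(train.n_items), W, H,
        np.nan, (0.0, 0.0, 0.0, 0.0), f, history, seed, converged, "mult",
    )


# -- MICE ----------------------------------------------------------------


class ImputationError(RuntimeError):
    """Raised when chained-equations imputation cannot be estimated."""


def mice_impute(train: RatingsMatrix, n_rounds: int = 10, seed: int = 0) -> RatingsMatrix:
    """Complete the matrix by chained per-item linear regressions.

    Missing cells start at their item (column) means. Each round visits the
    items in a fresh seeded random order; each item is regressed on all
    other items (in their current imputed state) using the rows where the
    target item was originally observed, and the originally-missing cells
    of that item are re-imputed from the fitted regression. After the final
    round the imputed cells are clipped to the [min, max] of the observed
    training data.

    Raises
    ------
    ImputationError
        If any item column has no observed rating, or has fewer than two
        observed rows to support a regression, or a regression fit fails.
    """
    obs = np.isfinite(train.values)
    counts = obs.sum(axis=0)
    if np.any(counts == 0):
        raise ImputationError("imputation failed: item column with no observed ratings")
    if np.any(counts < 2):
        raise ImputationError("imputation failed: item column with fewer than 2 observed rows")
    filled = train.values.copy()
    col_means = np.nansum(np.where(obs, filled, 0.0), axis=0) / counts
    for j in range(train.n_items):
        filled[~obs[:, j], j] = col_means[j]
    rng = np.random.default_rng(seed)
    others = {j: np.array([c for c in range(train.n_items) if c != j]) for j in range(train.n_items)}
    for _ in range(int(n_rounds)):
        for j in rng.permutation(train.n_items):
            rows_obs = obs[:, j]
            X = filled[:, others[j]]
            try:
                reg = LinearRegression().fit(X[rows_obs], train.values[rows_obs, j])
            except Exception as exc:  # singular / numerical failure
                raise ImputationError(f"imputation failed: regression error ({exc})") from exc
            if rows_obs.sum() < train.n_users:
                filled[~rows_obs, j] = reg.predict(X[~rows_obs])
    lo = float(train.values[obs].min())
    hi = float(train.values[obs].max())
    imputed = ~obs
    filled[imputed] = np.clip(filled[imputed], lo, hi)
    return train.with_values(filled)


def mice_predict(train: RatingsMatrix, cells, n_rounds: int = 10, seed: int = 0) -> Predictions:
    """Impute the full matrix and read off the requested cells."""
    cells = _as_cells(cells)
    _check_cells(cells, train.n_users, train.n_items)
    completed = mice_impute(train, n_rounds=n_rounds, seed=seed)
    out = Predictions()
    for u, i in cells:
        out.append(Prediction(int(u), int(i), float(completed.values[u, i]), MODEL))
    return out
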