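"""User x item rating matrices with explicit missingness.

The central container is :class:`RatingsMatrix`: a dense real matrix whose
rows are users (participants) and whose columns are items (stimuli, trials,
or -- when a time axis is declared -- consecutive time points sampled at a
fixed interval). Missing entries are NaN. Ratings optionally carry a declared
scale ``(r_min, r_max)`` used downstream for normalized error and for
clipping imputations.

Long-form ("tidy") records with one rating per row are the interchange
format: :func:`from_long` pivots them into a matrix, :func:`to_long` inverts
the pivot for every observed cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RatingsMatrix",
    "ObservationSplit",
    "from_long",
    "to_long",
    "mask_random",
    "resample_time",
    "read_long_csv",
    "write_long_csv",
    "read_wide_csv",
    "write_wide_csv",
]


@dataclass
class RatingsMatrix:
    """Dense user x item rating matrix with NaN as the missingness marker.

    Parameters
    ----------
    user_ids, item_ids
        Ordered, unique row/column labels.
    values
        Real matrix of shape ``(len(user_ids), len(item_ids))``; NaN marks a
        missing rating.
    scale
        Optional ``(r_min, r_max)`` declaring the legal rating range. When
        present every observed entry must lie inside it.
    sample_interval_s
        When not None, items are consecutive time points spaced this many
        seconds apart (the matrix "has a time axis").
    """

    user_ids: list
    item_ids: list
    values: np.ndarray
    scale: tuple[float, float] | None = None
    sample_interval_s: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.user_ids = list(self.user_ids)
        self.item_ids = list(self.item_ids)
        if self.values.shape != (len(self.user_ids), len(self.item_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.user_ids)} users x {len(self.item_ids)} items"
            )
        if len(set(self.user_ids)) != len(self.user_ids):
            raise ValueError("duplicate user ids")
        if len(set(self.item_ids)) != len(self.item_ids):
            raise ValueError("duplicate item ids")
        if not np.any(np.isfinite(self.values)):
            raise ValueError("matrix has no observed entries")
        if np.any(np.isinf(self.values)):
            raise ValueError("infinite rating values are not allowed")
        if self.scale is not None:
            r_min, r_max = map(float, self.scale)
            if not r_max > r_min:
                raise ValueError(f"degenerate scale ({r_min}, {r_max})")
            obs = self.values[np.isfinite(self.values)]
            if obs.size and (obs.min() < r_min or obs.max() > r_max):
                raise ValueError(
                    "observed ratings fall outside the declared scale "
                    f"[{r_min}, {r_max}]"
                )
            self.scale = (r_min, r_max)
        if self.sample_interval_s is not None:
            if not self.sample_interval_s > 0:
                raise ValueError("sample_interval_s must be positive")

    # -- basic views ---------------------------------------------------

    @property
    def n_users(self) -> int:
        return len(self.user_ids)

    @property
    def n_items(self) -> int:
        return len(self.item_ids)

    @property
    def has_time_axis(self) -> bool:
        return self.sample_interval_s is not None

    def observed_mask(self) -> np.ndarray:
        """Boolean matrix: True where a rating is observed."""
        return np.isfinite(self.values)

    @property
    def n_observed(self) -> int:
        return int(np.isfinite(self.values).sum())

    def user_index(self, user) -> int:
        try:
            return self.user_ids.index(user)
        except ValueError:
            raise KeyError(f"unknown user {user!r}") from None

    def item_index(self, item) -> int:
        try:
            return self.item_ids.index(item)
        except ValueError:
            raise KeyError(f"unknown item {item!r}") from None

    def copy(self) -> "RatingsMatrix":
        return RatingsMatrix(
            list(self.user_ids),
            list(self.item_ids),
            self.values.copy(),
            self.scale,
            self.sample_interval_s,
        )

    def with_values(self, values: np.ndarray) -> "RatingsMatrix":
        """Same labels/metadata, new values (does not re-check the scale)."""
        out = RatingsMatrix.__new__(RatingsMatrix)
        out.user_ids = list(self.user_ids)
        out.item_ids = list(self.item_ids)
        out.values = np.asarray(values, dtype=float)
        out.scale = self.scale
        out.sample_interval_s = self.sample_interval_s
        return out

    def value_range(self) -> tuple[float, float]:
        """Declared scale if present, else the observed data range."""
        if self.scale is not None:
            return self.scale
        obs = self.values[np.isfinite(self.values)]
        return float(obs.min()), float(obs.max())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.user_ids, columns=self.item_ids)


@dataclass
class ObservationSplit:
    """Disjoint train/test masks over the observed cells of a matrix.

    ``train_mask | test_mask`` equals the observed mask of the source matrix
    and the two never overlap; ``sparsity`` is the fraction of observed cells
    routed to the test side.
    """

    train_mask: np.ndarray
    test_mask: np.ndarray
    sparsity: float
    seed: int

    def __post_init__(self) -> None:
        self.train_mask = np.asarray(self.train_mask, dtype=bool)
        self.test_mask = np.asarray(self.test_mask, dtype=bool)
        if self.train_mask.shape != self.test_mask.shape:
            raise ValueError("mask shapes differ")
        if np.any(self.train_mask & self.test_mask):
            raise ValueError("train and test masks overlap")

    @property
    def n_train(self) -> int:
        return int(self.train_mask.sum())

    @property
    def n_test(self) -> int:
        return int(self.test_mask.sum())

    def train_matrix(self, matrix: RatingsMatrix) -> RatingsMatrix:
        """The source matrix with every test cell blanked out."""
        values = np.where(self.train_mask, matrix.values, np.nan)
        return matrix.with_values(values)

    def test_cells(self) -> np.ndarray:
        """(row, col) index pairs of test cells, row-major order."""
        return np.argwhere(self.test_mask)


def from_long(records: Iterable[Sequence], scale=None, sample_interval_s=None) -> RatingsMatrix:
    """Pivot long-form ``(user, item, rating[, time_s])`` records to a matrix.

    User and item order follow first appearance in the input. Duplicate
    ``(user, item)`` pairs are averaged. A fourth column, when present, is
    carried only as the time stamp of the item and otherwise ignored.
    """
    records = list(records)
    if not records:
        raise ValueError("no records supplied")
    users: dict = {}
    items: dict = {}
    sums: dict[tuple[int, int], float] = {}
    counts: dict[tuple[int, int], int] = {}
    for rec in records:
        user, item, rating = rec[0], rec[1], float(rec[2])
        if not np.isfinite(rating):
            raise ValueError(f"non-finite rating for user {user!r}, item {item!r}")
        u = users.setdefault(user, len(users))
        i = items.setdefault(item, len(items))
        sums[(u, i)] = sums.get((u, i), 0.0) + rating
        counts[(u, i)] = counts.get((u, i), 0) + 1
    values = np.full((len(users), len(items)), np.nan)
    for (u, i), total in sums.items():
        values[u, i] = total / counts[(u, i)]
    return RatingsMatrix(
        list(users), list(items), values, scale=scale, sample_interval_s=sample_interval_s
    )


def to_long(matrix: RatingsMatrix) -> list[tuple]:
    """One ``(user, item, rating)`` record per observed cell, row-major."""
    out = []
    for u, i in np.argwhere(np.isfinite(matrix.values)):
        out.append((matrix.user_ids[u], matrix.item_ids[i], float(matrix.values[u, i])))
    return out


def mask_random(matrix: RatingsMatrix, masked_fraction: float, seed: int) -> ObservationSplit:
    """Mask a uniformly random subset of observed cells as the test set.

    Selection is uniform over all observed cells of the whole matrix (not
    stratified per user), so at high fractions a user can lose every rating.
    Exactly ``round(masked_fraction * n_observed)`` cells are masked;
    identical inputs and seed reproduce the identical split.
    """
    if not 0.0 < masked_fraction < 1.0:
        raise ValueError(f"masked_fraction must be in (0, 1), got {masked_fraction}")
    observed = matrix.observed_mask()
    obs_cells = np.argwhere(observed)
    n_obs = len(obs_cells)
    if n_obs == 0:
        raise ValueError("matrix has no observed cells")
    n_test = int(round(masked_fraction * n_obs))
    rng = np.random.default_rng(seed)
    picked = rng.choice(n_obs, size=n_test, replace=False)
    test_mask = np.zeros_like(observed)
    test_mask[obs_cells[picked, 0], obs_cells[picked, 1]] = True
    train_mask = observed & ~test_mask
    return ObservationSplit(train_mask, test_mask, masked_fraction, seed)


def resample_time(matrix: RatingsMatrix, factor: int, direction: str) -> RatingsMatrix:
    """Temporal down- or upsampling of a time-axis matrix.

    ``down``: non-overlapping blocks of ``factor`` consecutive time points
    are reduced to the mean of their observed values (an all-missing block
    stays missing); a trailing partial block is averaged over what it holds.
    ``up``: each time point is repeated ``factor`` times. The sample interval
    is rescaled accordingly.
    """
    if not matrix.has_time_axis:
        raise ValueError("matrix has no time axis")
    factor = int(factor)
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return matrix.copy()
    v = matrix.values
    if direction == "down":
        n_blocks = int(np.ceil(matrix.n_items / factor))
        out = np.full((matrix.n_users, n_blocks), np.nan)
        for b in range(n_blocks):
            block = v[:, b * factor : (b + 1) * factor]
            with np.errstate(invalid="ignore"):
                counts = np.isfinite(block).sum(axis=1)
                means = np.where(counts > 0, np.nansum(block, axis=1) / np.maximum(counts, 1), np.nan)
            out[:, b] = means
        items = [matrix.item_ids[b * factor] for b in range(n_blocks)]
        return RatingsMatrix(
            matrix.user_ids, items, out, scale=matrix.scale,
            sample_interval_s=matrix.sample_interval_s * factor,
        )
    if direction == "up":
        out = np.repeat(v, factor, axis=1)
        items = [f"{it}.{k}" if k else it for it in matrix.item_ids for k in range(factor)]
        return RatingsMatrix(
            matrix.user_ids, items, out, scale=matrix.scale,
            sample_interval_s=matrix.sample_interval_s / factor,
        )
    raise ValueError(f"direction must be 'down' or 'up', got {direction!r}")


# -- CSV interchange ----------------------------------------------------


def write_long_csv(matrix: RatingsMatrix, path) -> None:
    """Write observed cells as ``user,item,rating[,time_s]`` rows."""
    rows = to_long(matrix)
    df = pd.DataFrame(rows, columns=["user", "item", "rating"])
    if matrix.has_time_axis:
        pos = {it: k for k, it in enumerate(matrix.item_ids)}
        df["time_s"] = [pos[it] * matrix.sample_interval_s for it in df["item"]]
    df.to_csv(path, index=False)


def read_long_csv(path, scale=None) -> RatingsMatrix:
    """Read a ``user,item,rating[,time_s]`` CSV into a matrix.

    When a ``time_s`` column is present and items are equally spaced, the
    result carries a time axis at the implied sample interval.
    """
    df = pd.read_csv(path)
    required = {"user", "item", "rating"}
    if not required.issubset(df.columns):
        raise ValueError(f"long-form CSV needs columns {sorted(required)}")
    interval = None
    if "time_s" in df.columns:
        times = df.drop_duplicates("item").sort_values("time_s")["time_s"].to_numpy(float)
        if len(times) > 1:
            diffs = np.diff(times)
            if np.allclose(diffs, diffs[0]) and diffs[0] > 0:
                interval = float(diffs[0])
    records = list(df[["user", "item", "rating"]].itertuples(index=False, name=None))
    return from_long(records, scale=scale, sample_interval_s=interval)


def write_wide_csv(matrix: RatingsMatrix, path) -> None:
    """Wide CSV: rows = users, columns = items, empty cell = missing."""
    matrix.to_frame().to_csv(path, index=True, index_label="user", na_rep="")


def read_wide_csv(path, scale=None, sample_interval_s=None) -> RatingsMatrix:
    df = pd.read_csv(path, index_col=0)
    return RatingsMatrix(
        list(df.index), list(df.columns), df.to_numpy(dtype=float),
        scale=scale, sample_interval_s=sample_interval_s,
    )
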