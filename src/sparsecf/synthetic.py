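"""Seeded generators for three rating-data archetypes.

Each generator emits a *dense* matrix (sparsity is always induced
afterwards with :func:`sparsecf.core.mask_random`, matching a masking
validation design on fully observed data) with the inter-individual
agreement structure typical of one experimental context:

``gen_normed_images``
    Static normed affective stimuli: a strong shared item signal, plus
    individual deviations that are partly stable low-rank "taste" profiles
    and partly trial noise, so users agree highly (pairwise ISC mean
    around 0.72).
``gen_affect_timeseries``
    Continuous 1 Hz bipolar valence annotation of a dynamic stimulus: each
    user mixes a shared smooth AR(1) latent (heterogeneous loadings), a
    few additional latent AR(1) time-courses with signed user loadings,
    a large stable scale offset, and a small unique AR(1) residual.
    Agreement is low (ISC mean around 0.20) but the individual variation
    is mostly structured, and series are smooth enough for temporal
    dilation to help.
``gen_subgroup_decisions``
    Repeated social/economic decisions by users drawn from latent
    sub-groups with distinct item-response profiles over a small common
    component (ISC mean around 0.34; within-group agreement exceeds
    between-group agreement). Group labels are returned as a sidecar and
    must never be passed to any predictor.

A deliberate design point: most of each archetype's individual variation
is *structured* (latent low-rank profiles, offsets, group membership)
rather than independent cell noise. Stable individual response tendencies
are exactly what makes unobserved ratings inferable from other users, and
they are what collaborative filtering exploits; pure iid noise would make
individual deviation unrecoverable by any method. Pairwise correlation is
insensitive to how deviation variance is split between the structured and
noise parts (and to offsets entirely), so the ISC calibration constrains
the totals while the split controls how much of the deviation is
learnable. Variance parameters are in rating units on the declared scale;
the default calibrations target the ISC levels above.
"""

from __future__ import annotations

import numpy as np

from .core import RatingsMatrix

__all__ = [
    "gen_normed_images",
    "gen_affect_timeseries",
    "gen_subgroup_decisions",
    "DEFAULT_GROUP_PROPORTIONS",
]

DEFAULT_GROUP_PROPORTIONS = (0.10, 0.15, 0.35, 0.40)


def _check_common(n_users: int, n_items: int, scale) -> tuple[float, float]:
    if n_users < 2 or n_items < 2:
        raise ValueError("need at least 2 users and 2 items")
    r_min, r_max = map(float, scale)
    if not r_max > r_min:
        raise ValueError("degenerate scale")
    return r_min, r_max


def gen_normed_images(
    n_users: int = 52,
    n_items: int = 112,
    seed: int = 0,
    scale: tuple[float, float] = (0.0, 100.0),
    item_signal_sd: float = 17.0,
    user_bias_sd: float = 4.0,
    taste_sd: float = 8.2,
    n_taste_dims: int = 4,
    noise_sd: float = 6.7,
) -> RatingsMatrix:
    """High-consensus ratings of normed static stimuli.

    r_ui = clip(s_i + b_u + a_u . g_i + eps_ui): item signal s_i ~
    N(midpoint, item_signal_sd) shared by everyone, user offset b_u,
    a stable low-rank taste profile (user loadings a_u ~ N(0, I) on
    ``n_taste_dims`` latent item dimensions g with total SD ``taste_sd``),
    and trial noise eps ~ N(0, noise_sd). The shared item signal dominates,
    putting the expected pairwise ISC near item_signal_sd^2 /
    (item_signal_sd^2 + taste_sd^2 + noise_sd^2) ~ 0.72. A noise level so
    large that clipping saturates the scale triggers a warning.
    """
    r_min, r_max = _check_common(n_users, n_items, scale)
    if min(item_signal_sd, user_bias_sd, taste_sd, noise_sd) < 0:
        raise ValueError("standard deviations must be non-negative")
    if n_taste_dims < 1:
        raise ValueError("n_taste_dims must be >= 1")
    rng = np.random.default_rng(seed)
    mid = (r_min + r_max) / 2.0
    s = rng.normal(mid, item_signal_sd, size=n_items)
    b = rng.normal(0.0, user_bias_sd, size=n_users)
    g = rng.normal(0.0, taste_sd / np.sqrt(n_taste_dims), size=(n_taste_dims, n_items))
    a = rng.normal(0.0, 1.0, size=(n_users, n_taste_dims))
    eps = rng.normal(0.0, noise_sd, size=(n_users, n_items))
    raw = s[None, :] + b[:, None] + a @ g + eps
    values = np.clip(raw, r_min, r_max)
    if np.mean((raw < r_min) | (raw > r_max)) > 0.5:
        import warnings

        warnings.warn("noise saturates the rating scale; ISC calibration is unreliable")
    return RatingsMatrix(
        [f"u{k}" for k in range(n_users)],
        [f"img{k}" for k in range(n_items)],
        values,
        scale=(r_min, r_max),
    )


def gen_affect_timeseries(
    n_users: int = 30,
    n_items: int = 600,
    seed: int = 0,
    scale: tuple[float, float] = (0.0, 100.0),
    sample_interval_s: float = 1.0,
    ar_coefficient: float = 0.9,
    shared_sd: float = 1.0,
    latent_sd: float = 2.0,
    n_latent: int = 3,
    noise_sd: float = 0.5,
    loading_mean: float = 1.0,
    loading_sd: float = 0.4,
    signal_gain: float = 10.0,
    user_bias_sd: float = 18.0,
) -> RatingsMatrix:
    """Low-consensus autocorrelated valence time-series.

    Each user's latent series is ``a_u s(t) + c_u . z(t) + e_u(t)``: a
    shared AR(1) latent s with stationary SD ``shared_sd`` and per-user
    loading a_u ~ N(loading_mean, loading_sd); ``n_latent`` further AR(1)
    time-courses z with signed user loadings c_u ~ N(0, I) and total
    stationary SD ``latent_sd``; and a unique AR(1) residual e_u with
    stationary SD ``noise_sd``. All AR processes share the lag-1
    coefficient. The series maps to the rating scale as midpoint + b_u +
    signal_gain * latent (then clipped), with a large stable per-user
    offset b_u ~ N(0, user_bias_sd) capturing how differently raters
    center a bipolar scale.

    With the defaults the shared latent carries roughly a fifth of the
    (offset-free) variance, giving pairwise ISC near 0.2, while the
    signed-loading latents and the offsets keep individual deviation
    mostly structured and hence recoverable.
    """
    r_min, r_max = _check_common(n_users, n_items, scale)
    if not 0.0 <= ar_coefficient < 1.0:
        raise ValueError("ar_coefficient must be in [0, 1)")
    if n_latent < 0:
        raise ValueError("n_latent must be >= 0")
    rng = np.random.default_rng(seed)

    def ar1(shape, sd):
        innov_sd = sd * np.sqrt(1.0 - ar_coefficient**2)
        x = np.empty(shape)
        x[..., 0] = rng.normal(0.0, sd, size=shape[:-1])
        for t in range(1, shape[-1]):
            x[..., t] = ar_coefficient * x[..., t - 1] + rng.normal(
                0.0, innov_sd, size=shape[:-1]
            )
        return x

    shared = ar1((n_items,), shared_sd) if shared_sd > 0 else np.zeros(n_items)
    loadings = rng.normal(loading_mean, loading_sd, size=n_users)
    if n_latent and latent_sd > 0:
        z = ar1((n_latent, n_items), latent_sd / np.sqrt(n_latent))
        c = rng.normal(0.0, 1.0, size=(n_users, n_latent))
        structured = c @ z
    else:
        structured = np.zeros((n_users, n_items))
    unique = ar1((n_users, n_items), noise_sd) if noise_sd > 0 else np.zeros((n_users, n_items))
    b = rng.normal(0.0, user_bias_sd, size=n_users)
    mid = (r_min + r_max) / 2.0
    latent = loadings[:, None] * shared[None, :] + structured + unique
    values = np.clip(mid + b[:, None] + signal_gain * latent, r_min, r_max)
    return RatingsMatrix(
        [f"u{k}" for k in range(n_users)],
        [f"t{k}" for k in range(n_items)],
        values,
        scale=(r_min, r_max),
        sample_interval_s=sample_interval_s,
    )


def gen_subgroup_decisions(
    n_users: int = 60,
    n_items: int = 76,
    seed: int = 0,
    scale: tuple[float, float] = (0.0, 100.0),
    n_groups: int = 4,
    group_proportions: tuple[float, ...] = DEFAULT_GROUP_PROPORTIONS,
    common_sd: float = 4.7,
    group_sd: float = 13.4,
    user_bias_sd: float = 8.0,
    noise_sd: float = 4.7,
    antithetic_profiles: bool = False,
) -> tuple[RatingsMatrix, np.ndarray]:
    """Decision profiles with latent user sub-groups.

    r_ui = clip(c_i + g_{group(u), i} + b_u + eps_ui): a small common item
    component c shared by everyone, a dominant group-specific profile g, a
    stable user offset b_u and decision noise eps. Within-group pairs
    correlate through c and g, between-group pairs only through c, so
    within-group ISC exceeds between-group ISC; the default variance split
    targets an overall ISC mean near 0.34 while keeping most individual
    variation structured (group membership plus offset). Unequal default
    proportions mirror unequal sub-group sizes in decision data.

    ``antithetic_profiles`` (two groups only) makes the second group's
    profile the exact negation of the first -- the fully polarized case.

    Returns the matrix and the integer group label per user (a sidecar for
    stratified evaluation only -- never an input to a predictor).
    """
    r_min, r_max = _check_common(n_users, n_items, scale)
    if n_groups < 1:
        raise ValueError("n_groups must be >= 1")
    props = np.asarray(group_proportions, dtype=float)
    if props.size != n_groups:
        raise ValueError("group_proportions length must equal n_groups")
    if not np.isclose(props.sum(), 1.0):
        raise ValueError("group_proportions must sum to 1")
    if antithetic_profiles and n_groups != 2:
        raise ValueError("antithetic_profiles requires exactly 2 groups")
    sizes = np.floor(props * n_users).astype(int)
    sizes[-1] = n_users - sizes[:-1].sum()
    if np.any(sizes < 1):
        raise ValueError("a group would be empty at this size; adjust proportions")
    rng = np.random.default_rng(seed)
    labels = np.repeat(np.arange(n_groups), sizes)
    mid = (r_min + r_max) / 2.0
    c = rng.normal(mid, common_sd, size=n_items)
    g = rng.normal(0.0, group_sd, size=(n_groups, n_items))
    if antithetic_profiles:
        g[1] = -g[0]
    b = rng.normal(0.0, user_bias_sd, size=n_users)
    eps = rng.normal(0.0, noise_sd, size=(n_users, n_items))
    values = np.clip(c[None, :] + g[labels] + b[:, None] + eps, r_min, r_max)
    matrix = RatingsMatrix(
        [f"u{k}" for k in range(n_users)],
        [f"trial{k}" for k in range(n_items)],
        values,
        scale=(r_min, r_max),
    )
    return matrix, labels
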