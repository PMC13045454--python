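"""Group statistics for paired awake/sleep velocity and power maps.

The paired design is tested with a one-sample sign-flip permutation test
on subject-wise difference maps, with family-wise error control by the
max-statistic null distribution over the map.  Voxel statistics can be
enhanced with threshold-free cluster enhancement (TFCE), which integrates
cluster extent e(h)^E times height h^H across thresholds, removing the
need for an arbitrary cluster-forming threshold.  Directional reversals
between conditions are mapped by testing the positive and negative parts
of each vector component separately and combining the component maps.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats as spstats

__all__ = [
    "PermutationResult",
    "ReversalMap",
    "tfce_enhance",
    "paired_permutation_test",
    "directional_reversal_map",
    "spatial_correlation",
    "power_delta_regression",
]

_CONNECTIVITY = {6: 1, 18: 2, 26: 3}


@dataclass
class PermutationResult:
    """Outcome of a max-statistic sign-flip permutation test.

    ``stat_map`` is the signed voxel statistic (paired t); ``p_corr_map``
    holds FWER-corrected p-values; ``sig_mask`` flags p < alpha.
    """

    stat_map: np.ndarray
    p_corr_map: np.ndarray
    sig_mask: np.ndarray
    n_permutations: int
    alpha: float
    alternative: str = "two-sided"
    exhaustive: bool = False


@dataclass
class ReversalMap:
    """Voxels whose pulse direction reverses significantly between states."""

    reversal: np.ndarray
    per_component: np.ndarray  # (3, ...) boolean, contribution of x/y/z
    alpha: float


def tfce_enhance(
    stat_map: np.ndarray,
    h_power: float = 2.0,
    e_power: float = 0.5,
    dh: float | None = None,
    connectivity: int = 26,
) -> np.ndarray:
    """Threshold-free cluster enhancement of a non-negative statistic map.

    enhanced(v) = sum over thresholds h of e(h, v)^E * h^H * dh, where
    e(h, v) is the extent of the supra-threshold cluster containing v.
    ``dh`` defaults to max(stat)/100.  Negative statistics are handled by
    the caller via separate positive/negative contrasts.
    """
    stat = np.asarray(stat_map, dtype=np.float64)
    if np.any(stat < 0):
        raise ValueError("tfce_enhance expects a non-negative map; "
                         "split signed statistics into two contrasts")
    top = stat.max()
    if top == 0:
        return np.zeros_like(stat)
    if dh is None:
        dh = top / 100.0
    if dh <= 0:
        raise ValueError("dh must be positive")
    structure = ndimage.generate_binary_structure(stat.ndim, _CONNECTIVITY[connectivity])
    out = np.zeros_like(stat)
    h = dh
    while h <= top + 1e-12:
        mask = stat >= h
        labels, n = ndimage.label(mask, structure=structure)
        if n == 0:
            break
        sizes = np.bincount(labels.ravel())
        out[mask] += sizes[labels[mask]] ** e_power * h**h_power * dh
        h += dh
    return out


def _t_stat(diffs: np.ndarray) -> np.ndarray:
    """Paired t statistic over axis 0, defined as 0 where variance and mean vanish."""
    n = diffs.shape[0]
    mean = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    se = sd / np.sqrt(n)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / se
    t = np.where(se == 0, np.where(mean == 0, 0.0, np.sign(mean) * 1e30), t)
    return t


def _sign_matrix(n: int, n_perm: int, rng: np.random.Generator) -> tuple[np.ndarray, bool]:
    """Sign-flip matrix: exhaustive (2^n rows incl. identity) when feasible."""
    if 2**n <= n_perm:
        signs = np.array(list(itertools.product((1.0, -1.0), repeat=n)))
        return signs, True
    signs = rng.choice([1.0, -1.0], size=(n_perm, n))
    return signs, False


def paired_permutation_test(
    maps_a: np.ndarray,
    maps_b: np.ndarray,
    n_perm: int = 5000,
    alpha: float = 0.05,
    use_tfce: bool = True,
    seed: int | None = None,
    alternative: str = "two-sided",
    tfce_kwargs: dict | None = None,
) -> PermutationResult:
    """Paired sign-flip permutation test between condition maps.

    ``maps_a`` and ``maps_b`` are per-subject maps of identical shape
    ``(n_subjects, ...)`` with matched rows (same subject in both).  The
    voxel statistic is the paired t on differences a - b, optionally TFCE
    enhanced; FWER-corrected p-values come from the permutation null of
    the map-wide maximum statistic.  When ``2**n <= n_perm`` all sign
    flips are enumerated exactly.  ``alternative`` is ``"two-sided"``,
    ``"greater"`` (a > b) or ``"less"``.
    """
    a = np.asarray(maps_a, dtype=np.float64)
    b = np.asarray(maps_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"unpaired inputs: shapes {a.shape} vs {b.shape}")
    n = a.shape[0]
    if n < 5:
        raise ValueError(f"need >= 5 subject pairs, got {n}")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    diffs = a - b
    rng = np.random.default_rng(seed)
    signs, exhaustive = _sign_matrix(n, n_perm, rng)
    n_eff = signs.shape[0]

    tfce_kwargs = tfce_kwargs or {}

    def enhanced(t_map: np.ndarray) -> np.ndarray:
        pos = np.maximum(t_map, 0.0)
        neg = np.maximum(-t_map, 0.0)
        if use_tfce:
            pos = tfce_enhance(pos, **tfce_kwargs)
            neg = tfce_enhance(neg, **tfce_kwargs)
        if alternative == "greater":
            return pos, np.zeros_like(neg)
        if alternative == "less":
            return np.zeros_like(pos), neg
        return pos, neg

    t_obs = _t_stat(diffs)
    pos_obs, neg_obs = enhanced(t_obs)
    obs = np.maximum(pos_obs, neg_obs)

    flat = diffs.reshape(n, -1)
    if not use_tfce:
        # vectorized: sign flips leave d^2 unchanged, so only the permuted
        # mean is needed to rebuild the t statistic
        msq = (flat**2).mean(axis=0)
        mean_p = signs @ flat / n
        var_p = (msq[None, :] - mean_p**2) * (n / (n - 1))
        se_p = np.sqrt(var_p / n)
        with np.errstate(divide="ignore", invalid="ignore"):
            t_p = mean_p / se_p
        t_p = np.where(se_p == 0, np.where(mean_p == 0, 0.0, np.sign(mean_p) * 1e30), t_p)
        if alternative == "greater":
            null_max = np.max(np.maximum(t_p, 0.0), axis=1)
        elif alternative == "less":
            null_max = np.max(np.maximum(-t_p, 0.0), axis=1)
        else:
            null_max = np.max(np.abs(t_p), axis=1)
    else:
        null_max = np.empty(n_eff)
        for i in range(n_eff):
            t_p = _t_stat(signs[i][:, None] * flat).reshape(t_obs.shape)
            pos_p, neg_p = enhanced(t_p)
            null_max[i] = max(pos_p.max(), neg_p.max())

    null_sorted = np.sort(null_max)
    ge = (
        len(null_sorted)
        - np.searchsorted(null_sorted, obs.ravel() - 1e-12, side="left")
    ).reshape(obs.shape)
    if exhaustive:
        p = ge / n_eff
    else:
        p = (1.0 + ge) / (n_eff + 1.0)
    p = np.minimum(p, 1.0)
    return PermutationResult(
        t_obs, p, p < alpha, n_eff, alpha, alternative, exhaustive
    )


def directional_reversal_map(
    dir_a: np.ndarray,
    dir_b: np.ndarray,
    n_perm: int = 5000,
    alpha: float = 0.05,
    use_tfce: bool = True,
    seed: int | None = None,
    combine: str = "union",
    tfce_kwargs: dict | None = None,
) -> ReversalMap:
    """Map voxels where the mean pulse direction reverses between states.

    ``dir_a``/``dir_b`` hold per-subject mean unit-direction maps of shape
    ``(n_subjects, ..., 3)`` (NaN where undefined, treated as zero).  Each
    Cartesian component is split into its positive part max(c, 0) and
    negative part max(-c, 0); a voxel reverses along a component when the
    positive part significantly decreases while the negative part
    significantly increases between conditions (or vice versa).  Component
    maps are combined by ``"union"`` (default) or ``"intersection"``.
    """
    a = np.nan_to_num(np.asarray(dir_a, dtype=np.float64))
    b = np.nan_to_num(np.asarray(dir_b, dtype=np.float64))
    if a.shape != b.shape or a.shape[-1] != 3:
        raise ValueError("direction maps must share shape (n, ..., 3)")
    if combine not in ("union", "intersection"):
        raise ValueError("combine must be 'union' or 'intersection'")
    per_comp = []
    for c in range(3):
        pos_a, neg_a = np.maximum(a[..., c], 0), np.maximum(-a[..., c], 0)
        pos_b, neg_b = np.maximum(b[..., c], 0), np.maximum(-b[..., c], 0)
        kw = dict(n_perm=n_perm, alpha=alpha, use_tfce=use_tfce,
                  seed=seed, tfce_kwargs=tfce_kwargs)
        pos_down = paired_permutation_test(pos_a, pos_b, alternative="greater", **kw)
        pos_up = paired_permutation_test(pos_a, pos_b, alternative="less", **kw)
        neg_down = paired_permutation_test(neg_a, neg_b, alternative="greater", **kw)
        neg_up = paired_permutation_test(neg_a, neg_b, alternative="less", **kw)
        flagged = (pos_down.sig_mask & neg_up.sig_mask) | (
            pos_up.sig_mask & neg_down.sig_mask
        )
        per_comp.append(flagged)
    per_comp = np.stack(per_comp)
    if combine == "union":
        reversal = per_comp.any(axis=0)
    else:
        reversal = per_comp.all(axis=0)
    return ReversalMap(reversal, per_comp, alpha)


def spatial_correlation(
    map_a: np.ndarray, map_b: np.ndarray, mask: np.ndarray | None = None
) -> float:
    """Pearson correlation between two maps over in-mask voxels."""
    a = np.asarray(map_a, dtype=np.float64)
    b = np.asarray(map_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("maps must share shape")
    m = np.ones(a.shape, bool) if mask is None else np.asarray(mask, bool)
    av, bv = a[m], b[m]
    if av.size < 3:
        raise ValueError("need at least 3 in-mask voxels")
    if av.std() == 0 or bv.std() == 0:
        raise ValueError("zero-variance map: correlation undefined")
    r, _ = spstats.pearsonr(av, bv)
    return float(r)


def power_delta_regression(
    log_band_power: np.ndarray,
    log_delta_power: np.ndarray,
    sigma_threshold: float = 4.0,
) -> tuple[float, float, list[int]]:
    """Correlate subject log band power with log slow-delta EEG power.

    Subjects lying more than ``sigma_threshold`` standard deviations from
    the mean in either coordinate are excluded first (a stringent outlier
    rule justified by Chebyshev's inequality).  Returns
    ``(pearson_r, slope, excluded_subject_indices)``.
    """
    x = np.asarray(log_delta_power, dtype=np.float64)
    y = np.asarray(log_band_power, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be matching 1D arrays")
    if len(x) < 4:
        raise ValueError("need >= 4 subjects")

    def z(v: np.ndarray) -> np.ndarray:
        sd = v.std()
        return np.zeros_like(v) if sd == 0 else (v - v.mean()) / sd

    out = (np.abs(z(x)) > sigma_threshold) | (np.abs(z(y)) > sigma_threshold)
    keep = ~out
    if keep.sum() < 3:
        raise ValueError("all (or nearly all) subjects excluded as outliers")
    xs, ys = x[keep], y[keep]
    if xs.std() == 0 or ys.std() == 0:
        # perfectly degenerate after exclusion; slope/r undefined
        raise ValueError("zero variance after outlier exclusion")
    res = spstats.linregress(xs, ys)
    return float(res.rvalue), float(res.slope), list(np.flatnonzero(out))
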