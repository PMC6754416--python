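"""Model-based signal-to-noise (STN) test with a resampled null.

The STN statistic for a protein compares its two condition means scaled by
the *model* standard deviations from the power-law error model:

    STN = (mean_a − mean_b) / (σ_model(mean_a) + σ_model(mean_b))

Significance comes from an empirical null: the baseline condition's
replicates are repeatedly split into two pseudo-conditions, the STN is
recomputed per protein for each split, and values are pooled across
proteins and splits.  A protein's two-sided p-value is the fraction of the
pooled null whose magnitude reaches its observed |STN|.

Because a split of n baseline replicates produces pseudo-groups smaller
than the real conditions (for triplicates, sizes 1 and 2 versus 3 vs 3),
the raw split mean-difference is more variable than the observed one.  By
default each null STN is rescaled by

    sqrt((1/n_a + 1/n_b) / (1/s1 + 1/s2))

(the ratio of mean-difference variances under homoscedastic replicates) so
that null and observed statistics are on the same footing; pass
``scale_to_design=False`` for the raw split statistic.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd

from .counts_io import CountMatrix
from .plgem_model import PlgemFit, model_sd_or_zero

__all__ = [
    "stn_statistic",
    "null_stn_distribution",
    "stn_pvalues",
    "stratified_pvalue_summary",
    "enumerate_splits",
]


def stn_statistic(mean_a: float, mean_b: float, sd_a: float, sd_b: float) -> float:
    """Signed signal-to-noise statistic (mean_a − mean_b)/(sd_a + sd_b)."""
    if sd_a + sd_b <= 0:
        raise ValueError("sd_a + sd_b must be positive")
    return (mean_a - mean_b) / (sd_a + sd_b)


def _stn_vector(
    mean_a: np.ndarray, mean_b: np.ndarray, fit: PlgemFit
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised STN with model SDs; STN = 0 where both SDs vanish.

    Both SDs vanish only when both means are zero (protein undetected in
    every replicate of both groups), where 'no change' is the only
    defensible value.
    """
    sd_a = model_sd_or_zero(fit, mean_a)
    sd_b = model_sd_or_zero(fit, mean_b)
    denom = sd_a + sd_b
    ok = denom > 0
    stn = np.zeros_like(denom)
    stn[ok] = (mean_a[ok] - mean_b[ok]) / denom[ok]
    return stn, sd_a, sd_b, ok


def enumerate_splits(n: int) -> list[tuple[tuple[int, ...], tuple[int, ...]]]:
    """All ordered partitions of range(n) into two non-empty groups.

    2^n − 2 splits; for triplicates the 3 distinct {1}|{2} partitions in
    both orientations.
    """
    idx = set(range(n))
    splits = []
    for size in range(1, n):
        for group in combinations(range(n), size):
            splits.append((group, tuple(sorted(idx - set(group)))))
    return splits


def null_stn_distribution(
    matrix: CountMatrix,
    fit: PlgemFit,
    baseline: str,
    n_iter: int = 500,
    seed: int | None = None,
    mode: str = "auto",
    scale_to_design: bool = True,
) -> np.ndarray:
    """Pooled null STN sample from pseudo-splits of the baseline replicates.

    Parameters
    ----------
    n_iter
        Number of random splits in resampling mode.  In ``auto`` mode the
        enumeration is exhaustive whenever the number of ordered splits
        (2^n − 2) does not exceed ``n_iter``.
    mode
        ``"exhaustive"``, ``"resample"`` or ``"auto"``.
    scale_to_design
        Rescale each split's STN values to the real design's group sizes
        (see module docstring).
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    runs = matrix.runs(baseline)
    n = len(runs)
    if n < 3:
        raise ValueError(
            f"baseline {baseline!r} needs >= 3 replicates to split, has {n}"
        )
    values = matrix.counts[runs].to_numpy(dtype=float)

    all_splits = enumerate_splits(n)
    if mode == "exhaustive" or (mode == "auto" and len(all_splits) <= n_iter):
        splits = all_splits
    elif mode in ("resample", "auto"):
        rng = np.random.default_rng(seed)
        picks = rng.integers(0, len(all_splits), size=n_iter)
        splits = [all_splits[i] for i in picks]
    else:
        raise ValueError(f"unknown mode {mode!r}")

    cond_a, cond_b = matrix.conditions
    f_obs = 1.0 / len(matrix.runs(cond_a)) + 1.0 / len(matrix.runs(cond_b))

    pool = []
    for group_a, group_b in splits:
        mean_a = values[:, list(group_a)].mean(axis=1)
        mean_b = values[:, list(group_b)].mean(axis=1)
        stn, _, _, _ = _stn_vector(mean_a, mean_b, fit)
        # proteins absent from every baseline replicate carry no noise
        # information; they are excluded from the pool
        both_zero = (mean_a == 0) & (mean_b == 0)
        stn = stn[~both_zero]
        if scale_to_design:
            f_split = 1.0 / len(group_a) + 1.0 / len(group_b)
            stn = stn * np.sqrt(f_obs / f_split)
        pool.append(stn)
    return np.concatenate(pool)


def _empirical_pvalues(
    observed: np.ndarray, null_pool: np.ndarray, pseudocount: bool = False
) -> np.ndarray:
    """Two-sided tail fraction p = #{|null| >= |obs|} / N (vectorised).

    With ``pseudocount`` the (r+1)/(N+1) estimator is used instead, which
    never returns exactly 0.
    """
    abs_null = np.sort(np.abs(null_pool))
    n = len(abs_null)
    # number of null values strictly below |obs|
    below = np.searchsorted(abs_null, np.abs(observed), side="left")
    tail = n - below
    if pseudocount:
        return (tail + 1) / (n + 1)
    return tail / n


def stn_pvalues(
    matrix: CountMatrix,
    fit: PlgemFit,
    null_pool: np.ndarray,
    conditions: tuple[str, str] | None = None,
    pseudocount: bool = False,
    pass_label: str = "pass1",
) -> pd.DataFrame:
    """Observed STN and empirical p-value for every protein.

    Returns a DataFrame indexed by protein id with columns mean_a, mean_b,
    sd_model_a, sd_model_b, stn, p_value, pass_label.  Proteins undetected
    in both conditions get stn = 0, p = 1.
    """
    if len(null_pool) == 0:
        raise ValueError("null pool is empty")
    if conditions is None:
        conditions = matrix.conditions
    cond_a, cond_b = conditions
    mean_a = matrix.condition_counts(cond_a).to_numpy(dtype=float).mean(axis=1)
    mean_b = matrix.condition_counts(cond_b).to_numpy(dtype=float).mean(axis=1)
    stn, sd_a, sd_b, ok = _stn_vector(mean_a, mean_b, fit)
    p = _empirical_pvalues(stn, null_pool, pseudocount=pseudocount)
    p[~ok] = 1.0
    return pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "sd_model_a": sd_a,
            "sd_model_b": sd_b,
            "stn": stn,
            "p_value": p,
            "pass_label": pass_label,
        },
        index=matrix.protein_ids,
    )


def stratified_pvalue_summary(
    results: pd.DataFrame,
    matrix: CountMatrix,
    threshold_mean: float = 5.0,
) -> dict:
    """Mean p-value and protein count per abundance stratum.

    Strata are defined by the protein's mean count over all runs being
    below vs at/above ``threshold_mean`` (the classic low-abundance
    boundary of 5 spectra).  An empty stratum is reported as absent.
    """
    mean_all = matrix.counts.to_numpy(dtype=float).mean(axis=1)
    mean_all = pd.Series(mean_all, index=matrix.protein_ids)
    p = results["p_value"].reindex(mean_all.index)
    out: dict[str, dict] = {}
    low = mean_all < threshold_mean
    for name, mask in (("low", low), ("high", ~low)):
        if mask.any():
            out[name] = {
                "n": int(mask.sum()),
                "mean_p": float(p[mask].mean()),
            }
    out["threshold_mean"] = threshold_mean
    return out
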