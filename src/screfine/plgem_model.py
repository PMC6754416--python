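"""Power Law Global Error Model (PLGEM) for replicate spectral counts.

Replicate noise in spectral counting grows with abundance roughly as a
power law: the standard deviation s of repeated measures of a protein with
replicate mean x̄ follows

    ln(s) = k · ln(x̄) + c + ε

with slope k, intercept c and residual ε.  Fitting this regression over
all proteins of a baseline condition yields a *model* standard deviation
σ_expected(m) = exp(c) · m^k at any mean m, which downstream code uses in
place of the noisy three-replicate sample SD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .counts_io import CountMatrix

__all__ = [
    "PlgemFit",
    "fit_plgem",
    "model_sd",
    "variance_diagnostics",
    "loglog_regression_summary",
]


@dataclass(frozen=True)
class PlgemFit:
    """Fitted power-law error model ln(SD) = k·ln(mean) + c."""

    k: float
    c: float
    r_squared: float
    n_points: int
    condition: str
    residual_sd: float

    def as_dict(self) -> dict:
        return {
            "k": self.k,
            "c": self.c,
            "r_squared": self.r_squared,
            "n_points": self.n_points,
            "condition": self.condition,
            "residual_sd": self.residual_sd,
        }


def _mean_sd(counts: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Per-protein replicate mean and sample SD (n−1 denominator)."""
    values = counts.to_numpy(dtype=float)
    return values.mean(axis=1), values.std(axis=1, ddof=1)


def _loglog_ols(mean: np.ndarray, sd: np.ndarray) -> tuple[float, float, float, int, float]:
    """OLS of ln(sd) on ln(mean) over points with mean>0 and sd>0."""
    ok = (mean > 0) & (sd > 0)
    n = int(ok.sum())
    if n < 3:
        raise ValueError(
            f"need at least 3 proteins with positive mean and SD, got {n}"
        )
    x = np.log(mean[ok])
    y = np.log(sd[ok])
    res = stats.linregress(x, y)
    resid = y - (res.slope * x + res.intercept)
    return (
        float(res.slope),
        float(res.intercept),
        float(res.rvalue**2),
        n,
        float(resid.std(ddof=1)),
    )


def fit_plgem(matrix: CountMatrix, condition: str) -> PlgemFit:
    """Fit the power-law error model on one condition's replicates.

    Unbinned ordinary least squares of ln(sample SD) on ln(replicate mean)
    over all proteins with positive mean and SD; proteins with mean = 0 or
    SD = 0 are excluded from fitting but still receive a model SD later.
    Natural logarithms throughout.
    """
    counts = matrix.condition_counts(condition)
    if counts.shape[1] < 2:
        raise ValueError(f"condition {condition!r} has fewer than 2 replicates")
    mean, sd = _mean_sd(counts)
    k, c, r2, n, resid_sd = _loglog_ols(mean, sd)
    return PlgemFit(
        k=k, c=c, r_squared=r2, n_points=n, condition=condition,
        residual_sd=resid_sd,
    )


def model_sd(fit: PlgemFit, mean):
    """Model-expected SD at a replicate mean: exp(c) · mean^k.

    Accepts a scalar or array; every mean must be strictly positive.
    """
    m = np.asarray(mean, dtype=float)
    if (m <= 0).any():
        raise ValueError("model_sd requires mean > 0")
    out = np.exp(fit.c) * m**fit.k
    return float(out) if np.isscalar(mean) else out


def model_sd_or_zero(fit: PlgemFit, mean) -> np.ndarray:
    """Vectorised model SD with the k>0 limit value 0 at mean = 0.

    Used where zero condition means legitimately occur (undetected
    proteins); the power law exp(c)·m^k → 0 as m → 0 for k > 0.
    """
    m = np.asarray(mean, dtype=float)
    out = np.zeros_like(m)
    pos = m > 0
    out[pos] = np.exp(fit.c) * m[pos] ** fit.k
    return out


def variance_diagnostics(matrix: CountMatrix, fit: PlgemFit) -> pd.DataFrame:
    """Per-protein σ_expected / σ_measured table for the fitted condition.

    One row per protein with replicate mean > 0.  ``ratio`` is NaN (and
    ``ratio_defined`` False) when the measured SD is zero.
    """
    counts = matrix.condition_counts(fit.condition)
    mean, sd = _mean_sd(counts)
    keep = mean > 0
    sigma_expected = model_sd(fit, mean[keep])
    sigma_measured = sd[keep]
    with np.errstate(divide="ignore"):
        ratio = np.where(
            sigma_measured > 0, sigma_expected / np.where(sigma_measured > 0, sigma_measured, 1.0), np.nan
        )
    return pd.DataFrame(
        {
            "protein_id": matrix.protein_ids[keep],
            "sc_mean": mean[keep],
            "sigma_measured": sigma_measured,
            "sigma_expected": sigma_expected,
            "ratio": ratio,
            "ratio_defined": sigma_measured > 0,
        }
    ).set_index("protein_id")


def loglog_regression_summary(
    matrix: CountMatrix,
    protein_subset=None,
    condition: str | None = None,
) -> tuple[float, float, float]:
    """(slope, intercept, R²) of ln(SD) vs ln(mean) over a protein subset.

    With ``protein_subset=None`` and the baseline condition this equals
    ``fit_plgem`` on the same data; with a subset it gives the
    before/after-refinement comparison on e.g. the called-DEP set.
    """
    if condition is None:
        condition = matrix.conditions[0]
    counts = matrix.condition_counts(condition)
    if protein_subset is not None:
        keep = matrix.protein_ids.isin(set(protein_subset))
        counts = counts.loc[keep]
    mean, sd = _mean_sd(counts)
    slope, intercept, r2, _, _ = _loglog_ols(mean, sd)
    return slope, intercept, r2
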