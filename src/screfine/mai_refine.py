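"""Moment Adjusted Imputation (MAI) refinement of replicate spectral counts.

MAI treats the replicate counts W₁ ≤ … ≤ Wₙ of a protein as error-prone
measurements of a latent abundance X and replaces the most suspect one by a
convex combination of itself and the replicate mean:

    X̂ᵢ = Wᵢ·â + W̄·(1 − â),    â = (σ̂ₓ² / σ̂_w²)^½

where σ̂_w is the n⁻¹-denominator SD of the replicates and σ̂ₓ the
error-free SD predicted by the power-law error model at the replicate
mean.  Which replicate is adjusted is decided by the skewness of the
triplicate: positive skew means the largest count is an overestimate (it
is shrunk), negative skew means the smallest is an underestimate, zero
skew leaves the data untouched.

The raw â exceeds 1 whenever the model SD exceeds the measured SD; an
unclamped â would then move the extreme value *away* from the mean,
inflating rather than reducing variability, so â is clamped to 1 by
default (the raw value is kept in the audit record).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .counts_io import CountMatrix
from .plgem_model import PlgemFit, model_sd

__all__ = [
    "MaiAdjustment",
    "skewness",
    "shrinkage_coefficient",
    "mai_adjust",
    "refine_protein",
]

#: |skewness| below this counts as "truly estimated" (no adjustment)
SKEW_TOL = 1e-12


@dataclass
class MaiAdjustment:
    """Audit record of one protein-condition MAI adjustment."""

    protein_id: str
    condition: str
    w: tuple  # measured replicate values, input order
    w_bar: float
    sigma_w: float  # n^-1-denominator SD of w
    sigma_x: float  # model SD at w_bar
    a_hat_raw: float  # sigma_x / sigma_w before clamping (nan if sigma_w = 0)
    a_hat: float  # coefficient actually used
    skewness: float
    adjusted_index: str  # "largest" | "smallest" | "none"
    refined: tuple = field(default=())

    def as_row(self) -> dict:
        return {
            "protein_id": self.protein_id,
            "condition": self.condition,
            "w": ";".join(f"{v:g}" for v in self.w),
            "w_bar": self.w_bar,
            "sigma_w": self.sigma_w,
            "sigma_x": self.sigma_x,
            "a_hat_raw": self.a_hat_raw,
            "a_hat": self.a_hat,
            "skewness": self.skewness,
            "adjusted_index": self.adjusted_index,
            "refined": ";".join(f"{v:g}" for v in self.refined),
        }


def skewness(values) -> float:
    """Population third-moment skewness g₁ = m₃ / m₂^{3/2}.

    Moments use the n denominator; returns 0 for constant input.  Only the
    sign matters for MAI targeting, but the magnitude is kept for audit.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValueError("skewness needs at least 3 values")
    d = v - v.mean()
    m2 = np.mean(d**2)
    if m2 == 0:
        return 0.0
    # scale-invariant form avoids under/overflow of m2**1.5
    z = d / np.sqrt(m2)
    return float(np.mean(z**3))


def shrinkage_coefficient(
    sigma_x: float, sigma_w: float, clamp: bool = True
) -> float:
    """MAI coefficient â = (σ̂ₓ²/σ̂_w²)^½ = σ̂ₓ/σ̂_w, clamped to ≤ 1.

    Raises if σ̂_w = 0 (no spread: nothing to adjust).
    """
    if sigma_w <= 0:
        raise ValueError("sigma_w must be positive (no adjustment possible)")
    if sigma_x <= 0:
        raise ValueError("sigma_x must be positive")
    a = sigma_x / sigma_w
    return min(1.0, a) if clamp else a


def mai_adjust(
    values,
    sigma_x: float,
    clamp: bool = True,
    protein_id: str = "",
    condition: str = "",
) -> tuple[np.ndarray, MaiAdjustment]:
    """Apply the skewness-directed MAI adjustment to one replicate vector.

    Positive skew: the largest value Wₙ becomes Wₙ·â + W̄·(1−â).
    Negative skew: the smallest value W₁ becomes W₁·â + W̄·(1−â).
    Zero skew or zero spread: values are returned unchanged.
    Exactly one position ever changes; ties go to the first extreme.
    """
    w = np.asarray(values, dtype=float)
    if w.size < 3:
        raise ValueError("mai_adjust needs at least 3 replicate values")
    n = w.size
    w_bar = float(w.mean())
    sigma_w = float(np.sqrt(np.mean((w - w_bar) ** 2)))  # n^-1 denominator
    g1 = skewness(w)

    record = MaiAdjustment(
        protein_id=protein_id,
        condition=condition,
        w=tuple(w),
        w_bar=w_bar,
        sigma_w=sigma_w,
        sigma_x=float(sigma_x),
        a_hat_raw=float(sigma_x / sigma_w) if sigma_w > 0 else float("nan"),
        a_hat=1.0,
        skewness=g1,
        adjusted_index="none",
        refined=tuple(w),
    )
    if sigma_w == 0 or abs(g1) <= SKEW_TOL:
        return w.copy(), record

    a = shrinkage_coefficient(sigma_x, sigma_w, clamp=clamp)
    refined = w.copy()
    if g1 > 0:
        i = int(np.argmax(w))
        record.adjusted_index = "largest"
    else:
        i = int(np.argmin(w))
        record.adjusted_index = "smallest"
    refined[i] = w[i] * a + w_bar * (1 - a)
    record.a_hat = float(a)
    record.refined = tuple(refined)
    return refined, record


def refine_protein(
    matrix: CountMatrix,
    fit: PlgemFit,
    protein_id: str,
    clamp: bool = True,
) -> tuple[dict, list[MaiAdjustment]]:
    """MAI-refine one protein's replicates, independently per condition.

    σ̂ₓ is the power-law model SD evaluated at that condition's replicate
    mean.  A condition with mean 0 (protein undetected) cannot be placed on
    the power law and is left unadjusted, recorded as such.

    Returns ``(refined, records)`` where ``refined`` maps condition ->
    refined replicate array (input run order) and ``records`` holds one
    :class:`MaiAdjustment` per condition.
    """
    if protein_id not in matrix.protein_ids:
        raise KeyError(f"unknown protein {protein_id!r}")
    refined: dict[str, np.ndarray] = {}
    records: list[MaiAdjustment] = []
    for cond in matrix.conditions:
        w = matrix.condition_counts(cond).loc[protein_id].to_numpy(dtype=float)
        w_bar = w.mean()
        if w_bar <= 0:
            rec = MaiAdjustment(
                protein_id=protein_id,
                condition=cond,
                w=tuple(w),
                w_bar=float(w_bar),
                sigma_w=0.0,
                sigma_x=float("nan"),
                a_hat_raw=float("nan"),
                a_hat=1.0,
                skewness=0.0,
                adjusted_index="none",
                refined=tuple(w),
            )
            refined[cond] = w.copy()
            records.append(rec)
            continue
        sigma_x = model_sd(fit, float(w_bar))
        vals, rec = mai_adjust(
            w, sigma_x, clamp=clamp, protein_id=protein_id, condition=cond
        )
        refined[cond] = vals
        records.append(rec)
    return refined, records


def adjustments_table(records: list[MaiAdjustment]) -> pd.DataFrame:
    """Audit table (one row per protein-condition adjustment record)."""
    if not records:
        return pd.DataFrame(
            columns=[
                "protein_id", "condition", "w", "w_bar", "sigma_w", "sigma_x",
                "a_hat_raw", "a_hat", "skewness", "adjusted_index", "refined",
            ]
        )
    return pd.DataFrame([r.as_row() for r in records])
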