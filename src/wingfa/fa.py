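"""Two-way mixed-model ANOVA and the FA10a fluctuating-asymmetry index.

Model: for individual i (random), side s (fixed, L/R) and replicate k,

    y_isk = mu + I_i + D_s + A_is + e_isk

where I is inter-individual size variation, D the directional-asymmetry
(fixed side) effect, A the individual x side interaction — the biological
signal, true fluctuating asymmetry — and e replicate-level measurement
error.  With a balanced block (n individuals x 2 sides x r >= 2 replicates)
the expected mean squares are

    E[MS_res] = sigma_ME^2
    E[MS_int] = sigma_ME^2 + r * sigma_FA^2
    E[MS_side] = sigma_ME^2 + r * sigma_FA^2 + n*r/2 * delta_DA^2   (2 sides)

so FA10a = (MS_int - MS_res) / r is an unbiased estimator of sigma_FA^2,
the variance of true left-right developmental noise, with measurement error
partitioned out.  Repeated measurement (r >= 2) is what makes the residual
stratum identifiable; with r = 1 measurement error and FA are confounded.

FA differences between two genotypes are tested by an F ratio.  The default
statistic is the ratio of interaction mean squares, which is exactly
F-distributed with (n_a - 1, n_b - 1) df under H0 when both genotypes share
the same measurement-error variance (same measurer and protocol).  An
alternative mode tests the FA10a ratio directly with the same reference
distribution; it is approximate and provided for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import stats

from .io import GenotypeSample

__all__ = [
    "AnovaTable",
    "FAResult",
    "ComparisonResult",
    "batch_anova",
    "anova_two_way_mixed",
    "fa10a",
    "fa10a_from_ms",
    "directional_asymmetry",
    "compare_fa",
    "two_sided_f_p",
]


@dataclass(frozen=True)
class AnovaTable:
    """Mean squares and degrees of freedom of the balanced two-way mixed model.

    ``side_diff`` carries the mean signed R - L difference so directional
    asymmetry can be reported in original units from the table alone.
    """

    ms_side: float
    ms_individual: float
    ms_interaction: float
    ms_residual: float
    n: int
    r: int
    side_diff: float = float("nan")
    s: int = 2

    @property
    def df_side(self) -> int:
        return self.s - 1

    @property
    def df_individual(self) -> int:
        return self.n - 1

    @property
    def df_interaction(self) -> int:
        return (self.n - 1) * (self.s - 1)

    @property
    def df_residual(self) -> int:
        return self.n * self.s * (self.r - 1)

    def total_ss(self) -> float:
        return (self.df_side * self.ms_side
                + self.df_individual * self.ms_individual
                + self.df_interaction * self.ms_interaction
                + self.df_residual * self.ms_residual)


@dataclass(frozen=True)
class FAResult:
    """FA10a estimate with its provenance.

    ``fa10a`` is in squared length units.  A raw estimate below zero (sampling
    noise when true FA is small relative to measurement error) is reported
    as-is with ``negative_flag`` set — never clamped, since clamping would
    bias simulation-based calibration and averages.
    """

    fa10a: float
    me_variance: float
    df_interaction: int
    n: int
    r: int
    negative_flag: bool


@dataclass
class ComparisonResult:
    """Two-genotype FA comparison (genotype a versus reference b)."""

    f_statistic: float
    df_num: int
    df_den: int
    p_raw: float
    fold_change: float          # FA10a(a) / FA10a(b); NaN when undefined
    ms_ratio: float             # MS_int(a) / MS_int(b)
    p_adjusted: float | None = None
    fold_undefined: bool = False

    @property
    def direction(self) -> str | None:
        if self.fold_undefined or not np.isfinite(self.fold_change):
            return None
        return "increase" if self.fold_change > 1 else "decrease"


# ---------------------------------------------------------------------------

def batch_anova(y: np.ndarray) -> dict[str, np.ndarray]:
    """Balanced two-way mean squares, vectorized over leading axes.

    ``y`` has shape ``(..., n, s, r)``.  Returns arrays of shape ``(...)``
    for each mean square plus the mean signed difference between the last
    and first level of the side axis (R - L with the (L, R) convention).
    """
    y = np.asarray(y, dtype=float)
    if y.ndim < 3:
        raise ValueError("y must have shape (..., n, s, r)")
    n, s, r = y.shape[-3:]
    if n < 2:
        raise ValueError("need at least 2 individuals (df_interaction >= 1)")
    if r < 2:
        raise ValueError("measurement error not separable: need r >= 2 replicates")

    grand = y.mean(axis=(-3, -2, -1), keepdims=True)
    ind_mean = y.mean(axis=(-2, -1), keepdims=True)     # (..., n, 1, 1)
    side_mean = y.mean(axis=(-3, -1), keepdims=True)    # (..., 1, s, 1)
    cell_mean = y.mean(axis=-1, keepdims=True)          # (..., n, s, 1)

    ss_ind = (s * r) * ((ind_mean - grand) ** 2).sum(axis=(-3, -2, -1))
    ss_side = (n * r) * ((side_mean - grand) ** 2).sum(axis=(-3, -2, -1))
    ss_int = r * ((cell_mean - ind_mean - side_mean + grand) ** 2).sum(axis=(-3, -2, -1))
    ss_res = ((y - cell_mean) ** 2).sum(axis=(-3, -2, -1))

    df_res = n * s * (r - 1)
    return {
        "ms_side": ss_side / (s - 1),
        "ms_individual": ss_ind / (n - 1),
        "ms_interaction": ss_int / ((n - 1) * (s - 1)),
        "ms_residual": ss_res / df_res,
        "side_diff": (y[..., :, -1, :].mean(axis=(-2, -1))
                      - y[..., :, 0, :].mean(axis=(-2, -1))),
        "n": n, "s": s, "r": r,
    }


def anova_two_way_mixed(sample: GenotypeSample) -> AnovaTable:
    """ANOVA of one balanced block: individual random, side fixed, replicates residual."""
    ms = batch_anova(sample.values)
    return AnovaTable(
        ms_side=float(ms["ms_side"]),
        ms_individual=float(ms["ms_individual"]),
        ms_interaction=float(ms["ms_interaction"]),
        ms_residual=float(ms["ms_residual"]),
        n=sample.n, r=sample.r,
        side_diff=float(ms["side_diff"]),
    )


def fa10a_from_ms(ms_interaction, ms_residual, r):
    """FA10a = (MS_int - MS_res) / r, vectorized."""
    return (np.asarray(ms_interaction) - np.asarray(ms_residual)) / r


def fa10a(tbl: AnovaTable) -> FAResult:
    """Measurement-error-corrected FA index from the ANOVA table."""
    if tbl.r < 2:
        raise ValueError("FA10a requires r >= 2 replicates")
    est = (tbl.ms_interaction - tbl.ms_residual) / tbl.r
    return FAResult(
        fa10a=float(est),
        me_variance=float(tbl.ms_residual),
        df_interaction=tbl.df_interaction,
        n=tbl.n, r=tbl.r,
        negative_flag=bool(tbl.ms_interaction < tbl.ms_residual),
    )


def directional_asymmetry(tbl: AnovaTable) -> tuple[float, float, float]:
    """Test of the fixed side effect: F = MS_side / MS_int on (1, df_int) df.

    Returns (mean signed R - L difference in original units, F, p).  The
    interaction mean square is the correct denominator because the side
    effect is tested against individual-by-side variation in a mixed model.
    """
    if tbl.df_interaction < 1:
        raise ValueError("df_interaction = 0: cannot test the side effect")
    if tbl.ms_interaction == 0:
        f = np.inf if tbl.ms_side > 0 else np.nan
        p = 0.0 if tbl.ms_side > 0 else np.nan
    else:
        f = tbl.ms_side / tbl.ms_interaction
        p = float(stats.f.sf(f, tbl.df_side, tbl.df_interaction))
    return tbl.side_diff, float(f), p


def two_sided_f_p(f, dfn, dfd):
    """Two-sided p for an F ratio: double the smaller tail, capped at 1."""
    f = np.asarray(f, dtype=float)
    p = 2.0 * np.minimum(stats.f.sf(f, dfn, dfd), stats.f.cdf(f, dfn, dfd))
    return np.minimum(p, 1.0)


def compare_fa(a: AnovaTable, b: AnovaTable,
               mode: Literal["ms_ratio", "fa10a_ratio"] = "ms_ratio") -> ComparisonResult:
    """Compare the FA of genotype ``a`` against reference genotype ``b``.

    Default mode tests F = MS_int(a)/MS_int(b) with (df_int(a), df_int(b))
    degrees of freedom, two-sided (the screen seeks both enhancers and
    suppressors).  The reported fold change is the FA10a ratio, undefined
    (NaN, flagged) when the reference FA10a is non-positive; the comparison
    itself is still reported on the mean-square ratio.
    """
    fa_a, fa_b = fa10a(a), fa10a(b)
    ms_ratio = a.ms_interaction / b.ms_interaction if b.ms_interaction > 0 else np.inf

    if mode == "ms_ratio":
        f = ms_ratio
    elif mode == "fa10a_ratio":
        f = fa_a.fa10a / fa_b.fa10a if fa_b.fa10a > 0 else np.inf
    else:
        raise ValueError(f"unknown comparison mode {mode!r}")

    dfn, dfd = a.df_interaction, b.df_interaction
    if np.isfinite(f) and f > 0:
        p = float(two_sided_f_p(f, dfn, dfd))
    elif f == 0 or not np.isfinite(f):
        p = 0.0 if (f == 0 or f == np.inf) else float("nan")
    else:  # negative FA10a ratio in fa10a_ratio mode: no meaningful test
        p = float("nan")

    undefined = fa_b.fa10a <= 0
    fold = fa_a.fa10a / fa_b.fa10a if not undefined else float("nan")
    if fold is not None and np.isfinite(fold) and fold <= 0:
        # numerator non-positive: ratio not a usable fold change either
        undefined, fold = True, float("nan")
    return ComparisonResult(
        f_statistic=float(f), df_num=dfn, df_den=dfd, p_raw=p,
        fold_change=fold, ms_ratio=float(ms_ratio), fold_undefined=undefined,
    )
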