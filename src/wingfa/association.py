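"""Cross-genotype association analyses downstream of the screen.

Three descriptive relations are examined across genotype groups: FA fold
change versus deficiency span (does deleting more genes perturb symmetry
more?), FA10a versus mean wing size (a positive relation would indicate
allometric confounding), and log10 FA10a versus log10 inter-individual
variance (developmental stability versus canalization).  Inter-individual
variance — the variance of per-individual mean wing length within a group —
proxies canalization: robustness to the small genetic and environmental
differences among individuals of the same genotype.

Pearson correlations are reported with a two-sided t-based p-value that is
descriptive only (group estimates are not independent draws from a simple
bivariate normal).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import GenotypeSample

__all__ = ["GroupSummary", "CorrelationResult", "interindividual_variance", "correlate"]


@dataclass(frozen=True)
class GroupSummary:
    """Per-genotype quantities entering the association analyses."""

    genotype: str
    fa10a: float
    mean_size: float
    interindividual_variance: float
    span_length: float = float("nan")
    category: str = "neutral"    # decreasing / enhancing / neutral / control


@dataclass
class CorrelationResult:
    pearson_r: float
    p_value: float               # descriptive two-sided t-based p
    n: int
    transform: str = "identity"
    excluded: int = 0            # rows dropped (non-positive under log10)
    flags: list[str] = field(default_factory=list)


def interindividual_variance(sample: GenotypeSample) -> float:
    """Variance (denominator n-1) of per-individual mean wing length."""
    if sample.n < 2:
        raise ValueError("inter-individual variance undefined for n < 2")
    means = sample.values.mean(axis=(1, 2))
    return float(np.var(means, ddof=1))


def correlate(pairs: Sequence[tuple[float, float]] | np.ndarray,
              transform: Literal["identity", "log10"] = "identity") -> CorrelationResult:
    """Pearson correlation of (x, y) pairs, optionally on log10-log10 scale.

    Under ``log10`` both variables must be positive; violating rows are
    excluded and counted.  Zero variance in either variable makes the
    coefficient undefined (NaN, flagged).
    """
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be a sequence of (x, y)")
    excluded = 0
    if transform == "log10":
        ok = np.all(arr > 0, axis=1)
        excluded = int((~ok).sum())
        arr = np.log10(arr[ok])
    elif transform != "identity":
        raise ValueError(f"unknown transform {transform!r}")
    n = arr.shape[0]
    if n < 3:
        return CorrelationResult(float("nan"), float("nan"), n, transform, excluded,
                                 flags=["fewer_than_3_points"])
    x, y = arr[:, 0], arr[:, 1]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(float("nan"), float("nan"), n, transform, excluded,
                                 flags=["zero_variance_undefined"])
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(float(r), float(p), n, transform, excluded)


def summaries_to_frame(groups: Sequence[GroupSummary]) -> pd.DataFrame:
    return pd.DataFrame([vars(g) for g in groups])
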