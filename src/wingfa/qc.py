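"""Sample quality control on signed left-right asymmetry.

The FA indices assume the per-individual signed asymmetry d_i (mean over
replicates of R minus mean over replicates of L) is normally distributed:
departures signal antisymmetry (bimodality), gross measurement blunders, or
other interference.  Each sample is screened with Shapiro-Wilk and
Lilliefors normality tests and with moment thresholds on bias-adjusted
skewness g1 and excess kurtosis g2 (pass requires -0.5 <= g1 <= 0.5 and
-3 <= g2 <= 3; the kurtosis bound is read as excess kurtosis, normal = 0,
since a raw kurtosis below -3 is impossible).

A failing sample undergoes deterministic outlier elimination: repeatedly
remove the individual with the largest modified robust z-score
0.6745 |d_i - median| / MAD and re-test, up to a hard cap — but only while
that score marks an obvious measurement blunder (above ``min_robust_z``);
a sample failing the thresholds without such an outlier, or still failing
at the cap, is flagged, never silently passed.  QC alters sample membership
only, never measurement values.

"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors as _lilliefors

from .fa import FAResult
from .io import GenotypeSample

__all__ = [
    "QCThresholds",
    "QCReport",
    "signed_asymmetry",
    "normality_and_moments",
    "filter_outliers",
    "size_dependence_check",
]


@dataclass(frozen=True)
class QCThresholds:
    """Thresholds of the QC battery; defaults follow the screening protocol."""

    alpha_norm: float = 0.05     # for both normality tests
    g1_bound: float = 0.5        # |skewness| limit
    g2_low: float = -3.0         # excess-kurtosis limits
    g2_high: float = 3.0
    removal_cap: int = 3         # max individuals eliminated per sample
    min_n: int = 10              # below this the sample is unusable
    # modified z-score an "obvious error" must exceed before elimination;
    # 6 is essentially impossible under normality at these sample sizes
    # (expected max |z| at n=30 is ~2.1), so only gross blunders qualify
    min_robust_z: float = 6.0
    lilliefors_pvalmethod: str = "table"


@dataclass
class QCReport:
    """Result of QC on one genotype sample."""

    genotype_label: str
    series_id: str
    n_initial: int
    n_final: int
    signed_asymmetries: np.ndarray
    shapiro_p: float = float("nan")
    lilliefors_p: float = float("nan")
    skewness: float = float("nan")      # bias-adjusted g1
    excess_kurtosis: float = float("nan")
    removed_ids: list[str] = field(default_factory=list)
    passed: bool = False
    flags: list[str] = field(default_factory=list)
    lilliefors_mode: str = "table"


def signed_asymmetry(sample: GenotypeSample) -> tuple[list[str], np.ndarray]:
    """Per-individual d_i = mean_R - mean_L over replicates, in input order."""
    d = sample.values[:, 1, :].mean(axis=1) - sample.values[:, 0, :].mean(axis=1)
    return list(sample.individual_ids), d


def _moments(d: np.ndarray) -> tuple[float, float]:
    # bias-adjusted sample skewness g1 and excess kurtosis g2
    g1 = float(stats.skew(d, bias=False))
    g2 = float(stats.kurtosis(d, fisher=True, bias=False))
    return g1, g2


def normality_and_moments(d: np.ndarray,
                          thresholds: QCThresholds = QCThresholds()) -> dict:
    """Shapiro-Wilk p, Lilliefors p, g1, g2 and the joint pass verdict.

    With fewer than 4 values, or a (near-)constant vector, the tests are
    undefined: they are skipped and the fragment is flagged rather than
    failed.
    """
    d = np.asarray(d, dtype=float)
    out = {"shapiro_p": float("nan"), "lilliefors_p": float("nan"),
           "skewness": float("nan"), "excess_kurtosis": float("nan"),
           "passed": False, "flags": [],
           "lilliefors_mode": thresholds.lilliefors_pvalmethod}
    if d.size < 4:
        out["flags"].append("too_few_individuals_for_normality_tests")
        return out
    if np.ptp(d) == 0 or np.std(d, ddof=1) == 0:
        out["flags"].append("degenerate_constant_asymmetry")
        return out
    out["shapiro_p"] = float(stats.shapiro(d).pvalue)
    _, lp = _lilliefors(d, dist="norm", pvalmethod=thresholds.lilliefors_pvalmethod)
    out["lilliefors_p"] = float(lp)
    g1, g2 = _moments(d)
    out["skewness"], out["excess_kurtosis"] = g1, g2
    out["passed"] = bool(
        out["shapiro_p"] > thresholds.alpha_norm
        and out["lilliefors_p"] > thresholds.alpha_norm
        and -thresholds.g1_bound <= g1 <= thresholds.g1_bound
        and thresholds.g2_low <= g2 <= thresholds.g2_high
    )
    return out


def _modified_z(d: np.ndarray) -> np.ndarray:
    """Modified z-scores |d - median| / (1.4826 * MAD), normal-consistent.

    With a zero MAD (a majority of identical values) any deviation from
    the median is treated as infinitely extreme; ties resolve to the first
    occurrence downstream, keeping removal order deterministic.
    """
    med = np.median(d)
    dev = np.abs(d - med)
    mad = np.median(dev)
    if mad > 0:
        return dev / (1.4826 * mad)
    out = np.zeros_like(dev)
    out[dev > 0] = np.inf
    return out


def filter_outliers(sample: GenotypeSample,
                    thresholds: QCThresholds = QCThresholds()) -> tuple[GenotypeSample, QCReport]:
    """Iterative QC: test, remove the most extreme obvious error, re-test.

    Removal is gated: a failing sample only loses its most extreme
    individual when that individual's modified robust z-score exceeds
    ``min_robust_z`` — the signature of a gross measurement blunder rather
    than ordinary sampling noise in the test statistics.  A sample that
    fails the thresholds without any such obvious outlier is flagged
    (``failing_without_obvious_outlier``) and retained intact.  Removal
    also stops at the cap (flag ``cap_reached_still_failing``) or when the
    sample would drop below the usable minimum (flag
    ``unusable_below_min_n``).
    """
    current = sample
    removed: list[str] = []
    while True:
        ids, d = signed_asymmetry(current)
        frag = normality_and_moments(d, thresholds)
        if frag["passed"] or frag["flags"]:
            break
        z = _modified_z(d)
        worst_idx = int(np.argmax(z))
        if z[worst_idx] < thresholds.min_robust_z:
            frag["flags"].append("failing_without_obvious_outlier")
            break
        if len(removed) >= thresholds.removal_cap:
            frag["flags"].append("cap_reached_still_failing")
            break
        if current.n - 1 < thresholds.min_n:
            frag["flags"].append("unusable_below_min_n")
            break
        worst = ids[worst_idx]
        removed.append(worst)
        current = current.subset([i for i in ids if i != worst])

    ids, d = signed_asymmetry(current)
    report = QCReport(
        genotype_label=sample.genotype_label,
        series_id=sample.series_id,
        n_initial=sample.n,
        n_final=current.n,
        signed_asymmetries=d,
        shapiro_p=frag["shapiro_p"],
        lilliefors_p=frag["lilliefors_p"],
        skewness=frag["skewness"],
        excess_kurtosis=frag["excess_kurtosis"],
        removed_ids=removed,
        passed=frag["passed"],
        flags=frag["flags"],
        lilliefors_mode=frag["lilliefors_mode"],
    )
    if current.n < thresholds.min_n and "unusable_below_min_n" not in report.flags:
        report.flags.append("unusable_below_min_n")
    return current, report


@dataclass
class SizeDependence:
    pearson_r: float
    p_value: float
    slope_sign: int          # sign of the FA-vs-size association
    allometry_concern: bool  # True when larger groups are more asymmetric
    n_groups: int
    flags: list[str] = field(default_factory=list)


def size_dependence_check(results: list[tuple[FAResult, float]]) -> SizeDependence:
    """Correlate FA10a against group mean size across genotypes.

    A positive association (larger genotypes more asymmetric) would signal
    positive allometry confounding the FA comparisons; a negative or null
    association indicates FA differences are not size artifacts.
    """
    if len(results) < 3:
        return SizeDependence(float("nan"), float("nan"), 0, False, len(results),
                              flags=["fewer_than_3_groups_skipped"])
    fa_vals = np.array([fr.fa10a for fr, _ in results], dtype=float)
    sizes = np.array([sz for _, sz in results], dtype=float)
    if np.ptp(fa_vals) == 0 or np.ptp(sizes) == 0:
        return SizeDependence(float("nan"), float("nan"), 0, False, len(results),
                              flags=["zero_variance_correlation_undefined"])
    r, p = stats.pearsonr(fa_vals, sizes)
    return SizeDependence(float(r), float(p), int(np.sign(r)), bool(r > 0),
                          len(results))
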