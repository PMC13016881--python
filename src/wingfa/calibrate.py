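"""Monte-Carlo calibration of the estimator, test and screen.

Each routine here answers one design question by simulation under the
generative model with known truth:

* is FA10a unbiased for sigma_fa^2 (and MS_res for sigma_me^2)?
* does the two-genotype F comparison hold its nominal size, with uniform
  p-values, under the null?
* does Holm keep the family-wise error of a 25-test series at alpha?
* what does the full two-stage screen recover when modifiers are planted?
* does QC identify a planted gross mis-measurement, and nothing else?

Simulations run on the vectorized batch path (arrays of shape
``(batch, n, 2, r)``); a regression test pins the batch ANOVA to the
per-sample path so the two routes cannot diverge.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .fa import batch_anova, fa10a_from_ms, two_sided_f_p
from .io import GenotypeSample
from .qc import QCThresholds, filter_outliers
from .screen import aggregate_two_stage, run_series
from .simulate import (ScreenScenario, SimulationConfig, simulate_screen_samples,
                       simulate_values, substream)

__all__ = [
    "fa10a_recovery",
    "comparison_null_calibration",
    "holm_fwer",
    "holm_adjust_batch",
    "planted_screen_scorecard",
    "qc_planted_error_recovery",
    "PLANTED_FOLDS",
]


def fa10a_recovery(cfg: SimulationConfig, n_sims: int = 2000,
                   seed: int | None = None) -> dict:
    """Mean FA10a and measurement-error variance over simulated samples.

    Returns the Monte-Carlo means with their standard errors and the true
    values (sigma_fa^2, sigma_me^2) they estimate.
    """
    rng = substream(cfg.seed if seed is None else seed, "fa10a-recovery")
    y = simulate_values(cfg, rng, size=(n_sims,))
    ms = batch_anova(y)
    fa = fa10a_from_ms(ms["ms_interaction"], ms["ms_residual"], cfg.r)
    me = ms["ms_residual"]
    return {
        "mean_fa10a": float(fa.mean()),
        "se_fa10a": float(fa.std(ddof=1) / np.sqrt(n_sims)),
        "true_fa": cfg.sigma_fa ** 2,
        "mean_me_variance": float(me.mean()),
        "se_me_variance": float(me.std(ddof=1) / np.sqrt(n_sims)),
        "true_me": cfg.sigma_me ** 2,
        "n_sims": n_sims,
    }


def comparison_null_calibration(cfg: SimulationConfig, n_pairs: int = 10_000,
                                alpha: float = 0.05,
                                seed: int | None = None) -> dict:
    """Size and p-value uniformity of the default comparison under H0.

    Two independent genotype samples per pair share every variance
    component; the two-sided MS-ratio F test should reject at alpha with
    uniformly distributed p-values.
    """
    rng = substream(cfg.seed if seed is None else seed, "null-calibration")
    ya = simulate_values(cfg, rng, size=(n_pairs,))
    yb = simulate_values(cfg, rng, size=(n_pairs,))
    ms_a, ms_b = batch_anova(ya), batch_anova(yb)
    dfn = (cfg.n - 1)
    f = ms_a["ms_interaction"] / ms_b["ms_interaction"]
    p = two_sided_f_p(f, dfn, dfn)
    ks = stats.kstest(p, "uniform")
    return {
        "rejection_rate": float((p < alpha).mean()),
        "ks_statistic": float(ks.statistic),
        "ks_p": float(ks.pvalue),
        "alpha": alpha,
        "n_pairs": n_pairs,
    }


def holm_fwer(cfg: SimulationConfig, n_series: int = 10_000, m: int = 25,
              alpha: float = 0.05, seed: int | None = None) -> dict:
    """Family-wise error of Holm over simulated null series.

    Each series holds ``m`` experimental genotypes plus one shared control,
    all at identical parameters, so every rejection is a false positive.
    The shared control makes the m tests positively dependent, as in the
    real screen; Holm controls FWER under arbitrary dependence.
    """
    rng = substream(cfg.seed if seed is None else seed, "holm-fwer")
    dfn = cfg.n - 1
    hits = 0
    done = 0
    while done < n_series:     # chunked to bound memory
        chunk = min(2000, n_series - done)
        y = simulate_values(cfg, rng, size=(chunk, m + 1))
        ms_int = batch_anova(y)["ms_interaction"]
        f = ms_int[:, 1:] / ms_int[:, :1]      # each vs its series control
        p = two_sided_f_p(f, dfn, dfn)
        hits += int((holm_adjust_batch(p) < alpha).any(axis=1).sum())
        done += chunk
    fwer = hits / n_series
    return {"fwer": fwer, "alpha": alpha, "n_series": n_series, "m": m,
            "se": float(np.sqrt(fwer * (1 - fwer) / n_series))}


def holm_adjust_batch(p: np.ndarray) -> np.ndarray:
    """Row-wise Holm adjustment, vectorized for Monte-Carlo use.

    Exactly the step-down rule of :func:`wingfa.screen.holm_adjust`
    ((m - k + 1) multipliers on the sorted p, running maximum, clipped at
    1), applied to every row of a (series x tests) matrix at once.
    """
    p = np.asarray(p, dtype=float)
    m = p.shape[-1]
    order = np.argsort(p, axis=-1)
    p_sorted = np.take_along_axis(p, order, axis=-1)
    adj = np.minimum(np.maximum.accumulate(p_sorted * (m - np.arange(m)), axis=-1), 1.0)
    out = np.empty_like(adj)
    np.put_along_axis(out, order, adj, axis=-1)
    return out


#: planted truth used by the screen scorecard: three strong enhancers and
#: three strong suppressors spread over both series of a 2 x 25 design
PLANTED_FOLDS = {
    "Df002": 5.0, "Df018": 5.0, "Df030": 5.0,
    "Df007": 0.2, "Df026": 0.2, "Df044": 0.2,
}


def _run_stage(scn: ScreenScenario, stage: str, alpha: float, min_n: int):
    samples, layouts, truth = simulate_screen_samples(scn, stage=stage)
    rows = []
    for layout in layouts:
        rows.extend(run_series(layout, samples[layout.series_id],
                               stage=stage, alpha=alpha, min_n=min_n))
    return rows, truth


def planted_screen_scorecard(baseline: SimulationConfig | None = None,
                             folds: dict[str, float] | None = None,
                             n_seeds: int = 100, seed: int = 0,
                             alpha: float = 0.05, min_n: int = 10) -> dict:
    """Sensitivity/specificity of the full two-stage screen with planted truth.

    Per seed: simulate independent primary and secondary stages (2 series x
    25 deficiencies), run the complete series pipeline (ANOVA, F tests,
    within-series Holm, classification) and aggregate the two stages.
    Returns the mean number of planted modifiers confirmed with the correct
    direction, and the rate of seeds in which any truly neutral deficiency
    was (falsely) confirmed.
    """
    baseline = baseline or SimulationConfig()
    folds = PLANTED_FOLDS if folds is None else folds
    n_planted = len(folds)
    correct = np.zeros(n_seeds)
    any_false = np.zeros(n_seeds, dtype=bool)
    false_count = 0
    for k in range(n_seeds):
        scn = ScreenScenario(n_series=2, deficiencies_per_series=25,
                             baseline=baseline, fold_changes=dict(folds),
                             seed=seed + k)
        prim, _ = _run_stage(scn, "primary", alpha, min_n)
        seco, truth = _run_stage(scn, "secondary", alpha, min_n)
        confirmed, _ = aggregate_two_stage(prim, seco, alpha=alpha)
        confirmed = confirmed[confirmed["status"] == "confirmed"]
        for _, row in confirmed.iterrows():
            true_fold = folds.get(row["deficiency"], 1.0)
            want = ("enhancing" if true_fold > 1
                    else "decreasing" if true_fold < 1 else "neutral")
            if want == row["classification"] and want != "neutral":
                correct[k] += 1
            elif true_fold == 1.0:
                any_false[k] = True
                false_count += 1
    return {
        "mean_correct_confirmations": float(correct.mean()),
        "n_planted": n_planted,
        "seed_rate_any_false_confirmation": float(any_false.mean()),
        "total_false_confirmations": int(false_count),
        "n_seeds": n_seeds,
    }


def qc_planted_error_recovery(cfg: SimulationConfig | None = None,
                              n_seeds: int = 100, seed: int = 0,
                              factor: float = 10.0,
                              thresholds: QCThresholds = QCThresholds()) -> dict:
    """Recovery of a planted gross mis-measurement by the QC battery.

    Per seed: simulate a clean sample, inflate one randomly chosen single
    measurement ``factor``-fold (a transcription-type blunder), run the
    iterative outlier filter, and score whether exactly the affected
    individual — and nobody else — was removed.
    """
    cfg = cfg or SimulationConfig()
    exact = 0
    for k in range(n_seeds):
        rng = substream(seed + k, "qc-recovery")
        values = simulate_values(cfg, rng)
        i = int(rng.integers(cfg.n))
        s = int(rng.integers(2))
        rep = int(rng.integers(cfg.r))
        values = values.copy()
        values[i, s, rep] *= factor
        ids = [f"ind-{j + 1:03d}" for j in range(cfg.n)]
        sample = GenotypeSample("planted", "S0", ids, values)
        _, report = filter_outliers(sample, thresholds)
        if report.removed_ids == [ids[i]]:
            exact += 1
    return {"exact_recovery_rate": exact / n_seeds, "n_seeds": n_seeds,
            "factor": factor}
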