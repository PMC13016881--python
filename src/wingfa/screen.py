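"""Series-controlled two-stage modifier screen.

Each experimental series is a batch of crosses processed together (same
food batch, incubator, handling window) containing up to 25 deficiency
genotypes plus internal controls: a positive control (driver + transgene,
no deficiency) whose FA is the reference every experimental genotype is
compared against, and — in the secondary stage — a negative control (driver
alone) against which the deficiency-alone genotypes are compared to detect
FA effects independent of the sensitized background.

Within a series, the experimental-vs-positive-control F tests form one
multiple-testing family and receive a step-down Holm adjustment; the
deficiency-alone-vs-negative-control tests form their own family.  A
deficiency is classified *decreasing* (suppressor) when its Holm-adjusted p
is below alpha and its FA10a fold change relative to the positive control
is below 1, *enhancing* when above 1; otherwise neutral.  A deficiency is a
*confirmed modifier* only when significant with the same direction in both
the primary and the secondary stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .fa import AnovaTable, ComparisonResult, anova_two_way_mixed, compare_fa, fa10a
from .io import GenotypeSample

__all__ = [
    "SeriesLayout",
    "ScreenRow",
    "ScreenError",
    "holm_adjust",
    "classify",
    "run_series",
    "aggregate_two_stage",
    "rows_to_frame",
]

Classification = Literal["decreasing", "enhancing", "neutral", "lethal", "unmeasurable"]


class ScreenError(RuntimeError):
    """Series-level failure (e.g. missing positive control)."""


@dataclass
class SeriesLayout:
    """Genotype roles within one experimental series.

    ``experimental`` maps deficiency name -> genotype label of the
    deficiency combined with the sensitized (driver + transgene) background;
    ``df_alone`` maps deficiency name -> genotype label of the deficiency
    over the driver alone (secondary stage only).
    """

    series_id: str
    experimental: dict[str, str]
    positive_control_label: str
    negative_control_label: str | None = None
    df_alone: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if len(self.experimental) > 25:
            raise ScreenError(
                f"series {self.series_id!r}: {len(self.experimental)} experimental "
                "genotypes exceeds the 25-deficiency series design")


@dataclass
class ScreenRow:
    """One deficiency's outcome in one stage of the screen."""

    deficiency: str
    series_id: str
    stage: Literal["primary", "secondary"]
    classification: Classification = "neutral"
    vs_positive_control: ComparisonResult | None = None
    df_alone_vs_negative_control: ComparisonResult | None = None
    fa10a_experimental: float = float("nan")
    fa10a_control: float = float("nan")
    n_experimental: int = 0
    flags: list[str] = field(default_factory=list)


def holm_adjust(p) -> np.ndarray:
    """Step-down Holm adjustment with monotonicity enforcement."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


def classify(comparison: ComparisonResult, alpha: float = 0.05) -> Classification:
    """Classify one adjusted comparison: decreasing / enhancing / neutral.

    Uses the Holm-adjusted p (falls back to raw p only if no adjustment was
    applied) and the FA10a fold change; an undefined fold change yields
    neutral (callers flag it).
    """
    p = comparison.p_adjusted if comparison.p_adjusted is not None else comparison.p_raw
    if comparison.fold_undefined or not np.isfinite(comparison.fold_change):
        return "neutral"
    if np.isfinite(p) and p < alpha:
        return "enhancing" if comparison.fold_change > 1 else "decreasing"
    return "neutral"


def run_series(layout: SeriesLayout,
               samples: Mapping[str, GenotypeSample],
               stage: Literal["primary", "secondary"] = "primary",
               alpha: float = 0.05,
               min_n: int = 10,
               mode: str = "ms_ratio",
               unmeasurable: tuple[str, ...] = ()) -> list[ScreenRow]:
    """Screen one series against its internal controls.

    ``samples`` maps genotype label -> QC-processed sample.  Genotypes
    absent from ``samples`` or below ``min_n`` individuals are recorded as
    lethal (no cross progeny / too few usable wings) without a test.  Holm
    adjustment is applied within the series, separately to the
    vs-positive-control family and (secondary stage) the df-alone family.
    """
    pos = samples.get(layout.positive_control_label)
    if pos is None:
        raise ScreenError(
            f"series {layout.series_id!r}: positive control "
            f"{layout.positive_control_label!r} missing — series aborted")
    pos_tbl = anova_two_way_mixed(pos)
    pos_fa = fa10a(pos_tbl).fa10a

    neg_tbl: AnovaTable | None = None
    if stage == "secondary" and layout.df_alone:
        neg = samples.get(layout.negative_control_label) if layout.negative_control_label else None
        if neg is None:
            raise ScreenError(
                f"series {layout.series_id!r}: secondary stage requires the "
                "negative control — series aborted")
        neg_tbl = anova_two_way_mixed(neg)

    rows: list[ScreenRow] = []
    testable: list[ScreenRow] = []
    for dfname, label in layout.experimental.items():
        row = ScreenRow(deficiency=dfname, series_id=layout.series_id, stage=stage,
                        fa10a_control=pos_fa)
        sample = samples.get(label)
        if dfname in unmeasurable:
            row.classification = "unmeasurable"
            row.flags.append("wings_unmeasurable")
        elif sample is None or sample.n == 0:
            row.classification = "lethal"
            row.flags.append("no_sample")
        elif sample.n < min_n:
            row.classification = "lethal"
            row.flags.append(f"n={sample.n}_below_min_{min_n}")
            row.n_experimental = sample.n
        else:
            tbl = anova_two_way_mixed(sample)
            row.vs_positive_control = compare_fa(tbl, pos_tbl, mode=mode)
            row.fa10a_experimental = fa10a(tbl).fa10a
            row.n_experimental = sample.n
            if row.vs_positive_control.fold_undefined:
                row.flags.append("fold_change_undefined")
            testable.append(row)
        rows.append(row)

    if testable:
        adj = holm_adjust([r.vs_positive_control.p_raw for r in testable])
        for row, p_adj in zip(testable, adj):
            row.vs_positive_control.p_adjusted = float(p_adj)
            row.classification = classify(row.vs_positive_control, alpha)

    if neg_tbl is not None:
        df_alone_rows = []
        by_name = {r.deficiency: r for r in rows}
        for dfname, label in layout.df_alone.items():
            row = by_name.get(dfname)
            if row is None:
                continue
            sample = samples.get(label)
            if sample is None or sample.n < min_n:
                row.flags.append("df_alone_unavailable")
                continue
            row.df_alone_vs_negative_control = compare_fa(
                anova_two_way_mixed(sample), neg_tbl, mode=mode)
            df_alone_rows.append(row)
        if df_alone_rows:
            adj = holm_adjust([r.df_alone_vs_negative_control.p_raw for r in df_alone_rows])
            for row, p_adj in zip(df_alone_rows, adj):
                row.df_alone_vs_negative_control.p_adjusted = float(p_adj)
    return rows


def aggregate_two_stage(primary_rows: list[ScreenRow],
                        secondary_rows: list[ScreenRow],
                        alpha: float = 0.05) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cross the two stages: confirmed modifiers and df-alone effects.

    A deficiency is confirmed iff it is classified decreasing in both stages
    or enhancing in both stages.  Separately lists deficiencies whose
    deficiency-alone comparison against the negative control is significant
    (an FA effect independent of the sensitized background).
    """
    prim = {r.deficiency: r for r in primary_rows}
    confirmed = []
    df_alone_effects = []
    for row in secondary_rows:
        p = prim.get(row.deficiency)
        if p is None:
            confirmed.append({"deficiency": row.deficiency, "status": "secondary_only",
                              "classification": "unconfirmable",
                              "fold_change": np.nan, "p_adjusted": np.nan})
        elif (row.classification in ("decreasing", "enhancing")
                and row.classification == p.classification):
            cmpres = row.vs_positive_control
            confirmed.append({"deficiency": row.deficiency, "status": "confirmed",
                              "classification": row.classification,
                              "fold_change": cmpres.fold_change,
                              "p_adjusted": cmpres.p_adjusted})
        if row.df_alone_vs_negative_control is not None:
            c = row.df_alone_vs_negative_control
            p_adj = c.p_adjusted if c.p_adjusted is not None else c.p_raw
            if np.isfinite(p_adj) and p_adj < alpha and not c.fold_undefined:
                df_alone_effects.append({
                    "deficiency": row.deficiency,
                    "direction": c.direction,
                    "fold_change": c.fold_change,
                    "p_adjusted": p_adj,
                })
    cols = ["deficiency", "status", "classification", "fold_change", "p_adjusted"]
    acols = ["deficiency", "direction", "fold_change", "p_adjusted"]
    return (pd.DataFrame(confirmed, columns=cols),
            pd.DataFrame(df_alone_effects, columns=acols))


def rows_to_frame(rows: list[ScreenRow]) -> pd.DataFrame:
    """Flatten screen rows into the per-stage report table."""
    recs = []
    for r in rows:
        c = r.vs_positive_control
        d = r.df_alone_vs_negative_control
        recs.append({
            "deficiency": r.deficiency,
            "series": r.series_id,
            "stage": r.stage,
            "n": r.n_experimental,
            "fa10a": r.fa10a_experimental,
            "fa10a_positive_control": r.fa10a_control,
            "fold_change": c.fold_change if c else np.nan,
            "f_statistic": c.f_statistic if c else np.nan,
            "p_raw": c.p_raw if c else np.nan,
            "p_adjusted": (c.p_adjusted if c and c.p_adjusted is not None else np.nan),
            "classification": r.classification,
            "df_alone_fold_change": d.fold_change if d else np.nan,
            "df_alone_p_adjusted": (d.p_adjusted if d and d.p_adjusted is not None else np.nan),
            "flags": ";".join(r.flags),
        })
    return pd.DataFrame(recs)
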