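"""End-to-end pipeline: QC -> FA estimation -> screen -> associations.

Everything the command-line surface does funnels through
:func:`run_pipeline`, which is deterministic given its inputs and config:
two runs on equal inputs produce byte-identical numeric outputs.  Every
artifact is TSV/JSON; the run log records thresholds, seeds, versions and
all removed individuals so a screen outcome can be audited.
"""

from __future__ import annotations

import json
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .association import correlate, interindividual_variance
from .fa import anova_two_way_mixed, fa10a
from .io import DataError, GenotypeSample, assemble_samples, read_measurements
from .qc import QCThresholds, filter_outliers, size_dependence_check
from .screen import ScreenError, SeriesLayout, aggregate_two_stage, rows_to_frame, run_series

__all__ = ["PipelineConfig", "run_pipeline", "load_layouts", "PipelineError"]


class PipelineError(RuntimeError):
    """Fatal pipeline failure, raised with stage context."""


@dataclass
class PipelineConfig:
    """Pipeline-wide settings; every threshold lands in the run log."""

    column_map: dict[str, str] = field(default_factory=dict)
    qc: QCThresholds = field(default_factory=QCThresholds)
    test_mode: str = "ms_ratio"          # or "fa10a_ratio"
    alpha: float = 0.05                  # on Holm-adjusted p
    min_n: int = 10                      # below this a genotype counts as lethal
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise PipelineError(f"alpha must be in (0, 1), got {self.alpha}")
        if not 0 < self.qc.alpha_norm < 1:
            raise PipelineError(f"alpha_norm must be in (0, 1), got {self.qc.alpha_norm}")
        if self.qc.removal_cap < 0 or self.min_n < 2:
            raise PipelineError("removal_cap must be >= 0 and min_n >= 2")
        if self.test_mode not in ("ms_ratio", "fa10a_ratio"):
            raise PipelineError(f"unknown test mode {self.test_mode!r}")

    def provenance(self) -> dict:
        d = asdict(self)
        d["wingfa_version"] = __version__
        return d


def load_layouts(path) -> list[tuple[SeriesLayout, str]]:
    """Read the series-layout YAML; returns (layout, stage) pairs."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    out = []
    for entry in doc["series"]:
        layout = SeriesLayout(
            series_id=str(entry["series_id"]),
            experimental={str(k): str(v) for k, v in entry["experimental"].items()},
            positive_control_label=str(entry["positive_control"]),
            negative_control_label=(str(entry["negative_control"])
                                    if entry.get("negative_control") else None),
            df_alone={str(k): str(v) for k, v in (entry.get("df_alone") or {}).items()},
        )
        out.append((layout, str(entry.get("stage", "primary"))))
    return out


def layouts_to_yaml(pairs: list[tuple[SeriesLayout, str]], path) -> None:
    doc = {"series": [{
        "series_id": lay.series_id,
        "stage": stage,
        "positive_control": lay.positive_control_label,
        "negative_control": lay.negative_control_label,
        "experimental": lay.experimental,
        "df_alone": lay.df_alone,
    } for lay, stage in pairs]}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def _fa_row(sample: GenotypeSample) -> dict:
    tbl = anova_two_way_mixed(sample)
    res = fa10a(tbl)
    return {
        "genotype": sample.genotype_label, "series": sample.series_id,
        "n": sample.n, "r": sample.r,
        "ms_side": tbl.ms_side, "ms_individual": tbl.ms_individual,
        "ms_interaction": tbl.ms_interaction, "ms_residual": tbl.ms_residual,
        "fa10a": res.fa10a, "me_variance": res.me_variance,
        "negative_flag": res.negative_flag,
        "mean_size": sample.mean_size(),
        "interindividual_variance": interindividual_variance(sample),
    }


def run_pipeline(config: PipelineConfig, measurements_path, layout_path,
                 outdir) -> dict[str, Path]:
    """Execute qc -> fa -> screen -> association and write all artifacts.

    Returns a name -> path map of everything written.  Raises
    :class:`PipelineError` (with stage context) on any fatal problem.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    log: dict = {"config": config.provenance(), "python": sys.version.split()[0],
                 "stages": {}}

    # --- load & assemble -------------------------------------------------
    try:
        records = read_measurements(measurements_path, colmap=config.column_map or None)
        assembly = assemble_samples(records)
    except DataError as exc:
        raise PipelineError(f"[load] {exc}") from exc
    layout_pairs = load_layouts(layout_path)
    if assembly.samples and all(s.n < config.min_n for s in assembly.samples):
        raise PipelineError(
            f"[validate] min_n={config.min_n} exceeds every sample size — "
            "no genotype would be testable")
    log["stages"]["load"] = {
        "n_records": len(records), "n_samples": len(assembly.samples),
        "excluded_individuals": assembly.excluded.to_dict("records"),
        "unusable_samples": assembly.unusable,
    }

    # --- QC ---------------------------------------------------------------
    samples: dict[tuple[str, str], GenotypeSample] = {}
    qc_rows = []
    for sample in assembly.samples:
        filtered, report = filter_outliers(sample, config.qc)
        samples[(sample.series_id, sample.genotype_label)] = filtered
        qc_rows.append({
            "genotype": report.genotype_label, "series": report.series_id,
            "n_initial": report.n_initial, "n_final": report.n_final,
            "removed_ids": ";".join(report.removed_ids),
            "shapiro_p": report.shapiro_p, "lilliefors_p": report.lilliefors_p,
            "skewness": report.skewness, "excess_kurtosis": report.excess_kurtosis,
            "pass": report.passed, "flags": ";".join(report.flags),
            "lilliefors_mode": report.lilliefors_mode,
        })
    qc_df = pd.DataFrame(qc_rows)
    artifacts["qc_report"] = outdir / "qc_report.tsv"
    qc_df.to_csv(artifacts["qc_report"], sep="\t", index=False)
    log["stages"]["qc"] = {"n_removed": int(sum(len(r["removed_ids"].split(";")) if r["removed_ids"] else 0
                                                for r in qc_rows))}

    # --- FA ----------------------------------------------------------------
    fa_df = pd.DataFrame([_fa_row(s) for s in samples.values() if s.n >= 2])
    artifacts["fa_results"] = outdir / "fa_results.tsv"
    fa_df.to_csv(artifacts["fa_results"], sep="\t", index=False)

    # --- screen ------------------------------------------------------------
    stage_rows: dict[str, list] = {"primary": [], "secondary": []}
    for layout, stage in layout_pairs:
        series_samples = {gt: s for (ser, gt), s in samples.items()
                          if ser == layout.series_id}
        try:
            rows = run_series(layout, series_samples, stage=stage,
                              alpha=config.alpha, min_n=config.min_n,
                              mode=config.test_mode)
        except ScreenError as exc:
            raise PipelineError(f"[screen] {exc}") from exc
        stage_rows[stage].extend(rows)
    for stage, rows in stage_rows.items():
        if rows:
            artifacts[f"screen_{stage}"] = outdir / f"screen_{stage}.tsv"
            rows_to_frame(rows).to_csv(artifacts[f"screen_{stage}"], sep="\t", index=False)
    if stage_rows["primary"] and stage_rows["secondary"]:
        confirmed, df_alone = aggregate_two_stage(
            stage_rows["primary"], stage_rows["secondary"], alpha=config.alpha)
        artifacts["confirmed_modifiers"] = outdir / "confirmed_modifiers.tsv"
        confirmed.to_csv(artifacts["confirmed_modifiers"], sep="\t", index=False)
        artifacts["df_alone_effects"] = outdir / "df_alone_effects.tsv"
        df_alone.to_csv(artifacts["df_alone_effects"], sep="\t", index=False)
        log["stages"]["screen"] = {
            "n_confirmed": int((confirmed["status"] == "confirmed").sum()) if len(confirmed) else 0}

    # --- associations -------------------------------------------------------
    assoc_rows = []
    if len(fa_df) >= 3:
        size_dep = size_dependence_check(
            [(fa10a(anova_two_way_mixed(s)), s.mean_size())
             for s in samples.values() if s.n >= 2])
        assoc_rows.append({"analysis": "fa10a_vs_mean_size", "transform": "identity",
                           "pearson_r": size_dep.pearson_r, "p": size_dep.p_value,
                           "n": size_dep.n_groups,
                           "note": ("allometry_concern" if size_dep.allometry_concern
                                    else "no_allometry_concern")})
        pairs = [(row.fa10a, row.interindividual_variance)
                 for row in fa_df.itertuples() if row.fa10a > 0]
        cr = correlate(pairs, transform="log10")
        assoc_rows.append({"analysis": "log10_fa10a_vs_log10_interindividual_variance",
                           "transform": "log10", "pearson_r": cr.pearson_r,
                           "p": cr.p_value, "n": cr.n, "note": ";".join(cr.flags)})
    assoc_df = pd.DataFrame(assoc_rows,
                            columns=["analysis", "transform", "pearson_r", "p", "n", "note"])
    artifacts["associations"] = outdir / "associations.tsv"
    assoc_df.to_csv(artifacts["associations"], sep="\t", index=False)

    artifacts["run_log"] = outdir / "run_log.json"
    with open(artifacts["run_log"], "w") as fh:
        json.dump(log, fh, indent=2, default=str)
    return artifacts
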