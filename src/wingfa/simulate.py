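"""Synthetic wing-measurement generator with known ground truth.

Generates datasets with exactly the statistical structure the asymmetry
ANOVA assumes:

    m_isr = mu_size + I_i + D_s + A_is + e_isr

with I ~ N(0, sigma_ind^2) per individual, a fixed directional-asymmetry
offset split across sides (D_L = -delta_da/2, D_R = +delta_da/2),
A ~ N(0, sigma_fa^2) independent per (individual, side) — the true
fluctuating asymmetry — and replicate measurement error
e ~ N(0, sigma_me^2).  Under this model E[FA10a] = sigma_fa^2 and
E[MS_residual] = sigma_me^2, so every estimator in the pipeline has a known
target.

Defaults mirror the screen's design: n = 30 sampled females per genotype,
r = 2 repeated measurements per wing, wing length on a micrometre-like
scale.  ``simulate_screen`` lays out whole experimental series (up to 25
deficiencies plus internal controls each) with per-deficiency true fold
changes on sigma_fa^2 and an optional lethal fraction, and returns the
ground-truth table alongside the data.

Randomness: one global seed expands into independent substreams via a
stable CRC-32 hash of (stage, series, genotype), so adding or removing a
genotype never perturbs the values generated for the others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd

from .io import GenotypeSample, measurements_to_frame
from .screen import SeriesLayout

__all__ = [
    "SimulationConfig",
    "ScreenScenario",
    "substream",
    "simulate_values",
    "simulate_sample",
    "simulate_screen",
    "simulate_screen_samples",
]

#: floor applied (and counted) when a draw comes out non-positive
LENGTH_FLOOR = 1e-6


@dataclass(frozen=True)
class SimulationConfig:
    """Variance components of one simulated genotype sample.

    Units are arbitrary but micrometre-like: the default mean wing length
    and inter-individual spread are plausible for a Drosophila wing, and
    the default FA and measurement-error SDs put E[FA10a] = 4 with a
    measurement-error variance a quarter of that — repeated measurement
    matters but does not dominate.
    """

    mu_size: float = 2500.0      # mean wing length
    sigma_ind: float = 50.0      # inter-individual size SD
    delta_da: float = 1.0        # fixed R - L offset (directional asymmetry)
    sigma_fa: float = 2.0        # SD of the individual x side effect (true FA)
    sigma_me: float = 1.0        # replicate measurement-error SD
    n: int = 30                  # individuals per genotype
    r: int = 2                   # replicate measurements per wing
    seed: int = 0

    def __post_init__(self):
        if self.n < 2 or self.r < 2:
            raise ValueError("simulation requires n >= 2 and r >= 2")
        if min(self.sigma_ind, self.sigma_fa, self.sigma_me) < 0:
            raise ValueError("standard deviations must be non-negative")


def substream(seed: int, *key: str) -> np.random.Generator:
    """Independent generator for a named stream under one global seed."""
    digest = zlib.crc32("/".join(key).encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), digest]))


def simulate_values(cfg: SimulationConfig, rng: np.random.Generator,
                    size: tuple[int, ...] = ()) -> np.ndarray:
    """Draw measurement arrays of shape ``size + (n, 2, r)``.

    The batch form is what Monte-Carlo calibrations consume; a single
    sample is ``size=()``.  Non-positive draws (possible only under extreme
    parameter choices) are floored at a small positive value and counted; a
    floored fraction above 0.1% triggers a warning.
    """
    shape = tuple(size) + (cfg.n, 2, cfg.r)
    ind = rng.normal(0.0, cfg.sigma_ind, size=tuple(size) + (cfg.n, 1, 1))
    da = np.array([-cfg.delta_da / 2, cfg.delta_da / 2]).reshape(2, 1)
    fa = rng.normal(0.0, cfg.sigma_fa, size=tuple(size) + (cfg.n, 2, 1))
    err = rng.normal(0.0, cfg.sigma_me, size=shape)
    y = cfg.mu_size + ind + da + fa + err
    bad = y <= 0
    if bad.any():
        frac = bad.mean()
        y = np.where(bad, LENGTH_FLOOR, y)
        if frac > 1e-3:
            import warnings
            warnings.warn(f"{frac:.2%} of simulated lengths floored at {LENGTH_FLOOR}; "
                          "parameters imply non-positive wing lengths", stacklevel=2)
    return y


def simulate_sample(cfg: SimulationConfig,
                    genotype_label: str = "sim",
                    series_id: str = "S0",
                    rng: np.random.Generator | None = None) -> GenotypeSample:
    """One balanced genotype sample, reproducible from the config seed."""
    if rng is None:
        rng = substream(cfg.seed, series_id, genotype_label)
    values = simulate_values(cfg, rng)
    # series-qualified ids keep (individual, side, replicate) unique dataset-wide
    ids = [f"{series_id}:{genotype_label}-{i + 1:03d}" for i in range(cfg.n)]
    return GenotypeSample(genotype_label, series_id, ids, values)


@dataclass(frozen=True)
class ScreenScenario:
    """Layout and ground truth of a simulated modifier screen.

    ``fold_changes`` maps deficiency name -> true multiplicative effect on
    sigma_fa^2 in the sensitized background (1 = neutral); unnamed
    deficiencies are padded in as neutral up to ``n_series *
    deficiencies_per_series``.  The negative control's sigma_fa is the
    baseline's divided by sqrt(control_fa_ratio), emulating the much lower
    FA of the driver-alone genotype (positive/negative FA10a ratio ~ 50 by
    default, within the 30-70 range seen between sensitized and
    driver-alone controls).
    """

    n_series: int = 2
    deficiencies_per_series: int = 25
    baseline: SimulationConfig = field(default_factory=SimulationConfig)
    fold_changes: dict[str, float] = field(default_factory=dict)
    df_alone_fold_changes: dict[str, float] = field(default_factory=dict)
    lethal: tuple[str, ...] = ()
    lethal_fraction: float = 0.0
    control_fa_ratio: float = 50.0
    seed: int = 0

    def __post_init__(self):
        if self.deficiencies_per_series > 25:
            raise ValueError("series design allows at most 25 deficiencies")


def _scale_fa(cfg: SimulationConfig, factor: float) -> SimulationConfig:
    # factor multiplies sigma_fa^2
    return replace(cfg, sigma_fa=cfg.sigma_fa * float(np.sqrt(factor)))


def simulate_screen_samples(scn: ScreenScenario,
                            stage: Literal["primary", "secondary"] = "primary"
                            ) -> tuple[dict[str, dict[str, GenotypeSample]],
                                       list[SeriesLayout], pd.DataFrame]:
    """Generate one screen stage as in-memory samples plus layout and truth.

    Per series: a positive control at baseline sigma_fa, a negative control
    at the reduced driver-alone sigma_fa, and experimental genotypes whose
    sigma_fa^2 is scaled by their true fold change.  In the secondary stage
    each deficiency additionally appears over the driver alone.  Lethal
    deficiencies (named, or drawn at ``lethal_fraction``) emit no
    individuals.  Stages use disjoint random substreams, so primary and
    secondary are independent experiments as in a real replication.

    Returns ``samples[series_id][genotype_label]``, the series layouts, and
    the ground-truth table.
    """
    total = scn.n_series * scn.deficiencies_per_series
    names = list(scn.fold_changes)
    names += [f"Df{i + 1:03d}" for i in range(total) if f"Df{i + 1:03d}" not in scn.fold_changes]
    names = names[:total]
    folds = {nm: scn.fold_changes.get(nm, 1.0) for nm in names}

    lethal = set(scn.lethal)
    if scn.lethal_fraction > 0:
        rng = substream(scn.seed, stage, "lethality")
        extra = rng.random(len(names)) < scn.lethal_fraction
        lethal |= {nm for nm, hit in zip(names, extra) if hit}

    neg_cfg = _scale_fa(scn.baseline, 1.0 / scn.control_fa_ratio)

    def _sample(cfg, label, series_id):
        return simulate_sample(cfg, label, series_id,
                               rng=substream(scn.seed, stage, series_id, label))

    samples: dict[str, dict[str, GenotypeSample]] = {}
    layouts, truth = [], []
    for si in range(scn.n_series):
        series_id = f"{stage[:4].upper()}{si + 1:02d}"
        block = names[si * scn.deficiencies_per_series:(si + 1) * scn.deficiencies_per_series]
        pos_label, neg_label = "ctrl+CycG", "ctrl+driver"
        experimental, df_alone = {}, {}
        per_series: dict[str, GenotypeSample] = {}
        for nm in block:
            truth.append({"deficiency": nm, "series": series_id, "stage": stage,
                          "true_fold": folds[nm],
                          "true_class": ("lethal" if nm in lethal else
                                         "enhancing" if folds[nm] > 1 else
                                         "decreasing" if folds[nm] < 1 else "neutral")})
            label = f"{nm}+CycG"
            experimental[nm] = label            # layout slot exists even when lethal
            if nm in lethal:
                continue
            per_series[label] = _sample(_scale_fa(scn.baseline, folds[nm]), label, series_id)
            if stage == "secondary":
                alabel = f"{nm}+driver"
                df_alone[nm] = alabel
                acfg = _scale_fa(neg_cfg, scn.df_alone_fold_changes.get(nm, 1.0))
                per_series[alabel] = _sample(acfg, alabel, series_id)
        per_series[pos_label] = _sample(scn.baseline, pos_label, series_id)
        if stage == "secondary":
            per_series[neg_label] = _sample(neg_cfg, neg_label, series_id)
        samples[series_id] = per_series
        layouts.append(SeriesLayout(
            series_id=series_id,
            experimental=experimental,
            positive_control_label=pos_label,
            negative_control_label=neg_label if stage == "secondary" else None,
            df_alone=df_alone,
        ))
    return samples, layouts, pd.DataFrame(truth)


def simulate_screen(scn: ScreenScenario,
                    stage: Literal["primary", "secondary"] = "primary"
                    ) -> tuple[pd.DataFrame, list[SeriesLayout], pd.DataFrame]:
    """Like :func:`simulate_screen_samples`, serialized to a long-format table."""
    samples, layouts, truth = simulate_screen_samples(scn, stage)
    records = []
    for per_series in samples.values():
        for sample in per_series.values():
            records.extend(sample.to_measurements())
    return measurements_to_frame(records), layouts, truth
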