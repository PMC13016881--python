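#!/usr/bin/env python
"""Simulate a two-stage deficiency screen with planted ground truth.

Generates a full genome-screen-style experiment: two series of 25
deficiency genotypes per stage, each series with its internal positive
(sensitized driver + transgene) and negative (driver alone) controls,
n = 30 individuals per genotype measured twice per wing.  Three strong FA
enhancers (true fold 5 on the FA variance) and three strong suppressors
(fold 0.2) are planted; 8% of deficiencies are lethal in combination, as a
screen of this kind typically loses a fraction of crosses.

Writes measurements.csv, layout.yaml and truth.tsv under results/simulated/.
"""

from pathlib import Path

import pandas as pd

from wingfa.calibrate import PLANTED_FOLDS
from wingfa.pipeline import layouts_to_yaml
from wingfa.simulate import ScreenScenario, simulate_screen

OUT = Path(__file__).resolve().parent.parent / "results" / "simulated"
SEED = 20260919


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    scn = ScreenScenario(n_series=2, deficiencies_per_series=25,
                         fold_changes=dict(PLANTED_FOLDS),
                         lethal_fraction=0.08, seed=SEED)
    frames, pairs, truths = [], [], []
    for stage in ("primary", "secondary"):
        frame, layouts, truth = simulate_screen(scn, stage=stage)
        frames.append(frame)
        pairs.extend((lay, stage) for lay in layouts)
        truths.append(truth)
    measurements = pd.concat(frames)
    truth = pd.concat(truths)
    measurements.to_csv(OUT / "measurements.csv", index=False)
    layouts_to_yaml(pairs, OUT / "layout.yaml")
    truth.to_csv(OUT / "truth.tsv", sep="\t", index=False)

    by_class = truth[truth["stage"] == "primary"]["true_class"].value_counts()
    print(f"wrote {len(measurements)} measurement rows to {OUT / 'measurements.csv'}")
    print(f"planted truth (primary stage): {by_class.to_dict()}")
    print(f"series layouts: {[lay.series_id for lay, _ in pairs]}")


if __name__ == "__main__":
    main()
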