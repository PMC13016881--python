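import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wingfa.fa import ComparisonResult
from wingfa.screen import (ScreenError, SeriesLayout, aggregate_two_stage,
                           classify, holm_adjust, rows_to_frame, run_series)
from wingfa.simulate import (ScreenScenario, SimulationConfig,
                             simulate_screen_samples, simulate_sample, substream)


def comparison(p_adj, fold):
    return ComparisonResult(f_statistic=1.0, df_num=29, df_den=29, p_raw=p_adj,
                            fold_change=fold, ms_ratio=fold, p_adjusted=p_adj,
                            fold_undefined=not np.isfinite(fold))


class TestHolm:
    def test_worked_example(self):
        adj = holm_adjust([0.01, 0.04])
        assert adj[0] == pytest.approx(0.02, abs=1e-12)
        assert adj[1] == pytest.approx(0.04, abs=1e-12)

    def test_single_p_unchanged(self):
        assert holm_adjust([0.03]).tolist() == [0.03]

    def test_all_ones(self):
        assert holm_adjust([1.0, 1.0, 1.0]).tolist() == [1.0, 1.0, 1.0]

    def test_rejects_invalid_p(self):
        with pytest.raises(ValueError):
            holm_adjust([0.5, 1.5])

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_adjusted_at_least_raw_and_order_preserving(self, p):
        p = np.asarray(p)
        adj = holm_adjust(p)
        assert np.all(adj >= p - 1e-15)
        assert np.all(adj <= 1.0)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-15)


class TestClassify:
    # fold-change / adjusted-p pairs as they appear in secondary-screen
    # report tables, plus a non-significant case
    @pytest.mark.parametrize("fold,p_adj,expect", [
        (0.37329, 4.68e-2, "decreasing"),
        (3.67005, 4.34e-3, "enhancing"),
        (2.0, 0.2, "neutral"),
        (0.5, 0.051, "neutral"),
    ])
    def test_rule(self, fold, p_adj, expect):
        assert classify(comparison(p_adj, fold)) == expect

    def test_undefined_fold_neutral(self):
        assert classify(comparison(0.001, float("nan"))) == "neutral"

    def test_pure_function_of_alpha(self):
        c = comparison(0.04, 2.0)
        assert classify(c, alpha=0.05) == "enhancing"
        assert classify(c, alpha=0.01) == "neutral"


class TestRunSeries:
    def layout(self, k=3, df_alone=False):
        return SeriesLayout(
            series_id="S1",
            experimental={f"Df{i}": f"Df{i}+CycG" for i in range(1, k + 1)},
            positive_control_label="ctrl+CycG",
            negative_control_label="ctrl+driver" if df_alone else None,
            df_alone={f"Df{i}": f"Df{i}+driver" for i in range(1, k + 1)} if df_alone else {},
        )

    def test_null_series_all_neutral(self):
        # every experimental genotype IS the control sample: F = 1, p = 1
        control = simulate_sample(SimulationConfig(seed=4), "ctrl+CycG", "S1")
        samples = {"ctrl+CycG": control}
        for i in range(1, 4):
            samples[f"Df{i}+CycG"] = control
        rows = run_series(self.layout(), samples)
        assert all(r.classification == "neutral" for r in rows)
        assert all(r.vs_positive_control.f_statistic == 1.0 for r in rows)
        assert all(r.vs_positive_control.p_adjusted == pytest.approx(1.0) for r in rows)

    def test_missing_positive_control_aborts(self):
        with pytest.raises(ScreenError, match="positive control"):
            run_series(self.layout(), {})

    def test_absent_genotype_recorded_lethal_without_test(self):
        samples = {"ctrl+CycG": simulate_sample(SimulationConfig(seed=4), "ctrl+CycG", "S1"),
                   "Df1+CycG": simulate_sample(SimulationConfig(seed=5), "Df1+CycG", "S1")}
        rows = run_series(self.layout(k=2), samples)
        by_name = {r.deficiency: r for r in rows}
        assert by_name["Df2"].classification == "lethal"
        assert by_name["Df2"].vs_positive_control is None

    def test_small_sample_counts_as_lethal(self):
        samples = {"ctrl+CycG": simulate_sample(SimulationConfig(seed=4), "ctrl+CycG", "S1"),
                   "Df1+CycG": simulate_sample(SimulationConfig(n=5, seed=5), "Df1+CycG", "S1")}
        rows = run_series(self.layout(k=1), samples, min_n=10)
        assert rows[0].classification == "lethal"

    def test_unmeasurable_marking(self):
        samples = {"ctrl+CycG": simulate_sample(SimulationConfig(seed=4), "ctrl+CycG", "S1"),
                   "Df1+CycG": simulate_sample(SimulationConfig(seed=5), "Df1+CycG", "S1")}
        rows = run_series(self.layout(k=1), samples, unmeasurable=("Df1",))
        assert rows[0].classification == "unmeasurable"

    def test_planted_strong_enhancer_detected(self):
        base = SimulationConfig(seed=0)
        samples = {"ctrl+CycG": simulate_sample(base, "ctrl+CycG", "S1",
                                                rng=substream(0, "c"))}
        for i in range(1, 4):
            fold = 25.0 if i == 2 else 1.0
            cfg = SimulationConfig(sigma_fa=base.sigma_fa * np.sqrt(fold), seed=0)
            samples[f"Df{i}+CycG"] = simulate_sample(cfg, f"Df{i}+CycG", "S1",
                                                     rng=substream(0, f"d{i}"))
        rows = run_series(self.layout(), samples)
        by_name = {r.deficiency: r for r in rows}
        assert by_name["Df2"].classification == "enhancing"
        assert by_name["Df2"].vs_positive_control.fold_change > 1

    def test_oversized_series_rejected(self):
        with pytest.raises(ScreenError, match="25"):
            SeriesLayout("S1", {f"Df{i}": f"g{i}" for i in range(26)}, "pos")

    def test_secondary_requires_negative_control(self):
        samples = {"ctrl+CycG": simulate_sample(SimulationConfig(seed=4), "ctrl+CycG", "S1")}
        with pytest.raises(ScreenError, match="negative control"):
            run_series(self.layout(df_alone=True), samples, stage="secondary")

    def test_holm_family_is_per_series_tests_only(self):
        # two identical series must give identical adjusted p for shared
        # deficiencies regardless of what other series contain
        samples1, layouts1, _ = simulate_screen_samples(
            ScreenScenario(n_series=1, deficiencies_per_series=5, seed=6))
        rows1 = run_series(layouts1[0], samples1[layouts1[0].series_id])
        samples2, layouts2, _ = simulate_screen_samples(
            ScreenScenario(n_series=2, deficiencies_per_series=5, seed=6))
        rows2 = run_series(layouts2[0], samples2[layouts2[0].series_id])
        p1 = [r.vs_positive_control.p_adjusted for r in rows1]
        p2 = [r.vs_positive_control.p_adjusted for r in rows2]
        assert p1 == p2


class TestAggregate:
    def row(self, name, stage, classification, p=0.01, fold=2.0, df_alone=None):
        from wingfa.screen import ScreenRow
        r = ScreenRow(deficiency=name, series_id="S1", stage=stage,
                      classification=classification,
                      vs_positive_control=comparison(p, fold))
        if df_alone is not None:
            r.df_alone_vs_negative_control = comparison(*df_alone)
        return r

    def test_same_direction_confirmed(self):
        prim = [self.row("DfA", "primary", "enhancing")]
        seco = [self.row("DfA", "secondary", "enhancing")]
        confirmed, _ = aggregate_two_stage(prim, seco)
        assert list(confirmed["status"]) == ["confirmed"]

    def test_secondary_neutral_drops_candidate(self):
        prim = [self.row("DfA", "primary", "enhancing")]
        seco = [self.row("DfA", "secondary", "neutral", p=0.5)]
        confirmed, _ = aggregate_two_stage(prim, seco)
        assert len(confirmed) == 0

    def test_direction_flip_not_confirmed(self):
        prim = [self.row("DfA", "primary", "enhancing")]
        seco = [self.row("DfA", "secondary", "decreasing", fold=0.4)]
        confirmed, _ = aggregate_two_stage(prim, seco)
        assert len(confirmed) == 0

    def test_secondary_only_reported_unconfirmable(self):
        confirmed, _ = aggregate_two_stage([], [self.row("DfB", "secondary", "enhancing")])
        assert list(confirmed["status"]) == ["secondary_only"]

    def test_df_alone_effects_listed(self):
        prim = [self.row("DfA", "primary", "neutral", p=0.9)]
        seco = [self.row("DfA", "secondary", "neutral", p=0.9, df_alone=(0.001, 3.3))]
        _, df_alone = aggregate_two_stage(prim, seco)
        assert list(df_alone["deficiency"]) == ["DfA"]
        assert df_alone["direction"].iloc[0] == "increase"

    def test_rows_to_frame_columns(self):
        frame = rows_to_frame([self.row("DfA", "primary", "enhancing")])
        for col in ("deficiency", "fold_change", "p_adjusted", "classification"):
            assert col in frame.columns
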