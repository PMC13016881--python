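import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wingfa.fa import (anova_two_way_mixed, batch_anova, compare_fa,
                       directional_asymmetry, fa10a, two_sided_f_p)
from wingfa.simulate import SimulationConfig, simulate_sample

from conftest import anova_oracle, make_sample


def random_block(rng, n=None, r=None):
    n = n or int(rng.integers(2, 11))
    r = r or int(rng.integers(2, 4))
    return 100 + rng.normal(0, 3, size=(n, 2, r))


class TestAnova:
    def test_matches_brute_force_oracle(self, rng):
        for _ in range(25):
            y = random_block(rng)
            tbl = anova_two_way_mixed(make_sample(y))
            ora = anova_oracle(y)
            for key in ("ms_side", "ms_individual", "ms_interaction", "ms_residual"):
                assert getattr(tbl, key) == pytest.approx(ora[key], rel=1e-10)
            assert tbl.total_ss() == pytest.approx(ora["ss_total"], rel=1e-9)

    def test_matches_independent_mixed_anova_fit(self):
        # frozen mean squares from an R aov() fit (y ~ side + ind + side:ind)
        # of this 4x2x2 block, printed to 12 digits
        y = np.array([[[98.815, 97.389], [99.787, 98.218]],
                      [[91.383, 96.702], [97.044, 99.943]],
                      [[98.251, 99.303], [104.125, 101.114]],
                      [[97.043, 101.088], [98.202, 97.034]]])
        tbl = anova_two_way_mixed(make_sample(y))
        assert tbl.ms_side == pytest.approx(15.002065562500, rel=1e-10)
        assert tbl.ms_individual == pytest.approx(13.116023562500, rel=1e-10)
        assert tbl.ms_interaction == pytest.approx(7.493432729167, rel=1e-10)
        assert tbl.ms_residual == pytest.approx(4.318142062500, rel=1e-10)

    def test_constant_data_all_ms_zero(self):
        tbl = anova_two_way_mixed(make_sample(np.full((3, 2, 2), 7.0)))
        assert (tbl.ms_side, tbl.ms_individual, tbl.ms_interaction, tbl.ms_residual) \
            == (0.0, 0.0, 0.0, 0.0)

    def test_location_invariance(self, rng):
        y = random_block(rng, n=5, r=2)
        a = anova_two_way_mixed(make_sample(y))
        b = anova_two_way_mixed(make_sample(y + 1234.5))
        for key in ("ms_side", "ms_individual", "ms_interaction", "ms_residual"):
            assert getattr(a, key) == pytest.approx(getattr(b, key), rel=1e-9, abs=1e-9)

    @given(c=st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_scale_equivariance(self, c):
        y = 100 + np.random.default_rng(7).normal(0, 3, size=(4, 2, 2))
        a = anova_two_way_mixed(make_sample(y))
        b = anova_two_way_mixed(make_sample(y * c))
        for key in ("ms_side", "ms_individual", "ms_interaction", "ms_residual"):
            assert getattr(b, key) == pytest.approx(getattr(a, key) * c * c, rel=1e-9)
        # F statistics and p-values are scale-free
        ca = compare_fa(a, a)
        cb = compare_fa(b, b)
        assert cb.f_statistic == pytest.approx(ca.f_statistic)
        assert cb.p_raw == pytest.approx(ca.p_raw)

    def test_side_swap_leaves_fa_invariant_flips_da(self, rng):
        y = random_block(rng, n=6, r=2)
        a = anova_two_way_mixed(make_sample(y))
        b = anova_two_way_mixed(make_sample(y[:, ::-1, :]))
        assert b.ms_interaction == pytest.approx(a.ms_interaction, rel=1e-12)
        assert fa10a(b).fa10a == pytest.approx(fa10a(a).fa10a, rel=1e-12)
        da_a, f_a, _ = directional_asymmetry(a)
        da_b, f_b, _ = directional_asymmetry(b)
        assert da_b == pytest.approx(-da_a, rel=1e-12)
        assert f_b == pytest.approx(f_a, rel=1e-12)

    def test_rejects_single_replicate_and_single_individual(self):
        with pytest.raises(ValueError, match="r >= 2"):
            batch_anova(np.zeros((3, 2, 1)))
        with pytest.raises(ValueError, match="2 individuals"):
            batch_anova(np.zeros((1, 2, 2)))

    def test_batch_path_agrees_with_per_sample_path(self, rng):
        y = 100 + rng.normal(0, 2, size=(8, 5, 2, 3))
        batch = batch_anova(y)
        for b in range(8):
            tbl = anova_two_way_mixed(make_sample(y[b]))
            for key in ("ms_side", "ms_individual", "ms_interaction", "ms_residual"):
                assert batch[key][b] == pytest.approx(getattr(tbl, key), rel=1e-12)


class TestFA10a:
    def test_definition_and_negative_flag(self):
        from wingfa.fa import AnovaTable
        tbl = AnovaTable(ms_side=1, ms_individual=1, ms_interaction=5,
                         ms_residual=1, n=30, r=2)
        res = fa10a(tbl)
        assert res.fa10a == (5 - 1) / 2
        assert res.me_variance == 1
        assert not res.negative_flag
        tbl2 = AnovaTable(ms_side=1, ms_individual=1, ms_interaction=0.5,
                          ms_residual=1, n=30, r=2)
        res2 = fa10a(tbl2)
        assert res2.fa10a == pytest.approx(-0.25)
        assert res2.negative_flag

    def test_equal_interaction_and_residual_gives_zero(self):
        from wingfa.fa import AnovaTable
        tbl = AnovaTable(ms_side=0, ms_individual=0, ms_interaction=2.5,
                         ms_residual=2.5, n=10, r=2)
        assert fa10a(tbl).fa10a == 0.0

    def test_side_symmetric_replicate_identical_data_is_exactly_zero(self, rng):
        # individuals differ in size but L == R and replicates identical:
        # no asymmetry, no measurement error
        sizes = 100 + rng.normal(0, 5, size=6)
        y = np.tile(sizes[:, None, None], (1, 2, 2))
        res = fa10a(anova_two_way_mixed(make_sample(y)))
        assert res.fa10a == 0.0


class TestDirectionalAsymmetry:
    def test_constant_right_offset_recovered(self, rng):
        y = random_block(rng, n=10, r=2)
        delta = 3.25
        y2 = y.copy()
        y2[:, 1, :] += delta
        da, _, _ = directional_asymmetry(anova_two_way_mixed(make_sample(y2)))
        da0, _, _ = directional_asymmetry(anova_two_way_mixed(make_sample(y)))
        assert da - da0 == pytest.approx(delta, rel=1e-9)

    def test_null_p_uniform(self):
        # no side effect: p of the side test should be uniform
        from wingfa.fa import batch_anova
        from scipy import stats
        rng = np.random.default_rng(11)
        cfg = SimulationConfig(delta_da=0.0, seed=11)
        from wingfa.simulate import simulate_values
        y = simulate_values(cfg, rng, size=(2000,))
        ms = batch_anova(y)
        f = ms["ms_side"] / ms["ms_interaction"]
        p = stats.f.sf(f, 1, cfg.n - 1)
        assert stats.kstest(p, "uniform").pvalue > 0.01


class TestCompareFA:
    def test_identity(self, rng):
        tbl = anova_two_way_mixed(make_sample(random_block(rng, n=8, r=2)))
        res = compare_fa(tbl, tbl)
        assert res.f_statistic == 1.0
        assert res.p_raw == pytest.approx(1.0)
        assert res.fold_change == 1.0 or res.fold_undefined

    def test_reciprocity(self, rng):
        a = anova_two_way_mixed(make_sample(
            simulate_sample(SimulationConfig(seed=1), "a").values))
        b = anova_two_way_mixed(make_sample(
            simulate_sample(SimulationConfig(seed=2), "b").values))
        ab, ba = compare_fa(a, b), compare_fa(b, a)
        assert ab.fold_change * ba.fold_change == pytest.approx(1.0, rel=1e-12)
        assert ab.f_statistic * ba.f_statistic == pytest.approx(1.0, rel=1e-12)
        assert ab.p_raw == pytest.approx(ba.p_raw, rel=1e-9)
        assert {ab.direction, ba.direction} <= {"increase", "decrease"}

    def test_undefined_fold_when_reference_fa_nonpositive(self):
        from wingfa.fa import AnovaTable
        a = AnovaTable(ms_side=0, ms_individual=0, ms_interaction=4, ms_residual=1, n=30, r=2)
        b = AnovaTable(ms_side=0, ms_individual=0, ms_interaction=1, ms_residual=2, n=30, r=2)
        res = compare_fa(a, b)
        assert res.fold_undefined
        assert np.isnan(res.fold_change)
        assert np.isfinite(res.f_statistic) and np.isfinite(res.p_raw)

    def test_two_sided_p_doubles_smaller_tail(self):
        from scipy import stats
        f, dfn, dfd = 2.0, 29, 29
        expect = 2 * min(stats.f.sf(f, dfn, dfd), stats.f.cdf(f, dfn, dfd))
        assert two_sided_f_p(f, dfn, dfd) == pytest.approx(expect)
        assert two_sided_f_p(1.0, dfn, dfd) == pytest.approx(1.0)

    def test_fa10a_ratio_mode_reported(self, rng):
        a = anova_two_way_mixed(make_sample(random_block(rng, n=20, r=2)))
        b = anova_two_way_mixed(make_sample(random_block(rng, n=20, r=2)))
        res = compare_fa(a, b, mode="fa10a_ratio")
        if not res.fold_undefined:
            assert res.f_statistic == pytest.approx(res.fold_change, rel=1e-12)
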