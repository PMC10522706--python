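"""Statistical machinery: signed-rank exactness, Holm, bootstrap, margins."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from segnoninfer import (
    AgreementTable,
    InsufficientDataError,
    Margins,
    NonInferiorityConfig,
    bootstrap_median_ci,
    derive_margins,
    holm_bonferroni,
    metric_spec,
    noninferiority_test,
    run_noninferiority_battery,
    shapiro_normality_p,
    spearman_rho,
    wilcoxon_signed_rank_one_sided,
)
from segnoninfer.stats import INTER, MODEL, oriented_deltas
from tests.oracles import enumerate_wilcoxon_greater, holm_by_hand


def make_table(inter: dict[str, np.ndarray], model: dict[str, np.ndarray]) -> AgreementTable:
    n = len(next(iter(inter.values())))
    cols = {}
    for m, v in inter.items():
        cols[(INTER, m)] = v
    for m, v in model.items():
        cols[(MODEL, m)] = v
    df = pd.DataFrame(cols, index=[f"case_{i:03d}" for i in range(n)])
    df.columns = pd.MultiIndex.from_tuples(df.columns, names=["pairing", "metric"])
    return AgreementTable(df)


class TestShapiro:
    def test_normal_draws_rarely_rejected(self):
        hits = 0
        for seed in range(100):
            x = np.random.default_rng(seed).standard_normal(200)
            hits += shapiro_normality_p(x) > 0.05
        assert hits >= 90

    def test_skewed_draws_rejected(self):
        hits = 0
        for seed in range(100):
            x = np.random.default_rng(seed).exponential(size=200)
            hits += shapiro_normality_p(x) < 0.05
        assert hits >= 99

    def test_constant_input_degenerate(self):
        with pytest.warns(UserWarning, match="constant"):
            assert shapiro_normality_p([2.0] * 10) == 0.0

    def test_too_few_values(self):
        with pytest.raises(InsufficientDataError):
            shapiro_normality_p([1.0, 2.0])


class TestWilcoxon:
    def test_all_positive_n5_exact(self):
        assert wilcoxon_signed_rank_one_sided([0.1, 0.2, 0.3, 0.4, 0.5]) == pytest.approx(1 / 32)

    def test_matches_enumeration_small_n(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = rng.integers(5, 13)
            d = rng.standard_normal(n)
            d = d[d != 0]
            if np.unique(np.abs(d)).size < d.size or d.size < 5:
                continue
            p_impl = wilcoxon_signed_rank_one_sided(d)
            p_enum = enumerate_wilcoxon_greater(d)
            assert p_impl == pytest.approx(p_enum, abs=1e-12)

    def test_sign_flip_complementarity(self):
        rng = np.random.default_rng(3)
        d = rng.standard_normal(8)
        p = wilcoxon_signed_rank_one_sided(d)
        p_flip = wilcoxon_signed_rank_one_sided(-d)
        assert p + p_flip >= 1.0  # discrete mass at the observed statistic counted twice

    def test_symmetric_pairs_near_half(self):
        d = np.array([1.0, -1.1, 2.0, -2.1, 3.0, -3.1, 4.0, -4.1])
        p = enumerate_wilcoxon_greater(d)
        assert wilcoxon_signed_rank_one_sided(d) == pytest.approx(p, abs=1e-12)
        assert 0.3 < p < 0.8

    def test_all_zero_deltas(self):
        with pytest.warns(UserWarning, match="zero"):
            assert wilcoxon_signed_rank_one_sided([0.0] * 10) == 1.0

    def test_too_few_nonzero(self):
        with pytest.raises(InsufficientDataError):
            wilcoxon_signed_rank_one_sided([1.0, 2.0, 0.0, 0.0, 0.0])


class TestHolm:
    def test_hand_worked_example(self):
        assert holm_bonferroni([0.01, 0.04, 0.03]) == pytest.approx([0.03, 0.06, 0.06])

    def test_single_p_unchanged(self):
        assert holm_bonferroni([0.2]) == pytest.approx([0.2])

    def test_capped_at_one(self):
        assert holm_bonferroni([0.5, 0.9]) == pytest.approx([1.0, 1.0])

    def test_matches_hand_implementation(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            p = rng.random(rng.integers(1, 10)).tolist()
            assert holm_bonferroni(p) == pytest.approx(holm_by_hand(p))

    def test_permutation_equivariance_and_bounds(self):
        rng = np.random.default_rng(5)
        p = rng.random(7)
        adj = np.asarray(holm_bonferroni(p.tolist()))
        perm = rng.permutation(7)
        adj_perm = np.asarray(holm_bonferroni(p[perm].tolist()))
        np.testing.assert_allclose(adj[perm], adj_perm)
        assert np.all(adj >= p)  # never below the unadjusted p

    def test_family_size_padding(self):
        # correcting a single p in a family of 3 is plain Bonferroni here
        assert holm_bonferroni([0.01], family_size=3) == pytest.approx([0.03])

    def test_domain_error(self):
        with pytest.raises(ValueError):
            holm_bonferroni([0.5, 1.5])


class TestBootstrap:
    def test_constant_vector(self):
        assert bootstrap_median_ci([3.0] * 10, 1000, 0.95, 0) == (3.0, 3.0, 3.0)

    def test_deterministic_under_seed(self):
        x = np.random.default_rng(0).standard_normal(32)
        assert bootstrap_median_ci(x, 2000, 0.95, 42) == bootstrap_median_ci(x, 2000, 0.95, 42)

    def test_widens_with_level(self):
        x = np.random.default_rng(1).standard_normal(32)
        _, lo90, hi90 = bootstrap_median_ci(x, 5000, 0.90, 7)
        _, lo99, hi99 = bootstrap_median_ci(x, 5000, 0.99, 7)
        assert lo99 <= lo90 and hi99 >= hi90

    def test_needs_two_values(self):
        with pytest.raises(InsufficientDataError):
            bootstrap_median_ci([1.0], 1000, 0.95, 0)


class TestSpearman:
    def test_monotone_transform_is_one(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        assert spearman_rho(x, np.exp(x)) == pytest.approx(1.0)

    def test_reversed_is_minus_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert spearman_rho(x, x[::-1]) == pytest.approx(-1.0)

    def test_hand_value(self):
        assert spearman_rho([1, 2, 3, 4], [2, 1, 4, 3]) == pytest.approx(0.6)

    def test_constant_flagged(self):
        with pytest.warns(UserWarning, match="constant"):
            assert np.isnan(spearman_rho([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]))


class TestNonInferiorityTest:
    def test_identical_series_rejects(self):
        rng = np.random.default_rng(2)
        inter = rng.uniform(0.3, 0.9, size=32)
        spec = metric_spec("Dice")
        cfg = NonInferiorityConfig(n_boot=1000)
        res = noninferiority_test(inter, inter.copy(), spec, 0.2, cfg)
        assert res.p_raw < 0.05
        assert res.n_cases_used == 32
        assert res.test_used in ("paired_t", "wilcoxon")

    def test_boundary_null_all_zero_deltas(self):
        # dyadic values keep the subtraction exact so every delta is exactly 0
        inter = 0.5 + np.arange(32) / 128.0
        model = inter - 0.25  # exactly margin worse
        res = noninferiority_test(inter, model, metric_spec("Dice"), 0.25,
                                  NonInferiorityConfig(n_boot=1000))
        assert res.p_raw == 1.0
        assert res.test_used == "degenerate"

    def test_lower_better_orientation(self):
        # for AVD smaller is better: model exceeding inter by > margin must not pass
        rng = np.random.default_rng(8)
        inter = rng.uniform(2, 6, size=32)
        model = inter + 6.0 + rng.normal(0, 0.1, 32)  # 2x the 3 ml margin worse
        res = noninferiority_test(inter, model, metric_spec("AVD"), 3.0,
                                  NonInferiorityConfig(n_boot=1000))
        assert res.p_raw > 0.5
        deltas = oriented_deltas(inter, model, metric_spec("AVD"), 3.0)
        assert np.median(deltas) < 0

    def test_pairwise_complete_deletion(self):
        inter = np.array([0.5] * 8 + [np.nan, 0.6])
        model = np.array([0.7] * 8 + [0.6, np.nan])
        res = noninferiority_test(inter, model, metric_spec("Dice"), 0.2,
                                  NonInferiorityConfig(n_boot=1000))
        assert res.n_cases_used == 8

    def test_too_few_pairs(self):
        with pytest.raises(InsufficientDataError, match="Dice"):
            noninferiority_test([0.5] * 4, [0.6] * 4, metric_spec("Dice"), 0.2,
                                NonInferiorityConfig(n_boot=1000))


class TestBattery:
    def _identical_table(self, n=32, seed=4):
        rng = np.random.default_rng(seed)
        inter, model = {}, {}
        from segnoninfer import default_battery

        for spec in default_battery():
            vals = (rng.uniform(0.2, 0.9, n) if spec.range == "unit_interval"
                    else rng.uniform(1.0, 20.0, n))
            inter[spec.label] = vals
            model[spec.label] = vals.copy()
        return make_table(inter, model)

    def test_identical_series_all_non_inferior(self):
        table = self._identical_table()
        results = run_noninferiority_battery(table, NonInferiorityConfig(n_boot=1000, seed=1))
        assert len(results) == 7
        assert all(r.non_inferior for r in results)
        for r in results:
            assert r.p_adjusted >= r.p_raw

    def test_uniformly_much_worse_model_never_passes(self):
        rng = np.random.default_rng(9)
        from segnoninfer import default_battery

        inter, model = {}, {}
        for spec in default_battery():
            if spec.range == "unit_interval":
                base = rng.uniform(0.5, 0.9, 32)
                worse = base - 0.6  # 3x the 0.2 margin
            else:
                base = rng.uniform(10, 20, 32)
                worse = base + 9.0  # 3x the 3 ml / 3 mm margin
            inter[spec.label] = base
            model[spec.label] = worse + rng.normal(0, 0.01, 32)
        results = run_noninferiority_battery(make_table(inter, model),
                                             NonInferiorityConfig(n_boot=1000, seed=2))
        assert not any(r.non_inferior for r in results)

    def test_undefined_metric_isolated(self):
        table = self._identical_table()
        df = table.data.copy()
        df[(MODEL, "HD95")] = np.nan
        results = run_noninferiority_battery(AgreementTable(df),
                                             NonInferiorityConfig(n_boot=1000, seed=3))
        by_name = {r.metric.label: r for r in results}
        assert by_name["HD95"].p_raw is None and by_name["HD95"].n_cases_used == 0
        others = [r for r in results if r.metric.label != "HD95"]
        assert all(r.non_inferior for r in others)

    def test_battery_deterministic(self):
        table = self._identical_table()
        cfg = NonInferiorityConfig(n_boot=1000, seed=5)
        r1 = run_noninferiority_battery(table, cfg)
        r2 = run_noninferiority_battery(table, cfg)
        for a, b in zip(r1, r2):
            assert a.ci_inter == b.ci_inter and a.p_raw == b.p_raw

    def test_agreement_table_csv_round_trip(self, tmp_path):
        table = self._identical_table()
        table.to_csv(tmp_path / "agg.csv")
        back = AgreementTable.from_csv(tmp_path / "agg.csv")
        pd.testing.assert_frame_equal(
            table.data.sort_index(axis=1), back.data.sort_index(axis=1), check_names=False
        )


class TestDeriveMargins:
    def _tables(self, diff_unit=0.19, diff_si=2.5, n=16):
        rng = np.random.default_rng(6)
        from segnoninfer import default_battery

        inter1, inter2, dummy = {}, {}, {}
        for spec in default_battery():
            if spec.range == "unit_interval":
                base = rng.uniform(0.3, 0.7, n)
                other = base + diff_unit
            else:
                base = rng.uniform(5, 15, n)
                other = base + diff_si
            inter1[spec.label] = base
            inter2[spec.label] = other
            dummy[spec.label] = base
        return make_table(inter1, dummy), make_table(inter2, dummy)

    def test_constant_difference_recovered(self):
        t1, t2 = self._tables()
        d = derive_margins([t1, t2])
        assert d.unit_interval == pytest.approx(0.19)
        assert d.si_units == pytest.approx(2.5)
        assert d.defaults == Margins()

    def test_identical_series_warns_zero(self):
        t1, _ = self._tables(diff_unit=0.0, diff_si=0.0)
        with pytest.warns(UserWarning, match="zero"):
            d = derive_margins([t1, t1])
        assert d.unit_interval == 0.0

    def test_needs_two_tables(self):
        t1, _ = self._tables()
        with pytest.raises(InsufficientDataError):
            derive_margins([t1])

    def test_deterministic(self):
        t1, t2 = self._tables()
        assert derive_margins([t1, t2]) == derive_margins([t1, t2])
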