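"""KS statistic oracle checks, p-value summaries and alternative flag rules."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ksdiag import (
    DiagnosticSummary,
    GenerationConfig,
    ImputationSet,
    NoMissingDataError,
    ScenarioSpec,
    diagnose,
    diagnose_pooled,
    flag_extreme,
    generate_dataset,
    impose_mcar,
    impute_normal,
    ks_two_sample,
    run_replicate,
    stuart_flags,
)


def brute_force_d(a, b):
    """sup |F_a - F_b| evaluated by direct ECDF counting at every pooled point."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    points = np.concatenate([a, b])
    return max(
        abs((a <= t).mean() - (b <= t).mean()) for t in points
    )


class TestKsTwoSample:
    def test_identical_samples(self, rng):
        a = rng.normal(size=20)
        res = ks_two_sample(a, a.copy())
        assert res.d_stat == 0.0
        assert res.p_value == 1.0

    def test_disjoint_supports(self):
        res = ks_two_sample([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert res.d_stat == 1.0

    def test_interleaved_hand_example(self):
        assert ks_two_sample([1.0, 3.0], [2.0, 4.0]).d_stat == pytest.approx(0.5)

    def test_matches_brute_force_oracle_on_random_instances(self):
        rng = np.random.default_rng(2024)
        for _ in range(1000):
            na, nb = rng.integers(1, 31, size=2)
            if rng.random() < 0.5:  # integer draws force ties and duplicates
                a = rng.integers(0, 8, size=na).astype(float)
                b = rng.integers(0, 8, size=nb).astype(float)
            else:
                a = rng.normal(size=na)
                b = rng.normal(size=nb)
            assert ks_two_sample(a, b).d_stat == pytest.approx(
                brute_force_d(a, b), abs=1e-12
            )

    def test_matches_scipy_references(self, rng):
        # Statistic against scipy's ks_2samp; p-value against scipy's
        # kolmogorov survival function evaluated at sqrt(n_e)*D (ks_2samp's
        # own asymp mode adds a small-sample correction to lambda, which we
        # deliberately do not apply).
        from scipy.special import kolmogorov
        from scipy.stats import ks_2samp

        for _ in range(50):
            a = rng.normal(size=rng.integers(50, 200))
            b = rng.normal(0.3, 1.0, size=rng.integers(50, 200))
            res = ks_two_sample(a, b)
            assert res.d_stat == pytest.approx(ks_2samp(a, b).statistic, abs=1e-12)
            n_e = a.size * b.size / (a.size + b.size)
            assert res.p_value == pytest.approx(
                kolmogorov(np.sqrt(n_e) * res.d_stat), abs=1e-10
            )

    def test_p_value_monotone_in_d(self):
        # Growing location shift at fixed sizes: d never decreases and the
        # p-value never increases.
        base = np.linspace(-1.0, 1.0, 40)
        results = [ks_two_sample(base, base + shift) for shift in np.linspace(0, 2, 15)]
        ds = [r.d_stat for r in results]
        ps = [r.p_value for r in results]
        assert all(x <= y + 1e-15 for x, y in zip(ds, ds[1:]))
        assert all(x >= y - 1e-15 for x, y in zip(ps, ps[1:]))

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_two_sample([], [1.0])

    @settings(max_examples=200, derandomize=True)
    @given(
        a=st.lists(st.integers(0, 6), min_size=1, max_size=30),
        b=st.lists(st.integers(0, 6), min_size=1, max_size=30),
    )
    def test_oracle_agreement_property(self, a, b):
        res = ks_two_sample(np.array(a, float), np.array(b, float))
        assert 0.0 <= res.d_stat <= 1.0
        assert res.d_stat == pytest.approx(brute_force_d(a, b), abs=1e-12)


@pytest.fixture()
def imps(rng):
    data = generate_dataset(GenerationConfig(n=200), rng)
    return impute_normal(impose_mcar(data, 0.3, rng), 10, rng)


class TestDiagnose:
    def test_summary_ordering_and_size(self, imps):
        summary = diagnose(imps)
        assert summary.m == imps.m
        assert summary.p_min <= summary.p_median <= summary.p_max

    def test_identical_imputations_collapse_summaries(self, imps):
        clone = ImputationSet(
            completed_x=np.tile(imps.completed_x[0], (5, 1)), mask=imps.mask, y=imps.y
        )
        summary = diagnose(clone)
        assert summary.p_min == summary.p_median == summary.p_max

    def test_order_invariance_of_summaries(self, imps, rng):
        perm = rng.permutation(imps.m)
        shuffled = ImputationSet(
            completed_x=imps.completed_x[perm], mask=imps.mask, y=imps.y
        )
        a, b = diagnose(imps), diagnose(shuffled)
        assert a.p_min == b.p_min
        assert a.p_median == b.p_median
        assert a.p_max == b.p_max
        assert sorted(a.p_values) == sorted(b.p_values)

    def test_threshold_one_counts_everything_below_one(self, imps):
        summary = diagnose(imps, threshold=1.0)
        assert summary.prop_below == (summary.p_values < 1.0).mean()

    def test_no_missing_positions_signalled(self, rng):
        data = generate_dataset(GenerationConfig(n=100), rng)
        complete = impute_normal(impose_mcar(data, 0.001, rng), 3, rng)
        with pytest.raises(NoMissingDataError):
            diagnose(complete)

    def test_mcar_null_p_values_exceed_mar_strong(self):
        # The directional contrast behind the diagnostic's failure mode:
        # under MAR the imputed values *should* differ from the observed.
        mcar = ScenarioSpec.from_labels(0.0, 1000.0, "mcar", 0.2, reps=2, seed=3)
        mar = ScenarioSpec.from_labels(0.0, 1000.0, "mar-strong", 0.2, reps=2, seed=3)
        p_mcar = np.median([run_replicate(mcar, i).summary.p_median for i in range(60)])
        p_mar = np.median([run_replicate(mar, i).summary.p_median for i in range(60)])
        assert p_mar < 0.05 < p_mcar
        assert p_mcar / max(p_mar, 1e-300) > 100


class TestDiagnosePooled:
    def test_single_imputation_equals_per_imputation_test(self, rng):
        data = generate_dataset(GenerationConfig(n=200), rng)
        single = impute_normal(impose_mcar(data, 0.3, rng), 1, rng)
        pooled = diagnose_pooled(single)
        per_imp = ks_two_sample(single.x_observed, single.imputed_values(0))
        assert pooled.d_stat == per_imp.d_stat
        assert pooled.p_value == per_imp.p_value

    def test_pooled_sample_size_bookkeeping(self, imps):
        res = diagnose_pooled(imps)
        assert res.n_imp == imps.m * imps.mask.sum()
        assert res.n_obs == (~imps.mask).sum()

    def test_pooled_p_decreases_with_m_under_fixed_difference(self, rng):
        # A persistent location shift: more imputations inflate the pooled
        # sample and drive the single p-value down.
        n, n_mis = 200, 60
        x = rng.normal(size=n)
        mask = np.zeros(n, bool)
        mask[:n_mis] = True
        y = rng.normal(size=n)
        shifted = rng.normal(0.25, 1.0, size=n_mis)  # same draw reused per imputation
        p_by_m = []
        for m in (2, 10, 40):
            cx = np.tile(x, (m, 1))
            cx[:, mask] = shifted  # D fixed; pooled n_imp grows with m
            p_by_m.append(
                diagnose_pooled(ImputationSet(completed_x=cx, mask=mask, y=y)).p_value
            )
        assert p_by_m[0] > p_by_m[1] > p_by_m[2]


class TestStuartFlags:
    def test_identical_samples_unflagged(self, rng):
        x = rng.normal(size=100)
        assert stuart_flags(x, x.copy()) == (False, False)

    def test_three_sd_shift_flags_mean(self, rng):
        x = rng.normal(size=100)
        shifted = x + 3.0 * x.std(ddof=1)
        mean_flag, var_flag = stuart_flags(x, shifted)
        assert mean_flag and not var_flag

    def test_scale_change_flags_variance(self, rng):
        x = rng.normal(size=100)
        scaled = x.mean() + 1.5 * (x - x.mean())  # variance ratio 2.25
        mean_flag, var_flag = stuart_flags(x, scaled)
        assert var_flag and not mean_flag

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            stuart_flags([1.0], [1.0, 2.0])


class TestFlagExtreme:
    def test_single_minimum_flagged_at_ten_percent(self):
        p = {f"v{i}": 0.1 * (i + 1) for i in range(10)}
        assert flag_extreme(p, 0.10) == ["v0"]

    def test_full_fraction_flags_everything(self):
        p = {"a": 0.5, "b": 0.1}
        assert set(flag_extreme(p, 1.0)) == {"a", "b"}

    def test_hand_ranked_pair(self):
        p = {"a": 0.01, "b": 0.5, "c": 0.02, "d": 0.9}
        p.update({f"x{i}": 0.1 + 0.01 * i for i in range(6)})
        assert flag_extreme(p, 0.2) == ["a", "c"]

    def test_ties_broken_by_name(self):
        p = {"b": 0.05, "a": 0.05, "c": 0.9, "d": 0.9, "e": 0.9}
        assert flag_extreme(p, 0.2) == ["a"]

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            flag_extreme({}, 0.1)
        with pytest.raises(ValueError):
            flag_extreme({"a": 0.1}, 0.0)


def test_summary_prop_below_granularity():
    summary = DiagnosticSummary.from_p_values([0.01, 0.2, 0.6, 0.9], threshold=0.05)
    assert summary.prop_below == pytest.approx(0.25)
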