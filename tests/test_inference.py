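import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from ppsbound import (
    ConfigurationError,
    EstimationError,
    GeneratorParams,
    facilitation_test,
    newman_keuls,
    partial_eta_sq,
    rm_anova,
    simulate_cohort,
    studentized_range_cdf,
    studentized_range_ppf,
)
from ppsbound.geometry import LOOMING, MULTISENSORY


def long_frame(cube: np.ndarray) -> pd.DataFrame:
    n, a, b = cube.shape
    idx = pd.MultiIndex.from_product(
        [[f"s{i}" for i in range(n)], [f"a{i}" for i in range(a)], [f"b{i}" for i in range(b)]],
        names=["subject_id", "A", "B"],
    )
    return pd.Series(cube.ravel(), index=idx, name="y").reset_index()


def brute_force_ss(cube: np.ndarray) -> dict:
    """Independent sums-of-squares decomposition by explicit loops."""
    n, a, b = cube.shape
    gm = cube.mean()
    ss = {k: 0.0 for k in ("A", "B", "AB", "AS", "BS")}
    for i in range(a):
        ss["A"] += n * b * (cube[:, i, :].mean() - gm) ** 2
    for j in range(b):
        ss["B"] += n * a * (cube[:, :, j].mean() - gm) ** 2
    for i in range(a):
        for j in range(b):
            ss["AB"] += n * (
                cube[:, i, j].mean() - cube[:, i, :].mean() - cube[:, :, j].mean() + gm
            ) ** 2
    for s in range(n):
        for i in range(a):
            ss["AS"] += b * (
                cube[s, i, :].mean() - cube[:, i, :].mean() - cube[s].mean() + gm
            ) ** 2
        for j in range(b):
            ss["BS"] += a * (
                cube[s, :, j].mean() - cube[:, :, j].mean() - cube[s].mean() + gm
            ) ** 2
    ss_subj = sum(a * b * (cube[s].mean() - gm) ** 2 for s in range(n))
    ss_total = ((cube - gm) ** 2).sum()
    ss["ABS"] = ss_total - ss_subj - sum(ss[k] for k in ("A", "B", "AB", "AS", "BS"))
    return ss


class TestRmAnova:
    def test_toy_table_matches_hand_decomposition(self):
        cube = np.array(
            [[[3.0, 5.0], [7.0, 9.0]], [[2.0, 4.0], [9.0, 12.0]], [[4.0, 4.0], [8.0, 11.0]]]
        )  # 3 subjects x 2 x 2, integers
        ss = brute_force_ss(cube)
        res = rm_anova(long_frame(cube), dv="y", within=["A", "B"])
        n = 3
        expect = [
            ("A", ss["A"] / 1, ss["AS"] / (n - 1)),
            ("B", ss["B"] / 1, ss["BS"] / (n - 1)),
            ("A x B", ss["AB"] / 1, ss["ABS"] / (n - 1)),
        ]
        for r, (name, ms_eff, ms_err) in zip(res, expect):
            assert r.effect == name
            assert r.F == pytest.approx(ms_eff / ms_err, abs=1e-9)
            assert r.eta_p2 == pytest.approx(r.ss_effect / (r.ss_effect + r.ss_error), abs=1e-12)
            assert r.ss_effect == pytest.approx(ms_eff, abs=1e-9)  # df_num = 1 throughout

    def test_identical_cells_give_zero_f(self):
        cube = np.full((4, 2, 2), 7.0)
        for r in rm_anova(long_frame(cube), dv="y", within=["A", "B"]):
            assert r.F == 0.0 and r.ss_effect == 0.0

    def test_one_factor_two_levels_equals_paired_t_squared(self):
        rng = np.random.default_rng(5)
        x = rng.normal(500, 30, 12)
        y = x + rng.normal(20, 15, 12)
        df = pd.DataFrame(
            {
                "subject_id": np.repeat(np.arange(12), 2),
                "A": np.tile(["x", "y"], 12),
                "y": np.column_stack([x, y]).ravel(),
            }
        )
        res = rm_anova(df, dv="y", within=["A"])
        t, p = stats.ttest_rel(x, y)
        assert len(res) == 1
        assert res[0].F == pytest.approx(t**2, rel=1e-10)
        assert res[0].p == pytest.approx(p, rel=1e-9)
        assert res[0].df_num == 1 and res[0].df_den == 11

    def test_sum_of_squares_conservation(self):
        rng = np.random.default_rng(9)
        cube = rng.normal(0, 5, (7, 3, 4))
        res = rm_anova(long_frame(cube), dv="y", within=["A", "B"])
        gm = cube.mean()
        ss_subject = 3 * 4 * np.sum((cube.mean(axis=(1, 2)) - gm) ** 2)
        ss_total = np.sum((cube - gm) ** 2)
        parts = sum(r.ss_effect + r.ss_error for r in res) + ss_subject
        assert parts == pytest.approx(ss_total, rel=1e-9)

    def test_cross_check_against_reference_implementation(self):
        import warnings

        import pingouin as pg

        rng = np.random.default_rng(17)
        for _ in range(10):
            n, a, b = rng.integers(4, 9), rng.integers(2, 5), rng.integers(2, 4)
            cube = rng.normal(0, 5, (n, a, b)) + 8 * np.arange(a)[None, :, None]
            df = long_frame(cube)
            mine = rm_anova(df, dv="y", within=["A", "B"], subject="subject_id")
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ref = pg.rm_anova(data=df, dv="y", within=["A", "B"], subject="subject_id")
            for r, src in zip(mine, ["A", "B", "A * B"]):
                row = ref[ref.Source == src].iloc[0]
                assert r.F == pytest.approx(row["F"], rel=1e-8)
                assert r.p == pytest.approx(row["p_unc"], rel=1e-6, abs=1e-12)

    def test_gg_epsilon_matches_reference_for_main_effects(self):
        import warnings

        import pingouin as pg

        rng = np.random.default_rng(23)
        cube = rng.normal(0, 5, (9, 4, 3)) * np.array([1, 2, 4])[None, None, :]
        df = long_frame(cube)
        mine = rm_anova(df, dv="y", within=["A", "B"], correction="gg")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ref = pg.rm_anova(data=df, dv="y", within=["A", "B"], subject="subject_id")
        for r, src in zip(mine[:2], ["A", "B"]):
            assert r.eps == pytest.approx(float(ref[ref.Source == src].eps.iloc[0]), abs=1e-9)
            assert r.p_gg is not None and 0.0 < r.p_gg <= 1.0

    def test_incomplete_design_rejected(self):
        df = long_frame(np.zeros((3, 2, 2))).iloc[:-1]
        with pytest.raises(ConfigurationError, match="missing cells"):
            rm_anova(df, dv="y", within=["A", "B"])

    def test_single_subject_rejected(self):
        df = long_frame(np.zeros((2, 2, 2))).query("subject_id == 's0'")
        with pytest.raises(ConfigurationError, match="2 subjects"):
            rm_anova(df, dv="y", within=["A", "B"])


class TestPartialEtaSq:
    @pytest.mark.parametrize("ss_e,ss_r,expected", [(10, 30, 0.25), (0, 5, 0.0), (5, 0, 1.0)])
    def test_values(self, ss_e, ss_r, expected):
        assert partial_eta_sq(ss_e, ss_r) == pytest.approx(expected)

    def test_undefined_when_both_zero(self):
        with pytest.raises(EstimationError):
            partial_eta_sq(0.0, 0.0)


class TestStudentizedRange:
    def test_r2_reduces_to_paired_t_relation(self):
        for q in (0.5, 2.0, 3.5):
            lhs = studentized_range_cdf(q, 2, 10)
            rhs = 2 * stats.t.cdf(q / np.sqrt(2), 10) - 1
            assert lhs == pytest.approx(rhs, abs=1e-4)

    def test_tabulated_quantile(self):
        assert studentized_range_ppf(0.95, 3, 12) == pytest.approx(3.773, abs=0.005)

    def test_zero_and_errors(self):
        assert studentized_range_cdf(0.0, 3, 10) == 0.0
        with pytest.raises(ConfigurationError):
            studentized_range_cdf(1.0, 1, 10)
        with pytest.raises(ConfigurationError):
            studentized_range_cdf(1.0, 3, 0.5)
        with pytest.raises(ConfigurationError):
            studentized_range_ppf(1.5, 3, 10)


class TestNewmanKeuls:
    def test_two_means_match_t_type_decision(self):
        means = {"a": 500.0, "b": 540.0}
        for ms_error, n in ((400.0, 10), (4000.0, 4)):
            res = newman_keuls(means, n_per_mean=n, ms_error=ms_error, df_error=n - 1)
            q = 40.0 / np.sqrt(ms_error / n)
            expected = q > studentized_range_ppf(0.95, 2, n - 1)
            assert res[0].significant == expected

    def test_forced_pattern(self):
        res = newman_keuls(
            {"m1": 0.0, "m2": 0.0, "m3": 10.0}, n_per_mean=5, ms_error=1e-6, df_error=8
        )
        sig = {r.pair: r.significant for r in res}
        assert sig[("m1", "m3")] and sig[("m2", "m3")]
        assert not sig[("m1", "m2")]

    def test_unequal_n_rejected(self):
        with pytest.raises(ConfigurationError, match="n_per_mean|unequal"):
            newman_keuls({"a": 1.0, "b": 2.0}, n_per_mean=[5, 6], ms_error=1.0, df_error=9)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(
        means=st.lists(st.floats(min_value=-50, max_value=50), min_size=3, max_size=6),
        ms_error=st.floats(min_value=0.1, max_value=500.0),
    )
    def test_containment_rule(self, means, ms_error):
        labels = {f"m{i}": v for i, v in enumerate(means)}
        res = newman_keuls(labels, n_per_mean=8, ms_error=ms_error, df_error=14)
        order = sorted(labels, key=lambda k: (labels[k], k))
        pos = {lab: i for i, lab in enumerate(order)}
        spans = {(pos[r.pair[0]], pos[r.pair[1]]): r.significant for r in res}
        for (lo, hi), sig in spans.items():
            if not sig:
                for (l2, h2), s2 in spans.items():
                    if lo <= l2 and h2 <= hi and (l2, h2) != (lo, hi):
                        assert not s2, "pair nested in a non-significant span must be non-significant"

    def test_distance_gradient_posthoc_pattern(self):
        """Far distances (D1, D2) are slower than near ones (D3-D5) in most cohorts."""
        hits = 0
        n_runs = 20
        for seed in range(n_runs):
            trials = simulate_cohort(GeneratorParams(), seed=3000 + seed)
            loom = trials[(trials.modality == MULTISENSORY) & (trials.direction == LOOMING)]
            cell = (
                loom.groupby(["subject_id", "distance_label"], observed=True)["rt_ms"]
                .mean()
                .reset_index()
            )
            res = rm_anova(cell, dv="rt_ms", within=["distance_label"])
            means = cell.groupby("distance_label")["rt_ms"].mean().to_dict()
            nk = newman_keuls(
                means,
                n_per_mean=cell.subject_id.nunique(),
                ms_error=res[0].ms_error,
                df_error=res[0].df_den,
            )
            sig = {frozenset(r.pair): r.significant for r in nk}
            ok = all(
                sig[frozenset((far, near))]
                for far in ("D1", "D2")
                for near in ("D3", "D4", "D5")
            )
            hits += ok
        assert hits >= 0.9 * n_runs


class TestFacilitationTest:
    def test_identical_columns_give_zero_f(self):
        x = np.array([500.0, 520.0, 540.0])
        assert facilitation_test(x, x).F == 0.0

    def test_offset_matches_paired_t_squared(self):
        rng = np.random.default_rng(31)
        a = rng.normal(500, 25, 10)
        b = a + 10.0 + rng.normal(0, 5, 10)
        res = facilitation_test(a, b)
        t, p = stats.ttest_rel(a, b)
        assert res.F == pytest.approx(t**2, rel=1e-9)
        assert res.p == pytest.approx(p, rel=1e-9)

    def test_unpaired_rejected(self):
        with pytest.raises(ConfigurationError):
            facilitation_test([1.0, 2.0], [1.0, 2.0, 3.0])
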