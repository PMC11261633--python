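import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ais_mito_quant as amq
from ais_mito_quant.errors import ValidationError
from ais_mito_quant.stats import _mann_whitney


def long_table(rows):
    return pd.DataFrame(rows, columns=["fly_id", "hemisphere", "genotype", "age",
                                       "metric", "value"])


class TestCollapseReplicates:
    def test_hemispheres_average(self):
        t = long_table([
            ("f1", "L", "WT", "larva", "ratio", 1.0),
            ("f1", "R", "WT", "larva", "ratio", 3.0),
        ])
        out = amq.collapse_replicates(t)
        assert len(out) == 1
        assert out.loc[0, "value"] == 2.0

    def test_single_hemisphere_passes_through(self):
        t = long_table([("f1", "L", "WT", "larva", "ratio", 1.7)])
        out = amq.collapse_replicates(t)
        assert out.loc[0, "value"] == 1.7

    def test_three_flies_two_hemispheres_give_three_rows(self):
        rows = [
            (f"f{i}", h, "WT", "larva", "ratio", float(i))
            for i in range(3) for h in ("L", "R")
        ]
        assert len(amq.collapse_replicates(long_table(rows))) == 3

    def test_duplicate_replicates_rejected(self):
        t = long_table([
            ("f1", "L", "WT", "larva", "ratio", 1.0),
            ("f1", "L", "WT", "larva", "ratio", 2.0),
        ])
        with pytest.raises(ValidationError, match="duplicate"):
            amq.collapse_replicates(t)

    def test_collapse_is_idempotent(self):
        t = long_table([
            ("f1", "L", "WT", "larva", "ratio", 1.0),
            ("f1", "R", "WT", "larva", "ratio", 3.0),
            ("f2", "L", "WT", "larva", "ratio", 5.0),
        ])
        once = amq.collapse_replicates(t)
        again = amq.collapse_replicates(once.assign(hemisphere="pooled"))
        pd.testing.assert_frame_equal(
            once.sort_values("fly_id").reset_index(drop=True),
            again[once.columns].sort_values("fly_id").reset_index(drop=True),
        )


class TestNormality:
    def test_normal_samples_usually_pass(self):
        rng = np.random.default_rng(0)
        passes = sum(
            amq.normality_check(rng.normal(size=500)) > 0.05 for _ in range(100)
        )
        assert passes >= 90

    def test_exponential_samples_usually_fail(self):
        rng = np.random.default_rng(1)
        fails = sum(
            amq.normality_check(rng.exponential(size=500)) < 0.05 for _ in range(100)
        )
        assert fails >= 90

    def test_constant_sample_is_degenerate(self):
        assert amq.normality_check([2.0, 2.0, 2.0, 2.0]) == 0.0

    def test_needs_three_values(self):
        with pytest.raises(ValidationError):
            amq.normality_check([1.0, 2.0])


class TestTwoGroups:
    def test_identical_groups_give_t_zero_p_one(self):
        r = amq.compare_two_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert "t-test" in r.test_name
        assert r.statistic == pytest.approx(0.0)
        assert r.p_value == pytest.approx(1.0)

    def test_mann_whitney_exact_matches_enumeration(self):
        u, p, method = _mann_whitney(np.array([1.0, 2.0]), np.array([3.0, 4.0]))
        assert method == "exact"
        assert u == 0.0
        assert p == pytest.approx(1.0 / 3.0, abs=1e-12)

        # enumeration oracle over all 6 assignments of ranks {1..4} to group A
        values = [1.0, 2.0, 3.0, 4.0]
        e_u = 2.0  # n1*n2/2
        obs = abs(0.0 - e_u)
        hits = 0
        for combo in itertools.combinations(range(4), 2):
            a = [values[i] for i in combo]
            b = [values[i] for i in range(4) if i not in combo]
            u_c = sum(ai > bj for ai in a for bj in b)
            hits += abs(u_c - e_u) >= obs
        assert hits / 6 == pytest.approx(p)

    def test_swapping_groups_flips_statistic_keeps_p(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0.0, 1.0, size=12)
        b = rng.normal(1.0, 1.0, size=12)
        r1 = amq.compare_two_groups(a, b, labels=("a", "b"))
        r2 = amq.compare_two_groups(b, a, labels=("b", "a"))
        assert r1.statistic == pytest.approx(-r2.statistic)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_skewed_data_takes_mann_whitney_branch(self):
        rng = np.random.default_rng(4)
        a = rng.exponential(size=40) ** 3
        b = rng.exponential(size=40) ** 3
        r = amq.compare_two_groups(a, b)
        assert "Mann-Whitney" in r.test_name
        assert "normality failed" in r.decision_path

    def test_unequal_variances_switch_to_welch(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0, 1.0, size=30)
        b = rng.normal(0, 6.0, size=30)
        r = amq.compare_two_groups(a, b)
        if "t-test" in r.test_name:  # normality gate permitting
            assert "Welch" in r.test_name

    def test_small_groups_rejected(self):
        with pytest.raises(ValidationError):
            amq.compare_two_groups([1.0, 2.0], [3.0, 4.0])


class TestSidak:
    def test_forced_arithmetic(self):
        assert amq.sidak_adjust(0.05, 2) == pytest.approx(0.0975)

    def test_single_comparison_is_identity(self):
        assert amq.sidak_adjust(0.2, 1) == pytest.approx(0.2)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        p=st.floats(min_value=0.0, max_value=1.0),
        m=st.integers(min_value=1, max_value=20),
    )
    def test_monotone_in_p_and_m(self, p, m):
        adj = amq.sidak_adjust(p, m)
        assert adj >= p - 1e-15
        assert adj <= amq.sidak_adjust(min(1.0, p + 0.01), m) + 1e-12
        assert adj <= amq.sidak_adjust(p, m + 1) + 1e-15


def two_way_table(rng, cell_means, n_per_cell=8, sd=1.0):
    rows = []
    i = 0
    for (g, a), mu in cell_means.items():
        n = n_per_cell[(g, a)] if isinstance(n_per_cell, dict) else n_per_cell
        for _ in range(n):
            rows.append({"fly_id": f"f{i}", "genotype": g, "age": a,
                         "value": rng.normal(mu, sd)})
            i += 1
    return pd.DataFrame(rows)


class TestTwoWay:
    CELLS = [("WT", "d10"), ("WT", "d30"), ("KO", "d10"), ("KO", "d30")]

    def test_null_data_shows_no_significance(self):
        rng = np.random.default_rng(6)
        df = two_way_table(rng, {c: 5.0 for c in self.CELLS}, n_per_cell=10, sd=0.01)
        results = amq.compare_two_way(df, metric="ratio")
        assert all(r.adjusted_p > 0.05 for r in results)

    def test_sidak_applied_to_contrasts(self):
        rng = np.random.default_rng(7)
        df = two_way_table(rng, {c: 1.0 for c in self.CELLS})
        results = amq.compare_two_way(df)
        contrasts = [r for r in results if "|" in r.contrast]
        assert len(contrasts) == 2  # one genotype pair within each age
        for r in contrasts:
            assert r.adjusted_p == pytest.approx(amq.sidak_adjust(r.p_value, 2))

    def test_genotype_shift_detected_with_high_power(self):
        rng = np.random.default_rng(8)
        hits = 0
        for _ in range(100):
            df = two_way_table(
                rng,
                {("WT", "d10"): 0.0, ("WT", "d30"): 0.0,
                 ("KO", "d10"): 1.0, ("KO", "d30"): 1.0},
                n_per_cell=50,
            )
            results = {r.contrast: r for r in amq.compare_two_way(df)}
            hits += results["main:genotype"].p_value < 0.05
        assert hits >= 95

    def test_empty_cell_named_in_error(self):
        rng = np.random.default_rng(9)
        df = two_way_table(rng, {c: 1.0 for c in self.CELLS})
        df = df[~((df.genotype == "KO") & (df.age == "d30"))]
        with pytest.raises(ValidationError, match="KO.*d30"):
            amq.compare_two_way(df)

    def test_unbalanced_design_independent_of_factor_order(self):
        rng = np.random.default_rng(10)
        df = two_way_table(
            rng,
            {("WT", "d10"): 0.0, ("WT", "d30"): 0.4,
             ("KO", "d10"): 0.8, ("KO", "d30"): 1.0},
            n_per_cell={("WT", "d10"): 24, ("WT", "d30"): 14,
                        ("KO", "d10"): 8, ("KO", "d30"): 7},
        )
        r_ga = {r.contrast: r for r in amq.compare_two_way(df, factors=("genotype", "age"))}
        r_ag = {r.contrast: r for r in amq.compare_two_way(df, factors=("age", "genotype"))}
        assert r_ga["main:genotype"].p_value == pytest.approx(
            r_ag["main:genotype"].p_value, rel=1e-9
        )
        assert r_ga["main:age"].p_value == pytest.approx(
            r_ag["main:age"].p_value, rel=1e-9
        )
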