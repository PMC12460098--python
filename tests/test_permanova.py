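"""Distance-based ANOVA partition, permutation tests, pooling, pairwise."""

import itertools

import numpy as np
import pandas as pd
import pytest

from pensonar import (
    Design,
    Factor,
    count_unique_permutations,
    pairwise,
    partition,
    permanova,
    pmc_value,
    pool_terms,
    total_ss,
)
from pensonar.errors import DegenerateDesignError, DegenerateTestError
from pensonar.permanova import _euclidean_D


def one_factor_table(groups):
    rows = [{"g": name, "y": v} for name, vals in groups.items() for v in vals]
    return pd.DataFrame(rows)


ONE_FACTOR = Design(factors=(Factor("g"),), terms=(("g",),), response="y")


class TestTotalSS:
    def test_hand_computed_value(self):
        D = _euclidean_D(np.arange(1.0, 7.0))
        assert total_ss(D) == pytest.approx(17.5)

    def test_constant_response_is_zero(self):
        assert total_ss(_euclidean_D(np.full(5, 3.0))) == pytest.approx(0.0)

    def test_duplicating_observations_doubles_ss(self):
        y = np.array([1.0, 4.0, 2.0, 8.0])
        ss1 = total_ss(_euclidean_D(y))
        ss2 = total_ss(_euclidean_D(np.r_[y, y]))
        assert ss2 == pytest.approx(2 * ss1)

    def test_asymmetric_matrix_rejected(self):
        D = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError):
            total_ss(D)


class TestPartition:
    def test_one_factor_classical_values(self):
        tab = one_factor_table({"a": [1, 2, 3], "b": [4, 5, 6]})
        res = partition(tab, ONE_FACTOR)
        assert res.table.loc[0, "ss"] == pytest.approx(13.5)
        assert res.residual_ss == pytest.approx(4.0)
        assert res.table.loc[0, "ss"] / res.residual_ms == pytest.approx(13.5 * 4 / 4)

    def test_cellwise_constant_response_has_zero_residual(self):
        tab = pd.DataFrame(
            {
                "a": ["x", "x", "y", "y"] * 2,
                "b": ["u"] * 4 + ["v"] * 4,
                "y": [1.0, 1.0, 2.0, 2.0, 5.0, 5.0, 3.0, 3.0],
            }
        )
        design = Design(
            factors=(Factor("a"), Factor("b")),
            terms=(("a",), ("b",), ("a", "b")),
            response="y",
        )
        res = partition(tab, design)
        assert res.residual_ss == pytest.approx(0.0, abs=1e-10)

    def test_three_factor_additivity_on_random_tables(self):
        rng = np.random.default_rng(0)
        levels = dict(a=list("xy"), b=list("uvw"), c=list("pq"))
        rows = [
            dict(a=a, b=b, c=c, y=rng.normal())
            for a, b, c in itertools.product(*levels.values())
            for _ in range(3)
        ]
        tab = pd.DataFrame(rows)
        design = Design.full_factorial(
            [Factor("a"), Factor("b"), Factor("c")], response="y"
        )
        res = partition(tab, design)
        assert res.table["ss"].sum() + res.residual_ss == pytest.approx(
            res.total_ss, rel=1e-10
        )

    def test_empty_interaction_cell_rejected(self):
        tab = pd.DataFrame(
            {"a": ["x", "x", "y", "y"], "b": ["u", "u", "u", "u"], "y": [1.0, 2, 3, 4]}
        )
        design = Design(
            factors=(Factor("a"), Factor("b")), terms=(("a", "b"),), response="y"
        )
        with pytest.raises(DegenerateDesignError):
            partition(tab, design)


class TestPseudoFEquivalence:
    """Pseudo-F from the distance partition must equal classical ANOVA F."""

    @pytest.mark.parametrize("n_factors", [1, 2, 3])
    def test_matches_statsmodels_on_random_balanced_tables(self, n_factors):
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        rng = np.random.default_rng(n_factors)
        names = ["a", "b", "c"][:n_factors]
        levels = {"a": list("xyz"), "b": list("uv"), "c": list("pq")}
        combos = list(itertools.product(*[levels[n] for n in names]))
        rows = [
            dict(**dict(zip(names, combo)), y=rng.normal()) for combo in combos for _ in range(3)
        ]
        tab = pd.DataFrame(rows)
        design = Design.full_factorial([Factor(n) for n in names], response="y")
        mine = permanova(tab, design, n_perm=19, seed=0)

        formula = "y ~ " + " * ".join(f"C({n})" for n in names)
        sm_tab = anova_lm(smf.ols(formula, tab).fit())
        sm_ms = sm_tab["sum_sq"] / sm_tab["df"]
        resid_ms = sm_ms["Residual"]
        for _, row in mine.table.iterrows():
            label = ":".join(f"C({f})" for f in row["term"].split(":"))
            assert row["ss"] == pytest.approx(sm_tab.loc[label, "sum_sq"], rel=1e-8)
            assert row["F"] == pytest.approx(sm_ms[label] / resid_ms, rel=1e-8)

    def test_mixed_design_uses_interaction_denominator(self):
        rng = np.random.default_rng(5)
        rows = [
            dict(Timing=t, Pen=p, y=rng.normal())
            for t in ("before", "during", "after")
            for p in ("A", "B")
            for _ in range(4)
        ]
        tab = pd.DataFrame(rows)
        design = Design(
            factors=(Factor("Timing"), Factor("Pen", "random")),
            terms=(("Timing",), ("Pen",), ("Timing", "Pen")),
            response="y",
        )
        res = permanova(tab, design, n_perm=19, seed=0)
        by_term = res.table.set_index("term")
        # EMS: fixed Timing over MS(Timing:Pen); random Pen over residual
        assert by_term.loc["Timing", "denominator"] == "Timing:Pen"
        assert by_term.loc["Pen", "denominator"] == "residual"
        expect = by_term.loc["Timing", "ms"] / by_term.loc["Timing:Pen", "ms"]
        assert by_term.loc["Timing", "F"] == pytest.approx(expect, rel=1e-10)


class TestPermutationTests:
    def test_exhaustive_two_group_p(self):
        tab = one_factor_table({"a": [1, 2, 3], "b": [4, 5, 6]})
        res = permanova(tab, ONE_FACTOR, method="exact")
        assert res.table.loc[0, "p_perm"] == pytest.approx(2 / 20)
        assert res.table.loc[0, "n_unique"] == 20

    def test_exhaustive_matches_direct_enumeration(self):
        # independent oracle: direct F over all assignments of 4+4 labels
        rng = np.random.default_rng(3)
        y = rng.normal(size=8)
        tab = pd.DataFrame({"g": ["a"] * 4 + ["b"] * 4, "y": y})
        res = permanova(tab, ONE_FACTOR, method="exact")

        def f_stat(mask):
            a, b = y[mask], y[~mask]
            ssb = len(a) * (a.mean() - y.mean()) ** 2 + len(b) * (b.mean() - y.mean()) ** 2
            ssw = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
            return (ssb / 1) / (ssw / 6)

        obs = f_stat(np.array([True] * 4 + [False] * 4))
        count = 0
        combos = list(itertools.combinations(range(8), 4))
        for idx in combos:
            mask = np.zeros(8, bool)
            mask[list(idx)] = True
            if f_stat(mask) >= obs * (1 - 1e-9):
                count += 1
        assert res.table.loc[0, "p_perm"] == pytest.approx(count / len(combos))

    def test_row_order_invariance_of_observed_f(self):
        tab = one_factor_table({"a": [1.0, 5, 2], "b": [7.0, 3, 8], "c": [2.0, 9, 4]})
        res1 = permanova(tab, ONE_FACTOR, n_perm=99, seed=1)
        shuffled = tab.sample(frac=1.0, random_state=7).reset_index(drop=True)
        res2 = permanova(shuffled, ONE_FACTOR, n_perm=99, seed=1)
        assert res1.table.loc[0, "F"] == pytest.approx(res2.table.loc[0, "F"])

    def test_p_perm_bounds_and_seed_determinism(self):
        rng = np.random.default_rng(0)
        tab = one_factor_table({"a": rng.normal(size=6), "b": rng.normal(size=6)})
        r1 = permanova(tab, ONE_FACTOR, n_perm=99, seed=11)
        r2 = permanova(tab, ONE_FACTOR, n_perm=99, seed=11)
        p = r1.table.loc[0, "p_perm"]
        assert 1 / 100 <= p <= 1.0
        assert p == r2.table.loc[0, "p_perm"]

    def test_power_monotone_in_effect_size(self):
        rng = np.random.default_rng(1)
        rejections = []
        for effect in (0.0, 1.0, 2.5):
            hits = 0
            for _ in range(40):
                y0 = rng.normal(size=18)
                y0[6:12] += effect
                tab = pd.DataFrame({"g": ["a"] * 6 + ["b"] * 6 + ["c"] * 6, "y": y0})
                res = permanova(tab, ONE_FACTOR, n_perm=199, seed=int(rng.integers(2**31)))
                hits += res.table.loc[0, "p_perm"] <= 0.05
            rejections.append(hits)
        assert rejections[0] <= rejections[1] <= rejections[2]
        assert rejections[2] > rejections[0]


class TestUniquePermutationsAndPMC:
    @pytest.mark.parametrize(
        "sizes,expected", [((3, 3), 20), ((6,), 1), ((1, 5), 6)]
    )
    def test_multinomial_counts(self, sizes, expected):
        groups = {f"g{i}": [0.0] * s for i, s in enumerate(sizes)}
        tab = one_factor_table(groups)
        assert count_unique_permutations(ONE_FACTOR, ("g",), tab) == expected

    def test_f_median_symmetry(self):
        assert pmc_value(1.0, 3, 3) == pytest.approx(0.5)

    def test_matches_numerical_integration(self):
        from scipy.integrate import quad
        from scipy.special import beta as beta_fn

        df1, df2, F = 1, 4, 13.5

        def density(x):
            return (
                (df1 / df2) ** (df1 / 2)
                * x ** (df1 / 2 - 1)
                * (1 + df1 * x / df2) ** (-(df1 + df2) / 2)
                / beta_fn(df1 / 2, df2 / 2)
            )

        oracle, _ = quad(density, F, np.inf)
        assert pmc_value(F, df1, df2) == pytest.approx(oracle, abs=1e-10)

    def test_tail_monotone_in_f(self):
        ps = [pmc_value(f, 2, 10) for f in (0.5, 1.0, 2.0, 5.0)]
        assert ps == sorted(ps, reverse=True)


class TestPooling:
    @pytest.fixture
    def mixed_table(self):
        rng = np.random.default_rng(4)
        rows = [
            dict(Timing=t, Pen=p, y=rng.normal() + 3.0 * (t == "during"))
            for t in ("before", "during", "after")
            for p in ("A", "B")
            for _ in range(4)
        ]
        return pd.DataFrame(rows)

    def test_nonsignificant_interaction_pools_into_residual(self, mixed_table):
        design = Design(
            factors=(Factor("Timing"), Factor("Pen", "random")),
            terms=(("Timing",), ("Pen",), ("Timing", "Pen")),
            response="y",
        )
        res = permanova(mixed_table, design, n_perm=499, seed=0)
        pooled, pooled_design = pool_terms(res, mixed_table, design, threshold=0.25, seed=0)
        dropped = {e["term"] for e in pooled.pooling_log}
        assert dropped  # the pure-noise terms leave the model
        assert ("Timing",) in pooled_design.terms  # the real effect stays
        dropped_df = sum(e["df"] for e in pooled.pooling_log)
        assert pooled.residual_df == res.residual_df + dropped_df

    def test_significant_terms_retained(self, mixed_table):
        design = Design(factors=(Factor("Timing"), Factor("Pen", "random")),
                        terms=(("Timing",), ("Pen",), ("Timing", "Pen")), response="y")
        res = permanova(mixed_table, design, n_perm=499, seed=0)
        pooled, pooled_design = pool_terms(res, mixed_table, design, threshold=0.25, seed=0)
        assert all(e["p_perm"] >= 0.25 for e in pooled.pooling_log)

    def test_additivity_preserved_after_pooling(self, mixed_table):
        design = Design(factors=(Factor("Timing"), Factor("Pen", "random")),
                        terms=(("Timing",), ("Pen",), ("Timing", "Pen")), response="y")
        res = permanova(mixed_table, design, n_perm=199, seed=0)
        pooled, _ = pool_terms(res, mixed_table, design, threshold=0.25, seed=0)
        assert pooled.table["ss"].sum() + pooled.residual_ss == pytest.approx(
            pooled.total_ss, rel=1e-10
        )


class TestPairwise:
    def test_identical_groups_give_t_zero_p_one(self):
        tab = one_factor_table({"a": [2.0, 2.0, 2.0], "b": [2.0, 2.0, 2.0]})
        res = pairwise(tab, "g", n_perm=99, seed=0, design=ONE_FACTOR)
        row = res.table.iloc[0]
        assert row["t"] == 0.0 and row["p_perm"] == 1.0

    def test_two_group_t_and_exact_p(self):
        tab = one_factor_table({"a": [1, 2, 3], "b": [4, 5, 6]})
        res = pairwise(tab, "g", seed=0, design=ONE_FACTOR, method="exact")
        row = res.table.iloc[0]
        assert row["t"] == pytest.approx(np.sqrt(13.5))
        assert row["p_perm"] == pytest.approx(0.1)

    def test_two_level_factor_pairwise_equals_omnibus(self):
        rng = np.random.default_rng(4)
        tab = one_factor_table({"a": rng.normal(size=5), "b": rng.normal(size=5) + 1})
        omnibus = permanova(tab, ONE_FACTOR, n_perm=199, seed=9)
        pw = pairwise(tab, "g", n_perm=199, seed=9, design=ONE_FACTOR)
        assert pw.table.iloc[0]["p_perm"] == omnibus.table.loc[0, "p_perm"]
        assert pw.table.iloc[0]["F"] == pytest.approx(omnibus.table.loc[0, "F"])

    def test_undersized_level_rejected(self):
        tab = one_factor_table({"a": [1.0], "b": [2.0, 3.0]})
        with pytest.raises(DegenerateTestError):
            pairwise(tab, "g", n_perm=99, seed=0, design=ONE_FACTOR)
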