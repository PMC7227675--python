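"""Unimportance Index: dominant rules, prevalence, median ranges, UI, selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import garpselect as g
from garpselect.garp import BestSubset, GarpModelResult, GarpRuleset, ModelEvaluation
from garpselect.grids import GridSpec, Landscape
from garpselect.rules import Rule
from garpselect.ui import (
    DominantRule,
    DominantRuleSet,
    dominant_presence_rules,
    lowest_k,
    median_range,
    prevalence,
    rescale_ui,
    rule_bounds,
    scaled_median_range,
    select_variables,
    unimportance_index,
    variable_contributions,
)


def _member(rules, rule_index, names, omission=0.0):
    """Model result with a hand-built deciding-rule-index raster."""
    rule_index = np.asarray(rule_index, dtype=np.int32)
    cons = np.array([r.consequent for r in rules], dtype=np.int8)
    binary = np.where(rule_index >= 0, cons[np.clip(rule_index, 0, None)], 0).astype(np.uint8)
    est = GarpRuleset()
    est.rules_ = rules
    est.feature_names_ = list(names)
    est._name_to_col = {n: j for j, n in enumerate(names)}
    commission = 100.0 * float(binary.mean())
    return GarpModelResult(est, ModelEvaluation(omission, commission), binary, rule_index)


def _best_with_coverages(coverages, names=("t",)):
    """One-model BestSubset whose presence rules decide given cell shares."""
    n_cells = 100
    rules = [
        Rule("range", 1, tuple(names), lower=np.array([-(i + 1.0)] * len(names)),
             upper=np.array([i + 1.0] * len(names)))
        for i in range(len(coverages))
    ]
    idx = np.full(n_cells, -1, dtype=np.int32)
    pos = 0
    for i, cov in enumerate(coverages):
        k = int(round(cov * n_cells))
        idx[pos:pos + k] = i
        pos += k
    member = _member(rules, idx.reshape(10, 10), names)
    return BestSubset(members=[member], agreement=member.binary.astype(np.int32),
                      median_commission=0.0)


class TestDominantRules:
    def test_prefix_rule_with_strict_inequality(self):
        best = _best_with_coverages([0.50, 0.30, 0.15, 0.05])
        dom = dominant_presence_rules(best)
        assert len(dom) == 3  # 0.95 > 0.90 after three rules
        assert dom.cumulative_coverage == pytest.approx(0.95)

    def test_single_total_coverage_rule(self):
        dom = dominant_presence_rules(_best_with_coverages([1.0]))
        assert len(dom) == 1

    def test_exact_ninety_percent_is_not_enough(self):
        dom = dominant_presence_rules(_best_with_coverages([0.90, 0.10]))
        assert len(dom) == 2  # 0.90 is not > 0.90

    def test_no_presence_anywhere_raises(self):
        rules = [Rule("range", 0, ("t",), lower=np.array([0.0]), upper=np.array([1.0]))]
        member = _member(rules, np.zeros((10, 10), dtype=int), ("t",))
        best = BestSubset([member], np.zeros((10, 10), dtype=np.int32), 0.0)
        with pytest.raises(ValueError, match="presence nowhere"):
            dominant_presence_rules(best)

    def test_pooled_across_models(self):
        a = _best_with_coverages([1.0]).members[0]
        b = _best_with_coverages([1.0]).members[0]
        best = BestSubset([a, b], a.binary.astype(np.int32) * 2, 0.0)
        dom = dominant_presence_rules(best)
        assert len(dom) == 2  # each model contributes half the decisions


class TestPrevalence:
    def _dom(self, var_lists):
        rules = [
            DominantRule(0, i, Rule("range", 1, tuple(vs),
                                    lower=np.zeros(len(vs)), upper=np.ones(len(vs))),
                         1.0 / len(var_lists))
            for i, vs in enumerate(var_lists)
        ]
        return DominantRuleSet(rules, 1.0)

    def test_direct_fractions(self):
        dom = self._dom([("a",)] * 10)
        assert prevalence("a", dom) == 1.0
        assert prevalence("b", dom) == 0.0
        dom = self._dom([("a", "b")] * 3 + [("b",)] * 9)
        assert prevalence("a", dom) == pytest.approx(3 / 12)


class TestBounds:
    grid = GridSpec(n_rows=2, n_cols=3, resolution=1.0)
    land = Landscape(grid, {"t": np.array([[8.0, 10.0, 14.0], [9.0, 11.0, 13.0]])})

    def test_range_rule_returns_stored_bounds(self):
        rule = Rule("range", 1, ("t",), lower=np.array([10.2]), upper=np.array([13.5]))
        e = DominantRule(0, 0, rule, 1.0)
        best = BestSubset([_member([rule], np.zeros((2, 3), int), ("t",))],
                          np.zeros((2, 3), np.int32), 0.0)
        assert rule_bounds(e, "t", best, self.land) == (10.2, 13.5, False)

    def test_logit_rule_uses_zonal_min_max(self):
        rule = Rule("logit", 1, ("t",), coefficients=np.array([1.0]), intercept=0.0)
        idx = np.array([[0, 0, -1], [0, -1, 0]])  # decides 4 cells: t = 8, 10, 9, 13
        member = _member([rule], idx, ("t",))
        best = BestSubset([member], member.binary.astype(np.int32), 0.0)
        e = DominantRule(0, 0, rule, 1.0)
        assert rule_bounds(e, "t", best, self.land) == (8.0, 13.0, False)

    def test_logit_rule_with_no_deciding_cells_is_undefined(self):
        rule = Rule("logit", 1, ("t",), coefficients=np.array([1.0]), intercept=0.0)
        member = _member([rule], np.full((2, 3), -1, int), ("t",))
        best = BestSubset([member], member.binary.astype(np.int32), 0.0)
        assert rule_bounds(DominantRule(0, 0, rule, 1.0), "t", best, self.land) is None

    def test_atomic_rule_is_a_point(self):
        rule = Rule("atomic", 1, ("t",), atoms=np.array([12.5]))
        member = _member([rule], np.zeros((2, 3), int), ("t",))
        best = BestSubset([member], member.binary.astype(np.int32), 0.0)
        assert rule_bounds(DominantRule(0, 0, rule, 1.0), "t", best, self.land) == (
            12.5, 12.5, True)


class TestMedianRange:
    grid = GridSpec(n_rows=1, n_cols=2, resolution=1.0)
    land = Landscape(grid, {"t": np.array([[0.0, 36.0]])})

    def _dom_with_bounds(self, bounds):
        rules, entries = [], []
        for i, (lo, hi) in enumerate(bounds):
            r = Rule("range", 1, ("t",), lower=np.array([lo]), upper=np.array([hi]))
            rules.append(r)
            entries.append(DominantRule(0, i, r, 1.0 / len(bounds)))
        member = _member(rules, np.zeros((1, 2), int), ("t",))
        best = BestSubset([member], member.binary.astype(np.int32), 0.0)
        return DominantRuleSet(entries, 1.0), best

    def test_median_of_bounds(self):
        dom, best = self._dom_with_bounds([(10, 20), (12, 18), (11, 25)])
        assert median_range("t", dom, best, self.land) == pytest.approx(9.0)

    def test_single_and_identical_rules(self):
        dom, best = self._dom_with_bounds([(0, 1)])
        assert median_range("t", dom, best, self.land) == 1.0
        dom, best = self._dom_with_bounds([(3, 7)] * 5)
        assert median_range("t", dom, best, self.land) == 4.0

    def test_absent_covariate_is_undefined(self):
        dom, best = self._dom_with_bounds([(0, 1)])
        with pytest.raises(ValueError):
            median_range("other", dom, best, self.land)

    def test_scaling_by_landscape_range(self):
        assert scaled_median_range("t", 9.0, self.land) == pytest.approx(0.25)
        assert scaled_median_range("t", 36.0, self.land) == 1.0
        assert scaled_median_range("t", 0.0, self.land) == 0.0
        assert scaled_median_range("t", 72.0, self.land) == 1.0  # clipped

    def test_constant_covariate_rejected(self):
        flat = Landscape(self.grid, {"t": np.zeros((1, 2))})
        with pytest.raises(ValueError, match="constant"):
            scaled_median_range("t", 1.0, flat)


class TestIndex:
    @pytest.mark.parametrize(
        "prev, srange, expected",
        [(1.0, 0.7, 0.0), (0.25, 0.4, 0.3), (0.0, 1.0, 1.0)],
    )
    def test_formula(self, prev, srange, expected):
        assert unimportance_index(prev, srange) == pytest.approx(expected)

    def test_rescale(self):
        np.testing.assert_allclose(rescale_ui([0.1, 0.3, 0.5]), [0.0, 0.5, 1.0])

    def test_rescale_degenerate_warns_and_zeroes(self):
        with pytest.warns(UserWarning, match="equal"):
            out = rescale_ui([0.2, 0.2, 0.2])
        np.testing.assert_array_equal(out, 0.0)

    @given(st.lists(st.floats(0, 1), min_size=2, max_size=10, unique=True),
           st.floats(0.01, 100), st.floats(-10, 10))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_rescale_affine_invariance(self, uis, a, b):
        """Rescaled UI is unchanged by positive affine maps of the raw UIs."""
        from hypothesis import assume

        uis = np.array(uis)
        assume(uis.max() - uis.min() > 1e-9)  # non-degenerate after scaling
        np.testing.assert_allclose(rescale_ui(uis), rescale_ui(a * uis + b), atol=1e-9)

    @given(st.floats(0, 1), st.floats(0, 1), st.floats(0, 1))
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_monotonicity(self, prev, s1, s2):
        """UI increases with scaled range and decreases with prevalence."""
        lo_s, hi_s = sorted([s1, s2])
        assert unimportance_index(prev, lo_s) <= unimportance_index(prev, hi_s)
        lo_p, hi_p = sorted([prev, s1])
        assert unimportance_index(hi_p, s2) <= unimportance_index(lo_p, s2)


class TestSelection:
    table = pd.DataFrame({
        "covariate": ["a", "b", "c"],
        "ui": [0.1, 0.3, 0.5],
        "rescaled_ui": [0.0, 0.5, 1.0],
        "rank": [1, 2, 3],
    })

    def test_strict_threshold(self):
        assert select_variables(self.table, 0.5) == ["a"]
        assert select_variables(self.table, 0.51) == ["a", "b"]
        # the maximum rescaled UI (1.0) is excluded at threshold 1.0 ...
        assert select_variables(self.table, 1.0) == ["a", "b"]
        # ... and included just above it
        assert select_variables(self.table, 1.0 + 1e-9) == ["a", "b", "c"]

    def test_empty_selection_falls_back_to_lowest(self):
        with pytest.warns(UserWarning, match="lowest-UI"):
            assert select_variables(self.table, 0.0) == ["a"]

    def test_lowest_k(self):
        assert lowest_k(self.table, 2) == ["a", "b"]


class TestContributionsPipeline:
    def test_unreferenced_covariate_is_maximally_unimportant(self):
        grid = GridSpec(n_rows=10, n_cols=10, resolution=1.0)
        rng = np.random.default_rng(0)
        land = Landscape(grid, {"used": rng.normal(size=(10, 10)),
                                "unused": rng.normal(size=(10, 10))})
        rule = Rule("range", 1, ("used",), lower=np.array([-0.5]), upper=np.array([0.5]))
        member = _member([rule], np.zeros((10, 10), int), ["used", "unused"])
        best = BestSubset([member], member.binary.astype(np.int32), 0.0)
        table = variable_contributions(best, land).set_index("covariate")
        assert table.loc["unused", "prevalence"] == 0.0
        assert table.loc["unused", "scaled_median_range"] == 1.0
        assert table.loc["unused", "ui"] == 1.0
        assert table.loc["unused", "rank"] == 2
        assert table.loc["used", "rank"] == 1

    def test_rank_is_a_permutation(self, separable_best, land_small):
        table = variable_contributions(separable_best, land_small)
        assert sorted(table["rank"]) == list(range(1, land_small.n_covariates + 1))
        assert table["rescaled_ui"].min() == 0.0
        assert table["rescaled_ui"].max() == 1.0

    def test_separable_species_driver_ranks_first(self, separable_best, land_small,
                                                  separable_species):
        table = variable_contributions(separable_best, land_small)
        top = table.loc[table["rank"] == 1, "covariate"].item()
        assert top == separable_species["variable"]


@pytest.mark.timeout(600)
def test_true_drivers_get_lower_ui_than_decoys():
    """Parameter recovery: over 30 strong-scenario species on the desk-scale
    study landscape, the three true covariates have lower mean rescaled UI
    than the seven decoys (one-sided Wilcoxon p < 0.05)."""
    from scipy.stats import wilcoxon

    land = g.simulate_landscape(g.default_grid(desk_scale=True), seed=2024)
    diffs = []
    master = np.random.SeedSequence(2024)
    for child in master.spawn(30):
        sp_ss, model_ss = child.spawn(2)
        sp = g.simulate_species(land, g.STRONG, sp_ss)
        results = g.run_experiment(sp.presences, land, n_models=15, seed=model_ss,
                                   max_iter=50)
        best = g.best_subset(results, n_low_omission=15, n_best=8)
        table = g.variable_contributions(best, land).set_index("covariate")
        true_ui = table.loc[sp.true_vars, "rescaled_ui"].mean()
        decoys = [n for n in land.names if n not in sp.true_vars]
        diffs.append(true_ui - table.loc[decoys, "rescaled_ui"].mean())
    p = wilcoxon(diffs, alternative="less").pvalue
    assert p < 0.05, (p, diffs)
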