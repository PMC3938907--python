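import numpy as np
import pytest

from catflow import (
    CategoryScheme,
    LagSpec,
    MarkovPanelSpec,
    build_lag_design,
    fit_transition,
    panel_from_values,
    probability_tree,
    select_lags,
    simulate_panel,
    transition_matrix,
    transition_probabilities,
)

ACT = CategoryScheme("activity", ("low", "moderate", "high"))
SMOKING = CategoryScheme(
    "smoking", ("never", "current", "ex"), monotone_absorbing_source="never"
)


def _empirical_matrix(panel):
    J = panel.scheme.n_levels
    out = np.zeros((J, J))
    for t in range(panel.n_waves - 1):
        for a in range(J):
            sel = panel.codes[:, t] == a
            out[a] += np.bincount(panel.codes[sel, t + 1], minlength=J)
    return out / out.sum(axis=1, keepdims=True)


class TestBuildLagDesign:
    def test_first_order_indicator_coding(self):
        panel = panel_from_values(
            [["moderate", "high"], ["low", "low"]], (1, 2), ACT
        )
        design = build_lag_design(panel, LagSpec(1), "last", lag_reference="low")
        assert design.colnames == ("const", "moderate[-1]", "high[-1]")
        row = design.X[list(design.row_meta["subject"]).index("s0")]
        assert row.tolist() == [1.0, 1.0, 0.0]

    def test_smoking_joint_indicator_additive_coding(self):
        # history (never, ex, ex): at the target wave lag-1 = ex, lag-2 = ex
        panel = panel_from_values(
            [["never", "ex", "ex", "ex"], ["never"] * 4], (2, 3, 4, 5), SMOKING
        )
        spec = LagSpec(
            2, single_lags=(1,), joint_indicators=(("ex", "ex"),),
            lag_reference="never",
        )
        design = build_lag_design(panel, spec, "last")
        assert design.colnames == ("const", "current[-1]", "ex[-1]", "ex[-1]&ex[-2]")
        assert design.X[0].tolist() == [1.0, 0.0, 1.0, 1.0]
        assert design.X[1].tolist() == [1.0, 0.0, 0.0, 0.0]

    def test_mutually_exclusive_coding_zeroes_constituents(self):
        panel = panel_from_values(
            [
                ["never", "ex", "ex", "ex"],
                ["never", "never", "ex", "current"],
                ["never"] * 4,
            ],
            (2, 3, 4, 5),
            SMOKING,
        )
        spec = LagSpec(
            2, single_lags=(1,), joint_indicators=(("ex", "ex"),),
            coding="mutually_exclusive", lag_reference="never",
        )
        design = build_lag_design(panel, spec, "last")
        # first subject: joint fires, so the plain ex[-1] indicator is zeroed
        assert design.X[0].tolist() == [1.0, 0.0, 0.0, 1.0]
        # second subject: ex at lag 1 only, joint does not fire
        assert design.X[1].tolist() == [1.0, 0.0, 1.0, 0.0]

    def test_ever_smoking_history_masks_never_outcome(self):
        panel = panel_from_values(
            [["current", "ex", "ex"], ["never", "never", "never"]],
            (3, 4, 5),
            SMOKING,
        )
        design = build_lag_design(panel, LagSpec(1), "last", lag_reference="never")
        never_idx = SMOKING.index("never")
        assert not design.allowed[0, never_idx]
        assert design.allowed[1].all()

    def test_absent_lag_reference_is_error(self):
        panel = panel_from_values(
            [["moderate", "high"], ["high", "low"]], (1, 2), ACT
        )
        with pytest.raises(ValueError, match="never observed at lag 1"):
            build_lag_design(panel, LagSpec(1), "last", lag_reference="low")


class TestFitTransition:
    def test_saturated_fit_reproduces_empirical_frequencies(self, smoking_panel):
        f = fit_transition(
            smoking_panel, LagSpec(1), reference="current", target_wave="pooled"
        )
        mat = transition_matrix(f).to_numpy()
        emp = _empirical_matrix(smoking_panel)
        assert np.abs(mat - emp).max() < 1e-9

    def test_recovers_simulated_transition_matrix(self):
        T = np.array([[0.6, 0.25, 0.15], [0.3, 0.5, 0.2], [0.2, 0.3, 0.5]])
        spec = MarkovPanelSpec(
            ACT, 5000, (2, 3, 4, 5), np.array([0.4, 0.35, 0.25]), T
        )
        panel = simulate_panel(spec, 77)
        f = fit_transition(panel, LagSpec(1), reference="low", target_wave="pooled")
        mat = transition_matrix(f).to_numpy()
        # 3 transitions x 5000 subjects; each row has >= 3500 draws
        mc_se = np.sqrt(T * (1 - T) / 3500)
        assert np.all(np.abs(mat - T) < 3 * mc_se + 1e-12)

    def test_second_order_fit_converges(self):
        rng_T = np.zeros((3, 3, 3))
        rng_T[..., :] = [0.5, 0.3, 0.2]
        rng_T[:, 2, :] = [0.2, 0.3, 0.5]  # previous-wave level matters
        spec = MarkovPanelSpec(
            ACT, 3000, (2, 3, 4, 5), np.array([1 / 3, 1 / 3, 1 / 3]), rng_T, order=2
        )
        panel = simulate_panel(spec, 13)
        f = fit_transition(
            panel, LagSpec(2), reference="moderate", target_wave="pooled"
        )
        assert f.converged

    def test_mutually_exclusive_and_additive_codings_agree_on_probabilities(
        self, smoking_panel
    ):
        common = dict(n_lags=2, single_lags=(1,), joint_indicators=(("ex", "ex"),),
                      lag_reference="never")
        fits = [
            fit_transition(
                smoking_panel, LagSpec(coding=c, **common), reference="current",
                target_wave="pooled",
            )
            for c in ("additive", "mutually_exclusive")
        ]
        tables = [
            transition_probabilities(f).pivot("prob").to_numpy() for f in fits
        ]
        assert np.allclose(tables[0], tables[1], atol=1e-7)

    def test_pooled_fit_invariant_to_subject_relabelling(self, smoking_panel):
        f1 = fit_transition(smoking_panel, LagSpec(1), reference="current",
                            target_wave="pooled")
        shuffled = type(smoking_panel)(
            tuple(f"z{i}" for i in range(smoking_panel.n_subjects)),
            smoking_panel.waves,
            smoking_panel.codes,
            smoking_panel.scheme,
        )
        f2 = fit_transition(shuffled, LagSpec(1), reference="current",
                            target_wave="pooled")
        assert np.allclose(f1.beta, f2.beta, atol=1e-10)
        assert np.allclose(f1.vcov_robust, f2.vcov_robust, atol=1e-10)


class TestTransitionProbabilities:
    def test_null_fit_gives_uniform_probabilities_and_zero_sum_gradient(self):
        rows = [[a, b] for a in ACT.levels for b in ACT.levels]
        panel = panel_from_values(rows, (1, 2), ACT)
        f = fit_transition(panel, LagSpec(1), reference="low")
        est = transition_probabilities(f)
        probs = est.pivot("prob").to_numpy()
        assert np.allclose(probs, 1 / 3, atol=1e-8)
        # per history, probabilities sum to one: SE of the sum is zero, which
        # the per-level delta SEs reflect via gradients summing to zero
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-12)

    def test_saturated_counts_table_rows_are_reproduced(self, activity_panel):
        f = fit_transition(activity_panel, LagSpec(1), reference="low")
        est = transition_probabilities(f)
        mat = est.pivot("prob")
        mat.index = [h[0] for h in mat.index]
        from conftest import ACTIVITY_ROWS

        for prev, probs in ACTIVITY_ROWS.items():
            expect = np.asarray(probs) / np.sum(probs)
            got = mat.loc[prev, list(ACT.levels)].to_numpy()
            assert np.allclose(got, expect, atol=1e-4)

    def test_delta_se_agrees_with_parametric_monte_carlo(self, smoking_panel):
        f = fit_transition(
            smoking_panel, LagSpec(1), reference="current", target_wave="pooled"
        )
        patterns = [(l,) for l in SMOKING.levels]

        def pmat(fit_obj, what="prob"):
            tab = transition_probabilities(fit_obj, patterns).table
            levels = list(fit_obj.levels)
            out = np.zeros((len(patterns), len(levels)))
            for _, row in tab.iterrows():
                out[patterns.index(row["history"]), levels.index(row["outcome"])] = row[what]
            return out

        delta_se = pmat(f, "se")
        rng = np.random.default_rng(123)
        free = np.flatnonzero(f.free_mask.ravel())
        V = f.vcov_robust[np.ix_(free, free)]
        draws = rng.multivariate_normal(
            f.beta.ravel()[free], V, size=2000, method="cholesky"
        )
        import copy

        sims = np.empty((len(draws), len(patterns), len(f.levels)))
        for i, d in enumerate(draws):
            g = copy.deepcopy(f)
            flat = g.beta.ravel()
            flat[free] = d
            g.beta = flat.reshape(f.beta.shape)
            sims[i] = pmat(g)
        mc_se = sims.std(axis=0, ddof=1)
        tiny = mc_se < 1e-12
        assert np.all(delta_se[tiny] < 1e-12)
        rel = np.abs(delta_se[~tiny] - mc_se[~tiny]) / mc_se[~tiny]
        assert rel.max() < 0.10

    def test_structural_zero_probability_and_se_are_exactly_zero(self, smoking_panel):
        f = fit_transition(
            smoking_panel, LagSpec(1), reference="current", target_wave="pooled"
        )
        t = transition_probabilities(f).table
        sub = t[(t["outcome"] == "never")
                & t["history"].map(lambda h: h in (("current",), ("ex",)))]
        assert len(sub) == 2
        assert (sub[["prob", "se", "ci_low", "ci_high"]] == 0.0).all().all()

    def test_logit_scale_intervals_stay_inside_unit_interval(self, smoking_panel):
        f = fit_transition(
            smoking_panel, LagSpec(1), reference="current", target_wave="pooled"
        )
        est = transition_probabilities(f, scale="logit")
        sub = est.table[est.table["prob"] > 0]
        assert (sub["ci_low"] > 0).all() and (sub["ci_high"] < 1).all()
        assert (sub["ci_low"] <= sub["prob"]).all()
        assert (sub["prob"] <= sub["ci_high"]).all()


class TestSelectLags:
    def test_near_independent_chain_recommends_one_lag(self):
        T = np.full((3, 3), 1 / 3)
        spec = MarkovPanelSpec(ACT, 3000, (1, 2, 3, 4, 5), np.full(3, 1 / 3), T)
        panel = simulate_panel(spec, 21)
        rec, diag = select_lags(panel, max_lags=3, reference="low")
        assert rec.n_lags == 1
        assert len(diag) == 3

    def test_persistent_chain_inflates_vifs(self):
        strong = np.array([[0.9, 0.05, 0.05], [0.05, 0.9, 0.05], [0.05, 0.05, 0.9]])
        weak = np.array([[0.4, 0.3, 0.3], [0.3, 0.4, 0.3], [0.3, 0.3, 0.4]])
        diags = {}
        for name, T in (("strong", strong), ("weak", weak)):
            spec = MarkovPanelSpec(ACT, 3000, (1, 2, 3, 4, 5), np.full(3, 1 / 3), T)
            panel = simulate_panel(spec, 22)
            _, diag = select_lags(panel, max_lags=2, reference="low")
            diags[name] = diag
        assert (
            diags["strong"].loc[1, "max_vif"] > diags["weak"].loc[1, "max_vif"]
        )

    def test_deterministic_chain_still_emits_recommendation(self):
        spec = MarkovPanelSpec(ACT, 200, (1, 2, 3, 4), np.full(3, 1 / 3), np.eye(3))
        panel = simulate_panel(spec, 23)
        with pytest.warns(UserWarning, match="separation"):
            rec, diag = select_lags(panel, max_lags=2, reference="low")
        assert rec.n_lags in (1, 2)
        assert len(diag) == 2


class TestProbabilityTree:
    def test_constant_panel_single_path(self):
        panel = panel_from_values([["low"] * 4] * 5, (2, 3, 4, 5), ACT)
        tree = probability_tree(panel, "low", 2)
        node = tree.root
        assert node.count == 5
        while node.children:
            assert len(node.children) == 1
            node = node.children[0]
            assert node.prob == 1.0 and node.count == 5

    def test_hand_counted_fixture(self):
        rows = [
            ["low", "low", "low"],
            ["low", "low", "high"],
            ["low", "low", "high"],
            ["low", "moderate", "moderate"],
            ["low", "moderate", "low"],
            ["low", "moderate", "moderate"],
            ["low", "moderate", "moderate"],
            ["low", "low", "low"],
        ]
        panel = panel_from_values(rows, (1, 2, 3), ACT)
        tree = probability_tree(panel, "low", 1)
        assert tree.root.count == 8
        by_level = {c.level: c for c in tree.root.children}
        assert by_level["low"].count == 4 and by_level["low"].prob == 0.5
        assert by_level["moderate"].count == 4
        gl = {c.level: c for c in by_level["low"].children}
        assert gl["low"].count == 2 and gl["high"].count == 2
        gm = {c.level: c for c in by_level["moderate"].children}
        assert gm["moderate"].count == 3 and gm["moderate"].prob == 0.75

    def test_leaf_counts_conserve_root_count(self, smoking_panel):
        tree = probability_tree(smoking_panel, "current", 2)

        def leaves(node):
            if not node.children:
                return [node]
            out = []
            for c in node.children:
                out.extend(leaves(c))
            return out

        assert sum(l.count for l in leaves(tree.root)) == tree.root.count
        # children's conditional probabilities sum to one at every split
        def check(node):
            if node.children:
                assert np.isclose(sum(c.prob for c in node.children), 1.0)
                for c in node.children:
                    check(c)

        check(tree.root)

    def test_empty_root_is_error(self):
        panel = panel_from_values([["low", "low"]], (1, 2), ACT)
        with pytest.raises(ValueError, match="no subject"):
            probability_tree(panel, "high", 1)
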