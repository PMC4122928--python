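import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from famturnover import _fast
from famturnover.likelihood import (
    BranchModel,
    aic_rank,
    default_n_max,
    family_loglik,
    fit,
    lrt,
    transition_matrix,
    transition_prob,
    tree_arrays,
)
from famturnover.simulate import BDParams, simulate_counts
from famturnover.trees import label_branches, parse_dated_newick


class TestTransitionProb:
    def test_identity_at_zero_time(self):
        assert transition_prob(3, 3, 0.0, 0.1, 0.2) == 1.0
        assert transition_prob(3, 2, 0.0, 0.1, 0.2) == 0.0

    def test_zero_start_is_absorbing(self):
        assert transition_prob(0, 0, 5.0, 0.3, 0.1) == 1.0
        assert transition_prob(0, 1, 5.0, 0.3, 0.1) == 0.0

    def test_pure_death_closed_form(self):
        t, d = 10.0, 0.02
        assert transition_prob(1, 0, t, 0.0, d) == pytest.approx(1 - math.exp(-d * t))
        assert transition_prob(1, 1, t, 0.0, d) == pytest.approx(math.exp(-d * t))
        assert transition_prob(1, 2, t, 0.0, d) == 0.0

    def test_pure_birth_yule_form(self):
        t, b = 10.0, 0.05
        e = math.exp(-b * t)
        assert transition_prob(1, 1, t, b, 0.0) == pytest.approx(e)
        assert transition_prob(1, 3, t, b, 0.0) == pytest.approx(e * (1 - e) ** 2)
        assert transition_prob(2, 1, t, b, 0.0) == 0.0

    @pytest.mark.parametrize("n0", [1, 2, 5, 10])
    @pytest.mark.parametrize("t,beta,delta", [
        (60.0, 0.25, 0.25), (60.0, 0.02, 0.2), (15.0, 0.1, 0.05), (2.3, 0.002, 0.01),
    ])
    def test_rows_sum_to_one(self, n0, t, beta, delta):
        # summed to an adequate truncation the kernel is a distribution
        total = sum(transition_prob(n0, j, t, beta, delta) for j in range(2000))
        assert total == pytest.approx(1.0, abs=1e-9)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        n0=st.integers(0, 8), n1=st.integers(0, 16),
        t=st.floats(0.1, 60), beta=st.floats(0.0, 0.2), delta=st.floats(0.0, 0.2),
    )
    def test_matrix_agrees_with_scalar_form(self, n0, n1, t, beta, delta):
        P = transition_matrix(20, t, beta, delta)
        assert P[n0, n1] == pytest.approx(transition_prob(n0, n1, t, beta, delta), abs=1e-12)

    def test_compiled_kernel_matches_reference_matrix(self):
        for t, b, d in [(15, 0.03, 0.02), (62, 0.02, 0.02), (2.3, 0.002, 0.2), (10, 0, 0.05)]:
            P = np.zeros((41, 41))
            _fast.fill_transition_matrix(P, t, b, d, 40)
            assert np.abs(P - transition_matrix(40, t, b, d)).max() < 1e-13


class TestFamilyLoglik:
    def test_two_taxon_is_product_of_transitions(self):
        tree = parse_dated_newick("(A:2,B:2)r;")
        lab = label_branches(tree, "MGr")
        params = BDParams.uniform(0.05, 0.03, lab)
        ll = family_loglik({"A": 2, "B": 0}, tree, lab, params, root_count=1)
        expected = transition_prob(1, 2, 2, 0.05, 0.03) * transition_prob(1, 0, 2, 0.05, 0.03)
        assert ll == pytest.approx(math.log(expected))

    def test_three_taxon_equals_brute_force_state_sum(self, tree3):
        lab = label_branches(tree3, "MGr")
        b, d = 0.1, 0.05
        params = BDParams.uniform(b, d, lab)
        for counts in [{"A": 2, "B": 1, "C": 0}, {"A": 0, "B": 0, "C": 3}, {"A": 1, "B": 1, "C": 1}]:
            ll = family_loglik(counts, tree3, lab, params, root_count=1, n_max=40)
            brute = transition_prob(1, counts["C"], 2, b, d) * sum(
                transition_prob(1, s, 1, b, d)
                * transition_prob(s, counts["A"], 1, b, d)
                * transition_prob(s, counts["B"], 1, b, d)
                for s in range(60)
            )
            assert ll == pytest.approx(math.log(brute), abs=1e-8)

    def test_zero_rates_point_mass(self, tree3):
        lab = label_branches(tree3, "MGr")
        params = BDParams.uniform(0.0, 0.0, lab)
        assert family_loglik({"A": 1, "B": 1, "C": 1}, tree3, lab, params) == 0.0
        assert family_loglik({"A": 2, "B": 1, "C": 1}, tree3, lab, params) == -math.inf

    def test_truncation_warning(self, tree3):
        lab = label_branches(tree3, "MGr")
        params = BDParams.uniform(0.5, 0.1, lab)
        with pytest.warns(RuntimeWarning, match="truncation"):
            family_loglik({"A": 3, "B": 3, "C": 3}, tree3, lab, params, n_max=4)

    def test_compiled_kernel_matches_reference_on_tables(self, drosophila_tree):
        lab = label_branches(drosophila_tree, "MGr")
        params = BDParams.uniform(0.02, 0.015, lab)
        ct, _ = simulate_counts(drosophila_tree, lab, BDParams.uniform(0.02, 0.02, lab),
                                n_og=20, rng=31)
        n_max = default_n_max(int(ct.counts.to_numpy().max()))
        arr = tree_arrays(drosophila_tree)
        rows = ct.counts[drosophila_tree.leaves].to_numpy()
        beta_b = np.full(drosophila_tree.n_nodes - 1, 0.02)
        delta_b = np.full(drosophila_tree.n_nodes - 1, 0.015)
        S = n_max + 1
        fast = _fast.loglik_kernel(
            beta_b, delta_b, arr["T_b"], arr["child_left"], arr["child_right"],
            arr["leaf_col"], rows, np.ones(len(rows)), 1, n_max,
            np.empty((drosophila_tree.n_nodes - 1, S, S)),
            np.empty((drosophila_tree.n_nodes, len(rows), S)),
        )
        with np.errstate(all="ignore"):
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ref = sum(
                    family_loglik(ct.row(og), drosophila_tree, lab, params, 1, n_max)
                    for og in ct.og_ids
                )
        assert fast == pytest.approx(ref, abs=1e-8)

    def test_per_og_additivity_equals_totals_distribution(self):
        # the totals of m independent root-1 families are distributed as one
        # root-m family: P_tree(totals | root=m) = sum over per-OG splits
        tree = parse_dated_newick("(A:2,B:2)r;")
        lab = label_branches(tree, "MGr")
        b, d = 0.08, 0.05
        params = BDParams.uniform(b, d, lab)
        m = 2
        for tot_a, tot_b in [(2, 1), (0, 0), (3, 2)]:
            direct = (
                transition_prob(m, tot_a, 2, b, d) * transition_prob(m, tot_b, 2, b, d)
            )
            split = 0.0
            for a1 in range(tot_a + 1):
                for b1 in range(tot_b + 1):
                    p1 = transition_prob(1, a1, 2, b, d) * transition_prob(1, b1, 2, b, d)
                    p2 = transition_prob(1, tot_a - a1, 2, b, d) * transition_prob(
                        1, tot_b - b1, 2, b, d
                    )
                    split += p1 * p2
            assert split == pytest.approx(direct, rel=1e-10)


class TestFit:
    def test_zero_rate_data_drives_estimates_to_boundary(self, drosophila_tree):
        lab = label_branches(drosophila_tree, "MGr")
        ct, _ = simulate_counts(drosophila_tree, lab, BDParams.uniform(0, 0, lab), n_og=30, rng=1)
        fr = fit(ct, drosophila_tree, BranchModel.named(drosophila_tree, "MGr"),
                 n_restarts=2, rng=0)
        b, d = fr.rate("all")
        assert b < 1e-6 and d < 1e-6
        # lnL -> 0 up to the residual mass at the lower rate bound (1e-8)
        assert fr.loglik == pytest.approx(0.0, abs=1e-3)

    def test_nested_models_order_by_loglik(self, drosophila_tree):
        lab = label_branches(drosophila_tree, "MGr")
        ct, _ = simulate_counts(drosophila_tree, lab, BDParams.uniform(0.02, 0.02, lab),
                                n_og=50, rng=2)
        fits = {
            name: fit(ct, drosophila_tree, BranchModel.named(drosophila_tree, name),
                      n_restarts=4, rng=3)
            for name in ("MGr", "Mterm", "Msec")
        }
        assert fits["Msec"].loglik >= fits["Mterm"].loglik - 1e-4
        assert fits["Mterm"].loglik >= fits["MGr"].loglik - 1e-4

    def test_totals_mode_agrees_with_per_og_for_shared_rates(self, drosophila_tree):
        # same rate estimand: both modes should land near the truth
        lab = label_branches(drosophila_tree, "MGr")
        ct, _ = simulate_counts(drosophila_tree, lab, BDParams.uniform(0.02, 0.02, lab),
                                n_og=50, rng=4)
        bm = BranchModel.named(drosophila_tree, "MGr")
        f_og = fit(ct, drosophila_tree, bm, n_restarts=3, rng=5)
        f_tot = fit(ct, drosophila_tree, bm, n_restarts=3, rng=6, mode="totals")
        assert f_og.rate("all")[0] == pytest.approx(f_tot.rate("all")[0], abs=0.02)

    def test_equal_rates_constraint(self, drosophila_tree):
        lab = label_branches(drosophila_tree, "MGr")
        ct, _ = simulate_counts(drosophila_tree, lab, BDParams.uniform(0.02, 0.02, lab),
                                n_og=30, rng=7)
        fr = fit(ct, drosophila_tree, BranchModel.named(drosophila_tree, "MGr", equal_rates=True),
                 n_restarts=2, rng=8)
        b, d = fr.rate("all")
        assert b == d
        assert fr.k == 1

    def test_warm_start_and_early_stop(self, drosophila_tree):
        lab = label_branches(drosophila_tree, "MGr")
        ct, _ = simulate_counts(drosophila_tree, lab, BDParams.uniform(0.01, 0.01, lab),
                                n_og=30, rng=9)
        init = BDParams({"all": (0.01, 0.01)})
        fr = fit(ct, drosophila_tree, BranchModel.named(drosophila_tree, "MGr"),
                 n_restarts=6, rng=10, init_rates=init, min_agreeing=2)
        assert fr.multiplicity >= 2


class TestLrtAndAic:
    def _mk(self, model, k, lnl):
        from famturnover.likelihood import FitResult

        return FitResult(model=model, k=k, loglik=lnl, rates={}, aic=2 * k - 2 * lnl,
                         n_restarts=1, multiplicity=1, converged=True, mode="per_og", n_og=50)

    def test_identical_fits_give_p_one(self):
        assert lrt(self._mk("MGr", 2, -100.0), self._mk("Msec", 6, -100.0)) == 1.0

    def test_chi2_quantile_df4(self):
        # statistic 9.49 with df = 4 sits at the 5% tail
        p = lrt(self._mk("MGr", 2, -100.0), self._mk("Msec", 6, -100.0 + 9.49 / 2))
        assert p == pytest.approx(0.05, abs=1e-3)

    def test_non_nested_rejected(self):
        with pytest.raises(ValueError):
            lrt(self._mk("Msec", 6, -10.0), self._mk("MGr", 2, -9.0))

    def test_negative_statistic_clamped(self):
        assert lrt(self._mk("MGr", 2, -99.0), self._mk("Msec", 6, -100.0)) == 1.0

    def test_aic_ranking_and_ties(self):
        f1 = self._mk("MGr", 2, -100.0)
        f2 = self._mk("Msec", 6, -100.0)  # equal lnL: k=2 wins by delta 8
        tab = aic_rank([f2, f1])
        assert list(tab["model"]) == ["MGr", "Msec"]
        assert tab["delta_AIC"].iloc[1] == pytest.approx(8.0)
        assert tab["tied_best"].tolist() == [True, False]

    def test_single_fit_ranks_itself(self):
        tab = aic_rank([self._mk("MGr", 2, -5.0)])
        assert len(tab) == 1
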