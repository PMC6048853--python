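"""Birth-death family-size model: closed-form transition values, a
Monte-Carlo (Gillespie) oracle, pruning vs exhaustive enumeration, rate
recovery and ancestral reconstruction."""
import dendropy
import numpy as np
import pandas as pd
import pytest

from panforge.gainloss import (
    batch_loglik,
    bd_transition,
    bd_transition_matrix,
    estimate_lambda,
    family_loglik,
    reconstruct_and_count,
    simulate_family_sizes,
)
from panforge.simulate import simulate_species_tree


def get_tree(newick):
    return dendropy.Tree.get(data=newick, schema="newick")


class TestTransition:
    def test_identity_at_zero_time(self):
        for s in range(4):
            for c in range(4):
                expected = 1.0 if s == c else 0.0
                assert bd_transition(s, c, 1.0, 0.0) == expected

    def test_closed_form_at_quarter_alpha(self):
        # lambda*t = 1/3 -> alpha = 0.25
        assert bd_transition(1, 0, 1.0, 1 / 3) == pytest.approx(0.25)
        assert bd_transition(1, 1, 1.0, 1 / 3) == pytest.approx(0.5625)

    def test_zero_is_absorbing(self):
        assert bd_transition(0, 0, 0.7, 2.0) == 1.0
        assert bd_transition(0, 3, 0.7, 2.0) == 0.0

    def test_row_sums_to_one(self):
        total = sum(bd_transition(5, c, 0.3, 0.8) for c in range(250))
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_validity_bound(self):
        with pytest.raises(ValueError, match="alpha"):
            bd_transition(1, 1, 2.0, 1.0)

    def test_matches_gillespie_simulation(self):
        """Monte-Carlo oracle: linear birth-death with equal per-copy rates
        lambda, simulated exactly, reproduces the closed-form distribution."""
        rng = np.random.default_rng(2024)
        lam, t, s0 = 0.4, 0.9, 2
        n_sims = 20000
        counts = np.zeros(60, dtype=int)
        for _ in range(n_sims):
            size, clock = s0, 0.0
            while size > 0:
                rate = 2 * lam * size  # birth + death
                clock += rng.exponential(1.0 / rate)
                if clock > t:
                    break
                size += 1 if rng.random() < 0.5 else -1
            counts[min(size, 59)] += 1
        emp = counts / n_sims
        for c in range(8):
            p = bd_transition(s0, c, lam, t)
            se = np.sqrt(p * (1 - p) / n_sims)
            assert abs(emp[c] - p) <= 4 * se + 1e-4, c

    def test_matrix_rows_renormalised(self):
        m = bd_transition_matrix(0.3, 0.9, size_cap=6)
        assert np.allclose(m.sum(axis=1), 1.0, atol=1e-9)


class TestLikelihood:
    def test_pruning_equals_enumeration_three_leaves(self):
        tree = get_tree("((A:0.3,B:0.5):0.4,C:0.2);")
        cap, lam = 3, 0.6
        tips = {"A": 1, "B": 2, "C": 0}
        ll = family_loglik(tree, tips, lam, size_cap=cap)
        p = {t: bd_transition_matrix(lam, t, cap) for t in (0.2, 0.3, 0.4, 0.5)}
        brute = 0.0
        for r in range(1, cap + 1):
            for i in range(cap + 1):
                brute += (1 / cap) * p[0.4][r, i] * p[0.3][i, tips["A"]] \
                    * p[0.5][i, tips["B"]] * p[0.2][r, tips["C"]]
        assert ll == pytest.approx(np.log(brute))

    def test_pruning_equals_enumeration_random_instances(self):
        """Exhaustive-enumeration oracle over random 4-leaf instances."""
        rng = np.random.default_rng(31)
        tree = get_tree("((A:0.25,B:0.4):0.3,(C:0.2,D:0.35):0.15);")
        cap = 4
        for _ in range(8):
            lam = float(rng.uniform(0.1, 0.8))
            tips = {k: int(rng.integers(0, cap + 1)) for k in "ABCD"}
            ll = family_loglik(tree, tips, lam, size_cap=cap)
            p = {t: bd_transition_matrix(lam, t, cap)
                 for t in (0.25, 0.4, 0.3, 0.2, 0.35, 0.15)}
            brute = 0.0
            for r in range(1, cap + 1):
                for u in range(cap + 1):      # ancestor of A,B
                    for v in range(cap + 1):  # ancestor of C,D
                        brute += (1 / cap) * p[0.3][r, u] * p[0.15][r, v] \
                            * p[0.25][u, tips["A"]] * p[0.4][u, tips["B"]] \
                            * p[0.2][v, tips["C"]] * p[0.35][v, tips["D"]]
            assert ll == pytest.approx(np.log(brute), rel=1e-9)

    def test_change_requires_rate(self):
        """A family with sizes (0, 5) becomes impossible as lambda -> 0."""
        tree = get_tree("(A:0.5,B:0.5);")
        lls = [family_loglik(tree, {"A": 0, "B": 5}, lam, size_cap=12)
               for lam in (0.5, 0.1, 0.01)]
        assert lls[0] > lls[1] > lls[2]
        assert lls[2] < -10

    def test_tiny_branches_concentrate_on_observed_state(self):
        tree = get_tree("(A:0.001,B:0.001);")
        ll_same = family_loglik(tree, {"A": 1, "B": 1}, 0.1, size_cap=5)
        ll_diff = family_loglik(tree, {"A": 1, "B": 2}, 0.1, size_cap=5)
        assert ll_same > ll_diff
        assert ll_same == pytest.approx(np.log(1 / 5), abs=0.02)


@pytest.fixture(scope="module")
def eight_leaf():
    return simulate_species_tree(8, 1.0, 5)


class TestRateEstimation:
    def test_lambda_recovery(self, eight_leaf):
        rng = np.random.default_rng(7)
        roots = rng.integers(1, 6, size=300)
        tips = simulate_family_sizes(eight_leaf, 0.2, roots, rng, size_cap=20)
        lam_hat = estimate_lambda(eight_leaf, tips, size_cap=20)
        assert 0.1 <= lam_hat <= 0.3

    def test_rate_time_confounding(self, eight_leaf):
        """Doubling all branch lengths halves the estimated rate."""
        rng = np.random.default_rng(8)
        roots = rng.integers(1, 6, size=200)
        tips = simulate_family_sizes(eight_leaf, 0.2, roots, rng, size_cap=20)
        lam1 = estimate_lambda(eight_leaf, tips, size_cap=20)
        doubled = eight_leaf.clone(depth=1)
        for e in doubled.preorder_edge_iter():
            if e.length is not None:
                e.length *= 2
        lam2 = estimate_lambda(doubled, tips, size_cap=20)
        assert lam2 == pytest.approx(lam1 / 2, rel=0.05)

    def test_all_invariant_is_an_error(self, eight_leaf):
        leaves = [l.taxon.label for l in eight_leaf.leaf_node_iter()]
        tips = pd.DataFrame({"f1": {g: 2 for g in leaves},
                             "f2": {g: 1 for g in leaves}})
        with pytest.raises(ValueError, match="no signal"):
            estimate_lambda(eight_leaf, tips)

    def test_positive_rate_with_one_variable_family(self, eight_leaf):
        leaves = sorted(l.taxon.label for l in eight_leaf.leaf_node_iter())
        tips = pd.DataFrame({
            "f1": {g: 1 for g in leaves},
            "f2": {g: (2 if g == leaves[0] else 1) for g in leaves},
        })
        assert estimate_lambda(eight_leaf, tips, size_cap=8) > 0


class TestReconstruction:
    def test_invariant_family_all_zero_deltas(self):
        tree = get_tree("((A:0.2,B:0.2):0.2,(C:0.2,D:0.2):0.2);")
        tips = pd.DataFrame({"f": {g: 2 for g in "ABCD"}})
        dyn = reconstruct_and_count(tree, tips, 0.2, size_cap=6, n_null=200, seed=1)
        assert (dyn.deltas.loc["f"] == 0).all()
        assert dyn.p_values["f"] > 0.5

    def test_single_loss_on_star_like_tree(self):
        tree = get_tree("((A:0.3,B:0.3):0.01,(C:0.3,D:0.3):0.01);")
        tips = pd.DataFrame({"f": {"A": 0, "B": 2, "C": 2, "D": 2}})
        dyn = reconstruct_and_count(tree, tips, 0.2, size_cap=4, n_null=100, seed=2)
        deltas = dyn.deltas.loc["f"]
        assert (deltas < 0).sum() == 1
        assert deltas[(deltas < 0)].index[0] == "A"

    def test_branch_counts_match_delta_signs(self):
        tree = simulate_species_tree(6, 1.0, 3)
        rng = np.random.default_rng(4)
        roots = rng.integers(1, 5, size=60)
        tips = simulate_family_sizes(tree, 0.15, roots, rng, size_cap=15)
        dyn = reconstruct_and_count(tree, tips, 0.15, size_cap=15, n_null=100, seed=5)
        assert (dyn.branch_counts["expansions"]
                == (dyn.deltas > 0).sum(axis=0)).all()
        assert (dyn.branch_counts["contractions"]
                == (dyn.deltas < 0).sum(axis=0)).all()

    def test_contraction_counts_track_true_loss_events(self):
        """Per-branch contraction counts correlate with the gene-content
        generator's true per-branch loss events (root families only, the
        ones the model conditions on existing at the root)."""
        from scipy.stats import spearmanr

        from panforge.simulate import SimulationConfig, simulate_gene_content

        tree = simulate_species_tree(8, 1.0, 17, height=1.0)
        cfg = SimulationConfig(
            n_genomes=8, n_core_families=50, n_root_accessory=300,
            gain_rate=0.0, loss_rate=0.6, hgt_rate=0.0, seed=17, tree_height=1.0,
        )
        truth = simulate_gene_content(tree, cfg)
        leaves = sorted(l.taxon.label for l in tree.leaf_node_iter())
        root_fams = [f for f in truth.family_membership if f[0] in "CA"]
        tips = pd.DataFrame({
            f: {g: len(truth.family_membership[f].get(g, [])) for g in leaves}
            for f in root_fams
        })
        lam = estimate_lambda(tree, tips, size_cap=4)
        dyn = reconstruct_and_count(tree, tips, lam, size_cap=4, n_null=100, seed=18)
        true_losses = {}
        for branch, _fam, event in truth.event_log:
            if event == "loss":
                true_losses[branch] = true_losses.get(branch, 0) + 1
        branches = list(dyn.branch_counts.index)
        x = [true_losses.get(b, 0) for b in branches]
        y = dyn.branch_counts["contractions"].tolist()
        rho = spearmanr(x, y).statistic
        assert rho >= 0.8
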