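import numpy as np
import pandas as pd
import pytest

from modnet import Config, NGParams
from modnet.learning import (
    LearningData,
    em_step,
    learn_module_network,
    learn_regulation_tree,
    module_score_of_gene,
    network_to_json,
)
from modnet.module_init import ModuleAssignment, SplitRule, initial_assignment, normal_gamma_log_marginal


def _planted_data(rng, n_mods=2, targets_per_mod=6, n_samples=60, noise=0.3):
    """Targets shift whenever their own modulator crosses its threshold."""
    mod_ids = [f"m{i}" for i in range(n_mods)]
    mod_expr = np.vstack(
        [
            np.where(rng.random(n_samples) < 0.5, 2.0, 0.0) + rng.normal(0, noise, n_samples)
            for _ in mod_ids
        ]
    )
    thresholds = np.full(n_mods, 1.0)
    genes, rows, truth = [], [], {}
    for mi, mid in enumerate(mod_ids):
        active = mod_expr[mi] > 1.0
        for j in range(targets_per_mod):
            g = f"t{mi}_{j}"
            genes.append(g)
            rows.append(np.where(active, 2.0, 0.0) + rng.normal(0, noise, n_samples))
            truth[g] = mid
    Y = np.vstack(rows)
    Y = Y - Y.mean(axis=1, keepdims=True)
    return LearningData(Y, genes, mod_expr, mod_ids, thresholds), truth


def _true_assignment(truth):
    return dict(truth)


class TestLearnRegulationTree:
    def test_planted_root_split(self, params):
        data, truth = _planted_data(np.random.default_rng(0), n_mods=2)
        rows = [i for i, g in enumerate(data.genes) if truth[g] == "m0"]
        cfg = Config()
        tree = learn_regulation_tree(data, rows, range(len(data.mod_ids)), cfg, params)
        assert not tree.root.is_leaf
        assert tree.root.modulator == "m0"

    def test_depth_zero_gives_single_leaf(self, params):
        data, _ = _planted_data(np.random.default_rng(1))
        cfg = Config(max_tree_depth=0)
        tree = learn_regulation_tree(data, [0, 1], range(2), cfg, params)
        assert tree.root.is_leaf
        assert tree.depth() == 0

    @pytest.mark.parametrize("seed", range(10))
    def test_noise_members_stay_single_leaf(self, seed, params):
        """Pure-noise members: no split beats the default penalty."""
        rng = np.random.default_rng(seed)
        n = 50
        mod_expr = np.vstack([rng.normal(0, 1, n), rng.normal(0, 1, n)])
        Y = rng.normal(0, 1, size=(6, n))
        Y -= Y.mean(axis=1, keepdims=True)
        data = LearningData(Y, [f"g{i}" for i in range(6)], mod_expr, ["m0", "m1"], np.zeros(2))
        tree = learn_regulation_tree(data, range(6), range(2), Config(), params)
        assert tree.root.is_leaf

    def test_empty_module_rejected(self, params):
        data, _ = _planted_data(np.random.default_rng(2))
        with pytest.raises(ValueError, match="empty"):
            learn_regulation_tree(data, [], range(2), Config(), params)

    def test_leaves_partition_samples(self, params):
        data, truth = _planted_data(np.random.default_rng(3))
        tree = learn_regulation_tree(
            data, range(len(data.genes)), range(2), Config(), params
        )
        covered = np.sort(np.concatenate(tree.leaf_sample_sets()))
        np.testing.assert_array_equal(covered, np.arange(data.n_samples))


class TestModuleScoreOfGene:
    def test_single_leaf_reduces_to_plain_score(self, params):
        data, _ = _planted_data(np.random.default_rng(4))
        tree = learn_regulation_tree(data, [0], range(2), Config(max_tree_depth=0), params)
        gene = data.Y[0]
        assert module_score_of_gene(gene, tree) == pytest.approx(
            normal_gamma_log_marginal(gene, params)
        )

    def test_matching_tree_scores_higher(self, params):
        data, truth = _planted_data(np.random.default_rng(5))
        rows0 = [i for i, g in enumerate(data.genes) if truth[g] == "m0"]
        cfg = Config()
        tree = learn_regulation_tree(data, rows0, range(2), cfg, params)
        flat = learn_regulation_tree(data, rows0, range(2), Config(max_tree_depth=0), params)
        gene = data.Y[rows0[0]]
        assert module_score_of_gene(gene, tree) > module_score_of_gene(gene, flat)

    def test_additive_over_leaves(self, params):
        data, truth = _planted_data(np.random.default_rng(6))
        tree = learn_regulation_tree(data, range(4), range(2), Config(), params)
        gene = data.Y[2]
        by_leaf = sum(
            normal_gamma_log_marginal(gene[idx], params)
            for idx in tree.leaf_sample_sets()
        )
        assert module_score_of_gene(gene, tree) == pytest.approx(by_leaf)


class TestEmStep:
    def test_fixed_point_has_zero_pro(self, params):
        data, truth = _planted_data(np.random.default_rng(7))
        cfg = Config()
        rng = np.random.default_rng(0)
        # run to convergence first
        net = learn_module_network(_true_assignment(truth), data, cfg, seed=1)
        net2, pro = em_step(net.assignment, data, cfg, params, np.random.default_rng(2))
        assert pro == 0.0
        assert net2.assignment == net.assignment

    def test_swapped_init_recovers_and_score_increases(self, params):
        data, truth = _planted_data(np.random.default_rng(8), targets_per_mod=10)
        assignment = _true_assignment(truth)
        genes = sorted(assignment)
        for g in genes[:4]:  # corrupt 20% of the genes
            assignment[g] = "m1" if assignment[g] == "m0" else "m0"
        cfg = Config()
        net, pro = em_step(assignment, data, cfg, params, np.random.default_rng(3))
        assert pro > 0.0
        after_m, after_e = net.score_history[0]
        assert after_e > after_m

    def test_single_gene_single_module(self, params):
        data, truth = _planted_data(np.random.default_rng(9), n_mods=1, targets_per_mod=1)
        net, pro = em_step({"t0_0": "m0"}, data, Config(), params, np.random.default_rng(0))
        assert pro == 0.0


class TestLearnModuleNetwork:
    def test_immediate_convergence_on_optimal_init(self):
        data, truth = _planted_data(np.random.default_rng(10))
        cfg = Config()
        net = learn_module_network(_true_assignment(truth), data, cfg, seed=0)
        assert len(net.score_history) >= 1
        assert net.assignment == _true_assignment(truth)

    def test_determinism(self):
        data, truth = _planted_data(np.random.default_rng(11))
        cfg = Config()
        n1 = learn_module_network(_true_assignment(truth), data, cfg, seed=42)
        n2 = learn_module_network(_true_assignment(truth), data, cfg, seed=42)
        assert network_to_json(n1) == network_to_json(n2)
        assert n1.total_log_score == n2.total_log_score

    @pytest.mark.parametrize("seed", range(8))
    def test_estep_scores_never_decrease(self, seed):
        """The E-step never lowers the total log score (exact assertion)."""
        rng = np.random.default_rng(seed)
        data, truth = _planted_data(rng, n_mods=2, targets_per_mod=5, noise=1.0)
        # random (wrong) initial assignment
        assignment = {
            g: data.mod_ids[rng.integers(len(data.mod_ids))] for g in data.genes
        }
        net = learn_module_network(assignment, data, Config(), seed=seed)
        for after_m, after_e in net.score_history:
            assert after_e >= after_m

    def test_planted_recovery_across_seeds(self):
        """Final trees split on every planted modulator in >= 8/10 seeds."""
        full_recoveries = 0
        for seed in range(10):
            rng = np.random.default_rng(200 + seed)
            data, truth = _planted_data(rng, n_mods=3, targets_per_mod=10)
            assignment = {
                g: data.mod_ids[rng.integers(len(data.mod_ids))] for g in data.genes
            }
            net = learn_module_network(assignment, data, Config(), seed=seed)
            if set(data.mod_ids) <= net.split_modulators():
                full_recoveries += 1
        assert full_recoveries >= 8

    def test_self_regulation_excluded(self):
        """A modulator that is also a target never splits its own module."""
        rng = np.random.default_rng(13)
        data, truth = _planted_data(rng, n_mods=2, targets_per_mod=6)
        # add the modulators themselves as targets
        Y = np.vstack([data.Y, data.mod_expr - data.mod_expr.mean(axis=1, keepdims=True)])
        genes = data.genes + data.mod_ids
        data2 = LearningData(Y, genes, data.mod_expr, data.mod_ids, data.thresholds)
        assignment = dict(_true_assignment(truth))
        assignment["m0"] = "m1"
        assignment["m1"] = "m0"
        net = learn_module_network(assignment, data2, Config(), seed=5)
        for mid, members in net.modules.items():
            used = net.trees[mid].used_modulators()
            assert not (used & set(members))
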