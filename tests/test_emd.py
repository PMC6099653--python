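import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from modnet import Config, build_signature, emd, emd_qvalues, fdr_qvalues, select_differential_genes
from modnet.emd import Signature, emd_shared_grid

from oracles import emd_cdf_closed_form, emd_lp


class TestBuildSignature:
    def test_point_mass(self):
        sig = build_signature([3.0, 3.0, 3.0], bins=4)
        assert np.isclose(sig.weights.sum(), 1.0)
        assert (sig.weights == 1.0).sum() == 1

    def test_symmetric_two_bins(self):
        sig = build_signature([0.0, 0.0, 1.0, 1.0], bins=2)
        np.testing.assert_allclose(sig.weights, [0.5, 0.5])

    @given(
        st.lists(st.floats(-50, 50), min_size=1, max_size=40),
        st.integers(1, 12),
    )
    @settings(max_examples=60, deadline=None)
    def test_weights_always_normalized(self, values, bins):
        sig = build_signature(values, bins=bins)
        assert abs(sig.weights.sum() - 1.0) < 1e-12
        assert np.all(np.diff(sig.centers) > 0)

    def test_empty_and_bad_bins(self):
        with pytest.raises(ValueError):
            build_signature([], bins=2)
        with pytest.raises(ValueError):
            build_signature([1.0], bins=0)


class TestEmd:
    def test_identity(self):
        sig = build_signature([0.0, 1.0, 2.0], bins=3)
        assert emd(sig, sig) == 0.0

    def test_unit_flow(self):
        p = Signature(np.array([0.0]), np.array([1.0]))
        q = Signature(np.array([1.0]), np.array([1.0]))
        assert emd(p, q) == pytest.approx(1.0)

    def test_two_to_one_cell(self):
        p = Signature(np.array([0.0, 1.0]), np.array([0.5, 0.5]))
        q = Signature(np.array([0.0, 1.0]), np.array([1.0, 0.0]))
        assert emd(p, q) == pytest.approx(0.5)

    def test_rejects_unnormalized(self):
        p = Signature(np.array([0.0, 1.0]), np.array([0.5, 0.1]))
        q = Signature(np.array([0.0]), np.array([1.0]))
        with pytest.raises(ValueError, match="normalized"):
            emd(p, q)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_lp_transport_oracle(self, seed):
        """Transport cost equals the LP solution on small random signatures."""
        rng = np.random.default_rng(seed)
        m, n = rng.integers(1, 7), rng.integers(1, 7)
        cp = np.sort(rng.normal(0, 2, m))
        cq = np.sort(rng.normal(0, 2, n))
        cp += np.arange(m) * 1e-6  # ensure strictly increasing
        cq += np.arange(n) * 1e-6
        wp = rng.dirichlet(np.ones(m))
        wq = rng.dirichlet(np.ones(n))
        ours = emd(Signature(cp, wp), Signature(cq, wq))
        assert ours == pytest.approx(emd_lp(cp, wp, cq, wq), abs=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_cdf_closed_form_on_shared_bins(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, 60)
        b = rng.normal(0.5, 1.5, 45)
        lo, hi = min(a.min(), b.min()), max(a.max(), b.max())
        p = build_signature(a, bins=12, value_range=(lo, hi))
        q = build_signature(b, bins=12, value_range=(lo, hi))
        width = p.centers[1] - p.centers[0]
        closed = emd_cdf_closed_form(p.weights, q.weights, width)
        assert emd(p, q) == pytest.approx(closed, abs=1e-9)
        assert emd_shared_grid(p.weights, q.weights, width) == pytest.approx(
            closed, abs=1e-12
        )

    @given(st.data())
    @settings(max_examples=40, deadline=None)
    def test_metric_properties(self, data):
        """Symmetry, identity of indiscernibles, triangle inequality."""
        k = data.draw(st.integers(2, 6))
        centers = np.cumsum(
            np.array(data.draw(st.lists(st.floats(0.1, 3), min_size=k, max_size=k)))
        )
        def sig():
            w = np.array(
                data.draw(st.lists(st.floats(0.01, 1), min_size=k, max_size=k))
            )
            return Signature(centers, w / w.sum())

        p, q, r = sig(), sig(), sig()
        assert emd(p, q) == pytest.approx(emd(q, p), abs=1e-12)
        assert emd(p, p) == pytest.approx(0.0, abs=1e-12)
        assert emd(p, r) <= emd(p, q) + emd(q, r) + 1e-9


class TestFdrGrid:
    def test_hand_worked_two_gene_grid(self):
        """Null medians (.5,.5), observed (2.0,.1), T=1: q = (0, 1).

        Gene 1 reaches t=1 where no null median does (FDR 0/1 = 0); gene 2
        only reaches thresholds where both observed EMDs and both medians
        qualify (FDR 2/2 = 1).
        """
        q, T, _ = fdr_qvalues(
            np.array([2.0, 0.1]), np.array([0.5, 0.5]), delta=0.001, T=1.0
        )
        np.testing.assert_allclose(q, [0.0, 1.0])

    def test_default_grid_top(self):
        """T defaults to round(max observed) - 1, floored at delta."""
        _, T, thresholds = fdr_qvalues(
            np.array([3.2, 0.5]), np.array([0.1, 0.1]), delta=0.001
        )
        assert T == 2.0
        assert thresholds[0] == pytest.approx(2.0)
        assert thresholds[-1] == 0.0
        _, T_small, _ = fdr_qvalues(
            np.array([0.3, 0.2]), np.array([0.1, 0.1]), delta=0.001
        )
        assert T_small == pytest.approx(0.001)

    def test_qvalues_within_unit_interval(self):
        rng = np.random.default_rng(5)
        obs = rng.exponential(1.0, 200)
        med = rng.exponential(1.0, 200)
        q, _, _ = fdr_qvalues(obs, med, delta=0.01)
        assert np.all((q >= 0) & (q <= 1))


class TestEmdQvalues:
    def _two_group_frame(self, rng, n_genes=50, n_per_group=15, shift_first=0.0):
        X = rng.normal(0, 1, size=(n_genes, 2 * n_per_group))
        X[0, :n_per_group] += shift_first
        expr = pd.DataFrame(
            X,
            index=[f"g{i:03d}" for i in range(n_genes)],
            columns=[f"s{i:03d}" for i in range(2 * n_per_group)],
        )
        labels = ["A"] * n_per_group + ["B"] * n_per_group
        return expr, labels

    def test_constant_data_all_q_one(self):
        expr = pd.DataFrame(
            np.ones((5, 8)), index=list("abcde"), columns=[f"s{i}" for i in range(8)]
        )
        cfg = Config(n_permutations=20)
        res = emd_qvalues(expr, ["A"] * 4 + ["B"] * 4, cfg, seed=0)
        assert np.all(res["emd"] == 0.0)
        assert np.all(res["q_value"] == 1.0)

    def test_invariant_to_gene_order_and_relabeling(self):
        rng = np.random.default_rng(7)
        expr, labels = self._two_group_frame(rng, shift_first=3.0)
        cfg = Config(n_permutations=50)
        res = emd_qvalues(expr, labels, cfg, seed=3)
        shuffled = expr.sample(frac=1, random_state=1)
        res_shuffled = emd_qvalues(shuffled, labels, cfg, seed=3)
        pd.testing.assert_series_equal(
            res["q_value"].sort_index(), res_shuffled["q_value"].sort_index()
        )
        swapped = ["B" if l == "A" else "A" for l in labels]
        res_swapped = emd_qvalues(expr, swapped, cfg, seed=3)
        pd.testing.assert_frame_equal(res, res_swapped)

    def test_planted_gene_detected(self):
        rng = np.random.default_rng(11)
        expr, labels = self._two_group_frame(rng, shift_first=3.0)
        cfg = Config(n_permutations=100)
        res = emd_qvalues(expr, labels, cfg, seed=2)
        assert res.loc["g000", "q_value"] < 0.1

    def test_small_group_rejected(self):
        expr = pd.DataFrame(np.random.default_rng(0).normal(size=(3, 5)),
                            columns=[f"s{i}" for i in range(5)])
        with pytest.raises(ValueError, match="at least 2"):
            emd_qvalues(expr, ["A", "B", "B", "B", "B"], Config(), seed=0)


class TestSelectDifferential:
    def test_strict_threshold(self):
        res = pd.DataFrame({"q_value": [0.05, 0.1, 0.5]}, index=["a", "b", "c"])
        assert select_differential_genes(res, 0.1) == ["a"]

    def test_degenerate_thresholds(self):
        res = pd.DataFrame({"q_value": [0.05, 0.1, 0.5]}, index=["a", "b", "c"])
        assert select_differential_genes(res, 1.1) == ["a", "b", "c"]
        assert select_differential_genes(res, 0.0) == []
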