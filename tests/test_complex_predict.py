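"""Complex inference: abundance/expected counts, the four predictors, BH."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy import stats

from proxsim import (
    IterativeSettings,
    LRSettings,
    bh_adjust,
    ensemble_predict,
    expected_pla_count,
    fisher_detect,
    iterative_predict,
    lr_predict,
    pla_product_ids,
    protein_abundance,
    split_nonproximal,
)

from conftest import rank1_counts

IDS2 = pla_product_ids(["1", "2"])


def frame(rows, columns=IDS2):
    rows = np.atleast_2d(rows)
    return pd.DataFrame(rows, columns=columns,
                        index=[f"c{t}" for t in range(len(rows))])


class TestProteinAbundance:
    def test_homodimer_counts_twice(self):
        X = frame([[10, 0, 0, 0]])
        ab = protein_abundance(X)
        assert ab.loc["c0", "1"] == 20 and ab.loc["c0", "2"] == 0

    def test_heterodimer_counts_once_per_side(self):
        X = frame([[0, 7, 0, 0]])
        ab = protein_abundance(X)
        assert ab.loc["c0", "1"] == 7 and ab.loc["c0", "2"] == 7

    def test_tracks_true_abundance_on_simulated_data(self, fig3_sim):
        est = protein_abundance(fig3_sim.pla)
        truth = fig3_sim.truth.to_numpy().reshape(len(est), 3, 3)
        # true protein 1 copies = monomers + complex memberships; proxy via
        # complex counts dominates here, so rank correlation should be strong
        true_p1 = truth[:, 0, :].sum(1) + truth[:, :, 0].sum(1)
        rho = stats.spearmanr(est["1"], true_p1).statistic
        assert rho > 0.9


class TestExpectedPLACount:
    def test_two_by_two_diagonal(self):
        E = expected_pla_count(frame([[10, 0, 0, 10]]))
        assert E.loc["c0", "1:1"] == pytest.approx(5.0)
        assert E.loc["c0", "1:2"] == pytest.approx(5.0)

    def test_single_nonzero_entry_is_fixed_point(self):
        E = expected_pla_count(frame([[0, 9, 0, 0]]))
        np.testing.assert_allclose(E.loc["c0"], [0, 9, 0, 0])

    def test_margin_preservation_on_random_matrices(self, rng):
        ids3 = pla_product_ids(["a", "b", "c"])
        for _ in range(25):
            M = rng.integers(0, 30, size=(3, 3)).astype(float)
            X = pd.DataFrame([M.ravel()], columns=ids3, index=["c0"])
            E = expected_pla_count(X).to_numpy().reshape(3, 3)
            np.testing.assert_allclose(E.sum(1), M.sum(1), atol=1e-9)
            np.testing.assert_allclose(E.sum(0), M.sum(0), atol=1e-9)
            np.testing.assert_allclose(E.sum(), M.sum(), atol=1e-9)

    def test_all_zero_cell_yields_zero(self):
        E = expected_pla_count(frame([[0, 0, 0, 0]]))
        assert (E.to_numpy() == 0).all()


class TestIterativePredict:
    def test_first_iteration_matches_recurrence_by_hand(self):
        # X = [[10,0],[0,10]] per cell: Y11 after one sweep = 10 - 10*10/20
        X = frame(np.tile([10, 0, 0, 10], (5, 1)))
        pred = iterative_predict(X, IterativeSettings(max_iterations=1))
        assert pred.counts["1:1"].iloc[0] == pytest.approx(5.0)
        assert pred.counts["2:2"].iloc[0] == pytest.approx(5.0)
        assert not pred.converged

    def test_disjoint_homodimers_converge_to_full_attribution(self):
        # with zero off-diagonal counts the background shrinks to nothing
        X = frame(np.tile([10, 0, 0, 10], (5, 1)))
        pred = iterative_predict(X)
        assert pred.converged
        assert pred.counts["1:1"].iloc[0] == pytest.approx(10.0, abs=0.05)
        assert sorted(pred.detected[pred.detected].index) == ["1:1", "2:2"]

    def test_fixed_point_is_idempotent(self):
        # a converged solution does not move under one further sweep
        X = frame(np.tile([10, 0, 0, 10], (5, 1)))
        settings = IterativeSettings(tolerance=1e-9)
        converged = iterative_predict(X, settings)
        again = iterative_predict(X, IterativeSettings(max_iterations=1),
                                  init=converged.counts)
        np.testing.assert_allclose(again.counts.to_numpy(),
                                   converged.counts.to_numpy(), atol=1e-6)

    def test_null_simulation_detects_nothing(self, null_sim):
        pred = iterative_predict(null_sim.pla)
        assert not pred.detected.any()
        assert (pred.counts.to_numpy() == 0).all()

    def test_symmetry_rule_fills_failing_partner(self):
        # 1:2 enriched, 2:1 at expectation: after one sweep 2:1 is carried
        # by the symmetry condition at sym_weight times its mirror
        X = rank1_counts()
        pred = iterative_predict(
            X, IterativeSettings(sym_weight=0.5, max_iterations=1))
        assert pred.detected["1:2"] and pred.detected["2:1"]
        assert pred.pvalues_adj["2:1"] > 0.05  # failed its own test
        np.testing.assert_allclose(pred.counts["2:1"],
                                   0.5 * pred.counts["1:2"])

    def test_requires_two_cells(self):
        with pytest.raises(ValueError, match="2 cells"):
            iterative_predict(frame([[1, 0, 0, 1]]))


class TestLRPredict:
    @staticmethod
    def nonproximal(ap, bp, names=("1", "2")):
        cols = {f"{p}:free_oligo_B": ap[:, k] for k, p in enumerate(names)}
        cols.update({f"free_oligo_A:{p}": bp[:, k]
                     for k, p in enumerate(names)})
        return pd.DataFrame(cols, index=[f"c{t}" for t in range(len(ap))])

    def test_constant_response_gives_pure_intercept(self, rng):
        n = 30
        ap = rng.integers(5, 50, size=(n, 2)).astype(float)
        bp = rng.integers(5, 50, size=(n, 2)).astype(float)
        X = frame(np.tile([9.0, 0, 0, 0], (n, 1)))
        pred = lr_predict(X, self.nonproximal(ap, bp))
        assert pred.beta1["1:1"] == pytest.approx(0.0, abs=1e-10)
        assert pred.beta0["1:1"] == pytest.approx(9.0)
        assert pred.detected["1:1"]
        np.testing.assert_allclose(pred.counts["1:1"], 9.0)

    def test_pure_noise_is_not_called(self, rng):
        # X exactly proportional to A'B': zero intercept, no complex
        n = 30
        ap = rng.integers(50, 200, size=(n, 2)).astype(float)
        bp = rng.integers(50, 200, size=(n, 2)).astype(float)
        kappa = 2.5e-5 * 40  # keep counts O(10)
        rows = np.zeros((n, 4))
        rows[:, 0] = kappa * ap[:, 0] * bp[:, 0]
        pred = lr_predict(frame(rows), self.nonproximal(ap, bp))
        assert pred.beta0["1:1"] == pytest.approx(0.0, abs=1e-8)
        assert pred.beta1["1:1"] == pytest.approx(kappa)
        assert not pred.detected.any()
        assert (pred.counts.to_numpy() == 0).all()

    def test_zero_free_oligo_product_is_flagged_unreliable(self, rng):
        n = 30
        ap = rng.integers(5, 50, size=(n, 2)).astype(float)
        bp = rng.integers(5, 50, size=(n, 2)).astype(float)
        ap[:, 1] = 0  # protein 2 never has free probe A
        X = frame(np.tile([9.0, 0, 9.0, 0], (n, 1)))
        pred = lr_predict(X, self.nonproximal(ap, bp))
        assert not pred.detected["2:1"]
        assert "2:1" in pred.flags["unreliable"]
        assert pred.detected["1:1"]

    def test_missing_protein_in_free_oligo_table_raises(self, fig3_sim):
        incomplete = fig3_sim.nonproximal.drop(columns=["2:free_oligo_B"])
        with pytest.raises(ValueError, match="missing"):
            lr_predict(fig3_sim.pla, incomplete)

    def test_interaction_rescaling_leaves_fit_invariant(self, rng):
        # huge A'B' triggers the automatic 1e-6 rescale; slope and counts
        # must come out on the original scale
        n = 50
        ap = rng.integers(2000, 9000, size=(n, 2)).astype(float)
        bp = rng.integers(2000, 9000, size=(n, 2)).astype(float)
        kappa = 2.5e-5
        rows = np.zeros((n, 4))
        rows[:, 0] = 5.0 + kappa * ap[:, 0] * bp[:, 0] + rng.normal(0, .3, n)
        pred = lr_predict(frame(rows), self.nonproximal(ap, bp))
        assert pred.beta1["1:1"] == pytest.approx(kappa, rel=0.1)
        assert pred.beta0["1:1"] == pytest.approx(5.0, rel=0.2)


class TestEnsemblePredict:
    def test_reduces_to_iterative_when_lr_finds_nothing(self, null_sim):
        ens = ensemble_predict(null_sim.pla, null_sim.nonproximal)
        it = iterative_predict(null_sim.pla)
        pd.testing.assert_frame_equal(ens.counts, it.counts)
        assert ens.method == "ensemble"

    def test_detects_fig3_complex_block(self, fig3_sim):
        ens = ensemble_predict(fig3_sim.pla, fig3_sim.nonproximal)
        assert sorted(ens.detected[ens.detected].index) == [
            "1:1", "1:2", "2:1", "2:2"]


class TestFisherDetect:
    def test_zero_count_is_never_called(self):
        X = frame([[0, 5, 5, 20]])
        res = fisher_detect(X)
        assert res.pvalues_adj.loc["c0", "1:1"] == 1.0
        assert not res.calls.loc["c0", "1:1"]

    def test_matches_exact_tail_oracle_on_random_tables(self, rng):
        # brute-force hypergeometric tail sum over all tables with the
        # observed margins
        def oracle(x, r, c, tot):
            hi = min(r, c)
            return sum(stats.hypergeom.pmf(k, tot, r, c)
                       for k in range(x, hi + 1))

        tables = rng.integers(0, 40, size=(100, 4))
        for a, b, c, d in tables:
            tot = a + b + c + d
            if tot == 0:
                continue
            X = frame([[a, b, c, d]])
            res = fisher_detect(X)
            # undo the within-cell BH to compare the raw p for product 1:1
            raw = stats.hypergeom.sf(a - 1, tot, a + b, a + c)
            want = oracle(a, a + b, a + c, tot)
            assert raw == pytest.approx(want, rel=1e-10)
            p_scipy = stats.fisher_exact([[a, b], [c, d]],
                                         alternative="greater")[1]
            assert raw == pytest.approx(p_scipy, rel=1e-9)

    def test_fig3_population_fractions(self, fig3_sim):
        res = fisher_detect(fig3_sim.pla)
        frac = res.positive_fraction
        four = ["1:1", "1:2", "2:1", "2:2"]
        assert (frac[four] > 0.05).all()
        assert (frac.drop(four) < 0.02).all()


class TestBHAdjust:
    @staticmethod
    def oracle(p):
        # textbook step-up: p_(k) * m / k, cumulative minimum from the top
        p = np.asarray(p, float)
        m = len(p)
        order = np.argsort(p)
        adj = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            idx = order[rank - 1]
            running = min(running, p[idx] * m / rank)
            adj[idx] = running
        return adj

    def test_matches_step_up_oracle_exactly(self, rng):
        for m in [1, 2, 5, 11, 20]:
            for _ in range(20):
                p = rng.random(m)
                np.testing.assert_allclose(bh_adjust(p), self.oracle(p),
                                           atol=1e-12)

    def test_nan_treated_as_one(self):
        out = bh_adjust([0.01, np.nan, 0.02])
        assert out[1] == 1.0


@settings(max_examples=50, deadline=None, derandomize=True)
@given(arrays(np.int64, (3, 3), elements=st.integers(0, 50)))
def test_expected_count_margins_property(M):
    """Margin preservation of the expected-count estimate holds for any
    non-negative integer matrix."""
    X = pd.DataFrame([M.ravel().astype(float)],
                     columns=pla_product_ids(["a", "b", "c"]), index=["c0"])
    E = expected_pla_count(X).to_numpy().reshape(3, 3)
    np.testing.assert_allclose(E.sum(1), M.sum(1), atol=1e-9)
    np.testing.assert_allclose(E.sum(0), M.sum(0), atol=1e-9)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=20))
def test_bh_adjust_property(pvals):
    """BH output equals the step-up oracle and is monotone in the input
    order statistics."""
    adj = bh_adjust(pvals)
    np.testing.assert_allclose(adj, TestBHAdjust.oracle(pvals), atol=1e-12)
    order = np.argsort(pvals)
    assert (np.diff(adj[order]) >= -1e-12).all()
    assert (adj >= np.asarray(pvals) - 1e-12).all() and (adj <= 1).all()


def test_split_nonproximal_routing(fig3_sim):
    ap, bp = split_nonproximal(fig3_sim.nonproximal)
    assert list(ap.columns) == ["1", "2", "3"]
    assert list(bp.columns) == ["1", "2", "3"]
    with pytest.raises(ValueError, match="free_oligo"):
        split_nonproximal(pd.DataFrame({"1:2": [1]}))
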