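"""Band selectors: WRC peak semantics against an exhaustive scan, SFS
against a literal greedy loop, SPA against the projection recursion,
stepwise against closed-form partial-F statistics, pooling, and the
nesting / orthogonality invariants."""

import numpy as np
import pandas as pd
import pytest

from ovonir import selection
from ovonir.selection import (
    partial_f_pvalue,
    pool_bands,
    sfs_select,
    spa_chain,
    spa_select,
    stepwise_select,
    wrc_select,
    SelectionResult,
)
from ovonir.spectra import SpectraSet


def make_set(X, y, axis=None):
    X = np.asarray(X, dtype=float)
    axis = np.arange(X.shape[1], dtype=float) if axis is None else np.asarray(axis, float)
    return SpectraSet(
        X=X, axis=axis, y=np.asarray(y, int), egg_id=np.arange(len(y)).astype(str)
    )


def balanced_labels(n):
    return np.tile([0, 1, 2], int(np.ceil(n / 3)))[:n]


# ---------------------------------------------------------------------------
# WRC


class TestWRC:
    AXIS = np.linspace(500.0, 600.0, 51)

    def test_two_isolated_spikes_selected_exactly(self):
        wb = np.zeros(51)
        wb[[10, 30]] = [1.0, 2.0]
        res = wrc_select(wb, self.AXIS, np.ones(51), k_max=5)
        assert set(res.indices) == {10, 30}

    def test_monotone_curve_has_no_interior_peaks(self):
        with pytest.raises(ValueError, match="peak"):
            wrc_select(np.linspace(0, 1, 51), self.AXIS, np.ones(51), k_max=3)

    def test_matches_exhaustive_triple_scan_oracle(self):
        """Peaks and ranking equal a brute-force scan of all interior
        triples followed by an explicit sort."""
        rng = np.random.default_rng(0)
        t = np.linspace(0, 4 * np.pi, 51)
        wb = np.sin(t) + 0.3 * rng.normal(size=51)
        intensity = np.abs(rng.uniform(0.5, 1.0, size=51))
        res = wrc_select(wb, self.AXIS, intensity, k_max=4)
        mag = np.abs(wb)
        oracle_peaks = [
            j for j in range(1, 50) if mag[j] > mag[j - 1] and mag[j] > mag[j + 1]
        ]
        scored = sorted(oracle_peaks, key=lambda j: -(mag[j] * intensity[j]))
        assert set(res.indices) == set(scored[:4])

    def test_plateau_collapses_to_center(self):
        wb = np.zeros(51)
        wb[20:23] = 1.0  # plateau of width 3 -> center index 21
        res = wrc_select(wb, self.AXIS, np.ones(51), k_max=3)
        assert list(res.indices) == [21]

    def test_intensity_weighting_changes_ranking(self):
        wb = np.zeros(51)
        wb[[10, 30]] = [1.0, 0.9]
        intensity = np.ones(51)
        intensity[10], intensity[30] = 0.1, 1.0  # strong peak in a dark region
        res = wrc_select(wb, self.AXIS, intensity, k_max=1)
        assert list(res.indices) == [30]


# ---------------------------------------------------------------------------
# SFS


class TestSFS:
    def test_noiseless_label_column_found_first(self):
        rng = np.random.default_rng(1)
        y = balanced_labels(60)
        X = rng.normal(size=(60, 8))
        X[:, 5] = y
        res = sfs_select(make_set(X, y), k=1, folds=5, seed=0)
        assert list(res.indices) == [5]

    def test_matches_literal_greedy_loop(self):
        """Three steps on a p=6 toy set equal an independent re-run of the
        greedy candidate evaluation."""
        rng = np.random.default_rng(2)
        y = balanced_labels(45)
        X = rng.normal(size=(45, 6))
        X[:, 1] += y
        X[:, 4] += (y == 2) * 1.5
        ds = make_set(X, y)
        res = sfs_select(ds, k=3, folds=4, seed=3)

        chosen = []
        for _ in range(3):
            errs = {}
            for col in range(6):
                if col in chosen:
                    continue
                errs[col] = selection._cv_misclassification(
                    X[:, chosen + [col]], y, folds=4, seed=3
                )
            best = min(errs, key=lambda c: (errs[c], c))
            chosen.append(best)
        assert sorted(res.indices) == sorted(chosen)
        assert list(res.trace["index"]) == chosen

    def test_same_seed_identical_trace(self):
        rng = np.random.default_rng(4)
        y = balanced_labels(30)
        X = rng.normal(size=(30, 5))
        a = sfs_select(make_set(X, y), k=2, folds=3, seed=9)
        b = sfs_select(make_set(X, y), k=2, folds=3, seed=9)
        pd.testing.assert_frame_equal(a.trace, b.trace)

    def test_first_pick_is_single_column_optimum(self):
        """Greedy optimality at step 1, checked exhaustively over columns."""
        rng = np.random.default_rng(5)
        y = balanced_labels(60)
        X = rng.normal(size=(60, 12))
        X[:, 7] += 2 * y
        res = sfs_select(make_set(X, y), k=1, folds=5, seed=1)
        errs = [
            selection._cv_misclassification(X[:, [c]], y, folds=5, seed=1)
            for c in range(12)
        ]
        assert res.indices[0] == int(np.argmin(errs))

    def test_k_larger_than_p_rejected(self):
        ds = make_set(np.random.default_rng(6).normal(size=(9, 3)), balanced_labels(9))
        with pytest.raises(ValueError):
            sfs_select(ds, k=4)


# ---------------------------------------------------------------------------
# SPA


class TestSPA:
    def test_orthogonal_columns_picked_in_norm_order(self):
        """With mutually orthogonal columns, the chain from a fixed start
        follows descending residual norm exactly."""
        Q = np.linalg.qr(np.random.default_rng(7).normal(size=(20, 5)))[0]
        norms = np.array([5.0, 4.0, 3.0, 2.0, 1.0])
        X = Q * norms  # columns orthogonal with distinct norms
        chain, _ = spa_chain(X, start=3, k=5)
        # after the start column, the rest follow descending norms
        assert chain == [3, 0, 1, 2, 4]

    def test_duplicated_column_never_selected_twice(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(15, 6))
        X[:, 5] = X[:, 2]
        chain, _ = spa_chain(X - X.mean(axis=0), start=2, k=6)
        assert 5 not in chain or 2 not in chain[1:]
        assert len(set(chain)) == len(chain)

    def test_matches_literal_projection_recursion(self):
        """Chain from every start equals an independently coded
        project-then-argmax recursion on random 15 x 30 data."""
        rng = np.random.default_rng(9)
        X = rng.normal(size=(15, 30))
        Xc = X - X.mean(axis=0)
        for start in (0, 7, 21):
            chain, _ = spa_chain(Xc, start=start, k=5)
            ref = [start]
            for _ in range(4):
                projected = {}
                for j in range(30):
                    if j in ref:
                        continue
                    v = Xc[:, j].copy()
                    # Gram-Schmidt against the raw selected columns
                    basis = np.linalg.qr(Xc[:, ref])[0]
                    v = v - basis @ (basis.T @ v)
                    projected[j] = np.linalg.norm(v)
                ref.append(max(projected, key=projected.get))
            assert chain == ref

    def test_projected_candidates_orthogonal_to_selected_span(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(15, 30))
        Xc = X - X.mean(axis=0)
        chain, _ = spa_chain(Xc, start=4, k=6)
        for step in range(1, len(chain)):
            sel = Xc[:, chain[:step]]
            basis = np.linalg.qr(sel)[0]
            v = Xc[:, chain[step]]
            proj = v - basis @ (basis.T @ v)
            for s in range(step):
                inner = abs(proj @ Xc[:, chain[s]])
                assert inner <= 1e-10 * np.linalg.norm(Xc[:, chain[s]]) * (
                    np.linalg.norm(proj) + 1e-30
                ) + 1e-10

    def test_default_k_is_three(self, tiny_set):
        res = spa_select(tiny_set, seed=0)
        assert res.k == 3

    def test_rank_exhausted_chain_stops_early(self):
        base = np.random.default_rng(11).normal(size=(10, 1))
        X = np.hstack([base * s for s in (1.0, 2.0, 3.0)])  # rank 1
        chain, _ = spa_chain(X - X.mean(axis=0), start=0, k=3)
        assert len(chain) == 1


# ---------------------------------------------------------------------------
# Pooling


class TestPooling:
    def test_published_selector_sets_pool_to_their_union(self):
        """The three selector sets for the silver lamp pool to the sorted
        union of their wavelengths."""
        axis = np.arange(550.0, 600.0)

        def res(method, waves):
            idx = np.array([int(w - 550) for w in waves])
            return SelectionResult(method, np.array(waves, float), idx)

        wrc = res("wrc", [556, 566, 578, 596])
        sfs = res("sfs", [577, 597, 598])
        spa = res("spa", [577, 589, 598])
        pooled = pool_bands([wrc, sfs, spa])
        assert list(pooled.wavelengths_nm) == [556, 566, 577, 578, 589, 596, 597, 598]

    def test_disjoint_sets_concatenate(self):
        a = SelectionResult("sfs", np.array([510.0, 520.0, 530.0]), np.array([0, 1, 2]))
        b = SelectionResult("spa", np.array([540.0, 550.0, 560.0]), np.array([3, 4, 5]))
        assert pool_bands([a, b]).k == 6

    def test_identical_sets_deduplicate(self):
        a = SelectionResult("sfs", np.array([510.0, 520.0]), np.array([0, 1]))
        assert pool_bands([a, a]).k == 2

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            pool_bands([])


# ---------------------------------------------------------------------------
# Stepwise


def simulate_regression_set(seed, n=60, p=8, strong=()):
    rng = np.random.default_rng(seed)
    y = balanced_labels(n)
    X = rng.normal(size=(n, p))
    for col, scale in strong:
        X[:, col] += scale * y
    return make_set(X, y)


class TestStepwise:
    def test_single_true_effect_found_alone(self):
        """One strongly predictive column among noise enters; nothing else
        clears a 1e-4 threshold."""
        ds = simulate_regression_set(12, n=90, p=10, strong=[(4, 1.0)])
        res = stepwise_select(ds, p_enter=1e-4)
        assert list(res.indices) == [4]
        assert res.trace.iloc[0]["p_value"] < 1e-6

    def test_loose_threshold_admits_all_columns(self):
        ds = simulate_regression_set(13, n=60, p=5, strong=[(0, 1.0)])
        res = stepwise_select(ds, p_enter=0.999999)
        assert res.k == 5

    def test_pass_through_returns_pooled_set(self):
        ds = simulate_regression_set(14, n=30, p=6)
        res = stepwise_select(ds, p_enter=None)
        assert list(res.indices) == list(range(6))

    def test_pvalues_match_closed_form_nested_ols(self):
        """Every traced p-value equals the partial-F survival probability
        computed from independently fitted nested OLS models."""
        import statsmodels.api as sm

        ds = simulate_regression_set(15, n=60, p=6, strong=[(1, 0.8), (3, 0.5)])
        res = stepwise_select(ds, p_enter=0.999999)
        y = ds.y.astype(float)
        chosen: list[int] = []
        for _, row in res.trace.iterrows():
            col = int(row["index"])
            Z0 = sm.add_constant(ds.X[:, chosen]) if chosen else np.ones((ds.n, 1))
            Z1 = sm.add_constant(ds.X[:, chosen + [col]])
            fit0 = sm.OLS(y, Z0).fit()
            fit1 = sm.OLS(y, Z1).fit()
            fstat, pval, _ = fit1.compare_f_test(fit0)
            assert row["p_value"] == pytest.approx(pval, abs=1e-10)
            chosen.append(col)

    @pytest.mark.parametrize("seed", range(100))
    def test_nesting_across_thresholds(self, seed):
        """selected(1e-4) <= selected(1e-3) <= selected(1e-2) <= selected(0.05)
        over 100 simulated datasets."""
        ds = simulate_regression_set(seed, n=45, p=6, strong=[(0, 0.7), (3, 0.3)])
        sets = [
            set(stepwise_select(ds, p_enter=p).indices)
            for p in (1e-4, 1e-3, 1e-2, 0.05)
        ]
        for smaller, larger in zip(sets, sets[1:]):
            assert smaller <= larger

    def test_partial_f_pvalue_closed_form(self):
        from scipy import stats

        rss0, rss1, n, k1 = 10.0, 8.0, 50, 3
        f = (rss0 - rss1) / (rss1 / (n - k1 - 1))
        assert partial_f_pvalue(rss0, rss1, n, k1) == pytest.approx(
            stats.f.sf(f, 1, n - k1 - 1), abs=1e-15
        )


# ---------------------------------------------------------------------------
# Cascade (on the session-scoped default dataset)


class TestCascade:
    def test_every_selector_recovers_the_hemoglobin_band(self, default_cascade):
        """WRC, SFS and SPA each place a band within +-3 nm of the
        generative hemoglobin center at 577 nm."""
        results, _ = default_cascade
        for method in ("wrc", "sfs", "spa"):
            nearest = np.min(np.abs(results[method].wavelengths_nm - 577.0))
            assert nearest <= 3.0, f"{method} nearest band {nearest:.1f} nm away"

    def test_selector_cutoffs(self, default_cascade):
        results, _ = default_cascade
        assert results["sfs"].k == 3
        assert results["spa"].k == 3
        assert results["wrc"].k <= 5

    def test_pass_through_row_equals_pooled_set(self, default_cascade):
        results, rows = default_cascade
        pass_row = [r for r in rows if r.threshold is None][0]
        assert pass_row.n_bands == results["pooled"].k

    def test_report_has_four_thresholds_plus_pass_through(self, default_cascade):
        _, rows = default_cascade
        thresholds = [r.threshold for r in rows]
        assert thresholds == [None, 0.05, 0.01, 0.001, 0.0001]

    def test_band_counts_nested_across_thresholds(self, default_cascade):
        _, rows = default_cascade
        counts = [r.n_bands for r in rows]
        assert all(b >= a for a, b in zip(counts[1:], counts[:-1]))

    def test_selected_bands_inside_selection_window(self, default_cascade):
        results, _ = default_cascade
        for method in ("wrc", "sfs", "spa", "pooled"):
            waves = results[method].wavelengths_nm
            assert np.all((waves >= 550.0) & (waves <= 600.0))
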