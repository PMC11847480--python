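"""Feature extraction, GMM-EM, model selection, PCA and landscapes."""

import numpy as np
import pandas as pd
import pytest

from complexdyn.states import (
    FeatureTable,
    fit_gmm,
    free_energy_landscape,
    pca_features,
    representative_frames,
    select_k,
)
from complexdyn.structure_io import Trajectory
from complexdyn.synthetic import build_toy_complex, preset, simulate_trajectory
from complexdyn.states import extract_features


class TestExtractFeatures:
    def test_noise_free_single_state_exact(self):
        spec = preset("single-state-noise-free")
        toy = build_toy_complex(spec)
        traj, _ = simulate_trajectory(toy)
        feats = extract_features(
            traj, toy.domains["L"],
            (toy.domains["G1"], toy.domains["G2"]),
            (toy.domains["R1"], toy.domains["R2"]),
        )
        X = feats.matrix()
        np.testing.assert_allclose(X[:, 0], 60.0, atol=1e-6)
        np.testing.assert_allclose(X[:, 1], 57.0, atol=1e-6)
        np.testing.assert_allclose(X[:, 2], 58.0, atol=1e-6)
        np.testing.assert_allclose(X[:, 3], 44.0, atol=1e-6)

    def test_row_count_matches_frames(self, three_state_features):
        assert three_state_features.n_frames == 5000

    def test_frame_permutation_permutes_rows(self, single_state_run):
        toy, traj, _ = single_state_run
        sub = Trajectory(topology=traj.topology, coords=traj.coords[:50],
                         times=traj.times[:50])
        perm = np.random.default_rng(0).permutation(50)
        permuted = Trajectory(topology=traj.topology,
                              coords=sub.coords[perm], times=sub.times)
        args = (toy.domains["L"],
                (toy.domains["G1"], toy.domains["G2"]),
                (toy.domains["R1"], toy.domains["R2"]))
        a = extract_features(sub, *args).matrix()
        b = extract_features(permuted, *args).matrix()
        np.testing.assert_allclose(b, a[perm], atol=1e-12)


def _table(X):
    df = pd.DataFrame(X, columns=["angle_a_deg", "angle_b_deg",
                                  "dist_1_A", "dist_2_A"])
    df.insert(0, "time_ns", np.arange(len(X), dtype=float))
    df.insert(0, "frame", np.arange(len(X)))
    return FeatureTable(df=df)


def _two_component_data(seed=0, n=1000):
    """1-D bimodal signal embedded in 4-D (other features near-constant)."""
    rng = np.random.default_rng(seed)
    x = np.concatenate([rng.normal(0, 1, n), rng.normal(10, 1, n)])
    other = rng.normal(0, 1e-3, size=(2 * n, 3)) + 5.0
    return np.column_stack([x, other])


class TestGMM:
    def test_k1_closed_form(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(200, 4)) @ np.diag([1.0, 2.0, 0.5, 3.0]) + 1.0
        m = fit_gmm(X, 1, seed=0)
        np.testing.assert_allclose(m.means_physical[0], X.mean(axis=0),
                                   atol=1e-9)
        Z = m.standardize(X)
        sample_cov = (Z - Z.mean(0)).T @ (Z - Z.mean(0)) / len(Z)
        np.testing.assert_allclose(m.estimator.covariances_[0], sample_cov,
                                   atol=2e-6)
        assert m.weights[0] == pytest.approx(1.0)

    def test_log_likelihood_monotone(self):
        m = fit_gmm(_two_component_data(seed=1), 2, seed=0)
        trace = m.estimator.ll_trace_
        assert np.all(np.diff(trace) >= -1e-6 * np.abs(trace[:-1]))

    def test_two_component_recovery(self):
        """Means within 0.15 standardized units, weights within 0.05."""
        X = _two_component_data(seed=0, n=1000)
        m = fit_gmm(X, 2, seed=0)
        mean_x = np.sort(m.means_physical[:, 0])
        sd_x = m.scaler_sd[0]
        assert abs(mean_x[0] - 0.0) / sd_x <= 0.15
        assert abs(mean_x[1] - 10.0) / sd_x <= 0.15
        np.testing.assert_allclose(np.sort(m.weights), [0.5, 0.5], atol=0.05)

    def test_agrees_with_sklearn(self):
        """Independent EM implementation lands on the same solution."""
        from sklearn.mixture import GaussianMixture

        X = _two_component_data(seed=2, n=500)
        mine = fit_gmm(X, 2, seed=0)
        Z = mine.standardize(X)
        ref = GaussianMixture(2, covariance_type="full", n_init=3,
                              random_state=0).fit(Z)
        np.testing.assert_allclose(
            np.sort(mine.estimator.means_[:, 0]),
            np.sort(ref.means_[:, 0]), atol=0.02,
        )
        np.testing.assert_allclose(np.sort(mine.weights),
                                   np.sort(ref.weights_), atol=0.02)

    def test_reproducible_for_fixed_seed(self):
        X = _two_component_data(seed=4, n=300)
        a = fit_gmm(X, 2, seed=123)
        b = fit_gmm(X, 2, seed=123)
        np.testing.assert_array_equal(a.estimator.means_, b.estimator.means_)
        np.testing.assert_array_equal(a.estimator.responsibilities_,
                                      b.estimator.responsibilities_)

    def test_responsibilities_rows_sum_to_one(self):
        m = fit_gmm(_two_component_data(seed=5, n=200), 2, seed=0)
        np.testing.assert_allclose(
            m.estimator.responsibilities_.sum(axis=1), 1.0, atol=1e-9
        )

    def test_weights_sum_to_one(self):
        m = fit_gmm(_two_component_data(seed=6, n=200), 3, seed=0)
        assert m.weights.sum() == pytest.approx(1.0, abs=1e-9)

    def test_needs_ten_rows_per_component(self):
        with pytest.raises(ValueError, match="at least"):
            fit_gmm(_two_component_data(n=8)[:15], 2)

    def test_bic_aic_parameter_count(self):
        m = fit_gmm(_two_component_data(seed=7, n=200), 2, seed=0)
        # K-1 weights + K*d means + K*d(d+1)/2 covariance entries, d=4
        assert m.estimator.n_parameters_ == 1 + 8 + 20
        ll = m.estimator.log_likelihood_
        assert m.bic == pytest.approx(-2 * ll + 29 * np.log(400))
        assert m.aic == pytest.approx(-2 * ll + 2 * 29)


class TestSelectK:
    def test_table_has_requested_rows(self):
        ks = select_k(_two_component_data(seed=0, n=200), range(1, 5), seed=0)
        assert list(ks.table["K"]) == [1, 2, 3, 4]

    def test_three_state_preset_chooses_three(self, three_state_features):
        ks = select_k(three_state_features, range(1, 7), seed=0, n_restarts=3)
        assert ks.chosen_k == 3

    def test_single_gaussian_chooses_one(self):
        """BIC consistency: plain Gaussian data selects K=1 across seeds."""
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            X = rng.normal(size=(500, 4))
            ks = select_k(X, range(1, 4), seed=seed, n_restarts=2)
            hits += ks.chosen_k == 1
        assert hits >= 19

    def test_bic_tie_resolves_to_smaller_k(self):
        table = pd.DataFrame(
            {"K": [1, 2], "BIC": [10.0, 10.0], "AIC": [9.0, 8.0]}
        )
        # mimic the tie rule used by select_k
        best = table.loc[table["BIC"].idxmin()]
        chosen = int(table[np.isclose(table["BIC"], best["BIC"])]["K"].min())
        assert chosen == 1


class TestPCA:
    def test_single_direction_explains_everything(self):
        t = np.linspace(0, 1, 50)
        X = np.outer(t, [1.0, 2.0, -1.0, 0.5]) + 3.0
        res = pca_features(X)
        assert res.explained_fractions[0] == pytest.approx(1.0, abs=1e-9)

    def test_fractions_sum_to_one(self):
        X = np.random.default_rng(0).normal(size=(100, 4))
        res = pca_features(X)
        assert res.explained_fractions.sum() == pytest.approx(1.0, abs=1e-9)

    def test_isotropic_gaussian_equal_fractions(self):
        X = np.random.default_rng(1).normal(size=(5000, 4))
        res = pca_features(X)
        np.testing.assert_allclose(res.explained_fractions, 0.25, atol=0.03)

    def test_sign_convention(self):
        X = np.random.default_rng(2).normal(size=(200, 4))
        res = pca_features(X)
        for j in range(4):
            lead = np.argmax(np.abs(res.loadings[:, j]))
            assert res.loadings[lead, j] > 0

    def test_zero_variance_feature_named(self):
        X = np.random.default_rng(3).normal(size=(50, 4))
        X[:, 2] = 7.0
        with pytest.raises(ValueError, match="dist_1_A"):
            pca_features(X)


class TestRepresentatives:
    def test_exact_mean_frame_selected(self):
        X = _two_component_data(seed=0, n=100)
        m = fit_gmm(X, 2, seed=0)
        # plant a frame exactly at each standardized cluster mean
        planted = m.means_physical
        X2 = np.vstack([X, planted])
        m2 = fit_gmm(X2, 2, seed=0)
        reps = representative_frames(X2, m2)
        planted_rows = {len(X), len(X) + 1}
        picked = set(reps.values())
        # the planted rows are within numerical wiggle of the means
        Z = m2.standardize(X2)
        for k, idx in reps.items():
            d_planted = min(
                np.linalg.norm(Z[r] - m2.means_standardized[k])
                for r in planted_rows
            )
            d_picked = np.linalg.norm(Z[idx] - m2.means_standardized[k])
            assert d_picked <= d_planted + 1e-9

    def test_tie_resolves_to_earliest_frame(self):
        rng = np.random.default_rng(0)
        X = rng.normal(0, 1, size=(60, 4))
        m = fit_gmm(X, 1, seed=0)
        mu = m.means_physical[0]
        sd = m.scaler_sd
        # two frames equidistant from the mean (opposite offsets)
        X2 = np.vstack([X, mu + 0.001 * sd, mu - 0.001 * sd])
        m2 = fit_gmm(X2, 1, seed=0)
        reps = representative_frames(X2, m2)
        assert reps[0] == len(X)  # the earlier of the two equidistant frames

    def test_representatives_match_ground_truth_states(
        self, three_state_run, three_state_features
    ):
        toy, traj, sidecar = three_state_run
        m = fit_gmm(three_state_features, 3, seed=0)
        truth = np.array(sidecar["states"])
        reps = representative_frames(three_state_features, m)
        assert len(reps) == 3
        for k, frame in reps.items():
            member = np.flatnonzero(m.labels == k)
            majority = np.bincount(truth[member]).argmax()
            assert truth[frame] == majority


class TestLandscape:
    def test_equal_counts_both_zero(self):
        a = np.concatenate([np.zeros(100), np.ones(100)])
        g = free_energy_landscape(a, a, n_bins=2)
        occupied = g.counts > 0
        np.testing.assert_allclose(g.free_energy_kt[occupied], 0.0,
                                   atol=1e-12)

    def test_boltzmann_closed_form(self):
        """Counts 100 vs 36 -> dG = ln(100/36) = 1.0217 kT exactly."""
        a = np.concatenate([np.zeros(100), np.ones(36)])
        g = free_energy_landscape(a, a, n_bins=2)
        occ = np.sort(g.free_energy_kt[g.counts > 0])
        assert occ[0] == 0.0
        assert occ[1] == pytest.approx(np.log(100 / 36), abs=1e-9)

    def test_gaussian_inversion_matches_quadratic_form(self):
        """Boltzmann inversion of a 2-D Gaussian recovers the quadratic
        potential: mean deviation <=0.2 kT in populated bins, and every
        well-populated bin individually within 0.2 kT."""
        rng = np.random.default_rng(0)
        xy = rng.normal(0.0, 1.0, size=(200_000, 2))
        g = free_energy_landscape(xy[:, 0], xy[:, 1], n_bins=32)
        xc = 0.5 * (g.x_edges[:-1] + g.x_edges[1:])
        yc = 0.5 * (g.y_edges[:-1] + g.y_edges[1:])
        X, Y = np.meshgrid(xc, yc, indexing="ij")
        analytic = 0.5 * (X**2 + Y**2)
        analytic -= analytic[g.min_bin]
        dev = np.abs(g.free_energy_kt - analytic)
        assert dev[g.counts >= 50].mean() <= 0.2
        assert dev[g.counts >= 500].max() <= 0.2

    def test_designed_state_centers_recovered(self, three_state_features):
        """The dominant designed geometry (60, 57 deg) is the landscape
        minimum within one bin width at 5000 frames."""
        df = three_state_features.df
        g = free_energy_landscape(df["angle_a_deg"].to_numpy(),
                                  df["angle_b_deg"].to_numpy(), n_bins=32)
        wx = g.x_edges[1] - g.x_edges[0]
        wy = g.y_edges[1] - g.y_edges[0]
        assert abs(g.min_center[0] - 60.0) <= wx
        assert abs(g.min_center[1] - 57.0) <= wy

    def test_min_zero_cap_and_nonnegative(self, three_state_features):
        df = three_state_features.df
        g = free_energy_landscape(df["angle_a_deg"].to_numpy(),
                                  df["angle_b_deg"].to_numpy())
        occupied = g.counts > 0
        assert g.free_energy_kt[occupied].min() == 0.0
        assert np.all(g.free_energy_kt >= 0)
        np.testing.assert_allclose(
            g.free_energy_kt[~occupied], g.cap_kt, atol=1e-12
        )
        assert g.cap_kt == pytest.approx(
            g.free_energy_kt[occupied].max() + 1.0
        )

    def test_kj_per_mol_conversion(self):
        a = np.concatenate([np.zeros(100), np.ones(36)])
        g = free_energy_landscape(a, a, n_bins=2, temperature=310.0)
        ratio = g.free_energy_kj_per_mol / np.where(
            g.free_energy_kt == 0, 1.0, g.free_energy_kt
        )
        occupied_nonzero = (g.counts > 0) & (g.free_energy_kt > 0)
        np.testing.assert_allclose(ratio[occupied_nonzero],
                                   0.0083145 * 310.0, rtol=1e-9)

    def test_degenerate_single_bin_warns(self):
        with pytest.warns(UserWarning, match="degenerate"):
            free_energy_landscape(np.zeros(200), np.zeros(200), n_bins=4)

    def test_landscape_minimum_agrees_with_dominant_cluster(
        self, three_state_run, three_state_features
    ):
        """The most stable landscape basin and the most populated GMM
        cluster identify the same ground-truth state."""
        _, _, sidecar = three_state_run
        truth = np.array(sidecar["states"])
        df = three_state_features.df
        g = free_energy_landscape(df["angle_a_deg"].to_numpy(),
                                  df["angle_b_deg"].to_numpy())
        m = fit_gmm(three_state_features, 3, seed=0)
        reps = representative_frames(three_state_features, m)
        biggest = np.bincount(m.labels).argmax()
        assert truth[g.min_frame] == truth[reps[int(biggest)]]
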