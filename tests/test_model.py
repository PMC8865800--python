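import numpy as np
import pytest
import scipy.optimize
import scipy.stats

from primus import (
    NuisanceDesign,
    ari,
    bic,
    denoise,
    fit,
    load_model,
    log_likelihood,
    save_model,
    select_k,
    simulate_primus,
    update_memberships,
    update_profiles,
)
from primus.model import PrimusModel, poisson_loglik


def _model(X, Z, memberships, k):
    return PrimusModel(
        X=np.asarray(X, float),
        Z=np.asarray(Z, float),
        memberships=np.asarray(memberships),
        k=k,
        log_likelihood=0.0,
        bic=0.0,
        n_iter=1,
        converged=True,
    )


class TestLogLikelihood:
    def test_single_entry_at_mle(self, empty_design):
        m = _model(np.zeros((1, 0)), [[3.0]], [0], 1)
        ll = log_likelihood(np.array([[3]]), empty_design(1), m)
        assert ll == pytest.approx(3 * np.log(3) - 3, abs=1e-12)

    def test_all_zero_counts_zero_model(self, empty_design):
        m = _model(np.zeros((2, 0)), np.zeros((2, 1)), [0, 0], 1)
        assert log_likelihood(np.zeros((2, 2)), empty_design(2), m) == 0.0

    def test_zero_rate_positive_count_is_minus_inf(self, empty_design):
        m = _model(np.zeros((1, 0)), [[0.0]], [0], 1)
        assert log_likelihood(np.array([[2]]), empty_design(1), m) == -np.inf

    def test_matches_poisson_logpmf_oracle(self, rng, empty_design):
        """Direct per-entry Poisson log-pmf (minus constants) agrees to 1e-10."""
        Y = rng.poisson(2.0, size=(10, 15))
        Z = rng.gamma(2.0, 1.0, size=(10, 3))
        members = rng.integers(0, 3, 15)
        G = rng.uniform(0.5, 2.0, 15)
        d = NuisanceDesign.empty(15, G)
        m = _model(np.zeros((10, 0)), Z, members, 3)
        mu = Z[:, members] * G
        oracle = (scipy.stats.poisson.logpmf(Y, mu) + scipy.special.gammaln(Y + 1)).sum()
        assert log_likelihood(Y, d, m) == pytest.approx(oracle, abs=1e-8)


class TestUpdateProfiles:
    def test_single_cluster_closed_form(self, empty_design):
        Y = np.array([[3, 5]])
        _, Z = update_profiles(Y, empty_design(2), np.array([0, 0]), k=1)
        assert Z[0, 0] == pytest.approx(4.0, rel=1e-10)

    def test_two_clusters_separable(self, empty_design):
        Y = np.array([[2, 4, 10, 14]])
        members = np.array([0, 0, 1, 1])
        _, Z = update_profiles(Y, empty_design(4), members, k=2)
        assert Z[0] == pytest.approx([3.0, 12.0], rel=1e-10)

    def test_all_zero_gene_rows_zero(self, empty_design):
        Y = np.array([[0, 0], [3, 1]])
        _, Z = update_profiles(Y, empty_design(2), np.array([0, 0]), k=1)
        assert Z[0, 0] == 0.0

    def test_matches_constrained_optimizer_with_nuisance(self, rng):
        """r=1 all-ones design: per-gene fit agrees with a generic optimizer."""
        n = 40
        Y = rng.poisson(3.0, size=(3, n)).astype(float)
        G = rng.uniform(0.5, 2.0, n)
        members = rng.integers(0, 2, n)
        d = NuisanceDesign(np.ones((1, n)), ["ones"], G)
        X, Z = update_profiles(Y, d, members, k=2, max_inner=4000, tol=1e-14)

        onehot = np.zeros((2, n))
        onehot[members, np.arange(n)] = 1.0
        for j in range(3):
            def nll(params, j=j):
                x, z0, z1 = params
                mu = (x + z0 * onehot[0] + z1 * onehot[1]) * G
                return -poisson_loglik(Y[j], mu)

            res = scipy.optimize.minimize(
                nll, x0=[0.5, 1.0, 1.0], bounds=[(0, None)] * 3, method="L-BFGS-B",
                options={"ftol": 1e-15, "gtol": 1e-12},
            )
            ours = -poisson_loglik(Y[j], (X[j, 0] + Z[j] @ onehot) * G)
            assert ours <= res.fun + 1e-6

    def test_never_decreases_likelihood(self, rng, empty_design):
        Y = rng.poisson(2.0, size=(8, 30)).astype(float)
        members = rng.integers(0, 2, 30)
        d = empty_design(30)
        X, Z = update_profiles(Y, d, members, k=2, max_inner=2)
        ll_before = poisson_loglik(Y, Z[:, members])
        X2, Z2 = update_profiles(Y, d, members, k=2, init=(X, Z), max_inner=5)
        ll_after = poisson_loglik(Y, Z2[:, members])
        assert ll_after >= ll_before - 1e-9 * (abs(ll_before) + 1)


class TestUpdateMemberships:
    def test_hand_arithmetic_single_gene(self, empty_design):
        # Y=2, rates 1 vs 5: ll -1 vs 2 ln5 - 5 = -1.781 -> cluster 0
        out = update_memberships(np.array([[2]]), empty_design(1), np.zeros((1, 0)), np.array([[1.0, 5.0]]))
        assert out[0] == 0

    def test_centroid_cell_self_consistent(self, rng, empty_design):
        Z = rng.gamma(2, 1, size=(20, 3)) + 0.5
        Y = np.round(Z[:, 1]).reshape(-1, 1)
        out = update_memberships(Y, empty_design(1), np.zeros((20, 0)), Z)
        assert out[0] == 1

    def test_duplicated_clusters_tie_to_lowest(self, rng, empty_design):
        Z = np.tile(rng.gamma(2, 1, size=(10, 1)), (1, 3))
        Y = rng.poisson(Z[:, 0], size=(5, 10)).T
        out = update_memberships(Y, empty_design(5), np.zeros((10, 0)), Z)
        assert np.all(out == 0)


class TestFit:
    def test_k1_closed_form_single_sweep(self, empty_design):
        Y = np.array([[1, 2, 3], [0, 0, 6]])
        m = fit(Y, empty_design(3), k=1, n_init=1, seed=0)
        assert np.allclose(m.Z[:, 0], [2.0, 2.0])
        assert m.converged

    def test_same_seed_bit_identical(self, small_dataset):
        d = small_dataset
        m1 = fit(d.counts, d.design, k=3, n_init=3, seed=7)
        m2 = fit(d.counts, d.design, k=3, n_init=3, seed=7)
        assert np.array_equal(m1.memberships, m2.memberships)
        assert np.array_equal(m1.Z, m2.Z)
        assert m1.log_likelihood == m2.log_likelihood

    def test_k_exceeding_cells_rejected(self, empty_design):
        with pytest.raises(ValueError):
            fit(np.ones((2, 3)), empty_design(3), k=4)

    def test_recovers_well_separated_clusters(self, small_dataset):
        d = small_dataset
        m = fit(d.counts, d.design, k=3, n_init=5, seed=1)
        assert ari(d.group_labels, m.memberships) >= 0.95

    def test_em_trace_monotone_across_random_instances(self):
        """Log-likelihood is non-decreasing within every restart."""
        for seed in range(25):
            d = simulate_primus(n_genes=20, n_cells=60, r=2, k=3, seed=seed, separation=0.8)
            m = fit(d.counts, d.design, k=3, n_init=1, seed=seed)
            t = np.asarray(m.ll_trace)
            slack = 1e-9 * (np.abs(t[:-1]) + 1)
            assert np.all(np.diff(t) >= -slack)

    def test_nuisance_shift_absorbed(self):
        """A patient-specific multiplicative shift through D leaves recovery intact."""
        base = simulate_primus(n_genes=80, n_cells=300, r=2, k=3, seed=3, separation=1.2)
        m0 = fit(base.counts, base.design, k=3, n_init=5, seed=5)
        ari0 = ari(base.group_labels, m0.memberships)

        rng = np.random.default_rng(99)
        shift = rng.gamma(2.0, 1.0, size=(base.counts.n_genes, 2))
        mu_extra = shift @ base.design.design * base.design.size_factors
        Y2 = base.counts.values + rng.poisson(mu_extra)
        m1 = fit(Y2, base.design, k=3, n_init=5, seed=5)
        ari1 = ari(base.group_labels, m1.memberships)
        assert abs(ari0 - ari1) <= 0.02


class TestBic:
    def test_hand_arithmetic(self):
        assert bic(-100.0, n_genes=5, r=1, k=2, n_cells=50) == pytest.approx(
            200 + 15 * np.log(50), abs=1e-9
        )

    def test_penalty_strictly_increasing_in_k(self):
        vals = [bic(-100.0, 10, 1, k, 100) for k in range(1, 5)]
        assert np.all(np.diff(vals) > 0)


class TestSelectK:
    def test_single_cluster_data_selects_k1(self):
        d = simulate_primus(n_genes=40, n_cells=120, r=0, k=1, seed=2, separation=0.0)
        scan = select_k(d.counts, d.design, k_range=range(1, 4), n_init=3, seed=4)
        assert scan.selected_k == 1

    def test_true_k_recovered(self):
        d = simulate_primus(n_genes=60, n_cells=200, r=2, k=3, seed=6, separation=1.2)
        scan = select_k(d.counts, d.design, k_range=range(1, 7), n_init=5, seed=8)
        assert scan.selected_k == 3

    def test_confounded_nuisance_regularized(self):
        """With patient labels in D, extra patient-driven clusters are penalized:
        selected k stays at most k_true + 1."""
        d = simulate_primus(n_genes=60, n_cells=240, r=4, k=2, seed=9, separation=1.2)
        scan = select_k(d.counts, d.design, k_range=range(1, 7), n_init=5, seed=10)
        assert scan.selected_k <= 3

    def test_empty_range_rejected(self, small_counts, empty_design):
        with pytest.raises(ValueError):
            select_k(small_counts, empty_design(small_counts.n_cells), k_range=[])


class TestDenoise:
    def test_zero_counts_denoise_to_zero(self):
        d = NuisanceDesign(np.ones((1, 3)), ["x"], np.array([1.0, 2.0, 0.5]))
        out = denoise(np.zeros((2, 3)), d, np.ones((2, 1)))
        assert np.all(out == 0)

    def test_interior_stationarity(self):
        d = NuisanceDesign(np.ones((1, 1)), ["x"], np.array([2.0]))
        out = denoise(np.array([[10]]), d, np.array([[1.0]]))
        assert out[0, 0] == pytest.approx(4.0)

    def test_boundary_clip(self):
        d = NuisanceDesign(np.ones((1, 1)), ["x"], np.array([1.0]))
        out = denoise(np.array([[1]]), d, np.array([[5.0]]))
        assert out[0, 0] == 0.0

    def test_matches_numeric_maximizer(self, rng):
        """Closed form equals a 1-D numeric likelihood maximizer on random triples."""
        for _ in range(200):
            y = float(rng.integers(0, 20))
            g = float(rng.uniform(0.2, 3.0))
            a = float(rng.uniform(0.0, 5.0))
            d = NuisanceDesign(np.ones((1, 1)), ["x"], np.array([g]))
            ours = denoise(np.array([[y]]), d, np.array([[a]]))[0, 0]
            res = scipy.optimize.minimize_scalar(
                lambda z: -poisson_loglik(np.array([y]), np.array([(a + z) * g])),
                bounds=(0, max(1.0, 4 * y / g)),
                method="bounded",
                options={"xatol": 1e-12},
            )
            assert ours == pytest.approx(res.x, abs=1e-6) or -res.fun <= poisson_loglik(
                np.array([y]), np.array([(a + ours) * g])
            ) + 1e-8


def test_model_archive_round_trip(tmp_path, small_dataset):
    d = small_dataset
    m = fit(d.counts, d.design, k=3, n_init=2, seed=1)
    save_model(m, tmp_path / "model")
    back = load_model(tmp_path / "model")
    assert np.allclose(back.X, m.X)
    assert np.allclose(back.Z, m.Z)
    assert np.array_equal(back.memberships, m.memberships)
    assert back.bic == pytest.approx(m.bic)
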