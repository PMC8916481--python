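import numpy as np
import pytest

from mmrbss import (BSSTk, InfomaxICA, OddballDesign, SourceModel,
                    back_project, compute_delays, decompose_bsstk,
                    joint_diagonalize, lagged_correlation,
                    make_sensor_layout, simulate_recording, sphere)


class TestDelaySchedule:
    def test_printed_delay_table(self):
        sched = compute_delays(1000, 2, 8)
        assert sched.delays_samples == (500, 250, 166, 125, 100, 83, 71, 62)
        assert sched.delays_ms == (500, 250, 166, 125, 100, 83, 71, 62)

    def test_single_delay_is_full_period(self):
        assert compute_delays(1000, 2, 1).delays_samples == (500,)

    def test_truncation_at_lower_rate(self):
        # oracle: trunc(250/m) for m=1..4
        assert compute_delays(500, 2, 4).delays_samples == (250, 125, 83, 62)

    def test_nearest_integer_mode(self):
        sched = compute_delays(1000, 2, 8, rounding="nearest")
        assert sched.delays_samples == (500, 250, 167, 125, 100, 83, 71, 62)

    def test_k_exceeding_period_rejected(self):
        with pytest.raises(ValueError):
            compute_delays(10, 2, 6)

    def test_dedupe_removes_repeats(self):
        sched = compute_delays(8, 2, 4, dedupe=True)
        assert sched.delays_samples == (4, 2, 1)


class TestSphere:
    def test_identity_covariance_stays_identity(self, rng):
        X = rng.standard_normal((3, 50_000))
        # orthogonalize exactly
        Z0, *_ = sphere(X)
        Z, sph, desph, rank = sphere(Z0)
        assert rank == 3
        cov = Z @ Z.T / Z.shape[1]
        assert np.allclose(cov, np.eye(3), atol=1e-8)

    def test_anisotropic_covariance_whitened(self, rng):
        # eigendecomposition oracle: diag(4, 1) covariance
        base = rng.standard_normal((2, 20_000))
        base = sphere(base)[0]
        X = np.diag([2.0, 1.0]) @ base
        Z, sph, desph, rank = sphere(X)
        assert np.allclose(Z @ Z.T / Z.shape[1], np.eye(2), atol=1e-8)
        assert np.allclose(desph @ sph @ X, X, atol=1e-8)

    def test_rank_deficiency_detected(self, rng):
        X = rng.standard_normal((2, 5000))
        X3 = np.vstack([X, X[0] + X[1]])
        Z, _, _, rank = sphere(X3)
        assert rank == 2

    def test_constant_data_rejected(self):
        with pytest.raises(ValueError):
            sphere(np.zeros((3, 100)))


class TestLaggedCorrelation:
    def test_white_noise_off_diagonals_small(self, rng):
        Z = sphere(rng.standard_normal((4, 40_000)))[0]
        R = lagged_correlation(Z, 10, normalize=False)
        off = R[~np.eye(4, dtype=bool)]
        assert np.all(np.abs(off) < 3 / np.sqrt(Z.shape[1]))

    def test_zero_delay_on_whitened_is_identity(self, rng):
        Z = sphere(rng.standard_normal((3, 10_000)))[0]
        R = lagged_correlation(Z, 0, normalize=False)
        assert np.allclose(R, np.eye(3), atol=1e-10)

    def test_sinusoid_at_full_period(self):
        # trigonometric oracle: shifting by one period leaves the
        # correlation structure unchanged
        P = 100
        t = np.arange(60_000)
        Z = np.vstack([np.sqrt(2) * np.sin(2 * np.pi * t / P),
                       np.sqrt(2) * np.cos(2 * np.pi * t / P)])
        R0 = lagged_correlation(Z, 0, normalize=False)
        RP = lagged_correlation(Z, P, normalize=False)
        assert np.allclose(RP, R0, rtol=0.01, atol=0.01)

    def test_unit_frobenius_normalization(self, rng):
        Z = sphere(rng.standard_normal((4, 5000)))[0]
        R = lagged_correlation(Z, 7)
        assert np.linalg.norm(R) == pytest.approx(1.0)

    def test_excessive_delay_rejected(self):
        with pytest.raises(ValueError):
            lagged_correlation(np.zeros((2, 50)), 50)


def _planted_problem(rng, n, k):
    Q, _ = np.linalg.qr(rng.standard_normal((n, n)))
    mats = [Q @ np.diag(rng.standard_normal(n)) @ Q.T for _ in range(k)]
    return Q, mats


class TestJointDiagonalize:
    def test_diagonal_input_is_fixed_point(self):
        mats = [np.diag([3.0, 1.0, -2.0]), np.diag([0.5, 2.0, 1.0])]
        V, rec = joint_diagonalize(mats)
        # V is identity up to permutation/sign
        assert np.allclose(np.abs(V.T @ V), np.eye(3), atol=1e-12)
        assert np.count_nonzero(np.abs(V) > 1e-9) == 3
        assert rec.final_criterion < 1e-20

    def test_planted_rotation_recovered(self, rng):
        Q, mats = _planted_problem(rng, 8, 5)
        V, rec = joint_diagonalize(mats)
        cos = np.abs(Q.T @ V)
        assert np.all(cos.max(axis=0) >= 0.999)
        assert rec.final_criterion < 1e-10

    def test_criterion_non_increasing(self, rng):
        # noisy (not exactly diagonalizable) problem
        mats = [m + 0.05 * np.diag(rng.standard_normal(6))
                for m in _planted_problem(rng, 6, 4)[1]]
        mats = [0.5 * (m + m.T) for m in mats]
        _, rec = joint_diagonalize(mats, max_sweeps=20)
        hist = np.array(rec.criterion_history)
        assert np.all(np.diff(hist) <= 1e-10)

    def test_two_by_two_matches_analytic_eigenvectors(self):
        # closed-form 2x2 eigendecomposition oracle
        phi = 0.37
        Q = np.array([[np.cos(phi), -np.sin(phi)],
                      [np.sin(phi), np.cos(phi)]])
        mats = [Q @ np.diag(d) @ Q.T for d in ([2.0, -1.0], [0.3, 1.7])]
        V, _ = joint_diagonalize(mats)
        evals, evecs = np.linalg.eigh(mats[0])
        # both V and the eigenvectors diagonalize; compare column angles
        cos = np.abs(evecs.T @ V)
        assert np.all(cos.max(axis=0) >= 1 - 1e-8)

    def test_non_symmetric_rejected(self):
        bad = np.array([[0.0, 1.0], [0.0, 0.0]])
        with pytest.raises(ValueError):
            joint_diagonalize([bad])

    def test_mismatched_sizes_rejected(self):
        with pytest.raises(ValueError):
            joint_diagonalize([np.eye(2), np.eye(3)])


class TestDecomposeBSSTk:
    def test_noiseless_sources_recovered(self):
        # three noiseless sources with lag-distinct autocorrelations
        # (sinusoids whose periods divide the SOA, so concatenation of
        # epochs keeps them coherent)
        design = OddballDesign(min_deviants=10, seed=17)
        n_t = design.soa_samples
        t = np.arange(n_t)
        courses = np.stack([
            30.0 * np.sin(2 * np.pi * t / 500),
            20.0 * np.sin(2 * np.pi * t / 250),
            10.0 * np.sin(2 * np.pi * t / 125),
        ])
        positions, _ = make_sensor_layout(10)
        rng = np.random.default_rng(3)
        topos = rng.standard_normal((3, 10))
        topos /= np.linalg.norm(topos, axis=1, keepdims=True)
        model = SourceModel(topographies=topos, std_time_courses=courses,
                            dev_time_courses=courses,
                            gating=("both",) * 3, positions=positions,
                            sensor_noise_sd=0.0, pink_amplitude=0.0,
                            alpha_amplitude=0.0)
        raw, truth = simulate_recording(design, model)
        decomp = decompose_bsstk(raw)
        A = decomp.mixing / np.linalg.norm(decomp.mixing, axis=0)
        for j in range(3):
            topo = truth.true_mixing[:, j]
            topo = topo / np.linalg.norm(topo)
            assert np.abs(topo @ A).max() >= 0.99

    def test_full_back_projection_reconstructs_input(self, small_sim):
        raw, _ = small_sim
        decomp = decompose_bsstk(raw.data[:, :20_000], fs_hz=raw.fs_hz)
        recon = decomp.reconstruct()
        rel = np.linalg.norm(recon - raw.data[:, :20_000]) \
            / np.linalg.norm(raw.data[:, :20_000])
        assert rel < 1e-6

    def test_mixing_unmixing_identity(self, small_sim):
        raw, _ = small_sim
        decomp = decompose_bsstk(raw.data[:, :20_000], fs_hz=raw.fs_hz)
        assert np.allclose(decomp.unmixing @ decomp.mixing,
                           np.eye(decomp.n_components), atol=1e-8)

    def test_channel_permutation_equivariance(self, rng):
        X = rng.standard_normal((5, 8000))
        X[0] += np.sin(np.arange(8000) / 20)  # give some lag structure
        perm = rng.permutation(5)
        d0 = decompose_bsstk(X, fs_hz=1000.0, fp_hz=10.0, k=4)
        d1 = decompose_bsstk(X[perm], fs_hz=1000.0, fp_hz=10.0, k=4)
        assert np.allclose(d1.mixing, d0.mixing[perm], atol=1e-6)

    def test_sign_convention(self, small_sim):
        raw, _ = small_sim
        decomp = decompose_bsstk(raw.data[:, :10_000], fs_hz=raw.fs_hz)
        idx = np.argmax(np.abs(decomp.mixing), axis=0)
        assert np.all(decomp.mixing[idx, np.arange(decomp.n_components)]
                      > 0)


class TestBackProject:
    @pytest.fixture(scope="class")
    def decomp(self):
        design = OddballDesign(min_deviants=8, seed=21)
        model = SourceModel.default(n_channels=8, design=design)
        raw, _ = simulate_recording(design, model)
        return decompose_bsstk(raw), raw

    def test_all_components_complete(self, decomp):
        d, raw = decomp
        full = back_project(d, list(range(d.n_components)))
        rel = np.linalg.norm(full - raw.data) / np.linalg.norm(raw.data)
        assert rel < 1e-6

    def test_linearity_over_disjoint_subsets(self, decomp):
        d, _ = decomp
        q1, q2 = [0, 2], [1, 3]
        combined = back_project(d, q1) + back_project(d, q2)
        assert np.allclose(combined, back_project(d, q1 + q2))

    def test_empty_subset_rejected(self, decomp):
        with pytest.raises(ValueError):
            back_project(decomp[0], [])

    def test_out_of_range_rejected(self, decomp):
        with pytest.raises(ValueError):
            back_project(decomp[0], [decomp[0].n_components])


class TestInfomaxAdapter:
    @pytest.fixture(scope="class")
    def data(self):
        rng = np.random.default_rng(31)
        A = rng.standard_normal((6, 6))
        S = np.sign(rng.standard_normal((6, 6000)))  # super-Gaussian
        return A @ S

    def test_reconstruction(self, data):
        d = InfomaxICA(data, fs_hz=1000.0).fit()
        centered = data - data.mean(axis=1, keepdims=True)
        rel = np.linalg.norm(d.reconstruct() - centered) \
            / np.linalg.norm(centered)
        assert rel < 1e-6

    def test_component_count_is_rank(self, data):
        assert InfomaxICA(data, fs_hz=1000.0).fit().n_components == 6

    def test_seeded_determinism(self, data):
        d1 = InfomaxICA(data, fs_hz=1000.0, seed=4).fit()
        d2 = InfomaxICA(data, fs_hz=1000.0, seed=4).fit()
        assert np.array_equal(d1.mixing, d2.mixing)
        assert np.array_equal(d1.sources, d2.sources)


def test_summary_mentions_method_and_convergence(small_sim):
    raw, _ = small_sim
    d = decompose_bsstk(raw.data[:, :8000], fs_hz=raw.fs_hz, max_sweeps=10)
    text = d.summary()
    assert "bsstk" in text and "sweeps" in text
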