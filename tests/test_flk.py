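"""Reynolds distances, tree kinship, FLK, and the haplotype-cluster model."""

import numpy as np
import pandas as pd
import pytest

import sweepscan.flk as flk
from sweepscan.simulate import SimConfig, SweepSpec, balding_nichols_panel, simulate_panel

from conftest import make_panel


class TestReynolds:
    def test_identical_frequency_vectors_give_zero(self):
        f = np.array([0.2, 0.5, 0.8])
        assert flk.reynolds_distance(f, f) == 0.0

    def test_fixed_opposite_alleles_give_theta_one(self):
        p = np.array([1.0, 1.0, 0.0])
        q = np.array([0.0, 0.0, 1.0])
        assert flk.reynolds_distance(p, q) == pytest.approx(1.0)

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        p, q = rng.random(50), rng.random(50)
        assert flk.reynolds_distance(p, q) == flk.reynolds_distance(q, p)

    def test_sample_size_correction_removes_binomial_inflation(self):
        rng = np.random.default_rng(1)
        p_true = rng.uniform(0.1, 0.9, 20_000)
        n = 25
        p1 = rng.binomial(2 * n, p_true) / (2 * n)
        p2 = rng.binomial(2 * n, p_true) / (2 * n)
        naive = flk.reynolds_distance(p1, p2)
        corrected = flk.reynolds_distance(p1, p2, n, n)
        assert naive > 0.01  # pure sampling noise looks like drift
        assert corrected == pytest.approx(0.0, abs=0.005)

    def test_uninformative_input_raises(self):
        z = np.zeros(5)
        with pytest.raises(ValueError):
            flk.reynolds_distance(z, z)


class TestKinship:
    def test_two_equidistant_pops(self):
        d = pd.DataFrame([[0, 0.1], [0.1, 0]], index=["a", "b"], columns=["a", "b"])
        kin = flk.kinship_from_tree(d)
        assert np.allclose(kin.matrix, np.diag([0.05, 0.05]))

    def test_star_topology_gives_diagonal_kinship(self):
        # 4 equidistant leaves: NJ yields (near-)zero internal branches
        d = np.full((4, 4), 0.2)
        np.fill_diagonal(d, 0.0)
        labels = list("abcd")
        kin = flk.kinship_from_tree(pd.DataFrame(d, index=labels, columns=labels))
        off = kin.matrix[~np.eye(4, dtype=bool)]
        assert np.all(np.abs(off) < 1e-12)
        assert np.allclose(np.diag(kin.matrix), 0.1)

    def test_three_pop_matches_hand_neighbor_joining(self):
        # d(ab)=0.2, d(ac)=0.3, d(bc)=0.25 -> branches a=0.125, b=0.075,
        # c=0.175; midpoint root on the a-c path at depth 0.15
        labels = list("abc")
        d = pd.DataFrame(
            [[0, 0.2, 0.3], [0.2, 0, 0.25], [0.3, 0.25, 0]],
            index=labels, columns=labels,
        )
        kin = flk.kinship_from_tree(d)
        expected = np.array(
            [[0.15, 0.025, 0.0], [0.025, 0.10, 0.0], [0.0, 0.0, 0.15]]
        )
        assert np.allclose(kin.matrix, expected, atol=1e-12)

    def test_kinship_is_positive_semidefinite(self):
        rng = np.random.default_rng(3)
        pts = rng.random((5, 4))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        labels = list("abcde")
        kin = flk.kinship_from_tree(pd.DataFrame(d, index=labels, columns=labels))
        assert np.min(np.linalg.eigvalsh(kin.matrix)) > -1e-10


class TestFlkTest:
    def test_identical_frequencies_give_zero(self):
        T, p = flk.flk_test(np.array([0.4, 0.4, 0.4]), np.eye(3) * 0.05)
        assert T == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_two_pop_closed_form(self):
        # F = c*I: p0 = mean, T = (p1-p2)^2 / (2 c p0 (1-p0))
        p1, p2, c = 0.7, 0.4, 0.08
        p0 = (p1 + p2) / 2
        expected = (p1 - p2) ** 2 / (2 * c * p0 * (1 - p0))
        T, _ = flk.flk_test(np.array([p1, p2]), np.eye(2) * c)
        assert T == pytest.approx(expected, rel=1e-12)

    def test_invariant_to_allele_relabeling(self):
        rng = np.random.default_rng(2)
        F = np.diag(rng.uniform(0.02, 0.1, 4))
        p = rng.uniform(0.1, 0.9, 4)
        T1, _ = flk.flk_test(p, F)
        T2, _ = flk.flk_test(1 - p, F)
        assert T1 == pytest.approx(T2, rel=1e-10)

    def test_null_calibration_matches_chi_square_moments(self):
        panel = balding_nichols_panel(4, 30, 5000, 0.05, seed=0)
        kin = flk.KinshipMatrix(panel.subpop_labels(), np.eye(4) * 0.05, "")
        tab = flk.flk_scan(panel, kin)
        T = tab["T"].dropna()
        assert T.mean() == pytest.approx(3.0, abs=0.15)
        assert (tab["p"].dropna() < 0.05).mean() == pytest.approx(0.05, abs=0.02)

    def test_estimated_kinship_recovers_simulated_drift(self):
        panel = balding_nichols_panel(4, 40, 4000, 0.06, seed=3)
        kin = flk.drift_kinship(panel)
        assert np.diag(kin.matrix) == pytest.approx([0.06] * 4, abs=0.01)


class TestClusterModel:
    def test_k1_equals_independent_binomial_likelihood(self):
        cfg = SimConfig(n_subpops=1, samples_per_subpop=20, n_snps_per_chrom=40,
                        seed=2)
        panel, _ = simulate_panel(cfg)
        model = flk.fit_cluster_model(panel, K=1, n_fits=1, seed=0, max_iter=30)
        d = panel.dosage
        ll = 0.0
        for m in range(panel.n_markers):
            col = d[:, m][~np.isnan(d[:, m])]
            th = col.mean() / 2
            probs = {0: (1 - th) ** 2, 1: 2 * th * (1 - th), 2: th ** 2}
            ll += sum(np.log(max(probs[int(x)], 1e-300)) for x in col)
        assert model.best_fit["loglik"] == pytest.approx(ll, abs=0.1)

    def test_em_loglik_nondecreasing(self):
        cfg = SimConfig(n_subpops=2, samples_per_subpop=20, n_snps_per_chrom=80,
                        seed=3)
        panel, _ = simulate_panel(cfg)
        model = flk.fit_cluster_model(panel, K=3, n_fits=2, seed=0, max_iter=25)
        for fit in model.fits:
            trace = np.asarray(fit["loglik_trace"])
            assert np.all(np.diff(trace) >= -1e-6 * np.abs(trace[:-1]))

    def test_recovers_two_cluster_frequencies(self):
        # data from a known 2-founder mosaic with contrasting alleles
        rng = np.random.default_rng(5)
        M, N = 60, 80
        founders = np.stack([rng.random(M) < 0.85, rng.random(M) < 0.15]).astype(int)
        haps = []
        for _ in range(2 * N):
            k = rng.integers(2)
            path = np.empty(M, int)
            for m in range(M):
                if m and rng.random() < 0.02:
                    k = rng.integers(2)
                path[m] = k
            haps.append(founders[path, np.arange(M)])
        haps = np.asarray(haps)
        dosage = haps[0::2] + haps[1::2]
        g = make_panel(dosage.astype(float),
                       positions=[(i + 1) * 10_000 for i in range(M)])
        # several restarts: single EM runs can land in local optima
        model = flk.fit_cluster_model(g, K=2, n_fits=4, seed=0, max_iter=120)
        theta = model.best_fit["theta"]  # (M, 2)
        true = np.stack([founders[0], founders[1]], axis=1).astype(float)
        rmse = lambda a, b: np.sqrt(np.mean((a - b) ** 2))
        best = min(rmse(theta, true), rmse(theta[:, ::-1], true))
        assert best < 0.1

    def test_requires_single_chromosome(self):
        g = make_panel(np.zeros((4, 4)) + 1.0, chroms=["1", "1", "2", "2"])
        with pytest.raises(ValueError, match="one chromosome"):
            flk.fit_cluster_model(g, K=2)


@pytest.fixture(scope="module")
def sweep_setup():
    sweep = SweepSpec("pop1", "1", 4_000_000, 4_600_000, 0.9)
    cfg = SimConfig(n_subpops=2, samples_per_subpop=30, n_snps_per_chrom=200,
                    chrom_length=10_000_000, drift_f=0.05, sweeps=(sweep,),
                    seed=1)
    panel, _ = simulate_panel(cfg)
    kin = flk.drift_kinship(panel)
    model = flk.fit_cluster_model(panel, K=4, n_fits=2, seed=0, max_iter=30)
    return panel, kin, model, sweep


class TestHapflk:
    def test_identical_profiles_give_zero_statistic(self):
        # hand-built frequencies equal across pops -> quadratic form vanishes
        F = np.eye(3) * 0.05
        ones = np.ones(3)
        Finv = np.linalg.inv(F)
        fk = np.array([0.3, 0.3, 0.3])
        p0 = float(ones @ Finv @ fk) / float(ones @ Finv @ ones)
        dev = fk - p0
        assert float(dev @ Finv @ dev) == pytest.approx(0.0, abs=1e-12)

    def test_k2_reduces_to_biallelic_flk(self):
        cfg = SimConfig(n_subpops=3, samples_per_subpop=15, n_snps_per_chrom=50,
                        seed=9)
        panel, _ = simulate_panel(cfg)
        kin = flk.drift_kinship(panel)
        model = flk.fit_cluster_model(panel, K=2, n_fits=1, seed=0, max_iter=20)
        hf = flk.hapflk_scan(model, panel, kin)
        fit = model.best_fit
        freqs = np.stack(
            [flk.cluster_frequencies(fit, panel, p) for p in kin.labels]
        )
        n_per = np.array([panel.sample_mask(p).sum() for p in kin.labels], float)
        Fc = flk._corrected_kinship(kin.matrix, n_per)
        for m in range(0, panel.n_markers, 7):
            T, _ = flk.flk_test(freqs[:, m, 0], Fc)
            assert hf["hapflk"][m] == pytest.approx(T, abs=1e-10)

    def test_statistic_invariant_to_cluster_relabeling(self, sweep_setup):
        panel, kin, model, _ = sweep_setup
        hf1 = flk.hapflk_scan(model, panel, kin)
        shuffled = flk.ClusterModel(
            K=model.K, n_fits=model.n_fits, chrom=model.chrom,
            positions=model.positions,
            fits=[
                {**fit,
                 "alpha": fit["alpha"][:, ::-1].copy(),
                 "theta": fit["theta"][:, ::-1].copy()}
                for fit in model.fits
            ],
        )
        hf2 = flk.hapflk_scan(shuffled, panel, kin)
        assert np.allclose(hf1["hapflk"], hf2["hapflk"], atol=1e-8)

    def test_sweep_markers_exceed_threshold(self, sweep_setup):
        panel, kin, model, sweep = sweep_setup
        hf = flk.hapflk_scan(model, panel, kin)
        pos = hf["pos"].to_numpy()
        inside = (pos >= sweep.start) & (pos <= sweep.end)
        assert hf.loc[inside, "significant"].any()
        assert hf.loc[inside, "hapflk"].mean() > 3 * hf.loc[~inside, "hapflk"].mean()
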