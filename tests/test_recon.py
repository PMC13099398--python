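import numpy as np
import pytest

from lrtcmr.kspace import CoilSet, KSpaceData, cfftn, simulate_free_running, sigma_for_snr
from lrtcmr.phantom import PhantomConfig, build_phantom
from lrtcmr.recon import (
    BinConfig,
    BinningResult,
    NavigationError,
    ReconImage6D,
    SubspaceError,
    TemporalSubspace,
    assign_bins,
    compose_images,
    estimate_subspaces,
    extract_nav,
    nav_from_truth,
    solve_spatial,
)
from lrtcmr.schedule import SamplingSchedule, SequenceParams, build_schedule


@pytest.fixture(scope="module")
def nav_case():
    """Simulated free-running data long enough for self-navigation."""
    cfg = PhantomConfig(grid=(48, 48, 4), voxel_mm=(270 / 48, 270 / 48, 6.0))
    phantom = build_phantom(cfg, seed=0)
    params = SequenceParams(n_ky=48, n_kz=4, duration_s=240.0)
    schedule = build_schedule(params, seed=1)
    coils = CoilSet.gaussian_lobes(phantom.grid, 4)
    kdata = simulate_free_running(
        phantom, schedule, coils, noise_sigma=sigma_for_snr(phantom, params, 30.0), seed=2
    )
    return phantom, params, schedule, coils, kdata


class TestNavigation:
    def test_heart_rate_recovered_within_5pct(self, nav_case):
        phantom, *_, kdata = nav_case
        nav = extract_nav(kdata)
        assert nav.rr_ms_est == pytest.approx(phantom.motion.rr_ms, rel=0.05)

    def test_respiratory_period_recovered(self, nav_case):
        phantom, *_, kdata = nav_case
        nav = extract_nav(kdata)
        assert nav.resp_period_ms_est == pytest.approx(phantom.motion.resp_ms, rel=0.05)

    def test_static_phantom_raises_navigation_error(self):
        from lrtcmr.phantom import MotionModel

        cfg = PhantomConfig(
            grid=(48, 48, 4), voxel_mm=(270 / 48, 270 / 48, 6.0),
            motion=MotionModel(contraction_frac=0.0, resp_amp_mm=0.0),
        )
        phantom = build_phantom(cfg, seed=0)
        params = SequenceParams(n_ky=48, n_kz=4, duration_s=120.0)
        schedule = build_schedule(params, seed=1)
        kdata = simulate_free_running(
            phantom, schedule, CoilSet.uniform(phantom.grid),
            noise_sigma=sigma_for_snr(phantom, params, 30.0), seed=3,
        )
        with pytest.raises(NavigationError):
            extract_nav(kdata)

    def test_bypass_mode_returns_simulator_phases(self, nav_case):
        *_, kdata = nav_case
        nav = nav_from_truth(kdata)
        assert np.array_equal(nav.cardiac_phase, kdata.true_cardiac_phase)
        assert nav.source == "truth"


class TestBinning:
    def test_single_bin_everything_in_cell_zero(self, nav_case):
        _, _, schedule, _, kdata = nav_case
        nav = nav_from_truth(kdata)
        b = assign_bins(schedule, nav, BinConfig(1, 1, 1, "per-segment"))
        assert np.all(b.cardiac_bin == 0)
        assert np.all(b.resp_bin == 0)
        assert np.all(b.gd_bin == 0)

    def test_cardiac_occupancy_roughly_uniform(self, nav_case):
        _, _, schedule, _, kdata = nav_case
        b = assign_bins(schedule, nav_from_truth(kdata), BinConfig(24, 4, 8, 12))
        counts = np.bincount(b.cardiac_bin, minlength=24)
        assert counts.max() / counts.min() < 1.5

    def test_respiratory_quantile_occupancy_balanced(self, nav_case):
        _, _, schedule, _, kdata = nav_case
        b = assign_bins(schedule, nav_from_truth(kdata), BinConfig(24, 4, 8, 12))
        counts = np.bincount(b.resp_bin, minlength=4)
        assert counts.max() - counts.min() <= 0.05 * counts.mean() + 16

    def test_tau_decimation(self, nav_case):
        _, _, schedule, _, kdata = nav_case
        b = assign_bins(schedule, nav_from_truth(kdata), BinConfig(4, 2, 2, 12))
        assert b.n_tau == 16
        assert np.array_equal(b.tau_index, schedule.seg // 12)


def _exact_rank_case(seed=0, l_x=12, ranks=(4, 2, 3, 2, 2), grid=(32, 32, 4),
                     duration_s=240.0, n_gd=4, decim=24):
    """Synthesize k-space exactly from a random low-rank tensor model."""
    rng = np.random.default_rng(seed)
    params = SequenceParams(n_ky=grid[1], n_kz=grid[2], duration_s=duration_s)
    schedule = build_schedule(params, seed=seed + 1)
    bins = BinConfig(8, 2, n_gd, decim)
    n_ev = schedule.n_events
    t_ms = schedule.t_ms
    cb = np.minimum(((t_ms % 603.0) / 603.0 * bins.n_cardiac).astype(int), bins.n_cardiac - 1)
    rb = np.minimum(((t_ms % 4000.0) / 4000.0 * bins.n_resp).astype(int), bins.n_resp - 1)
    gb = np.minimum((t_ms / t_ms.max() * bins.n_gd).astype(int), bins.n_gd - 1)
    binning = BinningResult(
        cardiac_bin=cb, resp_bin=rb, gd_bin=gb, tau_index=schedule.seg // decim,
        bins=bins, n_tau=bins.n_tau(params.segments_per_ir), n_echo=params.n_echo,
    )
    shape = binning.cell_shape
    # random Tucker-structured temporal basis with orthonormal rows
    factors = [np.linalg.qr(rng.normal(size=(d, r)))[0]
               for d, r in zip(shape, (*ranks[:3], ranks[3], ranks[4]))]
    core = rng.normal(size=(l_x, *[f.shape[1] for f in factors]))
    phi = core
    for m, f in enumerate(factors):
        phi = np.moveaxis(np.tensordot(phi, f, axes=(m + 1, 1)), -1, m + 1)
    phi = phi.reshape(l_x, -1)
    q, _ = np.linalg.qr(phi.T)
    phi = q.T.astype(complex)
    # smooth random spatial factor
    u_x = rng.normal(size=(np.prod(grid), l_x)) + 1j * rng.normal(size=(np.prod(grid), l_x))
    u_x = u_x @ np.diag(1.0 / np.arange(1, l_x + 1))

    phi_t = phi.reshape(l_x, *shape)
    samples = np.empty((n_ev, 1, params.n_echo, grid[0]), dtype=complex)
    # k-space of each spatial component
    F = cfftn(np.moveaxis(u_x.reshape(*grid, l_x), -1, 0))
    iky = schedule.ky + grid[1] // 2
    ikz = schedule.kz + grid[2] // 2
    for e in range(params.n_echo):
        cols = phi_t[:, cb, rb, binning.tau_index, e, gb]      # (L, n_ev)
        lines = F[:, :, iky, ikz]                               # (L, kx, n_ev)
        samples[:, 0, e, :] = np.einsum("ln,lxn->nx", cols, lines)
    kdata = KSpaceData(schedule=schedule, samples=samples, noise_sigma=0.0,
                       n_coils=1, t_inject_offset_s=45.0)
    sub_true = TemporalSubspace(factors=[], core=None, phi=phi_t, svals=np.ones(l_x),
                                cell_shape=shape)
    return kdata, binning, sub_true, u_x, params, grid


class TestSubspaceEstimation:
    def test_exact_recovery_principal_angles(self):
        """Training data synthesized exactly from known factors: the
        estimated subspace spans the truth (largest principal angle small;
        limited only by the finite completion tolerance)."""
        kdata, binning, sub_true, *_ = _exact_rank_case()
        sub = estimate_subspaces(kdata, binning, ranks=(4, 2, 3, 2, 2),
                                 spatial_rank=12, max_sweeps=200, tol=1e-10)
        A = sub_true.phi_matrix()
        B = sub.phi_matrix()
        s = np.linalg.svd(A @ B.conj().T, compute_uv=False)
        angles = np.arccos(np.clip(s, 0, 1))
        assert angles.max() < 5e-3

    def test_rank_exceeding_dimension_rejected(self, nav_case):
        _, _, schedule, _, kdata = nav_case
        b = assign_bins(schedule, nav_from_truth(kdata), BinConfig(4, 2, 2, 12))
        with pytest.raises(SubspaceError):
            estimate_subspaces(kdata, b, ranks=(4, 2, 99, 2, 2))

    def test_orthonormal_rows(self, nav_case):
        _, _, schedule, _, kdata = nav_case
        b = assign_bins(schedule, nav_from_truth(kdata), BinConfig(8, 2, 4, 24))
        sub = estimate_subspaces(kdata, b, ranks=(4, 2, 3, 2, 2), spatial_rank=8,
                                 max_sweeps=20, tol=1e-4)
        g = sub.phi_matrix() @ sub.phi_matrix().conj().T
        assert np.max(np.abs(g - np.eye(g.shape[0]))) < 1e-8


class TestSolver:
    def _single_bin_case(self, rng):
        grid = (24, 24, 2)
        img = rng.normal(size=grid) + 1j * rng.normal(size=grid)
        p = SequenceParams(n_ky=24, n_kz=2, duration_s=10.0, te_ms=(1.47,))
        ky, kz = np.meshgrid(np.arange(-12, 12), np.arange(-1, 1), indexing="ij")
        n = ky.size
        sch = SamplingSchedule(
            params=p, seed=0, idx=np.arange(n), t_ticks=np.arange(n) * 132,
            ir_block=np.zeros(n, int), seg=np.zeros(n, int),
            ky=ky.ravel(), kz=kz.ravel(), is_training=np.zeros(n, bool),
        )
        K = cfftn(img)
        samples = K[:, ky.ravel() + 12, kz.ravel() + 1].T[:, None, None, :]
        kd = KSpaceData(schedule=sch, samples=samples.astype(complex), noise_sigma=0.0,
                        n_coils=1, t_inject_offset_s=45.0)
        sub = TemporalSubspace(factors=[], core=None,
                               phi=np.ones((1, 1, 1, 1, 1, 1), complex),
                               svals=np.ones(1), cell_shape=(1, 1, 1, 1, 1))
        binning = BinningResult(
            cardiac_bin=np.zeros(n, int), resp_bin=np.zeros(n, int),
            gd_bin=np.zeros(n, int), tau_index=np.zeros(n, int),
            bins=BinConfig(1, 1, 1, "per-segment"), n_tau=1, n_echo=1,
        )
        return img, kd, sub, binning, grid

    def test_fully_sampled_single_bin_matches_inverse_dft(self, rng):
        img, kd, sub, binning, grid = self._single_bin_case(rng)
        sp = solve_spatial(kd, CoilSet.uniform(grid), sub, binning,
                           lambda_reg=0.0, tol=1e-12, max_iter=30)
        rec = sp.u_x[..., 0]
        assert np.linalg.norm(rec - img) / np.linalg.norm(img) <= 1e-6

    def test_regularization_shrinks_solution(self, rng):
        img, kd, sub, binning, grid = self._single_bin_case(rng)
        norms = []
        for lam in (0.0, 1.0, 100.0):
            sp = solve_spatial(kd, CoilSet.uniform(grid), sub, binning,
                               lambda_reg=lam, tol=1e-10, max_iter=30)
            norms.append(np.linalg.norm(sp.u_x))
        assert norms[0] > norms[1] > norms[2]

    def test_linearity_in_data(self, rng):
        img, kd, sub, binning, grid = self._single_bin_case(rng)
        sp1 = solve_spatial(kd, CoilSet.uniform(grid), sub, binning,
                            lambda_reg=0.0, tol=1e-12, max_iter=30)
        kd.samples = 3.0 * kd.samples
        sp3 = solve_spatial(kd, CoilSet.uniform(grid), sub, binning,
                            lambda_reg=0.0, tol=1e-12, max_iter=30)
        assert np.allclose(sp3.u_x, 3.0 * sp1.u_x, atol=1e-8)


class TestCompose:
    def test_factorization_identity(self, rng):
        grid = (8, 8, 2)
        shape = (3, 2, 2, 2, 2)
        L = 4
        phi = rng.normal(size=(L, *shape)) + 1j * rng.normal(size=(L, *shape))
        u = rng.normal(size=(np.prod(grid), L)) + 1j * rng.normal(size=(np.prod(grid), L))
        from lrtcmr.recon import SpatialFactor

        sp = SpatialFactor(u_x=u.reshape(*grid, L), residuals=[], grid=grid)
        sub = TemporalSubspace(factors=[], core=None, phi=phi, svals=np.ones(L),
                               cell_shape=shape)
        dense = (u @ phi.reshape(L, -1)).reshape(*grid, *shape)
        q = (1, 0, 1, 1, 0)
        got = compose_images(sp, sub, [q], magnitude=False)[0]
        assert np.allclose(got, dense[..., q[0], q[1], q[2], q[3], q[4]])

    def test_out_of_range_query_rejected(self, rng):
        grid = (4, 4, 1)
        from lrtcmr.recon import SpatialFactor

        sp = SpatialFactor(u_x=np.ones((*grid, 1), complex), residuals=[], grid=grid)
        sub = TemporalSubspace(factors=[], core=None,
                               phi=np.ones((1, 2, 1, 1, 1, 1), complex),
                               svals=np.ones(1), cell_shape=(2, 1, 1, 1, 1))
        with pytest.raises(IndexError):
            compose_images(sp, sub, [(5, 0, 0, 0, 0)])

    def test_lge_inversion_time_arithmetic(self):
        # the displayed 396 ms recovery frame corresponds to segment
        # round((396-10)/13.2) = 29
        p = SequenceParams()
        assert round((396.0 - p.ti0_ms) / p.tr_ms) == 29
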