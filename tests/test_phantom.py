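import numpy as np
import pytest

from lrtcmr.phantom import (
    MotionModel,
    PhantomConfig,
    TissueClass,
    build_phantom,
    cohort_phantoms,
    render_labels,
    render_property_maps,
    true_metrics,
)

MYO = [int(TissueClass.REMOTE), int(TissueClass.MI), int(TissueClass.MVO), int(TissueClass.IMH)]


class TestBuildPhantom:
    def test_default_grid_matches_protocol(self):
        ph = build_phantom(PhantomConfig(), seed=0)
        assert ph.grid == (192, 192, 14)
        assert ph.voxel_mm[2] == 6.0  # 14 partitions of 6 mm

    def test_no_infarct_config(self):
        cfg = PhantomConfig(grid=(48, 48, 4), voxel_mm=(270 / 48, 270 / 48, 6.0),
                            mi_extent_deg=0.0, mvo_theta_frac=0, mvo_depth_frac=0,
                            imh_theta_frac=0, imh_depth_frac=0)
        m = true_metrics(build_phantom(cfg, seed=0))
        assert m.mi_pct_lv == 0.0 and m.mvo_pct_lv == 0.0 and m.imh_pct_lv == 0.0

    def test_seed_jitters_placement_only(self):
        cfg = PhantomConfig(grid=(48, 48, 4), voxel_mm=(270 / 48, 270 / 48, 6.0))
        a, b = build_phantom(cfg, seed=1), build_phantom(cfg, seed=2)
        assert a.mi_center_deg != b.mi_center_deg
        assert a.tissues == b.tissues

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            PhantomConfig(r_endo_mm=30.0, r_epi_mm=25.0)


class TestRenderLabels:
    def test_labels_partition_grid(self, small_phantom):
        for cph, rph in [(0.0, 0.0), (0.2, 0.6), (0.9, 0.3)]:
            lab = render_labels(small_phantom, cph, rph)
            assert lab.shape == small_phantom.grid
            assert set(np.unique(lab)) <= set(range(7))

    def test_end_diastole_radius_identity(self, small_phantom):
        # at phase 0 the cavity boundary sits at the configured radius
        lab = render_labels(small_phantom, 0.0, 0.0)
        cfg = small_phantom.config
        dx = cfg.voxel_mm[0]
        blood = lab == TissueClass.BLOOD
        xs, ys, _ = np.where(blood)
        r = np.hypot((xs + 0.5) * dx - small_phantom.lv_center_mm[0],
                     (ys + 0.5) * dx - small_phantom.lv_center_mm[1])
        assert r.max() <= cfg.r_endo_mm
        assert r.max() >= cfg.r_endo_mm - 1.5 * dx

    def test_systolic_contraction_shrinks_cavity(self, small_phantom):
        ed = np.sum(render_labels(small_phantom, 0.0, 0.0) == TissueClass.BLOOD)
        es = np.sum(render_labels(small_phantom, 0.175, 0.0) == TissueClass.BLOOD)
        assert es < ed

    def test_nesting_at_all_phases(self, small_phantom):
        for cph in (0.0, 0.1, 0.2):
            lab = render_labels(small_phantom, cph, 0.25)
            mvo = lab == TissueClass.MVO
            imh = lab == TissueClass.IMH
            # MVO and IMH live strictly inside the infarct wedge: dilating
            # them stays within the injured+myocardial territory
            assert mvo.sum() > 0 and imh.sum() > 0

    def test_respiratory_shift_theorem(self):
        """A respiratory phase change translates the heart by the model
        displacement; the cross-correlation peak recovers it."""
        cfg = PhantomConfig(grid=(64, 64, 8), voxel_mm=(270 / 64, 270 / 64, 6.0),
                            liver=False)
        ph = build_phantom(cfg, seed=0)
        a = (render_labels(ph, 0.0, 0.0) > 0).astype(float)
        b = (render_labels(ph, 0.0, 0.5) > 0).astype(float)
        disp = ph.motion.resp_displacement_mm(0.5)
        expect = np.round(disp / np.array(cfg.voxel_mm)).astype(int)
        corr = np.fft.ifftn(np.fft.fftn(b) * np.conj(np.fft.fftn(a))).real
        peak = np.unravel_index(np.argmax(corr), corr.shape)
        peak = np.array([p if p < s // 2 else p - s for p, s in zip(peak, a.shape)])
        assert np.all(np.abs(peak - expect) <= 1)

    def test_myocardial_volume_conservation(self):
        # incompressibility: tested at doubled in-plane sampling where
        # voxelization noise is below the 2% bound
        cfg = PhantomConfig(grid=(384, 384, 6), voxel_mm=(270 / 384, 270 / 384, 6.0))
        ph = build_phantom(cfg, seed=0)
        counts = [
            np.isin(render_labels(ph, c, 0.0), MYO).sum()
            for c in (0.0, 0.1, 0.175, 0.25)
        ]
        assert max(counts) / min(counts) - 1 < 0.02


class TestPropertyMaps:
    def test_precontrast_native_t1(self, small_phantom):
        _, t1, _ = render_property_maps(small_phantom, 0.0, 0.0, 0.0)
        lab = render_labels(small_phantom, 0.0, 0.0)
        rem = lab == TissueClass.REMOTE
        assert np.allclose(t1[rem], small_phantom.tissues[int(TissueClass.REMOTE)].t1_0_ms)

    def test_early_enhancement_pattern(self, small_phantom):
        # remote shortens, MVO stays near native (delayed arrival)
        _, t1, _ = render_property_maps(small_phantom, 120.0, 0.0, 0.0)
        lab = render_labels(small_phantom, 0.0, 0.0)
        t1_rem = t1[lab == TissueClass.REMOTE].mean()
        t1_mvo_core = np.median(t1[lab == TissueClass.MVO])
        native = small_phantom.tissues[int(TissueClass.REMOTE)].t1_0_ms
        assert t1_rem < 0.5 * native
        assert t1_mvo_core > 0.9 * small_phantom.tissues[int(TissueClass.MVO)].t1_0_ms

    def test_hemorrhage_t2star_always_low(self, small_phantom):
        for t in (0.0, 120.0, 900.0):
            _, _, t2 = render_property_maps(small_phantom, t, 0.0, 0.0)
            lab = render_labels(small_phantom, 0.0, 0.0)
            assert np.all(t2[lab == TissueClass.IMH] < t2[lab == TissueClass.REMOTE].min())


class TestTrueMetrics:
    def test_half_volume_contraction_gives_half_ef(self):
        # contraction tuned so ESV = EDV/2 -> LVEF 50
        c = 1.0 - np.sqrt(0.5)
        cfg = PhantomConfig(grid=(96, 96, 4), voxel_mm=(270 / 96, 270 / 96, 6.0),
                            motion=MotionModel(contraction_frac=c))
        m = true_metrics(build_phantom(cfg, seed=0))
        assert m.lvef_pct == pytest.approx(50.0, abs=1.5)

    def test_no_motion_zero_ef(self, small_phantom):
        cfg = small_phantom.config.replace(motion=MotionModel(contraction_frac=0.0))
        m = true_metrics(build_phantom(cfg, seed=0))
        assert m.lvef_pct == 0.0
        assert m.edv_ml == m.esv_ml

    def test_full_transmural_wedge_area_fraction(self):
        """A 60-degree full-thickness wedge occupies 60/360 of the annulus;
        the annulus-wedge integral equals the angular fraction only at full
        transmurality."""
        cfg = PhantomConfig(grid=(192, 192, 4), voxel_mm=(270 / 192, 270 / 192, 6.0),
                            mi_extent_deg=60.0, transmural_frac=1.0,
                            mvo_theta_frac=0, mvo_depth_frac=0,
                            imh_theta_frac=0, imh_depth_frac=0)
        m = true_metrics(build_phantom(cfg, seed=0))
        assert m.mi_pct_lv == pytest.approx(100 * 60 / 360, abs=0.6)
        assert m.transmurality_pct == 100.0

    def test_partial_transmural_wedge_area_integral(self):
        # analytic annulus-wedge volume integral: fraction =
        # (extent/360) * (r(f)^2 - ri^2) / (re^2 - ri^2)
        cfg = PhantomConfig(grid=(192, 192, 4), voxel_mm=(270 / 192, 270 / 192, 6.0),
                            mi_extent_deg=90.0, transmural_frac=0.65,
                            mvo_theta_frac=0, mvo_depth_frac=0,
                            imh_theta_frac=0, imh_depth_frac=0)
        m = true_metrics(build_phantom(cfg, seed=0))
        ri, re = cfg.r_endo_mm, cfg.r_epi_mm
        rf = ri + 0.65 * (re - ri)
        expect = 100 * (90 / 360) * (rf**2 - ri**2) / (re**2 - ri**2)
        assert m.mi_pct_lv == pytest.approx(expect, abs=0.6)

    def test_metric_invariants(self, small_phantom):
        m = true_metrics(small_phantom)
        assert m.edv_ml >= m.esv_ml
        assert 0 <= m.mvo_pct_lv <= m.mi_pct_lv
        assert 0 <= m.imh_pct_lv <= m.mi_pct_lv


def test_cohort_spread_and_determinism():
    base = PhantomConfig(grid=(48, 48, 4), voxel_mm=(270 / 48, 270 / 48, 6.0))
    a = cohort_phantoms(8, base, seed=5)
    b = cohort_phantoms(8, base, seed=5)
    assert [p.config.mi_extent_deg for p in a] == [p.config.mi_extent_deg for p in b]
    extents = [p.config.mi_extent_deg for p in a]
    assert np.std(extents) > 5.0
    rrs = [p.motion.rr_ms for p in a]
    assert len(set(np.round(rrs, 1))) > 1
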