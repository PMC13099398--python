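import numpy as np
import pytest

from lrtcmr.phantom import (
    MotionModel,
    PhantomConfig,
    TissueClass,
    build_phantom,
    render_labels,
    true_metrics,
)
from lrtcmr.tissue_metrics import (
    SegmentationError,
    cavity_volumes_radial,
    compute_lvef,
    compute_transmurality,
    quantify_imh,
    quantify_mi,
    quantify_mvo,
    remote_sector_roi,
    sector_table,
    segment_lv,
    segment_lv_oracle,
)

GRID = (96, 96, 4)
VOX = (270 / 96, 270 / 96, 6.0)


@pytest.fixture(scope="module")
def phantom():
    return build_phantom(PhantomConfig(grid=GRID, voxel_mm=VOX), seed=0)


@pytest.fixture(scope="module")
def synth_frames(phantom):
    """Noise-free blood-bright frames rendered straight from the labels."""
    levels = np.array([0.0, 1.0, 0.45, 0.55, 0.5, 0.42, 0.4, 0.5])
    phases = np.arange(24) / 24
    frames = np.stack([
        levels[render_labels(phantom, p, 0.0, property_classes=True)] for p in phases
    ])
    return frames


class TestSegmentation:
    def test_oracle_mode_matches_labels(self, phantom):
        roi = segment_lv_oracle(phantom, phases=[0.0, 0.175])
        lab = render_labels(phantom, 0.0, 0.0)
        assert np.array_equal(roi.blood[0], lab == TissueClass.BLOOD)
        assert roi.provenance == "oracle"

    def test_threshold_mode_dice_vs_oracle(self, phantom, synth_frames):
        roi = segment_lv(synth_frames[:1], (48, 48))
        lab = render_labels(phantom, 0.5 / 24, 0.0)
        truth = lab == TissueClass.BLOOD
        inter = (roi.blood[0] & truth).sum()
        dice = 2 * inter / (roi.blood[0].sum() + truth.sum())
        assert dice >= 0.95

    def test_empty_cavity_raises(self, phantom):
        flat = np.zeros((1, *GRID))
        with pytest.raises(SegmentationError):
            segment_lv(flat, (48, 48))


class TestLvef:
    def test_definitional_zero_and_recovery(self, phantom, synth_frames):
        roi = segment_lv(synth_frames, (48, 48))
        lvef, edv, esv, ed, es = compute_lvef(roi, VOX)
        truth = true_metrics(phantom)
        assert lvef == pytest.approx(truth.lvef_pct, abs=2.0)
        assert edv >= esv

    def test_no_motion_zero_ef(self):
        cfg = PhantomConfig(grid=GRID, voxel_mm=VOX,
                            motion=MotionModel(contraction_frac=0.0))
        ph = build_phantom(cfg, seed=0)
        levels = np.array([0.0, 1.0, 0.45, 0.55, 0.5, 0.42, 0.4, 0.5])
        frames = np.stack([
            levels[render_labels(ph, p, 0.0, property_classes=True)]
            for p in np.arange(8) / 8
        ])
        lvef, *_ = compute_lvef(segment_lv(frames, (48, 48)), VOX)
        assert lvef == pytest.approx(0.0, abs=0.5)

    def test_radial_volumes_track_contraction(self, phantom, synth_frames):
        vols = cavity_volumes_radial(synth_frames, (48, 48), VOX,
                                     blood_ref=1.0, myo_ref=0.45)
        truth = true_metrics(phantom)
        ef = 100 * (1 - vols.min() / vols.max())
        assert ef == pytest.approx(truth.lvef_pct, abs=2.5)


def _lge_frame(phantom, remote=0.05, mi=0.8, mvo=0.1, imh=0.7, blood=0.75, noise=0.0, seed=0):
    levels = np.array([0.0, blood, remote, mi, mvo, imh, 0.1, mvo])
    lab = render_labels(phantom, 0.0, 0.0, property_classes=True)
    img = levels[lab]
    if noise > 0:
        img = img + np.random.default_rng(seed).normal(0, noise, img.shape)
    return img, lab


class TestInjuryQuantification:
    def test_uniform_myocardium_zero_mi(self, phantom):
        img, lab = _lge_frame(phantom, mi=0.05, mvo=0.05, imh=0.05, noise=1e-3)
        myo = np.isin(lab, [2, 3, 4, 5, 7])
        remote = remote_sector_roi(img, myo, (48, 48))
        _, pct, _ = quantify_mi(img, myo, remote, smooth_sigma=0.0)
        assert pct < 1.0

    def test_wedge_recovery_with_enclosed_core(self, phantom):
        # total infarct territory = enhancing mask plus the detected
        # no-reflow core (the clinical sizing convention)
        img, lab = _lge_frame(phantom, noise=5e-3)
        myo = np.isin(lab, [2, 3, 4, 5, 7])
        cavity = lab == 1
        remote = remote_sector_roi(img, myo, (48, 48))
        mask, pct, _ = quantify_mi(img, myo, remote, cavity_mask=cavity, smooth_sigma=0.0)
        # core detection happens on the long-inversion-time frame where the
        # unenhanced core is dark against recovered remote tissue
        mvo_img, _ = _lge_frame(phantom, remote=0.4, mi=0.8, mvo=0.02, imh=0.75, noise=5e-3)
        mvo_mask, _ = quantify_mvo(mvo_img, mask, myo,
                                   remote_sector_roi(mvo_img, myo, (48, 48)))
        total = mask | mvo_mask
        pct = 100.0 * total.sum() / myo.sum()
        truth = true_metrics(phantom)
        assert pct == pytest.approx(truth.mi_pct_lv, abs=2.0)

    def test_threshold_monotone_in_nsd(self, phantom):
        img, lab = _lge_frame(phantom, noise=2e-2)
        myo = np.isin(lab, [2, 3, 4, 5, 7])
        remote = remote_sector_roi(img, myo, (48, 48))
        pcts = [quantify_mi(img, myo, remote, n_sd=n, smooth_sigma=0.0)[1]
                for n in (2.0, 5.0, 8.0)]
        assert pcts[0] >= pcts[1] >= pcts[2]

    def test_mvo_hypointense_core(self, phantom):
        img, lab = _lge_frame(phantom, remote=0.4, mi=0.8, mvo=0.02, imh=0.75, noise=5e-3)
        myo = np.isin(lab, [2, 3, 4, 5, 7])
        cavity = lab == 1
        remote = remote_sector_roi(img + 0.0, myo, (48, 48))
        # MI mask from a bright-wedge frame
        lge, _ = _lge_frame(phantom, noise=5e-3)
        mi_mask, _, _ = quantify_mi(lge, myo, remote_sector_roi(lge, myo, (48, 48)),
                                    cavity_mask=cavity, smooth_sigma=0.0)
        _, mvo_pct = quantify_mvo(img, mi_mask, myo, remote)
        truth = true_metrics(phantom)
        assert mvo_pct == pytest.approx(truth.mvo_pct_lv, abs=1.5)

    def test_mvo_absent_when_no_core(self, phantom):
        img, lab = _lge_frame(phantom, mvo=0.8, noise=5e-3)  # core enhances like MI
        myo = np.isin(lab, [2, 3, 4, 5, 7])
        remote = remote_sector_roi(img, myo, (48, 48))
        mi_mask, _, _ = quantify_mi(img, myo, remote, cavity_mask=lab == 1, smooth_sigma=0.0)
        _, mvo_pct = quantify_mvo(img, mi_mask, myo, remote)
        assert mvo_pct < 0.5

    def test_imh_rules_and_agreement(self, phantom):
        lab = render_labels(phantom, 0.0, 0.0, property_classes=True)
        t2 = np.array([100.0, 25.0, 30.0, 38.0, 36.0, 10.0, 25.0, 36.0])[lab]
        rng = np.random.default_rng(0)
        t2 = t2 + rng.normal(0, 1.0, t2.shape)
        myo = np.isin(lab, [2, 3, 4, 5, 7])
        mi_mask = np.isin(lab, [3, 4, 5, 7])
        remote = lab == 2
        m20, p20 = quantify_imh(t2, mi_mask, myo, remote, rule="fixed20")
        m2sd, p2sd = quantify_imh(t2, mi_mask, myo, remote, rule="remote_minus_2sd")
        truth = true_metrics(phantom)
        assert p20 == pytest.approx(truth.imh_pct_lv, abs=1.0)
        inter = (m20 & m2sd).sum()
        dice = 2 * inter / max(m20.sum() + m2sd.sum(), 1)
        assert dice >= 0.8

    def test_nesting_enforced(self, phantom):
        img, lab = _lge_frame(phantom, noise=5e-3)
        myo = np.isin(lab, [2, 3, 4, 5, 7])
        remote = remote_sector_roi(img, myo, (48, 48))
        mi_mask, _, _ = quantify_mi(img, myo, remote, cavity_mask=lab == 1, smooth_sigma=0.0)
        mvo_mask, _ = quantify_mvo(img, mi_mask, myo, remote)
        mi_total = mi_mask | mvo_mask
        t2map = np.full(GRID, 30.0)
        imh_mask, _ = quantify_imh(t2map, mi_total, myo, remote)
        assert np.all(mvo_mask <= mi_total)
        assert np.all(imh_mask <= mi_total)


class TestTransmurality:
    def test_full_thickness_wedge(self):
        cfg = PhantomConfig(grid=GRID, voxel_mm=VOX, mi_extent_deg=90.0,
                            transmural_frac=1.0, mvo_theta_frac=0, mvo_depth_frac=0,
                            imh_theta_frac=0, imh_depth_frac=0)
        ph = build_phantom(cfg, seed=0)
        lab = render_labels(ph, 0.0, 0.0)
        myo = np.isin(lab, [2, 3, 4, 5])
        mi = lab == 3
        tm = compute_transmurality(mi, myo, (48, 48))
        assert tm == pytest.approx(100.0, abs=3.0)

    def test_half_thickness_subendocardial_wedge(self):
        cfg = PhantomConfig(grid=GRID, voxel_mm=VOX, mi_extent_deg=90.0,
                            transmural_frac=0.5, mvo_theta_frac=0, mvo_depth_frac=0,
                            imh_theta_frac=0, imh_depth_frac=0)
        ph = build_phantom(cfg, seed=0)
        lab = render_labels(ph, 0.0, 0.0)
        tm = compute_transmurality(lab == 3, np.isin(lab, [2, 3]), (48, 48))
        assert tm == pytest.approx(50.0, abs=4.0)

    def test_chord_count_refinement_stable(self, phantom):
        lab = render_labels(phantom, 0.0, 0.0)
        myo = np.isin(lab, [2, 3, 4, 5])
        mi = np.isin(lab, [3, 4, 5])
        a = compute_transmurality(mi, myo, (48, 48), chords_per_slice=100)
        b = compute_transmurality(mi, myo, (48, 48), chords_per_slice=400)
        assert abs(a - b) < 1.0

    def test_empty_mi_returns_nan(self, phantom):
        lab = render_labels(phantom, 0.0, 0.0)
        myo = np.isin(lab, [2, 3, 4, 5])
        assert np.isnan(compute_transmurality(np.zeros_like(myo), myo, (48, 48)))


def test_sector_table_partitions_myocardium(phantom):
    lab = render_labels(phantom, 0.0, 0.0)
    myo = np.isin(lab, [2, 3, 4, 5])
    sect = sector_table(myo, (48, 48), n_sectors=6)
    assert np.all(sect[myo] >= 0)
    assert np.all(sect[~myo] == -1)
    assert np.unique(sect[myo]).size == 6 * GRID[2]
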