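"""Deformable digital left-ventricle phantom with infarct substructure.

The heart is an analytic annulus stack (short-axis): a cylindrical blood
pool surrounded by a myocardial shell, with an infarct (MI) wedge, a
microvascular-obstruction (MVO) core and an intramyocardial-hemorrhage
(IMH) band nested inside the wedge, plus a static liver slab as an
off-heart reference.  Geometry is evaluated analytically at voxel centres,
so ground truth is available at any motion phase.

Cardiac contraction scales the endocardial radius with a raised-cosine
systolic window; the epicardial radius is adjusted so that myocardial
cross-sectional area is conserved exactly (incompressibility).
Respiration is a rigid translation of the whole heart along a mostly
superior-inferior direction with an in-plane component.  Sub-regions are
defined in material coordinates (angle, normalized transmural depth), so
nesting is preserved under deformation.

Gadolinium kinetics differ per tissue; the MVO core is split internally
into a rim that fills in by the late window and a core that stays
unenhanced, reproducing time-dependent MVO shrinkage.  The public label
map always uses the 7 tissue codes of :class:`TissueClass`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import IntEnum

import numpy as np

from .signal_model import GdKinetics, effective_t1, gd_concentration

__all__ = [
    "TissueClass",
    "TissueProperties",
    "MotionModel",
    "PhantomConfig",
    "DigitalPhantom",
    "TissueMetrics",
    "build_phantom",
    "cohort_phantoms",
    "render_labels",
    "render_property_maps",
    "true_metrics",
    "default_tissues",
]


class TissueClass(IntEnum):
    BACKGROUND = 0
    BLOOD = 1
    REMOTE = 2        # remote (non-infarcted) myocardium
    MI = 3            # necrotic, gadolinium-enhancing infarct
    MVO = 4           # microvascular obstruction, inside MI
    IMH = 5           # intramyocardial hemorrhage, inside MI
    LIVER = 6         # static reference tissue

# internal property subclass: MVO rim with faster fill-in kinetics.
# Public labels map it back to TissueClass.MVO.
_MVO_RIM = 7
N_PROPERTY_CLASSES = 8


@dataclass(frozen=True)
class TissueProperties:
    """Relaxation, proton density and gadolinium behaviour of one tissue.

    ``t2_ms`` (spin-echo T2, > T2*) only enters the balanced-SSFP cine of
    the conventional comparator; None falls back to T2*."""

    t1_0_ms: float
    t2star_ms: float
    pd: float
    r1_per_mM_s: float = 4.5
    kinetics: GdKinetics = field(default_factory=lambda: GdKinetics(0.0, 0.0, 1.0, 1.0))
    t2_ms: float | None = None

    def __post_init__(self):
        if self.t1_0_ms <= 0 or self.t2star_ms <= 0 or self.pd < 0 or self.r1_per_mM_s < 0:
            raise ValueError("invalid tissue properties")

    def t1_ms(self, t_s: float) -> float:
        """Effective T1 at time ``t_s`` after contrast injection."""
        return effective_t1(self.t1_0_ms, self.r1_per_mM_s, gd_concentration(t_s, self.kinetics))


def default_tissues() -> dict[int, TissueProperties]:
    """Native 3 T tissue values (literature-typical; user-overridable).

    Kinetics: remote myocardium and blood enhance promptly and wash out;
    the necrotic infarct enhances and retains contrast (slow wash-out,
    the basis of LGE); the MVO core has a long arrival delay and barely
    fills; the MVO rim fills in between the early and late windows.
    """
    return {
        int(TissueClass.BACKGROUND): TissueProperties(1e9, 1e9, 0.0, 0.0),
        int(TissueClass.BLOOD): TissueProperties(
            1800.0, 25.0, 1.0, t2_ms=250.0,
            kinetics=GdKinetics(A=1.1, t_arr_s=12.0, tau_in_s=8.0, tau_out_s=1100.0),
        ),
        int(TissueClass.REMOTE): TissueProperties(
            1200.0, 30.0, 0.8, t2_ms=45.0,
            kinetics=GdKinetics(A=0.55, t_arr_s=18.0, tau_in_s=14.0, tau_out_s=520.0),
        ),
        int(TissueClass.MI): TissueProperties(
            1400.0, 38.0, 0.85, kinetics=GdKinetics(A=0.75, t_arr_s=25.0, tau_in_s=45.0, tau_out_s=2500.0)
        ),
        int(TissueClass.MVO): TissueProperties(
            1400.0, 36.0, 0.85, kinetics=GdKinetics(A=0.25, t_arr_s=480.0, tau_in_s=900.0, tau_out_s=5000.0)
        ),
        int(TissueClass.IMH): TissueProperties(
            1300.0, 10.0, 0.8, kinetics=GdKinetics(A=0.65, t_arr_s=28.0, tau_in_s=55.0, tau_out_s=2500.0)
        ),
        int(TissueClass.LIVER): TissueProperties(
            800.0, 25.0, 0.9, kinetics=GdKinetics(A=0.7, t_arr_s=15.0, tau_in_s=10.0, tau_out_s=400.0)
        ),
        _MVO_RIM: TissueProperties(
            1400.0, 36.0, 0.85, kinetics=GdKinetics(A=0.55, t_arr_s=120.0, tau_in_s=250.0, tau_out_s=4000.0)
        ),
    }


@dataclass(frozen=True)
class MotionModel:
    """Cardiac contraction and respiratory translation parameters."""

    rr_ms: float = 603.0               # 99.5 bpm
    resp_ms: float = 4000.0
    contraction_frac: float = 0.17     # peak systolic endocardial radius reduction
    wall_thickening_frac: float | None = None  # None -> exact area conservation
    resp_amp_mm: float = 8.0
    resp_dir: tuple[float, float, float] = (0.4, 0.0, 0.9165)  # AP + SI drift
    systole_frac: float = 0.35         # fraction of the cycle in systole

    def __post_init__(self):
        if self.rr_ms <= 0 or self.resp_ms <= 0:
            raise ValueError("periods must be positive")
        if not (0.0 <= self.contraction_frac <= 0.6):
            raise ValueError("contraction_frac must be in [0, 0.6]")

    def cardiac_window(self, phase):
        """Raised-cosine systolic weight w(phi) in [0, 1]; w(0) = 0 at ED."""
        phi = np.asarray(phase, dtype=float) % 1.0
        w = np.where(
            phi < self.systole_frac,
            0.5 * (1.0 - np.cos(2.0 * np.pi * phi / self.systole_frac)),
            0.0,
        )
        return w if w.ndim else float(w)

    def resp_weight(self, phase):
        phi = np.asarray(phase, dtype=float) % 1.0
        w = 0.5 * (1.0 - np.cos(2.0 * np.pi * phi))
        return w if w.ndim else float(w)

    def resp_displacement_mm(self, phase) -> np.ndarray:
        d = np.asarray(self.resp_dir, dtype=float)
        d = d / np.linalg.norm(d)
        return self.resp_amp_mm * np.asarray(self.resp_weight(phase))[..., None] * d


@dataclass(frozen=True)
class PhantomConfig:
    """Parameter set for :func:`build_phantom`.

    Angles in degrees; the MI wedge is (centre, extent) with a transmural
    fraction; MVO/IMH descriptors are material-coordinate fractions of the
    wedge.  ``seed`` only jitters the wedge centre (subject-to-subject
    placement variation); sizes are varied by :func:`cohort_phantoms`.
    """

    grid: tuple[int, int, int] = (192, 192, 14)
    voxel_mm: tuple[float, float, float] = (270.0 / 192, 270.0 / 192, 6.0)
    lv_center_mm: tuple[float, float] | None = None  # in-plane; None = FOV centre
    r_endo_mm: float = 22.0
    r_epi_mm: float = 34.0
    lv_z_frac: float = 0.85            # LV length as fraction of the z FOV
    mi_center_deg: float = 40.0
    mi_extent_deg: float = 90.0
    transmural_frac: float = 0.72
    mi_z_frac: float = 1.0             # fraction of LV slices with infarct
    mvo_theta_frac: float = 0.75       # of the wedge extent, centred
    mvo_depth_frac: float = 0.32       # of the transmural extent, from endo
    mvo_rim_frac: float = 0.35         # outer fraction of MVO that fills in late
    imh_theta_frac: float = 0.80
    imh_depth_frac: float = 0.22       # band thickness just outside the MVO core
    center_jitter_deg: float = 25.0
    liver: bool = True
    tissues: dict = field(default_factory=default_tissues)
    motion: MotionModel = field(default_factory=MotionModel)

    def __post_init__(self):
        if self.r_endo_mm >= self.r_epi_mm:
            raise ValueError("r_endo_mm must be < r_epi_mm")
        if not (0.0 <= self.mi_extent_deg < 360.0):
            raise ValueError("wedge extent must be in [0, 360)")
        if self.mi_extent_deg > 0 and not (0.0 < self.transmural_frac <= 1.0):
            raise ValueError("transmural_frac must be in (0, 1]")
        if self.mvo_depth_frac + self.imh_depth_frac > self.transmural_frac + 1e-9:
            raise ValueError("MVO + IMH depth must fit inside the MI wedge")

    def replace(self, **kw) -> "PhantomConfig":
        return replace(self, **kw)


@dataclass
class DigitalPhantom:
    """A built phantom: resolved geometry plus tissue and motion models."""

    config: PhantomConfig
    seed: int
    mi_center_deg: float   # after seed jitter
    lv_center_mm: np.ndarray  # (3,) includes z centre

    @property
    def grid(self):
        return self.config.grid

    @property
    def voxel_mm(self):
        return self.config.voxel_mm

    @property
    def voxel_volume_ml(self) -> float:
        dx, dy, dz = self.config.voxel_mm
        return dx * dy * dz / 1000.0

    @property
    def motion(self) -> MotionModel:
        return self.config.motion

    @property
    def tissues(self) -> dict:
        return self.config.tissues

    def property_t1_ms(self, t_s: float) -> np.ndarray:
        """Effective T1 per property class (length 8) at time ``t_s``."""
        return np.array([self.tissues[c].t1_ms(t_s) for c in range(N_PROPERTY_CLASSES)])

    def property_values(self, attr: str) -> np.ndarray:
        return np.array([getattr(self.tissues[c], attr) for c in range(N_PROPERTY_CLASSES)])


@dataclass
class TissueMetrics:
    """Ground-truth (or measured) per-subject quantification."""

    lvef_pct: float
    edv_ml: float
    esv_ml: float
    mi_pct_lv: float
    transmurality_pct: float
    mvo_pct_lv: float
    imh_pct_lv: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def build_phantom(config: PhantomConfig, seed: int) -> DigitalPhantom:
    """Deterministically build a phantom; ``seed`` jitters wedge placement."""
    rng = np.random.default_rng(seed)
    jitter = rng.uniform(-config.center_jitter_deg, config.center_jitter_deg)
    nx, ny, nz = config.grid
    dx, dy, dz = config.voxel_mm
    if config.lv_center_mm is None:
        cx, cy = nx * dx / 2.0, ny * dy / 2.0
    else:
        cx, cy = config.lv_center_mm
    cz = nz * dz / 2.0
    return DigitalPhantom(
        config=config,
        seed=seed,
        mi_center_deg=(config.mi_center_deg + jitter) % 360.0,
        lv_center_mm=np.array([cx, cy, cz]),
    )


def cohort_phantoms(n_subjects: int, base: PhantomConfig, seed: int) -> list[DigitalPhantom]:
    """Generate a cohort of subjects with jittered injury sizes.

    Draws mirror the spread of an acute reperfused-infarction cohort:
    MI extent/transmurality vary widely; roughly a quarter of subjects have
    no MVO (necrosis-only stage) and, of those with MVO, most also carry
    hemorrhage.  Heart rate ~ N(99.5, 13.7) bpm.
    """
    rng = np.random.default_rng(seed)
    subjects = []
    for i in range(n_subjects):
        extent = rng.uniform(60.0, 130.0)
        f = rng.uniform(0.55, 0.88)
        has_mvo = rng.random() < 0.75
        mvo_depth = rng.uniform(0.24, 0.38) if has_mvo else 0.0
        mvo_theta = rng.uniform(0.55, 0.85) if has_mvo else 0.0
        has_imh = has_mvo and rng.random() < 0.8
        # keep an enhancing rim outside the hemorrhage (as on in-vivo LGE)
        imh_depth = min(rng.uniform(0.16, 0.28), max(0.8 * f - mvo_depth, 0.0)) if has_imh else 0.0
        imh_theta = rng.uniform(0.6, 0.9) if has_imh else 0.0
        bpm = np.clip(rng.normal(99.5, 13.7), 60.0, 150.0)
        motion = replace(
            base.motion,
            rr_ms=60000.0 / bpm,
            resp_ms=rng.uniform(3200.0, 5000.0),
            contraction_frac=np.clip(rng.normal(0.17, 0.03), 0.08, 0.3),
        )
        cfg = base.replace(
            mi_extent_deg=extent,
            transmural_frac=f,
            mvo_theta_frac=mvo_theta,
            mvo_depth_frac=mvo_depth,
            imh_theta_frac=imh_theta,
            imh_depth_frac=imh_depth,
            mi_z_frac=rng.uniform(0.75, 1.0),
            motion=motion,
        )
        subjects.append(build_phantom(cfg, seed=int(rng.integers(0, 2**31 - 1))))
    return subjects


def _angular_distance_deg(theta, center):
    d = (theta - center + 180.0) % 360.0 - 180.0
    return np.abs(d)


def render_labels(
    phantom: DigitalPhantom,
    cardiac_phase: float,
    resp_phase: float,
    property_classes: bool = False,
) -> np.ndarray:
    """Voxel label volume at a motion state.

    With ``property_classes=True`` the internal MVO-rim subclass (code 7)
    is kept separate; otherwise it is reported as :class:`TissueClass.MVO`.
    """
    cfg = phantom.config
    nx, ny, nz = cfg.grid
    dx, dy, dz = cfg.voxel_mm
    m = cfg.motion

    disp = m.resp_displacement_mm(resp_phase)
    cx, cy, cz = phantom.lv_center_mm + np.asarray(disp).reshape(3)

    x = (np.arange(nx) + 0.5) * dx
    y = (np.arange(ny) + 0.5) * dy
    z = (np.arange(nz) + 0.5) * dz
    X, Y = np.meshgrid(x - cx, y - cy, indexing="ij")
    R = np.hypot(X, Y)
    TH = np.degrees(np.arctan2(Y, X)) % 360.0

    w = m.cardiac_window(cardiac_phase)
    r_endo = cfg.r_endo_mm * (1.0 - m.contraction_frac * w)
    if m.wall_thickening_frac is None:
        # exact per-slice area conservation of the shell
        r_epi = np.sqrt(r_endo**2 + cfg.r_epi_mm**2 - cfg.r_endo_mm**2)
    else:
        wall = (cfg.r_epi_mm - cfg.r_endo_mm) * (1.0 + m.wall_thickening_frac * w)
        r_epi = r_endo + wall

    lv_half = 0.5 * cfg.lv_z_frac * nz * dz
    in_lv_z = np.abs(z - cz) <= lv_half
    mi_half = 0.5 * cfg.mi_z_frac * cfg.lv_z_frac * nz * dz
    in_mi_z = np.abs(z - cz) <= mi_half

    blood2d = R < r_endo
    myo2d = (R >= r_endo) & (R < r_epi)
    rho = np.clip((R - r_endo) / max(r_epi - r_endo, 1e-9), 0.0, 1.0)

    adist = _angular_distance_deg(TH, phantom.mi_center_deg)
    in_wedge = myo2d & (adist <= cfg.mi_extent_deg / 2.0) & (rho < cfg.transmural_frac)
    in_mvo_full = (
        in_wedge
        & (adist <= cfg.mi_extent_deg * cfg.mvo_theta_frac / 2.0)
        & (rho < cfg.mvo_depth_frac)
    )
    mvo_core2d = in_mvo_full & (rho < cfg.mvo_depth_frac * (1.0 - cfg.mvo_rim_frac))
    mvo_rim2d = in_mvo_full & ~mvo_core2d
    imh2d = (
        in_wedge
        & (adist <= cfg.mi_extent_deg * cfg.imh_theta_frac / 2.0)
        & (rho >= cfg.mvo_depth_frac)
        & (rho < cfg.mvo_depth_frac + cfg.imh_depth_frac)
    )

    labels = np.zeros((nx, ny, nz), dtype=np.uint8)
    lab2d_lv = np.zeros((nx, ny), dtype=np.uint8)
    lab2d_lv[blood2d] = TissueClass.BLOOD
    lab2d_lv[myo2d] = TissueClass.REMOTE
    lab2d_lv[in_wedge] = TissueClass.MI
    lab2d_lv[imh2d] = TissueClass.IMH
    lab2d_lv[mvo_rim2d] = _MVO_RIM if property_classes else TissueClass.MVO
    lab2d_lv[mvo_core2d] = TissueClass.MVO
    lab2d_no_mi = np.zeros((nx, ny), dtype=np.uint8)
    lab2d_no_mi[blood2d] = TissueClass.BLOOD
    lab2d_no_mi[myo2d] = TissueClass.REMOTE

    labels[:, :, in_lv_z & in_mi_z] = lab2d_lv[:, :, None]
    labels[:, :, in_lv_z & ~in_mi_z] = lab2d_no_mi[:, :, None]

    if cfg.liver:
        # static slab in a corner of the FOV, away from the heart
        lx = x < 0.22 * nx * dx
        ly = y > 0.70 * ny * dy
        liver2d = np.outer(lx, ly)
        liver3d = liver2d[:, :, None] & (labels == 0)
        labels[liver3d] = TissueClass.LIVER
    return labels


def render_property_maps(
    phantom: DigitalPhantom,
    t_s: float,
    cardiac_phase: float,
    resp_phase: float,
):
    """PD, T1(t) and T2* volumes co-registered with the label volume."""
    labels = render_labels(phantom, cardiac_phase, resp_phase, property_classes=True)
    pd_map = phantom.property_values("pd")[labels]
    t2_map = phantom.property_values("t2star_ms")[labels]
    t1_map = phantom.property_t1_ms(t_s)[labels]
    return pd_map, t1_map, t2_map


def _counts(labels: np.ndarray) -> dict:
    myo_classes = (TissueClass.REMOTE, TissueClass.MI, TissueClass.MVO, TissueClass.IMH)
    c = {int(k): int(np.sum(labels == k)) for k in range(N_PROPERTY_CLASSES)}
    myo = sum(c[int(k)] for k in myo_classes)
    return {
        "blood": c[int(TissueClass.BLOOD)],
        "myo": myo,
        "mi": c[int(TissueClass.MI)] + c[int(TissueClass.MVO)] + c[int(TissueClass.IMH)],
        "mvo": c[int(TissueClass.MVO)],
        "imh": c[int(TissueClass.IMH)],
    }


def true_metrics(phantom: DigitalPhantom, n_phases: int = 24) -> TissueMetrics:
    """Ground-truth metrics by voxel counting on rendered labels.

    End-diastole/end-systole are the max/min cavity-volume phases over the
    cine phase grid, matching how the reconstruction is analysed, so truth
    and measurement share one discretization.  Injury fractions are counted
    at end-diastole, end-expiration.  Transmurality truth is the material
    transmural fraction.
    """
    phases = np.arange(n_phases) / n_phases
    blood = [
        _counts(render_labels(phantom, p, 0.0))["blood"] for p in phases
    ]
    ed, es = int(np.argmax(blood)), int(np.argmin(blood))
    vv = phantom.voxel_volume_ml
    edv, esv = blood[ed] * vv, blood[es] * vv
    c = _counts(render_labels(phantom, phases[ed], 0.0))
    myo = max(c["myo"], 1)
    cfg = phantom.config
    return TissueMetrics(
        lvef_pct=100.0 * (edv - esv) / edv if edv > 0 else 0.0,
        edv_ml=edv,
        esv_ml=esv,
        mi_pct_lv=100.0 * c["mi"] / myo,
        transmurality_pct=100.0 * cfg.transmural_frac if c["mi"] > 0 else 0.0,
        mvo_pct_lv=100.0 * c["mvo"] / myo,
        imh_pct_lv=100.0 * c["imh"] / myo,
    )
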