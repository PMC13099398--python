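"""Multi-coil Cartesian k-space simulation of the phantom.

Free-running arm: every scheduled readout sees the phantom at its cardiac/
respiratory state and contrast time; the per-voxel complex signal is the
IR-FLASH train value at the readout's segment times per-echo T2* decay.
Because the phantom is piecewise-constant over tissue classes, the k-space
line of an event is a tissue-signal-weighted sum of cached DFTs of
per-tissue, per-motion-state coil-weighted masks, which makes the 65k-line
simulation tractable.  Motion is rendered on a discrete state grid
(default 48 cardiac x 8 respiratory states, i.e. finer than the analysis
bins so that within-bin averaging behaves like smooth motion).

Conventional arm: an idealized breath-held, gated comparator rendered
directly in image space (fully sampled) with matched geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.fft

from .phantom import (
    N_PROPERTY_CLASSES,
    DigitalPhantom,
    TissueClass,
    render_labels,
)
from .schedule import SamplingSchedule, SequenceParams
from .signal_model import (
    echo_signal,
    flash_steady_state,
    gated_ir_signal,
    gd_concentration,
    effective_t1,
    ir_flash_train,
)

__all__ = [
    "CoilSet",
    "KSpaceData",
    "ConventionalProtocol",
    "ConventionalStudy",
    "simulate_free_running",
    "simulate_conventional",
    "cfftn",
    "cifftn",
    "sigma_for_snr",
    "reference_signal",
]


def cfftn(x, axes=(-3, -2, -1)):
    """Centered orthonormal DFT (image -> k-space); preserves single
    precision (scipy backend)."""
    return np.fft.fftshift(
        scipy.fft.fftn(np.fft.ifftshift(x, axes=axes), axes=axes, norm="ortho"), axes=axes
    )


def cifftn(x, axes=(-3, -2, -1)):
    """Centered orthonormal inverse DFT (k-space -> image)."""
    return np.fft.ifftshift(
        scipy.fft.ifftn(np.fft.fftshift(x, axes=axes), axes=axes, norm="ortho"), axes=axes
    )


@dataclass
class CoilSet:
    """Complex receive sensitivities, (n_coils, nx, ny, nz)."""

    maps: np.ndarray

    @property
    def n_coils(self) -> int:
        return self.maps.shape[0]

    @classmethod
    def uniform(cls, grid) -> "CoilSet":
        return cls(maps=np.ones((1, *grid), dtype=np.complex128))

    @classmethod
    def gaussian_lobes(cls, grid, n_coils: int = 8, center=None) -> "CoilSet":
        """Smooth Gaussian-lobe coils around the FOV perimeter with a
        linear phase roll; sum-of-squares normalized to 1 at the heart
        centre."""
        nx, ny, nz = grid
        x, y, z = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
        if center is None:
            center = (nx / 2.0, ny / 2.0, nz / 2.0)
        maps = np.empty((n_coils, nx, ny, nz), dtype=np.complex128)
        width = 0.55 * max(nx, ny)
        for c in range(n_coils):
            ang = 2 * np.pi * c / n_coils
            cx = nx / 2.0 + 0.65 * nx * np.cos(ang)
            cy = ny / 2.0 + 0.65 * ny * np.sin(ang)
            mag = np.exp(-(((x - cx) ** 2 + (y - cy) ** 2) / (2 * width**2)))
            phase = 2 * np.pi * (0.08 * (x - cx) / nx - 0.06 * (y - cy) / ny + 0.2 * c / n_coils)
            maps[c] = mag * np.exp(1j * phase)
        ic = tuple(int(round(v)) for v in center)
        sos = np.sqrt(np.sum(np.abs(maps[(slice(None), *ic)]) ** 2))
        maps /= sos
        return cls(maps=maps)


@dataclass
class KSpaceData:
    """Simulated (or imported) time-stamped k-space lines.

    ``samples`` is complex, indexed (event, coil, echo, kx); kx is fully
    sampled per readout.  Ground-truth motion/contrast tags from the
    simulator are carried for bypass navigation and binning oracles.
    """

    schedule: SamplingSchedule
    samples: np.ndarray
    noise_sigma: float
    n_coils: int
    t_inject_offset_s: float
    true_cardiac_phase: np.ndarray | None = None
    true_resp_weight: np.ndarray | None = None

    @property
    def n_kx(self) -> int:
        return self.samples.shape[-1]

    @property
    def n_echo(self) -> int:
        return self.samples.shape[2]

    def t_inject_s(self) -> np.ndarray:
        """Time since contrast injection at each readout, seconds."""
        return self.schedule.t_ms / 1000.0 + self.t_inject_offset_s


class GridMismatchError(ValueError):
    pass


def _signal_table(phantom: DigitalPhantom, schedule: SamplingSchedule, t_inject_offset_s: float):
    """Per-tissue transverse signal for every (block, segment, echo).

    Gadolinium concentration is frozen at each IR block's start time (the
    block is 2.5 s; enhancement varies slowly on that scale).  Returns
    (n_classes, n_blocks, S, n_echo) float64.
    """
    p = schedule.params
    n_blocks = int(schedule.ir_block.max()) + 1
    t_block_s = (np.arange(n_blocks) * p.block_ms) / 1000.0 + t_inject_offset_s
    tissues = phantom.tissues
    n_cls = N_PROPERTY_CLASSES
    t1 = np.empty((n_cls, n_blocks))
    for c in range(n_cls):
        tp = tissues[c]
        conc = gd_concentration(t_block_s, tp.kinetics)
        t1[c] = effective_t1(tp.t1_0_ms, tp.r1_per_mM_s, conc)
    _, s = ir_flash_train(t1, p)                     # (n_cls, n_blocks, S)
    pd = phantom.property_values("pd")
    t2 = phantom.property_values("t2star_ms")
    te = np.asarray(p.te_ms)
    decay = np.exp(-te[None, :] / t2[:, None])       # (n_cls, n_echo)
    table = s[..., None] * decay[:, None, None, :] * pd[:, None, None, None]
    table[int(TissueClass.BACKGROUND)] = 0.0
    return table


def simulate_free_running(
    phantom: DigitalPhantom,
    schedule: SamplingSchedule,
    coils: CoilSet,
    noise_sigma: float = 0.0,
    t_inject_offset_s: float = 45.0,
    seed: int = 0,
    motion_states: tuple[int, int] = (48, 8),
    dtype=np.complex64,
) -> KSpaceData:
    """Sample every scheduled k-space line through the signal model."""
    p = schedule.params
    nx, ny, nz = phantom.grid
    if p.n_ky != ny or p.n_kz != nz:
        raise GridMismatchError(f"schedule ({p.n_ky},{p.n_kz}) vs grid ({ny},{nz})")
    if coils.maps.shape[1:] != phantom.grid:
        raise GridMismatchError("coil maps do not match the phantom grid")

    n_cs, n_rs = motion_states
    m = phantom.motion
    t_ms = schedule.t_ms
    cphase = (t_ms % m.rr_ms) / m.rr_ms
    rphase = (t_ms % m.resp_ms) / m.resp_ms
    cstate = np.minimum((cphase * n_cs).astype(int), n_cs - 1)
    rstate = np.minimum((rphase * n_rs).astype(int), n_rs - 1)

    table = _signal_table(phantom, schedule, t_inject_offset_s)  # (cls, blk, S, E)
    n_cls = table.shape[0]
    n_ev = schedule.n_events
    n_echo = p.n_echo
    samples = np.empty((n_ev, coils.n_coils, n_echo, nx), dtype=dtype)

    iky = (schedule.ky + ny // 2).astype(int)
    ikz = (schedule.kz + nz // 2).astype(int)

    for cs in range(n_cs):
        for rs in range(n_rs):
            sel = np.where((cstate == cs) & (rstate == rs))[0]
            if sel.size == 0:
                continue
            labels = render_labels(
                phantom, (cs + 0.5) / n_cs, (rs + 0.5) / n_rs, property_classes=True
            )
            # cached per-tissue coil-weighted DFT volumes for this state
            fvols = np.empty((n_cls, coils.n_coils, nx, ny, nz), dtype=np.complex64)
            for c in range(n_cls):
                mask = (labels == c).astype(np.float32)
                if not mask.any():
                    fvols[c] = 0.0
                    continue
                fvols[c] = cfftn(coils.maps.astype(np.complex64) * mask[None])
            lines = fvols[:, :, :, iky[sel], ikz[sel]]     # (cls, coil, kx, ev)
            w = table[:, schedule.ir_block[sel], schedule.seg[sel], :]  # (cls, ev, E)
            samples[sel] = np.einsum(
                "cge,cdxg->gdex", w.astype(np.float32), lines, optimize=True
            )
            del fvols, lines

    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        scale = noise_sigma / np.sqrt(2)
        for lo in range(0, n_ev, 4096):  # chunked to bound memory
            blk = samples[lo : lo + 4096]
            re = rng.standard_normal(blk.shape, dtype=np.float32)
            im = rng.standard_normal(blk.shape, dtype=np.float32)
            blk += scale * (re + 1j * im).astype(dtype)

    return KSpaceData(
        schedule=schedule,
        samples=samples,
        noise_sigma=noise_sigma,
        n_coils=coils.n_coils,
        t_inject_offset_s=t_inject_offset_s,
        true_cardiac_phase=(cstate + 0.5) / n_cs,
        true_resp_weight=m.resp_weight((rstate + 0.5) / n_rs),
    )


@dataclass(frozen=True)
class ConventionalProtocol:
    """Idealized gated, breath-held comparator settings (2D stack).

    Contrast formulas follow the conventional column parameters: cine
    flip 50 deg / TR 2.68 ms, multi-echo GRE with 8 echoes for T2*, and
    inversion-recovery snapshots for EGE (fixed long TI) and LGE
    (remote-nulling TI), both with an inversion every other heartbeat.
    """

    n_cine_frames: int = 24
    cine_flip_deg: float = 50.0
    cine_tr_ms: float = 2.68
    t2star_te_ms: tuple[float, ...] = (1.47, 3.38, 5.39, 7.4, 9.41, 11.42, 13.43, 15.44)
    t2star_flip_deg: float = 20.0
    t2star_tr_ms: float = 17.32
    ege_time_s: float = 120.0
    lge_time_s: float = 900.0
    ege_ti_ms: float = 520.0
    ir_beats_per_inversion: int = 2


@dataclass
class ConventionalStudy:
    """Fully sampled comparator images on the phantom grid."""

    cine: np.ndarray            # (n_frames, nx, ny, nz) magnitude
    t2star_echoes: np.ndarray   # (n_echo, nx, ny, nz) pre-contrast magnitude
    ege: np.ndarray             # (nx, ny, nz)
    lge: np.ndarray             # remote-nulled, (nx, ny, nz)
    mvo_weighted_late: np.ndarray  # long-TI late-window frame for MVO
    protocol: ConventionalProtocol
    noise_sigma: float
    ed_frame: int = 0


def _render_tissue_image(phantom, signal_per_class, cardiac_phase, resp_phase):
    labels = render_labels(phantom, cardiac_phase, resp_phase, property_classes=True)
    return np.asarray(signal_per_class)[labels]


def _magnitude_with_noise(img, sigma, rng):
    if sigma <= 0:
        return np.abs(img)
    noise = rng.normal(scale=sigma / np.sqrt(2), size=(2, *img.shape))
    return np.abs(img + noise[0] + 1j * noise[1])


def simulate_conventional(
    phantom: DigitalPhantom,
    protocol: ConventionalProtocol | None = None,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> ConventionalStudy:
    """Render the idealized gated comparator study."""
    proto = protocol or ConventionalProtocol()
    rng = np.random.default_rng(seed)
    tissues = phantom.tissues
    n_cls = N_PROPERTY_CLASSES
    pd = phantom.property_values("pd")
    t2 = phantom.property_values("t2star_ms")
    t1_native = phantom.property_values("t1_0_ms")

    # --- cine: pre-contrast balanced-SSFP steady state, breath-hold
    # (resp 0); blood-bright T2/T1 contrast, s = PD sin(a) / (1 + cos(a)
    # + (1 - cos(a)) T1/T2).  Spin-echo T2 values are used where defined
    # (T2* would wrongly darken blood).
    alpha_c = np.deg2rad(proto.cine_flip_deg)
    t2b = np.array([
        (tissues[c].t2_ms if tissues[c].t2_ms else tissues[c].t2star_ms)
        for c in range(n_cls)
    ])
    s_cine = pd * np.sin(alpha_c) / (
        1 + np.cos(alpha_c) + (1 - np.cos(alpha_c)) * t1_native / t2b
    )
    s_cine[int(TissueClass.BACKGROUND)] = 0.0
    phases = np.arange(proto.n_cine_frames) / proto.n_cine_frames
    cine = np.stack(
        [
            _magnitude_with_noise(
                _render_tissue_image(phantom, s_cine, ph, 0.0), noise_sigma, rng
            )
            for ph in phases
        ]
    )

    # --- pre-contrast multi-echo GRE for T2*
    s0 = pd * flash_steady_state(t1_native, proto.t2star_flip_deg, proto.t2star_tr_ms)
    s0[int(TissueClass.BACKGROUND)] = 0.0
    echoes = np.stack(
        [
            _magnitude_with_noise(
                _render_tissue_image(
                    phantom, echo_signal(s0, t2, te * np.ones(n_cls)), 0.0, 0.0
                ),
                noise_sigma,
                rng,
            )
            for te in proto.t2star_te_ms
        ]
    )

    # --- IR snapshots at the EGE and LGE windows (gated: inversion every
    # other heartbeat), end-diastole, end-expiration
    period = proto.ir_beats_per_inversion * phantom.motion.rr_ms

    def t1_at(t_s):
        return np.array(
            [
                effective_t1(
                    tissues[c].t1_0_ms,
                    tissues[c].r1_per_mM_s,
                    gd_concentration(t_s, tissues[c].kinetics),
                )
                for c in range(n_cls)
            ]
        )

    def ir_image(t_s, ti_ms):
        t1 = t1_at(t_s)
        sig = pd * gated_ir_signal(t1, ti_ms, period)
        sig[int(TissueClass.BACKGROUND)] = 0.0
        return _magnitude_with_noise(
            _render_tissue_image(phantom, sig, 0.0, 0.0), noise_sigma, rng
        )

    # remote-nulling TI at the LGE window (closed-form null of the
    # periodic-inversion recovery for the remote tissue)
    t1_rem = effective_t1(
        tissues[int(TissueClass.REMOTE)].t1_0_ms,
        tissues[int(TissueClass.REMOTE)].r1_per_mM_s,
        gd_concentration(proto.lge_time_s, tissues[int(TissueClass.REMOTE)].kinetics),
    )
    E = np.exp(-period / t1_rem)
    ti_null = t1_rem * np.log(1.0 + (1.0 - E) / (1.0 + E))

    ege = ir_image(proto.ege_time_s, proto.ege_ti_ms)
    lge = ir_image(proto.lge_time_s, ti_null)
    mvo_late = ir_image(proto.lge_time_s, proto.ege_ti_ms)

    return ConventionalStudy(
        cine=cine,
        t2star_echoes=echoes,
        ege=ege,
        lge=lge,
        mvo_weighted_late=mvo_late,
        protocol=proto,
        noise_sigma=noise_sigma,
    )


def reference_signal(phantom: DigitalPhantom, params: SequenceParams,
                     t_s: float = 900.0) -> float:
    """Remote-myocardium signal amplitude at late tau / late contrast /
    first echo — the amplitude used to define acquisition SNR."""
    tp = phantom.tissues[int(TissueClass.REMOTE)]
    t1 = tp.t1_ms(t_s)
    _, s = ir_flash_train(t1, params)
    return float(abs(s[-1]) * tp.pd * np.exp(-params.te_ms[0] / tp.t2star_ms))


def sigma_for_snr(phantom: DigitalPhantom, params: SequenceParams, snr: float) -> float:
    """k-space noise SD giving image-domain SNR ``snr`` on remote
    myocardium (orthonormal DFT keeps noise SD equal in both domains)."""
    if snr <= 0 or not np.isfinite(snr):
        return 0.0
    return reference_signal(phantom, params) / snr
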