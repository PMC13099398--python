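"""Free-running acquisition timetable.

The sequence is an inversion-recovery-prepared multi-echo spoiled gradient
echo (IR-mGRE) that runs continuously: inversion pulses at a fixed block
period, ``segments_per_ir`` low-flip excitations per block, and a randomized
Gaussian-density Cartesian (ky, kz) phase-encode pattern.  Every
``training_every``-th readout revisits the k-space centre line; these
"training" lines drive both self-navigation and temporal-subspace
estimation downstream.

All event times are computed in integer 0.1 ms ticks so that timing
identities hold exactly in tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "SequenceParams",
    "SamplingSchedule",
    "build_schedule",
    "sampling_fraction",
    "gd_bin_edges",
]

TICKS_PER_MS = 10


class EmptyScheduleError(ValueError):
    """Raised when the scan duration admits no readout."""


@dataclass(frozen=True)
class SequenceParams:
    """Imaging parameters of the free-running IR-mGRE protocol.

    Defaults reproduce the whole-heart protocol: TR 13.2 ms, six echoes
    1.47-11.42 ms, 5 degree excitation, 10 ms delay from inversion to the
    first excitation, 192 segments per IR block, one training line every 6
    readouts, 14 min 20 s total, 192 x 14 phase encodes over a
    270 x 270 mm field of view with 6 mm partitions.
    """

    tr_ms: float = 13.2
    te_ms: tuple[float, ...] = (1.47, 3.38, 5.39, 7.4, 9.41, 11.42)
    flip_deg: float = 5.0
    ti0_ms: float = 10.0
    segments_per_ir: int = 192
    training_every: int = 6
    duration_s: float = 860.0
    n_ky: int = 192
    n_kz: int = 14
    fov_mm: tuple[float, float] = (270.0, 270.0)
    slice_mm: float = 6.0
    inv_efficiency: float = 1.0
    dead_time_ms: float = 0.0

    def __post_init__(self) -> None:
        te = np.asarray(self.te_ms, dtype=float)
        if te.size < 1 or np.any(np.diff(te) <= 0):
            raise ValueError("te_ms must be strictly increasing")
        if te.max() >= self.tr_ms:
            raise ValueError("max(te_ms) must be < tr_ms")
        if self.segments_per_ir < 1:
            raise ValueError("segments_per_ir must be >= 1")
        if self.training_every < 2:
            raise ValueError("training_every must be >= 2")
        if not (0.0 < self.inv_efficiency <= 1.0):
            raise ValueError("inv_efficiency must be in (0, 1]")
        if self.tr_ms <= 0 or self.ti0_ms < 0 or self.dead_time_ms < 0:
            raise ValueError("invalid timing parameters")

    @property
    def n_echo(self) -> int:
        return len(self.te_ms)

    @property
    def block_ms(self) -> float:
        """IR-block period: segments_per_ir * TR plus optional dead time."""
        return self.segments_per_ir * self.tr_ms + self.dead_time_ms

    def replace(self, **kw) -> "SequenceParams":
        return replace(self, **kw)


@dataclass
class SamplingSchedule:
    """Time-ordered readout events, stored as parallel arrays."""

    params: SequenceParams
    seed: int
    idx: np.ndarray          # global readout index, int64
    t_ticks: np.ndarray      # excitation time in 0.1 ms ticks, int64
    ir_block: np.ndarray
    seg: np.ndarray
    ky: np.ndarray           # in [-n_ky/2, n_ky/2 - 1]
    kz: np.ndarray
    is_training: np.ndarray  # bool

    @property
    def n_events(self) -> int:
        return self.idx.size

    @property
    def t_ms(self) -> np.ndarray:
        return self.t_ticks / TICKS_PER_MS

    @property
    def tau_ms(self) -> np.ndarray:
        """Time since the owning block's inversion pulse."""
        return self.params.ti0_ms + self.seg * self.params.tr_ms

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "idx": self.idx,
                "t_ms": self.t_ms,
                "ir_block": self.ir_block,
                "seg": self.seg,
                "tau_ms": self.tau_ms,
                "ky": self.ky,
                "kz": self.kz,
                "is_training": self.is_training.astype(int),
            }
        )

    def to_table(self, path) -> None:
        """Write the documented columnar text form (TSV, one row/event)."""
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_table(cls, path, params: SequenceParams, seed: int = -1) -> "SamplingSchedule":
        df = pd.read_csv(path, sep="\t")
        return cls(
            params=params,
            seed=seed,
            idx=df["idx"].to_numpy(np.int64),
            t_ticks=np.round(df["t_ms"].to_numpy(float) * TICKS_PER_MS).astype(np.int64),
            ir_block=df["ir_block"].to_numpy(np.int64),
            seg=df["seg"].to_numpy(np.int64),
            ky=df["ky"].to_numpy(np.int64),
            kz=df["kz"].to_numpy(np.int64),
            is_training=df["is_training"].to_numpy(bool),
        )


def _truncated_gaussian_int(rng, n, sigma, lo, hi):
    """Rejection-sample n integers ~ round(N(0, sigma)) within [lo, hi]."""
    out = np.empty(n, dtype=np.int64)
    filled = 0
    while filled < n:
        draw = np.round(rng.normal(0.0, sigma, size=2 * (n - filled) + 16)).astype(np.int64)
        draw = draw[(draw >= lo) & (draw <= hi)]
        take = min(draw.size, n - filled)
        out[filled : filled + take] = draw[:take]
        filled += take
    return out


def build_schedule(params: SequenceParams, seed: int) -> SamplingSchedule:
    """Realize the free-running timetable for one scan.

    Block ``b`` starts at ``b * block_ms``; segment ``s`` fires at block
    start + ``ti0_ms + s * tr_ms``.  Readouts with ``idx % training_every
    == 0`` are training lines at the k-space centre (ky = kz = 0); all
    others draw (ky, kz) independently from a truncated discrete Gaussian
    with sigma = N/6, rejection-sampled into the index bounds.
    Deterministic for fixed (params, seed).
    """
    p = params
    tr_t = int(round(p.tr_ms * TICKS_PER_MS))
    ti0_t = int(round(p.ti0_ms * TICKS_PER_MS))
    block_t = p.segments_per_ir * tr_t + int(round(p.dead_time_ms * TICKS_PER_MS))
    dur_t = int(round(p.duration_s * 1000 * TICKS_PER_MS))

    # upper bound on events, then trim by the duration rule t < duration
    n_max = (dur_t // tr_t) + p.segments_per_ir + 1
    idx = np.arange(n_max, dtype=np.int64)
    block = idx // p.segments_per_ir
    seg = idx % p.segments_per_ir
    t = block * block_t + ti0_t + seg * tr_t
    keep = t < dur_t
    idx, block, seg, t = idx[keep], block[keep], seg[keep], t[keep]
    if idx.size == 0:
        raise EmptyScheduleError("scan duration shorter than one readout")

    is_training = (idx % p.training_every) == 0
    n_img = int((~is_training).sum())
    rng = np.random.default_rng(seed)
    ky = np.zeros(idx.size, dtype=np.int64)
    kz = np.zeros(idx.size, dtype=np.int64)
    ky[~is_training] = _truncated_gaussian_int(
        rng, n_img, p.n_ky / 6.0, -p.n_ky // 2, p.n_ky // 2 - 1
    )
    kz[~is_training] = _truncated_gaussian_int(
        rng, n_img, p.n_kz / 6.0, -p.n_kz // 2, p.n_kz // 2 - 1
    )
    return SamplingSchedule(
        params=p, seed=seed, idx=idx, t_ticks=t, ir_block=block, seg=seg,
        ky=ky, kz=kz, is_training=is_training,
    )


def gd_bin_edges(t_min_s: float, t_max_s: float, n_gd: int) -> np.ndarray:
    """Contrast-dynamics bin edges uniform in sqrt(time since injection).

    The sqrt spacing concentrates bins early after injection, where
    gadolinium enhancement changes fastest.
    """
    u = np.linspace(np.sqrt(max(t_min_s, 0.0)), np.sqrt(t_max_s), n_gd + 1)
    return u**2


def sampling_fraction(
    schedule: SamplingSchedule,
    n_cardiac: int = 24,
    n_resp: int = 4,
    n_gd: int = 16,
    cardiac_bin: np.ndarray | None = None,
    resp_bin: np.ndarray | None = None,
    gd_bin: np.ndarray | None = None,
    rr_ms: float = 603.0,
    resp_ms: float = 4000.0,
    t_inject_offset_s: float = 45.0,
) -> float:
    """Filled fraction of the (ky, kz, cardiac, resp, Gd) sampling tensor.

    Echo and inversion-time dimensions are excluded from the denominator:
    every readout acquires all echoes at a known tau, so those dimensions
    are always complete.  If bin assignments are not supplied, nominal
    periodic cardiac/respiratory phases (rr_ms, resp_ms) and sqrt-uniform
    contrast bins are used.
    """
    if schedule.n_events == 0:
        raise EmptyScheduleError("empty schedule")
    t_ms = schedule.t_ms
    if cardiac_bin is None:
        cardiac_bin = np.minimum(
            ((t_ms % rr_ms) / rr_ms * n_cardiac).astype(np.int64), n_cardiac - 1
        )
    if resp_bin is None:
        resp_bin = np.minimum(
            ((t_ms % resp_ms) / resp_ms * n_resp).astype(np.int64), n_resp - 1
        )
    if gd_bin is None:
        t_inj = t_ms / 1000.0 + t_inject_offset_s
        edges = gd_bin_edges(t_inj.min(), t_inj.max() + 1e-9, n_gd)
        gd_bin = np.clip(np.searchsorted(edges, t_inj, side="right") - 1, 0, n_gd - 1)
    p = schedule.params
    cells = np.stack(
        [
            schedule.ky + p.n_ky // 2,
            schedule.kz + p.n_kz // 2,
            np.asarray(cardiac_bin),
            np.asarray(resp_bin),
            np.asarray(gd_bin),
        ],
        axis=1,
    )
    n_filled = np.unique(cells, axis=0).shape[0]
    denom = p.n_ky * p.n_kz * n_cardiac * n_resp * n_gd
    return n_filled / denom
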