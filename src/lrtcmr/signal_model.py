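"""Closed-form IR-prepared spoiled gradient echo (FLASH) signal evolution.

The free-running sequence applies an inversion every ``block_ms``
milliseconds and reads out ``segments_per_ir`` low-flip excitations per
block.  Under perfect spoiling, the longitudinal magnetization just before
excitation ``n`` (1-based) of a block obeys

    L_{n+1} = M0 (1 - E1) + a L_n,      E1 = exp(-TR/T1),  a = E1 cos(alpha)

so within a block ``L_n = M_ss + (L_1 - M_ss) a^(n-1)`` with the driven
steady state ``M_ss = M0 (1 - E1) / (1 - a)``.  Across blocks the
pre-inversion value relaxes over the residual block time, is inverted with
efficiency ``eta`` and relaxes for ``ti0``; the block-to-block map is
affine, and its unique fixed point defines the cyclic steady state in
closed form.  Transverse signal at echo time TE is ``L_n sin(alpha)
exp(-TE/T2*)``.

Gadolinium enhancement enters through a wash-in/wash-out concentration
curve and the standard relaxivity relation ``1/T1 = 1/T1_0 + r1 C``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .schedule import SequenceParams

__all__ = [
    "ir_flash_train",
    "ir_flash_recursion",
    "echo_signal",
    "gd_concentration",
    "effective_t1",
    "flash_steady_state",
    "gated_ir_signal",
    "null_segment",
]


@dataclass(frozen=True)
class GdKinetics:
    """Gadolinium concentration model: wash-in saturating exponential times
    wash-out decay, delayed by an arrival time.

    C(t) = A (1 - exp(-(t - t_arr)/tau_in)) exp(-(t - t_arr)/tau_out)
    for t >= t_arr, else 0.  All times in seconds, A in mM.
    """

    A: float
    t_arr_s: float
    tau_in_s: float
    tau_out_s: float

    def __post_init__(self):
        if min(self.A, self.t_arr_s, self.tau_in_s, self.tau_out_s) < 0:
            raise ValueError("GdKinetics parameters must be nonnegative")

    @property
    def t_peak_s(self) -> float:
        """Location of the concentration maximum (calculus identity)."""
        return self.t_arr_s + self.tau_in_s * np.log1p(self.tau_out_s / self.tau_in_s)


def gd_concentration(t_s, kinetics: GdKinetics):
    """Concentration in mM at time(s) ``t_s`` after injection."""
    t = np.asarray(t_s, dtype=float)
    dt = t - kinetics.t_arr_s
    c = np.where(
        dt > 0,
        kinetics.A * (-np.expm1(-dt / kinetics.tau_in_s)) * np.exp(-dt / kinetics.tau_out_s),
        0.0,
    )
    return c if c.ndim else float(c)


def effective_t1(t1_0_ms, r1_per_mM_s, c_mM):
    """Gadolinium-shortened T1 in ms: 1/T1 = 1/T1_0 + r1*C (unit-careful)."""
    t1_0 = np.asarray(t1_0_ms, dtype=float)
    rate = 1.0 / t1_0 + np.asarray(r1_per_mM_s) * np.asarray(c_mM) / 1000.0
    out = 1.0 / rate
    return out if out.ndim else float(out)


def ir_flash_train(t1_ms, params: SequenceParams, m0=1.0):
    """Cyclic-steady-state longitudinal values before each excitation.

    Parameters broadcast: ``t1_ms`` may be any array shape; returns
    ``(L, s)`` with trailing axis of length ``segments_per_ir`` where
    ``s = L sin(alpha)`` is the transverse signal at TE = 0.
    """
    t1 = np.atleast_1d(np.asarray(t1_ms, dtype=float))
    if np.any(t1 <= 0):
        raise ValueError("T1 must be positive")
    p = params
    alpha = np.deg2rad(p.flip_deg)
    eta = p.inv_efficiency
    S = p.segments_per_ir
    e1 = np.exp(-p.tr_ms / t1)
    a = e1 * np.cos(alpha)
    one_minus_a = np.maximum(1.0 - a, 1e-15)
    m_ss = m0 * (1.0 - e1) / one_minus_a

    # residual relaxation time from last excitation to the next inversion
    t_rem = p.block_ms - p.ti0_ms - (S - 1) * p.tr_ms
    if t_rem < 0:
        raise ValueError("block period shorter than the readout train")
    e_rem = np.exp(-t_rem / t1)
    e_ti0 = np.exp(-p.ti0_ms / t1)
    aS1 = a ** (S - 1)
    ca = np.cos(alpha)

    # L1 = m0 - (m0 + eta*M_pre) e_ti0
    # L_S = m_ss + (L1 - m_ss) a^(S-1)
    # M_pre' = m0 - (m0 - L_S cos(alpha)) e_rem   -> affine in M_pre
    # compose: M_pre' = u + v * M_pre
    l1_of_zero = m0 - m0 * e_ti0
    lS_coeff = aS1 * (-eta * e_ti0)                       # dL_S/dM_pre
    lS_of_zero = m_ss + (l1_of_zero - m_ss) * aS1
    u = m0 - (m0 - lS_of_zero * ca) * e_rem
    v = lS_coeff * ca * e_rem
    m_pre = u / (1.0 - v)

    l1 = m0 - (m0 + eta * m_pre) * e_ti0
    n = np.arange(S)
    L = m_ss[..., None] + (l1 - m_ss)[..., None] * a[..., None] ** n
    s = L * np.sin(alpha)
    if np.isscalar(t1_ms) or np.ndim(t1_ms) == 0:
        return L[0], s[0]
    return L, s


def ir_flash_recursion(t1_ms: float, params: SequenceParams, m0: float = 1.0,
                       n_blocks: int = 50, m_init: float | None = None):
    """Brute-force Bloch recursion oracle: step the magnetization through
    ``n_blocks`` IR blocks event by event and return the last block's
    pre-excitation longitudinal values.  Independent of the closed form.
    """
    p = params
    alpha = np.deg2rad(p.flip_deg)
    e1 = np.exp(-p.tr_ms / t1_ms)
    t_rem = p.block_ms - p.ti0_ms - (p.segments_per_ir - 1) * p.tr_ms
    m = m0 if m_init is None else m_init
    L = np.zeros(p.segments_per_ir)
    for _ in range(n_blocks):
        m = -p.inv_efficiency * m
        m = m0 - (m0 - m) * np.exp(-p.ti0_ms / t1_ms)
        for n in range(p.segments_per_ir):
            L[n] = m
            m = m * np.cos(alpha)                      # excitation
            m = m0 - (m0 - m) * e1                     # relax one TR
        # from the last excitation we already relaxed a full TR above;
        # rewind to (S-1) TR + t_rem of relaxation after the last flip
        m = L[-1] * np.cos(alpha)
        m = m0 - (m0 - m) * np.exp(-t_rem / t1_ms)
    return L


def echo_signal(s, t2star_ms, te_ms):
    """Apply mono-exponential T2* decay to transverse signal."""
    t2 = np.asarray(t2star_ms, dtype=float)
    if np.any(t2 <= 0):
        raise ValueError("T2* must be positive")
    te = np.asarray(te_ms, dtype=float)
    if np.any(te < 0):
        raise ValueError("TE must be nonnegative")
    return np.asarray(s) * np.exp(-te / t2)


def flash_steady_state(t1_ms, flip_deg, tr_ms, m0=1.0):
    """Driven steady-state transverse signal of a spoiled gradient echo."""
    e1 = np.exp(-tr_ms / np.asarray(t1_ms, dtype=float))
    alpha = np.deg2rad(flip_deg)
    return m0 * np.sin(alpha) * (1 - e1) / (1 - e1 * np.cos(alpha))


def gated_ir_signal(t1_ms, ti_ms, period_ms, m0=1.0, eta=1.0):
    """Longitudinal value at TI for an inversion repeated every ``period_ms``.

    Models the ECG-gated comparator's inversion-recovery snapshot: the
    pre-inversion magnetization saturates to the periodic fixed point
    m* = m0 (1 - E) / (1 + eta E), E = exp(-period/T1), and the sampled
    value is m0 - (m0 + eta m*) exp(-TI/T1).
    """
    t1 = np.asarray(t1_ms, dtype=float)
    E = np.exp(-period_ms / t1)
    m_pre = m0 * (1 - E) / (1 + eta * E)
    out = m0 - (m0 + eta * m_pre) * np.exp(-np.asarray(ti_ms, dtype=float) / t1)
    return out if np.ndim(out) else float(out)


def null_segment(t1_ms: float, params: SequenceParams, m0: float = 1.0) -> int:
    """Segment index whose inversion time best nulls a tissue with ``t1_ms``."""
    L, _ = ir_flash_train(t1_ms, params, m0=m0)
    return int(np.argmin(np.abs(L)))
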