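"""Steady-state signal models for SPGR and balanced SSFP.

Two model families live here:

* single-pool models (``spgr_signal``, ``bssfp_signal``) — the fitting model:
  one source of magnetization per voxel, characterized by T1, T2, M0 and an
  off-resonance Δf;
* two-pool magnetization-transfer models (``mt_spgr_signal``,
  ``mt_bssfp_signal``) — the generative model: a free water pool exchanging
  with a semisolid bound pool whose longitudinal magnetization is partially
  saturated by RF power at a rate W = π γ² B1rms² G(Δ), with G an absorption
  lineshape (super-Lorentzian in tissue).

Conventions (shared by simulation and fitting — do not change one side only):

* excitation rotates about the +x axis rotated by the cumulative RF phase;
  demodulation (receive phase) is locked to the transmit phase;
* off-resonance accumulates +2π·Δf·TR per TR, so in the demodulated frame the
  per-TR precession angle is θ = 2π·Δf·TR − Δφ with Δφ the RF phase increment;
* bSSFP is sampled at TE = TR/2 with e^{−TE/T2} decay and e^{+i2πΔf·TE} phase;
* SPGR TE decay is constant across all images and absorbed into the fitted M0.

All functions broadcast over numpy arrays in the tissue/field arguments.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.integrate import quad
from scipy.linalg import expm

from .pulse_design import GAMMA_UT, RFPulse, b1rms_over_tr, flip_angle_of

__all__ = [
    "SinglePoolTissue",
    "TwoPoolTissue",
    "SpgrAcq",
    "BssfpAcq",
    "spgr_signal",
    "bssfp_signal",
    "bloch_propagate_oracle",
    "spgr_rf_spoiled",
    "absorption_lineshape",
    "mt_saturation_rate",
    "pulse_mean_saturation_rate",
    "mt_spgr_signal",
    "mt_bssfp_signal",
]

# Super-Lorentzian lineshape: offsets below this cutoff are evaluated at the
# cutoff to sidestep the on-resonance pole (generative model only).
SL_CUTOFF_HZ = 1000.0


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SinglePoolTissue:
    """Single-pool voxel parameters (the fitting model).

    t1, t2 in ms; m0 in arbitrary units; delta_f in Hz. Fields may be numpy
    arrays of a common broadcast shape.
    """

    t1: object
    t2: object
    m0: object = 1.0
    delta_f: object = 0.0

    def __post_init__(self):
        if np.any(np.asarray(self.t1) <= 0) or np.any(np.asarray(self.t2) <= 0):
            raise ValueError("t1 and t2 must be positive")
        if np.any(np.asarray(self.t2) > np.asarray(self.t1)):
            raise ValueError("t2 must not exceed t1")
        if np.any(np.asarray(self.m0) < 0):
            raise ValueError("m0 must be non-negative")


@dataclass(frozen=True)
class TwoPoolTissue:
    """Binary spin-bath voxel parameters (the generative MT model).

    Free pool: t1_f/t2_f (ms), m0_f (arb). Bound pool: equilibrium fraction
    ``bound_fraction`` = M0b/M0f, transverse time t2_b (µs), longitudinal time
    t1_b (ms, conventionally fixed at 1000 ms). ``k_f`` is the free→bound
    exchange rate (s⁻¹); detailed balance fixes k_b = k_f / bound_fraction.
    A bound_fraction of exactly 0 disables the bound pool and exchange.
    """

    t1_f: float
    t2_f: float
    m0_f: float = 1.0
    bound_fraction: float = 0.0
    k_f: float = 0.0
    t2_b: float = 12.0
    t1_b: float = 1000.0
    delta_f: object = 0.0
    lineshape: str = "super-lorentzian"

    def __post_init__(self):
        if min(self.t1_f, self.t2_f, self.t2_b, self.t1_b) <= 0:
            raise ValueError("all relaxation times must be positive")
        if self.bound_fraction < 0 or self.k_f < 0:
            raise ValueError("bound_fraction and k_f must be non-negative")

    @property
    def k_b(self) -> float:
        """Bound→free rate from detailed balance (0 when no bound pool)."""
        if self.bound_fraction == 0:
            return 0.0
        return self.k_f / self.bound_fraction

    def free_pool(self) -> SinglePoolTissue:
        return SinglePoolTissue(t1=self.t1_f, t2=self.t2_f, m0=self.m0_f,
                                delta_f=self.delta_f)


@dataclass(frozen=True)
class SpgrAcq:
    """Spoiled gradient-echo acquisition: TR/TE (ms), nominal FA (deg),
    quadratic RF-spoiling increment seed (deg), and the excitation pulse."""

    tr: float = 7.0
    te: float = 3.5
    fa_nominal: float = 15.0
    rf_increment: float = 50.0
    pulse: RFPulse | None = None

    def __post_init__(self):
        if not (0 < self.te < self.tr):
            raise ValueError("require 0 < TE < TR")
        if self.fa_nominal <= 0:
            raise ValueError("fa_nominal must be positive")


@dataclass(frozen=True)
class BssfpAcq:
    """Balanced SSFP acquisition: TR/TE (ms), nominal FA (deg), constant
    per-TR RF phase increment (deg, 0 or 180 in the protocol), pulse."""

    tr: float = 7.0
    te: float = 3.5
    fa_nominal: float = 45.0
    phase_increment: float = 180.0
    pulse: RFPulse | None = None

    def __post_init__(self):
        if not (0 < self.te < self.tr):
            raise ValueError("require 0 < TE < TR")
        if not (0 <= self.phase_increment < 360):
            raise ValueError("phase_increment must lie in [0, 360)")
        if self.fa_nominal <= 0:
            raise ValueError("fa_nominal must be positive")


# ---------------------------------------------------------------------------
# single-pool closed forms
# ---------------------------------------------------------------------------

def spgr_signal(tissue: SinglePoolTissue, fa_eff: object, tr: float):
    """Ideally spoiled SPGR (Ernst) signal magnitude.

    ``fa_eff`` is the effective flip angle in radians (B1-scaled). TE decay is
    absorbed into m0. Broadcasts over arrays.
    """
    if tr <= 0:
        raise ValueError("tr must be positive")
    t1 = np.asarray(tissue.t1, dtype=float)
    if np.any(t1 <= 0):
        raise ValueError("t1 must be positive")
    fa = np.asarray(fa_eff, dtype=float)
    e1 = np.exp(-tr / t1)
    out = np.asarray(tissue.m0) * np.sin(fa) * (1 - e1) / (1 - e1 * np.cos(fa))
    return out if out.ndim else float(out)


def bssfp_signal(tissue: SinglePoolTissue, acq: BssfpAcq, b1_scale: object = 1.0):
    """Complex bSSFP steady state at TE = TR/2, demodulated by the RF phase.

    Exact periodic steady state of the per-TR affine recursion, obtained by a
    3×3 linear solve (Cramer's rule, vectorized). The magnitude is periodic
    in delta_f with period 1/TR (the TE phase factor is antiperiodic); with a
    180° increment the on-resonance voxel sits mid-passband and the banding
    minima fall at Δf = ±1/(2·TR).
    """
    if np.any(np.asarray(b1_scale) <= 0):
        raise ValueError("b1_scale must be positive")
    tr_s = acq.tr * 1e-3
    te_s = acq.te * 1e-3
    t1 = np.asarray(tissue.t1, float) * 1e-3
    t2 = np.asarray(tissue.t2, float) * 1e-3
    m0 = np.asarray(tissue.m0, float)
    df = np.asarray(tissue.delta_f, float)
    alpha = np.asarray(b1_scale, float) * math.radians(acq.fa_nominal)

    e1 = np.exp(-tr_s / t1)
    e2 = np.exp(-tr_s / t2)
    theta = 2 * np.pi * df * tr_s - math.radians(acq.phase_increment)
    ca, sa = np.cos(alpha), np.sin(alpha)
    ct, st = np.cos(theta), np.sin(theta)

    # M = I - Rz(theta) @ E @ Rx(alpha); b = (0, 0, m0 (1-E1))
    m11 = 1 - ct * e2
    m12 = st * e2 * ca
    m13 = st * e2 * sa
    m21 = -st * e2
    m22 = 1 - ct * e2 * ca
    m23 = -ct * e2 * sa
    m31 = np.zeros_like(m11)
    m32 = e1 * sa
    m33 = 1 - e1 * ca
    det = (m11 * (m22 * m33 - m23 * m32)
           - m12 * (m21 * m33 - m23 * m31)
           + m13 * (m21 * m32 - m22 * m31))
    b3 = m0 * (1 - e1)
    # Cramer's rule, exploiting b = (0, 0, b3).
    mx = b3 * (m12 * m23 - m13 * m22) / det
    my = b3 * (m13 * m21 - m11 * m23) / det
    mz = b3 * (m11 * m22 - m12 * m21) / det
    # apply the pulse, then evolve to TE
    mx_a = mx
    my_a = ca * my + sa * mz
    sig = (mx_a + 1j * my_a) * np.exp(-te_s / t2) * np.exp(1j * 2 * np.pi * df * te_s)
    return sig if np.ndim(sig) else complex(sig)


def bloch_propagate_oracle(tissue: SinglePoolTissue, acq, n_reps: int = 10_000):
    """Iterative Bloch propagation from equilibrium; test-suite reference.

    For a :class:`BssfpAcq`, iterates the per-TR recursion (pulse about the
    phase-cycled axis, relaxation, precession) in the demodulated frame and
    returns the complex signal at TE of the final TR. For a :class:`SpgrAcq`,
    iterates the ideally spoiled longitudinal recursion and returns the real
    Ernst-limit signal (TE absorbed into m0, matching ``spgr_signal``).
    Warns if the last two TRs differ by more than 1e−10 relative.
    """
    tr_s = acq.tr * 1e-3
    t1 = float(tissue.t1) * 1e-3
    t2 = float(tissue.t2) * 1e-3
    m0 = float(tissue.m0)
    alpha = math.radians(acq.fa_nominal)
    e1 = math.exp(-tr_s / t1)

    if isinstance(acq, SpgrAcq):
        mz = m0
        prev = None
        for _ in range(n_reps):
            sig = mz * math.sin(alpha)
            mz = mz * math.cos(alpha) * e1 + m0 * (1 - e1)
            prev = sig
        last = mz * math.sin(alpha)
        if prev is not None and abs(last - prev) > 1e-10 * max(abs(last), 1e-30):
            warnings.warn("Bloch propagation not converged", stacklevel=2)
        return prev

    e2 = math.exp(-tr_s / t2)
    te_s = acq.te * 1e-3
    df = float(tissue.delta_f)
    theta = 2 * math.pi * df * tr_s - math.radians(acq.phase_increment)
    ca, sa = math.cos(alpha), math.sin(alpha)
    ct, st = math.cos(theta), math.sin(theta)
    m = np.array([0.0, 0.0, m0])
    rx = np.array([[1, 0, 0], [0, ca, sa], [0, -sa, ca]])
    rz_e = np.array([[ct * e2, -st * e2, 0], [st * e2, ct * e2, 0], [0, 0, e1]])
    rec = np.array([0.0, 0.0, m0 * (1 - e1)])
    step = rz_e @ rx

    def _signal(m_pre):
        ma = rx @ m_pre
        return ((ma[0] + 1j * ma[1]) * math.exp(-te_s / t2)
                * np.exp(1j * 2 * math.pi * df * te_s))

    prev_sig = None
    for _ in range(n_reps):
        prev_sig = _signal(m)
        m = step @ m + rec
    last_sig = _signal(m)
    if abs(last_sig - prev_sig) > 1e-10 * max(abs(last_sig), 1e-30):
        warnings.warn("Bloch propagation not converged", stacklevel=2)
    return prev_sig


# ---------------------------------------------------------------------------
# isochromat RF-spoiling simulation
# ---------------------------------------------------------------------------

def spgr_rf_spoiled(tissue: SinglePoolTissue, acq: SpgrAcq, b1_scale: object = 1.0,
                    n_isochromats: int = 256, n_reps: int = 800,
                    average_last_trs: int = 1):
    """SPGR signal with quadratic RF spoiling, by isochromat ensemble simulation.

    An ensemble of isochromats uniformly dephased over 0–2π per TR (ideal
    gradient spoiling moment) is driven with RF phases φ_n = φ0·n(n+1)/2,
    φ0 = ``acq.rf_increment``; the receiver is phase-locked to the transmit.
    Returns the magnitude of the demodulated complex ensemble mean just after
    the final pulse (TE decay absorbed into m0, like ``spgr_signal``).
    Broadcasts over an array of ``b1_scale`` values (one ensemble per value).

    For compartments with T2 comparable to T1 (e.g. CSF) the ensemble signal
    stays quasi-periodic under the quadratic schedule and never settles to a
    fixed point; ``average_last_trs`` > 1 returns the mean magnitude over the
    last so-many TRs as a stable representative level.
    """
    if n_isochromats < 64:
        raise ValueError("need at least 64 isochromats")
    b1 = np.atleast_1d(np.asarray(b1_scale, float))
    nf = b1.size
    tr_s = acq.tr * 1e-3
    t1 = float(tissue.t1) * 1e-3
    t2 = float(tissue.t2) * 1e-3
    m0 = float(tissue.m0)
    e1, e2 = math.exp(-tr_s / t1), math.exp(-tr_s / t2)
    alpha = b1 * math.radians(acq.fa_nominal)          # (nf,)
    phi0 = math.radians(acq.rf_increment)

    psi = 2 * np.pi * (np.arange(n_isochromats) + 0.5) / n_isochromats
    cpsi, spsi = np.cos(psi), np.sin(psi)              # (niso,)

    # state per (fa, isochromat)
    mx = np.zeros((nf, n_isochromats))
    my = np.zeros((nf, n_isochromats))
    mz = np.full((nf, n_isochromats), m0)
    ca = np.cos(alpha)[:, None]
    sa = np.sin(alpha)[:, None]

    sig_hist = np.zeros((n_reps, nf), dtype=complex)
    for n in range(n_reps):
        phi = phi0 * n * (n + 1) / 2.0
        cp, sp = math.cos(phi), math.sin(phi)
        # rotate into pulse frame (Rz(-phi)), tip about x, rotate back
        x1 = cp * mx + sp * my
        y1 = -sp * mx + cp * my
        y2 = ca * y1 + sa * mz
        z2 = -sa * y1 + ca * mz
        mx = cp * x1 - sp * y2
        my = sp * x1 + cp * y2
        mz = z2
        # receiver demodulated by the transmit phase
        s = (mx + 1j * my) * complex(cp, -sp)
        sig_hist[n] = s.mean(axis=1)
        # relaxation then per-TR gradient dephasing
        mx *= e2
        my *= e2
        mz = mz * e1 + m0 * (1 - e1)
        x3 = cpsi * mx - spsi * my
        my = spsi * mx + cpsi * my
        mx = x3

    k = max(1, min(average_last_trs, n_reps))
    mag = np.abs(sig_hist[-k:]).mean(axis=0)
    if n_reps >= 100:
        # window-averaged drift: the RF-phase schedule leaves a small residual
        # TR-to-TR cycle, so compare 50-TR windows rather than single TRs
        a = np.abs(sig_hist[-50:]).mean(axis=0)
        b = np.abs(sig_hist[-100:-50]).mean(axis=0)
        if np.any(np.abs(a - b) > 1e-5 * np.maximum(a, 1e-30)):
            warnings.warn("RF-spoiled simulation not fully converged", stacklevel=2)
    return mag if np.ndim(b1_scale) else float(mag[0])


# ---------------------------------------------------------------------------
# bound-pool saturation
# ---------------------------------------------------------------------------

def absorption_lineshape(delta_hz: object, t2b_us: float,
                         lineshape: str = "super-lorentzian"):
    """Bound-pool absorption lineshape G(Δ, T2b) in seconds.

    ``super-lorentzian`` integrates over fiber orientation with the
    on-resonance pole handled by evaluating |Δ| < 1 kHz at 1 kHz.
    """
    t2b = t2b_us * 1e-6
    d = np.atleast_1d(np.asarray(delta_hz, float))
    if lineshape == "lorentzian":
        g = (t2b / math.pi) / (1.0 + (2 * math.pi * d * t2b) ** 2)
    elif lineshape == "gaussian":
        g = t2b / math.sqrt(2 * math.pi) * np.exp(-0.5 * (2 * math.pi * d * t2b) ** 2)
    elif lineshape == "super-lorentzian":
        dd = np.maximum(np.abs(d), SL_CUTOFF_HZ)
        g = np.empty_like(dd)
        for i, delta in enumerate(dd.ravel()):
            w = 2 * math.pi * delta * t2b

            def integrand(u, w=w):
                den = abs(3 * u * u - 1)
                den = max(den, 1e-12)
                return math.sqrt(2 / math.pi) * (t2b / den) * math.exp(-2 * (w / den) ** 2)

            val, _ = quad(integrand, 0.0, 1.0, points=[1 / math.sqrt(3)], limit=200)
            g.ravel()[i] = val
    else:
        raise ValueError(f"unknown lineshape {lineshape!r}")
    return g if np.ndim(delta_hz) else float(g[0])


def mt_saturation_rate(b1rms_ut: float, delta_hz: float, t2b_us: float,
                       lineshape: str = "super-lorentzian") -> float:
    """Bound-pool saturation rate W = π γ² B1rms² G(Δ, T2b), in s⁻¹."""
    if b1rms_ut < 0:
        raise ValueError("b1rms must be non-negative")
    g = absorption_lineshape(delta_hz, t2b_us, lineshape)
    return math.pi * (GAMMA_UT * b1rms_ut) ** 2 * g


def pulse_mean_saturation_rate(pulse: RFPulse, tr_ms: float, t2b_us: float,
                               lineshape: str = "super-lorentzian") -> float:
    """TR-averaged saturation rate ⟨W⟩ summed over the pulse's bands (s⁻¹).

    Each band contributes π γ² ⟨B1²⟩_TR G(Δ_band); the on-resonance band is
    evaluated at the lineshape cutoff offset (instantaneous-saturation
    approximation with a fixed-RMS-B1 design target in mind).
    """
    tr_s = tr_ms * 1e-3
    w = 0.0
    for sq, off in zip(pulse.band_sq_integrals(), pulse.band_offsets):
        b1rms_sq = sq / tr_s
        g = absorption_lineshape(off, t2b_us, lineshape)
        w += math.pi * GAMMA_UT**2 * b1rms_sq * g
    return w


# ---------------------------------------------------------------------------
# two-pool steady states
# ---------------------------------------------------------------------------

def _longitudinal_propagator(tissue: TwoPoolTissue, tr_s: float):
    """(expm(Λ·TR), Λ⁻¹(expm(Λ·TR)−I)·c) for the coupled longitudinal system.

    Λ couples (Mzf, Mzb) by relaxation and exchange; c is the recovery drive.
    Exchange is disabled when bound_fraction == 0.
    """
    r1f = 1.0 / (tissue.t1_f * 1e-3)
    r1b = 1.0 / (tissue.t1_b * 1e-3)
    f = tissue.bound_fraction
    kf = tissue.k_f if f > 0 else 0.0
    kb = tissue.k_b
    m0f = tissue.m0_f
    m0b = f * m0f
    lam = np.array([[-(r1f + kf), kb], [kf, -(r1b + kb)]])
    c = np.array([r1f * m0f, r1b * m0b])
    el = expm(lam * tr_s)
    affine = np.linalg.solve(lam, (el - np.eye(2)) @ c)
    return el, affine


def _mean_w(acq, tissue: TwoPoolTissue, b1_scale):
    """Per-voxel ⟨W⟩ in s⁻¹; local transmit scales B1, so W scales as b1²."""
    if acq.pulse is None:
        raise ValueError("acquisition carries no pulse; cannot compute saturation")
    w_nom = pulse_mean_saturation_rate(acq.pulse, acq.tr, tissue.t2_b,
                                       tissue.lineshape)
    return w_nom * np.asarray(b1_scale, float) ** 2


def mt_spgr_signal(tissue: TwoPoolTissue, acq: SpgrAcq, b1_scale: object = 1.0):
    """Two-pool SPGR steady-state magnitude under ideal spoiling.

    Per TR: instantaneous free-pool rotation by the effective flip angle and
    bound-pool saturation by exp(−⟨W⟩·TR); inter-pulse evolution of the
    coupled longitudinal system by its matrix exponential. The pre-pulse fixed
    point is found by a 2×2 linear solve. Reduces exactly to ``spgr_signal``
    at bound_fraction = 0. Broadcasts over ``b1_scale`` arrays.
    """
    tr_s = acq.tr * 1e-3
    b1 = np.asarray(b1_scale, float)
    alpha = b1 * math.radians(acq.fa_nominal)
    el, affine = _longitudinal_propagator(tissue, tr_s)
    sat = np.exp(-_mean_w(acq, tissue, b1) * tr_s)
    ca = np.cos(alpha)
    # A = EL @ diag(cos a, sat); solve (I - A) m = affine, 2x2 Cramer
    a11 = el[0, 0] * ca
    a12 = el[0, 1] * sat
    a21 = el[1, 0] * ca
    a22 = el[1, 1] * sat
    m11, m12, m21, m22 = 1 - a11, -a12, -a21, 1 - a22
    det = m11 * m22 - m12 * m21
    if np.any(np.abs(det) < 1e-300):
        raise ValueError("singular steady-state system (non-physical parameters)")
    mzf = (affine[0] * m22 - m12 * affine[1]) / det
    sig = np.abs(np.sin(alpha) * mzf)
    return sig if np.ndim(sig) else float(sig)


def mt_bssfp_signal(tissue: TwoPoolTissue, acq: BssfpAcq, b1_scale: object = 1.0):
    """Two-pool bSSFP complex steady state at TE = TR/2.

    State (Mxf, Myf, Mzf, Mzb) with constant drive: the free pool keeps its
    transverse components (decay E2f, precession θ = 2πΔf·TR − Δφ); the bound
    pool is longitudinal only. Fixed point by a batched 4×4 linear solve.
    Reduces to ``bssfp_signal`` at bound_fraction = 0.
    """
    tr_s = acq.tr * 1e-3
    te_s = acq.te * 1e-3
    b1 = np.asarray(b1_scale, float)
    df = np.asarray(tissue.delta_f, float)
    b1, df = np.broadcast_arrays(b1, df)
    shape = b1.shape
    b1f, dff = b1.ravel(), df.ravel()
    n = b1f.size

    alpha = b1f * math.radians(acq.fa_nominal)
    theta = 2 * np.pi * dff * tr_s - math.radians(acq.phase_increment)
    e2 = math.exp(-tr_s / (tissue.t2_f * 1e-3))
    el, affine = _longitudinal_propagator(tissue, tr_s)
    sat = np.exp(-_mean_w(acq, tissue, b1f) * tr_s)
    ca, sa = np.cos(alpha), np.sin(alpha)
    ct, st = np.cos(theta), np.sin(theta)

    # pulse operator P
    p = np.zeros((n, 4, 4))
    p[:, 0, 0] = 1.0
    p[:, 1, 1] = ca
    p[:, 1, 2] = sa
    p[:, 2, 1] = -sa
    p[:, 2, 2] = ca
    p[:, 3, 3] = sat
    # free evolution operator T and drive d
    t_op = np.zeros((n, 4, 4))
    t_op[:, 0, 0] = ct * e2
    t_op[:, 0, 1] = -st * e2
    t_op[:, 1, 0] = st * e2
    t_op[:, 1, 1] = ct * e2
    t_op[:, 2, 2] = el[0, 0]
    t_op[:, 2, 3] = el[0, 1]
    t_op[:, 3, 2] = el[1, 0]
    t_op[:, 3, 3] = el[1, 1]
    d = np.zeros((n, 4))
    d[:, 2] = affine[0]
    d[:, 3] = affine[1]

    a = t_op @ p
    m = np.linalg.solve(np.eye(4)[None] - a, d[..., None])[..., 0]
    # after the pulse, evolve transverse to TE
    mxa = m[:, 0]
    mya = ca * m[:, 1] + sa * m[:, 2]
    sig = ((mxa + 1j * mya) * math.exp(-te_s / (tissue.t2_f * 1e-3))
           * np.exp(1j * 2 * np.pi * dff * te_s))
    sig = sig.reshape(shape)
    return sig if shape else complex(sig)
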