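"""Joint system relaxometry: simultaneous single-pool fitting of T1, T2, M0
and off-resonance from SPGR and bSSFP magnitude volumes.

All volumes of a flip-angle subset enter one nonlinear least-squares problem
per voxel; evaluating both signal models simultaneously couples the SPGR
(T1-weighted) and bSSFP (T1/T2- and Δf-weighted) information through a shared
M0. Magnitudes are fitted — cross-vendor phase conventions are unknowable —
so Δf is identified through the two phase cycles of the 45° bSSFP and only up
to sign; estimates report the principal value in [−1/(2TR), +1/(2TR)).

Two fitting routes are provided: :func:`jsr_fit_voxel` wraps
``scipy.optimize.least_squares`` (reference, one voxel at a time), and
:func:`jsr_fit_volume` runs a vectorized bounded Levenberg–Marquardt over all
masked voxels at once (same model, same multistart policy). The fitting model
deliberately assumes ideal SPGR spoiling even when data were simulated with
imperfect RF spoiling — that mismatch is part of what the study examines.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .phantom import AcquisitionSet
from .signal_models import BssfpAcq, SinglePoolTissue, bssfp_signal, spgr_signal

__all__ = ["FitConfig", "JsrEstimate", "despot1_init", "jsr_residual",
           "jsr_fit_voxel", "jsr_fit_volume", "select_volumes"]


@dataclass(frozen=True)
class FitConfig:
    """Bounds, tolerances and multistart policy for the JSR fit."""

    t1_bounds: tuple = (100.0, 6000.0)   # ms
    t2_bounds: tuple = (5.0, 3000.0)     # ms
    m0_min: float = 1e-12
    tolerance: float = 1e-10             # cost-gradient stop
    max_iterations: int = 60
    n_multistart_delta_f: int = 4
    t2_init: float = 80.0                # ms
    seed: int = 0

    def __post_init__(self):
        if self.t1_bounds[0] >= self.t1_bounds[1] or self.t2_bounds[0] >= self.t2_bounds[1]:
            raise ValueError("bounds must be ordered")
        if self.n_multistart_delta_f < 1:
            raise ValueError("need at least one multistart point")


@dataclass
class JsrEstimate:
    """Per-voxel fit result. ``t2_gt_t1`` flags the soft t2 ≤ t1 check."""

    t1: float
    t2: float
    m0: float
    delta_f: float
    residual_norm: float
    converged: bool
    n_restarts_used: int
    t2_gt_t1: bool = False


# ---------------------------------------------------------------------------
# volume selection and metadata handling
# ---------------------------------------------------------------------------

def select_volumes(acq: AcquisitionSet, subset=None) -> list:
    """Indices of ``acq.volumes`` belonging to ``subset`` (None = all).

    ``subset`` needs attributes ``spgr_fas``, ``bssfp_fas_180`` and
    ``include_bssfp_0``. Raises if the selection is not identifiable
    (needs ≥1 SPGR and ≥2 bSSFP volumes, at least one at 180°).
    """
    idx = []
    for i, v in enumerate(acq.volumes):
        m = v.meta
        if subset is None:
            idx.append(i)
            continue
        if m["sequence"] == "spgr" and m["fa"] in subset.spgr_fas:
            idx.append(i)
        elif m["sequence"] == "bssfp" and m["phase_increment"] == 180.0 \
                and m["fa"] in subset.bssfp_fas_180:
            idx.append(i)
        elif m["sequence"] == "bssfp" and m["phase_increment"] == 0.0 \
                and subset is not None and subset.include_bssfp_0:
            idx.append(i)
    metas = [acq.volumes[i].meta for i in idx]
    n_spgr = sum(m["sequence"] == "spgr" for m in metas)
    n_b = sum(m["sequence"] == "bssfp" for m in metas)
    n_b180 = sum(m["sequence"] == "bssfp" and m["phase_increment"] == 180.0
                 for m in metas)
    if n_spgr < 1 or n_b < 2 or n_b180 < 1:
        raise ValueError(
            "subset not identifiable: need >=1 SPGR and >=2 bSSFP volumes "
            f"(one at 180 deg); got {n_spgr} SPGR, {n_b} bSSFP ({n_b180} at 180)")
    return idx


def _check_meta(meta: list) -> None:
    for m in meta:
        if m["sequence"] not in ("spgr", "bssfp"):
            raise ValueError(f"unknown sequence type {m['sequence']!r}")


# ---------------------------------------------------------------------------
# initialization and residual
# ---------------------------------------------------------------------------

def despot1_init(spgr_signals, fas_nominal, b1_scale, tr: float):
    """Linearized SPGR T1/M0 estimate: regress S/sin(α) on S/tan(α).

    The slope is E1 = exp(−TR/T1) and the intercept M0·(1−E1). Works on
    (..., K) signal stacks with K flip angles; broadcasts over leading axes.
    Raises on a degenerate design (fewer than 2 distinct effective FAs).
    """
    s = np.asarray(spgr_signals, float)
    fas = np.radians(np.asarray(fas_nominal, float))
    if fas.size < 2 or np.unique(fas).size < 2:
        raise ValueError("need at least 2 distinct flip angles")
    alpha = np.asarray(b1_scale, float)[..., None] * fas
    x = s / np.tan(alpha)
    y = s / np.sin(alpha)
    xm = x.mean(axis=-1, keepdims=True)
    ym = y.mean(axis=-1, keepdims=True)
    denom = ((x - xm) ** 2).sum(axis=-1)
    if np.any(denom == 0):
        raise ValueError("degenerate flip-angle design (zero variance)")
    slope = ((x - xm) * (y - ym)).sum(axis=-1) / denom
    slope = np.clip(slope, 1e-8, 1.0 - 1e-9)
    t1 = -tr / np.log(slope)
    m0 = (ym[..., 0] - slope * xm[..., 0]) / (1.0 - slope)
    return t1, m0


def _model(params, meta, b1, tr):
    """Predicted magnitudes, shape (..., M). params = (m0, t1, t2, delta_f)
    arrays of a common shape; b1 broadcasts against them."""
    m0, t1, t2, df = params
    out = []
    for m in meta:
        if m["sequence"] == "spgr":
            fa_eff = np.asarray(b1, float) * math.radians(m["fa"])
            e1 = np.exp(-tr / np.asarray(t1, float))
            s = m0 * np.sin(fa_eff) * (1 - e1) / (1 - e1 * np.cos(fa_eff))
        else:
            tis = SinglePoolTissue.__new__(SinglePoolTissue)
            object.__setattr__(tis, "t1", t1)
            object.__setattr__(tis, "t2", t2)
            object.__setattr__(tis, "m0", m0)
            object.__setattr__(tis, "delta_f", df)
            acq = BssfpAcq(tr=tr, te=m.get("te", tr / 2), fa_nominal=m["fa"],
                           phase_increment=m["phase_increment"])
            s = np.abs(bssfp_signal(tis, acq, b1))
        out.append(np.asarray(s, float))
    return np.stack(np.broadcast_arrays(*out), axis=-1) if len(out) > 1 \
        else np.asarray(out[0], float)[..., None]


def jsr_residual(params, measurements, meta, b1_scale, tr: float = 7.0):
    """(model − data) over all volumes of the subset; one shared M0.

    ``params`` = (m0, t1 ms, t2 ms, delta_f Hz); SPGR entries are independent
    of delta_f; bSSFP entries depend on it with period 1/TR.
    """
    _check_meta(meta)
    pred = _model(tuple(np.asarray(p, float) for p in params), meta, b1_scale, tr)
    return pred - np.asarray(measurements, float)


# ---------------------------------------------------------------------------
# per-voxel reference fit (scipy)
# ---------------------------------------------------------------------------

def _delta_f_starts(tr: float, n: int) -> np.ndarray:
    period = 1000.0 / tr  # Hz (tr in ms)
    return (np.arange(n) + 0.5) / n * period - period / 2.0


def jsr_fit_voxel(measurements, meta, b1_scale: float,
                  config: FitConfig | None = None, tr: float = 7.0) -> JsrEstimate:
    """Bounded nonlinear least squares on (m0, t1, t2, Δf) for one voxel.

    T1/M0 start from the DESPOT1 linearization, T2 from ``config.t2_init``,
    Δf is multistarted on an even grid over its period; the best final cost
    wins, ties broken by the smallest |Δf|.
    """
    config = config or FitConfig()
    _check_meta(meta)
    y = np.asarray(measurements, float)
    if len(meta) < 4:
        raise ValueError("need at least 4 volumes spanning both sequence families")
    spgr_i = [i for i, m in enumerate(meta) if m["sequence"] == "spgr"]
    bssfp_i = [i for i, m in enumerate(meta) if m["sequence"] == "bssfp"]
    if not spgr_i or not bssfp_i:
        raise ValueError("need both SPGR and bSSFP volumes (T2 not identifiable)")
    t1_0, m0_0 = despot1_init(y[spgr_i], [meta[i]["fa"] for i in spgr_i],
                              b1_scale, tr)
    t1_0 = float(np.clip(t1_0, *config.t1_bounds))
    m0_0 = float(max(m0_0, config.m0_min * 10))
    df_half = 1000.0 / (2 * tr)
    lb = [config.m0_min, config.t1_bounds[0], config.t2_bounds[0], -df_half]
    ub = [np.inf, config.t1_bounds[1], config.t2_bounds[1], df_half]

    def fun(p):
        return jsr_residual(p, y, meta, b1_scale, tr)

    best = None
    n_used = 0
    for df0 in _delta_f_starts(tr, config.n_multistart_delta_f):
        x0 = [m0_0, t1_0, config.t2_init, float(df0)]
        res = least_squares(fun, x0, bounds=(lb, ub), method="trf",
                            gtol=config.tolerance, xtol=1e-12, ftol=1e-12,
                            max_nfev=200 * config.max_iterations)
        n_used += 1
        cost, df_hat = res.cost, abs(res.x[3])
        if best is None or cost < best[0] - 1e-14 * (1 + best[0]) or (
                abs(cost - best[0]) <= 1e-12 * (1 + best[0]) and df_hat < abs(best[1][3])):
            best = (cost, res.x, res.success)
    cost, x, ok = best
    return JsrEstimate(t1=float(x[1]), t2=float(x[2]), m0=float(x[0]),
                       delta_f=float(x[3]),
                       residual_norm=float(math.sqrt(2 * cost)),
                       converged=bool(ok), n_restarts_used=n_used,
                       t2_gt_t1=bool(x[2] > x[1]))


# ---------------------------------------------------------------------------
# batched volume fit
# ---------------------------------------------------------------------------

def _batched_lm(y, meta, b1, tr, p0, lb, ub, max_iter, gtol):
    """Vectorized projected Levenberg–Marquardt over N voxels.

    y: (N, M) data; p0: (N, 4) starts; bounds enforced by clipping trial
    steps. Returns (params, cost, grad_inf_norm)."""
    n = y.shape[0]
    p = np.clip(p0, lb, ub)
    scale = np.maximum(np.abs(p), np.array([1e-3, 100.0, 10.0, 5.0]))
    lam = np.full(n, 1e-3)

    def resid(pp):
        return _model((pp[:, 0], pp[:, 1], pp[:, 2], pp[:, 3]), meta, b1, tr) - y

    r = resid(p)
    cost = 0.5 * np.sum(r * r, axis=1)
    eye = np.eye(4)
    g_norm = np.full(n, np.inf)
    for _ in range(max_iter):
        jac = np.empty((n, y.shape[1], 4))
        h = 1e-6 * scale
        for k in range(4):
            pk = p.copy()
            pk[:, k] = np.clip(pk[:, k] + h[:, k], lb[k], ub[k])
            hk = pk[:, k] - p[:, k]
            hk[hk == 0] = 1e-12
            jac[:, :, k] = (resid(pk) - r) / hk[:, None]
        g = np.einsum("nm,nmk->nk", r, jac)
        g_norm = np.abs(g).max(axis=1)
        hss = np.einsum("nmk,nml->nkl", jac, jac)
        diag = np.einsum("nkk->nk", hss)
        a = hss + lam[:, None, None] * (diag[:, :, None] * eye[None]
                                        + 1e-12 * eye[None])
        try:
            step = np.linalg.solve(a, -g[..., None])[..., 0]
        except np.linalg.LinAlgError:
            a = a + 1e-8 * eye[None]
            step = np.linalg.solve(a, -g[..., None])[..., 0]
        p_try = np.clip(p + step, lb, ub)
        r_try = resid(p_try)
        cost_try = 0.5 * np.sum(r_try * r_try, axis=1)
        better = cost_try < cost
        p[better] = p_try[better]
        r[better] = r_try[better]
        cost[better] = cost_try[better]
        lam = np.where(better, lam * 0.3, lam * 4.0)
        lam = np.clip(lam, 1e-12, 1e14)
        if np.all(g_norm <= gtol * (1 + cost)):
            break
    return p, cost, g_norm


def jsr_fit_volume(acq: AcquisitionSet, subset=None, b1_map=None, mask=None,
                   config: FitConfig | None = None) -> dict:
    """Voxel-wise JSR over a mask; returns parameter maps.

    Output dict holds float maps ``t1``, ``t2``, ``m0``, ``delta_f``,
    ``residual`` (NaN outside the mask) and a boolean ``converged`` map.
    Deterministic: the multistart order is fixed and no randomness is used.
    """
    config = config or FitConfig()
    idx = select_volumes(acq, subset)
    meta = [acq.volumes[i].meta for i in idx]
    tr = meta[0]["tr"]
    if b1_map is None:
        b1_map = acq.fields.b1_scale
    if mask is None:
        mask = acq.truth.head_mask()
    mask = np.asarray(mask, bool)
    vox = np.flatnonzero(mask.ravel())
    y = np.stack([acq.volumes[i].data.ravel()[vox] for i in idx], axis=1)
    b1 = np.asarray(b1_map, float).ravel()[vox]
    n = vox.size

    spgr_i = [j for j, m in enumerate(meta) if m["sequence"] == "spgr"]
    if len(spgr_i) >= 2:
        t1_0, m0_0 = despot1_init(y[:, spgr_i],
                                  [meta[j]["fa"] for j in spgr_i], b1, tr)
    else:
        # single-SPGR subsets: neutral start, the LM does the work
        t1_0 = np.full(n, 1000.0)
        m0_0 = y[:, spgr_i[0]] / np.maximum(
            spgr_signal(SinglePoolTissue(t1=1000.0, t2=80.0, m0=1.0),
                        b1 * math.radians(meta[spgr_i[0]]["fa"]), tr), 1e-12)
    t1_0 = np.clip(t1_0, *config.t1_bounds)
    m0_0 = np.maximum(m0_0, config.m0_min * 10)
    df_half = 1000.0 / (2 * tr)
    lb = np.array([config.m0_min, config.t1_bounds[0], config.t2_bounds[0], -df_half])
    ub = np.array([np.inf, config.t1_bounds[1], config.t2_bounds[1], df_half])

    best_p = None
    best_cost = None
    for df0 in _delta_f_starts(tr, config.n_multistart_delta_f):
        p0 = np.column_stack([m0_0, t1_0, np.full(n, config.t2_init),
                              np.full(n, df0)])
        p, cost, g_norm = _batched_lm(y, meta, b1, tr, p0, lb, ub,
                                      config.max_iterations, config.tolerance)
        if best_p is None:
            best_p, best_cost, best_g = p, cost, g_norm
        else:
            tol = 1e-12 * (1 + best_cost)
            take = (cost < best_cost - tol) | (
                (np.abs(cost - best_cost) <= tol)
                & (np.abs(p[:, 3]) < np.abs(best_p[:, 3])))
            best_p[take] = p[take]
            best_cost[take] = cost[take]
            best_g[take] = g_norm[take]

    shape = acq.volumes[0].data.shape
    maps = {}
    for name, col in (("m0", 0), ("t1", 1), ("t2", 2), ("delta_f", 3)):
        m = np.full(np.prod(shape), np.nan)
        m[vox] = best_p[:, col]
        maps[name] = m.reshape(shape)
    res_map = np.full(np.prod(shape), np.nan)
    res_map[vox] = np.sqrt(2 * best_cost)
    maps["residual"] = res_map.reshape(shape)
    conv = np.zeros(np.prod(shape), bool)
    conv[vox] = best_g <= 1e-4 * (1 + best_cost)
    maps["converged"] = conv.reshape(shape)
    maps["mask"] = mask
    maps["subset"] = getattr(subset, "name", "all")
    return maps
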