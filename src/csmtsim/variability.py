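"""Reproducibility statistics: WM-mask erosion, distribution medians,
pairwise variability, deviations from the grand mean, worst-case variability,
and voxelwise test/retest distributions, plus the end-to-end study runner.

Metric definitions (m_i, m_j are WM-distribution medians):

* variability_{i,j} = 100·(m_i − m_j) / (0.5·(m_i + m_j))   [%, signed]
* deviation_i       = 100·(m_i − m̄) / m̄,  m̄ the mean of all measures [%]
* worst-case variability = max over pairs of |variability_{i,j}|
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import binary_erosion

from . import jsr as _jsr
from .phantom import (LABEL_WM, ProtocolSpec, default_vendors,
                      make_digital_phantom, make_field_maps, noise_sd_for_snr,
                      simulate_acquisition)
from .pulse_design import CsmtDesign

__all__ = ["SubsetSpec", "default_subsets", "VariabilityReport", "erode_mask",
           "roi_median", "variability", "deviation", "worst_case_variability",
           "voxelwise_variability", "build_report", "run_study",
           "CONDITIONS"]

#: Acquisition conditions: (CSMT pulses?, RF-spoiling mode).
CONDITIONS = {
    "native": dict(csmt=False, rf_spoiling_mode="native"),
    "harmonized_spoiling": dict(csmt=False, rf_spoiling_mode="harmonized"),
    "csmt": dict(csmt=True, rf_spoiling_mode="harmonized"),
}


@dataclass(frozen=True)
class SubsetSpec:
    """A flip-angle subset drawn from the all-measures superset.

    Must keep the fit identifiable: at least one SPGR and two bSSFP volumes,
    one of them at the 180° phase increment.
    """

    name: str
    spgr_fas: tuple = (3.0, 7.0, 11.0, 15.0)
    bssfp_fas_180: tuple = (5.0, 25.0, 45.0)
    include_bssfp_0: bool = True

    def __post_init__(self):
        n_b = len(self.bssfp_fas_180) + int(self.include_bssfp_0)
        if len(self.spgr_fas) < 1 or n_b < 2 or len(self.bssfp_fas_180) < 1:
            raise ValueError("subset violates the identifiability rule")


def default_subsets() -> tuple:
    """The six configured estimation protocols (S1 = all measures)."""
    return (
        SubsetSpec("S1", (3.0, 7.0, 11.0, 15.0), (5.0, 25.0, 45.0), True),
        SubsetSpec("S2", (3.0, 15.0), (5.0, 45.0), True),
        SubsetSpec("S3", (7.0, 11.0), (25.0, 45.0), True),
        SubsetSpec("S4", (3.0, 7.0, 11.0, 15.0), (5.0, 45.0), True),
        SubsetSpec("S5", (3.0, 11.0), (5.0, 25.0), True),
        SubsetSpec("S6", (7.0, 15.0), (25.0, 45.0), True),
    )


# ---------------------------------------------------------------------------
# elementary metrics
# ---------------------------------------------------------------------------

def erode_mask(mask: np.ndarray, radius_mm: float, voxel_mm: float = 1.0) -> np.ndarray:
    """Morphological erosion by a discrete sphere of physical radius.

    Mitigates partial-volume contributions at tissue boundaries. Raises if
    the result is empty."""
    if radius_mm < 0:
        raise ValueError("radius must be non-negative")
    mask = np.asarray(mask, bool)
    r_vox = radius_mm / voxel_mm
    if r_vox == 0:
        return mask.copy()
    n = int(np.floor(r_vox))
    ax = np.arange(-n, n + 1)
    gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
    ball = gx**2 + gy**2 + gz**2 <= r_vox**2 + 1e-9
    out = binary_erosion(mask, structure=ball)
    if not out.any():
        raise ValueError(f"erosion by {radius_mm} mm left an empty mask")
    return out


def roi_median(volume: np.ndarray, mask: np.ndarray) -> float:
    """Median of masked finite voxels (robust to skewed WM distributions)."""
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("mask is empty")
    vals = np.asarray(volume, float)[mask]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("no finite values inside the mask")
    return float(np.median(vals))


def variability(m_i, m_j):
    """Signed percentage difference normalized by the pair mean."""
    m_i = np.asarray(m_i, float)
    m_j = np.asarray(m_j, float)
    mean = 0.5 * (m_i + m_j)
    if np.any(mean == 0):
        raise ValueError("pair mean is zero")
    out = 100.0 * (m_i - m_j) / mean
    return out if out.ndim else float(out)


def deviation(values) -> np.ndarray:
    """100·(m_i − mean)/mean for each value; sums to zero by construction."""
    v = np.asarray(values, float)
    if v.size < 2:
        raise ValueError("need at least 2 values")
    mean = v.mean()
    if mean == 0:
        raise ValueError("mean is zero")
    return 100.0 * (v - mean) / mean


def worst_case_variability(medians) -> float:
    """Largest |variability| over all pairs of medians (attained at extremes)."""
    v = np.asarray(medians, float)
    if v.size < 2:
        raise ValueError("need at least 2 medians")
    best = 0.0
    for a, b in itertools.combinations(v, 2):
        best = max(best, abs(variability(a, b)))
    return best


def voxelwise_variability(map_a: np.ndarray, map_b: np.ndarray,
                          mask: np.ndarray, bin_width: float = 0.5) -> dict:
    """Per-voxel variability of two maps over a mask.

    Returns the distribution median (its offset from zero is the systematic
    inter-measurement shift), the values, and a fixed-width histogram.
    """
    map_a = np.asarray(map_a, float)
    map_b = np.asarray(map_b, float)
    if map_a.shape != map_b.shape:
        raise ValueError("maps must share a grid")
    mask = np.asarray(mask, bool)
    a = map_a[mask]
    b = map_b[mask]
    ok = np.isfinite(a) & np.isfinite(b) & ((a + b) != 0)
    vals = variability(a[ok], b[ok])
    vals = np.atleast_1d(vals)
    med = float(np.median(vals))
    lo = np.floor(vals.min() / bin_width) * bin_width
    hi = np.ceil(vals.max() / bin_width) * bin_width + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, edges = np.histogram(vals, bins=edges)
    return {"values": vals, "median": med, "center_offset": med,
            "hist_counts": counts, "hist_edges": edges, "n": int(vals.size)}


# ---------------------------------------------------------------------------
# report assembly
# ---------------------------------------------------------------------------

@dataclass
class VariabilityReport:
    """Tidy tables mirroring the study's figure structure."""

    medians: pd.DataFrame
    worst_case: pd.DataFrame
    deviations: pd.DataFrame
    voxelwise: pd.DataFrame
    n_mask_voxels: int = 0
    failures: list = field(default_factory=list)

    def worst(self, condition: str, parameter: str, grouping: str) -> float:
        df = self.worst_case
        sel = df[(df.condition == condition) & (df.parameter == parameter)
                 & (df.grouping == grouping)]
        return float(sel.value.iloc[0])


def build_report(records: list, n_mask_voxels: int = 0,
                 failures: list | None = None) -> VariabilityReport:
    """Assemble the statistics tables from fitted-map records.

    Each record is a dict with keys ``condition``, ``vendor``, ``subset``,
    ``replicate`` and 1-D masked value arrays ``t1`` and ``t2`` (ms).
    """
    med_rows = []
    for r in records:
        for par in ("t1", "t2"):
            vals = r[par][np.isfinite(r[par])]
            med_rows.append(dict(condition=r["condition"], vendor=r["vendor"],
                                 subset=r["subset"], replicate=r["replicate"],
                                 parameter=par, median=float(np.median(vals))))
    medians = pd.DataFrame(med_rows)

    wc_rows, dev_rows = [], []
    for (cond, par), g in medians[medians.replicate == 0].groupby(
            ["condition", "parameter"]):
        by_vendor = [worst_case_variability(sub["median"].values)
                     for _, sub in g.groupby("vendor") if len(sub) >= 2]
        by_subset = [worst_case_variability(sub["median"].values)
                     for _, sub in g.groupby("subset") if len(sub) >= 2]
        if by_vendor:
            wc_rows.append(dict(condition=cond, parameter=par,
                                grouping="cross_protocol", value=max(by_vendor)))
        if by_subset:
            wc_rows.append(dict(condition=cond, parameter=par,
                                grouping="cross_vendor", value=max(by_subset)))
        if len(g) >= 2:
            wc_rows.append(dict(condition=cond, parameter=par, grouping="global",
                                value=worst_case_variability(g["median"].values)))
            devs = deviation(g["median"].values)
            for (_, row), d in zip(g.iterrows(), devs):
                dev_rows.append(dict(condition=cond, parameter=par,
                                     vendor=row.vendor, subset=row.subset,
                                     deviation=float(d)))
    worst_case = pd.DataFrame(wc_rows)
    deviations = pd.DataFrame(dev_rows)

    # voxelwise comparisons on the all-measures subset
    vox_rows = []
    first_subset = records[0]["subset"] if records else None
    key = {}
    for r in records:
        key[(r["condition"], r["vendor"], r["subset"], r["replicate"])] = r
    conds = sorted({r["condition"] for r in records})
    vendors = sorted({r["vendor"] for r in records})
    reps = sorted({r["replicate"] for r in records})
    for cond in conds:
        for par in ("t1", "t2"):
            # cross-vendor, same subset, replicate 0
            for va, vb in itertools.combinations(vendors, 2):
                ra = key.get((cond, va, first_subset, 0))
                rb = key.get((cond, vb, first_subset, 0))
                if ra is None or rb is None:
                    continue
                v = variability(ra[par], rb[par])
                vox_rows.append(dict(condition=cond, parameter=par,
                                     kind="cross_vendor", a=va, b=vb,
                                     subset=first_subset,
                                     median=float(np.median(v)), n=v.size))
            # test/retest, same vendor
            for vd in vendors:
                for r0, r1 in itertools.combinations(reps, 2):
                    ra = key.get((cond, vd, first_subset, r0))
                    rb = key.get((cond, vd, first_subset, r1))
                    if ra is None or rb is None:
                        continue
                    v = variability(ra[par], rb[par])
                    vox_rows.append(dict(condition=cond, parameter=par,
                                         kind="test_retest", a=vd, b=vd,
                                         subset=first_subset,
                                         median=float(np.median(v)), n=v.size))
    voxelwise = pd.DataFrame(vox_rows)
    return VariabilityReport(medians=medians, worst_case=worst_case,
                             deviations=deviations, voxelwise=voxelwise,
                             n_mask_voxels=n_mask_voxels,
                             failures=failures or [])


# ---------------------------------------------------------------------------
# end-to-end study
# ---------------------------------------------------------------------------

def _subsample_mask(mask: np.ndarray, n_max: int, seed: int) -> np.ndarray:
    """Deterministic random subsample of a boolean mask (fit-cost control)."""
    idx = np.flatnonzero(mask.ravel())
    if n_max and idx.size > n_max:
        rng = np.random.default_rng(seed)
        idx = rng.choice(idx, size=n_max, replace=False)
    out = np.zeros(mask.size, bool)
    out[idx] = True
    return out.reshape(mask.shape)


def run_study(config) -> VariabilityReport:
    """Phantom → simulate → fit → metrics for every vendor × condition ×
    subset × replicate in ``config`` (a :class:`csmtsim.io.StudyConfig`).

    Fully seeded: the phantom, fields, fit-mask subsample and per-volume
    noise streams all derive from ``config.seed``; noise seeds depend on
    (vendor, replicate) but not on the condition, so conditions are compared
    on identical noise. Failures in individual stages are recorded in the
    report's ``failures`` list and do not abort the remaining cells.
    """
    ss = np.random.SeedSequence(config.seed)
    s_phantom, s_fields, s_mask, s_noise = [
        int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(4)]
    phantom = make_digital_phantom(config.shape, seed=s_phantom)
    fields = make_field_maps(config.shape, config.b1_range, config.b0_range_hz,
                             seed=s_fields)
    wm = erode_mask(phantom.labels == LABEL_WM, config.erosion_radius_mm,
                    phantom.voxel_size)
    fit_mask = _subsample_mask(wm, config.fit_subsample, s_mask)
    csmt_design = config.csmt_design or CsmtDesign()
    vendors = config.vendors or default_vendors()
    subsets = config.subsets or default_subsets()
    fit_config = config.fit_config or _jsr.FitConfig()

    records, failures = [], []
    for cond_name in config.conditions:
        protocol = ProtocolSpec(tr=config.tr, te=config.te,
                                **CONDITIONS[cond_name])
        for vendor in vendors:
            sd = noise_sd_for_snr(phantom, fields, vendor, protocol,
                                  config.snr, csmt_design) if config.snr else 0.0
            for rep in range(config.n_replicates):
                vendor_tag = zlib.crc32(vendor.name.encode()) % (2**16)
                seed_noise = int(np.random.SeedSequence(
                    (s_noise, vendor_tag, rep)
                ).generate_state(1)[0] % (2**31 - 1))
                try:
                    acq = simulate_acquisition(
                        phantom, fields, vendor, protocol, noise_sd=sd,
                        seed=seed_noise, csmt_design=csmt_design,
                        replicate_id=rep)
                except Exception as exc:  # noqa: BLE001 - retained in manifest
                    failures.append(dict(stage="simulate", condition=cond_name,
                                         vendor=vendor.name, replicate=rep,
                                         error=str(exc)))
                    continue
                for subset in subsets:
                    try:
                        maps = _jsr.jsr_fit_volume(acq, subset, mask=fit_mask,
                                                   config=fit_config)
                    except Exception as exc:  # noqa: BLE001
                        failures.append(dict(stage="fit", condition=cond_name,
                                             vendor=vendor.name,
                                             subset=subset.name, replicate=rep,
                                             error=str(exc)))
                        continue
                    records.append(dict(
                        condition=cond_name, vendor=vendor.name,
                        subset=subset.name, replicate=rep,
                        t1=maps["t1"][fit_mask], t2=maps["t2"][fit_mask]))
    return build_report(records, n_mask_voxels=int(fit_mask.sum()),
                        failures=failures)
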