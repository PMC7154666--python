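import math

import numpy as np
import pytest

from conftest import protocol_meta
from csmtsim.jsr import (FitConfig, despot1_init, jsr_fit_volume, jsr_fit_voxel,
                         jsr_residual, select_volumes)
from csmtsim.signal_models import BssfpAcq, SinglePoolTissue, bssfp_signal, \
    spgr_signal
from csmtsim.variability import SubsetSpec, default_subsets

TR = 7.0


def single_pool_measurements(truth: SinglePoolTissue, b1: float, meta=None):
    meta = meta or protocol_meta()
    y = []
    for m in meta:
        if m["sequence"] == "spgr":
            y.append(spgr_signal(truth, b1 * math.radians(m["fa"]), m["tr"]))
        else:
            acq = BssfpAcq(tr=m["tr"], te=m["te"], fa_nominal=m["fa"],
                           phase_increment=m["phase_increment"])
            y.append(abs(bssfp_signal(truth, acq, b1)))
    return np.array(y), meta


def wrapped_df_error(est_df, true_df, tr=TR):
    """Magnitude fits identify |Δf| up to period wrap; compare accordingly."""
    period = 1000.0 / tr
    d = abs(abs(est_df) - abs(true_df))
    return min(d, abs(d - period))


class TestDespot1Init:
    def test_exact_on_noiseless_signals(self):
        t = SinglePoolTissue(t1=1000.0, t2=80.0, m0=1.4)
        fas = [3.0, 7.0, 11.0, 15.0]
        s = np.array([spgr_signal(t, 0.95 * math.radians(f), TR) for f in fas])
        t1, m0 = despot1_init(s, fas, 0.95, TR)
        assert t1 == pytest.approx(1000.0, rel=1e-6)
        assert m0 == pytest.approx(1.4, rel=1e-6)

    def test_wrong_b1_biases_t1(self):
        t = SinglePoolTissue(t1=1000.0, t2=80.0, m0=1.0)
        fas = [3.0, 15.0]
        s = np.array([spgr_signal(t, 0.9 * math.radians(f), TR) for f in fas])
        t1_biased, _ = despot1_init(s, fas, 1.0, TR)  # ignores the true 0.9
        assert abs(t1_biased - 1000.0) / 1000.0 > 0.05

    def test_degenerate_design_rejected(self):
        with pytest.raises(ValueError):
            despot1_init(np.array([1.0, 1.0]), [7.0, 7.0], 1.0, TR)


class TestResidual:
    def test_zero_at_truth_and_length(self):
        truth = SinglePoolTissue(t1=1100.0, t2=45.0, m0=0.7, delta_f=20.0)
        y, meta = single_pool_measurements(truth, 0.97)
        r = jsr_residual((0.7, 1100.0, 45.0, 20.0), y, meta, 0.97, TR)
        assert r.shape[-1] == len(meta)
        np.testing.assert_allclose(r, 0.0, atol=1e-12)

    def test_periodic_in_delta_f(self):
        truth = SinglePoolTissue(t1=1100.0, t2=45.0, m0=0.7, delta_f=20.0)
        y, meta = single_pool_measurements(truth, 1.0)
        r1 = jsr_residual((0.7, 1100.0, 45.0, 20.0), y, meta, 1.0, TR)
        r2 = jsr_residual((0.7, 1100.0, 45.0, 20.0 + 1000.0 / TR), y, meta, 1.0, TR)
        np.testing.assert_allclose(r1, r2, atol=1e-10)

    def test_unknown_sequence_rejected(self):
        with pytest.raises(ValueError):
            jsr_residual((1, 1000, 50, 0), np.zeros(1),
                         [{"sequence": "epi", "fa": 5.0}], 1.0, TR)


class TestVoxelFit:
    @pytest.mark.parametrize("df", [0.0, 22.0, -55.0])
    def test_recovers_noiseless_truth(self, df):
        truth = SinglePoolTissue(t1=1100.0, t2=45.0, m0=0.7, delta_f=df)
        y, meta = single_pool_measurements(truth, 0.93)
        est = jsr_fit_voxel(y, meta, 0.93)
        assert est.converged
        assert est.t1 == pytest.approx(1100.0, rel=1e-3)
        assert est.t2 == pytest.approx(45.0, rel=1e-3)
        assert wrapped_df_error(est.delta_f, df) < 0.5

    def test_band_edge_voxel_wraps_cleanly(self):
        edge = 1000.0 / (2 * TR)
        truth = SinglePoolTissue(t1=1100.0, t2=45.0, m0=0.7, delta_f=edge)
        y, meta = single_pool_measurements(truth, 1.0)
        est = jsr_fit_voxel(y, meta, 1.0)
        assert wrapped_df_error(est.delta_f, edge) < 0.5

    def test_requires_both_sequence_families(self):
        truth = SinglePoolTissue(t1=1100.0, t2=45.0, m0=0.7)
        meta = [m for m in protocol_meta() if m["sequence"] == "spgr"]
        y = np.array([spgr_signal(truth, math.radians(m["fa"]), TR) for m in meta])
        with pytest.raises(ValueError):
            jsr_fit_voxel(y, meta, 1.0)

    def test_requires_at_least_four_volumes(self):
        meta = protocol_meta()[:3]
        with pytest.raises(ValueError):
            jsr_fit_voxel(np.zeros(3), meta, 1.0)

    def test_batched_volume_route_agrees_with_scipy_route(self, sp_acq32):
        # the vectorized Levenberg-Marquardt must reproduce the per-voxel
        # reference fit on identical data
        mask = np.zeros(sp_acq32.truth.shape, bool)
        wm = np.argwhere(sp_acq32.truth.labels == 1)
        picks = wm[:: max(1, len(wm) // 12)][:12]
        mask[tuple(picks.T)] = True
        maps = jsr_fit_volume(sp_acq32, None, mask=mask)
        meta = [v.meta for v in sp_acq32.volumes]
        for i, j, k in picks:
            y = np.array([v.data[i, j, k] for v in sp_acq32.volumes])
            est = jsr_fit_voxel(y, meta, float(sp_acq32.fields.b1_scale[i, j, k]))
            assert maps["t1"][i, j, k] == pytest.approx(est.t1, rel=1e-6)
            assert maps["t2"][i, j, k] == pytest.approx(est.t2, rel=1e-6)


class TestVolumeFit:
    def test_noiseless_recovery_everywhere_in_mask(self, sp_acq32):
        mask = sp_acq32.truth.labels == 1
        # thin the mask for speed; recovery must hold at every fitted voxel
        flat = np.flatnonzero(mask.ravel())[::17]
        mask = np.zeros(mask.size, bool)
        mask[flat] = True
        mask = mask.reshape(sp_acq32.truth.shape)
        maps = jsr_fit_volume(sp_acq32, None, mask=mask)
        assert np.nanmax(np.abs(maps["t1"][mask] - 1100.0)) / 1100.0 < 1e-3
        assert np.nanmax(np.abs(maps["t2"][mask] - 45.0)) / 45.0 < 1e-3
        assert np.isnan(maps["t1"][~mask]).all()

    def test_subset_invariance_on_single_pool_truth(self, sp_acq32):
        mask = sp_acq32.truth.labels == 1
        flat = np.flatnonzero(mask.ravel())[::29]
        mask = np.zeros(mask.size, bool)
        mask[flat] = True
        mask = mask.reshape(sp_acq32.truth.shape)
        meds = []
        for subset in (default_subsets()[1], default_subsets()[2]):
            maps = jsr_fit_volume(sp_acq32, subset, mask=mask)
            meds.append(np.nanmedian(maps["t1"][mask]))
        assert abs(meds[0] - meds[1]) / meds[0] < 1e-3

    def test_unidentifiable_subset_rejected_before_fitting(self, sp_acq32):
        class BadSubset:
            name = "bad"
            spgr_fas = (3.0, 7.0)
            bssfp_fas_180 = ()
            include_bssfp_0 = True

        with pytest.raises(ValueError):
            select_volumes(sp_acq32, BadSubset())
        with pytest.raises(ValueError):
            jsr_fit_volume(sp_acq32, BadSubset())


class TestSubsetSpec:
    def test_identifiability_enforced_at_construction(self):
        with pytest.raises(ValueError):
            SubsetSpec("x", (3.0,), (), True)
        s = SubsetSpec("ok", (3.0,), (45.0,), True)
        assert s.include_bssfp_0

    def test_default_subsets_all_identifiable(self, sp_acq32):
        for s in default_subsets():
            idx = select_volumes(sp_acq32, s)
            assert len(idx) >= 4
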