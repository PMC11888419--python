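"""Intensity traces, edge normalization, regional AUC and fold-change."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ehtmech import synthetic as syn
from ehtmech.exceptions import AnalysisError, ParameterError
from ehtmech.intensity import (
    IntensityTrace,
    fold_change,
    long_axis_trace,
    normalize_to_edge,
    regional_auc,
)
from ehtmech.partition import default_partition

PARTITION = default_partition(2.0, 4.0)
PPM = 50.0


def _trace(values, normalized=False):
    values = np.asarray(values, float)
    return IntensityTrace(
        positions_px=np.arange(values.size, dtype=float),
        values=values,
        channel="fibroblast",
        normalized=normalized,
    )


class TestTrace:
    def test_uniform_image(self):
        img = np.full((40, 60), 100.0)
        mask = np.ones_like(img, bool)
        tr = long_axis_trace(img, mask)
        assert np.allclose(tr.values, 100.0)
        assert len(tr) == 60

    def test_step_image(self):
        img = np.concatenate(
            [np.full((40, 30), 100.0), np.full((40, 30), 50.0)], axis=1
        )
        tr = long_axis_trace(img, np.ones_like(img, bool))
        assert np.allclose(tr.values[:30], 100.0)
        assert np.allclose(tr.values[30:], 50.0)

    def test_empty_columns_dropped(self):
        img = np.full((40, 60), 7.0)
        mask = np.ones_like(img, bool)
        mask[:, 10] = False
        tr = long_axis_trace(img, mask)
        assert len(tr) == 59
        assert 10.0 not in tr.positions_px  # position of the dropped column

    def test_empty_mask_raises(self):
        with pytest.raises(AnalysisError):
            long_axis_trace(np.ones((4, 4)), np.zeros((4, 4), bool))


class TestNormalize:
    def test_uniform_trace_becomes_one(self):
        tr = normalize_to_edge(_trace(np.full(50, 100.0)))
        assert np.allclose(tr.values, 1.0)
        assert tr.normalized

    def test_band_mean_is_exactly_one(self):
        rng = np.random.default_rng(4)
        tr = normalize_to_edge(_trace(rng.uniform(10, 90, 80)))
        assert tr.values[:10].mean() == pytest.approx(1.0, rel=1e-12)

    def test_interior_scaled_by_edge_mean(self):
        vals = np.ones(40)
        vals[:10] = 2.0
        tr = normalize_to_edge(_trace(vals))
        assert np.allclose(tr.values[10:], 0.5)

    def test_both_ends_mode(self):
        vals = np.ones(40)
        vals[:10] = 2.0
        vals[-10:] = 4.0
        tr = normalize_to_edge(_trace(vals), mode="both")
        assert np.allclose(tr.values[10:-10], 1.0 / 3.0)

    def test_short_trace_raises(self):
        with pytest.raises(ParameterError):
            normalize_to_edge(_trace(np.ones(5)))

    def test_zero_edge_raises(self):
        with pytest.raises(AnalysisError):
            normalize_to_edge(_trace(np.zeros(40)))


class TestRegionalAuc:
    def test_unit_trace_unit_wound_auc(self):
        tr = _trace(np.ones(201), normalized=True)  # 4 mm span at 50 px/mm
        auc = regional_auc(tr, PARTITION, PPM)
        assert auc["wound"] == pytest.approx(1.0)  # 1 mm wound extent
        assert auc["border"] == pytest.approx(1.0)  # 2 x 0.5 mm

    def test_constant_wound_level(self):
        vals = np.ones(201)
        x_mm = np.arange(201) / PPM
        vals[np.abs(x_mm - 2.0) <= 0.5] = 0.6
        auc = regional_auc(_trace(vals, normalized=True), PARTITION, PPM)
        assert auc["wound"] == pytest.approx(0.6, abs=0.01)

    def test_matches_union_grid_trapezoid_oracle(self):
        rng = np.random.default_rng(9)
        vals = rng.uniform(0.2, 1.4, 201)
        tr = _trace(vals, normalized=True)
        auc = regional_auc(tr, PARTITION, PPM)
        x = tr.positions_px / PPM
        for zone, intervals in PARTITION.zone_extents.items():
            total = 0.0
            for a, b in intervals:
                lo, hi = max(a, x[0]), min(b, x[-1])
                if hi <= lo:
                    continue
                grid = np.unique(np.concatenate([[lo, hi], x[(x > lo) & (x < hi)]]))
                total += np.trapezoid(np.interp(grid, x, vals), grid)
            assert auc[zone] == pytest.approx(total, abs=1e-9)

    def test_zone_outside_trace_missing(self):
        tr = _trace(np.ones(30), normalized=True)  # 0.6 mm of trace only
        auc = regional_auc(tr, PARTITION, PPM)
        assert np.isnan(auc["wound"])
        assert np.isfinite(auc["remote"])

    def test_unnormalized_trace_rejected(self):
        with pytest.raises(ParameterError):
            regional_auc(_trace(np.ones(201)), PARTITION, PPM)


class TestFoldChange:
    def test_no_change_is_zero(self):
        assert fold_change({"wound": 1.0}, {"wound": 1.0})["wound"] == 0.0

    def test_forty_percent_reduction(self):
        out = fold_change({"wound": 0.6}, {"wound": 1.0})
        assert out["wound"] == pytest.approx(-0.4)

    def test_ten_percent_gain(self):
        out = fold_change({"remote": 1.1}, {"remote": 1.0})
        assert out["remote"] == pytest.approx(0.1)

    def test_zero_prewound_raises(self):
        with pytest.raises(AnalysisError):
            fold_change({"wound": 1.0}, {"wound": 0.0})


class TestScaleInvariance:
    @given(scale=st.floats(0.05, 50.0))
    def test_normalized_trace_and_auc_invariant_under_gain(self, scale):
        """Multiplying a channel image by any positive gain leaves the
        edge-normalized trace and the regional AUCs unchanged."""
        rng = np.random.default_rng(12)
        vals = rng.uniform(50, 250, 201)
        base = normalize_to_edge(_trace(vals))
        scaled = normalize_to_edge(_trace(vals * scale))
        assert np.allclose(base.values, scaled.values, rtol=1e-9)
        a0 = regional_auc(base, PARTITION, PPM)
        a1 = regional_auc(scaled, PARTITION, PPM)
        for z in a0:
            assert a0[z] == pytest.approx(a1[z], rel=1e-9)


def test_generator_reduction_recovered_noise_free():
    """A noise-free 40/30/7.5% reduction map yields fold-changes at the
    prescribed values (remote diluted by the unreduced edge band)."""
    spec = syn.SyntheticTissueSpec(seed=5)
    red = {"wound": 0.40, "border": 0.30, "remote": 0.075}
    mech = syn.ZoneMechanicsSpec(
        density_reduction_by_zone_channel={"fibroblast": red}
    )
    zero = syn.ZoneMechanicsSpec(
        density_reduction_by_zone_channel={"fibroblast": {z: 0.0 for z in red}}
    )
    mask = syn.tissue_mask(spec)
    part = default_partition(spec.wound_center_mm, spec.length_mm)

    def auc_of(m):
        img = syn.generate_fluorescence_maps(spec, m)["fibroblast"]
        tr = normalize_to_edge(long_axis_trace(img, mask))
        return regional_auc(tr, part, spec.px_per_mm)

    fc = fold_change(auc_of(mech), auc_of(zero))
    assert fc["wound"] == pytest.approx(-0.40, abs=0.01)
    assert fc["border"] == pytest.approx(-0.30, abs=0.01)
    # the 10 px edge band stays at baseline, diluting the remote estimate
    band_mm = 10 / spec.px_per_mm
    remote_len = 2.0
    expected = -0.075 * (remote_len - band_mm) / remote_len
    assert fc["remote"] == pytest.approx(expected, abs=0.01)
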