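"""Generator contracts: determinism, texture statistics, displacement
profiles, warping and the structure of ramp/fluorescence outputs."""

import numpy as np
import pytest

from ehtmech import synthetic as syn
from ehtmech.exceptions import ParameterError
from ehtmech.mechanics import ForceCalibration


class TestSpeckle:
    def test_deterministic_for_fixed_seed(self, small_spec):
        a = syn.generate_speckle(small_spec)
        b = syn.generate_speckle(small_spec)
        assert np.array_equal(a, b)

    def test_different_seeds_differ(self, small_spec):
        from dataclasses import replace

        other = syn.generate_speckle(replace(small_spec, seed=small_spec.seed + 1))
        assert not np.array_equal(syn.generate_speckle(small_spec), other)

    def test_zero_density_gives_uniform_tissue(self, small_spec):
        from dataclasses import replace

        spec = replace(small_spec, speckle_density=0.0)
        img = syn.generate_speckle(spec)
        m = syn.tissue_mask(spec)
        assert np.all(img[m] == spec.base_intensity)
        assert np.all(img[~m] == 0)

    def test_covered_fraction_matches_density(self):
        spec = syn.SyntheticTissueSpec(seed=1, speckle_density=0.3)
        img = syn.generate_speckle(spec)
        m = syn.tissue_mask(spec)
        frac = (img[m] > syn.speckle_threshold(spec)).mean()
        assert frac == pytest.approx(0.30, abs=0.02)

    def test_background_is_zero(self, small_spec, small_speckle, small_mask):
        assert np.all(small_speckle[~small_mask] == 0)

    @pytest.mark.parametrize(
        "kw",
        [
            {"px_per_mm": 0.0},
            {"speckle_density": 1.5},
            {"wound_width_mm": 3.0, "border_width_mm": 1.0},
            {"noise_sd": -0.1},
        ],
    )
    def test_invalid_spec_raises(self, kw):
        with pytest.raises(ParameterError):
            syn.SyntheticTissueSpec(**kw)


class TestDisplacementProfile:
    def test_zero_strain_gives_zero_displacement(self, small_spec):
        mech = syn.ZoneMechanicsSpec(
            systolic_strain_by_zone={"wound": 0.0, "remote": 0.0}
        )
        _, u = syn.axial_displacement_profile(small_spec, mech, "beat", 1.0)
        assert np.allclose(u, 0.0)

    def test_constant_strain_integrates_to_strain_times_length(self, small_spec):
        # equal zone values collapse the profile to a single constant zone
        mech = syn.ZoneMechanicsSpec(
            systolic_strain_by_zone={"wound": 0.02, "border": 0.02, "remote": 0.02}
        )
        x, u = syn.axial_displacement_profile(small_spec, mech, "beat", 1.0)
        assert u[-1] == pytest.approx(0.02 * small_spec.length_mm, rel=1e-9)

    def test_two_equal_zones_against_numeric_oracle(self):
        # displacement of a piecewise-constant strain profile: independent
        # dense-trapezoid oracle vs the running-integral implementation
        L, e1, e2 = 3.0, 0.04, -0.01
        x = np.linspace(0.0, L, 6001)
        e = np.where(x < L / 2, e1, e2)
        u = syn.displacement_from_strain(x, e)
        # discretisation of the strain jump limits agreement to ~dx/L
        assert u[-1] == pytest.approx((e1 + e2) * L / 2, rel=1e-3)
        oracle = np.trapezoid(e, x)
        assert u[-1] == pytest.approx(oracle, rel=1e-12)

    def test_ramp_mode_strain_equals_stress_over_modulus(self, small_spec):
        mech = syn.ZoneMechanicsSpec(
            modulus_by_zone={"wound": 30.0, "border": 20.0, "remote": 10.0}
        )
        stress = 0.6
        x, u = syn.axial_displacement_profile(small_spec, mech, "ramp_step", stress)
        e = np.gradient(u, x)
        c = small_spec.wound_center_mm
        assert e[np.argmin(np.abs(x - c))] == pytest.approx(stress / 30.0, rel=1e-3)
        assert e[np.argmin(np.abs(x - 0.1))] == pytest.approx(stress / 10.0, rel=1e-3)

    def test_unknown_mode_raises(self, small_spec):
        mech = syn.ZoneMechanicsSpec(systolic_strain_by_zone={"wound": 0.0})
        with pytest.raises(ParameterError):
            syn.axial_displacement_profile(small_spec, mech, "twist", 1.0)


class TestWarp:
    def test_zero_field_is_identity(self, small_speckle):
        img = small_speckle.astype(float)
        z = np.zeros_like(img)
        out = syn.warp_image(img, z, z)
        assert np.allclose(out, img, atol=1e-9)

    def test_integer_translation_is_exact_with_background_fill(self, small_speckle):
        img = small_speckle.astype(float)
        u = np.full_like(img, 5.0)
        v = np.zeros_like(img)
        out = syn.warp_image(img, u, v)
        assert np.allclose(out[:, 5:], img[:, :-5], atol=1e-8)
        assert np.allclose(out[:, :5], 0.0)

    def test_uniform_stretch_moves_tissue_edge(self, small_spec, small_speckle):
        img = small_speckle.astype(float)
        x0 = small_spec.margin_px
        cols = np.arange(img.shape[1], dtype=float)
        u = np.broadcast_to(np.maximum(0.05 * (cols - x0), 0.0), img.shape).copy()
        out = syn.warp_image(img, u, np.zeros_like(img), warn_oob=False)
        edge_ref = np.flatnonzero((img > 10).any(axis=0))[-1]
        edge_out = np.flatnonzero((out > 10).any(axis=0))[-1]
        expected = x0 + 1.05 * (edge_ref - x0)
        assert edge_out == pytest.approx(expected, abs=1.0)

    def test_mismatched_field_raises(self, small_speckle):
        img = small_speckle.astype(float)
        with pytest.raises(ParameterError):
            syn.warp_image(img, np.zeros((3, 3)), np.zeros((3, 3)))


class TestRampSequence:
    def test_single_zero_level_returns_reference(self, small_spec):
        mech = syn.ZoneMechanicsSpec(modulus_by_zone={"wound": 30.0, "remote": 10.0})
        protocol = syn.ForceProtocol(amperages=(0.0,))
        seq = syn.generate_ramp_sequence(
            small_spec, mech, protocol, ForceCalibration()
        )
        assert seq.frames.shape[0] == 1
        assert np.array_equal(seq.frames[0], syn.generate_speckle(small_spec))

    def test_nine_levels_monotone_end_displacement(self, small_spec):
        mech = syn.ZoneMechanicsSpec(
            modulus_by_zone={"wound": 30.0, "border": 20.0, "remote": 10.0}
        )
        seq = syn.generate_ramp_sequence(
            small_spec,
            mech,
            syn.ForceProtocol(),
            ForceCalibration(coefficients=(13.0,)),
        )
        assert seq.frames.shape[0] == 9
        assert list(seq.table["amperage_A"]) == pytest.approx(
            [0.1 * i for i in range(9)]
        )
        edges = [
            np.flatnonzero((f > 10).any(axis=0))[-1] for f in seq.frames.astype(float)
        ]
        assert np.all(np.diff(edges) >= 0) and edges[-1] > edges[0]


class TestFluorescence:
    def _mech(self, wound, border, remote, channels=("fibroblast",)):
        red = {"wound": wound, "border": border, "remote": remote}
        return syn.ZoneMechanicsSpec(
            density_reduction_by_zone_channel={ch: red for ch in channels}
        )

    def test_zero_reductions_uniform(self, small_spec):
        maps = syn.generate_fluorescence_maps(
            small_spec, self._mech(0.0, 0.0, 0.0), baseline_intensity=200.0
        )
        m = syn.tissue_mask(small_spec)
        assert np.allclose(maps["fibroblast"][m], 200.0)

    def test_full_wound_reduction_zeroes_wound(self):
        spec = syn.SyntheticTissueSpec(seed=3)
        maps = syn.generate_fluorescence_maps(spec, self._mech(1.0, 0.0, 0.0))
        row = spec.shape[0] // 2
        wound_col = spec.margin_px + int(spec.wound_center_mm * spec.px_per_mm)
        assert maps["fibroblast"][row, wound_col] == 0.0

    def test_wound_remote_intensity_ratio(self):
        spec = syn.SyntheticTissueSpec(seed=3)
        maps = syn.generate_fluorescence_maps(spec, self._mech(0.4, 0.2, 0.1))
        img = maps["fibroblast"]
        m = syn.tissue_mask(spec)
        x = spec.x_mm(np.arange(spec.shape[1]))
        wound_cols = np.abs(x - spec.wound_center_mm) < 0.4
        remote_cols = (x > 3.2) & (x < spec.length_mm - 0.02)
        wound_mean = img[:, wound_cols][m[:, wound_cols]].mean()
        remote_mean = img[:, remote_cols][m[:, remote_cols]].mean()
        assert wound_mean / remote_mean == pytest.approx(0.6 / 0.9, rel=1e-6)

    def test_reduction_out_of_range_raises(self):
        with pytest.raises(ParameterError):
            self._mech(1.2, 0.0, 0.0)
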