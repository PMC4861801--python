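import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oxspectra import (
    BandDef,
    MARKER_NAMES,
    MarkerPanel,
    SGFilterSpec,
    Spectrum,
    SyntheticConfig,
    band_amplitude,
    classify_effect,
    generate_cell_spectrum,
    marker_panel,
    relative_to_control,
    second_derivative,
    vector_normalize,
)


def second_deriv_of(wn, y, window=21):
    s = Spectrum(wn, y, kind="normalized")
    return second_derivative(s, SGFilterSpec(window=window))


class TestBandAmplitude:
    def test_gaussian_depth_matches_analytic(self):
        """Second-derivative depth of a Gaussian band is A / sigma^2.

        Measured on a dense grid with a short window so the SG estimate
        tracks the analytic derivative (the independent oracle); the
        default 21-point window attenuates absolute depths but cancels in
        same-spectrum ratios.
        """
        wn = np.arange(1600.0, 1900.0001, 0.25)
        A, sigma = 0.7, 8.0
        y = A * np.exp(-((wn - 1740.0) ** 2) / (2 * sigma**2))
        d = second_deriv_of(wn, y, window=5)
        amp = band_amplitude(d, BandDef("co", 1740.0))
        assert abs(amp / (A / sigma**2) - 1.0) < 0.02

    def test_flat_spectrum_returns_zero(self, grid, caplog):
        d = second_deriv_of(grid, np.zeros(grid.size))
        assert band_amplitude(d, BandDef("co", 1740.0)) == 0.0
        assert "no negative" in caplog.text

    def test_linear_in_global_scale(self, grid, rng):
        y = np.abs(rng.normal(0.2, 0.05, grid.size))
        d1 = second_deriv_of(grid, y)
        d2 = second_deriv_of(grid, 3.5 * y)
        b = BandDef("co", 1740.0)
        assert band_amplitude(d2, b) == pytest.approx(3.5 * band_amplitude(d1, b),
                                                      rel=1e-12)

    def test_window_outside_grid_rejected(self, grid):
        d = second_deriv_of(grid, np.zeros(grid.size))
        with pytest.raises(ValueError, match="outside grid"):
            band_amplitude(d, BandDef("x", 4100.0))

    def test_requires_second_derivative_kind(self, grid):
        s = Spectrum(grid, np.ones(grid.size))
        with pytest.raises(ValueError, match="second-derivative"):
            band_amplitude(s, BandDef("co", 1740.0))

    def test_off_center_band_found_within_halfwidth(self, grid):
        # band centred 4 cm^-1 off its nominal position is still picked up
        y = np.exp(-((grid - 1744.0) ** 2) / (2 * 8.0**2))
        d = second_deriv_of(grid, y)
        searched = band_amplitude(d, BandDef("co", 1740.0, halfwidth=8.0))
        exact = band_amplitude(d, BandDef("co", 1740.0), exact_point=True)
        assert searched > exact


class TestMarkerPanel:
    def test_equal_band_amplitudes_give_unit_ratios(self, grid):
        from oxspectra.markers import CANONICAL_BANDS

        y = np.zeros(grid.size)
        for b in CANONICAL_BANDS.values():
            y += 0.5 * np.exp(-((grid - b.center) ** 2) / (2 * 6.0**2))
        panel = marker_panel(second_deriv_of(grid, y))
        for m in MARKER_NAMES:
            assert getattr(panel, m) == pytest.approx(1.0, rel=0.02)

    def test_oxidation_gain_recovered(self, noiseless_config):
        """Noiseless generator: the 1740 gain appears as a (1 + k) factor
        on the lipid_oxidation ratio (2960 reference unchanged)."""
        def panel(delta):
            s = generate_cell_spectrum(noiseless_config, delta, seed=0)
            return marker_panel(second_derivative(vector_normalize(s)))

        p0, p1 = panel(0.0), panel(1.0)
        gains = {b.center: b.delta_gain for b in noiseless_config.bands}
        assert p1.lipid_oxidation / p0.lipid_oxidation == pytest.approx(
            1.0 + gains[1740.0], rel=0.03
        )
        assert p1.lipid_saturation / p0.lipid_saturation == pytest.approx(
            1.0 + gains[2920.0], rel=0.03
        )
        assert p1.lipid_desaturation / p0.lipid_desaturation == pytest.approx(
            1.0 + gains[3012.0], rel=0.03
        )

    def test_markers_invariant_to_raw_rescaling(self, noiseless_config):
        s = generate_cell_spectrum(noiseless_config, 0.5, seed=3)
        big = s.with_intensities(100.0 * s.intensities)
        p1 = marker_panel(second_derivative(vector_normalize(s)))
        p2 = marker_panel(second_derivative(vector_normalize(big)))
        for m in MARKER_NAMES:
            assert getattr(p1, m) == pytest.approx(getattr(p2, m), rel=1e-9)

    def test_monotone_in_oxidation_level(self, noiseless_config):
        deltas = [0.0, 0.25, 0.5, 0.75, 1.0]
        panels = []
        for d in deltas:
            s = generate_cell_spectrum(noiseless_config, d, seed=0)
            panels.append(marker_panel(second_derivative(vector_normalize(s))))
        for m, sign in [("lipid_oxidation", 1), ("lipid_saturation", -1),
                        ("lipid_desaturation", -1), ("protein_aggregation", 1)]:
            vals = np.array([getattr(p, m) for p in panels])
            assert np.all(sign * np.diff(vals) > 0), m

    def test_zero_reference_band_rejected(self, grid):
        # spectrum with no CH3 band at all: flat in the lipid region
        y = np.exp(-((grid - 1740.0) ** 2) / (2 * 8.0**2)) \
            + np.exp(-((grid - 1650.0) ** 2) / (2 * 8.0**2)) \
            + np.exp(-((grid - 1630.0) ** 2) / (2 * 8.0**2))
        with pytest.raises(ValueError, match="2960"):
            marker_panel(second_deriv_of(grid, y))


def make_panel(sid, treatment, value):
    return MarkerPanel(sid, treatment, value, value, value, value)


class TestRelativeToControl:
    def test_control_group_mean_is_one(self):
        panels = [make_panel("a", "control", 2.0), make_panel("b", "control", 4.0)]
        rel = relative_to_control(panels, "control")
        assert np.mean([p.lipid_oxidation for p in rel]) == pytest.approx(1.0)

    def test_double_control_maps_to_two(self):
        panels = [make_panel("a", "control", 1.5), make_panel("b", "T", 3.0)]
        rel = relative_to_control(panels, "control")
        assert rel[1].lipid_oxidation == pytest.approx(2.0)

    def test_elementwise_division_oracle(self, rng):
        panels = [
            MarkerPanel(f"s{i}", "control" if i < 4 else "T",
                        *np.abs(rng.normal(1.0, 0.2, 4)))
            for i in range(8)
        ]
        rel = relative_to_control(panels, "control")
        for m in MARKER_NAMES:
            mean = np.mean([getattr(p, m) for p in panels[:4]])
            for p, r in zip(panels, rel):
                assert getattr(r, m) == pytest.approx(getattr(p, m) / mean,
                                                      rel=1e-12)

    def test_missing_control_rejected(self):
        with pytest.raises(ValueError, match="control"):
            relative_to_control([make_panel("a", "T", 1.0)], "control")


class TestClassifyEffect:
    @pytest.mark.parametrize(
        "treatment,expected",
        [(1.0, "protective"), (2.0, "stress_like"), (1.5, "partial")],
    )
    def test_positions_on_control_stress_axis(self, treatment, expected):
        out = classify_effect(treatment, 1.0, 2.0, tol=0.1)
        assert out.label == expected

    def test_indistinguishable_stress_gives_no_effect(self):
        assert classify_effect(1.2, 1.0, 1.05, tol=0.15).label == "no_effect"

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            classify_effect(np.nan, 1.0, 2.0)

    @given(shift=st.floats(-0.5, 0.5), scale=st.floats(1, 10),
           p=st.floats(0, 1))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_invariant_to_joint_affine_rescaling(self, shift, scale, p):
        # shifts stay small relative to the control-stress separation so the
        # control-referenced no_effect guard keeps the same verdict
        control, stress = 1.0, 3.0
        treatment = control + p * (stress - control)
        base = classify_effect(treatment, control, stress).label
        moved = classify_effect(scale * treatment + shift,
                                scale * control + shift,
                                scale * stress + shift).label
        assert moved == base
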