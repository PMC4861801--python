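import numpy as np
import pytest

from oxspectra import (
    GridMismatchError,
    SpectraCollection,
    SpectraFormatError,
    Spectrum,
    SyntheticConfig,
    generate_experiment,
    read_jcamp,
    read_spectra_csv,
    resample_to_grid,
    write_spectra_csv,
)
from oxspectra.markers import BandDef, band_amplitude
from oxspectra.preprocess import second_derivative, vector_normalize


class TestSpectrum:
    def test_rejects_descending_grid(self):
        with pytest.raises(ValueError, match="ascending"):
            Spectrum(np.array([3.0, 2.0, 1.0]), np.zeros(3))

    def test_rejects_length_mismatch(self):
        with pytest.raises(ValueError, match="equally long"):
            Spectrum(np.arange(4.0), np.zeros(3))

    def test_rejects_unknown_kind(self):
        with pytest.raises(ValueError, match="kind"):
            Spectrum(np.arange(3.0), np.zeros(3), kind="smoothed")

    def test_sample_in_two_groups_rejected(self):
        s = Spectrum(np.arange(3.0), np.zeros(3), sample_id="a", treatment="x")
        with pytest.raises(ValueError, match="appears in groups"):
            SpectraCollection([s], groups={"x": ["a"], "y": ["a"]})


class TestCSV:
    def test_wide_descending_reversed(self, tmp_path):
        """A descending on-disk wide CSV comes back on an ascending grid."""
        wn = np.arange(4000.0, 800.0 - 1, -2.0)
        rows = ["wavenumber,s1|control,s2|H2O2,s3|H2O2"]
        vals = np.column_stack([wn * 1e-4, wn * 2e-4, wn * 3e-4])
        for w, v in zip(wn, vals):
            rows.append(f"{w},{v[0]},{v[1]},{v[2]}")
        path = tmp_path / "wide.csv"
        path.write_text("\n".join(rows))
        c = read_spectra_csv(path, "wide")
        assert len(c) == 3
        assert len(c.spectra[0]) == 1601
        assert np.all(np.diff(c.wavenumbers) > 0)
        assert c.groups == {"control": ["s1"], "H2O2": ["s2", "s3"]}
        np.testing.assert_allclose(c.get("s2").intensities, c.wavenumbers * 2e-4)

    def test_long_different_grids_rejected(self, tmp_path):
        rows = ["sample_id,treatment,wavenumber,intensity"]
        for w in (1000, 1002, 1004):
            rows.append(f"a,control,{w},0.1")
        for w in (1000, 1003, 1006):
            rows.append(f"b,control,{w},0.1")
        path = tmp_path / "long.csv"
        path.write_text("\n".join(rows))
        with pytest.raises(GridMismatchError, match="resample_to_grid"):
            read_spectra_csv(path, "long")

    def test_non_numeric_cell_reports_line(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("wavenumber,s1\n1000,0.1\n1002,oops\n")
        with pytest.raises(SpectraFormatError, match="line 3"):
            read_spectra_csv(path, "wide")

    @pytest.mark.parametrize("layout", ["wide", "long"])
    def test_round_trip_preserves_12_significant_digits(self, layout, tmp_path):
        exp = generate_experiment(SyntheticConfig(seed=7, n_per_group=2,
                                                  protection={"Cat": 1.0}))
        path = tmp_path / f"rt.{layout}.csv"
        write_spectra_csv(exp.spectra, path, layout)
        back = read_spectra_csv(path, layout)
        assert sorted(back.groups) == sorted(exp.spectra.groups)
        for s in exp.spectra:
            r = back.get(s.sample_id)
            np.testing.assert_allclose(r.wavenumbers, s.wavenumbers, rtol=1e-12)
            np.testing.assert_allclose(r.intensities, s.intensities, rtol=1e-11)

    def test_yaml_sidecar_assigns_groups(self, tmp_path):
        path = tmp_path / "w.csv"
        path.write_text("wavenumber,s1,s2\n1000,0.1,0.2\n1002,0.1,0.2\n")
        side = tmp_path / "groups.yaml"
        side.write_text("groups:\n  control: [s1]\n  H2O2: [s2]\n")
        c = read_spectra_csv(path, "wide", sidecar=side)
        assert c.groups == {"control": ["s1"], "H2O2": ["s2"]}


JCAMP_MINIMAL = """##TITLE=minimal
##JCAMP-DX=4.24
##XUNITS=1/CM
##YUNITS=ABSORBANCE
##FIRSTX=1000
##LASTX=1008
##NPOINTS=5
##XFACTOR=1
##YFACTOR=0.001
##XYDATA=(X++(Y..Y))
1000 1000 2000 3000
1006 2000 1000
##END=
"""


class TestJCAMP:
    def test_yfactor_applied(self, tmp_path):
        path = tmp_path / "m.jdx"
        path.write_text(JCAMP_MINIMAL)
        s = read_jcamp(path)
        np.testing.assert_allclose(s.intensities, [1.0, 2.0, 3.0, 2.0, 1.0])
        np.testing.assert_allclose(s.wavenumbers, [1000, 1002, 1004, 1006, 1008])

    def test_descending_grid_step(self, tmp_path):
        n = 1601
        lines = ["##TITLE=t", "##FIRSTX=4000", "##LASTX=800",
                 f"##NPOINTS={n}", "##XFACTOR=1", "##YFACTOR=1",
                 "##XYDATA=(X++(Y..Y))"]
        x = np.linspace(4000, 800, n)
        for i in range(0, n, 8):
            ys = " ".join(str(float(v)) for v in x[i:i + 8])
            lines.append(f"{x[i]} {ys}")
        path = tmp_path / "d.jdx"
        path.write_text("\n".join(lines) + "\n##END=\n")
        s = read_jcamp(path)
        assert len(s) == 1601
        steps = np.diff(s.wavenumbers)
        np.testing.assert_allclose(steps, 2.0, rtol=1e-10)
        # intensities follow the (reversed) abscissa exactly
        np.testing.assert_allclose(s.intensities, s.wavenumbers, rtol=1e-12)

    def test_missing_npoints_rejected(self, tmp_path):
        path = tmp_path / "bad.jdx"
        path.write_text(JCAMP_MINIMAL.replace("##NPOINTS=5\n", ""))
        with pytest.raises(SpectraFormatError, match="NPOINTS"):
            read_jcamp(path)


class TestResample:
    def test_identity_on_own_grid(self, small_collection):
        out = resample_to_grid(small_collection, small_collection.wavenumbers)
        for a, b in zip(out, small_collection):
            np.testing.assert_array_equal(a.intensities, b.intensities)

    def test_linear_ramp_exact_at_midpoints(self):
        wn = np.arange(1000.0, 1101.0, 2.0)
        c = SpectraCollection([Spectrum(wn, 3.0 * wn - 5.0, sample_id="r")])
        mid = wn[:-1] + 1.0
        out = resample_to_grid(c, mid)
        np.testing.assert_allclose(out.spectra[0].intensities, 3.0 * mid - 5.0,
                                   rtol=1e-12)

    def test_no_extrapolation(self, small_collection):
        with pytest.raises(ValueError, match="outside"):
            resample_to_grid(small_collection, np.array([700.0, 800.0]))

    def test_band_amplitude_survives_regridding(self):
        """Upsampling 2 -> 1 cm^-1 perturbs a band amplitude by < 1%.

        Oracle: the same Gaussian sampled analytically on the dense grid
        and pushed through the identical filter, so only the linear
        interpolation error of resample_to_grid is measured.
        """
        from oxspectra import SGFilterSpec

        coarse = np.arange(800.0, 4000.1, 2.0)
        gauss = lambda x: np.exp(-((x - 1740.0) ** 2) / (2 * 8.0**2))
        c = SpectraCollection([Spectrum(coarse, gauss(coarse), sample_id="g")])
        dense = np.arange(800.0, 4000.1, 1.0)
        out = resample_to_grid(c, dense)

        def amp(spec):
            d = second_derivative(spec.with_intensities(spec.intensities,
                                                        kind="normalized"),
                                  SGFilterSpec(window=41))
            return band_amplitude(d, BandDef("co", 1740.0))

        a_oracle = amp(Spectrum(dense, gauss(dense), sample_id="o"))
        a_interp = amp(out.spectra[0])
        assert abs(a_interp / a_oracle - 1.0) < 0.01
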