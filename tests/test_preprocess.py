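import numpy as np
import pytest
from hypothesis import given, strategies as st

from ibernir.preprocess import (
    DegenerateSpectrumError,
    PretreatmentPipeline,
    PretreatmentStep,
    apply_pipeline,
    detrend,
    get_preset,
    savgol_derivative,
    snv,
    to_absorbance,
)
from ibernir.spectra_io import SpectraError, SpectraSet

from conftest import make_small_set


def _from_matrix(X, lo=1000.0, step=1.0, mode="absorbance"):
    X = np.atleast_2d(np.asarray(X, dtype=float))
    wl = lo + step * np.arange(X.shape[1])
    return SpectraSet(wavelengths=wl, X=X, mode=mode)


class TestAbsorbance:
    @pytest.mark.parametrize("r, expected", [(1.0, 0.0), (0.01, 2.0), (0.1, 1.0)])
    def test_log_reciprocal_values(self, r, expected):
        s = _from_matrix([[r, r]], mode="reflectance")
        out = to_absorbance(s)
        assert out.mode == "absorbance"
        np.testing.assert_allclose(out.X, expected, atol=1e-12)

    def test_requires_reflectance_mode(self, small_set):
        with pytest.raises(SpectraError, match="reflectance"):
            to_absorbance(small_set)  # small_set is already absorbance


class TestSNV:
    def test_known_three_point_spectrum(self):
        out = snv(_from_matrix([[2.0, 4.0, 6.0]]))
        np.testing.assert_allclose(out.X, [[-1.0, 0.0, 1.0]], atol=1e-14)

    def test_constant_spectrum_errors_with_sample_name(self):
        s = _from_matrix([[5.0, 5.0, 5.0, 5.0]])
        with pytest.raises(DegenerateSpectrumError, match="S001"):
            snv(s)

    def test_output_rows_standardized_and_idempotent(self):
        rng = np.random.default_rng(42)
        s = _from_matrix(0.5 + 0.1 * rng.standard_normal((5, 801)))
        out = snv(s)
        np.testing.assert_allclose(out.X.mean(axis=1), 0, atol=1e-12)
        np.testing.assert_allclose(out.X.std(axis=1, ddof=1), 1, atol=1e-12)
        twice = snv(out)
        np.testing.assert_allclose(twice.X, out.X, atol=1e-10)


class TestDetrend:
    def test_annihilates_own_degree_polynomial(self):
        wl = 1000.0 + np.arange(50)
        X = (3 + 0.2 * wl + 0.01 * wl**2)[None, :]
        out = detrend(SpectraSet(wavelengths=wl, X=X, mode="absorbance"), 2)
        assert np.max(np.abs(out.X)) < 1e-9

    def test_degree_zero_is_mean_centering(self):
        s = make_small_set()
        out = detrend(s, 0)
        np.testing.assert_allclose(
            out.X, s.X - s.X.mean(axis=1, keepdims=True), atol=1e-12
        )

    def test_matches_normal_equations_oracle(self):
        # quadratic + sinusoid: residual must equal the sinusoid minus its
        # best quadratic approximation, solved independently by lstsq on
        # the raw-wavelength Vandermonde basis
        wl = 1000.0 + np.arange(120)
        spectrum = 1 + 0.01 * wl + 1e-5 * wl**2 + 0.3 * np.sin(wl / 7.0)
        s = SpectraSet(wavelengths=wl, X=spectrum[None, :], mode="absorbance")
        out = detrend(s, 2)
        V = np.vander(wl, 3, increasing=True)
        beta, *_ = np.linalg.lstsq(V, spectrum, rcond=None)
        expected = spectrum - V @ beta
        np.testing.assert_allclose(out.X[0], expected, atol=1e-9)

    def test_is_linear_projection(self):
        rng = np.random.default_rng(3)
        x, y = rng.standard_normal((2, 40))
        wl = 1000.0 + np.arange(40)

        def dt(v):
            return detrend(
                SpectraSet(wavelengths=wl, X=v[None, :], mode="absorbance"), 2
            ).X[0]

        np.testing.assert_allclose(
            dt(2.5 * x - 1.2 * y), 2.5 * dt(x) - 1.2 * dt(y), atol=1e-9
        )

    def test_degree_exceeding_grid_errors(self):
        with pytest.raises(SpectraError, match="degree"):
            detrend(_from_matrix([[1.0, 2.0, 3.0]]), 3)


class TestSavgolDerivative:
    def test_first_derivative_exact_on_linear(self):
        wl = 1000.0 + np.arange(30)
        X = (0.7 + 0.013 * wl)[None, :]
        out = savgol_derivative(
            SpectraSet(wavelengths=wl, X=X, mode="absorbance"),
            PretreatmentStep("savgol", (1, 4, 4, 1)),
        )
        np.testing.assert_allclose(out.X, 0.013, atol=1e-12)
        assert out.mode == "derivative"
        assert out.n_wavelengths == 30 - 8

    def test_second_derivative_exact_on_quadratic(self):
        wl = np.arange(40, dtype=float)
        c = 0.004
        X = (c * wl**2)[None, :]
        out = savgol_derivative(
            SpectraSet(wavelengths=1000 + wl, X=X, mode="absorbance"),
            PretreatmentStep("savgol", (2, 5, 5, 2)),
        )
        np.testing.assert_allclose(out.X, 2 * c, atol=1e-10)

    def test_derivative_scaling_is_per_nm(self):
        # same underlying function sampled at 1 nm and 2 nm must give the
        # same derivative values at shared interior points
        f = lambda wl: 0.5 + 0.02 * (wl - 1000) + 1e-4 * (wl - 1000) ** 2
        fine = 1000.0 + np.arange(41)
        coarse = 1000.0 + 2.0 * np.arange(21)
        step = PretreatmentStep("savgol", (1, 4, 4, 2))
        d_fine = savgol_derivative(
            SpectraSet(wavelengths=fine, X=f(fine)[None], mode="absorbance"), step
        )
        d_coarse = savgol_derivative(
            SpectraSet(wavelengths=coarse, X=f(coarse)[None], mode="absorbance"), step
        )
        shared = np.intersect1d(d_fine.wavelengths, d_coarse.wavelengths)
        i = np.isin(d_fine.wavelengths, shared)
        j = np.isin(d_coarse.wavelengths, shared)
        np.testing.assert_allclose(d_fine.X[0, i], d_coarse.X[0, j], atol=1e-10)

    def test_smoothing_preserves_polynomials(self):
        wl = 1000.0 + np.arange(25)
        X = (1 + 0.01 * wl - 3e-6 * wl**2)[None, :]
        out = savgol_derivative(
            SpectraSet(wavelengths=wl, X=X, mode="absorbance"),
            PretreatmentStep("savgol", (0, 4, 4, 2)),
        )
        np.testing.assert_allclose(out.X, X[:, 4:-4], atol=1e-9)

    def test_non_uniform_grid_errors(self):
        wl = np.array([1000.0, 1001, 1002, 1004, 1008, 1016, 1032, 1064, 1128, 1256])
        s = SpectraSet(wavelengths=wl, X=np.ones((1, 10)), mode="absorbance")
        with pytest.raises(SpectraError, match="uniform"):
            savgol_derivative(s, PretreatmentStep("savgol", (1, 4, 4, 1)))

    def test_asymmetric_kernel_rejected_at_construction(self):
        with pytest.raises(ValueError, match="symmetric"):
            PretreatmentStep("savgol", (1, 4, 5, 1))


class TestPipeline:
    def test_snv_de_preset_is_snv_then_detrend(self):
        s = make_small_set(n=4, p=20)
        via_preset = apply_pipeline(s, "SNV-DE")
        stepwise = detrend(snv(s), 2)
        np.testing.assert_allclose(via_preset.X, stepwise.X, atol=1e-12)
        assert via_preset.provenance[-2:] == ["snv", "detrend(2)"]

    def test_none_preset_is_identity(self, small_set):
        out = apply_pipeline(small_set, "none")
        np.testing.assert_array_equal(out.X, small_set.X)

    def test_full_winning_preset_composition(self):
        rng = np.random.default_rng(9)
        wl = 1000.0 + np.arange(801)
        R = np.clip(0.3 + 0.05 * rng.standard_normal((3, 801)), 0.05, 0.95)
        s = SpectraSet(wavelengths=wl, X=R, mode="reflectance")
        out = apply_pipeline(s, "SNV-DE SG 1,4,4,1")
        assert out.n_wavelengths == 793
        assert out.mode == "derivative"
        stepwise = savgol_derivative(
            detrend(snv(to_absorbance(s)), 2),
            PretreatmentStep("savgol", (1, 4, 4, 1)),
        )
        np.testing.assert_allclose(out.X, stepwise.X, atol=1e-12)

    def test_named_presets_convert_reflectance_first(self):
        s = make_small_set(mode="reflectance", p=20)
        out = apply_pipeline(s, "SNV-DE")
        assert out.provenance[0] == "absorbance"

    def test_unknown_preset_errors(self, small_set):
        with pytest.raises(KeyError, match="unknown"):
            apply_pipeline(small_set, "OSC")

    def test_step_order_constraints(self):
        with pytest.raises(ValueError, match="first"):
            PretreatmentPipeline(
                [PretreatmentStep("snv"), PretreatmentStep("absorbance")]
            )
        with pytest.raises(ValueError, match="last"):
            PretreatmentPipeline(
                [PretreatmentStep("savgol", (1, 4, 4, 1)), PretreatmentStep("snv")]
            )

    @given(
        a=st.floats(0.2, 5.0),
        b=st.floats(-0.5, 0.5),
    )
    def test_snv_removes_affine_scatter_exactly(self, a, b):
        # two samples sharing one underlying spectrum, one affinely
        # scattered: SNV then detrend must map both to the same output
        rng = np.random.default_rng(12)
        base = 0.5 + 0.1 * rng.standard_normal(60)
        s = _from_matrix(np.vstack([base, a * base + b]))
        out = apply_pipeline(s, get_preset("SNV-DE"))
        np.testing.assert_allclose(out.X[0], out.X[1], atol=1e-9)
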