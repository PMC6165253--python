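"""Polarimetric core: basis transform, dB conversion, Yamaguchi, RVI, span."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from polcropsar.polsar import (
    CHANNEL_NAMES,
    C3Field,
    _CHANNEL_STATES,
    _JONES,
    build_basis_transform,
    c3_matrices_to_params,
    c3_params_to_matrices,
    c3_to_intensity,
    intensity_to_db,
    rvi,
    span,
    t3_to_c3,
    yamaguchi4,
)

from conftest import coherent_c3, random_psd_matrices


def jones_oracle(sinclair: np.ndarray) -> np.ndarray:
    """Independent brute-force evaluation of |q^T S p|^2 per channel."""
    s = np.asarray(sinclair, dtype=complex)
    return np.array(
        [abs(_JONES[rx] @ s @ _JONES[tx]) ** 2 for rx, tx in _CHANNEL_STATES]
    )


TRIHEDRAL = np.eye(2, dtype=complex)
DIHEDRAL = np.diag([1.0, -1.0]).astype(complex)


class TestBasisTransform:
    def test_channel_order_documented(self):
        assert CHANNEL_NAMES == ("hh", "vv", "++45", "--45", "ll", "rr", "h+45", "hl", "+45l")

    def test_hh_vv_rows_single_coefficient(self):
        """hh/vv channels are pure C11/C33 picks (clean rows of the transform)."""
        tm = build_basis_transform()
        expected_hh = np.zeros(9)
        expected_hh[0] = 1.0
        np.testing.assert_allclose(tm.M[0], expected_hh, atol=1e-12)
        expected_vv = np.zeros(9)
        expected_vv[2] = 1.0
        np.testing.assert_allclose(tm.M[1], expected_vv, atol=1e-12)

    def test_inverse_exact(self):
        tm = build_basis_transform()
        assert np.abs(tm.M @ tm.B - np.eye(9)).max() < 1e-10

    def test_zero_input_zero_output(self):
        tm = build_basis_transform()
        np.testing.assert_array_equal(tm.M @ np.zeros(9), np.zeros(9))

    def test_trihedral_channel_pattern(self):
        """Trihedral maps to intensities prop. to (1,1,1,1,0,0,1/2,1/2,1/2)."""
        expected = np.array([1, 1, 1, 1, 0, 0, 0.5, 0.5, 0.5])
        np.testing.assert_allclose(jones_oracle(TRIHEDRAL), expected, atol=1e-12)
        p = c3_to_intensity(coherent_c3(TRIHEDRAL))
        np.testing.assert_allclose(p.channels[0, 0], expected, atol=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_jones_oracle_on_coherent_targets(self, seed):
        """M applied to C3 of a deterministic target equals direct |q^T S p|^2."""
        rng = np.random.default_rng(seed)
        s01 = rng.normal() + 1j * rng.normal()
        s = np.array(
            [
                [rng.normal() + 1j * rng.normal(), s01],
                [s01, rng.normal() + 1j * rng.normal()],
            ]
        )
        p = c3_to_intensity(coherent_c3(s))
        np.testing.assert_allclose(p.channels[0, 0], jones_oracle(s), atol=1e-10)

    def test_roundtrip_on_random_psd(self, psd_1000):
        tm = build_basis_transform()
        params = c3_matrices_to_params(psd_1000)
        back = (params @ tm.M.T) @ tm.B.T
        scale = np.abs(params).max(axis=1, keepdims=True)
        assert (np.abs(back - params) / scale).max() < 1e-10

    def test_intensities_nonnegative_on_psd(self, psd_1000):
        tm = build_basis_transform()
        intens = c3_matrices_to_params(psd_1000) @ tm.M.T
        assert intens.min() > -1e-10 * np.abs(intens).max()

    def test_hh_vv_agree_with_c3_diagonal(self, psd_1000):
        f = C3Field(psd_1000.reshape(10, 100, 3, 3))
        p = c3_to_intensity(f)
        np.testing.assert_allclose(p.channels[..., 0], f.hh, rtol=1e-12)
        np.testing.assert_allclose(p.channels[..., 1], f.vv, rtol=1e-12)

    def test_scale_constant_applied(self):
        tm = build_basis_transform(scale=0.25)
        p = c3_to_intensity(coherent_c3(TRIHEDRAL), transform=tm)
        np.testing.assert_allclose(
            p.channels[0, 0], 0.25 * np.array([1, 1, 1, 1, 0, 0, 0.5, 0.5, 0.5]), atol=1e-12
        )


class TestDbConversion:
    def test_closed_form_values(self):
        p = c3_to_intensity(coherent_c3(TRIHEDRAL))
        p.channels = np.array([[[1.0, 100.0, 0.0, 10.0, 1e-3, 1.0, 1.0, 1.0, 1.0]]])
        sig = intensity_to_db(p, floor_db=-50.0)
        np.testing.assert_allclose(
            sig.channels[0, 0, :5], [0.0, 20.0, -50.0, 10.0, -30.0], atol=1e-12
        )

    def test_finite_everywhere(self, psd_1000):
        f = C3Field(psd_1000.reshape(10, 100, 3, 3))
        sig = intensity_to_db(c3_to_intensity(f))
        assert np.isfinite(sig.channels).all()


class TestYamaguchi:
    def test_trihedral_pure_surface(self):
        y = yamaguchi4(coherent_c3(TRIHEDRAL))
        assert y.ps[0, 0] == pytest.approx(y.span[0, 0], rel=1e-12)
        assert y.pd[0, 0] == y.pv[0, 0] == y.pc[0, 0] == 0.0
        assert y.span[0, 0] == pytest.approx(2.0)

    def test_dihedral_pure_double_bounce(self):
        y = yamaguchi4(coherent_c3(DIHEDRAL))
        assert y.pd[0, 0] == pytest.approx(y.span[0, 0], rel=1e-12)
        assert y.ps[0, 0] == y.pv[0, 0] == y.pc[0, 0] == 0.0

    def test_conservation_and_nonnegativity_random_psd(self, psd_1000):
        f = C3Field(psd_1000.reshape(10, 100, 3, 3))
        y = yamaguchi4(f)
        total = y.ps + y.pd + y.pv + y.pc
        np.testing.assert_allclose(total, y.span, rtol=1e-6)
        for comp in (y.ps, y.pd, y.pv, y.pc):
            assert comp.min() >= 0.0

    def test_nonpsd_pixel_masked_and_counted(self):
        bad = np.diag([1.0, -0.5, 1.0]).astype(complex)  # negative eigenvalue
        good = np.eye(3, dtype=complex)
        f = C3Field.__new__(C3Field)  # bypass input validation to inject bad pixel
        f.data = np.stack([bad, good])[None]
        f.looks = 1
        f.mask = np.ones((1, 2), bool)
        f.pixel_spacing = (1.0, 1.0)
        y = yamaguchi4(f)
        assert y.n_nonpsd == 1
        assert not y.mask[0, 0] and y.mask[0, 1]


class TestRviSpan:
    def test_rvi_zero_without_crosspol(self):
        assert rvi(coherent_c3(TRIHEDRAL))[0, 0] == 0.0

    def test_rvi_dipole_cloud_is_one(self):
        c = np.diag([1.0, 2.0 / 3.0, 1.0]).astype(complex)  # <|HV|^2> = 1/3
        assert rvi(C3Field(c[None, None]))[0, 0] == pytest.approx(1.0)

    def test_rvi_upper_bound_attained(self):
        c = np.diag([0.0, 2.0, 0.0]).astype(complex)
        assert rvi(C3Field(c[None, None]))[0, 0] == pytest.approx(4.0)

    def test_rvi_bounds_and_monotonicity(self):
        hv = np.linspace(0.0, 5.0, 50)
        mats = np.zeros((50, 1, 3, 3), complex)
        mats[..., 0, 0] = 1.0
        mats[..., 2, 2] = 1.0
        mats[..., 1, 1] = 2.0 * hv[:, None]
        vals = rvi(C3Field(mats)).compressed()
        assert (vals >= 0).all() and (vals <= 4).all()
        assert (np.diff(vals) > 0).all()  # strictly increasing with <|HV|^2>

    def test_zero_span_pixel_masked(self):
        c = np.zeros((1, 1, 3, 3), complex)
        assert rvi(C3Field(c)).mask[0, 0]

    def test_span_equals_trace(self, psd_1000):
        f = C3Field(psd_1000[:100].reshape(10, 10, 3, 3))
        np.testing.assert_allclose(
            span(f), np.einsum("...ii->...", psd_1000[:100]).real.reshape(10, 10), rtol=1e-12
        )


class TestT3ToC3:
    def test_trace_preserved_random_hermitian(self):
        rng = np.random.default_rng(5)
        a = rng.normal(size=(20, 3, 3)) + 1j * rng.normal(size=(20, 3, 3))
        t3 = (a + a.conj().swapaxes(-1, -2)) / 2.0
        t3 = t3 + 4.0 * np.eye(3)  # keep diagonals positive
        c3 = t3_to_c3(t3.reshape(4, 5, 3, 3))
        np.testing.assert_allclose(
            span(c3), np.einsum("...ii->...", t3).real.reshape(4, 5), atol=1e-10
        )

    def test_trihedral_t3(self):
        c3 = t3_to_c3(np.diag([2.0, 0.0, 0.0]).astype(complex))
        expect = np.zeros((3, 3), complex)
        expect[0, 0] = expect[2, 2] = expect[0, 2] = expect[2, 0] = 1.0
        np.testing.assert_allclose(c3.data[0, 0], expect, atol=1e-12)

    def test_zero_maps_to_zero(self):
        np.testing.assert_array_equal(
            t3_to_c3(np.zeros((3, 3), complex)).data, np.zeros((1, 1, 3, 3))
        )

    def test_non_hermitian_rejected(self):
        bad = np.zeros((3, 3), complex)
        bad[0, 1] = 1.0  # missing conjugate partner
        with pytest.raises(ValueError, match="Hermitian"):
            t3_to_c3(bad)


class TestC3FieldValidation:
    def test_rejects_non_hermitian(self):
        bad = np.zeros((1, 1, 3, 3), complex)
        bad[0, 0, 0, 1] = 1.0
        with pytest.raises(ValueError, match="Hermitian"):
            C3Field(bad)

    def test_rejects_negative_diagonal(self):
        bad = np.zeros((1, 1, 3, 3), complex)
        bad[0, 0, 0, 0] = -1.0
        with pytest.raises(ValueError, match=">= 0"):
            C3Field(bad)

    def test_rejects_bad_looks_and_mask(self):
        ok = np.zeros((2, 2, 3, 3), complex)
        with pytest.raises(ValueError, match="looks"):
            C3Field(ok, looks=0)
        with pytest.raises(ValueError, match="mask"):
            C3Field(ok, mask=np.ones((3, 3), bool))


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_psd_pixel_properties(seed):
    """Any PSD pixel: non-negative intensities, exact power conservation."""
    mat = random_psd_matrices(1, seed=seed)
    f = C3Field(mat[None])
    p = c3_to_intensity(f)
    assert p.channels.min() >= 0.0
    y = yamaguchi4(f)
    total = y.ps + y.pd + y.pv + y.pc
    np.testing.assert_allclose(total, y.span, rtol=1e-6)
    v = rvi(f)[0, 0]
    if not np.ma.is_masked(v):
        assert -1e-12 <= v <= 4.0 + 1e-12
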