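"""Polarimetric data model and SAR-side feature extraction.

The central container is :class:`C3Field`, a per-pixel 3x3 Hermitian
covariance matrix field in the lexicographic basis (S_HH, sqrt2*S_HV, S_VV).
From it this module derives

* the nine-channel polarization-basis intensity vector (Hoekman transform):
  backscatter intensities on the linear (h, v), +/-45 deg linear and
  left/right circular bases, a lossless real re-parametrisation of C3 that
  stacks like optical spectral bands;
* its dB form, the backscattering-coefficient vector sigma;
* the Yamaguchi four-component power decomposition (surface, double-bounce,
  volume, helix);
* the radar vegetation index (RVI) and total power (span).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "C3Field",
    "Intensity9",
    "SigmaDb9",
    "BasisTransformMatrix",
    "YamaguchiPowers",
    "CHANNEL_NAMES",
    "build_basis_transform",
    "c3_to_intensity",
    "intensity_to_db",
    "yamaguchi4",
    "rvi",
    "span",
    "t3_to_c3",
    "c3_params_to_matrices",
    "c3_matrices_to_params",
]

#: Fixed channel order of the intensity vector.  Each name is
#: "<receive><transmit>" on the bases h, v, + (+45 deg), - (-45 deg),
#: l (left circular), r (right circular).
CHANNEL_NAMES = ("hh", "vv", "++45", "--45", "ll", "rr", "h+45", "hl", "+45l")

#: Jones vectors of the six polarization states (backscatter alignment).
_JONES = {
    "h": np.array([1.0, 0.0], dtype=complex),
    "v": np.array([0.0, 1.0], dtype=complex),
    "+45": np.array([1.0, 1.0], dtype=complex) / np.sqrt(2.0),
    "-45": np.array([1.0, -1.0], dtype=complex) / np.sqrt(2.0),
    "l": np.array([1.0, 1.0j], dtype=complex) / np.sqrt(2.0),
    "r": np.array([1.0, -1.0j], dtype=complex) / np.sqrt(2.0),
}

#: (receive, transmit) state pairs in channel order.
_CHANNEL_STATES = (
    ("h", "h"),
    ("v", "v"),
    ("+45", "+45"),
    ("-45", "-45"),
    ("l", "l"),
    ("r", "r"),
    ("h", "+45"),
    ("h", "l"),
    ("+45", "l"),
)

_HERMITIAN_RTOL = 1e-9
_DIAG_NEG_TOL = -1e-12


@dataclass
class C3Field:
    """Field of per-pixel 3x3 Hermitian covariance matrices (lexicographic).

    Parameters
    ----------
    data
        Complex array of shape (rows, cols, 3, 3).
    looks
        Equivalent number of looks L >= 1.
    mask
        Boolean validity raster of shape (rows, cols); True = valid.
    pixel_spacing
        (row, col) pixel spacing metadata, arbitrary units.
    """

    data: np.ndarray
    looks: int = 1
    mask: np.ndarray | None = None
    pixel_spacing: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=complex)
        if self.data.ndim != 4 or self.data.shape[-2:] != (3, 3):
            raise ValueError(
                f"C3 data must have shape (rows, cols, 3, 3), got {self.data.shape}"
            )
        if self.looks < 1:
            raise ValueError(f"looks must be >= 1, got {self.looks}")
        if self.mask is None:
            self.mask = np.ones(self.data.shape[:2], dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.data.shape[:2]:
                raise ValueError("mask shape does not match data grid")
        self._validate()

    def _validate(self) -> None:
        d = self.data[self.mask]
        if d.size == 0:
            return
        herm_err = np.abs(d - d.conj().swapaxes(-1, -2)).max()
        scale = max(np.abs(d).max(), 1.0)
        if herm_err > _HERMITIAN_RTOL * scale:
            raise ValueError(
                f"C3 matrices not Hermitian within tolerance (max dev {herm_err:.3e})"
            )
        for i in range(3):
            d_ii = self.data[..., i, i].real
            if d_ii[self.mask].min(initial=0.0) < _DIAG_NEG_TOL:
                raise ValueError("C3 diagonal entries must be >= 0")
            # tiny negative diagonals from numerical noise are clipped
            self.data[..., i, i] = np.clip(d_ii, 0.0, None)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[:2]

    def diag(self, i: int) -> np.ndarray:
        return self.data[..., i, i].real

    @property
    def hh(self) -> np.ndarray:
        """<|S_HH|^2> raster."""
        return self.diag(0)

    @property
    def hv(self) -> np.ndarray:
        """<|S_HV|^2> raster (half of the lexicographic C22)."""
        return self.diag(1) / 2.0

    @property
    def vv(self) -> np.ndarray:
        """<|S_VV|^2> raster."""
        return self.diag(2)


@dataclass
class Intensity9:
    """Nine polarization-basis intensities per pixel, fixed channel order."""

    channels: np.ndarray  # (rows, cols, 9), non-negative on valid pixels
    mask: np.ndarray
    scale: float = 1.0
    names: tuple[str, ...] = CHANNEL_NAMES


@dataclass
class SigmaDb9:
    """dB form of the intensity vector: sigma = 10 log10(P)."""

    channels: np.ndarray  # (rows, cols, 9)
    mask: np.ndarray
    floor_db: float = -50.0
    names: tuple[str, ...] = CHANNEL_NAMES


@dataclass
class BasisTransformMatrix:
    """Linear map between C3 parameters and the 9 channel intensities.

    ``M`` maps the real parameter vector
    (C11, C22, C33, ReC12, ImC12, ReC13, ImC13, ReC23, ImC23)
    to the nine intensities; ``B = M^-1`` is the inverse direction
    (intensities back to covariance elements).  The physical 1/(4 pi)
    antenna-pattern prefactor is carried as the single ``scale`` constant
    (default 1): it cancels in dB differences, min-max normalization, PCA
    and every classifier downstream.
    """

    M: np.ndarray
    B: np.ndarray
    scale: float = 1.0
    param_names: tuple[str, ...] = (
        "C11", "C22", "C33", "ReC12", "ImC12", "ReC13", "ImC13", "ReC23", "ImC23",
    )
    channel_names: tuple[str, ...] = CHANNEL_NAMES


@dataclass
class YamaguchiPowers:
    """Surface / double-bounce / volume / helix powers and their sum."""

    ps: np.ndarray
    pd: np.ndarray
    pv: np.ndarray
    pc: np.ndarray
    span: np.ndarray
    mask: np.ndarray
    n_nonpsd: int = 0


# ---------------------------------------------------------------------------
# parameter-vector helpers

def c3_matrices_to_params(c3: np.ndarray) -> np.ndarray:
    """Flatten (..., 3, 3) Hermitian matrices to 9 real parameters."""
    c3 = np.asarray(c3, dtype=complex)
    return np.stack(
        [
            c3[..., 0, 0].real,
            c3[..., 1, 1].real,
            c3[..., 2, 2].real,
            c3[..., 0, 1].real,
            c3[..., 0, 1].imag,
            c3[..., 0, 2].real,
            c3[..., 0, 2].imag,
            c3[..., 1, 2].real,
            c3[..., 1, 2].imag,
        ],
        axis=-1,
    )


def c3_params_to_matrices(params: np.ndarray) -> np.ndarray:
    """Inverse of :func:`c3_matrices_to_params`."""
    p = np.asarray(params, dtype=float)
    out = np.zeros(p.shape[:-1] + (3, 3), dtype=complex)
    out[..., 0, 0] = p[..., 0]
    out[..., 1, 1] = p[..., 1]
    out[..., 2, 2] = p[..., 2]
    out[..., 0, 1] = p[..., 3] + 1j * p[..., 4]
    out[..., 0, 2] = p[..., 5] + 1j * p[..., 6]
    out[..., 1, 2] = p[..., 7] + 1j * p[..., 8]
    out[..., 1, 0] = out[..., 0, 1].conj()
    out[..., 2, 0] = out[..., 0, 2].conj()
    out[..., 2, 1] = out[..., 1, 2].conj()
    return out


def _channel_form(receive: str, transmit: str) -> np.ndarray:
    """Lexicographic weight vector u such that DN = u^H C3 u.

    For receive state q and transmit state p, the backscattered amplitude is
    A = q^T S p = w^T k with k = (S_HH, sqrt2 S_HV, S_VV) and
    w = (q1 p1, (q1 p2 + q2 p1)/sqrt2, q2 p2); then E|A|^2 = u^H C3 u with
    u = conj(w).  Reciprocity (S_HV = S_VH) makes the channel symmetric in
    (p, q).
    """
    p, q = _JONES[transmit], _JONES[receive]
    w = np.array(
        [q[0] * p[0], (q[0] * p[1] + q[1] * p[0]) / np.sqrt(2.0), q[1] * p[1]],
        dtype=complex,
    )
    return w.conj()


def build_basis_transform(scale: float = 1.0) -> BasisTransformMatrix:
    """Construct the 9x9 polarization-basis transform analytically.

    Each row of M is the real linear form expressing one channel intensity
    DN_pq = <|q^T S p|^2> in the 9 real C3 parameters, derived from the
    Jones vectors of the six polarization states rather than transcribed
    numerically.
    """
    basis_params = np.eye(9)
    basis_mats = c3_params_to_matrices(basis_params)  # (9, 3, 3)
    M = np.empty((9, 9))
    for i, (rx, tx) in enumerate(_CHANNEL_STATES):
        u = _channel_form(rx, tx)
        M[i] = np.einsum("i,kij,j->k", u.conj(), basis_mats, u).real
    M *= scale
    B = np.linalg.inv(M)
    assert np.abs(M @ B - np.eye(9)).max() < 1e-10, "basis transform not invertible"
    return BasisTransformMatrix(M=M, B=B, scale=scale)


_DEFAULT_TRANSFORM = build_basis_transform()


def c3_to_intensity(
    c3: C3Field, transform: BasisTransformMatrix | None = None
) -> Intensity9:
    """Apply the polarization-basis transform: P = M c per pixel.

    Physically valid (PSD) input yields non-negative intensities; values
    below -1e-9 * span trigger a warning before being clipped to zero.
    """
    tm = transform if transform is not None else _DEFAULT_TRANSFORM
    params = c3_matrices_to_params(c3.data)
    intens = params @ tm.M.T
    sp = span(c3)
    neg = intens < (-1e-9 * np.maximum(sp, 1e-300))[..., None]
    neg &= c3.mask[..., None]
    if neg.any():
        warnings.warn(
            f"{int(neg.sum())} negative intensities beyond tolerance clipped "
            "(input not PSD?)",
            stacklevel=2,
        )
    np.clip(intens, 0.0, None, out=intens)
    return Intensity9(channels=intens, mask=c3.mask.copy(), scale=tm.scale)


def intensity_to_db(p: Intensity9, floor_db: float = -50.0) -> SigmaDb9:
    """Convert intensities to backscattering-coefficient form, 10 log10(P).

    Non-positive intensities map to ``floor_db`` so that downstream
    normalization sees finite values everywhere.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma = 10.0 * np.log10(p.channels)
    sigma = np.where(p.channels > 0.0, sigma, floor_db)
    return SigmaDb9(channels=sigma, mask=p.mask.copy(), floor_db=floor_db)


def span(c3: C3Field) -> np.ndarray:
    """Total power <|S_HH|^2> + 2<|S_HV|^2> + <|S_VV|^2> = trace(C3)."""
    return np.einsum("...ii->...", c3.data).real


def rvi(c3: C3Field) -> np.ma.MaskedArray:
    """Radar vegetation index, 8 <|S_HV|^2> / span, bounded in [0, 4].

    0 for depolarization-free targets, 1 for a random dipole cloud,
    approaching 4 as cross-pol dominates.  Zero-span pixels are masked.
    """
    sp = span(c3)
    valid = c3.mask & (sp > 0.0)
    out = np.zeros_like(sp)
    np.divide(8.0 * c3.hv, sp, out=out, where=valid)
    return np.ma.MaskedArray(out, mask=~valid)


# ---------------------------------------------------------------------------
# Yamaguchi four-component decomposition

# volume scattering covariance models (lexicographic basis, unit trace)
_CV_MID = np.array([[3, 0, 1], [0, 2, 0], [1, 0, 3]], dtype=complex) / 8.0
_CV_HH = np.array([[8, 0, 2], [0, 4, 0], [2, 0, 3]], dtype=complex) / 15.0
_CV_VV = np.array([[3, 0, 2], [0, 4, 0], [2, 0, 8]], dtype=complex) / 15.0


def yamaguchi4(c3: C3Field) -> YamaguchiPowers:
    """Four-component power decomposition (surface/double/volume/helix).

    The 2005 four-component scheme extends the Freeman-Durden three-component
    model with a helix term for non-reflection-symmetric targets:

    * helix power Pc = 2 |Im(<S_HH S_HV*> + <S_HV S_VV*>)|, capped at
      2 <|S_HV|^2> so the remaining cross-pol power is non-negative;
    * the volume covariance model is picked by the co-pol ratio
      10 log10(<|S_VV|^2> / <|S_HH|^2>) with branch thresholds at +/-2 dB,
      and its contribution sized to absorb all remaining cross-pol power;
    * the remaining matrix is split into surface (Ps) and double-bounce (Pd)
      terms, fixing alpha = -1 when the remaining Re<S_HH S_VV*> indicates
      surface dominance and beta = 1 otherwise;
    * negative Ps/Pd (over-subtracted volume) are clipped to zero with the
      deficit reassigned to the partner term, and Pv is capped so that
      Ps + Pd + Pv + Pc equals the span exactly on every pixel.

    Non-PSD pixels (negative eigenvalues beyond tolerance) are masked out and
    counted in ``n_nonpsd``.
    """
    c = c3.data
    mask = c3.mask.copy()

    eig = np.linalg.eigvalsh(np.where(mask[..., None, None], c, np.eye(3)))
    sp_all = span(c3)
    nonpsd = mask & (eig[..., 0] < -1e-9 * np.maximum(sp_all, 1e-300))
    n_nonpsd = int(nonpsd.sum())
    mask &= ~nonpsd

    hh = c[..., 0, 0].real
    vv = c[..., 2, 2].real
    hv = c[..., 1, 1].real / 2.0
    c13 = c[..., 0, 2]
    # <S_HH S_HV*> = C12/sqrt2, <S_HV S_VV*> = C23/sqrt2
    im_cross = (c[..., 0, 1].imag + c[..., 1, 2].imag) / np.sqrt(2.0)

    sp = hh + 2.0 * hv + vv

    fc = np.minimum(2.0 * np.abs(im_cross), 2.0 * hv)
    hv_rem = np.maximum(hv - fc / 4.0, 0.0)

    # volume branch by co-pol ratio (+/-2 dB); zeros fall in the outer branches
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio_db = 10.0 * (np.log10(np.maximum(vv, 1e-300)) - np.log10(np.maximum(hh, 1e-300)))
    branch = np.where(ratio_db < -2.0, 0, np.where(ratio_db > 2.0, 2, 1))

    cv_stack = np.stack([_CV_HH, _CV_MID, _CV_VV])  # (3, 3, 3)
    cv = cv_stack[branch]  # (..., 3, 3)
    cv_hv = cv[..., 1, 1].real / 2.0
    fv = hv_rem / cv_hv  # volume sized to absorb remaining cross-pol exactly

    pv = fv.copy()
    pc = fc.copy()
    # cap volume + helix at the total power
    over = pv + pc > sp
    pv = np.where(over, sp - pc, pv)
    fv_eff = np.where(over, pv, fv)

    # remaining surface + double-bounce system
    s11 = hh - fv_eff * cv[..., 0, 0].real - fc / 4.0
    s33 = vv - fv_eff * cv[..., 2, 2].real - fc / 4.0
    s13 = c13 - fv_eff * cv[..., 0, 2] - (-fc / 4.0)  # helix C13 = -fc/4

    tiny = 1e-30
    surface_dom = s13.real >= 0.0
    denom_s = s11 + s33 + 2.0 * s13.real  # alpha = -1 branch
    denom_d = s11 + s33 - 2.0 * s13.real  # beta = +1 branch
    det_rem = s11 * s33 - np.abs(s13) ** 2

    with np.errstate(divide="ignore", invalid="ignore"):
        fd_s = np.where(np.abs(denom_s) > tiny, det_rem / denom_s, 0.0)
        fs_d = np.where(np.abs(denom_d) > tiny, det_rem / denom_d, 0.0)

    # closed forms (Ps + Pd = s11 + s33 exactly; cross-pol fully absorbed):
    # alpha = -1 branch: Pd = fd (1 + |alpha|^2) = 2 fd, Ps = s11 + s33 - 2 fd
    # beta  = +1 branch: Ps = 2 fs,                      Pd = s11 + s33 - 2 fs
    ps = np.where(surface_dom, s11 + s33 - 2.0 * fd_s, 2.0 * fs_d)
    pd_ = np.where(surface_dom, 2.0 * fd_s, s11 + s33 - 2.0 * fs_d)

    rem = np.maximum(sp - pv - pc, 0.0)
    # clip negatives; deficit goes to the partner so the sum stays exact
    ps_neg = ps < 0.0
    pd_neg = pd_ < 0.0
    ps = np.where(ps_neg, 0.0, ps)
    pd_ = np.where(ps_neg, rem, pd_)
    pd_ = np.where(pd_neg, 0.0, pd_)
    ps = np.where(pd_neg & ~ps_neg, rem, ps)
    # final exact renormalisation of the surface/double pair
    pair = ps + pd_
    with np.errstate(divide="ignore", invalid="ignore"):
        scale = np.where(pair > tiny, rem / np.maximum(pair, tiny), 0.0)
    ps = ps * scale
    pd_ = pd_ * scale
    # degenerate pair (both ~0) with leftover power: assign by dominance
    leftover = (pair <= tiny) & (rem > 0.0)
    ps = np.where(leftover & surface_dom, rem, ps)
    pd_ = np.where(leftover & ~surface_dom, rem, pd_)

    zero = ~mask
    for arr in (ps, pd_, pv, pc):
        arr[zero] = 0.0
    sp = np.where(mask, sp, 0.0)

    return YamaguchiPowers(ps=ps, pd=pd_, pv=pv, pc=pc, span=sp, mask=mask, n_nonpsd=n_nonpsd)


# ---------------------------------------------------------------------------

# Pauli -> lexicographic change of basis: k_lex = U k_pauli
_PAULI_TO_LEX = np.array(
    [
        [1.0, 1.0, 0.0],
        [0.0, 0.0, np.sqrt(2.0)],
        [1.0, -1.0, 0.0],
    ],
    dtype=complex,
) / np.sqrt(2.0)


def t3_to_c3(
    t3: np.ndarray,
    looks: int = 1,
    mask: np.ndarray | None = None,
    pixel_spacing: tuple[float, float] = (1.0, 1.0),
) -> C3Field:
    """Convert a Pauli-basis coherency field T3 to a lexicographic C3Field.

    C3 = U T3 U^H with the standard fixed unitary; the trace (total power)
    is preserved to 1e-10.
    """
    t3 = np.asarray(t3, dtype=complex)
    if t3.ndim == 2:
        t3 = t3[None, None]
    herm_err = np.abs(t3 - t3.conj().swapaxes(-1, -2)).max()
    if herm_err > _HERMITIAN_RTOL * max(np.abs(t3).max(), 1.0):
        raise ValueError(f"T3 not Hermitian within tolerance (max dev {herm_err:.3e})")
    u = _PAULI_TO_LEX
    c3 = np.einsum("ij,...jk,lk->...il", u, t3, u.conj())
    return C3Field(data=c3, looks=looks, mask=mask, pixel_spacing=pixel_spacing)
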