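"""Optical-side feature extraction: NDVI, window entropy texture, band PCA.

Multispectral reflectance bands (R, G, B, NIR) carry the pigment/moisture
signal of crop canopies; NDVI summarises canopy density, a sliding-window
Shannon entropy summarises local texture, and a PCA across the bands removes
their strong mutual correlation before stacking with SAR features.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter
from sklearn.decomposition import PCA

log = logging.getLogger(__name__)

__all__ = ["OpticalBands", "TextureConfig", "PCAResult", "ndvi", "entropy_texture", "band_pca"]

BAND_ORDER = ("R", "G", "B", "NIR")


@dataclass
class OpticalBands:
    """Named co-registered reflectance rasters on one grid."""

    bands: dict[str, np.ndarray]
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        shapes = {b.shape for b in self.bands.values()}
        if len(shapes) != 1:
            raise ValueError(f"bands on different grids: {shapes}")
        (self.shape,) = shapes
        if self.mask is None:
            self.mask = np.ones(self.shape, dtype=bool)
        elif self.mask.shape != self.shape:
            raise ValueError("mask shape does not match bands")
        for name, b in self.bands.items():
            if not np.isfinite(b[self.mask]).all():
                raise ValueError(f"band {name!r} has non-finite values on valid pixels")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.bands[name]


@dataclass
class TextureConfig:
    """Sliding-window entropy parameters.

    window : odd side length of the centered window (pixels)
    bins : gray-level count of the histogram
    band : which reflectance band the texture is computed on
    """

    window: int = 7
    bins: int = 32
    band: str = "R"
    edge_mode: str = "reflect"

    def __post_init__(self) -> None:
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError(f"window must be odd and >= 3, got {self.window}")
        if self.bins < 2:
            raise ValueError(f"bins must be >= 2, got {self.bins}")


@dataclass
class PCAResult:
    """Kept principal components plus the full variance accounting."""

    components: np.ndarray        # (rows, cols, k) score rasters
    loadings: np.ndarray          # (k, n_vars), rows orthonormal
    explained_variance_ratio: np.ndarray  # all n_vars fractions, sums to 1
    n_kept: int
    mask: np.ndarray
    names: tuple[str, ...] = ()


def ndvi(red: np.ndarray, nir: np.ndarray, mask: np.ndarray | None = None) -> np.ma.MaskedArray:
    """Normalized difference vegetation index (NIR - R) / (NIR + R) in [-1, 1].

    Pixels where NIR + R == 0 are masked rather than propagated as NaN.
    """
    red = np.asarray(red, dtype=float)
    nir = np.asarray(nir, dtype=float)
    if red.shape != nir.shape:
        raise ValueError(f"grid mismatch: R {red.shape} vs NIR {nir.shape}")
    denom = nir + red
    valid = denom != 0.0
    if mask is not None:
        valid &= mask
    out = np.zeros_like(denom)
    np.divide(nir - red, denom, out=out, where=valid)
    return np.ma.MaskedArray(out, mask=~valid)


def entropy_texture(
    band: np.ndarray,
    cfg: TextureConfig | None = None,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Per-pixel Shannon entropy of the windowed gray-level histogram.

    Values are quantised into ``cfg.bins`` equal-width bins spanning the
    band's global valid min-max; within the centred ``cfg.window`` square the
    bin proportions p_i give H = -sum p_i log2 p_i, in [0, log2(bins)].
    A constant band (zero range) yields zero entropy everywhere.
    """
    cfg = cfg or TextureConfig()
    band = np.asarray(band, dtype=float)
    valid = np.ones(band.shape, bool) if mask is None else mask
    vals = band[valid]
    lo, hi = vals.min(), vals.max()
    if hi <= lo:
        log.warning("entropy_texture: constant band, entropy set to 0 everywhere")
        return np.zeros_like(band)
    # digitize to [0, bins-1]
    idx = np.clip(((band - lo) / (hi - lo) * cfg.bins).astype(int), 0, cfg.bins - 1)
    # per-bin occupancy proportions via a box filter on indicator rasters
    probs = np.empty(band.shape + (cfg.bins,))
    for b in range(cfg.bins):
        probs[..., b] = uniform_filter((idx == b).astype(float), size=cfg.window, mode=cfg.edge_mode)
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -np.sum(np.where(probs > 0.0, probs * np.log2(probs), 0.0), axis=-1)
    return np.clip(h, 0.0, np.log2(cfg.bins))


def _pca_of_layers(
    layers: np.ndarray,
    mask: np.ndarray,
    var_threshold: float,
    names_prefix: str,
    standardize: bool = False,
    min_components: int = 1,
) -> PCAResult:
    """PCA over valid pixels (observations) of stacked layers (variables).

    Shared by the optical-band and sigma-channel reductions.  Components are
    sign-fixed so each one's largest-magnitude loading is positive; the kept
    set is the smallest whose cumulative explained-variance fraction reaches
    ``var_threshold``.
    """
    rows, cols, n_vars = layers.shape
    x = layers[mask]
    if x.shape[0] < 2:
        raise ValueError("PCA needs at least 2 valid pixels")
    if standardize:
        sd = x.std(axis=0)
        sd[sd == 0.0] = 1.0
        x = x / sd
    p = PCA(n_components=n_vars, svd_solver="full")
    scores = p.fit_transform(x)
    evr = p.explained_variance_ratio_.copy()
    nz = p.explained_variance_ > 1e-12 * max(p.explained_variance_[0], 1e-300)
    cum = np.cumsum(evr)
    n_keep = int(np.searchsorted(cum, var_threshold - 1e-12) + 1)
    n_keep = max(n_keep, min(min_components, n_vars))
    if n_keep > nz.sum():
        warnings.warn("degenerate covariance: keeping all nonzero-variance components")
        n_keep = max(int(nz.sum()), 1)
    loadings = p.components_[:n_keep].copy()
    scores = scores[:, :n_keep].copy()
    # deterministic sign: largest-|loading| entry positive
    for i in range(n_keep):
        j = int(np.argmax(np.abs(loadings[i])))
        if loadings[i, j] < 0:
            loadings[i] *= -1.0
            scores[:, i] *= -1.0
    comp = np.zeros((rows, cols, n_keep))
    comp[mask] = scores
    names = tuple(f"{names_prefix}{i + 1}" for i in range(n_keep))
    return PCAResult(
        components=comp,
        loadings=loadings,
        explained_variance_ratio=evr,
        n_kept=n_keep,
        mask=mask.copy(),
        names=names,
    )


def band_pca(
    bands: OpticalBands,
    var_threshold: float = 0.99,
    standardize: bool = False,
    min_components: int = 1,
) -> PCAResult:
    """PCA of the optical bands; keeps components reaching ``var_threshold``.

    Bands are mean-centered but not rescaled by default (they share
    reflectance units); components are named Opband_pca1, Opband_pca2, ...
    """
    if len(bands.bands) < 2:
        raise ValueError("band_pca needs at least 2 bands")
    order = [b for b in BAND_ORDER if b in bands.bands]
    order += [b for b in bands.bands if b not in order]
    layers = np.stack([bands[b] for b in order], axis=-1)
    return _pca_of_layers(
        layers, bands.mask, var_threshold, "Opband_pca", standardize, min_components
    )
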