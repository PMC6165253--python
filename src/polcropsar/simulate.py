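"""Seeded simulator of labeled PolSAR + optical scenes.

Emulates the statistical structure the pipeline assumes: a rectangular
field mosaic of crop classes where each pixel's multilook covariance matrix
is complex-Wishart distributed around a class covariance (L looks of a
zero-mean circular complex Gaussian scattering vector) and each optical
reflectance is a truncated Gaussian in [0, 1].  No physical scattering
model is involved — speckle statistics and class separability are emulated,
not radiative transfer.

The default four-class preset is built so that the two data sources are
complementary by construction: the two rice classes share their optical
reflectances and differ only in the phase of <S_HH S_VV*> (visible in the
mixed-basis backscatter channels, invisible to RVI/span/Yamaguchi powers),
while lotus and grass share one covariance matrix and the R/NIR means (same
NDVI) and differ only in the G/B bands (visible to optical band PCA only).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .classify import ClassMap, TrainingSet
from .optical import OpticalBands
from .polsar import C3Field

__all__ = ["ClassSpec", "SimConfig", "Scene", "sample_wishart_c3", "generate_scene", "default_config"]


@dataclass
class ClassSpec:
    """One simulated land-cover class: SAR covariance + optical statistics."""

    name: str
    sigma: np.ndarray               # 3x3 Hermitian PSD covariance
    optical_mean: tuple[float, float, float, float]   # R, G, B, NIR in (0,1)
    optical_sd: tuple[float, float, float, float] = (0.03, 0.03, 0.03, 0.03)

    def __post_init__(self) -> None:
        self.sigma = np.asarray(self.sigma, dtype=complex)
        if self.sigma.shape != (3, 3):
            raise ValueError("sigma must be 3x3")
        if np.abs(self.sigma - self.sigma.conj().T).max() > 1e-9:
            raise ValueError(f"class {self.name!r}: sigma not Hermitian")
        if np.linalg.eigvalsh(self.sigma).min() < -1e-12:
            raise ValueError(f"class {self.name!r}: sigma not PSD")
        if not all(0.0 < m < 1.0 for m in self.optical_mean):
            raise ValueError(f"class {self.name!r}: reflectance means must be in (0,1)")


@dataclass
class SimConfig:
    """Scene geometry, class roster and noise level of a simulated scene."""

    classes: list[ClassSpec]
    looks: int = 9
    shape: tuple[int, int] = (160, 160)
    field_grid: tuple[int, int] = (8, 8)     # fields along rows, cols
    train_fields_per_class: int = 4
    seed: int = 42

    def __post_init__(self) -> None:
        if self.looks < 1:
            raise ValueError("looks must be >= 1")
        nf = self.field_grid[0] * self.field_grid[1]
        k = len(self.classes)
        if nf < k:
            raise ValueError(f"scene too small: {nf} fields for {k} classes")
        if self.train_fields_per_class * k >= nf:
            raise ValueError("no testing fields left after the training split")


@dataclass
class Scene:
    """A generated scene bundle: inputs plus ground truth and splits."""

    c3: C3Field
    optical: OpticalBands
    truth: ClassMap
    train: TrainingSet
    test: TrainingSet
    config: SimConfig
    field_ids: np.ndarray = field(repr=False, default=None)


def sample_wishart_c3(
    sigma: np.ndarray, looks: int, n: int, rng: np.random.Generator | int
) -> np.ndarray:
    """Draw n multilook sample covariance matrices around ``sigma``.

    Each draw is C = (1/L) sum_k z_k z_k^H with z_k ~ CN(0, sigma), i.e.
    (1/L) times a complex Wishart(L, sigma) matrix, so E[C] = sigma.
    Hermitian PSD by construction; works for singular sigma via the
    eigenvalue square root.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    sigma = np.asarray(sigma, dtype=complex)
    w = np.linalg.eigvalsh(sigma)
    if w.min() < -1e-12 * max(w.max(), 1e-300):
        raise ValueError("sigma must be positive semidefinite")
    vals, vecs = np.linalg.eigh(sigma)
    a = vecs * np.sqrt(np.clip(vals, 0.0, None))  # sigma = a a^H
    g = rng.standard_normal((n, looks, 3)) + 1j * rng.standard_normal((n, looks, 3))
    z = (g / np.sqrt(2.0)) @ a.T  # z = a g columnwise, so E[z z^H] = a a^H = sigma
    c = np.einsum("nlk,nlj->nkj", z, z.conj()) / looks
    return c


def default_config(seed: int = 42) -> SimConfig:
    """The documented four-class preset (see module docstring)."""
    rice_sigma = np.array(
        [[1.0, 0.0, 0.5 + 0.4j], [0.0, 0.4, 0.0], [0.5 - 0.4j, 0.0, 1.0]]
    )
    meadow_sigma = np.array(
        [[2.2, 0.0, 0.1], [0.0, 1.0, 0.0], [0.1, 0.0, 0.6]]
    )
    classes = [
        ClassSpec("rice_early", rice_sigma, (0.25, 0.30, 0.28, 0.55)),
        ClassSpec("rice_late", rice_sigma.conj(), (0.25, 0.30, 0.28, 0.55)),
        ClassSpec("lotus", meadow_sigma, (0.20, 0.18, 0.12, 0.45)),
        ClassSpec("grass", meadow_sigma, (0.20, 0.42, 0.38, 0.45)),
    ]
    return SimConfig(classes=classes, seed=seed)


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, size: int
) -> np.ndarray:
    """Gaussian truncated to [0, 1] by resampling (means are interior)."""
    out = rng.normal(mean, sd, size)
    bad = (out < 0.0) | (out > 1.0)
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = (out < 0.0) | (out > 1.0)
    return out


def generate_scene(cfg: SimConfig) -> Scene:
    """Generate a labeled scene: field mosaic, Wishart SAR, Gaussian optical.

    Fields are rectangles tiling the scene; each is assigned one class
    (balanced, seeded shuffle) and marked training or testing, so the two
    pixel splits are disjoint by field.  Deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    rows, cols = cfg.shape
    nfr, nfc = cfg.field_grid
    k = len(cfg.classes)
    n_fields = nfr * nfc

    # balanced class assignment over fields, shuffled
    assign = np.tile(np.arange(k), n_fields // k + 1)[:n_fields]
    rng.shuffle(assign)

    # rectangular tiling (last row/col of fields absorbs the remainder)
    r_edges = np.linspace(0, rows, nfr + 1).astype(int)
    c_edges = np.linspace(0, cols, nfc + 1).astype(int)
    labels = np.empty((rows, cols), dtype=int)
    field_ids = np.empty((rows, cols), dtype=int)
    for fi in range(nfr):
        for fj in range(nfc):
            f = fi * nfc + fj
            sl = np.s_[r_edges[fi]:r_edges[fi + 1], c_edges[fj]:c_edges[fj + 1]]
            labels[sl] = assign[f]
            field_ids[sl] = f

    # training/testing split by field
    train_mask_field = np.zeros(n_fields, dtype=bool)
    for cid in range(k):
        fields_c = np.flatnonzero(assign == cid)
        chosen = rng.choice(fields_c, size=cfg.train_fields_per_class, replace=False)
        train_mask_field[chosen] = True

    # SAR and optical draws per class
    c3 = np.empty((rows, cols, 3, 3), dtype=complex)
    bands = {b: np.empty((rows, cols)) for b in ("R", "G", "B", "NIR")}
    for cid, spec in enumerate(cfg.classes):
        sel = labels == cid
        n = int(sel.sum())
        c3[sel] = sample_wishart_c3(spec.sigma, cfg.looks, n, rng)
        for b, m, s in zip(("R", "G", "B", "NIR"), spec.optical_mean, spec.optical_sd):
            bands[b][sel] = _truncated_normal(rng, m, s, n)

    legend = {i: s.name for i, s in enumerate(cfg.classes)}
    truth = ClassMap(labels=labels, legend=legend, provenance={"seed": cfg.seed})

    def _pixel_set(field_selector: np.ndarray) -> TrainingSet:
        sel = field_selector[field_ids]
        r, c = np.nonzero(sel)
        return TrainingSet(
            rows=r, cols=c, labels=labels[r, c], legend=legend,
            plot_ids=field_ids[r, c],
        )

    return Scene(
        c3=C3Field(data=c3, looks=cfg.looks),
        optical=OpticalBands(bands=bands),
        truth=truth,
        train=_pixel_set(train_mask_field),
        test=_pixel_set(~train_mask_field),
        config=cfg,
        field_ids=field_ids,
    )
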