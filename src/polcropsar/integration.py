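"""Feature normalization, sigma-vector PCA, and integration-mode stacking.

SAR and optical features live on very different scales (dB, power, index,
bits), so every layer is min-max normalized to [0, 1] before classification.
The nine-channel dB backscatter vector is PCA-reduced (its channels are
strongly correlated), and three named integration modes select which SAR and
optical layers enter the final stack.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .optical import PCAResult, _pca_of_layers
from .polsar import SigmaDb9

log = logging.getLogger(__name__)

__all__ = [
    "FeatureStack",
    "IntegrationMode",
    "INTEGRATION_MODES",
    "minmax_normalize",
    "sigma_pca",
    "assemble",
]


@dataclass
class FeatureStack:
    """Ordered, named real-valued rasters on one grid with a joint mask."""

    layers: dict[str, np.ndarray]
    mask: np.ndarray
    provenance: dict[str, str] = field(default_factory=dict)  # name -> sar|optical
    norm_stats: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {a.shape for a in self.layers.values()} | {self.mask.shape}
        if len(shapes) != 1:
            raise ValueError(f"layers on different grids: {shapes}")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.layers)

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    def as_array(self) -> np.ndarray:
        """(rows, cols, n_layers) array in layer order."""
        return np.stack([self.layers[n] for n in self.layers], axis=-1)

    def table(self) -> np.ndarray:
        """(n_valid, n_layers) matrix of valid pixels, layer order preserved."""
        return self.as_array()[self.mask]


@dataclass(frozen=True)
class IntegrationMode:
    """A named selection of SAR and optical layers."""

    name: str
    sar_layers: tuple[str, ...]
    optical_layers: tuple[str, ...]

    @property
    def layers(self) -> tuple[str, ...]:
        return self.sar_layers + self.optical_layers


_SAR7 = ("sigma_pca1", "sigma_pca2", "RVI", "Ps", "Pd", "Ph", "Pv")
_SAR5 = ("RVI", "Ps", "Pd", "Ph", "Pv")
_OPT4 = ("Opband_pca1", "Opband_pca2", "NDVI", "H")
_OPT2 = ("NDVI", "H")

#: The three feature-integration modes (full = 7 SAR + 4 optical layers),
#: plus single-source stacks used in the comparison experiments.
INTEGRATION_MODES: dict[str, IntegrationMode] = {
    "full": IntegrationMode("full", _SAR7, _OPT4),
    "sar7_opt2": IntegrationMode("sar7_opt2", _SAR7, _OPT2),
    "sar5_opt4": IntegrationMode("sar5_opt4", _SAR5, _OPT4),
    "sar_only": IntegrationMode("sar_only", _SAR7, ()),
    "optical_only": IntegrationMode("optical_only", (), _OPT4),
}


def minmax_normalize(
    stack: FeatureStack,
    robust: bool = False,
    stats: dict[str, tuple[float, float]] | None = None,
) -> FeatureStack:
    """Rescale every layer to [0, 1] over valid pixels.

    Plain mode maps (min, max) -> (0, 1); robust mode uses the 1st/99th
    percentiles and clips.  Pass ``stats`` (from a training scene's
    ``norm_stats``) to reuse its constants on a prediction scene instead of
    recomputing them — avoids train/test leakage.  Zero-range layers become
    all-zero with a warning.
    """
    out_layers: dict[str, np.ndarray] = {}
    out_stats: dict[str, tuple[float, float]] = {}
    for name, layer in stack.layers.items():
        vals = layer[stack.mask]
        if stats is not None:
            lo, hi = stats[name]
        elif robust:
            lo, hi = np.percentile(vals, [1.0, 99.0])
        else:
            lo, hi = float(vals.min()), float(vals.max())
        if hi <= lo:
            log.warning("minmax_normalize: layer %r has zero range, set to 0", name)
            out_layers[name] = np.zeros_like(layer)
            out_stats[name] = (lo, lo + 1.0)
            continue
        scaled = np.clip((layer - lo) / (hi - lo), 0.0, 1.0)
        scaled[~stack.mask] = 0.0
        out_layers[name] = scaled
        out_stats[name] = (float(lo), float(hi))
    return FeatureStack(
        layers=out_layers,
        mask=stack.mask.copy(),
        provenance=dict(stack.provenance),
        norm_stats=out_stats,
    )


def sigma_pca(
    sigma: SigmaDb9, var_threshold: float = 0.98, min_components: int = 1
) -> PCAResult:
    """PCA of the nine dB backscatter channels.

    Keeps the smallest leading component set whose cumulative explained
    variance reaches ``var_threshold`` (default 0.98, the fraction the first
    two components carry on the reference scenes); components are named
    sigma_pca1, sigma_pca2, ...
    """
    return _pca_of_layers(
        sigma.channels, sigma.mask, var_threshold, "sigma_pca",
        min_components=min_components,
    )


def assemble(
    mode: IntegrationMode | str,
    sar_features: dict[str, np.ndarray],
    optical_features: dict[str, np.ndarray],
    sar_mask: np.ndarray | None = None,
    optical_mask: np.ndarray | None = None,
    normalize: bool = True,
    norm_stats: dict[str, tuple[float, float]] | None = None,
) -> FeatureStack:
    """Stack exactly the mode's layers, normalized, with a conservative mask.

    The joint mask is the AND of the source masks; a missing layer raises a
    configuration error naming it.
    """
    if isinstance(mode, str):
        try:
            mode = INTEGRATION_MODES[mode]
        except KeyError:
            raise KeyError(
                f"unknown integration mode {mode!r}; choose from {sorted(INTEGRATION_MODES)}"
            ) from None
    layers: dict[str, np.ndarray] = {}
    provenance: dict[str, str] = {}
    shape = None
    for name in mode.sar_layers:
        if name not in sar_features:
            raise KeyError(f"integration mode {mode.name!r} needs missing SAR layer {name!r}")
        layers[name] = np.ma.getdata(np.asarray(sar_features[name], dtype=float))
        provenance[name] = "sar"
    for name in mode.optical_layers:
        if name not in optical_features:
            raise KeyError(
                f"integration mode {mode.name!r} needs missing optical layer {name!r}"
            )
        layers[name] = np.ma.getdata(np.asarray(optical_features[name], dtype=float))
        provenance[name] = "optical"
    shapes = {a.shape for a in layers.values()}
    if len(shapes) != 1:
        raise ValueError(f"layers not co-registered: {shapes}")
    (shape,) = shapes
    mask = np.ones(shape, dtype=bool)
    if sar_mask is not None and mode.sar_layers:
        mask &= sar_mask
    if optical_mask is not None and mode.optical_layers:
        mask &= optical_mask
    for name, raw in list(sar_features.items()) + list(optical_features.items()):
        if name in layers and np.ma.isMaskedArray(raw):
            mask &= ~np.ma.getmaskarray(raw)
    stack = FeatureStack(layers=layers, mask=mask, provenance=provenance)
    if normalize:
        stack = minmax_normalize(stack, stats=norm_stats)
    return stack
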