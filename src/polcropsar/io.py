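"""Raster and configuration I/O.

Rasters travel as plain multi-band TIFF (band-interleaved, float64 or
int32) written with tifffile, with a JSON sidecar (<path>.json) carrying
band names, mask conventions, pixel spacing and the config hash.  Pixel
convention throughout: row-major, 0-based indices, pixel-center
registration.  Integer rasters round-trip bit-exactly; float rasters to
1e-12.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml

__all__ = [
    "C3_BAND_ORDER",
    "PipelineConfig",
    "read_config",
    "config_hash",
    "write_raster",
    "read_raster",
    "write_c3",
    "read_c3",
]

#: Band order of the canonical 9-band real C3 container.
C3_BAND_ORDER = (
    "C11", "C22", "C33", "ReC12", "ImC12", "ReC13", "ImC13", "ReC23", "ImC23",
)


def write_raster(
    path: str | Path,
    data: np.ndarray,
    band_names: tuple[str, ...] | list[str],
    meta: dict | None = None,
) -> Path:
    """Write (rows, cols[, bands]) to TIFF + JSON sidecar; returns the path."""
    path = Path(path)
    data = np.asarray(data)
    if data.ndim == 2:
        data = data[..., None]
    if data.shape[-1] != len(band_names):
        raise ValueError(
            f"{data.shape[-1]} bands but {len(band_names)} band names"
        )
    if data.dtype.kind in "ui":
        out = data.astype(np.int32)
    else:
        out = data.astype(np.float64)
    tifffile.imwrite(path, np.moveaxis(out, -1, 0), photometric="minisblack")
    sidecar = {
        "band_names": list(band_names),
        "shape": list(data.shape[:2]),
        "dtype": str(out.dtype),
        **(meta or {}),
    }
    Path(f"{path}.json").write_text(json.dumps(sidecar, indent=2))
    return path


def read_raster(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read a TIFF written by :func:`write_raster`; returns (data, meta).

    Data comes back as (rows, cols, bands).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"raster not found: {path}")
    try:
        arr = tifffile.imread(path)
    except Exception as exc:  # pragma: no cover - depends on corruption mode
        raise ValueError(f"malformed raster file {path}: {exc}") from exc
    if arr.ndim == 2:
        arr = arr[None]
    data = np.moveaxis(arr, 0, -1)
    meta: dict = {}
    sidecar = Path(f"{path}.json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return data, meta


def write_c3(path: str | Path, c3_data: np.ndarray, meta: dict | None = None) -> Path:
    """Write a complex C3 field as the canonical 9-band real raster."""
    from .polsar import c3_matrices_to_params

    params = c3_matrices_to_params(c3_data)
    return write_raster(path, params, C3_BAND_ORDER, {"container": "C3", **(meta or {})})


def read_c3(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read the canonical 9-band C3 raster back to complex matrices."""
    from .polsar import c3_params_to_matrices

    data, meta = read_raster(path)
    if data.shape[-1] != 9:
        raise ValueError(
            f"C3 raster must have 9 bands in order {C3_BAND_ORDER}, "
            f"got {data.shape[-1]} bands in {path}"
        )
    return c3_params_to_matrices(data), meta


# ---------------------------------------------------------------------------
# configuration

_CONFIG_SCHEMA: dict[str, type | tuple] = {
    # simulation (used when input paths are absent)
    "simulate": bool,
    "scene_size": list,
    "field_grid": list,
    "looks": int,
    "train_fields_per_class": int,
    # inputs (paths; optional when simulate=True)
    "c3_path": str,
    "optical_path": str,
    "train_labels_path": str,
    "test_labels_path": str,
    "optical_band_map": dict,
    # processing
    "mode": str,
    "classifier": str,
    "entropy_window": int,
    "entropy_bins": int,
    "entropy_band": str,
    "sigma_pca_threshold": float,
    "band_pca_threshold": float,
    "robust_normalize": bool,
    "db_floor": float,
    "svm_c_grid": list,
    "svm_gamma_grid": list,
    "svm_cv_folds": int,
    "max_train_per_class": int,
    # bookkeeping
    "seed": int,
    "output_dir": str,
}


@dataclass
class PipelineConfig:
    """Validated end-to-end pipeline configuration."""

    simulate: bool = True
    scene_size: list = field(default_factory=lambda: [160, 160])
    field_grid: list = field(default_factory=lambda: [8, 8])
    looks: int = 9
    train_fields_per_class: int = 4
    c3_path: str | None = None
    optical_path: str | None = None
    train_labels_path: str | None = None
    test_labels_path: str | None = None
    optical_band_map: dict = field(default_factory=lambda: {"R": 0, "G": 1, "B": 2, "NIR": 3})
    mode: str = "full"
    classifier: str = "svm"
    entropy_window: int = 7
    entropy_bins: int = 32
    entropy_band: str = "R"
    sigma_pca_threshold: float = 0.98
    band_pca_threshold: float = 0.99
    robust_normalize: bool = False
    db_floor: float = -50.0
    svm_c_grid: list = field(default_factory=lambda: [0.1, 1.0, 10.0, 100.0])
    svm_gamma_grid: list = field(default_factory=lambda: [0.01, 0.1, 1.0, 10.0])
    svm_cv_folds: int = 5
    max_train_per_class: int = 600
    seed: int = 42
    output_dir: str = "polcropsar_out"

    def validate(self) -> None:
        from .integration import INTEGRATION_MODES

        if self.mode not in INTEGRATION_MODES:
            raise ValueError(
                f"unknown mode {self.mode!r}; choose from {sorted(INTEGRATION_MODES)}"
            )
        if self.classifier not in ("svm", "wishart"):
            raise ValueError(f"classifier must be 'svm' or 'wishart', got {self.classifier!r}")
        if not self.simulate:
            for key in ("c3_path", "optical_path", "train_labels_path", "test_labels_path"):
                if getattr(self, key) is None:
                    raise ValueError(f"config without simulate=true requires {key}")


def read_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML config; unknown keys are rejected by name."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} must be a mapping")
    unknown = set(raw) - set(_CONFIG_SCHEMA)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key, val in raw.items():
        expected = _CONFIG_SCHEMA[key]
        if expected is float and isinstance(val, int):
            continue
        if not isinstance(val, expected):
            raise ValueError(
                f"config key {key!r}: expected {expected}, got {type(val).__name__}"
            )
    cfg = PipelineConfig(**raw)
    cfg.validate()
    return cfg


def config_hash(cfg: PipelineConfig) -> str:
    """Stable short hash identifying a configuration."""
    blob = json.dumps(asdict(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
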