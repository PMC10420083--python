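"""In-memory raster containers shared across the pipeline.

Arrays are band-first: ``values[b, r, c]``.  Masks mark *valid* pixels.
Pixel rectangles everywhere in the package are 0-based, half-open:
``[row0, row1) x [col0, col1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spectra import SensorModel


@dataclass(frozen=True)
class PanelRegion:
    """A uniform calibration panel of known reflectance embedded in a DN image."""

    reflectance: float
    row0: int
    row1: int
    col0: int
    col1: int

    @property
    def slices(self) -> tuple[slice, slice]:
        return (slice(self.row0, self.row1), slice(self.col0, self.col1))


def _default_mask(values: np.ndarray) -> np.ndarray:
    return np.ones(values.shape[1:], dtype=bool)


@dataclass
class ReflectanceImage:
    """Multiband surface-reflectance raster (float, nominally in [0, 1])."""

    values: np.ndarray  # (B, H, W)
    sensor: SensorModel
    mask: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("reflectance values must be (bands, rows, cols)")
        if self.values.shape[0] != self.sensor.n_bands:
            raise ValueError(
                f"{self.values.shape[0]} bands in array vs {self.sensor.n_bands} "
                f"declared by sensor {self.sensor.name!r}"
            )
        if self.mask is None:
            self.mask = _default_mask(self.values)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.values.shape[1:]:
            raise ValueError("mask shape must match image rows x cols")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape[1:]

    def band(self, role: str) -> np.ndarray:
        """The 2-D band image for a semantic role (blue/green/red/nir1/...)."""
        return self.values[self.sensor.band_index(role)]


@dataclass
class DNImage:
    """Raw digital-number raster plus embedded calibration-panel metadata."""

    values: np.ndarray  # (B, H, W) unsigned int
    sensor: SensorModel
    bit_depth: int = 8
    panels: tuple[PanelRegion, ...] = ()
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError("DN values must be (bands, rows, cols)")
        if self.values.shape[0] != self.sensor.n_bands:
            raise ValueError(
                f"{self.values.shape[0]} bands in array vs {self.sensor.n_bands} "
                f"declared by sensor {self.sensor.name!r}"
            )
        if self.bit_depth not in (8, 10, 12, 16):
            raise ValueError(f"unsupported bit depth {self.bit_depth}")

    @property
    def max_dn(self) -> int:
        return 2 ** self.bit_depth - 1

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape[1:]


@dataclass
class AbundanceImage:
    """Per-pixel endmember fractions on the 3-simplex, plus fit residuals.

    ``values[k]`` is the fraction of endmember k (FL, LF, SL order);
    ``residual`` is the per-pixel reconstruction RMSE in reflectance units.
    """

    values: np.ndarray  # (3, H, W)
    residual: np.ndarray  # (H, W)
    mask: np.ndarray | None = None
    endmember_names: tuple[str, ...] = ("FL", "LF", "SL")
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.residual = np.asarray(self.residual, dtype=float)
        if self.values.ndim != 3 or self.values.shape[0] != len(self.endmember_names):
            raise ValueError("abundance values must be (n_endmembers, rows, cols)")
        if self.residual.shape != self.values.shape[1:]:
            raise ValueError("residual shape must match rows x cols")
        if self.mask is None:
            self.mask = _default_mask(self.values)
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape[1:]

    def fraction(self, name: str) -> np.ndarray:
        return self.values[self.endmember_names.index(name)]
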