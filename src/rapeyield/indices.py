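"""The nine vegetation indices used for flowering-stage yield estimation.

All formulas are written in terms of semantic band roles so that the same
code serves the six-band UAV camera and generic four-band satellites
(blue/green/red/NIR standing in for rho490/rho550/rho670/rho800):

    NDVI    (nir - red) / (nir + red)
    CIgreen nir / green - 1
    VARI    (green - red) / (green + red)
    RVI     nir / red
    DVI     nir - red
    RDVI    (nir - red) / sqrt(nir + red)
    EVI     2.5 (nir - red) / (nir + 6 red - 7.5 blue + 1)
    TVI     0.5 [120 (nir - green) - 200 (red - green)]
    NDYI    (green - blue) / (green + blue)

RDVI is the renormalized difference index; a variant identical to NDVI is
available via ``rdvi_variant="as_printed"`` for comparison with sources that
typeset the two identically.  NDYI tracks the yellowness that rapeseed
flowers add to the canopy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .images import ReflectanceImage

_EPS_DENOM = 0.0  # exact-zero denominators are invalidated, nothing else


class ConfigurationError(ValueError):
    """A required band role is missing from the sensor."""


@dataclass(frozen=True)
class VIDefinition:
    name: str
    required_roles: tuple[str, ...]
    func: Callable[..., np.ndarray]
    denominator: Callable[..., np.ndarray] | None = None  # None: no denominator


def _safe(num, den):
    """Elementwise num/den with exact-zero denominators -> NaN."""
    den = np.asarray(den, dtype=float)
    out = np.full(np.broadcast(np.asarray(num, dtype=float), den).shape, np.nan)
    ok = den != 0
    np.divide(num, den, out=out, where=ok)
    return out


def _ndvi(red, nir):
    return _safe(nir - red, nir + red)


def _cigreen(green, nir):
    return _safe(nir, green) - 1.0


def _vari(green, red):
    return _safe(green - red, green + red)


def _rvi(red, nir):
    return _safe(nir, red)


def _dvi(red, nir):
    return np.asarray(nir - red, dtype=float)


def _rdvi(red, nir):
    s = np.asarray(nir + red, dtype=float)
    out = _safe(nir - red, np.sqrt(np.clip(s, 0.0, None)))
    out = np.where(s < 0, np.nan, out)
    return out


def _evi(blue, red, nir):
    return _safe(2.5 * (nir - red), nir + 6.0 * red - 7.5 * blue + 1.0)


def _tvi(green, red, nir):
    return np.asarray(0.5 * (120.0 * (nir - green) - 200.0 * (red - green)), dtype=float)


def _ndyi(blue, green):
    return _safe(green - blue, green + blue)


VI_REGISTRY: dict[str, VIDefinition] = {
    "NDVI": VIDefinition("NDVI", ("red", "nir1"), _ndvi),
    "CIgreen": VIDefinition("CIgreen", ("green", "nir1"), _cigreen),
    "VARI": VIDefinition("VARI", ("green", "red"), _vari),
    "RVI": VIDefinition("RVI", ("red", "nir1"), _rvi),
    "DVI": VIDefinition("DVI", ("red", "nir1"), _dvi),
    "RDVI": VIDefinition("RDVI", ("red", "nir1"), _rdvi),
    "EVI": VIDefinition("EVI", ("blue", "red", "nir1"), _evi),
    "TVI": VIDefinition("TVI", ("green", "red", "nir1"), _tvi),
    "NDYI": VIDefinition("NDYI", ("blue", "green"), _ndyi),
}

VI_NAMES = tuple(VI_REGISTRY)


def compute_vi_values(
    name: str, *, rdvi_variant: str = "renormalized", **bands: np.ndarray
) -> np.ndarray:
    """Evaluate one index from role-keyed reflectance arrays (or scalars).

    ``bands`` supplies the roles the index needs, e.g.
    ``compute_vi_values("NDVI", red=0.1, nir1=0.5)``.  Pixels with a zero
    denominator come back NaN.
    """
    if name not in VI_REGISTRY:
        raise KeyError(f"unknown vegetation index {name!r}; known: {VI_NAMES}")
    if name == "RDVI" and rdvi_variant == "as_printed":
        vi = VI_REGISTRY["NDVI"]
    else:
        vi = VI_REGISTRY[name]
    missing = [r for r in vi.required_roles if r not in bands]
    if missing:
        raise ConfigurationError(f"{name} requires band role(s) {missing}")
    args = [np.asarray(bands[r], dtype=float) for r in vi.required_roles]
    return vi.func(*args)


def compute_vi(
    image: ReflectanceImage, name: str, *, rdvi_variant: str = "renormalized"
) -> tuple[np.ndarray, int]:
    """Per-pixel vegetation index for a reflectance image.

    Returns (values, n_invalid): a 2-D float array with NaN at masked or
    zero-denominator pixels, and the count of denominator-invalidated pixels
    among the image's valid ones.
    """
    vi = VI_REGISTRY.get(name)
    if vi is None:
        raise KeyError(f"unknown vegetation index {name!r}; known: {VI_NAMES}")
    for role in vi.required_roles:
        if role not in image.sensor.band_roles:
            raise ConfigurationError(
                f"{name} needs band role {role!r}, absent from sensor {image.sensor.name!r}"
            )
    bands = {r: image.band(r) for r in vi.required_roles}
    values = compute_vi_values(name, rdvi_variant=rdvi_variant, **bands)
    values = np.where(image.mask, values, np.nan)
    n_invalid = int(np.sum(np.isnan(values) & image.mask))
    return values, n_invalid


def vi_bounds_check(name: str) -> tuple[float, float]:
    """Theoretical attainable range of an index for reflectances in (0, 1].

    The linear indices' endpoints follow from evaluating at the corners of
    the reflectance cube; normalized differences are open on (-1, 1); EVI's
    denominator can vanish, so its range is unbounded.
    """
    bounds = {
        "NDVI": (-1.0, 1.0),
        "VARI": (-1.0, 1.0),
        "NDYI": (-1.0, 1.0),
        "DVI": (-1.0, 1.0),
        "RDVI": (-1.0, 1.0),
        "RVI": (0.0, np.inf),
        "CIgreen": (-1.0, np.inf),
        "EVI": (-np.inf, np.inf),
        # TVI = 60 nir - 100 red + 40 green over (0, 1]^3
        "TVI": (-100.0, 100.0),
    }
    try:
        return bounds[name]
    except KeyError:
        raise KeyError(f"unknown vegetation index {name!r}") from None
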