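"""Endmember spectra, sensor band models, and spectral resampling.

A flowering rapeseed canopy is modelled as a linear mixture of three
endmembers — flower (FL), leaf (LF) and soil (SL) — each described by a
fine-grained (~1 nm) reflectance curve.  Multispectral sensors see these
curves through a handful of bands, each given as center@FWHM.  This module
resamples the fine curves to sensor bands (boxcar response, trapezoid
integration) and stacks them into the B x 3 endmember matrix used by the
linear mixing model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

ENDMEMBER_ORDER = ("FL", "LF", "SL")


class CoverageError(ValueError):
    """A band's support extends outside the spectrum's wavelength range."""


class LibraryError(ValueError):
    """The endmember library is missing or duplicating required members."""


@dataclass(frozen=True)
class Band:
    """One sensor band: boxcar response over [center - fwhm/2, center + fwhm/2]."""

    center_nm: float
    fwhm_nm: float
    role: str | None = None

    @property
    def support(self) -> tuple[float, float]:
        half = self.fwhm_nm / 2.0
        return (self.center_nm - half, self.center_nm + half)


@dataclass(frozen=True)
class SensorModel:
    """An ordered set of bands plus a role map (blue/green/red/red-edge/nir1/nir2).

    Band order is the declared acquisition order and is preserved as-is;
    centers are not required to be increasing.
    """

    name: str
    bands: tuple[Band, ...]

    def __post_init__(self) -> None:
        roles = [b.role for b in self.bands if b.role is not None]
        if len(roles) != len(set(roles)):
            raise ValueError(f"sensor {self.name!r}: duplicate band roles {roles}")

    @property
    def n_bands(self) -> int:
        return len(self.bands)

    @property
    def band_roles(self) -> dict[str, int]:
        return {b.role: i for i, b in enumerate(self.bands) if b.role is not None}

    def band_index(self, role: str) -> int:
        try:
            return self.band_roles[role]
        except KeyError:
            raise KeyError(
                f"sensor {self.name!r} has no band with role {role!r} "
                f"(available: {sorted(self.band_roles)})"
            ) from None

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "bands": [
                {"center": b.center_nm, "fwhm": b.fwhm_nm, "role": b.role}
                for b in self.bands
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SensorModel":
        bands = tuple(
            Band(float(b["center"]), float(b["fwhm"]), b.get("role"))
            for b in d["bands"]
        )
        return cls(name=d.get("name", "sensor"), bands=bands)


def uav6() -> SensorModel:
    """Six-band UAV camera: 490/550/670/720/800 nm @10 and 900 nm @20 FWHM."""
    return SensorModel(
        name="UAV6",
        bands=(
            Band(490.0, 10.0, "blue"),
            Band(550.0, 10.0, "green"),
            Band(670.0, 10.0, "red"),
            Band(720.0, 10.0, "red-edge"),
            Band(800.0, 10.0, "nir1"),
            Band(900.0, 20.0, "nir2"),
        ),
    )


def sat4() -> SensorModel:
    """Generic 4-band satellite (blue/green/red/NIR), mirroring the UAV roles."""
    return SensorModel(
        name="SAT4",
        bands=(
            Band(490.0, 10.0, "blue"),
            Band(550.0, 10.0, "green"),
            Band(670.0, 10.0, "red"),
            Band(800.0, 10.0, "nir1"),
        ),
    )


SENSOR_PRESETS = {"UAV6": uav6, "SAT4": sat4}


@dataclass
class EndmemberSpectrum:
    """A named fine-grained reflectance curve for one scene component.

    ``wavelength_nm`` must be strictly increasing; reflectance is a unitless
    fraction in [0, 1] per wavelength.
    """

    name: str
    wavelength_nm: np.ndarray
    reflectance: np.ndarray

    def __post_init__(self) -> None:
        self.wavelength_nm = np.asarray(self.wavelength_nm, dtype=float)
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        if self.wavelength_nm.ndim != 1 or self.wavelength_nm.shape != self.reflectance.shape:
            raise ValueError("wavelength and reflectance must be 1-D and equal length")
        if not np.all(np.diff(self.wavelength_nm) > 0):
            raise ValueError(f"spectrum {self.name!r}: wavelengths must be strictly increasing")
        if np.any(self.reflectance < 0) or np.any(self.reflectance > 1):
            raise ValueError(f"spectrum {self.name!r}: reflectance outside [0, 1]")


@dataclass
class EndmemberMatrix:
    """B x N matrix of band reflectances, rows in sensor order, columns (FL, LF, SL)."""

    values: np.ndarray
    sensor: SensorModel
    endmember_names: tuple[str, ...] = ENDMEMBER_ORDER

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.sensor.n_bands, len(self.endmember_names)):
            raise ValueError(
                f"endmember matrix shape {self.values.shape} does not match "
                f"{self.sensor.n_bands} bands x {len(self.endmember_names)} endmembers"
            )


def _band_mean(spectrum: EndmemberSpectrum, band: Band) -> float:
    lo, hi = band.support
    wl, rf = spectrum.wavelength_nm, spectrum.reflectance
    if lo < wl[0] or hi > wl[-1]:
        raise CoverageError(
            f"band {band.center_nm}@{band.fwhm_nm} nm support [{lo}, {hi}] not covered "
            f"by spectrum {spectrum.name!r} range [{wl[0]}, {wl[-1]}]"
        )
    # native grid points interior to the support, with interpolated endpoints
    inside = (wl > lo) & (wl < hi)
    grid = np.concatenate(([lo], wl[inside], [hi]))
    vals = np.interp(grid, wl, rf)
    return float(np.trapezoid(vals, grid) / (hi - lo))


def resample_to_bands(spectrum: EndmemberSpectrum, sensor: SensorModel) -> np.ndarray:
    """Boxcar-average a fine spectrum over each sensor band.

    Returns one reflectance per band in sensor order.  Raises
    :class:`CoverageError` naming the band if the spectrum does not cover a
    band's full support.
    """
    return np.array([_band_mean(spectrum, b) for b in sensor.bands])


def build_endmember_matrix(
    library: Sequence[EndmemberSpectrum], sensor: SensorModel
) -> EndmemberMatrix:
    """Stack the resampled FL/LF/SL spectra into the mixing matrix.

    The library must contain exactly the three endmembers FL, LF, SL (any
    order, matched case-insensitively); columns are normalized to
    (FL, LF, SL) order.
    """
    by_name: dict[str, EndmemberSpectrum] = {}
    for spec in library:
        key = spec.name.upper()
        if key in by_name:
            raise LibraryError(f"duplicate endmember {spec.name!r} in library")
        by_name[key] = spec
    missing = [n for n in ENDMEMBER_ORDER if n not in by_name]
    extra = [n for n in by_name if n not in ENDMEMBER_ORDER]
    if missing or extra:
        raise LibraryError(
            f"library must contain exactly {ENDMEMBER_ORDER}; missing {missing}, extra {extra}"
        )
    cols = [resample_to_bands(by_name[n], sensor) for n in ENDMEMBER_ORDER]
    return EndmemberMatrix(values=np.column_stack(cols), sensor=sensor)


# ---------------------------------------------------------------------------
# file formats

def read_endmember_library(path: str | Path) -> list[EndmemberSpectrum]:
    """Read an endmember library CSV.

    Wide format (canonical): columns ``wavelength_nm, FL, LF, SL``.
    Long format: columns ``wavelength_nm, endmember, reflectance``.
    """
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    if "wavelength_nm" not in cols:
        raise LibraryError(f"{path}: missing wavelength_nm column")
    if "endmember" in cols and "reflectance" in cols:
        out = []
        for name, grp in df.groupby(cols["endmember"]):
            grp = grp.sort_values(cols["wavelength_nm"])
            out.append(
                EndmemberSpectrum(
                    str(name), grp[cols["wavelength_nm"]].to_numpy(),
                    grp[cols["reflectance"]].to_numpy(),
                )
            )
        return out
    wl = df[cols["wavelength_nm"]].to_numpy()
    return [
        EndmemberSpectrum(c, wl, df[c].to_numpy())
        for c in df.columns
        if c != cols["wavelength_nm"]
    ]


def write_endmember_library(library: Sequence[EndmemberSpectrum], path: str | Path) -> None:
    """Write a library to wide-format CSV (requires a shared wavelength grid)."""
    wl = library[0].wavelength_nm
    for s in library[1:]:
        if not np.array_equal(s.wavelength_nm, wl):
            raise LibraryError("wide-format CSV requires a shared wavelength grid")
    df = pd.DataFrame({"wavelength_nm": wl})
    for s in library:
        df[s.name] = s.reflectance
    df.to_csv(path, index=False)


def read_sensor(path: str | Path) -> SensorModel:
    with open(path) as fh:
        return SensorModel.from_dict(json.load(fh))


def write_sensor(sensor: SensorModel, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(sensor.to_dict(), fh, indent=2)
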