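"""Empirical linear model (ELM) radiometric calibration.

Per band, surface reflectance is a linear function of the camera's digital
number:  rho(lambda) = gain(lambda) * DN(lambda) + bias(lambda).  Gain and
bias are fitted by ordinary least squares on calibration panels of known
reflectance (field defaults 0.06 / 0.24 / 0.48) laid in the scene.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .images import DNImage, ReflectanceImage

DEFAULT_PANEL_REFLECTANCES = (0.06, 0.24, 0.48)


class CalibrationError(ValueError):
    """Too few or degenerate panel observations for a band."""


@dataclass(frozen=True)
class PanelObservation:
    """Mean DN of one calibration panel in one band, with its known reflectance."""

    band: int
    known_reflectance: float
    mean_dn: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.known_reflectance <= 1.0:
            raise ValueError("panel reflectance must be in [0, 1]")


@dataclass
class GainBias:
    """Per-band ELM coefficients: reflectance = gain * DN + bias."""

    gain: np.ndarray
    bias: np.ndarray
    residual_rms: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.gain = np.atleast_1d(np.asarray(self.gain, dtype=float))
        self.bias = np.atleast_1d(np.asarray(self.bias, dtype=float))
        if self.gain.shape != self.bias.shape:
            raise ValueError("gain and bias must have one entry per band")
        if not (np.all(np.isfinite(self.gain)) and np.all(np.isfinite(self.bias))):
            raise ValueError("gain/bias must be finite")
        if np.any(self.gain == 0):
            raise ValueError("zero gain is not invertible")
        if np.any(self.gain < 0):
            warnings.warn("negative ELM gain fitted; check panel observations", stacklevel=2)

    @property
    def n_bands(self) -> int:
        return self.gain.shape[0]


def fit_elm_band(observations: list[PanelObservation], band: int) -> tuple[float, float, float]:
    """OLS fit of reflectance on DN for one band.

    Returns (gain, bias, residual_rms).  Needs at least two panels with
    distinct mean DN.
    """
    obs = [o for o in observations if o.band == band]
    if len(obs) < 2:
        raise CalibrationError(f"band {band}: need >= 2 panel observations, got {len(obs)}")
    dn = np.array([o.mean_dn for o in obs], dtype=float)
    rho = np.array([o.known_reflectance for o in obs], dtype=float)
    if np.ptp(dn) == 0:
        raise CalibrationError(f"band {band}: all panel DNs equal ({dn[0]}), slope undefined")
    gain, bias = np.polyfit(dn, rho, 1)
    resid = rho - (gain * dn + bias)
    return float(gain), float(bias), float(np.sqrt(np.mean(resid**2)))


def fit_elm(observations: list[PanelObservation], n_bands: int | None = None) -> GainBias:
    """Fit per-band gain/bias from panel observations across all bands."""
    bands = sorted({o.band for o in observations})
    if n_bands is None:
        n_bands = max(bands) + 1
    if bands != list(range(n_bands)):
        raise CalibrationError(f"observations cover bands {bands}, expected 0..{n_bands - 1}")
    gains, biases, rms = zip(*(fit_elm_band(observations, b) for b in range(n_bands)))
    return GainBias(np.array(gains), np.array(biases), np.array(rms))


def panel_observations(image: DNImage, agg: str = "mean") -> list[PanelObservation]:
    """Extract per-band panel observations from a DN image's embedded panels.

    ``agg`` selects the panel-pixel aggregate: ``"mean"`` (default) or
    ``"median"``.
    """
    if not image.panels:
        raise CalibrationError("DN image carries no panel metadata")
    reduce = {"mean": np.mean, "median": np.median}[agg]
    obs = []
    for panel in image.panels:
        block = image.values[(slice(None),) + panel.slices].astype(float)
        for b in range(image.sensor.n_bands):
            obs.append(PanelObservation(b, panel.reflectance, float(reduce(block[b]))))
    return obs


def fit_elm_from_image(image: DNImage, agg: str = "mean") -> GainBias:
    """Convenience: extract panel observations and fit per-band ELM."""
    return fit_elm(panel_observations(image, agg=agg), n_bands=image.sensor.n_bands)


def apply_elm(image: DNImage, gb: GainBias) -> ReflectanceImage:
    """Convert a DN image to reflectance, rho = gain * DN + bias, per band.

    Negative results are clipped to 0; values above 1 are retained.  Both are
    counted in the output's ``meta`` (``n_clipped_negative``, ``n_above_one``).
    """
    if gb.n_bands != image.sensor.n_bands:
        raise ValueError(f"{gb.n_bands} gain/bias pairs for {image.sensor.n_bands} bands")
    rho = gb.gain[:, None, None] * image.values.astype(float) + gb.bias[:, None, None]
    n_neg = int(np.sum(rho < 0))
    n_hi = int(np.sum(rho > 1))
    rho = np.clip(rho, 0.0, None)
    meta = dict(image.meta)
    meta.update({"n_clipped_negative": n_neg, "n_above_one": n_hi, "calibration": "ELM"})
    return ReflectanceImage(values=rho, sensor=image.sensor, meta=meta)


def read_panel_csv(path) -> list[PanelObservation]:
    """Panel file: CSV with columns band, known_reflectance, mean_dn."""
    df = pd.read_csv(path)
    return [
        PanelObservation(int(r.band), float(r.known_reflectance), float(r.mean_dn))
        for r in df.itertuples()
    ]
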