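"""Synthetic flowering-rapeseed scenes with known ground truth.

Everything downstream (calibration, unmixing, index regression) is testable
against this module's truth bundles, so no field campaign or satellite
download is needed.  The generator emulates:

* flower/leaf/soil endmember spectra on a 1-nm grid with the spectral
  ordering seen in flowering canopies — flowers brighter than leaves in the
  green and red, darker in the NIR; soil monotonically brightening with
  wavelength; a leaf green peak near 550 nm and chlorophyll absorption dip
  near 670 nm;
* a nitrogen-gradient trial of eight rates x three replicates (24 plots):
  leaf abundance rises from ~0.2 at N0 to ~0.7, saturating at N225; flower
  abundance stays near 0.2 with a mild decline; soil takes the remainder;
* plot yields driven linearly by the leaf-weighted canopy signal
  EVI_true * Abd_LF plus Gaussian noise, spanning roughly 1000-3500 kg/ha
  and peaking at N225;
* raw 8-bit DN imagery with three embedded calibration panels of
  reflectance 0.06 / 0.24 / 0.48.

Abundance curves are qualitative emulations (the trends, not measured
curves); their functional forms are documented defaults and configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .images import AbundanceImage, DNImage, PanelRegion, ReflectanceImage
from .indices import compute_vi_values
from .spectra import (
    EndmemberMatrix,
    EndmemberSpectrum,
    SensorModel,
    build_endmember_matrix,
    uav6,
)
from .yield_model import PlotRecord

DEFAULT_N_RATES = (0.0, 45.0, 90.0, 135.0, 180.0, 225.0, 270.0, 360.0)


class ParameterError(ValueError):
    """A generator parameter outside its valid domain."""


@dataclass(frozen=True)
class TrialDesign:
    """Layout and noise settings of a synthetic nitrogen-gradient trial.

    Defaults give 8 rates x 3 replicates = 24 plots of 10x10 pixels with a
    1-pixel boundary-avoiding ROI inset, yield noise sd 150 kg/ha, and
    plot-to-plot flower-fraction variation of sd 0.04.
    """

    n_rates: tuple[float, ...] = DEFAULT_N_RATES
    replicates: int = 3
    plot_shape: tuple[int, int] = (10, 10)
    roi_inset: int = 1
    yield_noise_sd: float = 150.0
    flower_plot_sd: float = 0.04
    leaf_plot_sd: float = 0.02
    jitter_concentration: float = 300.0
    yield_range: tuple[float, float] = (1000.0, 3500.0)
    seed: int = 0
    flower_trend: object = None  # callable N -> mean Abd_FL; None = module default
    leaf_trend: object = None  # callable N -> mean Abd_LF; None = module default

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ParameterError("replicates must be >= 1")
        if self.plot_shape[0] <= 2 * self.roi_inset or self.plot_shape[1] <= 2 * self.roi_inset:
            raise ParameterError("plot_shape too small for the ROI inset")
        if self.yield_noise_sd < 0:
            raise ParameterError("yield_noise_sd must be >= 0")

    @property
    def n_plots(self) -> int:
        return len(self.n_rates) * self.replicates

    @property
    def image_shape(self) -> tuple[int, int]:
        return (len(self.n_rates) * self.plot_shape[0], self.replicates * self.plot_shape[1])

    def plot_bounds(self, rate_idx: int, rep: int) -> tuple[int, int, int, int]:
        """Footprint (row0, row1, col0, col1) of one plot in the scene mosaic."""
        ph, pw = self.plot_shape
        return (rate_idx * ph, (rate_idx + 1) * ph, rep * pw, (rep + 1) * pw)

    def plot_roi(self, rate_idx: int, rep: int) -> tuple[int, int, int, int]:
        r0, r1, c0, c1 = self.plot_bounds(rate_idx, rep)
        k = self.roi_inset
        return (r0 + k, r1 - k, c0 + k, c1 - k)


# ---------------------------------------------------------------------------
# endmember spectra

_LEAF_KNOTS = (
    (400, 0.045), (460, 0.05), (500, 0.07), (550, 0.16), (600, 0.10),
    (640, 0.06), (670, 0.045), (700, 0.12), (740, 0.50), (780, 0.72),
    (850, 0.76), (1000, 0.74),
)
_FLOWER_KNOTS = (
    (400, 0.05), (460, 0.07), (490, 0.10), (520, 0.22), (550, 0.38),
    (600, 0.47), (670, 0.50), (720, 0.52), (800, 0.57), (1000, 0.62),
)


def _pchip_curve(knots, grid, scale):
    wl = np.array([k[0] for k in knots], dtype=float)
    rf = np.array([k[1] for k in knots], dtype=float) * scale
    return np.clip(PchipInterpolator(wl, rf)(grid), 0.0, 1.0)


def generate_endmember_library(
    seed: int, wavelength_nm: np.ndarray | None = None
) -> list[EndmemberSpectrum]:
    """Three seeded endmember spectra (FL, LF, SL) on a 1-nm 400-1000 nm grid.

    Construction guarantees the flowering-canopy ordering: FL > LF at 550 and
    670 nm, FL < LF at 800 nm, soil monotone non-decreasing, leaf local
    maximum near 550 nm and local minimum near 670 nm.
    """
    rng = np.random.default_rng(seed)
    grid = np.arange(400.0, 1000.5, 1.0) if wavelength_nm is None else np.asarray(wavelength_nm, float)
    leaf = _pchip_curve(_LEAF_KNOTS, grid, scale=1.0 + 0.08 * rng.uniform(-1, 1, len(_LEAF_KNOTS)))
    flower = _pchip_curve(_FLOWER_KNOTS, grid, scale=1.0 + 0.08 * rng.uniform(-1, 1, len(_FLOWER_KNOTS)))
    a = rng.uniform(0.10, 0.14)
    b = rng.uniform(0.14, 0.20)
    soil = np.clip(a + b * (grid - grid[0]) / (grid[-1] - grid[0]), 0.0, 1.0)
    lib = [
        EndmemberSpectrum("FL", grid, flower),
        EndmemberSpectrum("LF", grid, leaf),
        EndmemberSpectrum("SL", grid, soil),
    ]
    _check_library(lib)
    return lib


def _check_library(lib: list[EndmemberSpectrum]) -> None:
    fl, lf, sl = lib
    at = lambda s, w: float(np.interp(w, s.wavelength_nm, s.reflectance))
    assert at(fl, 550) > at(lf, 550) and at(fl, 670) > at(lf, 670), (
        "flower must exceed leaf in the green and red bands"
    )
    assert at(fl, 800) < at(lf, 800), "flower must be darker than leaf in the NIR"
    assert np.all(np.diff(sl.reflectance) >= 0), "soil must be monotone non-decreasing"
    assert at(lf, 550) > at(lf, 500) and at(lf, 550) > at(lf, 600), "leaf green peak near 550"
    assert at(lf, 670) < at(lf, 600) and at(lf, 670) < at(lf, 700), "leaf red dip near 670"


# ---------------------------------------------------------------------------
# trial generation

@dataclass
class TruthBundle:
    """Ground truth for one synthetic trial.

    ``table`` holds one row per plot: design means, realized abundances, the
    true driver EVI_true * Abd_LF, and true/noisy yields.  ``beta0``/``beta1``
    are the generating yield-line coefficients.  ``gains_bias_truth`` is
    filled once a DN encoding exists.
    """

    design: TrialDesign
    library: list[EndmemberSpectrum]
    sensor: SensorModel
    endmember_matrix: EndmemberMatrix
    table: pd.DataFrame
    plots: list[PlotRecord]
    beta0: float
    beta1: float
    gains_bias_truth: tuple[np.ndarray, np.ndarray] | None = None


def leaf_abundance_trend(n_rate: np.ndarray | float) -> np.ndarray:
    """Saturating leaf-abundance response: 0.2 at N0 up to 0.7, flat past N225."""
    return 0.2 + 0.5 * np.minimum(np.asarray(n_rate, float), 225.0) / 225.0


def flower_abundance_trend(n_rate: np.ndarray | float) -> np.ndarray:
    """Mildly declining flower abundance around 0.2."""
    return 0.22 - 0.04 * np.asarray(n_rate, float) / 360.0


def generate_trial(
    design: TrialDesign,
    library: list[EndmemberSpectrum] | None = None,
    sensor: SensorModel | None = None,
) -> TruthBundle:
    """Draw a trial: per-plot abundances, true canopy spectra, and yields.

    True yield is beta0 + beta1 * (EVI_true * Abd_LF), evaluated on the
    plot's true mixed spectrum; beta is set so true yields span the design's
    ``yield_range`` across plots.  Noisy yield adds N(0, yield_noise_sd).
    """
    if library is None:
        library = generate_endmember_library(design.seed)
    if sensor is None:
        sensor = uav6()
    E = build_endmember_matrix(library, sensor)
    rng = np.random.default_rng(design.seed)
    roles = sensor.band_roles
    rows = []
    plots_geo = []
    soil_floor = 0.02
    fl_trend = design.flower_trend or flower_abundance_trend
    lf_trend = design.leaf_trend or leaf_abundance_trend
    for i, rate in enumerate(design.n_rates):
        if fl_trend(rate) + lf_trend(rate) > 1.0 - soil_floor:
            raise ParameterError(
                f"rate {rate}: mean abundances exceed the simplex "
                f"(flower + leaf trend > {1.0 - soil_floor})"
            )
        for j in range(design.replicates):
            fl = float(np.clip(fl_trend(rate) + rng.normal(0, design.flower_plot_sd), 0.02, 0.45))
            # leaf draw clipped into the feasible region so soil keeps a small floor
            lf = float(np.clip(
                lf_trend(rate) + rng.normal(0, design.leaf_plot_sd),
                0.05, 1.0 - soil_floor - fl,
            ))
            sl = 1.0 - fl - lf
            a = np.array([fl, lf, sl])
            rho = E.values @ a
            evi = float(
                compute_vi_values(
                    "EVI",
                    blue=rho[roles["blue"]], red=rho[roles["red"]], nir1=rho[roles["nir1"]],
                )
            )
            rows.append(
                {
                    "plot_id": f"N{int(rate)}-r{j + 1}", "rate_idx": i, "replicate": j,
                    "nitrogen_rate": rate, "abd_FL": fl, "abd_LF": lf, "abd_SL": sl,
                    "evi_true": evi, "driver_true": evi * lf,
                }
            )
            plots_geo.append((i, j))
    table = pd.DataFrame(rows)
    x = table["driver_true"].to_numpy()
    lo, hi = design.yield_range
    if np.ptp(x) == 0:
        raise ParameterError("degenerate design: constant yield driver across plots")
    beta1 = (hi - lo) / np.ptp(x)
    beta0 = lo - beta1 * x.min()
    table["yield_true"] = beta0 + beta1 * x
    noise = rng.normal(0.0, design.yield_noise_sd, size=len(table))
    table["yield_kg_ha"] = np.maximum(table["yield_true"] + noise, 1.0)
    plots = [
        PlotRecord(
            plot_id=row.plot_id,
            roi=design.plot_roi(*geo),
            nitrogen_rate=row.nitrogen_rate,
            yield_kg_ha=row.yield_kg_ha,
        )
        for row, geo in zip(table.itertuples(), plots_geo)
    ]
    return TruthBundle(
        design=design, library=library, sensor=sensor, endmember_matrix=E,
        table=table, plots=plots, beta0=float(beta0), beta1=float(beta1),
    )


# ---------------------------------------------------------------------------
# scene rendering

def render_scene(
    bundle: TruthBundle,
    snr_db: float | None = 40.0,
    jitter: bool = True,
    seed: int | None = None,
) -> tuple[ReflectanceImage, AbundanceImage]:
    """Rasterize a trial into a mixed-pixel reflectance scene plus truth.

    Per-pixel truth abundances are Dirichlet-jittered around the plot means
    (concentration ``design.jitter_concentration``; exact simplex membership
    by construction) and forward-mixed through the endmember matrix.
    Per-band Gaussian noise is scaled so the band's SNR equals ``snr_db``
    (None disables noise); reflectance is clipped to [0, 1] and the clipped
    fraction logged in the image ``meta``.
    """
    if snr_db is not None and snr_db <= 0:
        raise ParameterError("snr_db must be positive (or None for noise-free)")
    design = bundle.design
    rng = np.random.default_rng(design.seed + 1 if seed is None else seed)
    H, W = design.image_shape
    B = bundle.sensor.n_bands
    ab = np.zeros((3, H, W))
    for row in bundle.table.itertuples():
        r0, r1, c0, c1 = design.plot_bounds(row.rate_idx, row.replicate)
        npix = (r1 - r0) * (c1 - c0)
        mean = np.array([row.abd_FL, row.abd_LF, row.abd_SL])
        if jitter:
            sample = rng.dirichlet(design.jitter_concentration * mean, size=npix)
        else:
            sample = np.tile(mean, (npix, 1))
        ab[:, r0:r1, c0:c1] = sample.T.reshape(3, r1 - r0, c1 - c0)
    refl = np.einsum("bk,khw->bhw", bundle.endmember_matrix.values, ab)
    if snr_db is not None and np.isfinite(snr_db):
        rms = np.sqrt(np.mean(refl**2, axis=(1, 2)))
        sd = rms / 10.0 ** (snr_db / 20.0)
        refl = refl + rng.normal(0.0, 1.0, refl.shape) * sd[:, None, None]
    n_clip = int(np.sum((refl < 0) | (refl > 1)))
    refl = np.clip(refl, 0.0, 1.0)
    meta = {
        "seed": design.seed, "snr_db": snr_db, "jitter": jitter,
        "clip_fraction": n_clip / refl.size,
    }
    image = ReflectanceImage(values=refl, sensor=bundle.sensor, meta=meta)
    truth = AbundanceImage(values=ab, residual=np.zeros((H, W)), meta={"source": "truth"})
    return image, truth


# ---------------------------------------------------------------------------
# DN encoding with calibration panels

DEFAULT_GAIN = 0.006  # reflectance per count: panels 0.06/0.24/0.48 -> DN 10/40/80


def encode_dn(
    image: ReflectanceImage,
    gains: np.ndarray | float = DEFAULT_GAIN,
    biases: np.ndarray | float = 0.0,
    bit_depth: int = 8,
    panel_reflectances: tuple[float, ...] = (0.06, 0.24, 0.48),
    panel_shape: tuple[int, int] = (4, 4),
) -> DNImage:
    """Quantize reflectance to raw DN and append a calibration-panel strip.

    DN = round((rho - bias) / gain), clamped to [0, 2^bits - 1].  Three
    uniform panels of the given reflectances are appended as extra rows below
    the scene; their pixel rectangles are recorded in the DN image's
    ``panels`` metadata, and the true gain/bias in ``meta``.
    """
    B, H, W = image.values.shape
    gains = np.broadcast_to(np.asarray(gains, dtype=float), (B,)).copy()
    biases = np.broadcast_to(np.asarray(biases, dtype=float), (B,)).copy()
    if np.any(gains == 0):
        raise ParameterError("gain must be nonzero")
    if bit_depth not in (8, 10, 12, 16):
        raise ParameterError(f"unsupported bit depth {bit_depth}")
    ph, pw = panel_shape
    strip = np.zeros((B, ph, W))
    panels = []
    col = 0
    for rho in panel_reflectances:
        if col + pw > W:
            raise ParameterError("scene too narrow for the panel strip")
        strip[:, :, col : col + pw] = rho
        panels.append(PanelRegion(reflectance=rho, row0=H, row1=H + ph, col0=col, col1=col + pw))
        col += pw + 1
    full = np.concatenate([image.values, strip], axis=1)
    t = (full - biases[:, None, None]) / gains[:, None, None]
    dn = np.clip(np.rint(t), 0, 2**bit_depth - 1)
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    meta = {
        "gains_truth": gains.tolist(), "biases_truth": biases.tolist(),
        "scene_rows": H, "panel_shape": list(panel_shape),
    }
    return DNImage(
        values=dn.astype(dtype), sensor=image.sensor, bit_depth=bit_depth,
        panels=tuple(panels), meta=meta,
    )


def calibration_sweep_scene(
    sensor: SensorModel,
    gain: float = DEFAULT_GAIN,
    bias: float = 0.0,
    max_dn: int = 160,
    per_cell: int = 8,
) -> ReflectanceImage:
    """A reflectance sweep that exercises every DN quantization cell evenly.

    Each band repeats the same dense ramp: within every quantization interval
    of width ``gain`` the scene places ``per_cell`` evenly spaced reflectance
    values, so the encode/decode quantization error takes its nominal
    stratified RMS gain/sqrt(12) * sqrt(1 - 1/per_cell^2) instead of a
    seed-dependent fluctuation around it.  Used as the calibration
    round-trip target.
    """
    k = np.arange(1, max_dn + 1)
    offs = (np.arange(per_cell) + 0.5) / per_cell - 0.5
    t = (k[:, None] + offs[None, :]).ravel()
    rho = np.clip(gain * t + bias, 0.0, 1.0)
    side = int(np.ceil(np.sqrt(rho.size)))
    # pad with an exactly representable value so padding adds no error
    padded = np.full(side * side, gain * 1.0 + bias)
    padded[: rho.size] = rho
    img = np.tile(padded.reshape(1, side, side), (sensor.n_bands, 1, 1))
    return ReflectanceImage(values=img, sensor=sensor, meta={"kind": "calibration_sweep"})
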