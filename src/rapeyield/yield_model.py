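"""Plot aggregation, linear yield models, and leave-one-out cross-validation.

Per plot, mean reflectance and mean endmember abundances are taken over a
boundary-avoiding rectangular ROI; plot-level vegetation indices are computed
from the plot's mean reflectance (the per-pixel-then-average alternative is
available).  Three model families relate each index to yield:

    yield ~ VI,   yield ~ VI * Abd_FL,   yield ~ VI * Abd_LF

each an ordinary least-squares line, scored by leave-one-out
cross-validation:  R^2 is the mean of the per-fold training R^2, RMSE is
sqrt(sum E_i^2 / K) over the held-out residuals E_i, and CV (%) expresses
RMSE relative to the mean observed yield.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .images import AbundanceImage, ReflectanceImage
from .indices import VI_NAMES, compute_vi, compute_vi_values, VI_REGISTRY

FAMILIES = ("VI", "VIxAbdFL", "VIxAbdLF")


class DegeneratePredictorError(ValueError):
    """The predictor is constant; the slope is not identifiable."""


class SampleSizeError(ValueError):
    """Too few plots for the requested fit or cross-validation."""


@dataclass(frozen=True)
class PlotRecord:
    """A plot's ROI (0-based, half-open rows/cols), nitrogen rate, and yield."""

    plot_id: str
    roi: tuple[int, int, int, int]  # (row0, row1, col0, col1)
    nitrogen_rate: float
    yield_kg_ha: float

    def __post_init__(self) -> None:
        r0, r1, c0, c1 = self.roi
        if not (r1 > r0 and c1 > c0):
            raise ValueError(f"plot {self.plot_id}: empty ROI {self.roi}")
        if self.yield_kg_ha <= 0:
            raise ValueError(f"plot {self.plot_id}: yield must be positive")


@dataclass
class LinearFit:
    slope: float
    intercept: float
    r2: float
    slope_stderr: float = float("nan")
    intercept_stderr: float = float("nan")

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.slope * np.asarray(x, dtype=float) + self.intercept


@dataclass
class CVReport:
    """LOOCV summary for one (VI, predictor-family) model."""

    label: str
    r2: float  # mean per-fold training R^2
    rmse: float  # kg/ha, over held-out residuals
    cv: float  # percent
    pooled_r2: float  # conventional predicted-vs-observed R^2
    fit: LinearFit  # full-sample fit
    fold_residuals: np.ndarray = field(repr=False, default=None)
    fold_r2: np.ndarray = field(repr=False, default=None)


def fit_linear(x: np.ndarray, y: np.ndarray) -> LinearFit:
    """OLS line y = a x + b with R^2 = squared Pearson correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise SampleSizeError(f"need >= 3 points, got {x.size}")
    if np.ptp(x) == 0:
        raise DegeneratePredictorError("constant predictor")
    res = stats.linregress(x, y)
    return LinearFit(
        slope=float(res.slope), intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        slope_stderr=float(res.stderr), intercept_stderr=float(res.intercept_stderr),
    )


def loocv_evaluate(
    x: np.ndarray, y: np.ndarray, label: str = "", cv_variant: str = "rmse_over_mean"
) -> CVReport:
    """Leave-one-out cross-validation of the line y ~ x.

    Per fold i the remaining K-1 plots are refitted; the training R^2_i and
    held-out residual E_i = y_i - yhat_i are recorded.  Summary: R^2 = mean
    R^2_i, RMSE = sqrt(mean E_i^2), and CV = 100 * RMSE / mean(y) by default
    (``cv_variant="mean_fold"`` instead averages per-fold
    CV_i = 100 |E_i| / mean(y_train_i)).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    K = x.size
    if K < 3:
        raise SampleSizeError(f"LOOCV needs >= 3 plots, got {K}")
    resid = np.empty(K)
    fold_r2 = np.empty(K)
    fold_cv = np.empty(K)
    for i in range(K):
        keep = np.arange(K) != i
        xt, yt = x[keep], y[keep]
        if np.ptp(xt) == 0:
            raise DegeneratePredictorError(f"fold {i}: training predictor constant")
        fit = fit_linear_unchecked(xt, yt)
        fold_r2[i] = fit.r2
        resid[i] = y[i] - fit.predict(x[i])
        fold_cv[i] = 100.0 * abs(resid[i]) / np.mean(yt)
    rmse = float(np.sqrt(np.mean(resid**2)))
    cv = float(np.mean(fold_cv)) if cv_variant == "mean_fold" else 100.0 * rmse / float(np.mean(y))
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    pooled = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return CVReport(
        label=label, r2=float(np.mean(fold_r2)), rmse=rmse, cv=float(cv),
        pooled_r2=pooled, fit=fit_linear(x, y),
        fold_residuals=resid, fold_r2=fold_r2,
    )


def fit_linear_unchecked(x: np.ndarray, y: np.ndarray) -> LinearFit:
    """Closed-form OLS without the n >= 3 guard (used inside LOOCV folds)."""
    xm, ym = x.mean(), y.mean()
    sxx = float(np.sum((x - xm) ** 2))
    sxy = float(np.sum((x - xm) * (y - ym)))
    slope = sxy / sxx
    intercept = ym - slope * xm
    syy = float(np.sum((y - ym) ** 2))
    r2 = (sxy**2 / (sxx * syy)) if syy > 0 else 0.0
    return LinearFit(slope=slope, intercept=intercept, r2=r2)


def plot_aggregate(
    reflectance: ReflectanceImage,
    abundance: AbundanceImage,
    plots: Sequence[PlotRecord],
    vi_names: Sequence[str] = VI_NAMES,
    vi_convention: str = "mean_reflectance",
    rdvi_variant: str = "renormalized",
) -> pd.DataFrame:
    """Build the per-plot predictor table.

    One row per plot: mean band reflectance, mean FL/LF/SL abundance, each
    requested vegetation index, and the VI x Abd_FL / VI x Abd_LF products.
    ``vi_convention="mean_reflectance"`` (default) evaluates each index on
    the plot's mean reflectance; ``"mean_pixel"`` averages per-pixel index
    values instead.  Plots with no valid ROI pixel are excluded with a
    warning.
    """
    H, W = reflectance.shape
    roles = reflectance.sensor.band_roles
    rows = []
    for plot in plots:
        r0, r1, c0, c1 = plot.roi
        if not (0 <= r0 < r1 <= H and 0 <= c0 < c1 <= W):
            raise ValueError(f"plot {plot.plot_id}: ROI {plot.roi} outside image {H}x{W}")
        sel = np.zeros((H, W), dtype=bool)
        sel[r0:r1, c0:c1] = True
        sel &= reflectance.mask
        if not np.any(sel):
            warnings.warn(f"plot {plot.plot_id}: no valid ROI pixels; excluded", stacklevel=2)
            continue
        row: dict = {
            "plot_id": plot.plot_id,
            "nitrogen_rate": plot.nitrogen_rate,
            "yield_kg_ha": plot.yield_kg_ha,
        }
        mean_rho = reflectance.values[:, sel].mean(axis=1)
        for b in range(reflectance.sensor.n_bands):
            row[f"rho_b{b}"] = mean_rho[b]
        for name in abundance.endmember_names:
            row[f"abd_{name}"] = float(np.nanmean(abundance.fraction(name)[sel]))
        mean_by_role = {role: mean_rho[idx] for role, idx in roles.items()}
        for vi in vi_names:
            if vi_convention == "mean_reflectance":
                needed = VI_REGISTRY[vi].required_roles
                val = float(
                    compute_vi_values(
                        vi, rdvi_variant=rdvi_variant,
                        **{r: mean_by_role[r] for r in needed},
                    )
                )
            elif vi_convention == "mean_pixel":
                img, _ = compute_vi(reflectance, vi, rdvi_variant=rdvi_variant)
                val = float(np.nanmean(img[sel]))
            else:
                raise ValueError(f"unknown vi_convention {vi_convention!r}")
            row[vi] = val
            row[f"{vi}xAbdFL"] = val * row["abd_FL"]
            row[f"{vi}xAbdLF"] = val * row["abd_LF"]
        rows.append(row)
    return pd.DataFrame(rows)


def rank_models(
    table: pd.DataFrame,
    vi_names: Sequence[str] = VI_NAMES,
    families: Sequence[str] = FAMILIES,
    cv_variant: str = "rmse_over_mean",
) -> list[CVReport]:
    """LOOCV every VI x family model and rank by R^2 (RMSE tie-break).

    Degenerate models (constant predictor or constant yield) are reported
    with R^2 = 0 and NaN RMSE rather than aborting the ranking.
    """
    y = table["yield_kg_ha"].to_numpy(dtype=float)
    reports: list[CVReport] = []
    for vi in vi_names:
        for fam in families:
            col = vi if fam == "VI" else f"{vi}x{fam[3:]}"
            label = vi if fam == "VI" else f"{vi} x Abd_{fam[-2:]}"
            x = table[col].to_numpy(dtype=float)
            try:
                reports.append(loocv_evaluate(x, y, label=label, cv_variant=cv_variant))
            except (DegeneratePredictorError, SampleSizeError) as exc:
                warnings.warn(f"model {label}: rejected ({exc})", stacklevel=2)
                reports.append(
                    CVReport(
                        label=label, r2=0.0, rmse=float("nan"), cv=float("nan"),
                        pooled_r2=float("nan"), fit=None,
                    )
                )
    reports.sort(key=lambda r: (-r.r2, r.rmse if np.isfinite(r.rmse) else np.inf))
    return reports


def reports_to_frame(reports: Sequence[CVReport]) -> pd.DataFrame:
    """Tabulate CVReports (columns mirror the R^2 / RMSE / CV summary layout)."""
    return pd.DataFrame(
        [
            {
                "model": r.label, "R2": r.r2, "RMSE_kg_ha": r.rmse, "CV_pct": r.cv,
                "pooled_R2": r.pooled_r2,
                "slope": r.fit.slope if r.fit else float("nan"),
                "intercept": r.fit.intercept if r.fit else float("nan"),
            }
            for r in reports
        ]
    )


def read_plots_csv(path: str | Path) -> list[PlotRecord]:
    """Plots CSV: plot_id, row0, col0, row1, col1, nitrogen_rate, yield_kg_ha."""
    df = pd.read_csv(path)
    return [
        PlotRecord(
            plot_id=str(r.plot_id),
            roi=(int(r.row0), int(r.row1), int(r.col0), int(r.col1)),
            nitrogen_rate=float(r.nitrogen_rate),
            yield_kg_ha=float(r.yield_kg_ha),
        )
        for r in df.itertuples()
    ]


def write_plots_csv(plots: Sequence[PlotRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "plot_id": p.plot_id, "row0": p.roi[0], "row1": p.roi[1],
                "col0": p.roi[2], "col1": p.roi[3],
                "nitrogen_rate": p.nitrogen_rate, "yield_kg_ha": p.yield_kg_ha,
            }
            for p in plots
        ]
    ).to_csv(path, index=False)
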