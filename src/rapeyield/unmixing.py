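"""Fully constrained least-squares (FCLS) spectral unmixing.

Each pixel's reflectance vector rho is decomposed as E @ a where the columns
of E are the flower/leaf/soil endmember spectra at the sensor's bands and the
abundance vector a lies on the probability simplex (a >= 0, sum a = 1).

The solver is exact: with N endmembers the simplex-constrained least-squares
problem is a tiny quadratic program, solved by enumerating the 2^N - 1
candidate active sets.  For each support the sum-to-one equality-constrained
least squares is solved through its KKT system; the best feasible candidate
is the global optimum.  Rank-deficient supports fall back to the minimum-norm
KKT solution, making ties deterministic.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

from .images import AbundanceImage, ReflectanceImage
from .spectra import EndmemberMatrix

_FEAS_TOL = 1e-10


class DataError(ValueError):
    """Non-finite or malformed pixel data."""


def _supports(n: int) -> list[tuple[int, ...]]:
    # largest supports first so full-rank interior solutions win ties
    out: list[tuple[int, ...]] = []
    for k in range(n, 0, -1):
        out.extend(combinations(range(n), k))
    return out


def _kkt_solver(E_s: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Affine map rho -> candidate abundances for one support.

    Solves  min ||E_s a - rho||^2  s.t.  1'a = 1  via the KKT system
    [[E'E, 1], [1', 0]] [a; lam] = [E' rho; 1].  Returns (A, c) with
    a = A @ rho + c.  Uses the pseudo-inverse so rank-deficient supports get
    the minimum-norm solution.
    """
    k = E_s.shape[1]
    kkt = np.zeros((k + 1, k + 1))
    kkt[:k, :k] = E_s.T @ E_s
    kkt[:k, k] = 1.0
    kkt[k, :k] = 1.0
    inv = np.linalg.pinv(kkt)
    A = inv[:k, :k] @ E_s.T  # maps rho -> a (through rhs E_s' rho)
    c = inv[:k, k]  # contribution of the constant rhs entry 1
    return A, c


def fcls(R: np.ndarray, E: EndmemberMatrix | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unmix a batch of pixels.

    Parameters
    ----------
    R : (P, B) array of pixel reflectances.
    E : endmember matrix (B x N).

    Returns
    -------
    abundances : (P, N) array on the simplex (each row sums to 1, entries >= 0).
    residual : (P,) per-pixel reconstruction RMSE, ||E a - rho||_2 / sqrt(B).
    """
    Em = E.values if isinstance(E, EndmemberMatrix) else np.asarray(E, dtype=float)
    R = np.atleast_2d(np.asarray(R, dtype=float))
    B, N = Em.shape
    if R.shape[1] != B:
        raise ValueError(f"pixel vectors have {R.shape[1]} bands, matrix has {B} rows")
    if B < N - 1:
        raise ValueError(f"need at least {N - 1} bands to unmix {N} endmembers")
    if not np.all(np.isfinite(R)):
        raise DataError("non-finite reflectance values in input")
    if not np.all(np.isfinite(Em)):
        raise DataError("non-finite entries in endmember matrix")

    P = R.shape[0]
    best_obj = np.full(P, np.inf)
    best_a = np.zeros((P, N))
    for sup in _supports(N):
        E_s = Em[:, sup]
        A, c = _kkt_solver(E_s)
        a_s = R @ A.T + c  # (P, k)
        feas = np.all(a_s >= -_FEAS_TOL, axis=1)
        if not np.any(feas):
            continue
        resid = a_s @ E_s.T - R  # (P, B)
        obj = np.einsum("pb,pb->p", resid, resid)
        better = feas & (obj < best_obj - 1e-15)
        if np.any(better):
            best_obj[better] = obj[better]
            full = np.zeros((int(better.sum()), N))
            full[:, sup] = a_s[better]
            best_a[better] = full
    # project tiny constraint violations back onto the simplex
    best_a = np.clip(best_a, 0.0, None)
    best_a /= best_a.sum(axis=1, keepdims=True)
    resid = best_a @ Em.T - R
    rmse = np.sqrt(np.einsum("pb,pb->p", resid, resid) / B)
    return best_a, rmse


def fcls_pixel(rho: np.ndarray, E: EndmemberMatrix | np.ndarray) -> tuple[np.ndarray, float]:
    """Simplex-constrained abundances and reconstruction RMSE for one pixel."""
    a, r = fcls(np.asarray(rho, dtype=float)[None, :], E)
    return a[0], float(r[0])


def oracle_fcls(
    rho: np.ndarray, E: EndmemberMatrix | np.ndarray, step: float
) -> np.ndarray:
    """Brute-force reference: exhaustive search over a simplex lattice.

    Evaluates ||E a - rho||_2 at every lattice point
    {(i*s, j*s, 1 - (i+j)*s) >= 0} and returns the minimizer.  Test oracle
    only — cost grows as 1/step^2.
    """
    Em = E.values if isinstance(E, EndmemberMatrix) else np.asarray(E, dtype=float)
    if step <= 0:
        raise ValueError("step must be positive")
    m = round(1.0 / step)
    if abs(m * step - 1.0) > 1e-9:
        raise ValueError("step must divide 1")
    grid = simplex_lattice(m)
    resid = grid @ Em.T - np.asarray(rho, dtype=float)
    obj = np.einsum("pb,pb->p", resid, resid)
    return grid[int(np.argmin(obj))]


def simplex_lattice(m: int) -> np.ndarray:
    """All points (i/m, j/m, 1 - (i+j)/m) with nonnegative coordinates."""
    i, j = np.meshgrid(np.arange(m + 1), np.arange(m + 1), indexing="ij")
    keep = (i + j) <= m
    a1 = i[keep] / m
    a2 = j[keep] / m
    a3 = np.maximum(1.0 - a1 - a2, 0.0)  # guard float dust at the boundary
    return np.column_stack([a1, a2, a3])


def unmix_image(image: ReflectanceImage, E: EndmemberMatrix) -> AbundanceImage:
    """Apply FCLS to every valid pixel of a reflectance image.

    Masked pixels propagate as invalid (abundance and residual NaN).  Summary
    statistics (mean abundance per endmember, residual quantiles) land in the
    output's ``meta``.
    """
    if image.sensor.n_bands != E.sensor.n_bands:
        raise ValueError(
            f"image has {image.sensor.n_bands} bands, endmember matrix expects "
            f"{E.sensor.n_bands}"
        )
    H, W = image.shape
    n_end = len(E.endmember_names)
    ab = np.full((n_end, H, W), np.nan)
    res = np.full((H, W), np.nan)
    valid = image.mask
    if np.any(valid):
        pixels = image.values[:, valid].T  # (P, B)
        a, r = fcls(pixels, E)
        for k in range(n_end):
            ab[k][valid] = a[:, k]
        res[valid] = r
    meta = {
        "n_valid": int(valid.sum()),
        "mean_abundance": {
            name: (float(np.nanmean(ab[k])) if np.any(valid) else float("nan"))
            for k, name in enumerate(E.endmember_names)
        },
        "residual_quantiles": (
            {q: float(np.nanquantile(res, float(q))) for q in ("0.5", "0.9", "1.0")}
            if np.any(valid)
            else {}
        ),
    }
    return AbundanceImage(
        values=ab, residual=res, mask=valid.copy(),
        endmember_names=tuple(E.endmember_names), meta=meta,
    )
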