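"""Fluorescence-anisotropy Kd fitting with the 1:1 depletion isotherm.

A FAM-labeled CTD peptide at fixed concentration L (75 nM in the assay this
models) is titrated with protein at concentrations P. Because L is not
negligible relative to Kd, the free-ligand approximation fails and the
bound fraction follows the quadratic (ligand-depletion) isotherm:

    f(P) = [(P + L + Kd) - sqrt((P + L + Kd)^2 - 4 P L)] / (2 L)

The measured anisotropy is A(P) = A_free + (A_bound - A_free) * f(P); Kd,
A_free, and A_bound are fitted by least squares with multi-start
initialization over a decade grid of Kd values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = ["BindingError", "BindingFit", "fraction_bound", "fit_titration"]


class BindingError(ValueError):
    pass


def fraction_bound(P, L: float, Kd: float):
    """Bound fraction of the labeled ligand under 1:1 binding with depletion.

    All concentrations in the same unit (nM by convention). Uses the
    algebraically equivalent form f = 2P / (s + sqrt(s^2 - 4PL)), s = P+L+Kd,
    which avoids catastrophic cancellation when the discriminant is small.
    """
    P = np.asarray(P, dtype=float)
    if L <= 0:
        raise BindingError("ligand concentration must be > 0")
    if Kd < 0 or np.any(P < 0):
        raise BindingError("concentrations and Kd must be >= 0")
    s = P + L + Kd
    disc = np.maximum(s * s - 4.0 * P * L, 0.0)
    denom = s + np.sqrt(disc)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(denom > 0, 2.0 * P / denom, 0.0)
    return f if f.ndim else float(f)


@dataclass
class BindingFit:
    kd: float
    a_free: float
    a_bound: float
    kd_se: float
    a_free_se: float
    a_bound_se: float
    residuals: np.ndarray
    converged: bool
    identifiable: bool
    ligand: float
    message: str = ""


def _model(params: np.ndarray, P: np.ndarray, L: float) -> np.ndarray:
    log_kd, a_free, a_bound = params
    return a_free + (a_bound - a_free) * fraction_bound(P, L, np.exp(log_kd))


def fit_titration(
    series: pd.DataFrame,
    ligand: float = 75.0,
    min_points: int = 5,
) -> BindingFit:
    """Fit (Kd, A_free, A_bound) to a titration.

    ``series`` needs columns concentration/anisotropy (replicate points may
    repeat concentrations; they are fitted pooled). Kd is optimized on a log
    scale from a grid of starts spanning the sampled concentration decades;
    standard errors come from the Jacobian at the optimum. A fit whose
    binding is already saturated at the lowest nonzero concentration is
    flagged non-identifiable.
    """
    P = np.asarray(series["concentration"], dtype=float)
    A = np.asarray(series["anisotropy"], dtype=float)
    if np.unique(P).size < min_points:
        raise BindingError(
            f"need >= {min_points} distinct concentrations, got {np.unique(P).size}"
        )
    if np.allclose(A, A[0]):
        raise BindingError("no binding signal: anisotropy is constant")
    if ligand <= 0:
        raise BindingError("ligand concentration must be > 0")

    pos = P[P > 0]
    lo = max(pos.min() / 10.0, 1e-6)
    hi = pos.max() * 10.0
    kd_grid = np.exp(np.linspace(np.log(lo), np.log(hi), 8))

    best = None
    a_lo, a_hi = float(A.min()), float(A.max())
    increasing = A[np.argmax(P)] >= A[np.argmin(P)]
    for kd0 in kd_grid:
        x0 = np.array(
            [np.log(kd0), a_lo if increasing else a_hi, a_hi if increasing else a_lo]
        )
        res = least_squares(
            lambda p: _model(p, P, ligand) - A, x0, method="lm", max_nfev=5000
        )
        if best is None or res.cost < best.cost - 1e-12:
            best = res

    log_kd, a_free, a_bound = best.x
    kd = float(np.exp(log_kd))
    # covariance from the Jacobian; delta method for Kd = exp(log_kd)
    dof = max(1, P.size - 3)
    s2 = 2.0 * best.cost / dof
    try:
        cov = s2 * np.linalg.inv(best.jac.T @ best.jac)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
        kd_se = float(se[0] * kd)
        a_free_se, a_bound_se = float(se[1]), float(se[2])
    except np.linalg.LinAlgError:
        kd_se = a_free_se = a_bound_se = float("nan")

    f_lowest = float(fraction_bound(pos.min(), ligand, kd))
    identifiable = f_lowest < 0.95 and kd < hi
    if a_bound == a_free:
        raise BindingError("degenerate fit: A_bound equals A_free")
    return BindingFit(
        kd=kd,
        a_free=float(a_free),
        a_bound=float(a_bound),
        kd_se=kd_se,
        a_free_se=a_free_se,
        a_bound_se=a_bound_se,
        residuals=_model(best.x, P, ligand) - A,
        converged=bool(best.success),
        identifiable=bool(identifiable),
        ligand=ligand,
        message=str(best.message),
    )
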