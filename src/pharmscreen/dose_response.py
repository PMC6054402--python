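"""Dose-response reduction: 4PL fitting, absolute IC50, AUC and Emax.

Each cell line's viability curve is summarized by a bounded least-squares
four-parameter logistic (4PL) fit

    v(d) = bottom + (top - bottom) / (1 + (d / ic50_fit)^hill),
    0 <= bottom <= top <= 1.2,  hill in [0.1, 10],

and three response metrics:

IC50
    *absolute* half-maximal concentration: the dose at which the fitted
    curve crosses viability 0.5, searched on [d_min/10, 10*d_max].  If the
    fitted curve never reaches 0.5 inside that window the IC50 is censored
    at 10*d_max (resistant) or reported at d_min/10 (fully inhibited at all
    doses); either way ``ic50_censored`` is set.
AUC
    trapezoidal area of the *observed* viabilities over log2(dose),
    normalized by the log-dose span, so a flat no-effect curve scores 1 and
    lower values mean greater sensitivity.
Emax
    minimum of the (replicate-mean) viabilities at the two highest doses —
    the maximum effect actually observed.

Curves that failed QC (or fits that do not converge) skip the 4PL step but
still receive AUC and Emax from the raw points, with IC50 censored, so
resistant lines remain representable downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .synth_screen import four_pl

_HILL_STARTS = (0.5, 1.0, 2.0)
_CENSOR_FACTOR = 10.0


@dataclass
class DoseResponseFit:
    cell_line_id: str
    top: float
    bottom: float
    hill: float
    ic50_fit: float         # 4PL midpoint parameter (uM)
    ic50: float             # absolute IC50 (uM), possibly censored
    ic50_censored: bool
    auc: float
    emax: float
    converged: bool
    rss: float
    qc_status: str = "pass"


def compute_auc(doses: np.ndarray, viabilities: np.ndarray) -> float:
    """Normalized trapezoidal AUC of observed viability over log2(dose)."""
    doses = np.asarray(doses, dtype=float)
    viabilities = np.asarray(viabilities, dtype=float)
    if doses.size < 2:
        raise ValueError("AUC needs >=2 dose points")
    order = np.argsort(doses)
    x = np.log2(doses[order])
    y = viabilities[order]
    return float(np.trapezoid(y, x) / (x[-1] - x[0]))


def compute_emax(doses: np.ndarray, viabilities: np.ndarray) -> float:
    """Minimum replicate-mean viability across the two highest doses."""
    doses = np.asarray(doses, dtype=float)
    viabilities = np.asarray(viabilities, dtype=float)
    if doses.size < 2:
        raise ValueError("Emax needs >=2 dose points")
    means = pd.Series(viabilities).groupby(pd.Series(doses)).mean()
    return float(means.iloc[-2:].min())  # groupby sorts doses ascending


def _fit_4pl(doses: np.ndarray, viab: np.ndarray):
    """Multi-start bounded least squares; returns (top, bottom, hill, ic50, rss, ok).

    Parametrized as (top, bottom_frac, hill, log10 ic50) with
    bottom = bottom_frac * top, which enforces 0 <= bottom <= top <= 1.2.
    Tie-break across starts: lowest RSS, then lowest hill.
    """
    log_d = np.log10(doses)
    lo = np.array([0.0, 0.0, 0.1, log_d.min() - 2.0])
    hi = np.array([1.2, 1.0, 10.0, log_d.max() + 2.0])

    def residuals(p):
        top, frac, hill, lic50 = p
        return four_pl(doses, top, frac * top, 10.0 ** lic50, hill) - viab

    geo_mid = float(np.mean(log_d))
    top0 = float(np.clip(viab.max(), 0.1, 1.2))
    frac0 = float(np.clip(viab.min() / top0 if top0 > 0 else 0.0, 0.0, 1.0))
    best = None
    for hill0 in _HILL_STARTS:
        x0 = np.clip([top0, frac0, hill0, geo_mid], lo, hi)
        try:
            sol = optimize.least_squares(residuals, x0, bounds=(lo, hi),
                                         method="trf")
        except Exception:
            continue
        if not sol.success:
            continue
        rss = float(2.0 * sol.cost)
        key = (round(rss, 12), sol.x[2])
        if best is None or key < best[0]:
            best = (key, sol.x, rss)
    if best is None:
        return None
    top, frac, hill, lic50 = best[1]
    return float(top), float(frac * top), float(hill), float(10.0 ** lic50), best[2]


def _absolute_ic50(top, bottom, hill, ic50_fit, d_min, d_max):
    """Dose where the fitted curve crosses viability 0.5, with censoring."""
    lo, hi = d_min / _CENSOR_FACTOR, d_max * _CENSOR_FACTOR

    def f(log_d):
        return four_pl(10.0 ** log_d, top, bottom, ic50_fit, hill) - 0.5

    f_lo, f_hi = f(np.log10(lo)), f(np.log10(hi))
    if f_lo <= 0:          # already at/below half-max at the lowest probe dose
        return lo, True
    if f_hi > 0:           # never reaches half-max: resistant, right-censored
        return hi, True
    root = optimize.brentq(f, np.log10(lo), np.log10(hi))
    return float(10.0 ** root), False


def fit_curve(cell_line_id: str, doses: np.ndarray, viabilities: np.ndarray,
              qc_status: str = "pass") -> DoseResponseFit:
    """Fit one viability curve and derive IC50 / AUC / Emax.

    QC-failed curves (``qc_status != 'pass'``) and non-convergent fits get
    ``converged=False`` with NaN 4PL parameters; AUC and Emax are still
    computed from the raw points and the IC50 is right-censored at
    10 x the maximum tested dose.
    """
    doses = np.asarray(doses, dtype=float)
    viabilities = np.asarray(viabilities, dtype=float)
    if doses.size < 4:
        raise ValueError("curve fitting needs >=4 dose points")
    order = np.argsort(doses)
    doses, viabilities = doses[order], viabilities[order]
    auc = compute_auc(doses, viabilities)
    emax = compute_emax(doses, viabilities)

    result = _fit_4pl(doses, viabilities) if qc_status == "pass" else None
    if result is None:
        return DoseResponseFit(
            cell_line_id=cell_line_id, top=np.nan, bottom=np.nan,
            hill=np.nan, ic50_fit=np.nan,
            ic50=float(doses[-1] * _CENSOR_FACTOR), ic50_censored=True,
            auc=auc, emax=emax, converged=False, rss=np.nan,
            qc_status=qc_status)
    top, bottom, hill, ic50_fit, rss = result
    ic50, censored = _absolute_ic50(top, bottom, hill, ic50_fit,
                                    doses[0], doses[-1])
    return DoseResponseFit(
        cell_line_id=cell_line_id, top=top, bottom=bottom, hill=hill,
        ic50_fit=ic50_fit, ic50=ic50, ic50_censored=censored,
        auc=auc, emax=emax, converged=True, rss=rss, qc_status=qc_status)


def fit_screen(curves: pd.DataFrame) -> pd.DataFrame:
    """Fit every cell line's curve in a long-format curves table.

    Expects columns cell_line_id, dose_um, viability, qc_status (as produced
    by ``plate_qc.build_curves``).  Returns one row per cell line.
    """
    rows = []
    for line_id, grp in curves.groupby("cell_line_id", sort=True):
        status = grp["qc_status"].iloc[0]
        fit = fit_curve(line_id, grp["dose_um"].to_numpy(),
                        grp["viability"].to_numpy(), qc_status=status)
        rows.append(fit.__dict__)
    cols = ["cell_line_id", "top", "bottom", "hill", "ic50_fit", "ic50",
            "ic50_censored", "auc", "emax", "converged", "rss", "qc_status"]
    return pd.DataFrame(rows, columns=cols)


def summarize_screen(fits: pd.DataFrame, tissues: pd.DataFrame) -> pd.DataFrame:
    """Per-tissue response table ordered for waterfall display.

    One row per cell line with tissue, ic50, ic50_censored, auc, emax;
    within each tissue rows are ordered by ascending AUC (most sensitive
    first).  Every fitted line must have a tissue label.
    """
    cols = ["cell_line_id", "tissue", "ic50", "ic50_censored", "auc", "emax"]
    if len(fits) == 0:
        return pd.DataFrame(columns=cols)
    tis = tissues.set_index("cell_line_id")["tissue"]
    missing = sorted(set(fits["cell_line_id"]) - set(tis.index))
    if missing:
        raise KeyError(f"cell lines without tissue label: {missing}")
    out = fits.copy()
    out["tissue"] = out["cell_line_id"].map(tis)
    out = out.sort_values(["tissue", "auc", "cell_line_id"],
                          kind="mergesort").reset_index(drop=True)
    return out[cols]
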