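"""Plate-level normalization and quality control for viability screens.

Raw fluorescence is normalized per plate to a viability fraction anchored at
the untreated-control mean (viability 1) and the cell-free blank mean
(viability 0).  Three QC filters are applied, each a strict inequality:

* control-well coefficient of variation must be below 20%,
* signal-over-noise (control mean over blank mean) must be over 5-fold,
* per-curve directionality — mean viability at the two lowest doses over the
  mean at the two highest — must be at least 1.2, otherwise the curve is
  rejected as responding in the wrong direction (or not at all).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class QCThresholds:
    max_control_cv: float = 0.20
    min_signal_over_noise: float = 5.0
    min_directionality_ratio: float = 1.2

    def __post_init__(self):
        if min(self.max_control_cv, self.min_signal_over_noise,
               self.min_directionality_ratio) <= 0:
            raise ValueError("QC thresholds must be strictly positive")


@dataclass(frozen=True)
class PlateQCReport:
    plate_id: str
    control_cv: float
    signal_over_noise: float
    pass_cv: bool
    pass_sn: bool

    @property
    def passed(self) -> bool:
        return self.pass_cv and self.pass_sn


class DegeneratePlateError(ValueError):
    """Plate with no usable dynamic range (control mean <= blank mean)."""


def _plate_means(wells: pd.DataFrame) -> tuple[float, float]:
    control = wells.loc[wells["role"] == "control", "raw_signal"]
    blank = wells.loc[wells["role"] == "blank", "raw_signal"]
    if len(control) < 2 or len(blank) < 1:
        raise ValueError("plate needs >=2 control wells and >=1 blank well")
    return float(control.mean()), float(blank.mean())


def normalize_plate(wells: pd.DataFrame) -> pd.DataFrame:
    """Normalize one plate's treated wells to viability fractions.

    viability = (raw - mean(blank)) / (mean(control) - mean(blank)); the
    control mean maps to exactly 1 and the blank mean to 0.  Values are not
    clamped: negative viabilities (signal below blank) are preserved.
    Requires at least 2 control and 2 blank wells.
    """
    blank = wells.loc[wells["role"] == "blank", "raw_signal"]
    if len(blank) < 2:
        raise ValueError("plate needs >=2 blank wells for normalization")
    control_mean, blank_mean = _plate_means(wells)
    if control_mean <= blank_mean:
        raise DegeneratePlateError(
            f"plate {wells['plate_id'].iat[0]!r}: control mean "
            f"({control_mean:g}) <= blank mean ({blank_mean:g})")
    treated = wells[wells["role"] == "treated"].copy()
    treated["viability"] = (treated["raw_signal"] - blank_mean) / (
        control_mean - blank_mean)
    return treated


def qc_plate(wells: pd.DataFrame,
             thresholds: QCThresholds = QCThresholds()) -> PlateQCReport:
    """Compute control CV and signal-over-noise for one plate.

    CV uses the sample (n-1) standard deviation over the mean of control raw
    signals.  Passing requires CV strictly below ``max_control_cv`` and
    signal-over-noise strictly above ``min_signal_over_noise``.
    """
    control = wells.loc[wells["role"] == "control", "raw_signal"]
    control_mean, blank_mean = _plate_means(wells)
    if control_mean == 0:
        raise ValueError("control mean is zero; CV undefined")
    cv = float(control.std(ddof=1)) / control_mean
    sn = control_mean / blank_mean if blank_mean > 0 else np.inf
    return PlateQCReport(
        plate_id=str(wells["plate_id"].iat[0]),
        control_cv=cv,
        signal_over_noise=sn,
        pass_cv=cv < thresholds.max_control_cv,
        pass_sn=sn > thresholds.min_signal_over_noise,
    )


def directionality_check(doses: np.ndarray, viabilities: np.ndarray,
                         thresholds: QCThresholds = QCThresholds()
                         ) -> tuple[bool, float]:
    """Check that the curve responds in the right direction.

    ratio = mean(viability at the two lowest doses) /
            mean(viability at the two highest doses);
    the curve fails iff the ratio is strictly below
    ``min_directionality_ratio`` (flat and inverted curves are rejected).
    A non-positive high-dose mean is a degenerate denominator: the curve is
    failed with ratio reported as NaN.

    Returns ``(passed, ratio)``.
    """
    doses = np.asarray(doses, dtype=float)
    viabilities = np.asarray(viabilities, dtype=float)
    if doses.size < 4:
        raise ValueError("directionality check needs >=4 dose points")
    order = np.argsort(doses)
    low = viabilities[order[:2]].mean()
    high = viabilities[order[-2:]].mean()
    if high <= 0:
        return False, float("nan")
    ratio = low / high
    return ratio >= thresholds.min_directionality_ratio, float(ratio)


def build_curves(wells: pd.DataFrame,
                 thresholds: QCThresholds = QCThresholds()) -> pd.DataFrame:
    """Normalize all plates and assemble per-line viability curves with QC.

    Returns a long-format table (cell_line_id, plate_id, dose_um, viability,
    qc_status) where qc_status is one of pass / fail_cv / fail_sn /
    fail_directionality, applied in that order of precedence.
    """
    frames = []
    for plate_id, plate in wells.groupby("plate_id", sort=True):
        report = qc_plate(plate, thresholds)
        treated = normalize_plate(plate)
        if not report.pass_cv:
            plate_status = "fail_cv"
        elif not report.pass_sn:
            plate_status = "fail_sn"
        else:
            plate_status = "pass"
        for line_id, grp in treated.groupby("cell_line_id", sort=True):
            mean_v = (grp.groupby("dose_um", sort=True)["viability"]
                      .mean())
            status = plate_status
            if status == "pass":
                ok, _ = directionality_check(mean_v.index.to_numpy(),
                                             mean_v.to_numpy(), thresholds)
                if not ok:
                    status = "fail_directionality"
            frames.append(pd.DataFrame({
                "cell_line_id": line_id,
                "plate_id": plate_id,
                "dose_um": mean_v.index.to_numpy(),
                "viability": mean_v.to_numpy(),
                "qc_status": status,
            }))
    if not frames:
        return pd.DataFrame(columns=["cell_line_id", "plate_id", "dose_um",
                                     "viability", "qc_status"])
    return pd.concat(frames, ignore_index=True)


def qc_report_table(wells: pd.DataFrame,
                    thresholds: QCThresholds = QCThresholds()) -> pd.DataFrame:
    """Per-plate QC report as a DataFrame."""
    rows = [qc_plate(plate, thresholds).__dict__
            for _, plate in wells.groupby("plate_id", sort=True)]
    return pd.DataFrame(rows)
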