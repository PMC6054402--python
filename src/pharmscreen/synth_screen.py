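"""Synthetic drug-sensitivity screens with planted ground truth.

Emulates the structure of a large cell-line viability screen: a cohort of
cell lines spread over many tissues of origin, multi-omic feature tables
(expression, copy number, binary mutations), and 384-well plates holding a
2-fold dilution dose series plus untreated-control and blank wells.  A small
set of *planted* genomic effects drives a latent log10(IC50) per cell line,
so every downstream stage (normalization, curve fitting, feature selection)
can be validated against known truth.

Response is generated as "mostly dichotomous": a subset of responder lines
follow a true four-parameter logistic (4PL) viability curve with IC50 taken
from the latent score, while non-responders stay flat at full viability even
at the maximum dose.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Tissues of origin represented in the screened cohort.
DEFAULT_TISSUES = (
    "Biliary Tract", "Bone", "Brain", "Breast", "Esophagus", "Head & Neck",
    "Intestine", "Kidney", "Leukemia", "Liver", "Lung", "Lymphoma", "Muscle",
    "Nervous System", "Ovary", "Pancreas", "Pleura", "Skin", "Stomach",
    "Thyroid", "Urinary Tract", "Uterus",
)

DEFAULT_N_LINES = 624
DEFAULT_TOP_DOSE_UM = 10.64
DEFAULT_N_DOSES = 7


def default_dose_series(top_dose_um: float = DEFAULT_TOP_DOSE_UM,
                        n_doses: int = DEFAULT_N_DOSES) -> np.ndarray:
    """Ascending 2-fold dilution series obtained by halving from the top dose.

    The default seven-point series runs 10.64, 5.32, 2.66, 1.33, 0.665,
    0.3325, 0.16625 uM — i.e. it spans ~0.16 to 10.64 uM.
    """
    if n_doses < 1:
        raise ValueError("n_doses must be >= 1")
    return np.array([top_dose_um / 2.0 ** k for k in range(n_doses)][::-1])


class ConfigurationError(ValueError):
    """Raised when a generator spec violates its invariants."""


@dataclass(frozen=True)
class CohortSpec:
    """Cohort of cell lines with tissue-of-origin proportions."""

    n_lines: int = DEFAULT_N_LINES
    tissues: tuple[str, ...] = DEFAULT_TISSUES
    proportions: tuple[float, ...] | None = None  # default: uniform
    seed: int = 0

    def __post_init__(self):
        if self.n_lines < 1:
            raise ConfigurationError("n_lines must be >= 1")
        if len(self.tissues) == 0:
            raise ConfigurationError("tissue list must be non-empty")
        props = self.effective_proportions()
        if abs(sum(props) - 1.0) > 1e-9:
            raise ConfigurationError("tissue proportions must sum to 1")

    def effective_proportions(self) -> tuple[float, ...]:
        if self.proportions is None:
            return tuple(1.0 / len(self.tissues) for _ in self.tissues)
        if len(self.proportions) != len(self.tissues):
            raise ConfigurationError("proportions must match tissues in length")
        return self.proportions


@dataclass(frozen=True)
class PlantedEffect:
    """A genomic feature with a known effect on drug response.

    ``beta`` is the signed shift in latent log10(IC50 uM) per standard
    deviation of the (z-scored) feature; negative beta marks a sensitivity
    feature (higher feature value -> lower IC50), positive beta resistance.
    """

    feature_name: str
    beta: float

    def __post_init__(self):
        if self.beta == 0:
            raise ConfigurationError("planted beta must be nonzero")

    @property
    def direction(self) -> str:
        return "sensitivity" if self.beta < 0 else "resistance"


@dataclass(frozen=True)
class GenomicsSpec:
    """Sizes of the omic feature tables and the list of planted effects."""

    n_exp: int = 500
    n_cn: int = 2000  # pre-cap pool; assembly later restricts to 1700
    n_mut: int = 300
    mutation_rate: float = 0.05
    planted: tuple[PlantedEffect, ...] = ()
    baseline_log10_ic50: float = 0.0
    residual_sd: float = 0.3

    def __post_init__(self):
        for n in (self.n_exp, self.n_cn, self.n_mut):
            if n < 0:
                raise ConfigurationError("feature counts must be >= 0")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ConfigurationError("mutation_rate must be in [0, 1]")
        if self.residual_sd < 0:
            raise ConfigurationError("residual_sd must be >= 0")


@dataclass(frozen=True)
class ScreenSpec:
    """Plate layout, dose series and response model for the screen."""

    doses_um: tuple[float, ...] = tuple(default_dose_series())
    responder_fraction: float = 0.3
    responder_ic50_log10_mean: float = 0.0   # 1 uM, inside the dose range
    responder_ic50_log10_sd: float = 0.5
    hill: float = 1.0
    top: float = 1.0
    bottom: float = 0.0
    noise_sd: float = 0.02          # fraction of the control-blank dynamic range
    control_level: float = 1000.0   # raw fluorescence of untreated controls
    blank_level: float = 100.0      # raw fluorescence of cell-free wells
    n_control_wells: int = 8
    n_blank_wells: int = 8
    plate_size: int = 384
    replicates: int = 1

    def __post_init__(self):
        doses = np.asarray(self.doses_um, dtype=float)
        if doses.size < 1 or np.any(doses <= 0):
            raise ConfigurationError("doses must be positive")
        if np.any(np.diff(doses) <= 0):
            raise ConfigurationError("doses must be strictly increasing")
        if not 0.0 <= self.responder_fraction <= 1.0:
            raise ConfigurationError("responder_fraction must be in [0, 1]")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.control_level <= self.blank_level:
            raise ConfigurationError("control_level must exceed blank_level")
        wells_needed = self.n_control_wells + self.n_blank_wells + len(self.doses_um)
        if self.plate_size < wells_needed:
            raise ConfigurationError("plate_size too small for layout")


def four_pl(dose: np.ndarray | float, top: float, bottom: float,
            ic50: float, hill: float) -> np.ndarray | float:
    """Four-parameter logistic viability: bottom + (top-bottom)/(1+(d/ic50)^hill)."""
    return bottom + (top - bottom) / (1.0 + (np.asarray(dose, dtype=float) / ic50) ** hill)


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a cohort of cell lines with multinomial tissue assignment.

    Returns a DataFrame with columns ``cell_line_id`` and ``tissue``;
    deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    counts = rng.multinomial(spec.n_lines, spec.effective_proportions())
    tissues = np.repeat(list(spec.tissues), counts)
    rng.shuffle(tissues)
    width = max(4, len(str(spec.n_lines)))
    ids = [f"CL{i + 1:0{width}d}" for i in range(spec.n_lines)]
    return pd.DataFrame({"cell_line_id": ids, "tissue": tissues})


def _gene_names(prefix: str, n: int) -> list[str]:
    return [f"{prefix}{i + 1:04d}" for i in range(n)]


@dataclass
class GenomicsTables:
    """Omic matrices (cell lines x genes) plus latent response and truth."""

    expression: pd.DataFrame
    cn: pd.DataFrame
    mutations: pd.DataFrame
    latent_log10_ic50: pd.Series
    truth: pd.DataFrame = field(repr=False)


def generate_genomics(cohort: pd.DataFrame, spec: GenomicsSpec,
                      seed: int) -> GenomicsTables:
    """Generate expression/CN/mutation tables and the latent log10(IC50).

    Expression and copy-number features are independent standard normals;
    mutations are Bernoulli(``mutation_rate``).  The latent score is
    ``baseline + sum(beta * z(feature)) + N(0, residual_sd)`` where ``z`` is
    the per-column z-score over the cohort (constant columns contribute 0).
    """
    if len(cohort) == 0:
        raise ValueError("cohort must be non-empty")
    rng = np.random.default_rng(seed)
    ids = cohort["cell_line_id"].to_numpy()
    n = len(ids)

    exp = pd.DataFrame(rng.standard_normal((n, spec.n_exp)),
                       index=ids, columns=_gene_names("G", spec.n_exp))
    cn = pd.DataFrame(rng.standard_normal((n, spec.n_cn)),
                      index=ids, columns=_gene_names("G", spec.n_cn))
    mut = pd.DataFrame(
        (rng.random((n, spec.n_mut)) < spec.mutation_rate).astype(int),
        index=ids, columns=_gene_names("G", spec.n_mut))

    tables = {"EXP": exp, "CN": cn, "MUT": mut}
    latent = np.full(n, spec.baseline_log10_ic50, dtype=float)
    truth_rows = []
    for effect in spec.planted:
        col = None
        for tname, table in tables.items():
            if effect.feature_name in table.columns:
                col = table[effect.feature_name].to_numpy(dtype=float)
                type_ = tname
                break
        if col is None:
            raise KeyError(
                f"planted feature {effect.feature_name!r} not present in any "
                f"generated table")
        sd = col.std()
        z = (col - col.mean()) / sd if sd > 0 else np.zeros_like(col)
        latent += effect.beta * z
        truth_rows.append({"feature": f"{type_}_{effect.feature_name}",
                           "true_beta": effect.beta,
                           "direction": effect.direction})
    latent += rng.normal(0.0, spec.residual_sd, size=n)
    truth = pd.DataFrame(truth_rows, columns=["feature", "true_beta", "direction"])
    return GenomicsTables(expression=exp, cn=cn, mutations=mut,
                          latent_log10_ic50=pd.Series(latent, index=ids),
                          truth=truth)


def _well_ids(plate_size: int) -> list[str]:
    # standard microplate coordinates, e.g. 384-well = rows A-P x columns 1-24
    n_rows = {96: 8, 384: 16, 1536: 32}.get(plate_size)
    if n_rows is None:
        n_rows = int(math.floor(math.sqrt(plate_size / 1.5)))
    n_cols = math.ceil(plate_size / n_rows)
    ids = []
    for r in range(n_rows):
        row = chr(ord("A") + r) if r < 26 else "A" + chr(ord("A") + r - 26)
        for c in range(n_cols):
            ids.append(f"{row}{c + 1:02d}")
    return ids[:plate_size]


def generate_screen(cohort: pd.DataFrame,
                    latent_scores: pd.Series | None,
                    spec: ScreenSpec,
                    seed: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Lay out the screen on plates and simulate raw fluorescence wells.

    Responders follow a true 4PL curve with IC50 = 10^latent; non-responders
    are flat at viability ~1 even at the top dose, giving the dichotomous
    response pattern.  When ``latent_scores`` is provided, the responding
    ``responder_fraction`` of lines are those with the *lowest* latent
    log10(IC50) — the dichotomy is driven by the planted genomics, so
    planted biomarkers propagate into the censored IC50 response.  When
    ``latent_scores`` is None, responder status is Bernoulli and responder
    IC50s are drawn log-normal per the spec.
    Raw signal = blank_level + viability * (control - blank) + Gaussian noise.

    Returns ``(wells, truth)``: the well table (plate_id, well_id,
    cell_line_id, role, dose_um, raw_signal) and the per-line ground truth
    (responder_flag, true_ic50_um).
    """
    rng = np.random.default_rng(seed)
    ids = cohort["cell_line_id"].to_numpy()
    if latent_scores is not None:
        missing = [i for i in ids if i not in latent_scores.index]
        if missing:
            raise KeyError(f"cell lines without latent score: {missing[:5]}")

    if latent_scores is not None:
        log_ic50 = latent_scores.loc[ids].to_numpy(dtype=float)
        n_resp = int(round(spec.responder_fraction * len(ids)))
        responder = np.zeros(len(ids), dtype=bool)
        responder[np.argsort(log_ic50, kind="stable")[:n_resp]] = True
    else:
        responder = rng.random(len(ids)) < spec.responder_fraction
        log_ic50 = rng.normal(spec.responder_ic50_log10_mean,
                              spec.responder_ic50_log10_sd, size=len(ids))
    true_ic50 = 10.0 ** log_ic50

    doses = np.asarray(spec.doses_um, dtype=float)
    dyn_range = spec.control_level - spec.blank_level
    noise_scale = spec.noise_sd * dyn_range
    wells_per_line = len(doses) * spec.replicates
    treated_capacity = spec.plate_size - spec.n_control_wells - spec.n_blank_wells
    lines_per_plate = max(1, treated_capacity // wells_per_line)

    well_names = _well_ids(spec.plate_size)
    records: list[dict] = []
    for p_start in range(0, len(ids), lines_per_plate):
        plate_lines = range(p_start, min(p_start + lines_per_plate, len(ids)))
        plate_id = f"P{p_start // lines_per_plate + 1:03d}"
        cursor = 0
        for _ in range(spec.n_control_wells):
            sig = spec.control_level + (rng.normal(0, noise_scale) if noise_scale else 0.0)
            records.append({"plate_id": plate_id, "well_id": well_names[cursor],
                            "cell_line_id": "", "role": "control",
                            "dose_um": np.nan, "raw_signal": max(sig, 0.0)})
            cursor += 1
        for _ in range(spec.n_blank_wells):
            sig = spec.blank_level + (rng.normal(0, noise_scale) if noise_scale else 0.0)
            records.append({"plate_id": plate_id, "well_id": well_names[cursor],
                            "cell_line_id": "", "role": "blank",
                            "dose_um": np.nan, "raw_signal": max(sig, 0.0)})
            cursor += 1
        for li in plate_lines:
            if responder[li]:
                viab = four_pl(doses, spec.top, spec.bottom, true_ic50[li], spec.hill)
            else:
                viab = np.ones_like(doses)
            for _ in range(spec.replicates):
                for d, v in zip(doses, viab):
                    sig = spec.blank_level + v * dyn_range
                    if noise_scale:
                        sig += rng.normal(0, noise_scale)
                    records.append({"plate_id": plate_id,
                                    "well_id": well_names[cursor],
                                    "cell_line_id": ids[li], "role": "treated",
                                    "dose_um": d, "raw_signal": max(sig, 0.0)})
                    cursor += 1

    wells = pd.DataFrame.from_records(records)
    truth = pd.DataFrame({"cell_line_id": ids,
                          "responder_flag": responder.astype(int),
                          "true_ic50_um": np.where(responder, true_ic50, np.nan)})
    return wells, truth
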