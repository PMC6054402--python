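"""Elastic-net stability selection for pharmacogenomic biomarkers.

The response model is a multivariate linear regression of log10(IC50) on
all genomic features, fitted with an elastic-net penalty.  To score the
stability of each feature, the fit is repeated ``n_runs`` times (default
100), each time leaving a random 10% of the cell lines out; within each
run the penalty strength is chosen by internal k-fold cross-validation on
the training split, after standardizing columns on that split only.

Per feature the procedure aggregates:

Freq
    fraction of runs in which the feature's coefficient was nonzero; a
    Freq of 1 means every model contained the feature.  Reported gene
    lists use the conventional threshold Freq > 0.7 (strict).
weight
    mean coefficient across the runs where the feature was selected
    (configurable to average over all runs instead).
effect
    normalized weight: weight / sqrt(number of features of that feature's
    type), so feature types of very different cardinality are comparable.
direction
    sensitivity for weight < 0 (higher feature value in lines with lower
    IC50), resistance for weight > 0.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNetCV
from sklearn.model_selection import KFold

from .feature_matrix import FeatureMatrix, feature_type


@dataclass(frozen=True)
class ENConfig:
    n_runs: int = 100
    holdout_fraction: float = 0.10
    l1_ratio: float = 0.5
    cv_folds: int = 5
    n_alphas: int = 60
    alphas: tuple[float, ...] | None = None  # explicit penalty grid override
    max_iter: int = 5000
    weight_over_all_runs: bool = False   # alternative "weight" semantics
    exclude_censored: bool = False
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.holdout_fraction < 1:
            raise ValueError("holdout_fraction must be in (0, 1)")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if not 0 < self.l1_ratio <= 1:
            raise ValueError("l1_ratio must be in (0, 1]")


@dataclass
class ENSummary:
    """Aggregated stability-selection output.

    ``features`` has one row per feature: type, freq, weight, effect,
    direction.  ``runs`` has one row per run: holdout R^2 and the selected
    penalty.  ``coefficients`` retains the full n_runs x p coefficient
    matrix so frequencies are auditable.
    """

    features: pd.DataFrame
    runs: pd.DataFrame
    coefficients: pd.DataFrame


def _standardize(train: np.ndarray, other: np.ndarray):
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    safe = np.where(sd > 0, sd, 1.0)  # zero-variance columns stay constant 0
    return (train - mu) / safe, (other - mu) / safe


def run_stability_selection(fm: FeatureMatrix,
                            cfg: ENConfig = ENConfig()) -> ENSummary:
    """Repeated leave-``holdout_fraction``-out elastic-net fits.

    Each run: draw a holdout of ceil(holdout_fraction * n) lines,
    standardize columns on the remaining training lines, fit an elastic net
    with the penalty chosen by internal ``cv_folds``-fold CV, and record the
    coefficient vector and held-out R^2.  Fully reproducible from
    ``cfg.seed``.
    """
    X = fm.X
    y = fm.y
    if cfg.exclude_censored:
        keep = ~fm.censored_mask.to_numpy()
        X, y = X.loc[keep], y.loc[keep]
    n, p = X.shape
    if n < 20:
        raise ValueError("stability selection needs >= 20 cell lines")
    if not np.all(np.isfinite(y.to_numpy(dtype=float))):
        raise ValueError("response vector contains non-finite values")
    n_hold = math.ceil(cfg.holdout_fraction * n)
    if n_hold > n - 10:
        raise ValueError("holdout leaves too few training lines")

    Xv = X.to_numpy(dtype=float)
    yv = y.to_numpy(dtype=float)
    constant_y = np.ptp(yv) == 0
    if constant_y:
        warnings.warn("response is constant; no selectable signal",
                      stacklevel=2)

    children = np.random.SeedSequence(cfg.seed).spawn(cfg.n_runs)
    coefs = np.zeros((cfg.n_runs, p))
    run_rows = []
    for r, child in enumerate(children):
        rng = np.random.default_rng(child)
        perm = rng.permutation(n)
        hold, train = perm[:n_hold], perm[n_hold:]
        Xtr, Xho = _standardize(Xv[train], Xv[hold])
        ytr, yho = yv[train], yv[hold]
        alpha, r2 = np.nan, np.nan
        if not constant_y:
            cv = KFold(n_splits=cfg.cv_folds, shuffle=True,
                       random_state=int(rng.integers(2 ** 31)))
            grid = list(cfg.alphas) if cfg.alphas is not None else cfg.n_alphas
            model = ElasticNetCV(l1_ratio=cfg.l1_ratio, cv=cv,
                                 alphas=grid, max_iter=cfg.max_iter,
                                 fit_intercept=True)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                model.fit(Xtr, ytr)
            coefs[r] = model.coef_
            alpha = float(model.alpha_)
            ss_res = float(((yho - model.predict(Xho)) ** 2).sum())
            ss_tot = float(((yho - yho.mean()) ** 2).sum())
            r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
        run_rows.append({"run": r, "holdout_r2": r2, "alpha": alpha,
                         "n_holdout": n_hold})

    selected = coefs != 0
    freq = selected.mean(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-zero columns
        if cfg.weight_over_all_runs:
            weight = coefs.mean(axis=0)
        else:
            weight = np.where(selected.any(axis=0),
                              coefs.sum(axis=0) / np.maximum(selected.sum(axis=0), 1),
                              0.0)
    types = [feature_type(c) for c in X.columns]
    type_counts = pd.Series(types).value_counts().to_dict()
    norm = np.array([math.sqrt(type_counts[t]) for t in types])
    effect = weight / norm
    direction = np.where(weight < 0, "sensitivity",
                         np.where(weight > 0, "resistance", "none"))
    features = pd.DataFrame({
        "feature": X.columns, "type": types, "freq": freq,
        "weight": weight, "effect": effect, "direction": direction,
    }).set_index("feature")
    return ENSummary(features=features,
                     runs=pd.DataFrame(run_rows),
                     coefficients=pd.DataFrame(coefs, columns=X.columns))


def summarize_features(summary: ENSummary,
                       freq_threshold: float = 0.7
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split stable features into sensitivity and resistance gene lists.

    Features with freq strictly above ``freq_threshold`` are partitioned by
    coefficient sign (negative = sensitivity, positive = resistance) and
    each list is ranked by |effect| descending, ties broken by name.
    """
    feats = summary.features
    stable = feats[feats["freq"] > freq_threshold].copy()
    stable["abs_effect"] = stable["effect"].abs()
    stable = stable.iloc[np.lexsort((stable.index.to_numpy(),
                                     -stable["abs_effect"].to_numpy()))]
    sens = stable[stable["weight"] < 0].drop(columns="abs_effect")
    resist = stable[stable["weight"] > 0].drop(columns="abs_effect")
    return sens, resist
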