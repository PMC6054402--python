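"""Assembly of the multi-omic design matrix for response modeling.

Columns are typed by prefix — TIS_ (tissue one-hot), CN_ (copy number),
EXP_ (expression), MUT_ (binary mutation) — and rows are the cell lines
common to every input table.  The copy-number block is restricted to the
``cn_cap`` genes (default 1700) whose copy number correlates most strongly
with that gene's expression across lines, i.e. the genes whose copy-number
alterations are actually translated into RNA expression.

The response vector is y = log10(IC50 uM); right-censored IC50s are kept at
their censoring bound (dropping them would delete the resistance signal the
downstream elastic net is meant to find) and flagged in ``censored_mask``.
Features are deliberately NOT standardized here — standardization happens
inside each training split of the stability selection to avoid leakage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_CN_CAP = 1700

TYPE_PREFIXES = ("TIS_", "CN_", "EXP_", "MUT_")


@dataclass
class FeatureMatrix:
    """Design matrix X (lines x typed features), response y and metadata."""

    X: pd.DataFrame
    y: pd.Series                  # log10(IC50 uM)
    censored_mask: pd.Series
    type_counts: dict[str, int]
    dropped_lines: list[str] = field(default_factory=list)

    def __post_init__(self):
        assert self.X.shape[1] == sum(self.type_counts.values())

    def block(self, prefix: str) -> pd.DataFrame:
        return self.X.loc[:, [c for c in self.X.columns
                              if c.startswith(prefix + "_")]]


def encode_tissue(tissue_labels: pd.Series) -> pd.DataFrame:
    """One-hot encode tissue of origin; one column per distinct tissue.

    Row sums are exactly 1.  Empty or missing labels raise.
    """
    labels = tissue_labels.astype(object)
    bad = labels.index[labels.isna() | (labels == "")]
    if len(bad):
        raise ValueError(f"empty tissue label for lines: {list(bad[:5])}")
    onehot = pd.get_dummies(labels, prefix="TIS", prefix_sep="_", dtype=float)
    return onehot.reindex(sorted(onehot.columns), axis=1)


def rank_cn_genes(cn: pd.DataFrame, expression: pd.DataFrame) -> pd.Series:
    """|Pearson r| between each CN gene and its matching expression gene.

    Genes absent from the expression table get correlation 0 (no evidence
    that their copy-number change is expressed).  Ties in downstream ranking
    break lexicographically by gene name.
    """
    shared = cn.columns.intersection(expression.columns)
    corr = pd.Series(0.0, index=cn.columns)
    if len(shared):
        a = cn[shared].to_numpy(dtype=float)
        b = expression.loc[cn.index, shared].to_numpy(dtype=float)
        a = a - a.mean(axis=0)
        b = b - b.mean(axis=0)
        denom = np.sqrt((a ** 2).sum(axis=0) * (b ** 2).sum(axis=0))
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(denom > 0, (a * b).sum(axis=0) / denom, 0.0)
        corr[shared] = np.abs(r)
    return corr


def assemble_features(expression: pd.DataFrame,
                      cn: pd.DataFrame,
                      mutations: pd.DataFrame,
                      tissues: pd.DataFrame,
                      fits: pd.DataFrame,
                      cn_cap: int = DEFAULT_CN_CAP) -> FeatureMatrix:
    """Join omic blocks and the IC50 response into one FeatureMatrix.

    Cell lines are intersected across all inputs; lines present in some
    inputs but not all are dropped and reported in ``dropped_lines``.
    The CN block is capped to the ``cn_cap`` genes with the highest
    |CN-expression correlation| (ties broken lexicographically).
    """
    tis = tissues.set_index("cell_line_id")["tissue"]
    fit_idx = fits.set_index("cell_line_id")
    tables = {"expression": expression, "cn": cn, "mutations": mutations}
    common = set(tis.index) & set(fit_idx.index)
    for t in tables.values():
        common &= set(t.index)
    union = set(tis.index) | set(fit_idx.index)
    for t in tables.values():
        union |= set(t.index)
    if len(common) < 2:
        raise ValueError("fewer than 2 cell lines shared across all inputs")
    lines = sorted(common)
    dropped = sorted(union - common)

    exp = expression.loc[lines]
    cnb = cn.loc[lines]
    mut = mutations.loc[lines]

    if cn_cap < cnb.shape[1]:
        score = rank_cn_genes(cnb, exp)
        order = sorted(cnb.columns, key=lambda g: (-score[g], g))
        cnb = cnb[order[:cn_cap]]
    elif cn_cap > cnb.shape[1]:
        warnings.warn(f"cn_cap={cn_cap} exceeds available CN genes "
                      f"({cnb.shape[1]}); keeping all", stacklevel=2)

    tis_block = encode_tissue(tis.loc[lines])
    blocks = [
        tis_block,
        cnb.add_prefix("CN_"),
        exp.add_prefix("EXP_"),
        mut.add_prefix("MUT_").astype(float),
    ]
    X = pd.concat(blocks, axis=1)
    if X.isna().any().any():
        raise ValueError("missing values in assembled feature matrix")

    ic50 = fit_idx.loc[lines, "ic50"].astype(float)
    y = pd.Series(np.log10(ic50.to_numpy()), index=lines, name="log10_ic50")
    censored = fit_idx.loc[lines, "ic50_censored"].astype(bool)
    counts = {"TIS": tis_block.shape[1], "CN": cnb.shape[1],
              "EXP": exp.shape[1], "MUT": mut.shape[1]}
    return FeatureMatrix(X=X, y=y, censored_mask=censored,
                         type_counts=counts, dropped_lines=dropped)


def feature_type(name: str) -> str:
    """Type prefix of a feature column name (TIS/CN/EXP/MUT)."""
    for p in TYPE_PREFIXES:
        if name.startswith(p):
            return p[:-1]
    raise ValueError(f"feature {name!r} has no valid type prefix")
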