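"""Tab-separated readers/writers for the pipeline's on-disk interfaces."""

from __future__ import annotations

from pathlib import Path

import pandas as pd


def read_wells(path) -> pd.DataFrame:
    """Read wells.tsv (plate_id, well_id, cell_line_id, role, dose_um, raw_signal)."""
    df = pd.read_csv(path, sep="\t", dtype={"plate_id": str, "well_id": str},
                     keep_default_na=False, na_values=[""])
    df["cell_line_id"] = df["cell_line_id"].fillna("")
    df["dose_um"] = pd.to_numeric(df["dose_um"], errors="coerce")
    df["raw_signal"] = pd.to_numeric(df["raw_signal"])
    return df


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


def read_matrix(path) -> pd.DataFrame:
    """Read a cell-lines x genes matrix with a header row of gene ids."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(df: pd.DataFrame, path) -> None:
    write_tsv(df, path, index=True)


def read_gene_set(path) -> list[str]:
    """One gene identifier per line; blank lines ignored."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT file: term <tab> description <tab> gene1 <tab> gene2 ...

    Returns term -> gene list; the description column is discarded.
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def read_edge_list(path) -> pd.DataFrame:
    """Read a 2- or 3-column edge list (gene_a, gene_b[, score])."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError("edge list needs at least two columns")
    return df
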