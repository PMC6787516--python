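"""Reading, validation and alignment of expression matrices and trait tables.

File conventions: expression matrices are TSV/CSV with gene (or probe) ids in
the first column and sample ids in the header; trait tables are TSV with
sample ids in the first column; probe maps are two-column TSV (probe, gene).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, TraitTable

log = logging.getLogger("coexnet")

_SEPS = {"tsv": "\t", "csv": ","}

#: Rows with at most this fraction of missing cells are mean-imputed; rows
#: with more are dropped (downstream correlations need complete data).
MAX_MISSING_FRACTION = 0.10


def read_expression(path, dialect: str = "tsv") -> ExpressionMatrix:
    """Read an expression matrix from a delimited text file.

    Non-numeric cells become missing values; rows with <10% missing are
    mean-imputed per row, rows with more are rejected (counts are logged).
    Duplicate gene or sample identifiers are a hard error.
    """
    sep = _SEPS[dialect]
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"empty expression matrix in {path}")
    df = df.apply(pd.to_numeric, errors="coerce")
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        dups = sorted(set(df.index[df.index.duplicated()]))
        raise ValueError(f"duplicate row identifiers in {path}: {dups}")

    frac_missing = df.isna().mean(axis=1)
    bad = frac_missing > MAX_MISSING_FRACTION
    if bad.any():
        log.warning("dropping %d rows with >%.0f%% missing/non-numeric cells",
                    int(bad.sum()), 100 * MAX_MISSING_FRACTION)
        df = df.loc[~bad]
    to_impute = df.isna().any(axis=1)
    if to_impute.any():
        log.info("mean-imputing %d rows with sporadic missing cells",
                 int(to_impute.sum()))
        row_means = df.mean(axis=1)
        df = df.apply(lambda col: col.fillna(row_means))
    return ExpressionMatrix(df)


def write_expression(expr: ExpressionMatrix, path, dialect: str = "tsv") -> None:
    """Write an expression matrix in the format :func:`read_expression` reads."""
    expr.data.to_csv(path, sep=_SEPS[dialect], index_label="gene",
                     float_format="%.10g")


def read_probe_map(path) -> pd.Series:
    """Read a two-column (probe, gene) TSV into a probe->gene Series."""
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"probe map {path} needs two columns (probe, gene)")
    s = pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values)
    if s.index.has_duplicates:
        dups = sorted(set(s.index[s.index.duplicated()]))
        raise ValueError(f"probes mapped more than once: {dups}")
    return s


def collapse_probes(probe_expr: ExpressionMatrix, probe_map: pd.Series) -> ExpressionMatrix:
    """Collapse probe-level rows to gene level by per-sample arithmetic mean.

    Probes absent from the map are dropped (and counted in the log); an empty
    intersection between map and matrix is a hard error.
    """
    probe_map = probe_map.astype(str)
    mapped = probe_expr.data.index.intersection(probe_map.index)
    if len(mapped) == 0:
        raise ValueError("no probe in the matrix is covered by the probe map")
    n_drop = probe_expr.n_genes - len(mapped)
    if n_drop:
        log.info("dropping %d unmapped probes", n_drop)
    sub = probe_expr.data.loc[mapped]
    genes = probe_map.loc[mapped]
    collapsed = sub.groupby(genes.values).mean()
    collapsed = collapsed.sort_index()
    return ExpressionMatrix(collapsed)


def read_trait_table(path, group_col: str = "group") -> TraitTable:
    """Read a trait table TSV; ``group_col`` holds the two-level phenotype."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if group_col not in df.columns:
        raise ValueError(f"trait table {path} lacks required column '{group_col}'")
    group = df[group_col].astype(str)
    traits = df.drop(columns=[group_col])
    return TraitTable(traits=traits, group=group)


def write_trait_table(traits: TraitTable, path, group_col: str = "group") -> None:
    out = traits.traits.copy()
    out.insert(0, group_col, traits.group)
    out.to_csv(path, sep="\t", index_label="sample", float_format="%.10g")


def align(expr: ExpressionMatrix, traits: TraitTable) -> tuple[ExpressionMatrix, TraitTable]:
    """Restrict both objects to their shared samples, in expression order.

    Sample order is canonicalized to the expression matrix's order; dropped
    samples are logged.  A disjoint sample set is a hard error.
    """
    shared = [s for s in expr.sample_ids if s in set(traits.sample_ids)]
    if not shared:
        raise ValueError("expression matrix and trait table share no samples")
    n_drop_e = expr.n_samples - len(shared)
    n_drop_t = len(traits.sample_ids) - len(shared)
    if n_drop_e or n_drop_t:
        log.info("alignment dropped %d expression and %d trait samples",
                 n_drop_e, n_drop_t)
    expr2 = expr.subset_samples(shared)
    traits2 = TraitTable(traits=traits.traits.loc[shared],
                         group=traits.group.loc[shared])
    return expr2, traits2


def encode_traits(raw: pd.DataFrame, group_col: str = "group") -> TraitTable:
    """One-hot encode categorical clinical columns into a :class:`TraitTable`.

    Each level of each categorical column becomes a 0/1 indicator named
    ``column_level`` (e.g. ``GOLD_4``); numeric columns that are already
    binary 0/1 pass through unchanged, other numeric columns are kept as
    ordered scores.  Constant columns are dropped with a warning.  The
    ``group_col`` column is preserved as the phenotype grouping.
    """
    if group_col not in raw.columns:
        raise ValueError(f"raw trait table lacks required column '{group_col}'")
    group = raw[group_col].astype(str)
    cols: dict[str, pd.Series] = {}
    for name in raw.columns:
        if name == group_col:
            continue
        col = raw[name]
        nun = col.nunique(dropna=True)
        if nun < 2:
            log.warning("dropping constant trait column %r", name)
            continue
        if pd.api.types.is_numeric_dtype(col) and set(col.dropna().unique()) <= {0, 1}:
            cols[name] = col.astype(float)
        elif pd.api.types.is_numeric_dtype(col) and nun > 8:
            cols[name] = col.astype(float)  # continuous / ordered score
        else:
            for level in sorted(col.dropna().unique(), key=str):
                cols[f"{name}_{level}"] = (col == level).astype(float)
    traits = pd.DataFrame(cols, index=raw.index)
    return TraitTable(traits=traits, group=group)
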