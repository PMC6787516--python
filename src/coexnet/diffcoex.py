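"""Differential coexpression between two phenotype groups.

Pearson correlation matrices are computed separately within each group; the
change dissimilarity d_ij = [ 1/2 |sign(c1) c1^2 - sign(c2) c2^2| ]^(beta/2)
is treated as an adjacency, converted to a topological-overlap dissimilarity,
clustered by average linkage and cut with the hybrid dynamic procedure.
Module-level significance uses a dispersion statistic (root-mean-square
correlation change across member pairs) with a group-label permutation null,
and gene-pair level results are exported as a deltaR = |R_1| - |R_2| edge
list for network viewers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import GREY, ExpressionMatrix, ModuleAssignment, TraitTable
from .wgcna import (
    TOMatrix,
    _row_correlations,
    cluster_genes,
    cut_modules,
    merge_similar_modules,
)

log = logging.getLogger("coexnet")

#: Softening exponent for the change dissimilarity.  beta = 2 keeps the raw
#: half-absolute-difference of signed squared correlations; larger values
#: progressively suppress all but near-maximal changes (see docs/methods.md).
DEFAULT_BETA = 2.0
DEFAULT_CUT_HEIGHT = 0.93
DEFAULT_MIN_SIZE = 20
DEFAULT_MERGE_HEIGHT = 0.2
DEFAULT_DELTA_R = 0.7


@dataclass
class ConditionCorrelations:
    gene_ids: list[str]
    c1: np.ndarray
    c2: np.ndarray
    n1: int
    n2: int
    levels: tuple[str, str]


@dataclass
class DiffCoExResult:
    modules: ModuleAssignment
    dispersion: pd.DataFrame        # module, size, T, p, n_perm
    params: dict = field(default_factory=dict)


def condition_correlations(expr: ExpressionMatrix,
                           group: pd.Series | TraitTable) -> ConditionCorrelations:
    """Within-group Pearson correlation matrices (sorted label order)."""
    if isinstance(group, TraitTable):
        group = group.group
    group = group.loc[expr.sample_ids]
    levels = sorted(group.unique())
    if len(levels) != 2:
        raise ValueError(f"group must have 2 levels, got {levels}")
    x = expr.values
    mats = []
    ns = []
    for level in levels:
        mask = (group == level).to_numpy()
        if mask.sum() < 4:
            raise ValueError(f"group {level!r} needs >=4 samples")
        mats.append(_row_correlations(x[:, mask]))
        ns.append(int(mask.sum()))
    return ConditionCorrelations(gene_ids=expr.gene_ids, c1=mats[0], c2=mats[1],
                                 n1=ns[0], n2=ns[1], levels=(levels[0], levels[1]))


def change_dissimilarity(cc: ConditionCorrelations, beta: float = DEFAULT_BETA) -> np.ndarray:
    """Sign-aware squared-correlation change, softened by beta/2; diagonal 0."""
    if beta < 1:
        raise ValueError("beta must be >= 1")
    diff = np.abs(cc.c1 * np.abs(cc.c1) - cc.c2 * np.abs(cc.c2))
    d = (0.5 * diff) ** (beta / 2.0)
    np.fill_diagonal(d, 0.0)
    return d


def diffcoex_tom(d: np.ndarray) -> TOMatrix:
    """Topological overlap of the change matrix, treated as an adjacency."""
    from .wgcna import tom_from_adjacency
    return TOMatrix(gene_ids=[], matrix=tom_from_adjacency(d))


def diffcoex_modules(expr: ExpressionMatrix,
                     cc: ConditionCorrelations,
                     beta: float = DEFAULT_BETA,
                     cut_height: float = DEFAULT_CUT_HEIGHT,
                     min_size: int = DEFAULT_MIN_SIZE,
                     merge_height: float = DEFAULT_MERGE_HEIGHT) -> ModuleAssignment:
    """Detect differential-coexpression modules.

    Average-linkage clustering of 1 - TOM(change dissimilarity), hybrid cut
    at ``cut_height`` with minimum module size ``min_size``, then
    eigengene-based merging at ``merge_height`` using the pooled samples of
    both conditions.
    """
    d = change_dissimilarity(cc, beta=beta)
    t = diffcoex_tom(d)
    diss = t.dissimilarity()
    z = cluster_genes(diss)
    modules = cut_modules(z, diss, cc.gene_ids, min_size=min_size,
                          cut_height=cut_height)
    if modules.modules():
        modules = merge_similar_modules(expr, modules,
                                        merge_height=merge_height,
                                        min_size=min_size)
    return modules


def _module_dispersion(c1: np.ndarray, c2: np.ndarray) -> float:
    """RMS correlation change over the unordered member pairs."""
    iu = np.triu_indices(c1.shape[0], k=1)
    diff = c1[iu] - c2[iu]
    return float(np.sqrt(np.mean(diff * diff)))


def dispersion_test(expr: ExpressionMatrix,
                    group: pd.Series | TraitTable,
                    modules: ModuleAssignment,
                    n_perm: int = 200,
                    seed: int = 0) -> pd.DataFrame:
    """Permutation significance of each module's correlation change.

    The statistic T_M = sqrt(mean over pairs (c1_ij - c2_ij)^2) is compared
    to a null obtained by randomly re-partitioning the samples into groups of
    the original sizes; p = (1 + #{T_perm >= T_obs}) / (1 + n_perm).
    Modules smaller than 3 genes are skipped with a warning.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if isinstance(group, TraitTable):
        group = group.group
    group = group.loc[expr.sample_ids]
    levels = sorted(group.unique())
    mask1 = (group == levels[0]).to_numpy()
    n1 = int(mask1.sum())
    n = expr.n_samples
    idx = pd.Index(expr.gene_ids)

    mod_rows = {}
    for m in modules.modules():
        genes = modules.genes_in(m)
        if len(genes) < 3:
            log.warning("module %s has <3 genes: dispersion test skipped", m)
            continue
        mod_rows[m] = idx.get_indexer(genes)

    x = expr.values
    obs = {}
    for m, rows in mod_rows.items():
        sub = x[rows]
        obs[m] = _module_dispersion(_row_correlations(sub[:, mask1]),
                                    _row_correlations(sub[:, ~mask1]))

    rng = np.random.default_rng([seed, 3])
    exceed = {m: 0 for m in mod_rows}
    for _ in range(n_perm):
        perm = rng.permutation(n)
        pmask = np.zeros(n, dtype=bool)
        pmask[perm[:n1]] = True
        for m, rows in mod_rows.items():
            sub = x[rows]
            t = _module_dispersion(_row_correlations(sub[:, pmask]),
                                   _row_correlations(sub[:, ~pmask]))
            if t >= obs[m]:
                exceed[m] += 1

    rows_out = [(m, len(mod_rows[m]), obs[m],
                 (1 + exceed[m]) / (1 + n_perm), n_perm)
                for m in mod_rows]
    return pd.DataFrame(rows_out, columns=["module", "size", "T", "p", "n_perm"])


def differential_edges(cc: ConditionCorrelations,
                       threshold: float = DEFAULT_DELTA_R,
                       restrict_to: list[str] | None = None) -> pd.DataFrame:
    """Gene pairs whose absolute correlation differs strongly between groups.

    deltaR = |r_cond1| - |r_cond2|; pairs with |deltaR| >= threshold are
    returned (both directions, so a viewer can colour by sign), gene_a <
    gene_b canonically, sorted by decreasing |deltaR|.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0,1]")
    ids = np.asarray(cc.gene_ids)
    if restrict_to is not None:
        keep = np.isin(ids, list(restrict_to))
        ids = ids[keep]
        c1 = cc.c1[np.ix_(keep, keep)]
        c2 = cc.c2[np.ix_(keep, keep)]
    else:
        c1, c2 = cc.c1, cc.c2
    delta = np.abs(c1) - np.abs(c2)
    iu, ju = np.triu_indices(len(ids), k=1)
    sel = np.abs(delta[iu, ju]) >= threshold
    iu, ju = iu[sel], ju[sel]
    swap = ids[iu] > ids[ju]
    a = np.where(swap, ids[ju], ids[iu])
    b = np.where(swap, ids[iu], ids[ju])
    df = pd.DataFrame({
        "gene_a": a,
        "gene_b": b,
        "r_cond1": c1[iu, ju],
        "r_cond2": c2[iu, ju],
        "deltaR": delta[iu, ju],
    })
    df = df.sort_values(["deltaR", "gene_a", "gene_b"],
                        key=lambda s: -s.abs() if s.name == "deltaR" else s,
                        ascending=True).reset_index(drop=True)
    return df
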