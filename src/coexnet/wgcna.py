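"""Weighted gene coexpression network construction and module statistics.

The network is unsigned: edge weight a_ij = |cor(x_i, x_j)|^beta, with the
soft-threshold power beta chosen as the smallest candidate whose connectivity
distribution reaches a target scale-free topology fit.  Genes are clustered
by average linkage on the topological-overlap dissimilarity 1 - TOM, modules
are found by a hybrid dynamic cut (height cut, minimum size, medoid
reassignment of unassigned genes), summarized by eigengenes (first principal
component of the standardized module submatrix), and related to clinical
traits by Pearson correlation with Student-t p-values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .datatypes import (
    GREY,
    EigengeneSet,
    ExpressionMatrix,
    ModuleAssignment,
    TraitTable,
    color_names,
)

log = logging.getLogger("coexnet")

_EPS = 1e-12

DEFAULT_POWERS = (1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 12, 14, 16, 18, 20)


# ---------------------------------------------------------------------------
# correlation helpers

def _row_correlations(x: np.ndarray) -> np.ndarray:
    """Pearson correlation between rows; zero-variance rows get 0 (warned)."""
    sd = x.std(axis=1)
    zero = sd == 0
    if zero.any():
        log.warning("%d zero-variance genes: correlations set to 0", int(zero.sum()))
    xs = x - x.mean(axis=1, keepdims=True)
    denom = np.where(zero, 1.0, sd * np.sqrt(x.shape[1]))
    xs = xs / denom[:, None]
    c = xs @ xs.T
    c[zero, :] = 0.0
    c[:, zero] = 0.0
    np.fill_diagonal(c, 1.0)
    return np.clip(c, -1.0, 1.0)


def correlation_pvalue(r, n: int):
    """Two-sided p for a Pearson correlation via t = r sqrt(n-2)/sqrt(1-r^2)."""
    r = np.asarray(r, dtype=float)
    df = n - 2
    denom = np.sqrt(np.maximum(1.0 - r * r, _EPS))
    t = np.abs(r) * np.sqrt(df) / denom
    p = 2.0 * stats.t.sf(t, df)
    return np.maximum(np.minimum(p, 1.0), np.finfo(float).tiny)


# ---------------------------------------------------------------------------
# adjacency, TOM, soft-threshold scan

@dataclass
class AdjacencyMatrix:
    gene_ids: list[str]
    matrix: np.ndarray
    power: float


@dataclass
class TOMatrix:
    gene_ids: list[str]
    matrix: np.ndarray

    def dissimilarity(self) -> np.ndarray:
        d = 1.0 - self.matrix
        np.fill_diagonal(d, 0.0)
        return np.clip(d, 0.0, 1.0)


@dataclass
class SoftThresholdScan:
    powers: list[float]
    fit_index: list[float | None]
    mean_connectivity: list[float]
    chosen_power: float | None
    target_fit: float

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "power": self.powers,
            "fit": [np.nan if f is None else f for f in self.fit_index],
            "mean_k": self.mean_connectivity,
        })


def adjacency(expr: ExpressionMatrix, power: float) -> AdjacencyMatrix:
    """Unsigned soft-threshold adjacency a_ij = |cor|^power, unit diagonal."""
    if power <= 0:
        raise ValueError("power must be > 0")
    c = _row_correlations(expr.values)
    a = np.abs(c) ** power
    np.fill_diagonal(a, 1.0)
    return AdjacencyMatrix(gene_ids=expr.gene_ids, matrix=a, power=power)


def tom_from_adjacency(a: np.ndarray) -> np.ndarray:
    """Topological overlap for a symmetric adjacency in [0,1].

    TOM_ij = (l_ij + a_ij) / (min(k_i,k_j) + 1 - a_ij) with
    l_ij = sum_u a_iu a_uj over u != i,j and k_i = sum_{u != i} a_iu.
    """
    ad = a.copy()
    np.fill_diagonal(ad, 0.0)
    k = ad.sum(axis=1)
    l = ad @ ad  # diagonal of ad is 0, so u=i and u=j terms vanish
    denom = np.minimum.outer(k, k) + 1.0 - ad
    t = (l + ad) / np.maximum(denom, _EPS)
    np.fill_diagonal(t, 1.0)
    return t


def tom(adj: AdjacencyMatrix) -> TOMatrix:
    return TOMatrix(gene_ids=adj.gene_ids, matrix=tom_from_adjacency(adj.matrix))


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> float | None:
    """Signed scale-free topology fit of a connectivity vector.

    Connectivities are split into ``n_bins`` equal-count bins; the log10
    frequency density (count / (N * bin width)) is regressed on the log10
    mean connectivity per bin, and the signed fit is -sign(slope) * R^2.
    Returns None when fewer than 3 usable bins remain.
    """
    k = np.sort(k[k > 0])
    if len(k) < 3 * n_bins:
        n_bins = max(3, len(k) // 3)
    log_dens, log_mean = [], []
    for chunk in np.array_split(k, n_bins):
        width = chunk[-1] - chunk[0]
        if len(chunk) < 2 or width <= 0:
            continue
        log_dens.append(np.log10(len(chunk) / (len(k) * width)))
        log_mean.append(np.log10(chunk.mean()))
    if len(log_mean) < 3:
        return None
    res = stats.linregress(log_mean, log_dens)
    return float(-np.sign(res.slope) * res.rvalue ** 2)


def soft_connectivity_scan(expr: ExpressionMatrix,
                           powers=DEFAULT_POWERS,
                           subsample: int = 5000,
                           target_fit: float = 0.85,
                           seed: int = 0,
                           n_bins: int = 10) -> SoftThresholdScan:
    """Scan candidate soft-threshold powers on a random gene subsample.

    For each power the whole-network connectivity k_i = sum_{j != i} a_ij is
    computed on the (seeded) subsample and the scale-free fit evaluated; the
    chosen power is the smallest one reaching ``target_fit``, or None when no
    candidate does.
    """
    powers = sorted(powers)
    x = expr.values
    if subsample < expr.n_genes:
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(expr.n_genes, size=subsample, replace=False))
        x = x[idx]
    absc = np.abs(_row_correlations(x))
    np.fill_diagonal(absc, 0.0)

    fits: list[float | None] = []
    mean_k: list[float] = []
    for beta in powers:
        k = (absc ** beta).sum(axis=1)
        fits.append(scale_free_fit(k, n_bins=n_bins))
        mean_k.append(float(k.mean()))
    chosen = None
    for beta, f in zip(powers, fits):
        if f is not None and f >= target_fit:
            chosen = beta
            break
    if chosen is None:
        log.warning("no candidate power reached scale-free fit %.2f", target_fit)
    return SoftThresholdScan(powers=list(powers), fit_index=fits,
                             mean_connectivity=mean_k, chosen_power=chosen,
                             target_fit=target_fit)


# ---------------------------------------------------------------------------
# clustering and module detection

def cluster_genes(diss: np.ndarray):
    """Average-linkage hierarchical clustering of a dissimilarity matrix."""
    if np.isnan(diss).any():
        raise ValueError("dissimilarity matrix contains NaN")
    condensed = squareform(diss, checks=False)
    return linkage(condensed, method="average")


def cut_modules(dendrogram: np.ndarray,
                diss: np.ndarray,
                gene_ids: list[str],
                min_size: int = 50,
                cut_height: float | None = None) -> ModuleAssignment:
    """Hybrid dynamic cut of a gene dendrogram.

    1. cut the tree at ``cut_height`` (default 99% of the maximum merge
       height) into candidate branches;
    2. branches smaller than ``min_size`` are dissolved to grey;
    3. each grey gene joins the retained module whose medoid it is closest
       to, provided that dissimilarity is below the cut height.

    The reassignment stage is deliberately permissive (any gene inside the
    cut radius of a medoid joins); membership is sharpened afterwards by
    :func:`prune_low_kme`.  Modules are named by decreasing size with
    colour-style labels.
    """
    if min_size < 2:
        raise ValueError("min_size must be >= 2")
    if cut_height is None:
        cut_height = 0.99 * float(dendrogram[:, 2].max())
    branches = fcluster(dendrogram, t=cut_height, criterion="distance")

    ids = np.asarray(gene_ids)
    labels = np.full(len(ids), GREY, dtype=object)
    kept: list[np.ndarray] = []
    for b in np.unique(branches):
        members = np.where(branches == b)[0]
        if len(members) >= min_size:
            kept.append(members)
    if not kept:
        log.warning("no branch reached min_size=%d: all genes grey", min_size)
        return ModuleAssignment(pd.Series(labels, index=ids))

    medoids = []
    for members in kept:
        sub = diss[np.ix_(members, members)]
        medoids.append(members[int(np.argmin(sub.sum(axis=0)))])
    for mi, members in enumerate(kept):
        labels[members] = f"_b{mi}"

    grey_idx = np.where(labels == GREY)[0]
    if len(grey_idx):
        d_to_medoids = diss[np.ix_(grey_idx, medoids)]
        best = np.argmin(d_to_medoids, axis=1)
        for row, (gi, bi) in enumerate(zip(grey_idx, best)):
            if d_to_medoids[row, bi] < cut_height:
                labels[gi] = f"_b{bi}"

    return _rename_by_size(pd.Series(labels, index=ids))


def _rename_by_size(labels: pd.Series) -> ModuleAssignment:
    """Map provisional labels to colour names by decreasing module size."""
    sizes = labels[labels != GREY].value_counts()
    ordered = sorted(sizes.index, key=lambda m: (-sizes[m], str(m)))
    names = color_names(len(ordered))
    mapping = {old: new for old, new in zip(ordered, names)}
    mapping[GREY] = GREY
    return ModuleAssignment(labels.map(mapping))


# ---------------------------------------------------------------------------
# eigengenes and module statistics

def _standardize_rows(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    return (x - mu) / sd


def module_eigengene(expr: ExpressionMatrix, modules: ModuleAssignment) -> EigengeneSet:
    """First principal component summary profile of each non-grey module.

    Member genes are standardized across samples; the eigengene is the
    unit-norm first right singular vector of the standardized submatrix,
    sign-flipped so its mean correlation with member genes is non-negative.
    Zero-variance genes are excluded from the decomposition with a warning.
    """
    profiles = {}
    data = expr.data
    for m in modules.modules():
        genes = modules.genes_in(m)
        x = data.loc[genes].to_numpy()
        keep = x.std(axis=1) > 0
        if not keep.all():
            log.warning("module %s: excluding %d zero-variance genes from SVD",
                        m, int((~keep).sum()))
        x = x[keep]
        if x.shape[0] < 2:
            raise ValueError(f"module {m} has <2 usable genes")
        xs = _standardize_rows(x)
        _, _, vt = np.linalg.svd(xs, full_matrices=False)
        me = vt[0]
        mean_cor = np.mean([np.corrcoef(me, row)[0, 1] for row in xs])
        if mean_cor < 0:
            me = -me
        profiles[m] = me
    eg = pd.DataFrame(profiles, index=expr.sample_ids).T
    eg.index.name = "module"
    return EigengeneSet(eigengenes=eg)


def merge_similar_modules(expr: ExpressionMatrix,
                          modules: ModuleAssignment,
                          merge_height: float = 0.25,
                          min_size: int = 50,
                          max_iter: int = 100) -> ModuleAssignment:
    """Union modules with similar eigengenes and absorb undersized modules.

    Iteratively: (a) merge the module pair whose eigengene dissimilarity
    1 - cor(ME_a, ME_b) is smallest, while it is <= ``merge_height``;
    (b) merge any module below ``min_size`` into the module with the most
    correlated eigengene.  Eigengenes are recomputed after every merge until
    the partition is stable.
    """
    if not 0 < merge_height < 1:
        raise ValueError("merge_height must be in (0,1)")
    labels = modules.labels.copy()
    for _ in range(max_iter):
        current = ModuleAssignment(labels.copy())
        mods = current.modules()
        if len(mods) < 2:
            break
        egs = module_eigengene(expr, current)
        me = egs.eigengenes.loc[mods].to_numpy()
        cor = np.corrcoef(me)
        np.fill_diagonal(cor, -np.inf)

        # (a) closest eigengene pair within merge_height
        i, j = np.unravel_index(np.argmax(cor), cor.shape)
        if 1.0 - cor[i, j] <= merge_height:
            a, b = sorted((mods[i], mods[j]))
            labels[labels == b] = a
            continue

        # (b) absorb the smallest undersized module
        sizes = current.sizes()
        small = [m for m in mods if sizes[m] < min_size]
        if small:
            m = min(small, key=lambda s: (sizes[s], s))
            mi = mods.index(m)
            partner = mods[int(np.argmax(cor[mi]))]
            labels[labels == m] = partner
            continue
        break
    return _rename_by_size(labels)


def prune_low_kme(expr: ExpressionMatrix,
                  modules: ModuleAssignment,
                  min_kme: float = 0.5,
                  min_size: int = 50) -> ModuleAssignment:
    """Remove weak members from each module by module membership.

    A gene stays in its module only if |kME| with the module's own eigengene
    is at least ``min_kme`` (default 0.5: the gene shares at least 25% of its
    variance with the eigengene).  Modules that fall below ``min_size`` after
    pruning are dissolved to grey.  This is the membership-cleanup stage of
    module detection: height-based branches inevitably pick up weakly
    attached genes, and membership is ultimately defined by kME.
    """
    labels = modules.labels.copy()
    egs = module_eigengene(expr, modules)
    kme = module_membership(expr, egs)
    for m in modules.modules():
        genes = modules.genes_in(m)
        weak = kme.loc[genes, m].abs() < min_kme
        labels[weak.index[weak]] = GREY
        if int((labels == m).sum()) < min_size:
            log.info("module %s below min_size=%d after kME pruning: dissolved",
                     m, min_size)
            labels[labels == m] = GREY
    return _rename_by_size(labels)


def module_trait_correlation(eigengenes: EigengeneSet, traits: TraitTable) -> pd.DataFrame:
    """Pearson correlation of every eigengene with every trait column.

    Returns a long-format frame (module, trait, cor, p, n); constant traits
    give NaN correlation and p.
    """
    n = len(eigengenes.sample_ids)
    if n < 4:
        raise ValueError("need >=4 samples for module-trait correlation")
    tdf = traits.traits.loc[eigengenes.sample_ids]
    rows = []
    for m in eigengenes.module_labels:
        me = eigengenes.profile(m)
        for trait in tdf.columns:
            tv = tdf[trait].to_numpy(dtype=float)
            if np.std(tv) == 0:
                rows.append((m, trait, np.nan, np.nan, n))
                continue
            r = float(np.corrcoef(me, tv)[0, 1])
            rows.append((m, trait, r, float(correlation_pvalue(r, n)), n))
    return pd.DataFrame(rows, columns=["module", "trait", "cor", "p", "n"])


def gene_significance(expr: ExpressionMatrix, traits: TraitTable) -> dict[str, pd.DataFrame]:
    """Per gene x trait correlation (GS) with Student-t p-values."""
    tdf = traits.traits.loc[expr.sample_ids]
    x = expr.values
    n = expr.n_samples
    gs = {}
    ps = {}
    for trait in tdf.columns:
        tv = tdf[trait].to_numpy(dtype=float)
        if np.std(tv) == 0:
            gs[trait] = np.full(expr.n_genes, np.nan)
            ps[trait] = np.full(expr.n_genes, np.nan)
            continue
        r = _cor_rows_with_vector(x, tv)
        gs[trait] = r
        ps[trait] = correlation_pvalue(r, n)
    idx = pd.Index(expr.gene_ids, name="gene")
    return {"gs": pd.DataFrame(gs, index=idx), "p": pd.DataFrame(ps, index=idx)}


def _cor_rows_with_vector(x: np.ndarray, v: np.ndarray) -> np.ndarray:
    xs = x - x.mean(axis=1, keepdims=True)
    vs = v - v.mean()
    num = xs @ vs
    den = np.sqrt((xs * xs).sum(axis=1) * (vs * vs).sum())
    out = np.zeros(x.shape[0])
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    return np.clip(out, -1.0, 1.0)


def module_membership(expr: ExpressionMatrix, eigengenes: EigengeneSet) -> pd.DataFrame:
    """Signed module membership kME = cor(gene, eigengene), genes x modules."""
    x = expr.values
    cols = {m: _cor_rows_with_vector(x, eigengenes.profile(m))
            for m in eigengenes.module_labels}
    return pd.DataFrame(cols, index=pd.Index(expr.gene_ids, name="gene"))


def hub_genes(adj: AdjacencyMatrix, modules: ModuleAssignment, top_n: int = 10) -> pd.DataFrame:
    """Rank genes within each module by intramodular connectivity.

    k_in(i) = sum of adjacency to other genes of the same module; ties are
    broken lexicographically by gene id.  Returns (module, rank, gene, k_in).
    """
    ids = pd.Index(adj.gene_ids)
    rows = []
    for m in modules.modules():
        genes = modules.genes_in(m)
        pos = ids.get_indexer(genes)
        sub = adj.matrix[np.ix_(pos, pos)]
        k_in = sub.sum(axis=1) - 1.0  # drop the unit self-adjacency
        order = sorted(range(len(genes)), key=lambda i: (-k_in[i], genes[i]))
        for rank, i in enumerate(order[:top_n], start=1):
            rows.append((m, rank, genes[i], float(k_in[i])))
    return pd.DataFrame(rows, columns=["module", "rank", "gene", "k_in"])
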