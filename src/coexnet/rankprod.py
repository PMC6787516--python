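"""Rank-product differential expression between two phenotype groups.

K between-group sample pairs are drawn as a seeded disjoint pairing (each
sample used at most once, K = min(n1, n2, cap)); for each pair the per-gene
log-ratio is ranked ascending (down-regulation in group 1) and descending
(up-regulation), and the rank product RP_g = (prod_k r_gk)^(1/K) is small
when a gene is consistently extreme.  Disjoint pairs make the comparisons
independent, which is what calibrates the permutation null: gene labels are
permuted independently within each comparison, permuted RP values are pooled,
and the p-value is the fraction of them at or below the observed RP.
Two-sided significance doubles the smaller one-sided p.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .datatypes import ExpressionMatrix, TraitTable

log = logging.getLogger("coexnet")

DEFAULT_COMPARISON_CAP = 50
DEFAULT_N_PERM = 1000


@dataclass
class RankProdResult:
    """Per-gene rank products and permutation p-values."""

    table: pd.DataFrame   # gene-indexed: RP_up, RP_down, p_up, p_down, two_sided_p
    n_comparisons: int
    n_perm: int

    def write(self, path, alpha: float = 0.05) -> None:
        out = self.table.copy()
        out["passed_filter"] = (out["two_sided_p"] < alpha).astype(int)
        out.to_csv(path, sep="\t", index_label="gene", float_format="%.10g")


def _comparison_pairs(samples1: list[str], samples2: list[str],
                      cap: int, rng: np.random.Generator) -> list[tuple[str, str]]:
    """Seeded disjoint between-group sample pairing, K = min(n1, n2, cap).

    Each sample is used in at most one comparison, so the per-comparison
    log-ratios are mutually independent — the condition under which the
    within-comparison permutation null is calibrated.  The pairing is a
    deterministic function of the two sample *sets* (not of which phenotype
    label is attached to which), so swapping group labels yields the same
    comparisons with the ratio sign flipped.
    """
    a, b = sorted(samples1), sorted(samples2)
    if (len(a), a) > (len(b), b):
        a, b = b, a
    a = [a[i] for i in rng.permutation(len(a))]
    b = [b[i] for i in rng.permutation(len(b))]
    k = min(len(a), len(b), cap)
    return list(zip(a[:k], b[:k]))


def rank_product(expr: ExpressionMatrix,
                 group: pd.Series | TraitTable,
                 n_comparisons_cap: int = DEFAULT_COMPARISON_CAP,
                 n_perm: int = DEFAULT_N_PERM,
                 seed: int = 0) -> RankProdResult:
    """Rank-product statistics for group level 1 vs level 2 (sorted order).

    ``group`` maps sample id to one of two labels (a TraitTable's group is
    accepted directly).  Log-ratios are level1 - level2 on the log-scale
    data, so RP_up flags genes consistently higher in the first (sorted)
    level.  Ties get average ranks.  Requires >=2 samples per group and
    ``n_perm >= 100``.
    """
    if isinstance(group, TraitTable):
        group = group.group
    group = group.loc[expr.sample_ids]
    levels = sorted(group.unique())
    if len(levels) != 2:
        raise ValueError(f"group must have 2 levels, got {levels}")
    s1 = [s for s in expr.sample_ids if group[s] == levels[0]]
    s2 = [s for s in expr.sample_ids if group[s] == levels[1]]
    if len(s1) < 2 or len(s2) < 2:
        raise ValueError("each group needs >=2 samples")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")

    # rng for pair subsampling is independent of label order: pairs are
    # enumerated canonically, so swapping levels swaps ratios on the same set
    rng_pairs = np.random.default_rng([seed, 1])
    pairs = _comparison_pairs(s1, s2, n_comparisons_cap, rng_pairs)
    K = len(pairs)
    G = expr.n_genes

    data = expr.data
    in_g1 = set(s1)
    ratios = np.column_stack([
        data[a].to_numpy() - data[b].to_numpy() if a in in_g1
        else data[b].to_numpy() - data[a].to_numpy()
        for a, b in pairs
    ])                                                   # G x K, level1 - level2

    r_down = np.column_stack([rankdata(ratios[:, k]) for k in range(K)])
    r_up = np.column_stack([rankdata(-ratios[:, k]) for k in range(K)])

    log_rp_down = np.log(r_down).mean(axis=1)
    log_rp_up = np.log(r_up).mean(axis=1)

    # permutation null: permute gene labels within each comparison; the same
    # permutation indices are applied to the ascending- and descending-rank
    # vectors so that swapping group labels swaps the two null pools exactly
    rng_perm = np.random.default_rng([seed, 2])
    pooled_down = np.empty(n_perm * G)
    pooled_up = np.empty(n_perm * G)
    log_rd = np.log(r_down)
    log_ru = np.log(r_up)
    for b in range(n_perm):
        acc_d = np.zeros(G)
        acc_u = np.zeros(G)
        for k in range(K):
            perm = rng_perm.permutation(G)
            acc_d += log_rd[perm, k]
            acc_u += log_ru[perm, k]
        pooled_down[b * G:(b + 1) * G] = acc_d / K
        pooled_up[b * G:(b + 1) * G] = acc_u / K
    pooled_down.sort()
    pooled_up.sort()

    p_down = np.searchsorted(pooled_down, log_rp_down, side="right") / (n_perm * G)
    p_up = np.searchsorted(pooled_up, log_rp_up, side="right") / (n_perm * G)
    two_sided = np.minimum(1.0, 2.0 * np.minimum(p_up, p_down))

    table = pd.DataFrame({
        "RP_up": np.exp(log_rp_up),
        "RP_down": np.exp(log_rp_down),
        "p_up": p_up,
        "p_down": p_down,
        "two_sided_p": two_sided,
    }, index=pd.Index(expr.gene_ids, name="gene"))
    log.info("rank product: %d genes, %d comparisons, %d permutations",
             G, K, n_perm)
    return RankProdResult(table=table, n_comparisons=K, n_perm=n_perm)


def filter_degs(result: RankProdResult, alpha: float = 0.05) -> list[str]:
    """Genes with two-sided permutation p below ``alpha``, input order kept."""
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must be in [0,1]")
    if alpha >= 1:
        return list(result.table.index)
    mask = result.table["two_sided_p"] < alpha
    return list(result.table.index[mask])
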