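"""Two-condition synthetic expression data with planted network structure.

The generator emulates a two-phenotype microarray study: a genes-by-samples
log-scale matrix in which each planted module is driven by a latent factor
shared by its member genes, with a per-module loading ``a`` controlling the
within-module correlation (E[cor] = a^2).  Modules can be coexpressed in both
conditions or only in one (the factor is replaced by independent noise where
inactive), a clinical trait can be linearly coupled to a module's factor, and
a chosen set of background genes receives a mean shift in condition 2.  All
randomness flows from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .datatypes import GREY, ExpressionMatrix, ModuleAssignment, SyntheticTruth, TraitTable

MODES = ("shared", "cond1_only", "cond2_only")


@dataclass
class ModuleSpec:
    size: int
    loading: float          # a in (0, 1]; within-module correlation -> a^2
    mode: str = "shared"    # shared | cond1_only | cond2_only

    def __post_init__(self) -> None:
        if not 0 < self.loading <= 1:
            raise ValueError(f"loading must be in (0,1], got {self.loading}")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.size < 2:
            raise ValueError("module size must be >=2")


@dataclass
class TraitSpec:
    module: int             # index into the module list
    weight: float           # coupling of trait to the module's latent factor
    noise_sd: float | None = None   # default sqrt(1 - weight^2): unit-variance trait


@dataclass
class DESpec:
    n_genes: int
    shift: float            # mean shift in condition 2, in within-gene SD units
    direction: int = 1      # +1 up in condition 2, -1 down


@dataclass
class SyntheticSpec:
    n_genes: int
    n_samples: tuple[int, int]               # (n1, n2) per condition
    modules: list[ModuleSpec] = field(default_factory=list)
    traits: list[TraitSpec] = field(default_factory=list)
    de: list[DESpec] = field(default_factory=list)
    noise_sd: float = 1.0
    seed: int = 0
    group_labels: tuple[str, str] = ("cond1", "cond2")

    def validate(self) -> None:
        planted = sum(m.size for m in self.modules)
        n_de = sum(d.n_genes for d in self.de)
        if planted + n_de > self.n_genes:
            raise ValueError(
                f"{planted} module genes + {n_de} DE genes exceed n_genes={self.n_genes}"
            )
        if min(self.n_samples) < 3:
            raise ValueError("need >=3 samples per condition")
        for t in self.traits:
            if not 0 <= t.module < len(self.modules):
                raise ValueError(f"trait coupled to unknown module index {t.module}")
            if self.modules[t.module].mode != "shared":
                raise ValueError("traits can only couple to shared modules")


@dataclass
class SyntheticDataset:
    expr: ExpressionMatrix
    traits: TraitTable
    truth: SyntheticTruth


def generate(spec: SyntheticSpec) -> SyntheticDataset:
    """Sample a dataset from ``spec``; bit-reproducible for a fixed seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n1, n2 = spec.n_samples
    n = n1 + n2
    g = spec.n_genes

    gene_ids = [f"g{i+1:05d}" for i in range(g)]
    sample_ids = [f"s{j+1:03d}" for j in range(n)]
    cond = np.array([0] * n1 + [1] * n2)  # 0 = condition 1, 1 = condition 2

    # latent factors: one per (module, condition)
    z = rng.standard_normal((len(spec.modules), 2, max(n1, n2)))
    noise = spec.noise_sd * rng.standard_normal((g, n))

    x = np.empty((g, n))
    labels = np.full(g, GREY, dtype=object)
    modes: dict[str, str] = {}
    start = 0
    for m, ms in enumerate(spec.modules):
        name = f"M{m+1}"
        rows = slice(start, start + ms.size)
        labels[rows] = name
        modes[name] = ms.mode
        a = ms.loading
        for k, cols in enumerate((np.arange(n1), np.arange(n1, n))):
            active = (ms.mode == "shared"
                      or (ms.mode == "cond1_only" and k == 0)
                      or (ms.mode == "cond2_only" and k == 1))
            zk = z[m, k, : len(cols)]
            if active:
                x[rows, cols[0]:cols[-1] + 1] = (
                    a * zk[None, :]
                    + np.sqrt(1 - a * a) * noise[rows, cols[0]:cols[-1] + 1]
                )
            else:
                x[rows, cols[0]:cols[-1] + 1] = noise[rows, cols[0]:cols[-1] + 1]
        start += ms.size

    # background genes: pure noise
    x[start:, :] = noise[start:, :]

    # DE genes drawn from the background block, mean-shifted in condition 2
    de_genes: dict[str, int] = {}
    pos = start
    for d in spec.de:
        for _ in range(d.n_genes):
            x[pos, cond == 1] += d.direction * d.shift
            de_genes[gene_ids[pos]] = int(np.sign(d.direction))
            pos += 1

    # traits coupled to shared-module factors, over all samples in order
    trait_cols: dict[str, np.ndarray] = {}
    couplings: dict[str, str] = {}
    for i, ts in enumerate(spec.traits):
        zfull = np.concatenate([z[ts.module, 0, :n1], z[ts.module, 1, :n2]])
        sd = ts.noise_sd
        if sd is None:
            sd = float(np.sqrt(max(0.0, 1 - ts.weight ** 2)))
        name = f"trait{i+1}"
        trait_cols[name] = ts.weight * zfull + sd * rng.standard_normal(n)
        couplings[name] = f"M{ts.module+1}"

    l1, l2 = spec.group_labels
    group = pd.Series(np.where(cond == 0, l1, l2), index=sample_ids)
    traits_df = pd.DataFrame(trait_cols, index=sample_ids)
    # indicator for membership in condition 2, usable directly as a trait
    traits_df[l2] = (cond == 1).astype(float)

    expr = ExpressionMatrix(pd.DataFrame(x, index=gene_ids, columns=sample_ids))
    traits = TraitTable(traits=traits_df, group=group)
    truth = SyntheticTruth(
        module_labels=pd.Series(labels, index=gene_ids, name="module"),
        module_modes=modes,
        trait_couplings=couplings,
        de_genes=de_genes,
    )
    return SyntheticDataset(expr=expr, traits=traits, truth=truth)


def benchmark_a(seed: int = 20190818) -> SyntheticSpec:
    """The standard recovery benchmark: 2000 genes, 35+35 samples.

    Four shared modules (150/120/100/80 genes, loading 0.8), one 60-gene
    module coexpressed only in condition 1 (loading 0.85), one trait coupled
    to the first module (weight 0.6), and 50 background genes shifted
    +1.5 SD in condition 2.
    """
    return SyntheticSpec(
        n_genes=2000,
        n_samples=(35, 35),
        modules=[
            ModuleSpec(150, 0.8, "shared"),
            ModuleSpec(120, 0.8, "shared"),
            ModuleSpec(100, 0.8, "shared"),
            ModuleSpec(80, 0.8, "shared"),
            ModuleSpec(60, 0.85, "cond1_only"),
        ],
        traits=[TraitSpec(module=0, weight=0.6)],
        de=[DESpec(n_genes=50, shift=1.5, direction=1)],
        seed=seed,
    )


def recovery_scores(truth: SyntheticTruth | pd.Series,
                    predicted: ModuleAssignment) -> tuple[float, dict[str, float]]:
    """Score a predicted partition against the planted one.

    Returns the adjusted Rand index over all genes (grey/background counts as
    its own class) and, per planted module, the best Jaccard overlap with any
    predicted non-grey module.
    """
    true_labels = truth.module_labels if isinstance(truth, SyntheticTruth) else truth
    true_labels = true_labels.reindex(predicted.gene_ids)
    if true_labels.isna().any():
        raise ValueError("predicted assignment covers genes absent from the truth")
    ari = float(adjusted_rand_score(true_labels.values, predicted.labels.values))

    jaccard: dict[str, float] = {}
    pred_sets = {m: set(predicted.genes_in(m)) for m in predicted.modules()}
    for m in sorted(set(true_labels.unique()) - {GREY}):
        truth_set = set(true_labels.index[true_labels == m])
        best = 0.0
        for pset in pred_sets.values():
            inter = len(truth_set & pset)
            if inter:
                best = max(best, inter / len(truth_set | pset))
        jaccard[m] = best
    return ari, jaccard
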