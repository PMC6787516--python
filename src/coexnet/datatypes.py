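"""Core containers shared across the pipeline.

Expression data live in a genes-by-samples :class:`pandas.DataFrame`; the thin
dataclasses here add the validation every downstream step relies on (unique
identifiers, complete numeric values, minimum shapes) and carry metadata such
as the two-level phenotype grouping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Reserved module label for genes not assigned to any module.
GREY = "grey"

#: WGCNA-style module colour names, assigned to modules by decreasing size.
MODULE_COLORS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "skyblue", "saddlebrown", "steelblue",
    "paleturquoise", "violet", "darkolivegreen", "darkmagenta",
]


def color_names(n: int) -> list[str]:
    """Return ``n`` distinct module labels (colours first, then numbered)."""
    if n <= len(MODULE_COLORS):
        return MODULE_COLORS[:n]
    extra = [f"module{i}" for i in range(len(MODULE_COLORS) + 1, n + 1)]
    return MODULE_COLORS + extra


@dataclass
class ExpressionMatrix:
    """Log-scale expression values, genes in rows, samples in columns.

    Parameters
    ----------
    data
        Numeric DataFrame indexed by gene (or probe) identifier with sample
        identifiers as columns.  Must be complete (no missing values), with
        unique identifiers on both axes, at least 2 genes and 3 samples.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.shape[0] < 2 or df.shape[1] < 3:
            raise ValueError(
                f"expression matrix needs >=2 genes and >=3 samples, got {df.shape}"
            )
        for axis, name in ((df.index, "gene"), (df.columns, "sample")):
            if axis.has_duplicates:
                dups = sorted(set(axis[axis.duplicated()].astype(str)))
                raise ValueError(f"duplicate {name} identifiers: {dups}")
        if not all(np.issubdtype(t, np.number) for t in df.dtypes):
            raise ValueError("expression matrix contains non-numeric columns")
        if df.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        self.data = df.astype(float)
        self.data.index = self.data.index.astype(str)
        self.data.columns = self.data.columns.astype(str)
        self.data.index.name = "gene"
        self.data.columns.name = None

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_genes(self, genes) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[list(genes)])

    def subset_samples(self, samples) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data[list(samples)])


@dataclass
class TraitTable:
    """Per-sample clinical traits plus a two-level phenotype grouping.

    ``traits`` holds numeric columns (binary indicators or ordered scores)
    indexed by sample id; ``group`` is the two-level phenotype label used to
    split samples in the differential analyses.
    """

    traits: pd.DataFrame
    group: pd.Series

    def __post_init__(self) -> None:
        self.group = self.group.astype(str)
        self.group.index = self.group.index.astype(str)
        self.traits.index = self.traits.index.astype(str)
        if not self.traits.index.equals(self.group.index):
            raise ValueError("traits and group must be indexed by the same samples")
        if self.traits.index.has_duplicates:
            raise ValueError("duplicate sample identifiers in trait table")
        levels = self.group.value_counts()
        if len(levels) != 2:
            raise ValueError(f"group must have exactly 2 levels, got {list(levels.index)}")
        if (levels < 3).any():
            raise ValueError(f"each group level needs >=3 samples, got {levels.to_dict()}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.traits.index)

    @property
    def group_levels(self) -> list[str]:
        """The two phenotype levels in sorted (deterministic) order."""
        return sorted(self.group.unique())

    def samples_in(self, level: str) -> list[str]:
        return list(self.group.index[self.group == level])


@dataclass
class ModuleAssignment:
    """Partition of genes into modules; :data:`GREY` marks unassigned genes."""

    labels: pd.Series

    def __post_init__(self) -> None:
        self.labels = self.labels.astype(str)
        self.labels.index = self.labels.index.astype(str)
        self.labels.name = "module"

    @property
    def gene_ids(self) -> list[str]:
        return list(self.labels.index)

    def modules(self) -> list[str]:
        """Non-grey module labels ordered by decreasing size, then name."""
        sizes = self.labels[self.labels != GREY].value_counts()
        return sorted(sizes.index, key=lambda m: (-sizes[m], m))

    def genes_in(self, module: str) -> list[str]:
        return list(self.labels.index[self.labels == module])

    def sizes(self) -> dict[str, int]:
        return {m: int((self.labels == m).sum()) for m in self.modules()}

    def n_assigned(self) -> int:
        return int((self.labels != GREY).sum())


@dataclass
class EigengeneSet:
    """Module eigengenes: one unit-norm summary profile per module.

    Rows are module labels, columns are sample ids; each row is the
    sign-oriented first principal component of the standardized module
    submatrix.
    """

    eigengenes: pd.DataFrame  # modules x samples

    @property
    def module_labels(self) -> list[str]:
        return list(self.eigengenes.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.eigengenes.columns)

    def profile(self, module: str) -> np.ndarray:
        return self.eigengenes.loc[module].to_numpy()


@dataclass
class SyntheticTruth:
    """Ground truth planted by the synthetic generator.

    ``module_labels`` uses planted names ``M1..Mk`` with :data:`GREY` for
    background genes; ``module_modes`` records whether each planted module is
    coexpressed in both conditions or only one; ``de_genes`` maps gene id to
    the sign of its condition-2 mean shift.
    """

    module_labels: pd.Series
    module_modes: dict[str, str]          # module -> shared | cond1_only | cond2_only
    trait_couplings: dict[str, str]       # trait name -> coupled module
    de_genes: dict[str, int] = field(default_factory=dict)
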