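"""Over-representation analysis of gene lists against GMT gene-set collections.

The core is the upper-tail hypergeometric test: drawing |query| genes from a
background of size M containing K members of a set, the p-value is
P(X >= observed overlap).  Benjamini-Hochberg q-values are reported
alongside; the reporting rule keeps the top k terms with raw p below alpha.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

log = logging.getLogger("coexnet")


@dataclass
class GeneSetCollection:
    """Named gene sets: set_id -> (name, members)."""

    sets: dict[str, tuple[str, frozenset[str]]]
    source: str = ""

    def __len__(self) -> int:
        return len(self.sets)

    def members(self, set_id: str) -> frozenset[str]:
        return self.sets[set_id][1]


def read_gmt(path, source: str = "") -> GeneSetCollection:
    """Parse a GMT file (set_id <tab> description <tab> members...)."""
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs id, "
                                 f"description and >=1 member")
            set_id, name = parts[0], parts[1]
            members = frozenset(g for g in parts[2:] if g)
            if not members:
                raise ValueError(f"{path}:{lineno}: empty gene set {set_id!r}")
            if set_id in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set id {set_id!r}")
            sets[set_id] = (name, members)
    return GeneSetCollection(sets=sets, source=source)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for set_id, (name, members) in collection.sets.items():
            fh.write("\t".join([set_id, name, *sorted(members)]) + "\n")


def ora(query: list[str], background: list[str],
        sets: GeneSetCollection) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` within each gene set.

    ``query`` must be a subset of ``background``.  Gene sets are intersected
    with the background before testing.  Returns one row per set: overlap,
    set_size (in background), query_size, background_size, p, q (BH over all
    sets) and the overlapping genes.
    """
    bg = set(background)
    q = set(query)
    if not q <= bg:
        missing = sorted(q - bg)[:5]
        raise ValueError(f"query genes missing from background, e.g. {missing}")
    M, N = len(bg), len(q)
    rows = []
    for set_id in sorted(sets.sets):
        name, members = sets.sets[set_id]
        in_bg = members & bg
        K = len(in_bg)
        overlap = sorted(in_bg & q)
        k = len(overlap)
        p = 1.0 if (K == 0 or N == 0) else float(hypergeom.sf(k - 1, M, K, N))
        rows.append((set_id, name, k, K, N, M, min(max(p, 0.0), 1.0),
                     ";".join(overlap)))
    df = pd.DataFrame(rows, columns=["set_id", "name", "overlap", "set_size",
                                     "query_size", "background_size", "p",
                                     "genes"])
    if len(df):
        df["q"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    else:
        df["q"] = []
    return df[["set_id", "name", "overlap", "set_size", "query_size",
               "background_size", "p", "q", "genes"]]


def top_terms(result: pd.DataFrame, k: int = 20, alpha: float = 0.05) -> pd.DataFrame:
    """Terms with raw p below ``alpha``, sorted by p (ties by set id), top k."""
    sig = result[result["p"] < alpha]
    return (sig.sort_values(["p", "set_id"])
               .head(k)
               .reset_index(drop=True))
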