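"""Fold-change-filtered gene lists and hypergeometric gene-set enrichment.

Probes are collapsed to genes (a gene inherits its largest-|log2FC| probe),
genes are split into up-at-d110 and up-at-d90 lists at |log2FC| >= log2(1.4),
and each gene set is tested for over-representation in a list with the
upper-tail hypergeometric probability against the universe of annotated
genes expressed on the array, with BH control across sets.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dge import adjust_pvalues

logger = logging.getLogger(__name__)

#: |log2FC| gate for the regulated lists: fold change 1.4 on the linear scale
DEFAULT_FC_THRESHOLD = float(np.log2(1.4))


@dataclass
class GeneSetCollection:
    """Named gene sets restricted to a universe of measured genes."""

    sets: dict[str, list[str]]
    universe: set[str]

    def __post_init__(self) -> None:
        self.universe = set(self.universe)
        restricted = {}
        for name, members in self.sets.items():
            restricted[name] = sorted(set(members) & self.universe)
        self.sets = restricted

    def __len__(self) -> int:
        return len(self.sets)


def collapse_probes_to_genes(results: pd.DataFrame, annotation: pd.Series,
                             fc_column: str = "log2fc_age_overall") -> pd.DataFrame:
    """One row per annotated gene; keep each gene's largest-|log2FC| probe.

    Unannotated probes (absent from the annotation, or annotated as
    "unannotated") are dropped and their count logged.  Idempotent: applying
    to an already-collapsed table returns it unchanged.
    """
    tab = results.copy()
    tab["gene"] = [annotation.get(p, "unannotated") for p in tab.index]
    dropped = int((tab["gene"] == "unannotated").sum())
    if dropped:
        logger.info("dropping %d unannotated probe(s) in gene collapse", dropped)
    tab = tab[tab["gene"] != "unannotated"]
    fc_cols = [c for c in tab.columns if c.startswith("log2fc")]
    order = tab[fc_column].abs().sort_values(ascending=False, kind="stable")
    tab = tab.loc[order.index]
    out = tab.drop_duplicates(subset="gene", keep="first").set_index("gene")
    return out.sort_index()


def select_regulated(per_gene: pd.DataFrame,
                     fc_threshold: float = DEFAULT_FC_THRESHOLD,
                     fc_column: str = "log2fc_age_overall") -> tuple[list[str], list[str]]:
    """Split genes into (up_at_d110, up_at_d90) lists at |log2FC| >= threshold.

    The boundary is inclusive; the sign convention is d110 minus d90, so
    positive fold changes are up-regulated at d110.
    """
    fc = per_gene[fc_column]
    up_110 = list(per_gene.index[fc >= fc_threshold])
    up_90 = list(per_gene.index[fc <= -fc_threshold])
    return up_110, up_90


def hypergeom_test(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    ``k`` overlap, ``n`` query size, ``K`` set size, ``N`` universe size.
    """
    if not (0 <= k <= min(n, K) <= N) or n > N:
        raise ValueError(f"inconsistent hypergeometric counts: k={k}, n={n}, K={K}, N={N}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich(query, collection: GeneSetCollection, q_threshold: float = 0.01) -> pd.DataFrame:
    """Hypergeometric over-representation of each set in the query list.

    Genes outside the universe are dropped with a warning.  One test per
    set, BH across sets, sorted by raw p; ``significant`` flags q below the
    threshold.
    """
    query = list(dict.fromkeys(query))  # dedupe, keep order
    outside = [g for g in query if g not in collection.universe]
    if outside:
        warnings.warn(f"{len(outside)} query gene(s) outside the universe dropped", stacklevel=2)
    qset = set(query) & collection.universe
    if not qset:
        warnings.warn("empty query after universe restriction", stacklevel=2)
    N = len(collection.universe)
    n = len(qset)
    rows = []
    for name in sorted(collection.sets):
        members = set(collection.sets[name])
        overlap = sorted(qset & members)
        p = hypergeom_test(len(overlap), n, len(members), N) if n else 1.0
        rows.append(
            {
                "set": name,
                "overlap": len(overlap),
                "query_size": n,
                "set_size": len(members),
                "universe_size": N,
                "p_raw": p,
                "overlapping_genes": ",".join(overlap),
            }
        )
    res = pd.DataFrame(rows).set_index("set") if rows else pd.DataFrame(
        columns=["overlap", "query_size", "set_size", "universe_size", "p_raw",
                 "overlapping_genes"]
    )
    if len(res):
        res["q_bh"] = adjust_pvalues(res["p_raw"].to_numpy(), "bh")
        res["significant"] = res["q_bh"] < q_threshold
        res = res.sort_values(["p_raw", "set"], kind="stable")
    return res
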