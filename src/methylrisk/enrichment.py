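"""Gene-set over-representation of CpG lists and CpG-set overlap tests.

A query CpG list (e.g. the hypermethylated half of a signature) is
mapped to genes through the annotation, deduplicated, and each gene set
is tested for over-representation against the scanned universe with an
upper-tail hypergeometric p-value; Benjamini-Hochberg adjusts across
sets.  The same hypergeometric tail tests whether two CpG signatures
overlap more than chance within a common probe universe.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .methio import CpGAnnotation, GeneSetCollection

__all__ = ["EnrichmentTable", "hypergeom_enrichment", "cpg_set_overlap_test"]


@dataclass
class EnrichmentTable:
    """Per-set over-representation results, sorted by p-value."""

    data: pd.DataFrame  # index set_name; columns n_query_in_set,
    #                     n_set_in_universe, expected_overlap, p_value, adjusted_p

    def __len__(self) -> int:
        return len(self.data)


def hypergeom_enrichment(query_cpgs, annotation: CpGAnnotation,
                         sets: GeneSetCollection, universe_cpgs) -> EnrichmentTable:
    """Hypergeometric over-representation of query CpGs' genes per set.

    The universe is the scanned CpG set mapped to genes; a gene with
    several query CpGs counts once.  p = P(overlap >= observed) under
    sampling |query genes| genes from the universe without replacement.
    """
    query = pd.Index(query_cpgs).unique()
    universe = pd.Index(universe_cpgs).unique()
    if len(query) == 0 or len(universe) == 0:
        raise ValueError("query and universe must be non-empty")
    if not query.isin(universe).all():
        raise ValueError("query CpGs must be a subset of the universe")
    universe_genes = annotation.genes_for(universe)
    query_genes = annotation.genes_for(query)
    N, n = len(universe_genes), len(query_genes)
    rows = []
    for name in sets:
        set_in_universe = sets[name] & universe_genes
        K = len(set_in_universe)
        k = len(sets[name] & query_genes)
        expected = n * K / N if N else 0.0
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append((name, k, K, expected, min(p, 1.0)))
    df = pd.DataFrame(rows, columns=["set_name", "n_query_in_set",
                                     "n_set_in_universe", "expected_overlap",
                                     "p_value"]).set_index("set_name")
    df["adjusted_p"] = multipletests(df["p_value"], method="fdr_bh")[1]
    return EnrichmentTable(df.sort_values("p_value"))


def cpg_set_overlap_test(set_a, set_b, universe_size: int) -> tuple[int, float]:
    """Overlap count of two CpG sets and its upper-tail hypergeometric p
    within a universe of ``universe_size`` probes."""
    a, b = set(set_a), set(set_b)
    if len(a) > universe_size or len(b) > universe_size:
        raise ValueError("sets cannot exceed the universe")
    overlap = len(a & b)
    p = float(stats.hypergeom.sf(overlap - 1, universe_size, len(a), len(b)))
    return overlap, min(p, 1.0)
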