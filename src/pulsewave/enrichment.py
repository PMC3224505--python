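"""Term enrichment: hypergeometric tests and the dp detection parameter.

Two statistics serve two kinds of gene set.  Clusters of differentially
expressed genes are scored with the upper-tail hypergeometric probability
of drawing at least ``n`` term-annotated genes in a sample of ``t`` from a
background of ``N`` containing ``N_term`` annotated genes; published tables
additionally carry a Bonferroni correction over the number of terms tested.
Network modules are scored with the detection parameter dp = n^2 / t,
gated at dp > 0.05 / g where g is the number of distinct terms annotating
the module.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .types import AnnotationTable

__all__ = ["hypergeom_pvalue", "hypergeom_enrich", "dp_enrich", "dp_value"]


def hypergeom_pvalue(n: int, t: int, n_term: int, n_background: int) -> float:
    """Exact upper-tail hypergeometric probability P(X >= n).

    ``n`` annotated genes observed in a query of size ``t`` drawn from a
    background of ``n_background`` genes of which ``n_term`` carry the term.
    """
    if not (0 <= n <= min(t, n_term)):
        raise ValueError("need 0 <= n <= min(t, n_term)")
    if not (0 < t <= n_background and 0 <= n_term <= n_background):
        raise ValueError("need 0 < t <= N and 0 <= n_term <= N")
    return float(hypergeom.sf(n - 1, n_background, n_term, t))


def hypergeom_enrich(
    query,
    background,
    annotations: AnnotationTable,
    alpha: float = 1e-3,
    n_terms_tested: int | None = None,
) -> pd.DataFrame:
    """Hypergeometric term enrichment of a query set against a background.

    Returns one row per term annotating at least one background gene, with
    columns ``term_id, term_name, n, t, n_term, n_background, p_hyper,
    p_bonferroni, q_bh, selected``; ``selected`` gates the raw p at
    ``alpha``.  ``p_bonferroni`` multiplies by ``n_terms_tested`` (the
    number of terms in the table unless given), the correction applied to
    published enrichment tables.
    """
    query = set(query)
    background = set(background)
    if len(background) < 2:
        raise ValueError("background must contain at least 2 genes")
    stray = sorted(query - background)
    if stray:
        raise ValueError(f"query genes missing from background: {stray[:10]}")
    t = len(query)
    n_bg = len(background)
    rows = []
    for term, genes in sorted(annotations.term_to_genes().items()):
        genes_bg = genes & background
        if not genes_bg:
            continue
        n = len(genes_bg & query)
        p = hypergeom_pvalue(n, t, len(genes_bg), n_bg) if t else 1.0
        rows.append((term, annotations.term_names.get(term, ""), n, t, len(genes_bg), n_bg, p))
    table = pd.DataFrame(
        rows,
        columns=["term_id", "term_name", "n", "t", "n_term", "n_background", "p_hyper"],
    )
    if table.empty:
        table["p_bonferroni"] = table["q_bh"] = table["selected"] = []
        return table
    m = n_terms_tested if n_terms_tested is not None else len(table)
    table["p_bonferroni"] = np.minimum(1.0, table["p_hyper"] * m)
    table["q_bh"] = multipletests(table["p_hyper"].to_numpy(), method="fdr_bh")[1]
    table["selected"] = table["p_hyper"] < alpha
    return table.sort_values("p_hyper", kind="stable").reset_index(drop=True)


def dp_value(n: int, t: int, formula: str = "n2_over_t") -> float:
    """Detection parameter of a term in a module of ``t`` genes, ``n`` of
    which carry the term.  Default reading dp = n^2 / t; the alternative
    exponent placement n / t^2 is selectable."""
    if t < 1 or n < 0 or n > t:
        raise ValueError("need 0 <= n <= t with t >= 1")
    if formula == "n2_over_t":
        return n * n / t
    if formula == "n_over_t2":
        return n / (t * t)
    raise ValueError("formula must be 'n2_over_t' or 'n_over_t2'")


def dp_enrich(
    module_genes,
    annotations: AnnotationTable,
    slim_map: dict | None = None,
    formula: str = "n2_over_t",
) -> pd.DataFrame:
    """Detection-parameter enrichment of a network module.

    ``g`` is the number of distinct terms annotating the module's genes; a
    term is selected iff dp > 0.05 / g.  An optional term -> slim mapping is
    applied before counting.  Rows are sorted by dp, descending.
    """
    module_genes = set(module_genes)
    if not module_genes:
        raise ValueError("module is empty")
    if slim_map:
        annotations = annotations.mapped(slim_map)
    t = len(module_genes)
    term_counts = {
        term: len(genes & module_genes)
        for term, genes in annotations.term_to_genes().items()
        if genes & module_genes
    }
    g = len(term_counts)
    rows = []
    for term in sorted(term_counts):
        n = term_counts[term]
        dp = dp_value(n, t, formula)
        rows.append(
            (term, annotations.term_names.get(term, ""), n, t, dp, g, dp > 0.05 / g if g else False)
        )
    table = pd.DataFrame(
        rows, columns=["term_id", "term_name", "n", "t", "dp", "g", "selected"]
    )
    return table.sort_values("dp", ascending=False, kind="stable").reset_index(drop=True)
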