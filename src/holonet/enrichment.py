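"""Functional term enrichment of modules by the classic one-sided
hypergeometric (Fisher) test over a gene universe.

Annotations are accepted pre-propagated (every gene lists all applicable
terms); no ontology-graph decorrelation is performed, and p-values are raw
by default with an optional Benjamini-Hochberg column.
"""

from __future__ import annotations

import pandas as pd
from scipy.stats import hypergeom

from .data_io import AnnotationMap


def hypergeometric_enrichment(
    module_genes,
    annotation: AnnotationMap,
    universe,
    bh: bool = False,
) -> pd.DataFrame:
    """Upper-tail hypergeometric p per term with >= 1 module overlap.

    ``p = P(X >= overlap)`` with X hypergeometric on (universe size,
    term size, module size); annotation is restricted to the universe.
    Result is sorted ascending by p.
    """
    universe = set(universe)
    module = set(module_genes)
    if not module <= universe:
        missing = sorted(module - universe)
        raise ValueError(f"module genes outside the universe: {missing[:5]}")
    term_genes: dict[str, set[str]] = {}
    for gene in universe:
        for term in annotation.gene_terms.get(gene, ()):
            term_genes.setdefault(term, set()).add(gene)
    rows = []
    n_univ, n_mod = len(universe), len(module)
    for term, genes in term_genes.items():
        overlap = len(genes & module)
        if overlap == 0:
            continue
        p = float(hypergeom.sf(overlap - 1, n_univ, len(genes), n_mod))
        rows.append(
            {
                "term_id": term,
                "description": annotation.term_description.get(term, ""),
                "overlap": overlap,
                "module_size": n_mod,
                "term_size": len(genes),
                "universe_size": n_univ,
                "p": min(max(p, 0.0), 1.0),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=["term_id", "description", "overlap", "module_size", "term_size", "universe_size", "p"],
    )
    out = out.sort_values(["p", "term_id"]).reset_index(drop=True)
    if bh and len(out):
        m = len(out)
        adj = (out["p"] * m / (out.index + 1))[::-1].cummin()[::-1]
        out["p_bh"] = adj.clip(upper=1.0)
    return out
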