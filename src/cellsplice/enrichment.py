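"""Gene-set over-representation with the EASE-modified Fisher statistic.

For a gene list of size n drawn against a background of size N, a term
annotating K background genes and overlapping the list in k genes, the
one-tailed Fisher p-value is the hypergeometric upper tail P(X >= k).
The EASE score is the same tail evaluated at k - 1 (floored at 0): one
gene is removed from the observed overlap, which penalizes terms
supported by very few genes (a single-gene overlap scores 1.0).  EASE is
therefore always at least as large as the Fisher p-value.

Both p-values are reported per term, together with the fold enrichment
(k/n) / (K/N) and a Benjamini-Hochberg adjustment of the EASE scores
across terms.  The background should be the set of genes that passed
the same quality filters as the list under test.
"""
from __future__ import annotations

from typing import Mapping

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .models import EnrichmentResult, GeneSet


def ease_score(k: int, K: int, n: int, N: int) -> tuple[float, float]:
    """(ease_p, fisher_p) for an overlap of k list genes with a term.

    fisher_p = P(X >= k), ease_p = P(X >= k - 1) with the overlap
    floored at 0, X ~ Hypergeometric(N, K, n).
    """
    if n <= 0 or N <= 0:
        raise ValueError("list size n and background size N must be > 0")
    if not (0 <= k <= min(K, n) <= N):
        raise ValueError(f"inadmissible counts k={k}, K={K}, n={n}, N={N}")
    fisher_p = float(hypergeom.sf(k - 1, N, K, n))
    ease_p = float(hypergeom.sf(max(k - 1, 0) - 1, N, K, n))
    # extreme tails underflow to 0.0; keep p-values strictly positive
    floor = 1e-300
    return min(max(ease_p, floor), 1.0), min(max(fisher_p, floor), 1.0)


def enrich(gene_list: GeneSet, terms: Mapping[str, GeneSet],
           background: GeneSet) -> list[EnrichmentResult]:
    """Test every term against the list, restricted to the background.

    The list and each term are intersected with the background first;
    terms with no overlap (k = 0) are omitted.  Results are sorted by
    EASE p-value ascending with BH-adjusted EASE p-values appended.
    """
    if len(background) == 0:
        raise ValueError("background gene set is empty")
    bg = background.members
    lst = gene_list.members & bg
    n, N = len(lst), len(bg)
    if n == 0:
        return []
    results = []
    for name in sorted(terms):
        term_genes = terms[name].members & bg
        K = len(term_genes)
        k = len(term_genes & lst)
        if k == 0:
            continue
        ease_p, fisher_p = ease_score(k, K, n, N)
        fold = (k / n) / (K / N)
        results.append(EnrichmentResult(term=name, k=k, K=K, n=n, N=N,
                                        ease_p=ease_p, fisher_p=fisher_p,
                                        fold_enrichment=fold))
    if not results:
        return []
    adj = multipletests([r.ease_p for r in results], method="fdr_bh")[1]
    results = [EnrichmentResult(**{**r.__dict__, "ease_p_bh": float(q)})
               for r, q in zip(results, adj)]
    return sorted(results, key=lambda r: (r.ease_p, r.term))
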