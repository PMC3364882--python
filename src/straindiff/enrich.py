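"""Gene-category enrichment via the EASE score with Bonferroni correction.

The EASE score is a conservative variant of the one-sided Fisher exact
(hypergeometric) test: the observed list-category overlap k is reduced by
one before computing the upper-tail probability, so a single-gene overlap
is never significant (p = 1). The background is the set of genes in the
supplied annotation map, and every category overlapping the list is
tested; Bonferroni multiplies by the number of categories tested.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats


@dataclass(frozen=True)
class EnrichmentResult:
    category: str
    k: int  # genes in list AND category
    n: int  # list size
    K: int  # category size in background
    N: int  # background size
    ease_p: float
    bonferroni_p: float
    significant: bool


def ease_score(k: int, n: int, K: int, N: int) -> float:
    """One-sided hypergeometric upper tail with the overlap reduced by one.

    P(X >= k-1) for X ~ Hypergeom(N, K, n); returns 1.0 for k <= 1.
    """
    if not (0 <= k <= min(n, K) and n <= N and K <= N):
        raise ValueError(f"inconsistent counts k={k} n={n} K={K} N={N}")
    if k <= 1:
        return 1.0
    # sf(k-2) = P(X > k-2) = P(X >= k-1)
    return float(min(1.0, stats.hypergeom.sf(k - 2, N, K, n)))


def enrich_gene_list(
    gene_list: list[str],
    categories: dict[str, list[str]],
    background: list[str] | None = None,
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Test every category with at least one list gene for enrichment.

    ``categories`` maps gene id -> list of category ids. The background
    defaults to all genes in the annotation map. Raises if a list gene is
    missing from the background."""
    bg = set(background) if background is not None else set(categories)
    offenders = sorted(set(gene_list) - bg)
    if offenders:
        raise ValueError(f"list genes absent from background: {offenders[:10]}")
    lset = set(gene_list)
    by_cat: dict[str, set[str]] = {}
    for gene, cats in categories.items():
        if gene not in bg:
            continue
        for c in cats:
            by_cat.setdefault(c, set()).add(gene)
    N, n = len(bg), len(lset)
    tested = []
    for cat, members in sorted(by_cat.items()):
        k = len(lset & members)
        if k < 1:
            continue
        tested.append((cat, k, len(members)))
    m = len(tested)
    out = []
    for cat, k, K in tested:
        p = ease_score(k, n, K, N)
        bp = min(1.0, p * m)
        out.append(EnrichmentResult(cat, k, n, K, N, p, bp, bp < alpha))
    out.sort(key=lambda r: (r.ease_p, r.category))
    return out


def read_category_map(path) -> dict[str, list[str]]:
    """TSV with columns gene, category (extra columns ignored)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    gcol, ccol = cols.get("gene", df.columns[0]), cols.get("category", df.columns[1])
    out: dict[str, list[str]] = {}
    for _, row in df.iterrows():
        out.setdefault(str(row[gcol]), []).append(str(row[ccol]))
    return out


def results_to_frame(results: list[EnrichmentResult]):
    import pandas as pd

    return pd.DataFrame(
        {
            "category": [r.category for r in results],
            "k": [r.k for r in results],
            "n": [r.n for r in results],
            "K": [r.K for r in results],
            "N": [r.N for r in results],
            "ease_p": [r.ease_p for r in results],
            "bonferroni_p": [r.bonferroni_p for r in results],
            "significant": [r.significant for r in results],
        }
    )
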