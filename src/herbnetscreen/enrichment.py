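"""Over-representation analysis (ORA) of a gene list against gene-set
collections, with Benjamini-Hochberg FDR control.

For a query of n genes drawn from a background of N, a set annotating K
background genes, and k query genes falling in the set, the enrichment
p-value is the hypergeometric upper tail

    P[X >= k] = sum_{i=k}^{min(K,n)} C(K,i) C(N-K, n-i) / C(N,n),

evaluated in log space so tiny tails stay accurate.
"""

from __future__ import annotations

from scipy.special import gammaln, logsumexp
import numpy as np

from .models import Category, EnrichmentResult, GeneSetCollection

__all__ = ["hypergeom_tail", "bh_adjust", "run_ora", "top_terms"]


def _log_binom(n: float, k: np.ndarray) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """Exact upper-tail probability P[X >= k], X ~ Hypergeometric(N, K, n).

    Parameters follow the ORA convention: N background genes of which K are
    annotated; n drawn (the query); k annotated among the drawn.
    """
    for name, v in (("k", k), ("K", K), ("n", n), ("N", N)):
        if int(v) != v or v < 0:
            raise ValueError(f"{name}={v} must be a non-negative integer")
    if K > N or n > N or k > min(K, n):
        raise ValueError(f"inconsistent bounds: k={k} K={K} n={n} N={N}")
    hi = min(K, n)
    if k <= max(0, n - (N - K)):
        return 1.0  # k at or below the support minimum: whole distribution
    i = np.arange(k, hi + 1, dtype=float)
    log_terms = _log_binom(K, i) + _log_binom(N - K, n - i) - _log_binom(N, np.array(n, dtype=float))
    return float(min(1.0, np.exp(logsumexp(log_terms))))


def bh_adjust(p_values: list[float] | np.ndarray) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    q_(i) = min_{j >= i} p_(j) * m / j over the ascending order, clipped at 1.
    Idempotent, and monotone non-decreasing along the sorted-p order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q.tolist()


def run_ora(
    query: set[str],
    collection: GeneSetCollection,
    background: set[str] | None = None,
    alpha: float = 0.05,
    min_size: int = 3,
    max_size: int = 500,
    filter_on: str = "p_adj",
) -> list[EnrichmentResult]:
    """Test every size-eligible set in the collection against the query.

    ``background`` defaults to the union of all collection members (the
    clusterProfiler-like universe); the query must be a subset of it. Set
    sizes K are counted after intersecting members with the background.
    Results are filtered to ``p < alpha`` on ``filter_on`` ("p_adj" by
    default, "p_raw" to reproduce raw-p screens, "none" to keep all) and
    sorted by (p_raw, set_id).
    """
    if filter_on not in ("p_adj", "p_raw", "none"):
        raise ValueError(f"filter_on must be p_adj, p_raw or none, got {filter_on!r}")
    if background is None:
        background = collection.all_members()
    if not background:
        raise ValueError("background universe is empty")
    stray = set(query) - set(background)
    if stray:
        raise ValueError(
            f"query genes outside the background: {', '.join(sorted(stray)[:10])}"
        )
    N = len(background)
    n = len(query)
    rows: list[tuple[str, Category, int, int, frozenset[str]]] = []
    for gs in collection:
        members = gs.members & background
        K = len(members)
        if K < min_size or K > max_size:
            continue
        hits = frozenset(query & members)
        rows.append((gs.set_id, gs.category, len(hits), K, hits))
    if not rows:
        return []
    p_raw = [hypergeom_tail(k, K, n, N) for _, _, k, K, _ in rows]
    p_adj = bh_adjust(p_raw)
    results = [
        EnrichmentResult(set_id, cat, k, K, n, N, pr, pa, hits)
        for (set_id, cat, k, K, hits), pr, pa in zip(rows, p_raw, p_adj)
    ]
    results.sort(key=lambda r: (r.p_raw, r.set_id))
    if filter_on == "p_adj":
        results = [r for r in results if r.p_adj < alpha]
    elif filter_on == "p_raw":
        results = [r for r in results if r.p_raw < alpha]
    return results


def top_terms(
    results: list[EnrichmentResult],
    per_category_limits: dict[Category | str, int],
) -> list[EnrichmentResult]:
    """Keep at most the stated number of best-p terms per category.

    Input order (best p first, ties by set_id) is preserved; categories
    without a stated limit pass through uncapped.
    """
    limits = {Category(c): v for c, v in per_category_limits.items()}
    taken: dict[Category, int] = {c: 0 for c in limits}
    out: list[EnrichmentResult] = []
    for r in sorted(results, key=lambda r: (r.p_raw, r.set_id)):
        if r.category in limits:
            if taken[r.category] >= limits[r.category]:
                continue
            taken[r.category] += 1
        out.append(r)
    return out
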