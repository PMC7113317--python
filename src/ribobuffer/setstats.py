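"""Exact set statistics: hypergeometric tails, BH adjustment, enrichment.

These primitives back every over-representation analysis in the package
(AU-rich elements, protein complexes, stage-specific gene sets).  The
hypergeometric upper tail is computed by exact summation in log space so it
stays finite and accurate for universes far beyond 10^3 genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import exp, lgamma, log
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "EnrichmentResult",
    "hypergeometric_tail",
    "bh_adjust",
    "gene_set_enrichment",
    "read_gmt",
]


@dataclass(frozen=True)
class EnrichmentResult:
    """One gene-set test: overlap ``k`` of a query of size ``n`` with a term
    of size ``K`` in a universe of size ``N``, with upper-tail p and BH q."""

    term_id: str
    k: int
    K: int
    n: int
    N: int
    p: float
    fdr: float


def _log_comb(n: int, k: int) -> float:
    return lgamma(n + 1) - lgamma(k + 1) - lgamma(n - k + 1)


def hypergeometric_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n).

    X counts successes in ``n`` draws without replacement from a universe of
    ``N`` items of which ``K`` are successes.  The upper tail includes ``k``
    itself (the standard over-representation convention).

    Raises
    ------
    ValueError
        If the parameters are inconsistent (k > min(K, n), K > N, n > N,
        or any negative).
    """
    if not (0 <= k <= min(K, n) <= N) or K > N or n > N:
        raise ValueError(
            f"inconsistent hypergeometric parameters k={k}, K={K}, n={n}, N={N}"
        )
    lo = max(k, n + K - N)
    hi = min(K, n)
    if k <= max(0, n + K - N):
        return 1.0
    denom = _log_comb(N, n)
    logs = [
        _log_comb(K, x) + _log_comb(N - K, n - x) - denom for x in range(lo, hi + 1)
    ]
    m = max(logs)
    total = m + log(sum(exp(v - m) for v in logs))
    return float(min(1.0, exp(total)))


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    q(i) = min_{j >= i} (m * p(j) / j) over the sorted p-values, clipped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def gene_set_enrichment(
    query: set,
    term_sets: Mapping[str, Iterable],
    universe: set,
    min_term_size: int = 1,
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of ``query`` in each term set.

    Term sets are intersected with the universe before testing; terms smaller
    than ``min_term_size`` (after intersection) are not tested.  BH adjustment
    runs across the tested terms only.  Results are sorted by p, ties broken
    by term id.
    """
    if not universe:
        raise ValueError("empty universe")
    query = set(query)
    if not query <= set(universe):
        raise ValueError("query is not a subset of the universe")
    N = len(universe)
    n = len(query)
    rows: list[tuple[str, int, int]] = []
    for term_id, members in term_sets.items():
        members_u = set(members) & universe
        if len(members_u) < min_term_size:
            continue
        rows.append((term_id, len(members_u & query), len(members_u)))
    pvals = [hypergeometric_tail(k, K, n, N) for _, k, K in rows]
    fdrs = bh_adjust(pvals)
    results = [
        EnrichmentResult(term_id, k, K, n, N, p, q)
        for (term_id, k, K), p, q in zip(rows, pvals, fdrs)
    ]
    results.sort(key=lambda r: (r.p, r.term_id))
    return results


def read_gmt(path) -> dict[str, set]:
    """Read a GMT file (term, description, members...) into term -> set."""
    terms: dict[str, set] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line: {line!r}")
            terms[fields[0]] = set(fields[2:])
    return terms
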