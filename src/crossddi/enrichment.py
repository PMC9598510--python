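"""Hypergeometric over-representation analysis with Benjamini-Hochberg control.

Given a query gene set (e.g. the top-ranked cancer partners of an
interactome), annotation term sets in GMT form, and an explicit background
universe, each term is tested with the upper tail of the hypergeometric
distribution

    P(X >= k),  X ~ Hypergeom(N population, K term genes, n query genes),

computed exactly in log space from binomial coefficients.  P-values are
adjusted by the Benjamini-Hochberg step-up procedure; terms with adjusted
p <= alpha (default 0.01) are flagged significant.  The background is always
an explicit input — there is no built-in gene universe.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import exp, lgamma, log
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from crossddi.core_io import FormatError, ValidationError


def _log_comb(n: int, k: int) -> float:
    if k < 0 or k > n:
        return float("-inf")
    return lgamma(n + 1) - lgamma(k + 1) - lgamma(n - k + 1)


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n), exact via log-space binomials.

    k: query genes in the term; K: background genes in the term; n: query
    size; N: background size.
    """
    if not (0 <= k <= n <= N) or K > N or K < 0:
        raise ValidationError(f"inconsistent counts k={k} K={K} n={n} N={N}")
    if k > K:
        raise ValidationError(f"k={k} exceeds term size K={K}")
    if k == 0:
        return 1.0
    log_denom = _log_comb(N, n)
    terms = []
    for i in range(k, min(K, n) + 1):
        t = _log_comb(K, i) + _log_comb(N - K, n - i) - log_denom
        if t != float("-inf"):
            terms.append(t)
    if not terms:
        return 0.0
    m = max(terms)
    total = m + log(sum(exp(t - m) for t in terms))
    return min(1.0, exp(total))


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjustment, input order preserved.

    Each p_(i) (ascending) becomes min over j >= i of p_(j) * m / j, capped
    at 1.
    """
    m = len(p_values)
    for p in p_values:
        if not 0.0 < p <= 1.0:
            raise ValidationError(f"p-value {p} outside (0, 1]")
    order = sorted(range(m), key=lambda i: p_values[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running_min = min(running_min, p_values[idx] * m / rank)
        adjusted[idx] = running_min
    return adjusted


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    term_name: str
    k: int  # query genes in term
    K: int  # background genes in term
    n: int  # query size
    N: int  # background size
    p_value: float
    adj_p: float
    significant: bool

    def __post_init__(self) -> None:
        if not 0 <= self.k <= min(self.K, self.n):
            raise ValidationError(f"{self.term_id}: k outside [0, min(K, n)]")
        if self.adj_p < self.p_value - 1e-15:
            raise ValidationError(f"{self.term_id}: adjusted p below raw p")


def enrich(
    query_genes: Iterable[str],
    term_sets: Mapping[str, tuple[str, Iterable[str]]] | Mapping[str, Iterable[str]],
    background_genes: Iterable[str],
    alpha: float = 0.01,
) -> list[EnrichmentResult]:
    """Test every term for over-representation of the query in the background.

    ``term_sets`` maps term_id to either (description, genes) or a bare gene
    collection.  Query genes outside the background are dropped with a
    warning; term sets are intersected with the background, and terms empty
    after intersection are excluded.  Results sort by adjusted p then term id.
    """
    background = set(background_genes)
    if not background:
        raise ValidationError("background gene set is empty")
    query_all = set(query_genes)
    query = query_all & background
    dropped = query_all - background
    if dropped:
        import logging

        logging.getLogger(__name__).warning(
            "%d query genes outside the background dropped", len(dropped)
        )

    n, N = len(query), len(background)
    rows: list[tuple[str, str, int, int]] = []
    for term_id in sorted(term_sets):
        value = term_sets[term_id]
        if isinstance(value, tuple) and len(value) == 2 and isinstance(value[0], str):
            name, genes = value
        else:
            name, genes = "", value
        term_genes = set(genes) & background
        if not term_genes:
            continue
        rows.append((term_id, name, len(query & term_genes), len(term_genes)))

    p_values = [hypergeom_upper_tail(k, K, n, N) for _, _, k, K in rows]
    adj = bh_adjust(p_values) if p_values else []
    results = [
        EnrichmentResult(
            term_id=tid, term_name=name, k=k, K=K, n=n, N=N,
            p_value=p, adj_p=q, significant=q <= alpha,
        )
        for (tid, name, k, K), p, q in zip(rows, p_values, adj)
    ]
    results.sort(key=lambda r: (r.adj_p, r.term_id))
    return results


def read_gmt(path: str | Path) -> dict[str, tuple[str, frozenset[str]]]:
    """GMT format: term_id <TAB> description <TAB> gene1 <TAB> gene2 ..."""
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT row needs term, description, >=1 gene")
            terms[fields[0]] = (fields[1], frozenset(g for g in fields[2:] if g))
    return terms


def write_enrichment_results(results: Sequence[EnrichmentResult], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# term_id\tterm_name\tk\tK\tn\tN\tp_value\tadj_p\tsignificant\n")
        for r in results:
            fh.write(
                f"{r.term_id}\t{r.term_name}\t{r.k}\t{r.K}\t{r.n}\t{r.N}\t"
                f"{r.p_value:.6g}\t{r.adj_p:.6g}\t{int(r.significant)}\n"
            )
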