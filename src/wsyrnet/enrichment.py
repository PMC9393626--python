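"""Over-representation analysis of gene sets.

A query gene set is tested against each annotation term with the
upper-tail hypergeometric test: with a universe of ``N`` genes, ``K`` of
which carry the term, a query of ``n`` genes overlapping the term in
``k`` genes has ``p = P(X >= k)``, ``X ~ Hypergeometric(N, K, n)``.
Benjamini-Hochberg q-values are reported alongside; the enrichment flag
is applied to the raw p (the convention of the pipeline's p <= 1e-3 /
1e-5 filters).  The universe is the set of genes carried by the
annotation, which matches targeted-panel usage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import ParameterError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnnotationSet:
    """Term -> gene-set annotation with its gene universe."""

    terms: dict[str, frozenset]
    universe: frozenset
    term_names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for term, genes in self.terms.items():
            if not genes:
                raise ParameterError(f"term {term} annotates no genes")
            if not genes <= self.universe:
                raise ParameterError(f"term {term} annotates genes outside the universe")

    @classmethod
    def from_pairs(
        cls,
        pairs: Iterable[tuple[str, object]],
        term_names: Mapping[str, str] | None = None,
        universe: Iterable | None = None,
    ) -> "AnnotationSet":
        terms: dict[str, set] = {}
        for term, gene in pairs:
            terms.setdefault(str(term), set()).add(gene)
        annotated = frozenset(g for gs in terms.values() for g in gs)
        uni = frozenset(universe) | annotated if universe is not None else annotated
        return cls(
            terms={t: frozenset(g) for t, g in terms.items()},
            universe=uni,
            term_names=dict(term_names or {}),
        )


def hypergeom_upper_p(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric p-value ``P(X >= k)``.

    ``N`` universe size, ``K`` term size, ``n`` query size, ``k``
    query/term overlap.
    """
    if not (0 <= k <= min(K, n) and 0 <= K <= N and 0 <= n <= N):
        raise ParameterError(
            f"inconsistent hypergeometric counts: k={k}, K={K}, n={n}, N={N}"
        )
    if k == 0:
        return 1.0
    p = float(hypergeom.sf(k - 1, N, K, n))
    return min(max(p, np.finfo(float).tiny), 1.0)


def bh_adjust(pvals: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ParameterError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich(
    query: Iterable,
    annotation: AnnotationSet,
    p_max: float = 1e-3,
) -> pd.DataFrame:
    """Score every annotation term against ``query``.

    Genes outside the universe are dropped (count logged).  Returns one
    row per term with overlap ``k >= 1``, columns
    ``term, name, k, K, n, N, p, q, enriched``, sorted by ``(p, term)``.
    """
    if not annotation.universe:
        raise ParameterError("annotation universe is empty")
    query_set = set(query)
    inside = query_set & set(annotation.universe)
    dropped = len(query_set) - len(inside)
    if dropped:
        logger.info("enrich: dropped %d query genes outside the universe", dropped)
    n, N = len(inside), len(annotation.universe)
    rows = []
    for term in sorted(annotation.terms):
        genes = annotation.terms[term]
        k = len(inside & genes)
        if k < 1:
            continue
        rows.append(
            {
                "term": term,
                "name": annotation.term_names.get(term, term),
                "k": k,
                "K": len(genes),
                "n": n,
                "N": N,
                "p": hypergeom_upper_p(k, len(genes), n, N),
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["term", "name", "k", "K", "n", "N", "p", "q", "enriched"]
        )
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"])
    out["enriched"] = out["p"] <= p_max
    return out.sort_values(["p", "term"]).reset_index(drop=True)


def compare_term_sets(
    per_herb: Mapping[str, Iterable],
) -> dict[tuple[str, ...], frozenset]:
    """Venn partition of enriched-term sets across herbs.

    Returns a mapping from sorted herb combinations to the terms found
    in exactly those herbs; every term of the union appears in exactly
    one cell.  Empty cells are omitted.
    """
    sets = {h: frozenset(s) for h, s in per_herb.items()}
    if len(sets) < 2:
        raise ParameterError("need enriched term sets for at least two herbs")
    membership: dict[object, tuple[str, ...]] = {}
    for term in frozenset().union(*sets.values()):
        combo = tuple(sorted(h for h, s in sets.items() if term in s))
        membership.setdefault(term, combo)
    partition: dict[tuple[str, ...], set] = {}
    for term, combo in membership.items():
        partition.setdefault(combo, set()).add(term)
    return {combo: frozenset(terms) for combo, terms in partition.items()}
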