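"""Disease-gene union and herb-target intersection.

Disease genes are collected from several named sources (e.g. OMIM-style
curated lists) and deduplicated into one universe; each herb's
compound-target set is then intersected with that universe to give the
herb's therapeutic targets.  Gene identity is the Entrez id when
present, else the case-folded symbol (symbols are case-inconsistent
across sources, Entrez ids are not).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .errors import ParameterError

GeneKey = int | str


def gene_key(symbol: object = None, entrez: object = None) -> GeneKey:
    """Canonical identity for a gene record: Entrez id if available,
    otherwise the upper-cased symbol."""
    if entrez is not None and not pd.isna(entrez):
        return int(entrez)
    if symbol is None or pd.isna(symbol) or str(symbol).strip() == "":
        raise ParameterError("gene record needs a symbol or an entrez id")
    return str(symbol).strip().upper()


def keys_from_frame(frame: pd.DataFrame) -> list[GeneKey]:
    """Gene keys for a DataFrame with ``symbol`` and/or ``entrez`` columns."""
    symbols = frame["symbol"] if "symbol" in frame.columns else pd.Series(
        [None] * len(frame), index=frame.index
    )
    entrez = frame["entrez"] if "entrez" in frame.columns else pd.Series(
        [None] * len(frame), index=frame.index
    )
    return [gene_key(s, e) for s, e in zip(symbols, entrez)]


@dataclass(frozen=True)
class GeneUnion:
    """Deduplicated union of named gene sources."""

    genes: frozenset[GeneKey]
    provenance: dict[GeneKey, frozenset[str]] = field(default_factory=dict)
    per_source_counts: dict[str, int] = field(default_factory=dict)
    #: symbols mapped to >1 entrez id across sources (entrez wins).
    reconciliation_warnings: tuple[str, ...] = ()
    symbol_of: dict[GeneKey, str] = field(default_factory=dict)


@dataclass(frozen=True)
class TherapeuticTargetSet:
    """Per-herb and recipe-wide therapeutic targets."""

    per_herb: dict[str, frozenset[GeneKey]]
    union: frozenset[GeneKey]
    provenance: dict[GeneKey, frozenset[str]]


def union_gene_sources(sources: Mapping[str, pd.DataFrame]) -> GeneUnion:
    """Union named gene lists keyed by Entrez id (fallback: symbol).

    Each source frame carries ``symbol`` and/or ``entrez`` columns.
    Symbols observed with more than one Entrez id across sources are
    reported as reconciliation warnings; the Entrez keys stand.
    """
    if not sources:
        raise ParameterError("at least one gene source is required")
    provenance: dict[GeneKey, set[str]] = {}
    per_source: dict[str, int] = {}
    symbol_of: dict[GeneKey, str] = {}
    symbol_to_entrez: dict[str, set[int]] = {}
    for name, frame in sources.items():
        keys = set(keys_from_frame(frame))
        per_source[name] = len(keys)
        for key in keys:
            provenance.setdefault(key, set()).add(name)
        if "symbol" in frame.columns and "entrez" in frame.columns:
            for sym, ent in zip(frame["symbol"], frame["entrez"]):
                if pd.isna(sym) or pd.isna(ent):
                    continue
                sym_u = str(sym).strip().upper()
                symbol_of[int(ent)] = sym_u
                symbol_to_entrez.setdefault(sym_u, set()).add(int(ent))
    warnings = tuple(
        f"symbol {sym} maps to entrez ids {sorted(ids)}; entrez ids retained"
        for sym, ids in sorted(symbol_to_entrez.items())
        if len(ids) > 1
    )
    return GeneUnion(
        genes=frozenset(provenance),
        provenance={k: frozenset(v) for k, v in provenance.items()},
        per_source_counts=per_source,
        reconciliation_warnings=warnings,
        symbol_of=symbol_of,
    )


def intersect_targets(
    herb_targets: Mapping[str, Iterable[GeneKey]],
    disease_genes: Iterable[GeneKey],
) -> TherapeuticTargetSet:
    """Intersect each herb's target set with the disease-gene universe.

    An empty disease set is valid and yields empty per-herb sets.
    """
    disease = frozenset(disease_genes)
    per_herb = {
        herb: frozenset(genes) & disease for herb, genes in herb_targets.items()
    }
    union: set[GeneKey] = set()
    provenance: dict[GeneKey, set[str]] = {}
    for herb, genes in per_herb.items():
        union |= genes
        for g in genes:
            provenance.setdefault(g, set()).add(herb)
    return TherapeuticTargetSet(
        per_herb=per_herb,
        union=frozenset(union),
        provenance={g: frozenset(h) for g, h in provenance.items()},
    )
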