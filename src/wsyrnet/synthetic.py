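"""Seeded synthetic-data generators for every pipeline stage.

Each generator emulates the statistical structure its consumer assumes
and returns both the data table and the planted ground truth, so that
every stage can be tested end-to-end without external downloads.  One
global integer seed feeds a named substream per generator (derived via
``SeedSequence``), so adding a generator never perturbs the draws of an
existing one.  Identical (seed, parameters) give byte-identical output.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ParameterError
from .herbs import HERB_ORDER

OB_MIN = 30.0
DL_MIN = 0.18


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, reproducible RNG substream of a global seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) % 2**31, zlib.crc32(name.encode())])
    )


# ---------------------------------------------------------------- compounds


@dataclass(frozen=True)
class CompoundTruth:
    active_ids: frozenset[str]
    per_herb_active: dict[str, frozenset[str]] = field(default_factory=dict)
    shared_ids: frozenset[str] = frozenset()


def gen_compound_table(
    n_per_herb: int | Mapping[str, int],
    frac_active: float,
    seed: int,
    n_shared: int = 0,
    herbs: tuple[str, ...] = HERB_ORDER,
) -> tuple[pd.DataFrame, CompoundTruth]:
    """Compound table with a planted fraction passing the OB/DL screen.

    Exactly ``round(frac_active * n)`` compounds per herb pass both
    cutoffs; the rest fail at least one.  ``n_shared`` additional rows
    duplicate existing compounds into a second herb (same OB/DL, so a
    shared compound passes or fails identically everywhere).
    """
    if not 0 <= frac_active <= 1:
        raise ParameterError("frac_active must be in [0, 1]")
    if isinstance(n_per_herb, Mapping):
        per_herb = {h: int(n_per_herb[h]) for h in herbs}
    else:
        per_herb = {h: int(n_per_herb) for h in herbs}
    if any(n < 0 for n in per_herb.values()):
        raise ParameterError("compound counts must be non-negative")
    if n_shared < 0:
        raise ParameterError("n_shared must be non-negative")
    rng = substream(seed, "compound_table")
    rows: list[dict] = []
    per_herb_active: dict[str, set[str]] = {h: set() for h in herbs}
    counter = 0
    for herb in herbs:
        n = per_herb[herb]
        n_active = round(frac_active * n)
        for i in range(n):
            counter += 1
            mol_id = f"SYN{counter:05d}"
            if i < n_active:
                ob = rng.uniform(30.5, 95.0)
                dl = rng.uniform(0.185, 0.95)
                per_herb_active[herb].add(mol_id)
            else:
                mode = rng.integers(3)  # 0: low OB, 1: low DL, 2: both
                ob = rng.uniform(5.0, 29.5) if mode in (0, 2) else rng.uniform(30.5, 95.0)
                dl = rng.uniform(0.02, 0.175) if mode in (1, 2) else rng.uniform(0.185, 0.95)
            rows.append(
                {
                    "mol_id": mol_id,
                    "name": f"compound-{counter}",
                    "ob": round(float(ob), 2),
                    "dl": round(float(dl), 3),
                    "herb": herb,
                }
            )
    table = pd.DataFrame(rows, columns=["mol_id", "name", "ob", "dl", "herb"])

    shared_ids: set[str] = set()
    if n_shared:
        if len(herbs) < 2 or len(table) == 0:
            raise ParameterError("sharing requires >= 2 herbs and a non-empty table")
        candidates = table.drop_duplicates("mol_id")
        pick = rng.choice(len(candidates), size=min(n_shared, len(candidates)), replace=False)
        extra = []
        for j in np.sort(pick):
            row = candidates.iloc[int(j)]
            others = [h for h in herbs if h != row["herb"]]
            target = others[int(rng.integers(len(others)))]
            extra.append({**row.to_dict(), "herb": target})
            shared_ids.add(row["mol_id"])
            if row["mol_id"] in per_herb_active[row["herb"]]:
                per_herb_active[target].add(row["mol_id"])
        table = pd.concat([table, pd.DataFrame(extra)], ignore_index=True)

    truth = CompoundTruth(
        active_ids=frozenset().union(*per_herb_active.values()) if per_herb_active else frozenset(),
        per_herb_active={h: frozenset(s) for h, s in per_herb_active.items()},
        shared_ids=frozenset(shared_ids),
    )
    return table, truth


# -------------------------------------------------------------------- graph


@dataclass(frozen=True)
class PpiTruth:
    hub_ids: tuple[str, ...]
    n_edges: int


def gen_ppi_graph(
    n_nodes: int,
    n_hubs: int,
    base_degree: int = 4,
    seed: int = 0,
    hub_factor: float = 5.0,
) -> tuple[pd.DataFrame, PpiTruth]:
    """Random graph with ``n_hubs`` planted high-degree nodes.

    Background edges appear independently with probability
    ``base_degree / (n_nodes - 1)``; each hub additionally connects to
    every node with probability ``hub_factor`` times that (capped at 1)
    and hubs form a clique, so planted hubs have expected degree well
    above three times the background.  Edge confidences are uniform on
    (0, 1).  Returns a ``u, v, confidence`` edge list.
    """
    if n_nodes < 1:
        raise ParameterError("n_nodes must be positive")
    if n_hubs < 0 or n_hubs >= n_nodes:
        raise ParameterError("need 0 <= n_hubs < n_nodes")
    if base_degree < 1:
        raise ParameterError("base_degree must be positive")
    rng = substream(seed, "ppi_graph")
    names = [f"P{i + 1:04d}" for i in range(n_nodes)]
    hubs = set(names[:n_hubs])
    p_base = min(1.0, base_degree / max(n_nodes - 1, 1))
    p_hub = min(1.0, hub_factor * p_base)
    rows = []
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            u, v = names[i], names[j]
            n_hub_ends = (u in hubs) + (v in hubs)
            if n_hub_ends == 2:
                p = 1.0
            elif n_hub_ends == 1:
                p = p_hub
            else:
                p = p_base
            if rng.random() < p:
                rows.append({"u": u, "v": v, "confidence": float(rng.uniform(0, 1))})
            else:
                rng.uniform(0, 1)  # keep the stream aligned across densities
    edges = pd.DataFrame(rows, columns=["u", "v", "confidence"])
    return edges, PpiTruth(hub_ids=tuple(sorted(hubs)), n_edges=len(edges))


# ------------------------------------------------------------------- counts


@dataclass(frozen=True)
class CountTruth:
    deg_ids: frozenset[str]
    log2fc: float


def gen_count_matrix(
    n_genes: int,
    n_deg: int,
    log2fc: float,
    dispersion: float = 0.1,
    n_reps_per_group: int = 5,
    seed: int = 0,
    mean_log10_range: tuple[float, float] = (1.3, 2.3),
) -> tuple[pd.DataFrame, pd.Series, CountTruth]:
    """Negative-binomial count matrix with planted fold changes.

    Counts follow NB(mean mu, variance mu + dispersion * mu^2); planted
    DEGs have treated/control mean ratio ``2**log2fc``, all other genes
    ratio 1.  Baseline means are log-uniform over
    ``10**mean_log10_range`` (roughly 20-200 by default, a typical
    targeted-panel depth).  Returns (counts, sample->group labels,
    truth).
    """
    if n_deg > n_genes or n_deg < 0:
        raise ParameterError("need 0 <= n_deg <= n_genes")
    if dispersion <= 0:
        raise ParameterError("dispersion must be positive")
    if n_reps_per_group < 2:
        raise ParameterError("need at least two replicates per group")
    rng = substream(seed, "count_matrix")
    genes = [f"G{i + 1:05d}" for i in range(n_genes)]
    base = 10 ** rng.uniform(*mean_log10_range, size=n_genes)
    deg_idx = rng.choice(n_genes, size=n_deg, replace=False) if n_deg else np.array([], dtype=int)
    mu_control = np.repeat(base[:, None], n_reps_per_group, axis=1)
    mu_treated = mu_control.copy()
    mu_treated[deg_idx] *= 2.0 ** log2fc
    size = 1.0 / dispersion

    def draw(mu: np.ndarray) -> np.ndarray:
        return rng.negative_binomial(size, size / (size + mu))

    counts = np.concatenate([draw(mu_control), draw(mu_treated)], axis=1)
    columns = [f"control_{i + 1}" for i in range(n_reps_per_group)] + [
        f"treated_{i + 1}" for i in range(n_reps_per_group)
    ]
    frame = pd.DataFrame(counts, index=genes, columns=columns)
    groups = pd.Series(
        ["control"] * n_reps_per_group + ["treated"] * n_reps_per_group, index=columns
    )
    truth = CountTruth(
        deg_ids=frozenset(genes[i] for i in deg_idx), log2fc=float(log2fc)
    )
    return frame, groups, truth


# --------------------------------------------------------------- annotation


@dataclass(frozen=True)
class AnnotationTruth:
    planted_term: str | None
    query: frozenset[str]


def gen_annotation(
    n_terms: int,
    universe_size: int,
    planted_term_enrichment: float,
    seed: int,
    term_size_range: tuple[int, int] = (10, 50),
    query_size: int = 40,
) -> tuple[dict[str, frozenset[str]], frozenset[str], AnnotationTruth]:
    """Term -> gene annotation with at most one planted enriched term.

    The query set draws ``round(planted_term_enrichment * query_size)``
    genes from the planted term and the rest uniformly; an enrichment
    fraction of 0 yields a pure null query.  Returns (terms, universe,
    truth).
    """
    if universe_size <= 0:
        raise ParameterError("universe_size must be positive")
    if not 0 <= planted_term_enrichment <= 1:
        raise ParameterError("planted_term_enrichment must be in [0, 1]")
    if n_terms < 1:
        raise ParameterError("need at least one term")
    rng = substream(seed, "annotation")
    universe = [f"G{i + 1:05d}" for i in range(universe_size)]
    lo, hi = term_size_range
    terms: dict[str, frozenset[str]] = {}
    for t in range(n_terms):
        size = int(rng.integers(lo, min(hi, universe_size) + 1))
        members = rng.choice(universe_size, size=size, replace=False)
        terms[f"T{t + 1:03d}"] = frozenset(universe[i] for i in members)

    query_size = min(query_size, universe_size)
    planted: str | None = None
    query: set[str] = set()
    if planted_term_enrichment > 0:
        planted = f"T{int(rng.integers(n_terms)) + 1:03d}"
        members = sorted(terms[planted])
        k = min(round(planted_term_enrichment * query_size), len(members))
        picked = rng.choice(len(members), size=k, replace=False)
        query |= {members[i] for i in picked}
    remaining = [g for g in universe if g not in query]
    n_fill = query_size - len(query)
    if n_fill > 0:
        fill = rng.choice(len(remaining), size=n_fill, replace=False)
        query |= {remaining[i] for i in fill}
    truth = AnnotationTruth(planted_term=planted, query=frozenset(query))
    return terms, frozenset(universe), truth


# ------------------------------------------------------------------ docking


@dataclass(frozen=True)
class DockingTruth:
    hit_ids: frozenset[str]


def gen_docking_table(
    n_compounds: int,
    control_score: float,
    fraction: float,
    n_hits: int,
    seed: int,
    n_missing: int = 0,
) -> tuple[pd.DataFrame, DockingTruth]:
    """Docking table with a control row and a planted number of hits.

    Exactly ``n_hits`` non-control compounds score strictly above
    ``fraction * control_score``; ``n_missing`` of the non-hits carry a
    no-pose missing flag instead of a score.
    """
    if not 0 < fraction <= 1:
        raise ParameterError("fraction must be in (0, 1]")
    if n_hits > n_compounds or n_hits < 0:
        raise ParameterError("need 0 <= n_hits <= n_compounds")
    if n_missing < 0 or n_hits + n_missing > n_compounds:
        raise ParameterError("too many missing rows")
    rng = substream(seed, "docking_table")
    threshold = fraction * control_score
    rows = [
        {
            "mol_id": "CTRL",
            "name": "positive control",
            "herb": "control",
            "score": float(control_score),
            "is_control": 1,
            "missing": 0,
        }
    ]
    hit_ids = set()
    for i in range(n_compounds):
        mol_id = f"SYND{i + 1:04d}"
        herb = HERB_ORDER[i % len(HERB_ORDER)]
        if i < n_hits:
            score = float(rng.uniform(threshold + 0.01 * abs(control_score) + 1e-6, max(control_score, threshold + 1.0)))
            hit_ids.add(mol_id)
            rows.append({"mol_id": mol_id, "name": f"ligand-{i + 1}", "herb": herb,
                         "score": round(score, 4), "is_control": 0, "missing": 0})
        elif i < n_hits + n_missing:
            rows.append({"mol_id": mol_id, "name": f"ligand-{i + 1}", "herb": herb,
                         "score": np.nan, "is_control": 0, "missing": 1})
        else:
            score = float(rng.uniform(min(0.0, threshold - 10.0), threshold - 0.01 * abs(control_score) - 1e-6))
            rows.append({"mol_id": mol_id, "name": f"ligand-{i + 1}", "herb": herb,
                         "score": round(score, 4), "is_control": 0, "missing": 0})
    table = pd.DataFrame(
        rows, columns=["mol_id", "name", "herb", "score", "is_control", "missing"]
    )
    return table, DockingTruth(hit_ids=frozenset(hit_ids))


# --------------------------------------------------------------------- qPCR


def gen_ct_table(
    true_ddct: float,
    noise_sd: float,
    n_reps: int,
    seed: int,
    base_ct: float = 18.0,
    dct_control: float = 4.0,
) -> pd.DataFrame:
    """Replicated Ct table with a known ddCt.

    The reference gene sits at ``base_ct`` in both conditions; the
    target gene at ``base_ct + dct_control`` in control and additionally
    shifted by ``true_ddct`` in treated, plus Gaussian noise of sd
    ``noise_sd`` on every well.  Expected ddCt equals ``true_ddct``.
    """
    if n_reps < 1:
        raise ParameterError("need at least one replicate")
    if noise_sd < 0:
        raise ParameterError("noise_sd must be non-negative")
    rng = substream(seed, "ct_table")
    rows = []
    means = {
        ("REF", "reference", "control"): base_ct,
        ("REF", "reference", "treated"): base_ct,
        ("TGT", "target", "control"): base_ct + dct_control,
        ("TGT", "target", "treated"): base_ct + dct_control + true_ddct,
    }
    for (gene, role, condition), mean in means.items():
        for rep in range(1, n_reps + 1):
            ct = mean + (rng.normal(0, noise_sd) if noise_sd > 0 else 0.0)
            rows.append(
                {"gene": gene, "role": role, "condition": condition,
                 "replicate": rep, "ct": float(ct)}
            )
    return pd.DataFrame(rows)
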