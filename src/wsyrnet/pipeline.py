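"""End-to-end orchestration of the pipeline stages.

``run_pipeline`` executes, in order: ADME compound screen ->
therapeutic-target intersection -> (optional) enrichment -> (optional)
interaction-network hub ranking -> DEG classification (and, when a
count matrix is configured, the count-based test) -> docking screen ->
(optional) qPCR quantification -> multipartite network assembly.  The
optional stages run only when the config supplies their inputs; a bare
run with no paths uses the packaged reference tables and reproduces
their headline counts.  Reports are plain JSON with sorted keys, so a
fixed config and seed give byte-identical output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import deg, docking, enrichment, fixtures, io, ppin, qpcr
from .compounds import screen_compounds, shared_compounds
from .errors import ParameterError
from .herbs import HERB_ORDER
from .network import assemble_hctp, export_network
from .targets import intersect_targets, keys_from_frame

#: Counts the packaged tables are expected to reproduce.
EXPECTED_FIXTURE_COUNTS = {
    "active_compounds": 43,
    "shared_compounds": 4,
    "therapeutic_targets": 44,
    "degs": 92,
    "ESR1_hits": 7,
    "ESR2_hits": 5,
}


@dataclass
class PipelineConfig:
    """Declarative pipeline configuration.

    Unset paths fall back to the packaged reference tables (compounds,
    targets, DEG statistics, docking) or disable optional stages
    (annotation, edge list, counts, Ct table).  Every threshold
    defaults to the study's published value.
    """

    compounds_path: str | None = None
    targets_path: str | None = None
    deg_stats_path: str | None = None
    docking_paths: dict[str, str] = field(default_factory=dict)
    annotation_path: str | None = None
    edges_path: str | None = None
    counts_path: str | None = None
    groups_path: str | None = None
    ct_path: str | None = None

    ob_min: float = 30.0
    dl_min: float = 0.18
    enrichment_p_max: float = 1e-3
    confidence_min: float = 0.9
    fc_up: float = 1.5
    fc_down: float = 0.67
    p_max: float = 0.05
    docking_fractions: dict[str, float] = field(
        default_factory=lambda: dict(fixtures.DOCKING_FRACTIONS)
    )
    rmsd_max: float = 2.0
    top_k: int = 5
    seed: int = 0
    export_formats: tuple[str, ...] = ("graphml", "sif", "node-link")

    def __post_init__(self) -> None:
        if not 0 <= self.confidence_min <= 1:
            raise ParameterError("confidence_min must be in [0, 1]")
        if not self.fc_down < 1 < self.fc_up:
            raise ParameterError("need fc_down < 1 < fc_up")
        if not 0 < self.p_max <= 1:
            raise ParameterError("p_max must be in (0, 1]")
        if self.top_k < 1:
            raise ParameterError("top_k must be >= 1")
        for receptor, fraction in self.docking_fractions.items():
            if not 0 < fraction <= 1:
                raise ParameterError(f"docking fraction for {receptor} must be in (0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        if "export_formats" in raw:
            raw["export_formats"] = tuple(raw["export_formats"])
        return cls(**raw)


def _digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _round_floats(obj: Any, ndigits: int = 6) -> Any:
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def run_pipeline(
    config: PipelineConfig, output_dir: str | Path | None = None
) -> dict[str, Any]:
    """Run every configured stage and return the run report."""
    out = Path(output_dir) if output_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {
        "seed": config.seed,
        "thresholds": {
            "ob_min": config.ob_min,
            "dl_min": config.dl_min,
            "enrichment_p_max": config.enrichment_p_max,
            "confidence_min": config.confidence_min,
            "fc_up": config.fc_up,
            "fc_down": config.fc_down,
            "p_max": config.p_max,
            "docking_fractions": dict(sorted(config.docking_fractions.items())),
            "rmsd_max": config.rmsd_max,
            "top_k": config.top_k,
        },
        "inputs": {},
    }
    using_fixtures = config.compounds_path is None

    # ------------------------------------------------------ compound screen
    if config.compounds_path:
        compound_table = io.read_table(config.compounds_path)
        report["inputs"]["compounds"] = _digest(config.compounds_path)
    else:
        compound_table = fixtures.load_compound_table()
    actives = screen_compounds(compound_table, config.ob_min, config.dl_min)
    shared = shared_compounds(actives)
    report["compounds"] = {
        "per_herb": dict(sorted(actives.per_herb_counts.items())),
        "unique_active": len(actives.unique_ids),
        "n_shared": len(shared),
        "shared": [
            {"mol_id": m, "name": n, "herbs": list(h)} for m, n, h in shared
        ],
    }
    if out is not None:
        io.write_table(actives.records, out / "active_compounds.tsv")

    # ---------------------------------------------------- therapeutic targets
    if config.targets_path:
        target_table = io.read_table(config.targets_path)
        report["inputs"]["targets"] = _digest(config.targets_path)
    else:
        target_table = fixtures.load_target_table()
    if len(target_table):
        keyed = target_table.assign(key=keys_from_frame(target_table))
        herb_sets = {
            herb: set(sub["key"]) for herb, sub in keyed.groupby("herb")
        }
    else:
        herb_sets = {}
    disease = set().union(*herb_sets.values()) if herb_sets else set()
    therapeutic = intersect_targets(herb_sets, disease)
    report["targets"] = {
        "per_herb": {h: len(s) for h, s in sorted(therapeutic.per_herb.items())},
        "union": len(therapeutic.union),
    }

    # ------------------------------------------------------------ enrichment
    if config.annotation_path:
        report["inputs"]["annotation"] = _digest(config.annotation_path)
        pairs = io.read_annotation_pairs(config.annotation_path)
        annotation = enrichment.AnnotationSet.from_pairs(pairs)
        symbol_query = set(target_table["symbol"].astype(str)) if len(target_table) else set()
        table = enrichment.enrich(symbol_query, annotation, config.enrichment_p_max)
        report["enrichment"] = {
            "n_terms_tested": int(len(table)),
            "n_enriched": int(table["enriched"].sum()) if len(table) else 0,
        }
        if out is not None:
            io.write_table(table, out / "enrichment.tsv")

    # ------------------------------------------------------------------ PPIN
    if config.edges_path:
        report["inputs"]["edges"] = _digest(config.edges_path)
        edges = io.read_edge_list(config.edges_path)
        graph = ppin.build_graph(edges, config.confidence_min)
        if graph.number_of_nodes():
            ranked = ppin.composite_score(ppin.centralities(graph))
            key_targets = ppin.top_k_targets(ranked, config.top_k)
            if out is not None:
                io.write_table(ranked, out / "centrality.tsv")
        else:
            key_targets = []
        report["ppin"] = {
            "n_nodes": graph.number_of_nodes(),
            "n_edges": graph.number_of_edges(),
            "key_targets": [str(t) for t in key_targets],
        }

    # ------------------------------------------------------------------ DEGs
    if config.deg_stats_path:
        deg_table = io.read_table(config.deg_stats_path)
        report["inputs"]["deg_stats"] = _digest(config.deg_stats_path)
    else:
        deg_table = fixtures.load_deg_table()
    if config.counts_path:
        report["inputs"]["counts"] = _digest(config.counts_path)
        counts = io.read_counts(config.counts_path)
        groups = io.read_table(config.groups_path).set_index("sample")["group"]
        computed = deg.count_test(counts, groups)
        if out is not None:
            io.write_table(computed, out / "count_test_stats.tsv")
    calls = (
        deg.classify_degs(deg_table, config.fc_up, config.fc_down, config.p_max)
        if len(deg_table)
        else deg_table.assign(direction=pd.Series(dtype=str))
    )
    merged = deg.merge_deg_sets(calls)
    per_herb_calls = {
        herb: sub for herb, sub in calls.groupby("herb")
    } if len(calls) else {}
    report["degs"] = {
        "per_herb": {
            h: {
                "total": int(len(sub)),
                "up": int((sub["direction"] == "up").sum()),
                "down": int((sub["direction"] == "down").sum()),
            }
            for h, sub in sorted(per_herb_calls.items())
        },
        "union": len(merged.genes),
        "multi_herb": sorted(
            g for g, prov in merged.provenance.items() if len(prov) >= 2
        ),
    }
    if out is not None:
        io.write_table(calls, out / "deg_calls.tsv")

    # --------------------------------------------------------------- docking
    receptors = (
        dict(config.docking_paths)
        if config.docking_paths
        else {r: None for r in sorted(fixtures.DOCKING_FRACTIONS)}
    )
    retained: dict[str, pd.DataFrame] = {}
    report["docking"] = {}
    for receptor, path in sorted(receptors.items()):
        if path:
            table = io.read_table(path)
            report["inputs"][f"docking_{receptor}"] = _digest(path)
        else:
            table = fixtures.load_docking_table(receptor)
        if len(table) == 0:
            report["docking"][receptor] = {"n_hits": 0, "hits": []}
            continue
        fraction = config.docking_fractions.get(receptor)
        if fraction is None:
            raise ParameterError(f"no docking fraction configured for {receptor}")
        rule = docking.rule_from_table(table, fraction, receptor)
        hits = docking.screen_hits(table, rule)
        retained[receptor] = hits
        report["docking"][receptor] = {
            "control_score": rule.control_score,
            "fraction": rule.fraction,
            "threshold": rule.threshold,
            "n_hits": int(len(hits)),
            "hits": hits["name"].tolist(),
            "max_score": float(hits["score"].max()) if len(hits) else None,
            "min_score": float(hits["score"].min()) if len(hits) else None,
        }
        if out is not None:
            io.write_table(hits, out / f"docking_hits_{receptor}.tsv")
    if retained:
        summary = docking.summarize_screen(retained)
        report["docking"]["cross_receptor"] = {
            "n_compounds": int(len(summary)),
            "all_receptors": docking.both_receptor_hits(retained),
        }
        if out is not None:
            io.write_table(summary, out / "docking_summary.tsv")

    # ------------------------------------------------------------------ qPCR
    if config.ct_path:
        report["inputs"]["ct"] = _digest(config.ct_path)
        folds = qpcr.fold_changes_from_table(io.read_table(config.ct_path))
        report["qpcr"] = {
            row["gene"]: {"ddct": row["ddct"], "fold_change": row["fold_change"]}
            for _, row in folds.iterrows()
        }
        if out is not None:
            io.write_table(folds, out / "qpcr_fold_changes.tsv")

    # --------------------------------------------------------------- network
    net = assemble_hctp(actives, therapeutic=therapeutic)
    report["network"] = net.counts()
    if out is not None:
        suffix = {"graphml": "graphml", "sif": "sif", "node-link": "json"}
        for fmt in config.export_formats:
            export_network(net, out / f"hctp_network.{suffix[fmt]}", fmt)

    # ----------------------------------------------------------- paper parity
    if using_fixtures:
        observed = {
            "active_compounds": report["compounds"]["unique_active"],
            "shared_compounds": report["compounds"]["n_shared"],
            "therapeutic_targets": report["targets"]["union"],
            "degs": report["degs"]["union"],
            "ESR1_hits": report["docking"].get("ESR1", {}).get("n_hits", 0),
            "ESR2_hits": report["docking"].get("ESR2", {}).get("n_hits", 0),
        }
        report["paper_parity"] = {
            key: {
                "expected": EXPECTED_FIXTURE_COUNTS[key],
                "observed": observed[key],
                "match": observed[key] == EXPECTED_FIXTURE_COUNTS[key],
            }
            for key in sorted(EXPECTED_FIXTURE_COUNTS)
        }

    report = _round_floats(report)
    if out is not None:
        (out / "report.json").write_text(render_report(report))
    return report


def render_report(report: dict[str, Any]) -> str:
    """Canonical JSON rendering (sorted keys, fixed layout)."""
    return json.dumps(report, sort_keys=True, indent=2) + "\n"
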