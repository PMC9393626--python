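"""Docking-score screening against a positive-control-relative threshold.

Scores are docking interaction energies reported so that larger
positive values mean stronger predicted affinity.  A screened table
carries exactly one positive-control row (the receptor's co-crystal
ligand); a compound is retained when its score strictly exceeds
``fraction x control_score``.  Compounds for which the docking engine
produced no refined pose carry a missing flag and never participate in
retention or ranking.  A redocking model is considered reliable when
the RMSD between the original and redocked ligand poses is below 2 A.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError, ParseError
from .herbs import herb_sort_key, split_herbs

RMSD_RELIABLE_MAX = 2.0


@dataclass(frozen=True)
class ScreenRule:
    """Positive-control-relative retention rule."""

    control_score: float
    fraction: float
    receptor: str = ""

    def __post_init__(self) -> None:
        if not 0 < self.fraction <= 1:
            raise ParameterError("fraction must be in (0, 1]")
        if not math.isfinite(self.control_score):
            raise ParameterError("control score must be finite")

    @property
    def threshold(self) -> float:
        return self.fraction * self.control_score


@dataclass(frozen=True)
class PoseComparison:
    """RMSD between two same-ordering coordinate sets, in Angstroms."""

    rmsd_angstrom: float

    @property
    def reliable(self) -> bool:
        return self.rmsd_angstrom < RMSD_RELIABLE_MAX


def _validate_table(table: pd.DataFrame) -> pd.DataFrame:
    for col in ("mol_id", "name", "herb", "score", "is_control", "missing"):
        if col not in table.columns:
            raise ParseError(f"docking table lacks column {col!r}")
    table = table.copy()
    table["is_control"] = table["is_control"].astype(bool)
    table["missing"] = table["missing"].astype(bool)
    n_control = int(table["is_control"].sum())
    if n_control == 0:
        raise ParseError("docking table has no positive-control row")
    if n_control > 1:
        raise ParseError(f"docking table has {n_control} positive-control rows")
    return table


def rule_from_table(
    table: pd.DataFrame, fraction: float, receptor: str = ""
) -> ScreenRule:
    """Build a :class:`ScreenRule` from the table's control row."""
    table = _validate_table(table)
    control = float(table.loc[table["is_control"], "score"].iloc[0])
    if not math.isfinite(control):
        raise ParseError("positive-control score is not finite")
    return ScreenRule(control_score=control, fraction=fraction, receptor=receptor)


def screen_hits(table: pd.DataFrame, rule: ScreenRule) -> pd.DataFrame:
    """Retain non-control, non-missing rows scoring strictly above
    ``rule.threshold``; sorted by score descending, mol_id ascending."""
    table = _validate_table(table)
    candidates = table[~table["is_control"] & ~table["missing"]].copy()
    candidates["score"] = candidates["score"].astype(float)
    if not np.isfinite(candidates["score"]).all():
        raise ParseError("non-missing docking rows must carry finite scores")
    kept = candidates[candidates["score"] > rule.threshold]
    return kept.sort_values(
        ["score", "mol_id"], ascending=[False, True]
    ).reset_index(drop=True)


def rmsd(
    coords_a: Sequence[Sequence[float]], coords_b: Sequence[Sequence[float]]
) -> PoseComparison:
    """Root-mean-square deviation over paired atoms (no superposition:
    redocked poses share the receptor coordinate frame)."""
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3 or a.shape[0] < 1:
        raise ParameterError(
            f"coordinate sets must be matching (n, 3) arrays, got {a.shape} vs {b.shape}"
        )
    value = float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))
    return PoseComparison(rmsd_angstrom=value)


def summarize_screen(
    retained: Mapping[str, pd.DataFrame],
) -> pd.DataFrame:
    """Cross-receptor hit summary.

    ``retained`` maps receptor name -> :func:`screen_hits` output.
    Returns one row per compound passing at least one receptor, with
    columns ``mol_id, name, herb, receptors, n_receptors``; receptors
    are sorted by name, rows by (descending receptor count, mol_id).
    """
    if not retained:
        raise ParameterError("no screened receptors to summarize")
    info: dict[str, dict] = {}
    for receptor in sorted(retained):
        for _, row in retained[receptor].iterrows():
            entry = info.setdefault(
                row["mol_id"],
                {
                    "name": row["name"],
                    "herb": ";".join(
                        sorted(split_herbs(row["herb"]), key=herb_sort_key)
                    ),
                    "receptors": [],
                },
            )
            entry["receptors"].append(receptor)
    rows = [
        {
            "mol_id": mol_id,
            "name": entry["name"],
            "herb": entry["herb"],
            "receptors": ";".join(entry["receptors"]),
            "n_receptors": len(entry["receptors"]),
        }
        for mol_id, entry in info.items()
    ]
    return (
        pd.DataFrame(rows)
        .sort_values(["n_receptors", "mol_id"], ascending=[False, True])
        .reset_index(drop=True)
    )


def both_receptor_hits(retained: Mapping[str, pd.DataFrame]) -> list[str]:
    """mol_ids retained by every screened receptor."""
    sets = [set(df["mol_id"]) for df in retained.values()]
    if not sets:
        return []
    common = set.intersection(*sets)
    return sorted(common)
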