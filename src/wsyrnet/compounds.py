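"""ADME screening of herb compound tables.

Compounds are screened on two TCMSP-style descriptors: oral
bioavailability (OB, percent) and drug-likeness (DL, unitless in
[0, 1]).  A compound is an *active* component of its herb when
``OB >= ob_min`` and ``DL >= dl_min`` (both inclusive; the defaults are
the conventional OB >= 30 %, DL >= 0.18 cutoffs).  Compound identity is
the molecule accession (``mol_id``), not the display name, because names
vary in case and spelling across source tables; a compound present in
two herbs appears as two rows with the same ``mol_id``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .errors import ParameterError, ParseError
from .herbs import HERB_ORDER, herb_sort_key, normalize_herb

#: Default screening thresholds.
OB_MIN_DEFAULT = 30.0
DL_MIN_DEFAULT = 0.18

REQUIRED_COLUMNS = ("mol_id", "name", "ob", "dl", "herb")


@dataclass(frozen=True)
class ActiveCompoundSet:
    """Result of an ADME screen.

    Attributes
    ----------
    records:
        Retained rows (one per compound-herb pair), original schema.
    per_herb_counts:
        Herb -> number of retained compounds for that herb.
    unique_ids:
        Deduplicated ``mol_id`` set across herbs.
    shared:
        ``mol_id`` -> tuple of herbs, for compounds retained in >= 2
        herbs only; herbs sorted by declared order.
    """

    records: pd.DataFrame
    per_herb_counts: dict[str, int] = field(default_factory=dict)
    unique_ids: frozenset[str] = frozenset()
    shared: dict[str, tuple[str, ...]] = field(default_factory=dict)


def _validate_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ParseError(f"compound table lacks columns: {missing}")
    table = table.copy()
    for idx, row in table.iterrows():
        try:
            ob = float(row["ob"])
            dl = float(row["dl"])
        except (TypeError, ValueError):
            raise ParseError(
                f"row {idx} ({row['mol_id']}): malformed OB/DL "
                f"values {row['ob']!r}/{row['dl']!r}"
            ) from None
        if not (math.isfinite(ob) and math.isfinite(dl)):
            raise ParseError(f"row {idx} ({row['mol_id']}): non-finite OB/DL")
        if ob < 0:
            raise ParseError(f"row {idx} ({row['mol_id']}): OB must be >= 0, got {ob}")
        if not 0 <= dl <= 1:
            raise ParseError(f"row {idx} ({row['mol_id']}): DL must be in [0,1], got {dl}")
    table["ob"] = table["ob"].astype(float)
    table["dl"] = table["dl"].astype(float)
    table["herb"] = table["herb"].map(normalize_herb)
    dup = table.duplicated(subset=["mol_id", "herb"])
    if dup.any():
        first = table.loc[dup, ["mol_id", "herb"]].iloc[0]
        raise ParseError(
            f"duplicate (mol_id, herb) pair: ({first['mol_id']}, {first['herb']})"
        )
    return table


def screen_compounds(
    table: pd.DataFrame,
    ob_min: float = OB_MIN_DEFAULT,
    dl_min: float = DL_MIN_DEFAULT,
) -> ActiveCompoundSet:
    """Retain compounds with ``ob >= ob_min`` and ``dl >= dl_min``.

    Parameters
    ----------
    table:
        One row per compound-herb pair with columns
        ``mol_id, name, ob, dl, herb``.
    ob_min, dl_min:
        Inclusive screening thresholds.
    """
    if not (math.isfinite(ob_min) and math.isfinite(dl_min)):
        raise ParameterError("screening thresholds must be finite")
    table = _validate_table(table)
    kept = table[(table["ob"] >= ob_min) & (table["dl"] >= dl_min)].copy()
    kept = kept.sort_values(
        ["herb", "mol_id"], key=lambda s: s.map(herb_sort_key) if s.name == "herb" else s
    ).reset_index(drop=True)

    per_herb = {h: 0 for h in HERB_ORDER if h in set(table["herb"])}
    per_herb.update(kept.groupby("herb")["mol_id"].count().to_dict())
    unique_ids = frozenset(kept["mol_id"])
    herbs_by_id = kept.groupby("mol_id")["herb"].agg(
        lambda s: tuple(sorted(set(s), key=herb_sort_key))
    )
    shared = {m: hs for m, hs in herbs_by_id.items() if len(hs) >= 2}
    return ActiveCompoundSet(
        records=kept,
        per_herb_counts=per_herb,
        unique_ids=unique_ids,
        shared=shared,
    )


def shared_compounds(active: ActiveCompoundSet) -> list[tuple[str, str, tuple[str, ...]]]:
    """List compounds retained under two or more herbs.

    Returns ``(mol_id, name, herbs)`` tuples sorted by ``mol_id``; each
    herbs tuple follows the declared herb order.
    """
    names = (
        active.records.drop_duplicates("mol_id").set_index("mol_id")["name"].to_dict()
    )
    return [
        (mol_id, names.get(mol_id, ""), herbs)
        for mol_id, herbs in sorted(active.shared.items())
    ]
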