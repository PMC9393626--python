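"""Relative qPCR quantification by the 2^-ddCt (Livak) method.

Replicate Ct values are averaged on the Ct scale; the target gene is
normalized to a reference gene within each condition (dCt), the treated
condition to control (ddCt), and the fold change is 2^-ddCt.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParameterError, ParseError


@dataclass(frozen=True)
class CtMeasurement:
    """Replicate Ct values for one gene in one condition."""

    gene: str
    role: str  # "target" or "reference"
    condition: str  # "control" or "treated"
    cts: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.cts) < 1:
            raise ParameterError("need at least one Ct replicate")
        arr = np.asarray(self.cts, dtype=float)
        if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
            raise ParameterError(f"{self.gene}/{self.condition}: Ct values must be finite and > 0")

    @property
    def mean_ct(self) -> float:
        return float(np.mean(self.cts))


@dataclass(frozen=True)
class FoldChangeResult:
    gene: str
    ddct: float
    fold_change: float


def ddct_fold_change(
    target_treated: CtMeasurement,
    ref_treated: CtMeasurement,
    target_control: CtMeasurement,
    ref_control: CtMeasurement,
) -> FoldChangeResult:
    """2^-ddCt fold change of the target gene, treated vs control."""
    for m, cond in (
        (target_treated, "treated"),
        (ref_treated, "treated"),
        (target_control, "control"),
        (ref_control, "control"),
    ):
        if m.condition != cond:
            raise ParameterError(
                f"measurement {m.gene!r} labelled {m.condition!r}, expected {cond!r}"
            )
    dct_treated = target_treated.mean_ct - ref_treated.mean_ct
    dct_control = target_control.mean_ct - ref_control.mean_ct
    ddct = dct_treated - dct_control
    return FoldChangeResult(
        gene=target_treated.gene, ddct=ddct, fold_change=float(2.0 ** -ddct)
    )


def fold_changes_from_table(table: pd.DataFrame) -> pd.DataFrame:
    """Fold changes for every target gene in a long-format Ct table.

    Expects columns ``gene, role, condition, replicate, ct`` with one
    reference gene; returns ``gene, ddct, fold_change`` per target.
    """
    for col in ("gene", "role", "condition", "ct"):
        if col not in table.columns:
            raise ParseError(f"Ct table lacks column {col!r}")
    refs = table[table["role"] == "reference"]
    if refs.empty:
        raise ParseError("Ct table has no reference-gene rows")
    ref_gene = sorted(refs["gene"].unique())[0]

    def measure(gene: str, role: str, condition: str) -> CtMeasurement:
        rows = table[
            (table["gene"] == gene)
            & (table["role"] == role)
            & (table["condition"] == condition)
        ]
        if rows.empty:
            raise ParameterError(f"missing Ct rows for {gene}/{condition}")
        return CtMeasurement(
            gene=gene, role=role, condition=condition,
            cts=tuple(rows["ct"].astype(float)),
        )

    results = []
    for gene in sorted(table.loc[table["role"] == "target", "gene"].unique()):
        res = ddct_fold_change(
            measure(gene, "target", "treated"),
            measure(ref_gene, "reference", "treated"),
            measure(gene, "target", "control"),
            measure(ref_gene, "reference", "control"),
        )
        results.append({"gene": gene, "ddct": res.ddct, "fold_change": res.fold_change})
    return pd.DataFrame(results)
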