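"""Packaged reference tables.

The package ships five small delimited tables transcribed from the
published study surface: the per-herb compound table with OB/DL scores,
the per-herb therapeutic target lists, the per-herb DEG statistics, and
the two receptor docking-score tables (estrogen receptors alpha and
beta, each with its positive-control ligand row).  ``make_fixtures``
copies them to a working directory with a checksum manifest.
"""

from __future__ import annotations

import hashlib
from importlib import resources
from pathlib import Path

import pandas as pd

from .errors import ParameterError

FIXTURE_FILES = {
    "compounds": "herb_compounds.tsv",
    "targets": "therapeutic_targets.tsv",
    "deg_stats": "deg_stats.tsv",
    "docking_ESR1": "docking_esr1.tsv",
    "docking_ESR2": "docking_esr2.tsv",
}

#: Receptor -> retention fraction of the positive-control score.
DOCKING_FRACTIONS = {"ESR1": 0.75, "ESR2": 0.90}


def _read(name: str) -> pd.DataFrame:
    ref = resources.files("wsyrnet.data").joinpath(FIXTURE_FILES[name])
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def load_compound_table() -> pd.DataFrame:
    """Herb compound table: one row per compound-herb pair."""
    return _read("compounds")


def load_target_table() -> pd.DataFrame:
    """Per-herb therapeutic target lists (symbol, entrez, herb)."""
    return _read("targets")


def load_deg_table() -> pd.DataFrame:
    """Per-herb DEG statistics (gene, entrez, log2fc, pvalue, herb)."""
    return _read("deg_stats")


def load_docking_table(receptor: str) -> pd.DataFrame:
    """Docking-score table for ``receptor`` ("ESR1" or "ESR2")."""
    key = f"docking_{receptor}"
    if key not in FIXTURE_FILES:
        raise ParameterError(f"no docking fixture for receptor {receptor!r}")
    return _read(key)


def make_fixtures(output_dir: str | Path) -> dict[str, Path]:
    """Copy every packaged table into ``output_dir`` and write a
    sha256 manifest (``MANIFEST.tsv``).  Returns name -> written path."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    manifest_lines = ["file\tsha256"]
    for name, filename in FIXTURE_FILES.items():
        ref = resources.files("wsyrnet.data").joinpath(filename)
        data = ref.read_bytes()
        dest = out / filename
        dest.write_bytes(data)
        manifest_lines.append(f"{filename}\t{hashlib.sha256(data).hexdigest()}")
        written[name] = dest
    (out / "MANIFEST.tsv").write_text("\n".join(manifest_lines) + "\n")
    return written
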