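"""Readers and writers for the pipeline's delimited-text schemas."""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .errors import ParseError

logger = logging.getLogger(__name__)


def read_table(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    return pd.read_csv(path, sep=sep)


def write_table(frame: pd.DataFrame, path: str | Path, sep: str = "\t") -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep=sep, index=False)
    return path


def read_edge_list(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    """STRING-style edge list: protein1, protein2, combined_score.

    Scores are accepted either as 0-1000 integers (STRING convention)
    or 0-1 reals; the scale is auto-detected (logged) and the returned
    frame always carries ``u, v, confidence`` with confidence in [0, 1].
    """
    frame = pd.read_csv(path, sep=sep or r"\s+|\t|,", engine="python")
    cols = {c.lower(): c for c in frame.columns}
    try:
        u = cols.get("protein1") or cols["u"]
        v = cols.get("protein2") or cols["v"]
        score = cols.get("combined_score") or cols.get("confidence") or cols["score"]
    except KeyError:
        raise ParseError(
            f"{path}: edge list needs protein1/protein2/combined_score "
            f"(or u/v/confidence) columns, found {list(frame.columns)}"
        ) from None
    out = frame[[u, v, score]].copy()
    out.columns = ["u", "v", "confidence"]
    conf = out["confidence"].astype(float)
    if conf.max() > 1.0:
        logger.info("read_edge_list: %s uses the 0-1000 score scale", path)
        conf = conf / 1000.0
    out["confidence"] = conf
    return out


def read_annotation_pairs(path: str | Path) -> list[tuple[str, str]]:
    """Two-column term/gene annotation, or GMT when the path ends .gmt."""
    path = Path(path)
    pairs: list[tuple[str, str]] = []
    if path.suffix.lower() == ".gmt":
        for line in path.read_text().splitlines():
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}: GMT line needs term, description, genes: {line!r}")
            term = fields[0]
            pairs.extend((term, gene) for gene in fields[2:] if gene)
    else:
        frame = pd.read_csv(path, sep="\t")
        if not {"term_id", "gene"} <= set(frame.columns):
            raise ParseError(f"{path}: annotation needs term_id and gene columns")
        pairs = list(zip(frame["term_id"].astype(str), frame["gene"].astype(str)))
    return pairs


def read_counts(path: str | Path) -> pd.DataFrame:
    """Gene x sample count matrix: delimited text, or MTX triplets when
    the path ends .mtx (gene/sample names from sidecar .rows/.cols
    files next to it)."""
    path = Path(path)
    if path.suffix.lower() == ".mtx":
        from scipy.io import mmread

        matrix = mmread(path).toarray()
        rows = (path.with_suffix(".rows")).read_text().split()
        cols = (path.with_suffix(".cols")).read_text().split()
        if matrix.shape != (len(rows), len(cols)):
            raise ParseError(f"{path}: MTX shape {matrix.shape} does not match sidecars")
        return pd.DataFrame(matrix.astype(int), index=rows, columns=cols)
    return pd.read_csv(path, sep="\t", index_col=0)


def read_xyz(path: str | Path) -> list[tuple[float, float, float]]:
    """Plain coordinate list: three whitespace-separated floats per line
    (an optional leading atom label is ignored)."""
    coords = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        fields = line.split()
        if not fields:
            continue
        if len(fields) == 4:
            fields = fields[1:]
        if len(fields) != 3:
            raise ParseError(f"{path}:{ln}: expected 3 coordinates, got {len(fields)}")
        try:
            coords.append(tuple(float(f) for f in fields))
        except ValueError:
            raise ParseError(f"{path}:{ln}: malformed coordinate line {line!r}") from None
    return coords
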