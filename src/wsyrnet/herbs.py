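"""Herb vocabulary for the three-herb WSYR recipe.

The recipe combines Gusuibu (*Drynaria fortunei*), Roucongrong
(*Cistanche deserticola*) and Yinyanghuo (*Epimedium brevicornu*).
Upstream tables spell the pinyin names several ways (``GU_SUI_BU``,
``gusuibu`` ...); everything is normalized to the canonical declared
order used throughout the pipeline.
"""

from __future__ import annotations

from .errors import VocabularyError

#: Canonical herb names, in declared order.
HERB_ORDER: tuple[str, ...] = ("Gusuibu", "Roucongrong", "Yinyanghuo")

_CANONICAL = {h.lower(): h for h in HERB_ORDER}
_CANONICAL.update(
    {
        "gu_sui_bu": "Gusuibu",
        "rou_cong_rong": "Roucongrong",
        "yin_yang_huo": "Yinyanghuo",
    }
)


def normalize_herb(label: str) -> str:
    """Map any accepted spelling to the canonical herb name.

    Raises
    ------
    VocabularyError
        If ``label`` is not a recognized herb.
    """
    key = str(label).strip().lower().replace(" ", "_").replace("-", "_")
    try:
        return _CANONICAL[key]
    except KeyError:
        raise VocabularyError(f"unknown herb label: {label!r}") from None


def split_herbs(cell: str, sep: str = ";") -> tuple[str, ...]:
    """Split a multi-herb cell (``"Gusuibu;Yinyanghuo"``) into canonical
    names sorted by declared herb order."""
    parts = [p for p in (s.strip() for s in str(cell).split(sep)) if p]
    herbs = {normalize_herb(p) for p in parts}
    return tuple(sorted(herbs, key=HERB_ORDER.index))


def herb_sort_key(herb: str) -> int:
    return HERB_ORDER.index(normalize_herb(herb))
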