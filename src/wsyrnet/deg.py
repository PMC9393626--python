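"""Differential-expression calling.

Two entry points:

* :func:`classify_degs` applies fold-change and p-value thresholds to a
  table of precomputed per-gene statistics (log2 fold change, p value),
  labelling genes up / down / uncalled.  The default rule is
  FC > 1.5 or FC < 0.67 with p < 0.05, applied in log2 space with
  strict inequalities.
* :func:`count_test` computes those statistics from a raw count matrix
  with a negative-binomial conditional exact test (edgeR-style):
  library-size-normalized counts are compared between the two groups
  conditionally on the gene's total, with a common method-of-moments
  dispersion shared across genes.  This is a transparent count-based
  test, not a reimplementation of shrinkage-based DE frameworks.

:func:`merge_deg_sets` unions per-herb calls into the recipe-wide DEG
set with per-herb direction provenance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from scipy.stats import binom

from .errors import ParameterError, ParseError

FC_UP_DEFAULT = 1.5
FC_DOWN_DEFAULT = 0.67
P_MAX_DEFAULT = 0.05
DISPERSION_FLOOR = 1e-12
PSEUDOCOUNT = 0.5


def classify_degs(
    stats: pd.DataFrame,
    fc_up: float = FC_UP_DEFAULT,
    fc_down: float = FC_DOWN_DEFAULT,
    p_max: float = P_MAX_DEFAULT,
) -> pd.DataFrame:
    """Call DEGs from per-gene ``log2fc`` / ``pvalue`` statistics.

    A gene is *up* iff ``log2fc > log2(fc_up)`` and ``pvalue < p_max``,
    *down* iff ``log2fc < log2(fc_down)`` and ``pvalue < p_max``; all
    inequalities strict.  Returns only the called rows, with a
    ``direction`` column appended.
    """
    if not fc_down < 1 < fc_up:
        raise ParameterError("need fc_down < 1 < fc_up")
    for col in ("gene", "log2fc", "pvalue"):
        if col not in stats.columns:
            raise ParseError(f"DEG stats table lacks column {col!r}")
    lfc = stats["log2fc"].astype(float)
    pv = stats["pvalue"].astype(float)
    bad = ~(np.isfinite(lfc) & np.isfinite(pv) & (pv > 0) & (pv <= 1))
    if bad.any():
        idx = stats.index[bad.to_numpy()][0]
        raise ParseError(f"row {idx} ({stats.loc[idx, 'gene']}): non-finite or invalid stats")
    up = (lfc > math.log2(fc_up)) & (pv < p_max)
    down = (lfc < math.log2(fc_down)) & (pv < p_max)
    out = stats.copy()
    out["direction"] = np.where(up, "up", np.where(down, "down", ""))
    return out[out["direction"] != ""].reset_index(drop=True)


@dataclass(frozen=True)
class DEGUnion:
    """Recipe-wide deduplicated DEG set with per-herb provenance."""

    genes: frozenset[str]
    #: gene -> {herb: direction}
    provenance: dict[str, dict[str, str]] = field(default_factory=dict)


def merge_deg_sets(calls: pd.DataFrame) -> DEGUnion:
    """Union per-herb DEG calls keyed by gene id."""
    provenance: dict[str, dict[str, str]] = {}
    for _, row in calls.iterrows():
        provenance.setdefault(str(row["gene"]), {})[str(row["herb"])] = str(
            row["direction"]
        )
    return DEGUnion(genes=frozenset(provenance), provenance=provenance)


def _nb_logpmf(k: np.ndarray, size: float, mean: float) -> np.ndarray:
    """Negative-binomial log pmf parameterized by size r and mean m."""
    r, m = size, mean
    return (
        gammaln(k + r)
        - gammaln(r)
        - gammaln(k + 1)
        + r * math.log(r / (r + m))
        + k * math.log(m / (r + m))
    )


def _size_factors(raw: np.ndarray) -> np.ndarray:
    """Median-of-ratios library-size factors.

    Each sample's factor is the median across always-expressed genes of
    its ratio to the per-gene geometric mean (the estimator robust to a
    minority of truly changing genes, which biases plain total-count
    scaling).  Falls back to total-count scaling when no gene is
    expressed in every sample.
    """
    libs = raw.sum(axis=0)
    if (libs == 0).any():
        raise ParameterError("a sample has zero total counts")
    positive = (raw > 0).all(axis=1)
    if positive.sum() >= 10:
        logref = np.log(raw[positive]).mean(axis=1)
        factors = np.exp(np.median(np.log(raw[positive]) - logref[:, None], axis=0))
    else:
        factors = libs / libs.mean()
    return factors / factors.mean()


def _common_dispersion(norm: np.ndarray, group_a: np.ndarray, group_b: np.ndarray) -> float:
    """Across-gene mean of per-gene within-group method-of-moments
    dispersion estimates, alpha = (var - mean) / mean^2."""
    ests = []
    for cols in (group_a, group_b):
        block = norm[:, cols]
        if block.shape[1] < 2:
            continue
        m = block.mean(axis=1)
        v = block.var(axis=1, ddof=1)
        ok = m > 0
        ests.append((v[ok] - m[ok]) / m[ok] ** 2)
    if not ests:
        return DISPERSION_FLOOR
    pooled = np.concatenate(ests)
    if pooled.size == 0:
        return DISPERSION_FLOOR
    return max(float(pooled.mean()), DISPERSION_FLOOR)


def _exact_test(sa: int, sb: int, na: int, nb: int, alpha: float) -> float:
    """Two-sided conditional exact p for group sums under a common-mean
    negative-binomial model (minimum-likelihood two-sided rule)."""
    s = sa + sb
    if s == 0:
        return 1.0
    support = np.arange(s + 1)
    if alpha <= DISPERSION_FLOOR * 1.000001:
        # Poisson limit: conditional law is Binomial(s, na / (na + nb)).
        logw = binom.logpmf(support, s, na / (na + nb))
    else:
        mu = s / (na + nb)
        logw = _nb_logpmf(support, na / alpha, na * mu) + _nb_logpmf(
            support[::-1], nb / alpha, nb * mu
        )
    logw -= logsumexp(logw)
    obs = logw[sa]
    p = float(np.exp(logsumexp(logw[logw <= obs + 1e-8])))
    return min(max(p, np.finfo(float).tiny), 1.0)


def count_test(
    counts: pd.DataFrame,
    groups: Mapping[str, str] | pd.Series,
    reference: str | None = None,
) -> pd.DataFrame:
    """Per-gene log2 fold change and exact-test p from a count matrix.

    Parameters
    ----------
    counts:
        Genes x samples matrix of non-negative integer counts.
    groups:
        Sample -> group label, exactly two levels, >= 2 samples each.
    reference:
        The control level; defaults to ``"control"`` when present,
        else the alphabetically first level.

    Returns a DataFrame ``gene, log2fc, pvalue`` where ``log2fc`` is the
    treated/control ratio of library-size-normalized group means with a
    0.5 pseudocount, and ``pvalue`` comes from the conditional
    negative-binomial exact test with a common method-of-moments
    dispersion (floored at 1e-12).
    """
    groups = pd.Series(dict(groups) if not isinstance(groups, pd.Series) else groups)
    groups = groups.reindex(counts.columns)
    if groups.isna().any():
        raise ParameterError("every sample column needs a group label")
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise ParameterError(f"need exactly two group levels, got {levels}")
    if reference is None:
        reference = "control" if "control" in levels else levels[0]
    if reference not in levels:
        raise ParameterError(f"reference level {reference!r} not among {levels}")
    treated = next(l for l in levels if l != reference)
    mask_a = (groups == reference).to_numpy()
    mask_b = (groups == treated).to_numpy()
    if mask_a.sum() < 2 or mask_b.sum() < 2:
        raise ParameterError("each group needs at least two samples")

    raw = counts.to_numpy(dtype=float)
    if raw.size == 0:
        raise ParameterError("empty count matrix")
    if (raw < 0).any() or not np.allclose(raw, np.round(raw)):
        raise ParseError("counts must be non-negative integers")

    norm = raw / _size_factors(raw)

    mean_a = norm[:, mask_a].mean(axis=1)
    mean_b = norm[:, mask_b].mean(axis=1)
    log2fc = np.log2((mean_b + PSEUDOCOUNT) / (mean_a + PSEUDOCOUNT))
    log2fc[(mean_a == 0) & (mean_b == 0)] = 0.0

    alpha = _common_dispersion(norm, np.flatnonzero(mask_a), np.flatnonzero(mask_b))
    rounded = np.round(norm).astype(np.int64)
    na, nb = int(mask_a.sum()), int(mask_b.sum())
    pvals = np.ones(raw.shape[0])
    for i in range(raw.shape[0]):
        sa = int(rounded[i, mask_a].sum())
        sb = int(rounded[i, mask_b].sum())
        pvals[i] = _exact_test(sa, sb, na, nb, alpha)

    return pd.DataFrame(
        {"gene": counts.index.astype(str), "log2fc": log2fc, "pvalue": pvals}
    )
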