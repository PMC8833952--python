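"""Four-group Kruskal-Wallis differential analysis with BH correction and
six-trend classification of significant isoforms.

Group order everywhere is (W_N, W_T, BAA_N, BAA_T).
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .quantify import CountMatrix, GROUPS, cpm, geometric_mean, tmm_factors

__all__ = [
    "TREND_LABELS",
    "kruskal_wallis",
    "bh_adjust",
    "classify_trend",
    "differential_isomirs",
]

TREND_LABELS = (
    "MONOTONIC_INC",
    "MONOTONIC_DEC",
    "UP_BOTH",
    "DOWN_BOTH",
    "UP_W_DOWN_BAA",
    "DOWN_W_UP_BAA",
    "UNCLASSIFIED",
)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Kruskal-Wallis H (mid-ranks, tie-corrected) and chi-square p-value.

    All observations identical is a defined degenerate case: (0, 1).
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if sum(len(a) > 0 for a in arrays) < 2:
        raise ValueError("need at least two non-empty groups")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*[a for a in arrays if len(a)])
    return float(h), float(p)


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def classify_trend(g: Sequence[float]) -> str:
    """Six-trend label from the four group geometric means, evaluated in
    precedence order (monotonic first); any within-race equality that blocks
    every rule yields UNCLASSIFIED."""
    wn, wt, bn, bt = (float(x) for x in g)
    if any(x < 0 for x in (wn, wt, bn, bt)):
        raise ValueError("geometric means must be >= 0")
    if wn < wt < bn < bt:
        return "MONOTONIC_INC"
    if wn > wt > bn > bt:
        return "MONOTONIC_DEC"
    if wt > wn and bt > bn:
        return "UP_BOTH"
    if wt < wn and bt < bn:
        return "DOWN_BOTH"
    if wt > wn and bt < bn:
        return "UP_W_DOWN_BAA"
    if wt < wn and bt > bn:
        return "DOWN_W_UP_BAA"
    return "UNCLASSIFIED"


def differential_isomirs(
    m: CountMatrix,
    design: Mapping[str, str],
    alpha: float = 0.05,
    normalize: bool = True,
) -> pd.DataFrame:
    """Per-row Kruskal-Wallis across the four groups on TMM-scaled CPM,
    BH-adjusted; rows with fdr < alpha get a trend label.

    Returns a DataFrame (isomir, g_WN, g_WT, g_BN, g_BT, H, p, fdr, trend)
    sorted by fdr. `normalize=True` computes joint TMM factors across all
    samples before taking CPM.
    """
    cols_by_group = {g: [s for s in m.col_ids if design.get(s) == g] for g in GROUPS}
    for g, cols in cols_by_group.items():
        if not cols:
            raise ValueError(f"empty group {g}")
        if len(cols) < 2:
            warnings.warn(f"group {g} has < 2 samples; KW power is minimal")

    work = CountMatrix(m.counts.copy())
    if normalize:
        work.norm_factors = tmm_factors(work)
    expr = cpm(work)

    blocks = [expr[cols_by_group[g]].values for g in GROUPS]
    rows = []
    for i, isomir in enumerate(work.row_ids):
        per_group = [b[i] for b in blocks]
        h, p = kruskal_wallis(per_group)
        gms = [geometric_mean(v) for v in per_group]
        rows.append((isomir, *gms, h, p))

    out = pd.DataFrame(
        rows, columns=["isomir", "g_WN", "g_WT", "g_BN", "g_BT", "H", "p"]
    )
    out["fdr"] = bh_adjust(out["p"].values)
    out["trend"] = [
        classify_trend(r[["g_WN", "g_WT", "g_BN", "g_BT"]])
        if r["fdr"] < alpha
        else ""
        for _, r in out.iterrows()
    ]
    return out.sort_values("fdr", kind="mergesort").reset_index(drop=True)
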