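"""Count matrices, RPM geometric-mean expression filtering, and TMM
normalization factors computed from scratch."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "compute_rpm",
    "geometric_mean",
    "expression_filter",
    "tmm_factors",
    "group_expressed_sets",
    "cpm",
    "log_cpm",
]

GROUPS = ("W_N", "W_T", "BAA_N", "BAA_T")


@dataclass
class CountMatrix:
    """Non-negative integer counts, rows = features, columns = samples."""

    counts: pd.DataFrame
    norm_factors: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")
        if self.norm_factors is None:
            self.norm_factors = pd.Series(1.0, index=self.counts.columns)
        self.norm_factors = self.norm_factors.reindex(self.counts.columns)

    @property
    def row_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def col_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def lib_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @property
    def effective_lib_sizes(self) -> pd.Series:
        return self.lib_sizes * self.norm_factors

    def subset(self, rows=None, cols=None) -> "CountMatrix":
        df = self.counts
        if rows is not None:
            df = df.loc[list(rows)]
        if cols is not None:
            df = df[list(cols)]
        return CountMatrix(df.copy())

    def to_tsv(self, path: str | Path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="feature")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df)


def compute_rpm(m: CountMatrix) -> pd.DataFrame:
    """counts / library size * 1e6, per column."""
    lib = m.lib_sizes
    zero = lib[lib == 0]
    if len(zero):
        raise ValueError(f"zero library size for sample(s): {list(zero.index)}")
    return m.counts / lib * 1e6


def geometric_mean(values: Sequence[float] | np.ndarray) -> float:
    """Plain geometric mean; any zero (or negative) entry annihilates to 0."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("geometric mean of empty vector")
    if (x <= 0).any():
        return 0.0
    return float(np.exp(np.mean(np.log(x))))


def expression_filter(
    m: CountMatrix, scope: Sequence[str] | None = None
) -> list[str]:
    """Rows with floor(geometric mean of RPM over `scope`) > 1.

    The geometric mean uses no pseudocount, so a zero in any scoped sample
    drops the row.
    """
    cols = list(scope) if scope is not None else m.col_ids
    if not cols:
        raise ValueError("empty scope")
    rpm = compute_rpm(m)[cols].values
    pos = (rpm > 0).all(axis=1)
    gm = np.zeros(rpm.shape[0])
    with np.errstate(divide="ignore"):
        gm[pos] = np.exp(np.mean(np.log(rpm[pos]), axis=1))
    kept = np.floor(gm) > 1
    return [r for r, k in zip(m.row_ids, kept) if k]


# ---------------------------------------------------------------------------
# TMM


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float,
    n_ref: float,
    trim_M: float,
    trim_A: float,
) -> float:
    """Two-sample TMM factor (log2) of `obs` against reference `ref`."""
    both = (obs > 0) & (ref > 0)
    o, r = obs[both].astype(float), ref[both].astype(float)
    if o.size == 0:
        return 0.0
    po, pr = o / n_obs, r / n_ref
    M = np.log2(po / pr)
    A = 0.5 * np.log2(po * pr)
    # delta-method approximate variance of M; precision weights are 1/v
    v = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)

    if np.max(np.abs(M)) < 1e-6:
        return 0.0

    n = M.size
    lo_m = np.floor(n * trim_M) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_A) + 1
    hi_a = n + 1 - lo_a
    from scipy.stats import rankdata

    rm, ra = rankdata(M), rankdata(A)
    keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not keep.any() or np.sum(1.0 / v[keep]) == 0:
        return 0.0
    f = float(np.sum(M[keep] / v[keep]) / np.sum(1.0 / v[keep]))
    return 0.0 if not np.isfinite(f) else f


def tmm_factors(
    m: CountMatrix, trim_M: float = 0.30, trim_A: float = 0.05
) -> pd.Series:
    """Trimmed-mean-of-M-values normalization factors.

    Reference column: the one whose upper quartile of scaled counts is
    closest to the mean upper quartile. Per column, M/A statistics over rows
    positive in both columns are doubly trimmed (`trim_M` on M, `trim_A` on
    A) and combined with precision (inverse approximate variance) weights;
    factors are rescaled to geometric mean 1.
    """
    counts = m.counts.values.astype(float)
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least 2 columns")
    lib = counts.sum(axis=0)
    if (lib == 0).any():
        raise ValueError("zero library size")

    uq = np.quantile(counts / lib, 0.75, axis=0)
    ref_idx = int(np.argmin(np.abs(uq - uq.mean())))

    logf = np.zeros(counts.shape[1])
    for j in range(counts.shape[1]):
        n_pos = int((counts[:, j] > 0).sum())
        if n_pos <= 1:
            warnings.warn(
                f"degenerate column {m.col_ids[j]!r} ({n_pos} positive rows); "
                "factor set to 1"
            )
            logf[j] = 0.0
            continue
        logf[j] = _tmm_pair(
            counts[:, j], counts[:, ref_idx], lib[j], lib[ref_idx], trim_M, trim_A
        )
    logf -= logf.mean()  # geometric mean of factors == 1
    return pd.Series(2.0 ** logf, index=m.col_ids)


def cpm(m: CountMatrix, use_norm_factors: bool = True) -> pd.DataFrame:
    """Counts per million on effective (TMM-scaled) library sizes."""
    lib = m.effective_lib_sizes if use_norm_factors else m.lib_sizes
    return m.counts / lib * 1e6


def log_cpm(m: CountMatrix, pseudocount: float = 1.0) -> pd.DataFrame:
    return np.log2(cpm(m) + pseudocount)


def group_expressed_sets(
    m: CountMatrix, design: Mapping[str, str]
) -> dict[str, object]:
    """Per-group expressed row sets, their common core and exclusive sets.

    The expression filter runs independently per group (on that group's
    samples only); TMM factors are also computed per group and attached so
    downstream per-group summaries use within-group normalization.
    """
    missing = set(m.col_ids) - set(design)
    if missing:
        raise ValueError(f"design does not cover samples: {sorted(missing)}")
    by_group: dict[str, list[str]] = {}
    for s in m.col_ids:
        by_group.setdefault(design[s], []).append(s)
    for g, cols in by_group.items():
        if not cols:
            raise ValueError(f"empty group {g}")

    sets = {g: set(expression_filter(m, scope=cols)) for g, cols in by_group.items()}
    core = set.intersection(*sets.values()) if sets else set()
    exclusive = {
        g: sets[g] - set.union(*(sets[h] for h in sets if h != g))
        for g in sets
        if len(sets) > 1
    }
    return {"per_group": sets, "core": core, "exclusive": exclusive}
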