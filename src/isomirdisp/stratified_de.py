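"""Quartile stratification by one isomiR's expression, Q1-vs-Q3 gene-level
differential expression with a negative-binomial exact test, expression
correlation, and hypergeometric over-representation analysis."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln, logsumexp

from .cohort_stats import bh_adjust
from .quantify import CountMatrix, tmm_factors

__all__ = [
    "QuartileSplit",
    "quartile_groups",
    "filter_genes_fpkm",
    "nb_exact_test",
    "estimate_dispersion",
    "differential_genes",
    "correlate_expression",
    "ora_enrichment",
]

DE_P_THRESHOLD = 0.01
DE_FC_THRESHOLD = 1.5


@dataclass(frozen=True)
class QuartileSplit:
    target: str
    q1_samples: frozenset[str]
    q3_samples: frozenset[str]
    q1_cut: float
    q3_cut: float


def quartile_groups(expr: Mapping[str, float] | pd.Series, target: str = "") -> QuartileSplit:
    """Split samples at the first/third quartile of `expr` (linear
    interpolation quantiles); Q1 membership is value <= Q1 cut, Q3 is
    value >= Q3 cut."""
    s = pd.Series(expr, dtype=float)
    if len(s) < 8:
        raise ValueError("need at least 8 samples for a quartile split")
    values = s.values
    if np.all(values == values[0]):
        raise ValueError("all expression values identical; split undefined")
    q1 = float(np.quantile(values, 0.25))
    q3 = float(np.quantile(values, 0.75))
    if q1 == q3:
        raise ValueError("degenerate quartiles (Q1 == Q3); split undefined")
    return QuartileSplit(
        target=target,
        q1_samples=frozenset(s.index[values <= q1]),
        q3_samples=frozenset(s.index[values >= q3]),
        q1_cut=q1,
        q3_cut=q3,
    )


def filter_genes_fpkm(fpkm: pd.DataFrame, scope: Sequence[str] | None = None) -> list[str]:
    """Genes with floor(geometric mean FPKM) > 1 over `scope`.

    Same contract as the RPM expression filter: no pseudocount, zeros
    annihilate the geometric mean.
    """
    cols = list(scope) if scope is not None else list(fpkm.columns)
    if not cols:
        raise ValueError("empty scope")
    x = fpkm[cols].values.astype(float)
    pos = (x > 0).all(axis=1)
    gm = np.zeros(x.shape[0])
    gm[pos] = np.exp(np.mean(np.log(x[pos]), axis=1))
    return [g for g, k in zip(fpkm.index, np.floor(gm) > 1) if k]


# ---------------------------------------------------------------------------
# NB exact test


def estimate_dispersion(counts_g1: np.ndarray, counts_g2: np.ndarray) -> float:
    """Method-of-moments NB dispersion pooled over the two groups:
    phi = (var - mean) / mean^2, averaged and clipped at 0."""
    phis = []
    for c in (np.asarray(counts_g1, float), np.asarray(counts_g2, float)):
        if c.size < 2:
            continue
        m, v = c.mean(), c.var(ddof=1)
        if m > 0:
            phis.append((v - m) / m**2)
    if not phis:
        return 0.0
    return float(max(0.0, np.mean(phis)))


def _log_nb_pmf(k: np.ndarray, r: float) -> np.ndarray:
    # log NB(size r) pmf up to terms that cancel in the conditional
    return gammaln(k + r) - gammaln(k + 1) - gammaln(r)


def nb_exact_test(
    counts_g1: Sequence[int],
    counts_g2: Sequence[int],
    dispersion: float | None = None,
) -> float:
    """Two-sided exact test of equal means, conditional on the pooled sum,
    under NB with a common dispersion.

    Group sums S1 ~ NB(n1/phi), S2 ~ NB(n2/phi); conditional on S1+S2=s the
    success probability cancels and P(S1=a|s) ∝ f1(a) f2(s-a). The p-value
    sums the probabilities of all outcomes no more likely than the observed
    one. Dispersion 0 degenerates to the exact binomial test.
    """
    c1 = np.asarray(counts_g1, dtype=float)
    c2 = np.asarray(counts_g2, dtype=float)
    if (c1 < 0).any() or (c2 < 0).any():
        raise ValueError("counts must be non-negative")
    if dispersion is None:
        dispersion = estimate_dispersion(c1, c2)
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")

    s1, s2 = float(c1.sum()), float(c2.sum())
    s = int(round(s1 + s2))
    if s == 0:
        return 1.0
    n1, n2 = len(c1), len(c2)
    a = np.arange(s + 1, dtype=float)

    if dispersion == 0.0:
        # Poisson limit: conditional is Binomial(s, n1/(n1+n2))
        logp = stats.binom.logpmf(a, s, n1 / (n1 + n2))
    else:
        r1, r2 = n1 / dispersion, n2 / dispersion
        logp = _log_nb_pmf(a, r1) + _log_nb_pmf(s - a, r2)
        logp -= logsumexp(logp)

    obs = int(round(s1))
    p_obs = logp[obs]
    # small relative tolerance guards against FP noise on the equality edge
    mask = logp <= p_obs + 1e-7
    return float(min(1.0, np.exp(logsumexp(logp[mask]))))


def differential_genes(
    gene_counts: CountMatrix,
    split: QuartileSplit,
    dispersion: float | None = None,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Q1-vs-Q3 gene table: log2FC, signed linear FC, exact-test p, and the
    significance flag (p < 0.01 and |linear FC| > 1.5).

    Counts are TMM-normalized within the Q1 ∪ Q3 subset and scaled to a
    common library size before the exact test (which conditions on equal
    sizes); fold changes use normalized means with a pseudocount. FC
    direction is Q3 relative to Q1.
    """
    q1 = sorted(split.q1_samples)
    q3 = sorted(split.q3_samples)
    if not q1 or not q3:
        raise ValueError("empty Q1 or Q3 group")

    sub = gene_counts.subset(cols=q1 + q3)
    sub.norm_factors = tmm_factors(sub)
    eff = sub.effective_lib_sizes
    common = float(np.exp(np.mean(np.log(eff))))
    scaled = sub.counts / eff * common  # pseudo-counts at a common depth

    rows = []
    for gene in sub.row_ids:
        x1 = scaled.loc[gene, q1].values
        x3 = scaled.loc[gene, q3].values
        phi = dispersion if dispersion is not None else estimate_dispersion(x1, x3)
        p = nb_exact_test(np.round(x1).astype(int), np.round(x3).astype(int), phi)
        m1, m3 = x1.mean(), x3.mean()
        log2fc = float(np.log2((m3 + pseudocount) / (m1 + pseudocount)))
        ratio = 2.0 ** log2fc
        linear = ratio if ratio >= 1 else -1.0 / ratio
        rows.append((gene, log2fc, linear, p))

    out = pd.DataFrame(rows, columns=["gene", "log2FC", "linearFC", "p"])
    out["significant"] = (out["p"] < DE_P_THRESHOLD) & (
        out["linearFC"].abs() > DE_FC_THRESHOLD
    )
    return out


def correlate_expression(
    x: Sequence[float], y: Sequence[float], method: str = "pearson"
) -> tuple[float, float]:
    """Correlation coefficient and two-sided p for paired expression."""
    xa, ya = np.asarray(x, float), np.asarray(y, float)
    if xa.size != ya.size or xa.size < 3:
        raise ValueError("need >= 3 paired samples")
    if np.var(xa) == 0 or np.var(ya) == 0:
        raise ValueError("zero variance in one of the vectors")
    if method == "pearson":
        r, p = stats.pearsonr(xa, ya)
    elif method == "spearman":
        r, p = stats.spearmanr(xa, ya)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(p)


def ora_enrichment(
    de_genes: set[str],
    universe: set[str],
    gene_sets: Mapping[str, set[str]],
) -> pd.DataFrame:
    """Hypergeometric upper-tail over-representation per gene set, BH across
    sets. Gene sets are intersected with the universe first."""
    if not universe:
        raise ValueError("empty universe")
    if not de_genes <= universe:
        raise ValueError("de_genes must be a subset of the universe")
    M, n = len(universe), len(de_genes)
    rows = []
    for name, members in gene_sets.items():
        k_set = members & universe
        overlap = len(de_genes & k_set)
        # P(X >= overlap), X ~ Hypergeom(M, |set|, n)
        p = float(stats.hypergeom.sf(overlap - 1, M, len(k_set), n))
        rows.append((name, overlap, len(k_set), min(1.0, p)))
    out = pd.DataFrame(rows, columns=["gene_set", "overlap", "set_size", "p"])
    out["fdr"] = bh_adjust(out["p"].values) if len(out) else []
    return out
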