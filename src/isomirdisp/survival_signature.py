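"""Two-stage prognostic signature search.

Stage 1: cohort eligibility (>= 10 patients per event status) and assembly
of normalized expression with right-censored survival records.

Stage 2, swept over correlation thresholds 0.60..0.80: greedy correlation
pruning -> univariate Cox (BH-FDR < 0.05) -> multivariate Cox (p < 0.05)
-> recursive feature elimination over candidate signature sizes -> risk
score = sum_i exp_i * beta_i with the *univariate* coefficients -> median
split -> Kaplan-Meier / log-rank / ROC-AUC. The signature with the highest
AUC wins (ties: fewer features, then smaller threshold).

The Cox partial likelihood uses Efron tie handling and is maximized by
Newton-Raphson with step-halving.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_stats import bh_adjust

__all__ = [
    "SurvivalRecord",
    "CoxResult",
    "Signature",
    "NOT_TESTABLE",
    "check_eligibility",
    "correlation_prune",
    "cox_fit",
    "rfe_select",
    "risk_scores",
    "km_curve",
    "km_logrank",
    "roc_auc",
    "signature_search",
    "cross_apply",
]

NOT_TESTABLE = "NOT_TESTABLE"

MIN_EVENTS_PER_TYPE = 10
UNIVARIATE_FDR = 0.05
MULTIVARIATE_P = 0.05
DEFAULT_THRESHOLDS = tuple(np.round(np.arange(0.60, 0.801, 0.01), 2))
DEFAULT_SIZES = tuple(range(3, 16))


@dataclass(frozen=True)
class SurvivalRecord:
    sample_id: str
    time: float
    event: int

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError(f"{self.sample_id}: negative survival time")
        if self.event not in (0, 1):
            raise ValueError(f"{self.sample_id}: event must be 0/1")


def _records_frame(records: Sequence[SurvivalRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "time": [r.time for r in records],
            "event": [r.event for r in records],
        },
        index=[r.sample_id for r in records],
    )


def check_eligibility(records: Sequence[SurvivalRecord]) -> bool:
    """At least MIN_EVENTS_PER_TYPE patients with and without the event."""
    n1 = sum(r.event == 1 for r in records)
    n0 = sum(r.event == 0 for r in records)
    return n1 >= MIN_EVENTS_PER_TYPE and n0 >= MIN_EVENTS_PER_TYPE


def correlation_prune(expr: pd.DataFrame, threshold: float) -> list[str]:
    """Greedy removal of highly correlated features.

    While any pair of remaining features has |Pearson r| >= threshold, the
    feature with the largest mean |r| (over remaining features) among those
    involved in an offending pair is removed; ties break to removing the
    lexicographically larger name. `expr` is samples x features.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must lie in (0, 1]")
    feats = list(expr.columns)
    if len(feats) < 2:
        return feats
    corr = expr.corr().abs().values
    np.fill_diagonal(corr, 0.0)
    corr = np.nan_to_num(corr)
    alive = np.ones(len(feats), dtype=bool)

    while True:
        sub = corr[np.ix_(alive, alive)]
        if sub.size == 0 or (sub < threshold).all():
            break
        idx_alive = np.flatnonzero(alive)
        offending = np.flatnonzero((sub >= threshold).any(axis=1))
        mean_r = sub.sum(axis=1) / max(1, sub.shape[1] - 1)
        # remove the offending feature with max mean |r|; tie -> larger name
        best = max(offending, key=lambda i: (mean_r[i], feats[idx_alive[i]]))
        alive[idx_alive[best]] = False
    return [f for f, a in zip(feats, alive) if a]


# ---------------------------------------------------------------------------
# Cox partial likelihood (Efron ties), Newton-Raphson


def _cox_loglik(beta: np.ndarray, X: np.ndarray, time: np.ndarray, event: np.ndarray):
    """Efron partial log-likelihood with gradient and information matrix."""
    n, p = X.shape
    order = np.argsort(-time, kind="mergesort")  # descending time
    Xs, ts, es = X[order], time[order], event[order]
    eta = Xs @ beta
    eta -= eta.max()  # guard overflow; partial likelihood is shift-invariant
    w = np.exp(eta)

    ll = 0.0
    grad = np.zeros(p)
    info = np.zeros((p, p))

    # cumulative risk-set sums in descending-time order
    S0 = np.cumsum(w)
    S1 = np.cumsum(w[:, None] * Xs, axis=0)
    S2 = np.cumsum(w[:, None, None] * (Xs[:, :, None] * Xs[:, None, :]), axis=0)

    i = n - 1
    while i >= 0:
        t = ts[i]
        j = i
        while j >= 0 and ts[j] == t:
            j -= 1
        # block j+1 .. i shares this time; risk set = 0 .. i
        D = [k for k in range(j + 1, i + 1) if es[k] == 1]
        if D:
            d = len(D)
            wD = w[D]
            xD = Xs[D]
            s0r, s1r, s2r = S0[i], S1[i], S2[i]
            s0d = wD.sum()
            s1d = (wD[:, None] * xD).sum(axis=0)
            s2d = (wD[:, None, None] * (xD[:, :, None] * xD[:, None, :])).sum(axis=0)
            ll += eta[D].sum()
            grad += xD.sum(axis=0)
            for l in range(d):
                f = l / d
                phi0 = s0r - f * s0d
                phi1 = s1r - f * s1d
                phi2 = s2r - f * s2d
                ll -= np.log(phi0)
                u = phi1 / phi0
                grad -= u
                info += phi2 / phi0 - np.outer(u, u)
        i = j
    return ll, grad, info


@dataclass
class CoxResult:
    """Per-feature Cox summary: beta, se, Wald p (and BH fdr in univariate
    mode), plus convergence diagnostics."""

    table: pd.DataFrame
    mode: str
    converged: bool = True
    max_grad: float = np.nan
    loglik: float = np.nan


# |log HR| beyond this on (normalized) expression covariates indicates a
# monotone likelihood / perfect separation; the fit is flagged not-converged
_MONOTONE_BETA = 10.0


def _newton_cox(
    X: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 50,
):
    p = X.shape[1]
    beta = np.zeros(p)
    ll, grad, info = _cox_loglik(beta, X, time, event)
    for _ in range(max_iter):
        if np.max(np.abs(grad)) < tol:
            break
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            return beta, np.full(p, np.nan), ll, np.max(np.abs(grad)), False
        # step-halving; the acceptance slack is relative to |ll| because
        # near the optimum the "decrease" is pure floating-point noise
        slack = 1e-10 * (abs(ll) + 1.0)
        for _half in range(30):
            cand = beta + step
            ll_new, grad_new, info_new = _cox_loglik(cand, X, time, event)
            if np.isfinite(ll_new) and ll_new >= ll - slack:
                break
            step = step / 2.0
        beta, ll, grad, info = cand, ll_new, grad_new, info_new
        if np.max(np.abs(beta)) > _MONOTONE_BETA:
            return beta, np.full(p, np.nan), ll, np.max(np.abs(grad)), False
    converged = np.max(np.abs(grad)) < 1e-6
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
        converged = False
    return beta, se, ll, float(np.max(np.abs(grad))), converged


def cox_fit(
    expr: pd.DataFrame,
    records: Sequence[SurvivalRecord],
    mode: str = "univariate-each",
) -> CoxResult:
    """Cox proportional-hazards fit(s) on `expr` (samples x features).

    mode='univariate-each': each feature fit alone; p-values BH-adjusted
    across features. mode='multivariate': one joint fit. Non-converged /
    monotone-likelihood features are flagged (converged=False) and should be
    excluded downstream; constant features raise.
    """
    rec = _records_frame(records)
    common = [s for s in rec.index if s in expr.index]
    if len(common) != len(rec):
        missing = set(rec.index) - set(expr.index)
        raise ValueError(f"records without expression: {sorted(missing)}")
    X_all = expr.loc[rec.index]
    if (X_all.nunique() <= 1).any():
        const = list(X_all.columns[X_all.nunique() <= 1])
        raise ValueError(f"constant feature(s): {const}")
    time = rec["time"].values.astype(float)
    event = rec["event"].values.astype(int)

    rows = []
    if mode == "univariate-each":
        overall_converged = True
        max_grad = 0.0
        for f in X_all.columns:
            b, se, ll, g, conv = _newton_cox(X_all[[f]].values, time, event)
            if not conv:
                warnings.warn(f"Cox fit for feature {f!r} did not converge; flagged")
                overall_converged = False
            z = b[0] / se[0] if se[0] > 0 else np.nan
            rows.append(
                (f, b[0], se[0], 2 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan, conv)
            )
            max_grad = max(max_grad, g)
        tab = pd.DataFrame(
            rows, columns=["feature", "beta", "se", "p", "converged"]
        ).set_index("feature")
        ok = tab["converged"] & tab["p"].notna()
        tab["fdr"] = np.nan
        if ok.any():
            tab.loc[ok, "fdr"] = bh_adjust(tab.loc[ok, "p"].values)
        return CoxResult(table=tab, mode=mode, converged=overall_converged, max_grad=max_grad)

    if mode != "multivariate":
        raise ValueError(f"unknown mode {mode!r}")
    b, se, ll, g, conv = _newton_cox(X_all.values, time, event)
    if not conv:
        warnings.warn("multivariate Cox fit did not converge")
    z = np.divide(b, se, out=np.full_like(b, np.nan), where=se > 0)
    tab = pd.DataFrame(
        {
            "beta": b,
            "se": se,
            "p": 2 * stats.norm.sf(np.abs(z)),
            "converged": conv,
        },
        index=X_all.columns,
    )
    tab["fdr"] = np.nan
    return CoxResult(table=tab, mode=mode, converged=conv, max_grad=g, loglik=ll)


# ---------------------------------------------------------------------------
# RFE, scoring, KM / log-rank / AUC


def rfe_select(
    expr: pd.DataFrame,
    labels: Sequence[int],
    target_sizes: Sequence[int],
) -> dict[int, list[str]]:
    """Recursive feature elimination with an L2 logistic-regression
    estimator on standardized features; returns the retained feature list
    per requested size (sizes above the feature count are capped)."""
    from sklearn.feature_selection import RFE
    from sklearn.linear_model import LogisticRegression

    feats = list(expr.columns)
    y = np.asarray(labels, dtype=int)
    X = expr.values.astype(float)
    X = (X - X.mean(axis=0)) / np.where(X.std(axis=0) == 0, 1.0, X.std(axis=0))

    out: dict[int, list[str]] = {}
    if len(feats) == 1:
        return {s: list(feats) for s in target_sizes}
    est = LogisticRegression(C=1.0, solver="lbfgs", max_iter=1000)  # L2 default
    ranking = RFE(est, n_features_to_select=1, step=1).fit(X, y).ranking_
    # ranking 1 = last survivor; subset of size k = k smallest ranks
    order = np.argsort(ranking, kind="mergesort")
    for size in target_sizes:
        k = min(size, len(feats))
        if size > len(feats):
            warnings.warn(f"target size {size} > {len(feats)} features; capped")
        out[size] = sorted(feats[i] for i in order[:k])
    return out


def risk_scores(expr: pd.DataFrame, betas: Mapping[str, float]) -> pd.Series:
    """Risk score per patient: sum_i expression_i * beta_i."""
    missing = [f for f in betas if f not in expr.columns]
    if missing:
        raise ValueError(f"features missing from expression matrix: {missing}")
    feats = sorted(betas)
    b = np.array([betas[f] for f in feats], dtype=float)
    return pd.Series(expr[feats].values @ b, index=expr.index)


def km_curve(times: np.ndarray, events: np.ndarray) -> pd.DataFrame:
    """Product-limit survival estimate at each distinct event time."""
    order = np.argsort(times, kind="mergesort")
    t, e = np.asarray(times, float)[order], np.asarray(events, int)[order]
    rows = []
    s = 1.0
    n = len(t)
    for ut in np.unique(t[e == 1]):
        at_risk = int((t >= ut).sum())
        d = int(((t == ut) & (e == 1)).sum())
        s *= 1.0 - d / at_risk
        rows.append((float(ut), at_risk, d, s))
    return pd.DataFrame(rows, columns=["time", "n_at_risk", "n_events", "survival"])


def km_logrank(
    records: Sequence[SurvivalRecord],
    assignment: Mapping[str, str],
) -> tuple[dict[str, pd.DataFrame], float, float]:
    """Kaplan-Meier curves per group plus the two-group log-rank test.

    `assignment` maps sample id -> 'high' | 'low'. Returns (curves, chi2, p).
    """
    rec = _records_frame(records)
    groups = sorted(set(assignment.values()))
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {groups}")
    g = np.array([assignment[s] for s in rec.index])
    t = rec["time"].values.astype(float)
    e = rec["event"].values.astype(int)

    curves = {
        name: km_curve(t[g == name], e[g == name]) for name in groups
    }
    for name in groups:
        if e[g == name].sum() == 0:
            warnings.warn(f"group {name!r} has zero events")

    is1 = g == groups[0]
    O1 = E1 = V = 0.0
    for ut in np.unique(t[e == 1]):
        at = t >= ut
        n_all = at.sum()
        n1 = (at & is1).sum()
        d_all = ((t == ut) & (e == 1)).sum()
        d1 = ((t == ut) & (e == 1) & is1).sum()
        O1 += d1
        E1 += d_all * n1 / n_all
        if n_all > 1:
            V += d_all * (n1 / n_all) * (1 - n1 / n_all) * (n_all - d_all) / (n_all - 1)
    if V == 0:
        return curves, 0.0, 1.0
    chi2 = (O1 - E1) ** 2 / V
    return curves, float(chi2), float(stats.chi2.sf(chi2, 1))


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Probability a random positive outscores a random negative, ties 1/2
    (mid-rank formula)."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both label classes must be present")
    r = stats.rankdata(s)
    return float((r[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


# ---------------------------------------------------------------------------
# the two-stage search


@dataclass
class Signature:
    event_type: str
    group: str
    features: list[str]
    betas: dict[str, float]  # univariate Cox coefficients
    corr_threshold: float
    risk_scores: pd.Series = field(repr=False)
    cutoff: float = np.nan
    logrank_p: float = np.nan
    auc: float = np.nan

    def to_json(self, path=None) -> str:
        payload = {
            "event_type": self.event_type,
            "group": self.group,
            "features": self.features,
            "betas": self.betas,
            "corr_threshold": self.corr_threshold,
            "cutoff": self.cutoff,
            "logrank_p": self.logrank_p,
            "auc": self.auc,
            "risk_scores": {k: float(v) for k, v in self.risk_scores.items()},
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def median_split(scores: pd.Series) -> tuple[dict[str, str], float]:
    """score <= median -> 'low', else 'high'."""
    cutoff = float(scores.median())
    return (
        {s: ("low" if v <= cutoff else "high") for s, v in scores.items()},
        cutoff,
    )


def _evaluate_subset(
    feats: list[str],
    uni_betas: Mapping[str, float],
    expr: pd.DataFrame,
    records: Sequence[SurvivalRecord],
) -> tuple[pd.Series, float, float, float] | None:
    betas = {f: uni_betas[f] for f in feats}
    scores = risk_scores(expr, betas)
    assignment, cutoff = median_split(scores)
    if len(set(assignment.values())) < 2:
        return None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, _, logrank_p = km_logrank(records, assignment)
    events = [r.event for r in records]
    ordered = scores.loc[[r.sample_id for r in records]]
    auc = roc_auc(ordered.values, events)
    return scores, cutoff, logrank_p, auc


def signature_search(
    expr: pd.DataFrame,
    records: Sequence[SurvivalRecord],
    event_type: str = "os",
    group: str = "W",
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    sizes: Sequence[int] = DEFAULT_SIZES,
) -> Signature | None:
    """Run the full threshold-swept two-stage workflow; return the AUC-best
    signature, or None when no threshold yields a surviving feature set.

    `expr` is samples x features of normalized expression; `records` the
    right-censored survival data. Deterministic for fixed inputs.
    """
    if not check_eligibility(records):
        raise ValueError(
            f"cohort ineligible: needs >= {MIN_EVENTS_PER_TYPE} patients per "
            "event status"
        )
    ids = [r.sample_id for r in records]
    expr = expr.loc[ids].reindex(sorted(expr.columns), axis=1)
    events = [r.event for r in records]

    # univariate fits are threshold-independent; fit lazily, once per feature
    uni_cache: dict[str, tuple[float, float, bool]] = {}

    def uni(f: str) -> tuple[float, float, bool]:
        if f not in uni_cache:
            col = expr[[f]]
            if col[f].nunique() <= 1:
                uni_cache[f] = (np.nan, np.nan, False)
            else:
                res = cox_fit(col, records, mode="univariate-each")
                row = res.table.iloc[0]
                uni_cache[f] = (float(row["beta"]), float(row["p"]), bool(row["converged"]))
        return uni_cache[f]

    best: Signature | None = None
    best_key = None
    for thr in thresholds:
        retained = correlation_prune(expr, float(thr))
        stats_rows = [(f, *uni(f)) for f in retained]
        ok = [(f, b, p) for f, b, p, conv in stats_rows if conv and np.isfinite(p)]
        if not ok:
            continue
        fdr = bh_adjust([p for _, _, p in ok])
        uni_keep = [f for (f, _, _), q in zip(ok, fdr) if q < UNIVARIATE_FDR]
        if not uni_keep:
            continue

        if len(uni_keep) == 1:
            multi_keep = uni_keep
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                multi = cox_fit(expr[uni_keep], records, mode="multivariate")
            tab = multi.table
            multi_keep = list(tab.index[(tab["p"] < MULTIVARIATE_P) & tab["converged"]])
        if not multi_keep:
            continue

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            subsets = rfe_select(expr[multi_keep], events, sizes)
        uni_betas = {f: uni(f)[0] for f in multi_keep}
        seen: set[tuple[str, ...]] = set()
        for size in sorted(subsets):
            feats = subsets[size]
            key_f = tuple(feats)
            if key_f in seen:
                continue
            seen.add(key_f)
            evaluated = _evaluate_subset(feats, uni_betas, expr, records)
            if evaluated is None:
                continue
            scores, cutoff, logrank_p, auc = evaluated
            cand_key = (auc, -len(feats), -float(thr))
            if best_key is None or cand_key > best_key:
                best_key = cand_key
                best = Signature(
                    event_type=event_type,
                    group=group,
                    features=list(feats),
                    betas={f: uni_betas[f] for f in feats},
                    corr_threshold=float(thr),
                    risk_scores=scores,
                    cutoff=cutoff,
                    logrank_p=logrank_p,
                    auc=auc,
                )
    return best


def cross_apply(
    sig: Signature,
    expr: pd.DataFrame,
    records: Sequence[SurvivalRecord],
):
    """Apply a trained signature to another cohort.

    Returns (auc, logrank_p), or NOT_TESTABLE when any signature feature is
    absent from the target expression matrix. The median split is recomputed
    within the target cohort; betas are the original univariate ones.
    """
    if any(f not in expr.columns for f in sig.features):
        return NOT_TESTABLE
    ids = [r.sample_id for r in records]
    scores = risk_scores(expr.loc[ids], sig.betas)
    assignment, _ = median_split(scores)
    if len(set(assignment.values())) < 2:
        return NOT_TESTABLE
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, _, logrank_p = km_logrank(records, assignment)
    auc = roc_auc(scores.values, [r.event for r in records])
    return auc, logrank_p
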