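"""Cluster-level PC1 surrogates and stepwise polynomial response-surface models.

Each module of correlated responses is summarized by the first principal
component of its (autoscaled) member columns; that PC1 score is then
regressed on the coded experimental factors and their second-order terms
by forward stepwise selection with partial F-tests (entry and removal at a
reference significance level, 0.05 by default).  Because the outer product
of the PC1 scores with the PC1 loading vector reconstructs the member
columns, a model for the surrogate is simultaneously a model for every
member response.

The partial F statistic for adding (or removing) a single term t to a
model with residual sum of squares RSS_reduced, giving RSS_full on
p_full parameters (intercept included), is

    F = (RSS_reduced - RSS_full) / (RSS_full / (n - p_full)),

which is F(1, n - p_full) distributed under the null that t's coefficient
is zero — identical to the squared t-statistic of that coefficient in the
augmented model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .cluster import _fix_signs
from .preprocess import ResponseMatrix
from .terms import TermSet

__all__ = [
    "ClusterPCAModel",
    "StepwiseModelReport",
    "cluster_pc1",
    "stepwise_fit",
    "reconstruct",
    "summarize",
]


@dataclass
class ClusterPCAModel:
    """PCA of one cluster's member columns, PC1 acting as the surrogate."""

    cluster_id: int
    members: list[str]
    loadings_pc1: np.ndarray
    scores_pc1: np.ndarray
    explained: np.ndarray
    loadings_full: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    @property
    def cum_explained(self) -> np.ndarray:
        return np.cumsum(self.explained)


def cluster_pc1(
    X: ResponseMatrix, members: list[str], cluster_id: int = 0
) -> ClusterPCAModel:
    """PC1 surrogate of a cluster: loadings, per-run scores, explained %.

    A single-member cluster degenerates to loading (1,) and scores equal
    to the member's autoscaled column, explaining 100% of its variance.
    The PC1 sign is pinned so the largest-|loading| member loads
    positively.
    """
    if not members:
        raise ValueError("cluster must have at least one member")
    missing = [mname for mname in members if mname not in X.names]
    if missing:
        raise KeyError(f"members not in response matrix: {missing}")
    if not X.is_scaled:
        raise ValueError("cluster_pc1 requires an autoscaled ResponseMatrix")

    sub = X.data[members].to_numpy()
    if len(members) == 1:
        return ClusterPCAModel(
            cluster_id=cluster_id,
            members=list(members),
            loadings_pc1=np.array([1.0]),
            scores_pc1=sub[:, 0].copy(),
            explained=np.array([100.0]),
            loadings_full=np.array([[1.0]]),
        )
    corr = np.corrcoef(sub, rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = _fix_signs(eigvecs[:, order])
    explained = 100.0 * eigvals / eigvals.sum()
    return ClusterPCAModel(
        cluster_id=cluster_id,
        members=list(members),
        loadings_pc1=eigvecs[:, 0],
        scores_pc1=sub @ eigvecs[:, 0],
        explained=explained,
        loadings_full=eigvecs,
    )


@dataclass
class StepwiseModelReport:
    """Final stepwise model for one cluster's PC1 surrogate.

    ``beta``/``std_err``/``p_value`` are aligned with ``selected`` and
    reported on the standardized-regressor scale; the intercept is fitted
    but not reported.  ``selection_trace`` records every add/drop with its
    partial F and p, plus refused additions (degrees-of-freedom guard).
    """

    cluster_id: int
    selected: list[str]
    beta: np.ndarray
    std_err: np.ndarray
    p_value: np.ndarray
    r_squared: float
    selection_trace: list[dict]
    intercept: float = 0.0  # fitted but not reported in the ledger

    def to_dict(self) -> dict:
        return {
            "cluster_id": self.cluster_id,
            "selected": list(self.selected),
            "beta": [float(b) for b in self.beta],
            "std_err": [float(s) for s in self.std_err],
            "p_value": [float(p) for p in self.p_value],
            "r_squared": float(self.r_squared),
            "selection_trace": list(self.selection_trace),
        }


def _rss(y: np.ndarray, Xcols: np.ndarray) -> float:
    """Residual sum of squares of OLS of y on [1, Xcols]."""
    n = y.shape[0]
    X = np.column_stack([np.ones(n)] + ([Xcols] if Xcols.size else []))
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def _partial_f(rss_reduced: float, rss_full: float, n: int, p_full: int):
    """Partial F and p-value for a single-term nested comparison."""
    df_resid = n - p_full
    if df_resid <= 0:
        return np.inf, 1.0
    denom = rss_full / df_resid
    if denom <= 0:  # perfect fit: the term change is infinitely significant
        F = np.inf if rss_reduced > rss_full else 0.0
    else:
        F = (rss_reduced - rss_full) / denom
    F = max(F, 0.0)
    return F, float(stats.f.sf(F, 1, df_resid))


def stepwise_fit(
    y: np.ndarray,
    terms: TermSet,
    alpha_enter: float = 0.05,
    alpha_remove: float = 0.05,
    cluster_id: int = 0,
) -> StepwiseModelReport:
    """Forward stepwise selection with partial F entry and removal tests.

    At each iteration the excluded term with the smallest entry p-value is
    added if p < ``alpha_enter`` (ties broken by canonical term order);
    then included terms are re-tested and the largest-p term with
    p > ``alpha_remove`` is dropped.  The loop stops when no addition or
    removal changes the model.  Terms are standardized before fitting; the
    surrogate response is used as-is (it is centered by construction).

    A term whose addition would leave fewer than 2 residual degrees of
    freedom is ineligible that iteration and the refusal is recorded in
    the trace.
    """
    if not 0 < alpha_enter < 1 or not 0 < alpha_remove < 1:
        raise ValueError("significance levels must lie in (0, 1)")
    std = terms if terms.scaling is not None else terms.standardize()
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    if std.values.shape[0] != n:
        raise ValueError("response length does not match term matrix rows")
    cols = {lab: std.values[lab].to_numpy() for lab in std.labels}
    order = {lab: i for i, lab in enumerate(std.labels)}

    selected: list[str] = []
    trace: list[dict] = []
    # entry/removal at the same alpha can in principle cycle; cap the loop
    for _ in range(4 * len(std.labels) + 8):
        changed = False
        # --- entry scan ---
        current = np.column_stack([cols[t] for t in selected]) if selected else np.empty((n, 0))
        rss_cur = _rss(y, current)
        best: tuple[float, int, str, float] | None = None  # (p, order, label, F)
        for lab in std.labels:
            if lab in selected:
                continue
            p_full = len(selected) + 2  # intercept + candidates + new term
            if n - p_full < 2:
                trace.append(
                    {"action": "refuse", "term": lab, "partial_F": None, "p": None}
                )
                continue
            rss_new = _rss(y, np.column_stack([current, cols[lab]]))
            F, p = _partial_f(rss_cur, rss_new, n, p_full)
            if p < alpha_enter and (best is None or (p, order[lab]) < (best[0], best[1])):
                best = (p, order[lab], lab, F)
        if best is not None:
            _, _, lab, F = best
            selected.append(lab)
            trace.append({"action": "add", "term": lab, "partial_F": F, "p": best[0]})
            changed = True
        # --- removal scan ---
        if selected:
            current = np.column_stack([cols[t] for t in selected])
            rss_cur = _rss(y, current)
            worst: tuple[float, int, str, float] | None = None
            for i, lab in enumerate(selected):
                reduced = np.delete(current, i, axis=1)
                F, p = _partial_f(_rss(y, reduced), rss_cur, n, len(selected) + 1)
                if p > alpha_remove and (
                    worst is None or (p, -order[lab]) > (worst[0], -worst[1])
                ):
                    worst = (p, order[lab], lab, F)
            if worst is not None:
                p, _, lab, F = worst
                selected.remove(lab)
                trace.append({"action": "drop", "term": lab, "partial_F": F, "p": p})
                changed = True
        if not changed:
            break

    if selected:
        X = sm.add_constant(
            pd.DataFrame({lab: cols[lab] for lab in selected}), prepend=True
        )
        fit = sm.OLS(y, X).fit()
        beta = fit.params[selected].to_numpy()
        std_err = fit.bse[selected].to_numpy()
        p_value = fit.pvalues[selected].to_numpy()
        r_squared = float(fit.rsquared)
        intercept = float(fit.params["const"])
    else:
        beta = np.array([])
        std_err = np.array([])
        p_value = np.array([])
        r_squared = 0.0
        intercept = float(np.mean(y))
    return StepwiseModelReport(
        cluster_id=cluster_id,
        selected=selected,
        beta=beta,
        std_err=std_err,
        p_value=p_value,
        r_squared=r_squared,
        selection_trace=trace,
        intercept=intercept,
    )


def reconstruct(
    model: ClusterPCAModel,
    t_hat: np.ndarray,
    scaling: pd.DataFrame,
) -> pd.DataFrame:
    """Member responses in original units from (predicted) PC1 scores.

    The standardized prediction is the outer product t_hat (x) p; the
    per-member autoscaling (mean, sd) then maps back to original units.
    """
    t_hat = np.asarray(t_hat, dtype=float)
    missing = [m for m in model.members if m not in scaling.columns]
    if missing:
        raise ValueError(f"scaling state missing for members: {missing}")
    z_hat = np.outer(t_hat, model.loadings_pc1)
    mean = scaling.loc["mean", model.members].to_numpy()
    sd = scaling.loc["sd", model.members].to_numpy()
    return pd.DataFrame(mean + sd * z_hat, columns=model.members)


def summarize(
    reports: list[StepwiseModelReport], pca_models: list[ClusterPCAModel]
) -> pd.DataFrame:
    """Tidy ledger of the whole analysis, one row per (cluster, term).

    Mirrors the standard report layout: cluster id, composition, PC1
    loadings, cumulative explained variance, model R², then the selected
    terms with betas, standard errors and p-values.  Clusters with more
    members than selected terms (or vice versa) pad the shorter column
    with empty cells, exactly like a printed row block.
    """
    if len(reports) != len(pca_models):
        raise ValueError("need exactly one report per cluster PCA model")
    rows = []
    for rep, pc in sorted(
        zip(reports, pca_models), key=lambda pair: pair[0].cluster_id
    ):
        if rep.cluster_id != pc.cluster_id:
            raise ValueError("report/PCA cluster ids do not align")
        nrow = max(len(pc.members), len(rep.selected), 1)
        cum = pc.cum_explained
        for i in range(nrow):
            rows.append(
                {
                    "cluster_id": rep.cluster_id,
                    "composition": pc.members[i] if i < len(pc.members) else "",
                    "loading_pc1": (
                        float(pc.loadings_pc1[i]) if i < len(pc.members) else np.nan
                    ),
                    "cum_explained": float(cum[i]) if i < len(cum) else np.nan,
                    "r_squared": rep.r_squared if i == 0 else np.nan,
                    "term": rep.selected[i] if i < len(rep.selected) else "",
                    "beta": float(rep.beta[i]) if i < len(rep.selected) else np.nan,
                    "std_err": (
                        float(rep.std_err[i]) if i < len(rep.selected) else np.nan
                    ),
                    "p_value": (
                        float(rep.p_value[i]) if i < len(rep.selected) else np.nan
                    ),
                }
            )
    return pd.DataFrame(rows)


def ledger_to_json(
    reports: list[StepwiseModelReport], pca_models: list[ClusterPCAModel]
) -> str:
    """Loss-free JSON rendering of the per-cluster results."""
    payload = []
    for rep, pc in sorted(
        zip(reports, pca_models), key=lambda pair: pair[0].cluster_id
    ):
        payload.append(
            {
                "cluster_id": rep.cluster_id,
                "members": list(pc.members),
                "loadings_pc1": [float(v) for v in pc.loadings_pc1],
                "cum_explained": [float(v) for v in pc.cum_explained],
                **rep.to_dict(),
            }
        )
    return json.dumps(payload, indent=2, sort_keys=True)
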