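"""Model/Results interface over the full three-stage analysis.

:class:`ModularResponseSurface` is constructed from a coded design and a
response matrix; :meth:`~ModularResponseSurface.fit` runs autoscaling,
global PCA, variable clustering, per-cluster PC1 extraction, stepwise
response-surface modelling and reconstruction, and returns a
:class:`ModularSurfaceResults` holding every intermediate object plus a
``summary()`` table in the standard cluster-ledger layout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cluster import ClusterAssignment, PCAModel, ahc_cluster, pca
from .design import DesignTable
from .model import (
    ClusterPCAModel,
    StepwiseModelReport,
    cluster_pc1,
    ledger_to_json,
    reconstruct,
    stepwise_fit,
    summarize,
)
from .preprocess import ResponseMatrix, autoscale, correlation_matrix, level_summaries
from .terms import TermSet, build_terms

__all__ = ["ModularResponseSurface", "ModularSurfaceResults"]


class ModularResponseSurface:
    """Modular response-surface model for a multivariate designed experiment.

    Parameters
    ----------
    design : DesignTable
        Coded face-centered CCD (or any coded 3-level design).
    responses : ResponseMatrix
        Raw (unscaled) runs x responses matrix, row-aligned with the design.
    k_clusters : int
        Number of response modules to cut the variable dendrogram into.
    linkage : str
        AHC linkage criterion ("average", "complete", "single").
    distance : str
        Correlation-distance variant: "absolute" (1 - |r|) or "signed" (1 - r).
    alpha_enter, alpha_remove : float
        Partial-F significance levels for stepwise entry and removal.
    """

    def __init__(
        self,
        design: DesignTable,
        responses: ResponseMatrix,
        k_clusters: int = 5,
        linkage: str = "average",
        distance: str = "absolute",
        alpha_enter: float = 0.05,
        alpha_remove: float = 0.05,
    ) -> None:
        if design.n_runs != len(responses.run_ids):
            raise ValueError(
                f"design has {design.n_runs} runs but responses have "
                f"{len(responses.run_ids)} rows"
            )
        if not 1 <= k_clusters <= len(responses.names):
            raise ValueError("k_clusters must be between 1 and the response count")
        self.design = design
        self.responses = responses
        self.k_clusters = k_clusters
        self.linkage = linkage
        self.distance = distance
        self.alpha_enter = alpha_enter
        self.alpha_remove = alpha_remove

    @classmethod
    def from_csv(
        cls, design_path, responses_path, factors, **kwargs
    ) -> "ModularResponseSurface":
        """Build from a coded design CSV and a response CSV (run_id column)."""
        return cls(
            DesignTable.from_csv(design_path, factors),
            ResponseMatrix.from_csv(responses_path),
            **kwargs,
        )

    def fit(self) -> "ModularSurfaceResults":
        scaled = autoscale(self.responses)
        corr = correlation_matrix(scaled)
        summaries = level_summaries(self.design, self.responses)
        global_pca = pca(scaled)
        clusters = ahc_cluster(
            scaled, self.k_clusters, linkage=self.linkage, distance=self.distance
        )
        terms = build_terms(self.design).standardize()

        cluster_pcas: list[ClusterPCAModel] = []
        reports: list[StepwiseModelReport] = []
        fitted = {}
        for cid in clusters.cluster_ids:
            members = clusters.members(cid)
            pc = cluster_pc1(scaled, members, cluster_id=cid)
            rep = stepwise_fit(
                pc.scores_pc1,
                terms,
                alpha_enter=self.alpha_enter,
                alpha_remove=self.alpha_remove,
                cluster_id=cid,
            )
            cluster_pcas.append(pc)
            reports.append(rep)
            fitted[cid] = self._predict_scores(rep, terms)
        recon = self._reconstruct_all(cluster_pcas, fitted, scaled)
        return ModularSurfaceResults(
            model=self,
            scaled=scaled,
            correlations=corr,
            level_summaries=summaries,
            global_pca=global_pca,
            clusters=clusters,
            terms=terms,
            cluster_pcas=cluster_pcas,
            reports=reports,
            reconstruction=recon,
        )

    @staticmethod
    def _predict_scores(rep: StepwiseModelReport, terms: TermSet) -> np.ndarray:
        """Fitted PC1 scores from the selected standardized terms."""
        n = terms.values.shape[0]
        if not rep.selected:
            return np.full(n, rep.intercept)
        X = terms.values[rep.selected].to_numpy()
        return rep.intercept + X @ rep.beta

    def _reconstruct_all(
        self,
        cluster_pcas: list[ClusterPCAModel],
        fitted: dict[int, np.ndarray],
        scaled: ResponseMatrix,
    ) -> pd.DataFrame:
        parts = [
            reconstruct(pc, fitted[pc.cluster_id], scaled.scaling)
            for pc in cluster_pcas
        ]
        recon = pd.concat(parts, axis=1)
        recon.index = scaled.run_ids
        return recon[self.responses.names]


@dataclass
class ModularSurfaceResults:
    """Everything the three-stage analysis produced, ready for reporting."""

    model: ModularResponseSurface
    scaled: ResponseMatrix
    correlations: pd.DataFrame
    level_summaries: pd.DataFrame
    global_pca: PCAModel
    clusters: ClusterAssignment
    terms: TermSet
    cluster_pcas: list[ClusterPCAModel]
    reports: list[StepwiseModelReport]
    reconstruction: pd.DataFrame = field(repr=False, default=None)  # type: ignore[assignment]

    def summary(self) -> pd.DataFrame:
        """Cluster ledger: composition, PC1 loadings, cum. explained, model."""
        return summarize(self.reports, self.cluster_pcas)

    def summary_text(self) -> str:
        df = self.summary()
        with pd.option_context("display.float_format", "{:.4f}".format):
            return df.to_string(index=False, na_rep="")

    def to_json(self) -> str:
        return ledger_to_json(self.reports, self.cluster_pcas)

    def trace_frame(self) -> pd.DataFrame:
        rows = []
        for rep in self.reports:
            for step, ev in enumerate(rep.selection_trace):
                rows.append({"cluster_id": rep.cluster_id, "step": step, **ev})
        return pd.DataFrame(rows)

    @property
    def r_squared(self) -> dict[int, float]:
        return {rep.cluster_id: rep.r_squared for rep in self.reports}
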