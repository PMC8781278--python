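"""Response matrices, autoscaling and the numeric side of exploratory analysis.

Autoscaling (z-transformation of every response column to zero mean and
unit sample standard deviation) focuses all downstream latent-variable
analysis strictly on the correlation structure of the responses, which is
what matters when 18 responses live on wildly different physical scales
(hours, g/L, mg/L).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import DesignTable

__all__ = [
    "ResponseMatrix",
    "DegenerateColumnError",
    "autoscale",
    "level_summaries",
    "correlation_matrix",
]


class DegenerateColumnError(ValueError):
    """A response column has zero variance and cannot be autoscaled."""


class AlignmentError(ValueError):
    """Design and response tables do not describe the same runs."""


@dataclass
class ResponseMatrix:
    """Runs x responses numeric matrix with optional per-column scaling state.

    Attributes
    ----------
    data : DataFrame
        Index = run ids, columns = response names, no missing entries.
    scaling : DataFrame or None
        When the matrix has been autoscaled, a two-row frame (``mean``,
        ``sd``) per original column, enabling the inverse transform.
    """

    data: pd.DataFrame
    scaling: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        self.data = self.data.astype(float)
        if self.data.isna().any().any():
            bad = self.data.columns[self.data.isna().any()].tolist()
            raise ValueError(f"missing values in response columns: {bad}")

    @property
    def run_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def is_scaled(self) -> bool:
        return self.scaling is not None

    def inverse_transform(self) -> "ResponseMatrix":
        """Undo autoscaling, restoring the original units."""
        if self.scaling is None:
            raise ValueError("matrix carries no scaling state")
        raw = self.data * self.scaling.loc["sd"] + self.scaling.loc["mean"]
        return ResponseMatrix(raw)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index_label="run_id")

    @classmethod
    def from_csv(cls, path) -> "ResponseMatrix":
        df = pd.read_csv(path)
        if "run_id" in df.columns:
            df = df.set_index("run_id")
        return cls(df)


def autoscale(X: ResponseMatrix) -> ResponseMatrix:
    """Z-transform every column to zero mean and unit sample sd (n-1).

    Raises
    ------
    DegenerateColumnError
        If any column is constant.
    """
    mean = X.data.mean()
    sd = X.data.std(ddof=1)
    degenerate = sd.index[(sd == 0) | sd.isna()].tolist()
    if degenerate:
        raise DegenerateColumnError(
            f"constant response columns cannot be autoscaled: {degenerate}"
        )
    scaled = (X.data - mean) / sd
    scaling = pd.DataFrame({"mean": mean, "sd": sd}).T
    return ResponseMatrix(scaled, scaling=scaling)


def level_summaries(design: DesignTable, X: ResponseMatrix) -> pd.DataFrame:
    """Distribution of each response at each coded level of each factor.

    Returns a tidy table with one row per (response, factor, level):
    ``n``, ``mean``, ``q1``, ``q3``, ``min``, ``max`` — the numeric content
    of level-wise boxplots of the responses.
    """
    if design.n_runs != len(X.run_ids):
        raise AlignmentError(
            f"design has {design.n_runs} runs but responses have {len(X.run_ids)}"
        )
    rows = []
    for fi, fname in enumerate(design.factor_names):
        codes = design.runs[:, fi]
        for response in X.names:
            y = X.data[response].to_numpy()
            for level in (-1, 0, 1):
                vals = y[codes == level]
                if vals.size == 0:
                    continue
                rows.append(
                    {
                        "response": response,
                        "factor": fname,
                        "level": level,
                        "n": int(vals.size),
                        "mean": float(np.mean(vals)),
                        "q1": float(np.percentile(vals, 25)),
                        "q3": float(np.percentile(vals, 75)),
                        "min": float(np.min(vals)),
                        "max": float(np.max(vals)),
                    }
                )
    return pd.DataFrame(rows)


def correlation_matrix(X: ResponseMatrix) -> pd.DataFrame:
    """Pearson correlation matrix of the responses (symmetric, unit diagonal)."""
    if len(X.run_ids) < 3:
        raise ValueError("need at least 3 runs for a correlation matrix")
    sd = X.data.std(ddof=1)
    degenerate = sd.index[(sd == 0) | sd.isna()].tolist()
    if degenerate:
        raise DegenerateColumnError(
            f"constant response columns have no defined correlation: {degenerate}"
        )
    return X.data.corr()
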