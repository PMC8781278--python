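"""Polynomial candidate terms over coded factor levels.

For k factors the candidate set is the k main effects, the k(k-1)/2
pairwise interactions and the k quadratics — 14 terms for the 4-factor
design.  Labels use the field's notation: ``S``, ``N×T``, ``S²``; ASCII
spellings (``N*T``, ``NxT``, ``S^2``, ``S2``) are accepted on input and
canonicalized.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import DesignTable

__all__ = ["TermSet", "build_terms", "canonical_term"]

TIMES = "×"  # ×
SQUARED = "²"  # ²


class InvalidTermError(ValueError):
    """A term label does not parse against the design's factor names."""


def canonical_term(label: str, factor_names: list[str]) -> str:
    """Normalize a term label to the canonical ``A``, ``A×B`` or ``A²`` form.

    Interaction factor order follows the design's factor order, so
    ``T*N`` canonicalizes to ``N×T``.
    """
    s = label.strip().replace(" ", "")
    m = re.fullmatch(rf"(\w+)(?:\^2|2|{SQUARED})", s)
    if m and m.group(1) in factor_names:
        return m.group(1) + SQUARED
    for sep in (TIMES, "*", ":", "x"):
        if sep in s:
            parts = s.split(sep)
            if len(parts) == 2 and all(p in factor_names for p in parts):
                a, b = sorted(parts, key=factor_names.index)
                return f"{a}{TIMES}{b}"
    if s in factor_names:
        return s
    raise InvalidTermError(
        f"cannot interpret term {label!r} over factors {factor_names}"
    )


def _term_column(label: str, coded: pd.DataFrame) -> pd.Series:
    """Evaluate one canonical term label on a coded design frame."""
    if label.endswith(SQUARED):
        return coded[label[:-1]] ** 2
    if TIMES in label:
        a, b = label.split(TIMES)
        return coded[a] * coded[b]
    return coded[label]


@dataclass
class TermSet:
    """Candidate regressors evaluated on a coded design.

    Attributes
    ----------
    labels : list of str
        Canonical term labels in the deterministic order mains,
        interactions (lexicographic factor-pair order), quadratics.
    values : DataFrame
        Runs x terms matrix of raw (unstandardized) term values.
    scaling : DataFrame or None
        ``mean``/``sd`` rows per term once :meth:`standardize` has run.
    """

    labels: list[str]
    values: pd.DataFrame
    scaling: pd.DataFrame | None = field(default=None)

    def standardize(self) -> "TermSet":
        """Center each term and scale to unit sample sd (n-1 denominator)."""
        mean = self.values.mean()
        sd = self.values.std(ddof=1)
        if (sd == 0).any():
            bad = sd.index[sd == 0].tolist()
            raise ValueError(f"constant candidate terms cannot be standardized: {bad}")
        scaled = (self.values - mean) / sd
        return TermSet(
            labels=list(self.labels),
            values=scaled,
            scaling=pd.DataFrame({"mean": mean, "sd": sd}).T,
        )


def build_terms(design: DesignTable) -> TermSet:
    """Expand a coded design into its full quadratic candidate term set."""
    names = design.factor_names
    coded = pd.DataFrame(design.runs, columns=names, index=design.run_ids, dtype=float)
    labels = (
        list(names)
        + [f"{a}{TIMES}{b}" for a, b in itertools.combinations(names, 2)]
        + [f"{n}{SQUARED}" for n in names]
    )
    values = pd.DataFrame(
        {lab: _term_column(lab, coded) for lab in labels}, index=design.run_ids
    )
    return TermSet(labels=labels, values=values)


def evaluate_terms(
    labels: list[str], design: DesignTable
) -> tuple[list[str], np.ndarray]:
    """Canonicalize ``labels`` and evaluate them on the design's coded levels."""
    names = design.factor_names
    coded = pd.DataFrame(design.runs, columns=names, dtype=float)
    canon = [canonical_term(lab, names) for lab in labels]
    cols = np.column_stack([_term_column(lab, coded).to_numpy() for lab in canon])
    return canon, cols
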