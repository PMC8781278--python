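"""Face-centered central composite designs (CCD) and factor level coding.

A face-centered CCD for k factors combines a full 2^k factorial at coded
levels ±1, 2k axial ("star") points with one coordinate at ±1 and the rest
at 0, and replicated center points (all coordinates 0).  With the star
distance alpha = 1 every factor takes exactly three coded levels
{-1, 0, +1}, so three physical settings per factor suffice.

Coded levels are stored as exact integers; physical units are derived on
demand through the linear map of each :class:`FactorSpec`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FactorSpec",
    "DesignTable",
    "ValidationReport",
    "generate_ccd",
    "validate_design",
    "wine_fermentation_factors",
]


class UnsupportedDesignError(ValueError):
    """Raised for CCD variants outside the face-centered (alpha=1) case."""


@dataclass(frozen=True)
class FactorSpec:
    """One experimental factor with its three physical levels.

    Parameters
    ----------
    name : str
        Short label (e.g. ``"S"`` for initial sugar content).
    low, mid, high : float
        Physical values at coded -1, 0 and +1.  ``mid`` must be the
        arithmetic midpoint of ``low`` and ``high`` for the linear
        decode map to be exact.
    units : str
        Free-text units, for reporting only.
    """

    name: str
    low: float
    mid: float
    high: float
    units: str = ""

    def __post_init__(self) -> None:
        if not (self.low < self.mid < self.high):
            raise ValueError(
                f"factor {self.name!r}: levels must satisfy low < mid < high, "
                f"got {self.low}, {self.mid}, {self.high}"
            )
        span = self.high - self.low
        if abs(self.mid - (self.low + self.high) / 2.0) > 1e-9 * max(1.0, abs(span)):
            raise ValueError(
                f"factor {self.name!r}: mid level {self.mid} is not the midpoint "
                f"of ({self.low}, {self.high}); linear coding would be inexact"
            )

    def decode(self, coded: float) -> float:
        """Map a coded level in [-1, 1] to physical units."""
        if not -1.0 - 1e-12 <= coded <= 1.0 + 1e-12:
            raise ValueError(f"coded level {coded} outside [-1, 1]")
        return self.mid + coded * (self.high - self.mid)

    def encode(self, physical: float) -> float:
        """Inverse of :meth:`decode`."""
        return (physical - self.mid) / (self.high - self.mid)


def wine_fermentation_factors() -> list[FactorSpec]:
    """The four factors of the wine mixed-culture fermentation study.

    S: initial sugar content (g/L); N: initial yeast assimilable nitrogen
    (mg/L); T: fermentation temperature (degC); I: inoculum level of the
    non-Saccharomyces adjunct yeast (CFU/mL, 0 meaning no co-inoculation).
    """
    return [
        FactorSpec("S", 150.0, 225.0, 300.0, "g/L"),
        FactorSpec("N", 100.0, 300.0, 500.0, "mg/L"),
        FactorSpec("T", 10.0, 20.0, 30.0, "degC"),
        FactorSpec("I", 0.0, 5e5, 1e6, "CFU/mL"),
    ]


@dataclass
class DesignTable:
    """A coded experimental design: runs x factors at integer levels.

    Attributes
    ----------
    factors : list of FactorSpec
        Ordered factor specifications.
    runs : ndarray of int, shape (n_runs, k)
        Coded levels, each entry in {-1, 0, +1}.
    run_order : ndarray of int
        Execution-order permutation of the row indices.
    """

    factors: list[FactorSpec]
    runs: np.ndarray
    run_order: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.runs = np.asarray(self.runs)
        if np.issubdtype(self.runs.dtype, np.floating) and np.all(
            self.runs == np.round(self.runs)
        ):
            self.runs = self.runs.astype(int)  # keep non-integral levels for validation
        if self.runs.ndim != 2 or self.runs.shape[1] != len(self.factors):
            raise ValueError("runs matrix shape does not match factor count")
        if self.run_order is None:
            self.run_order = np.arange(self.n_runs)
        self.run_order = np.asarray(self.run_order, dtype=int)
        if sorted(self.run_order.tolist()) != list(range(self.n_runs)):
            raise ValueError("run_order is not a permutation of the rows")

    @property
    def n_runs(self) -> int:
        return self.runs.shape[0]

    @property
    def k(self) -> int:
        return len(self.factors)

    @property
    def factor_names(self) -> list[str]:
        return [f.name for f in self.factors]

    @property
    def center_mask(self) -> np.ndarray:
        """Boolean per run, True where every coded level is 0."""
        return np.all(self.runs == 0, axis=1)

    @property
    def run_ids(self) -> list[str]:
        return [f"run{i + 1:02d}" for i in range(self.n_runs)]

    def factor(self, name: str) -> FactorSpec:
        for f in self.factors:
            if f.name == name:
                return f
        raise KeyError(f"unknown factor {name!r}")

    def decode(self, factor: str, coded: float) -> float:
        """Physical value of ``factor`` at a coded level."""
        return self.factor(factor).decode(coded)

    def encode(self, factor: str, physical: float) -> float:
        return self.factor(factor).encode(physical)

    def to_dataframe(self) -> pd.DataFrame:
        """Coded design as a DataFrame with run_id and run_order columns."""
        df = pd.DataFrame(self.runs, columns=self.factor_names)
        df.insert(0, "run_id", self.run_ids)
        df.insert(1, "run_order", self.run_order)
        return df

    def to_physical_dataframe(self) -> pd.DataFrame:
        """Design decoded to physical units, one column per factor."""
        df = self.to_dataframe()
        for f in self.factors:
            df[f.name] = [f.decode(c) for c in self.runs[:, self.factor_names.index(f.name)]]
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, factors: list[FactorSpec]) -> "DesignTable":
        names = [f.name for f in factors]
        missing = [n for n in names if n not in df.columns]
        if missing:
            raise KeyError(f"design table missing factor columns: {missing}")
        runs = df[names].to_numpy()
        if not np.all(np.isin(runs, (-1, 0, 1))):
            raise ValueError("coded design entries must be in {-1, 0, +1}")
        run_order = (
            df["run_order"].to_numpy() if "run_order" in df.columns else None
        )
        return cls(factors=factors, runs=runs.astype(int), run_order=run_order)

    @classmethod
    def from_csv(cls, path, factors: list[FactorSpec]) -> "DesignTable":
        return cls.from_dataframe(pd.read_csv(path), factors)


def generate_ccd(
    k: int | None = None,
    alpha: float = 1.0,
    n_center: int = 7,
    seed: int | None = None,
    factors: list[FactorSpec] | None = None,
) -> DesignTable:
    """Generate a face-centered CCD.

    Parameters
    ----------
    k : int, optional
        Number of factors; defaults to ``len(factors)``.  When no factor
        specifications are given, the four wine-fermentation factors are
        used for k=4 and generic unit-range factors otherwise.
    alpha : float
        Star distance in coded units.  Only the face-centered case
        ``alpha=1`` is supported; anything else raises
        :class:`UnsupportedDesignError`.
    n_center : int
        Number of replicated center points (default 7, the study layout:
        2^4 + 2*4 + 7 = 31 runs).
    seed : int, optional
        Seed for the run-order randomization.  ``None`` leaves the rows in
        standard order (factorial, axial, center).

    Returns
    -------
    DesignTable
    """
    if factors is not None:
        if k is None:
            k = len(factors)
        elif k != len(factors):
            raise ValueError("k does not match the number of factor specs")
    elif k is None:
        k = 4
    if k < 2:
        raise ValueError(f"a CCD needs at least 2 factors, got k={k}")
    if alpha != 1:
        raise UnsupportedDesignError(
            f"only the face-centered CCD (alpha=1) is supported, got alpha={alpha}"
        )
    if n_center < 1:
        raise ValueError("n_center must be >= 1")
    if factors is None:
        factors = (
            wine_fermentation_factors()
            if k == 4
            else [FactorSpec(f"X{i + 1}", -1.0, 0.0, 1.0) for i in range(k)]
        )

    factorial = np.array(list(itertools.product((-1, 1), repeat=k)), dtype=int)
    axial = np.zeros((2 * k, k), dtype=int)
    for j in range(k):
        axial[2 * j, j] = -1
        axial[2 * j + 1, j] = 1
    center = np.zeros((n_center, k), dtype=int)
    runs = np.vstack([factorial, axial, center])

    if seed is None:
        run_order = np.arange(runs.shape[0])
    else:
        run_order = np.random.default_rng(seed).permutation(runs.shape[0])
    return DesignTable(factors=factors, runs=runs, run_order=run_order)


@dataclass
class ValidationReport:
    """Structural diagnosis of a coded design; caller decides severity."""

    n_runs: int
    n_factorial: int
    n_axial: int
    n_center: int
    expected_factorial: int
    expected_axial: int
    out_of_range: list[tuple[int, str]]
    duplicate_noncenter_rows: list[tuple[int, int]]
    decomposition_ok: bool

    @property
    def valid(self) -> bool:
        return self.decomposition_ok and not self.out_of_range


def validate_design(design: DesignTable) -> ValidationReport:
    """Check a design's row-count decomposition and level codes.

    Classifies each row as factorial (all entries +-1), axial (exactly one
    nonzero entry), or center (all zero); anything else, or any entry
    outside {-1, 0, +1}, is flagged.
    """
    k = design.k
    runs = design.runs
    out_of_range = [
        (int(i), design.factor_names[int(j)])
        for i, j in zip(*np.nonzero(~np.isin(runs, (-1, 0, 1))))
    ]
    nonzero = np.count_nonzero(runs, axis=1)
    is_center = nonzero == 0
    is_axial = nonzero == 1
    is_factorial = nonzero == k
    n_center = int(is_center.sum())
    n_axial = int(is_axial.sum())
    n_factorial = int(is_factorial.sum())
    unclassified = design.n_runs - n_center - n_axial - n_factorial

    noncenter = np.nonzero(~is_center)[0]
    dupes: list[tuple[int, int]] = []
    seen: dict[tuple, int] = {}
    for i in noncenter:
        key = tuple(runs[i])
        if key in seen:
            dupes.append((seen[key], int(i)))
        else:
            seen[key] = int(i)

    decomposition_ok = (
        n_factorial == 2**k
        and n_axial == 2 * k
        and n_center >= 1
        and unclassified == 0
        and not dupes
    )
    return ValidationReport(
        n_runs=design.n_runs,
        n_factorial=n_factorial,
        n_axial=n_axial,
        n_center=n_center,
        expected_factorial=2**k,
        expected_axial=2 * k,
        out_of_range=out_of_range,
        duplicate_noncenter_rows=dupes,
        decomposition_ok=decomposition_ok,
    )
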