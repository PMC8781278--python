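"""Synthetic response matrices with known modular latent structure.

The generator runs the analysis model in reverse: each module (cluster) of
responses is driven by one latent score that is a polynomial in the coded
factors, and every member is that score times its loading plus independent
Gaussian noise.  For run i with coded vector x_i and module c,

    s_c(x_i) = sum_t beta_ct * g_t(x_i)          (g_t: main, product, square)
    y_ij     = mu_j + lambda_j * (p_cj * s_c(x_i) + eps_ij),
    eps_ij ~ N(0, sigma_c^2)  i.i.d. across runs and members.

With sigma_c = 0 each module's data matrix is exactly rank one, which is
the regime in which the PC1-surrogate workflow is lossless; the defaults
(:func:`default_truth`) use the loading vectors and effect sizes of the
wine mixed-culture fermentation study as generating ground truth, with
sigma = 0.05 on the standardized scale reflecting realistic
center-replicate spread.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import DesignTable, generate_ccd
from .preprocess import ResponseMatrix
from .terms import evaluate_terms

__all__ = ["ModuleSpec", "SyntheticDataset", "simulate_responses", "default_truth"]

DEFAULT_NOISE_SD = 0.05


@dataclass
class ModuleSpec:
    """Generating parameters for one correlated module of responses.

    ``loadings`` is normalized to unit Euclidean norm on construction
    (printed loading vectors round-trip imperfectly at 4 decimals).
    """

    members: list[str]
    loadings: np.ndarray
    betas: dict[str, float]
    noise_sd: float = DEFAULT_NOISE_SD
    member_means: np.ndarray | None = None
    member_scales: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("module must have at least one member")
        self.loadings = np.asarray(self.loadings, dtype=float)
        if self.loadings.shape != (len(self.members),):
            raise ValueError("loadings length must match member count")
        norm = float(np.linalg.norm(self.loadings))
        if norm == 0:
            raise ValueError("loadings vector cannot be zero")
        self.loadings = self.loadings / norm
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        m = len(self.members)
        self.member_means = (
            np.zeros(m) if self.member_means is None
            else np.asarray(self.member_means, dtype=float)
        )
        self.member_scales = (
            np.ones(m) if self.member_scales is None
            else np.asarray(self.member_scales, dtype=float)
        )

    def latent_scores(self, design: DesignTable) -> np.ndarray:
        """Noise-free latent score s_c(x_i) per run."""
        labels, cols = evaluate_terms(list(self.betas), design)
        coef = np.array([self.betas[orig] for orig in self.betas], dtype=float)
        del labels  # canonical order matches dict order by construction
        return cols @ coef

    def to_dict(self) -> dict:
        return {
            "members": list(self.members),
            "loadings": self.loadings.tolist(),
            "betas": dict(self.betas),
            "noise_sd": self.noise_sd,
            "member_means": self.member_means.tolist(),
            "member_scales": self.member_scales.tolist(),
        }


@dataclass
class SyntheticDataset:
    """A simulated design/response pair together with its generating truth."""

    design: DesignTable
    responses: ResponseMatrix
    truth: list[ModuleSpec]
    seed: int | None = None

    @property
    def module_labels(self) -> dict[str, int]:
        """Ground-truth cluster id (1-based) per response name."""
        return {
            name: c + 1 for c, mod in enumerate(self.truth) for name in mod.members
        }

    def truth_to_json(self, path) -> None:
        payload = {
            "seed": self.seed,
            "modules": [m.to_dict() for m in self.truth],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def simulate_responses(
    design: DesignTable,
    modules: list[ModuleSpec] | None = None,
    seed: int | None = None,
) -> SyntheticDataset:
    """Simulate a response matrix over ``design`` from module specs.

    Member names must be disjoint across modules.  Fully reproducible:
    the same (design, modules, seed) triple gives bitwise-identical data.
    """
    if modules is None:
        modules = default_truth()
    all_names = [name for mod in modules for name in mod.members]
    if len(set(all_names)) != len(all_names):
        raise ValueError("module member names must be disjoint across modules")

    rng = np.random.default_rng(seed)
    n = design.n_runs
    columns: dict[str, np.ndarray] = {}
    for mod in modules:
        s = mod.latent_scores(design)
        eps = rng.normal(0.0, mod.noise_sd, size=(n, len(mod.members)))
        for j, name in enumerate(mod.members):
            columns[name] = mod.member_means[j] + mod.member_scales[j] * (
                mod.loadings[j] * s + eps[:, j]
            )
    data = pd.DataFrame(columns, index=design.run_ids)
    return SyntheticDataset(
        design=design, responses=ResponseMatrix(data), truth=modules, seed=seed
    )


def default_truth(noise_sd: float = DEFAULT_NOISE_SD) -> list[ModuleSpec]:
    """The five-module, 18-response generating truth of the fermentation study.

    Member lists, PC1 loading directions and effect sizes are the reported
    cluster-level results of the wine mixed-culture study: module 1 is the
    singleton ethyl acetate driven by inoculum; module 2 the fermentation
    kinetics pair (R100 fermentation length, anti-correlated with the
    maximum fermentation rate MFR); module 3 the ethyl esters / isoamyl
    acetate / 1-propanol block; module 4 the primary fermentation products
    (ethanol, acetic acid, glycerol) dominated by sugar; module 5 the
    higher alcohols and 2-phenylethyl acetate block driven negatively by
    nitrogen.
    """
    return [
        ModuleSpec(
            members=["Ethyl acetate"],
            loadings=[1.0],
            betas={"I": 0.7592, "N×I": -0.2088},
            noise_sd=noise_sd,
        ),
        ModuleSpec(
            members=["R100", "MFR"],
            loadings=[-0.7071, 0.7071],
            betas={
                "S": -0.6569,
                "N": 0.4962,
                "T": 0.8519,
                "I": -0.1458,
                "N×T": 0.1663,
                "S²": -0.2045,
                "N²": -0.2727,
            },
            noise_sd=noise_sd,
        ),
        ModuleSpec(
            members=[
                "Ethyl hexanoate",
                "Ethyl dodecanoate",
                "Isoamyl acetate",
                "Ethyl octanoate",
                "Ethyl decanoate",
                "1-propanol",
                "Ethyl butanoate",
            ],
            loadings=[0.3857, 0.3494, 0.4000, 0.4157, 0.4122, 0.3231, 0.3492],
            betas={"N": 0.8544, "S²": -1.9078},
            noise_sd=noise_sd,
        ),
        ModuleSpec(
            members=["Ethanol", "Acetic acid", "Glycerol"],
            loadings=[0.5446, 0.6202, 0.5646],
            betas={"S": 1.3519, "I": -0.2347, "N×T": -0.2327, "S²": 0.3637},
            noise_sd=noise_sd,
        ),
        ModuleSpec(
            members=[
                "2-Phenylethanol",
                "Phenylethyl acetate",
                "1-butanol",
                "Amyl alcohol",
                "Isoamyl alcohol",
            ],
            loadings=[0.3658, 0.3737, 0.4725, 0.5063, 0.4969],
            betas={"N": -1.0532, "T": 0.6838, "S×I": 0.4231},
            noise_sd=noise_sd,
        ),
    ]


def default_dataset(
    seed: int | None = 42,
    noise_sd: float = DEFAULT_NOISE_SD,
    design_seed: int | None = None,
) -> SyntheticDataset:
    """Convenience: 31-run face-centered CCD + default truth simulation."""
    design = generate_ccd(k=4, alpha=1, n_center=7, seed=design_seed)
    return simulate_responses(design, default_truth(noise_sd), seed=seed)
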