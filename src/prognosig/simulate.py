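"""Synthetic PRECOG-like data generators.

Every input the evaluation pipeline consumes can be generated here with the
statistical structure the downstream analysis assumes:

* gene-by-cancer-type matrices of prognostic z-scores (with a Stouffer meta-z
  column) in which poor-outcome gene modules of controlled effect size can be
  planted in chosen cancer types;
* expression + survival cohorts in which a designated signature's expression
  separates a latent high-hazard group from a low-hazard group under
  proportional exponential hazards, with independent uniform censoring tuned
  to a target censor rate;
* random gene-set collections (GMT-style) with optional planted sets.

All generators are pure functions of their configuration, seed included:
repeated calls are byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .containers import GeneSetCollection, PrognosticScoreMatrix, SurvivalCohort

__all__ = [
    "ZScoreSimConfig",
    "CohortSimConfig",
    "PlantedModule",
    "generate_zscore_matrix",
    "generate_survival_cohort",
    "generate_geneset_collection",
    "gene_labels",
]


def gene_labels(n_genes: int, prefix: str = "G") -> list[str]:
    """Plain synthetic gene labels ``G000001`` ... ``G<n>``."""
    width = max(6, len(str(n_genes)))
    return [f"{prefix}{i + 1:0{width}d}" for i in range(n_genes)]


@dataclass(frozen=True)
class PlantedModule:
    """A poor-outcome gene module planted into a z-score matrix.

    Parameters
    ----------
    gene_indices
        Row indices of the module genes, subset of ``[0, n_genes)``.
    shift
        Additive z-score shift applied to the module genes (z units).
        Positive shifts mean association with poor outcome under this
        artifact's sign convention.
    cancer_types
        Labels of the affected cancer-type columns.
    """

    gene_indices: tuple[int, ...]
    shift: float
    cancer_types: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_indices", tuple(int(i) for i in self.gene_indices))
        object.__setattr__(self, "cancer_types", tuple(self.cancer_types))
        if not np.isfinite(self.shift):
            raise ValueError("module shift must be finite")


@dataclass(frozen=True)
class ZScoreSimConfig:
    """Configuration for a synthetic prognostic z-score matrix.

    Each column holds per-gene z-scores for one cancer type, drawn
    N(0, baseline_sd^2) with planted module shifts added; the ``meta_z``
    column combines the per-type columns by the Stouffer rule.
    """

    n_genes: int
    cancer_types: tuple[str, ...]
    planted_modules: tuple[PlantedModule, ...] = ()
    baseline_sd: float = 1.0
    seed: int = 0
    #: "stouffer" (unweighted, sum z / sqrt(k)) or explicit per-type weights
    meta_weights: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "cancer_types", tuple(self.cancer_types))
        object.__setattr__(self, "planted_modules", tuple(self.planted_modules))
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if len(set(self.cancer_types)) != len(self.cancer_types):
            raise ValueError("cancer_type labels must be unique")
        if not self.cancer_types:
            raise ValueError("at least one cancer type is required")
        if self.baseline_sd <= 0:
            raise ValueError("baseline_sd must be positive")
        for mod in self.planted_modules:
            bad = [i for i in mod.gene_indices if not 0 <= i < self.n_genes]
            if bad:
                raise ValueError(f"planted gene indices out of range: {bad[:5]}")
            unknown = set(mod.cancer_types) - set(self.cancer_types)
            if unknown:
                raise ValueError(f"planted module names unknown cancer types: {sorted(unknown)}")
        if self.meta_weights is not None and len(self.meta_weights) != len(self.cancer_types):
            raise ValueError("meta_weights length must match cancer_types")


def _check_module_conflicts(config: ZScoreSimConfig) -> None:
    # Two modules may not place different shifts on the same (gene, type) cell.
    seen: dict[tuple[int, str], float] = {}
    for mod in config.planted_modules:
        for t in mod.cancer_types:
            for g in mod.gene_indices:
                prev = seen.get((g, t))
                if prev is not None and prev != mod.shift:
                    raise ValueError(
                        f"conflicting planted shifts for gene index {g}, type {t!r}: "
                        f"{prev} vs {mod.shift}"
                    )
                seen[(g, t)] = mod.shift


def stouffer_meta_z(z: np.ndarray, weights: Sequence[float] | None = None) -> np.ndarray:
    """Combine per-type z-scores into a meta-z per gene (Stouffer's rule).

    Unweighted: ``sum_j z_j / sqrt(k)``. With weights w_j:
    ``sum_j w_j z_j / sqrt(sum_j w_j^2)``, which reduces to the unweighted
    form for equal weights.
    """
    z = np.asarray(z, dtype=float)
    if weights is None:
        return z.sum(axis=1) / np.sqrt(z.shape[1])
    w = np.asarray(weights, dtype=float)
    return z @ w / np.sqrt((w**2).sum())


def generate_zscore_matrix(config: ZScoreSimConfig) -> PrognosticScoreMatrix:
    """Draw a genes x cancer-types z-score matrix with planted modules.

    Baseline cells are N(0, baseline_sd^2); planted module genes get their
    shift added in the affected types. The meta_z column is the Stouffer
    combination of the per-type columns.
    """
    _check_module_conflicts(config)
    rng = np.random.default_rng(config.seed)
    k = len(config.cancer_types)
    z = rng.normal(0.0, config.baseline_sd, size=(config.n_genes, k))
    col_index = {t: j for j, t in enumerate(config.cancer_types)}
    for mod in config.planted_modules:
        idx = np.fromiter(mod.gene_indices, dtype=int)
        for t in mod.cancer_types:
            z[idx, col_index[t]] += mod.shift
    meta = stouffer_meta_z(z, config.meta_weights)
    genes = gene_labels(config.n_genes)
    scores = pd.DataFrame(z, index=genes, columns=list(config.cancer_types))
    scores["meta_z"] = meta
    return PrognosticScoreMatrix(scores)


@dataclass(frozen=True)
class CohortSimConfig:
    """Configuration for a synthetic expression + survival cohort.

    A latent high-risk group (Bernoulli ``high_risk_fraction``) has its
    signature-gene expression shifted upward — ``expression_shift`` is the
    *mean* shift; per-gene magnitudes vary uniformly over 0.5–1.5x that
    mean, as genes in a real module respond with different strengths — and
    its event hazard multiplied by ``hazard_ratio``; event times are
    exponential with rate ``baseline_hazard`` in the low-risk group. Censoring times are
    uniform on (0, tau) with tau solved so the expected censored fraction is
    ``censor_rate``; ``follow_up_horizon`` administratively censors any
    follow-up beyond it.
    """

    n_samples: int
    n_genes: int
    signature_indices: tuple[int, ...]
    hazard_ratio: float = 2.0
    high_risk_fraction: float = 0.5
    expression_shift: float = 1.0
    noise_sd: float = 1.0
    baseline_hazard: float = 0.1
    censor_rate: float = 0.3
    follow_up_horizon: float = float("inf")
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "signature_indices", tuple(int(i) for i in self.signature_indices)
        )
        if self.n_samples <= 0 or self.n_genes <= 0:
            raise ValueError("n_samples and n_genes must be positive")
        if not self.signature_indices:
            raise ValueError("signature_indices must be non-empty")
        bad = [i for i in self.signature_indices if not 0 <= i < self.n_genes]
        if bad:
            raise ValueError(f"signature indices out of range: {bad[:5]}")
        if not (np.isfinite(self.hazard_ratio) and self.hazard_ratio > 0):
            raise ValueError("hazard_ratio must be a positive finite real")
        if not 0 < self.high_risk_fraction < 1:
            raise ValueError("high_risk_fraction must lie in (0, 1)")
        if self.noise_sd <= 0 or self.baseline_hazard <= 0:
            raise ValueError("noise_sd and baseline_hazard must be positive")
        if not 0 <= self.censor_rate < 1:
            raise ValueError("censor_rate must lie in [0, 1)")
        if self.follow_up_horizon <= 0:
            raise ValueError("follow_up_horizon must be positive")


def _uniform_censor_scale(config: CohortSimConfig) -> float:
    """Solve for tau such that P(U(0,tau) < T) = censor_rate.

    T is the exponential mixture over risk groups:
    P(C < T) = pi * g(h1) + (1-pi) * g(h0) with g(h) = (1 - exp(-h tau)) / (h tau).
    Monotone decreasing in tau from 1 to 0, so a root exists for any
    censor_rate in (0, 1).
    """
    h0 = config.baseline_hazard
    h1 = h0 * config.hazard_ratio
    pi = config.high_risk_fraction
    target = config.censor_rate

    def g(h: float, tau: float) -> float:
        x = h * tau
        return -np.expm1(-x) / x

    def f(tau: float) -> float:
        return pi * g(h1, tau) + (1 - pi) * g(h0, tau) - target

    lo, hi = 1e-9 / h0, 1.0 / h0
    while f(hi) > 0:
        hi *= 2.0
        if hi > 1e12 / h0:  # pragma: no cover - unreachable for valid rates
            raise RuntimeError("failed to bracket censoring scale")
    return float(brentq(f, lo, hi, xtol=1e-12, rtol=1e-12))


def generate_survival_cohort(config: CohortSimConfig) -> SurvivalCohort:
    """Simulate an expression matrix with survival outcomes.

    Returns a cohort whose ``extras`` attribute records the latent risk group
    per sample (ground truth for recovery tests; never consumed by the
    analysis itself).
    """
    rng = np.random.default_rng(config.seed)
    n, g = config.n_samples, config.n_genes
    high = rng.random(n) < config.high_risk_fraction
    expr = rng.normal(0.0, config.noise_sd, size=(n, g))
    sig = np.fromiter(config.signature_indices, dtype=int)
    # per-gene shift magnitudes: mean expression_shift, heterogeneous across
    # the module (uniform 0.5-1.5x) as in a real co-regulated gene module
    gene_shifts = config.expression_shift * rng.uniform(0.5, 1.5, size=sig.size)
    expr[np.ix_(high, sig)] += gene_shifts

    hazards = np.where(high, config.baseline_hazard * config.hazard_ratio, config.baseline_hazard)
    event_times = rng.exponential(1.0, size=n) / hazards

    if config.censor_rate > 0:
        tau = _uniform_censor_scale(config)
        censor_times = rng.uniform(0.0, tau, size=n)
    else:
        censor_times = np.full(n, np.inf)
    censor_times = np.minimum(censor_times, config.follow_up_horizon)

    time = np.minimum(event_times, censor_times)
    event = (event_times <= censor_times).astype(int)
    # exponential times are a.s. positive but guard against float underflow
    time = np.maximum(time, np.finfo(float).tiny)

    sample_ids = [f"S{i + 1:05d}" for i in range(n)]
    genes = gene_labels(g)
    return SurvivalCohort(
        expression=pd.DataFrame(expr, index=sample_ids, columns=genes),
        time=pd.Series(time, index=sample_ids, name="time"),
        event=pd.Series(event, index=sample_ids, name="event"),
        extras={"high_risk": pd.Series(high, index=sample_ids, name="high_risk")},
    )


def generate_geneset_collection(
    n_sets: int,
    size_range: tuple[int, int],
    universe: Sequence[str],
    planted: Mapping[str, Sequence[str]] | None = None,
    seed: int = 0,
) -> GeneSetCollection:
    """Random gene sets drawn without replacement from ``universe``.

    Planted sets are included verbatim under their names; random sets are
    named ``RANDOM_0001`` onwards with sizes uniform over ``size_range``.
    """
    lo, hi = size_range
    if not 1 <= lo <= hi <= len(universe):
        raise ValueError(f"size_range {size_range} not within [1, {len(universe)}]")
    universe = list(universe)
    uniset = set(universe)
    rng = np.random.default_rng(seed)
    sets: dict[str, tuple[str, ...]] = {}
    descriptions: dict[str, str] = {}
    if planted:
        for name, genes in planted.items():
            outside = set(genes) - uniset
            if outside:
                raise ValueError(
                    f"planted set {name!r} contains labels outside the universe: "
                    f"{sorted(outside)[:5]}"
                )
            sets[name] = tuple(genes)
            descriptions[name] = "planted"
    width = max(4, len(str(n_sets)))
    for i in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(len(universe), size=size, replace=False)
        name = f"RANDOM_{i + 1:0{width}d}"
        sets[name] = tuple(universe[j] for j in sorted(members))
        descriptions[name] = "random"
    return GeneSetCollection(sets, descriptions)
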