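"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately re-derive quantities by brute force (explicit
running-sum walks, per-event-time hypergeometric risk tables via scipy's
hypergeom) so they stay independent of the implementation paths they check.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import prognosig as pg
from prognosig.containers import GeneSet, RankedGeneList


# ---------------------------------------------------------------- oracles

def brute_force_running_sum(scores: np.ndarray, hit_positions, p: float):
    """O(N) exact-rational running-sum oracle.

    A hit at rank i adds |score_i|^p / sum_hits |score|^p; a miss subtracts
    1/(N - n_hit). Computed with Fraction arithmetic, so the curve and its
    ties are exact. Returns the curve as a list of Fractions (length N).
    """
    from fractions import Fraction

    N = len(scores)
    hits = set(int(i) for i in hit_positions)
    n_hit = len(hits)
    weights = {i: Fraction(float(abs(scores[i]) ** p)) for i in hits}
    denom_hit = sum(weights.values())
    if denom_hit == 0:
        weights = {i: Fraction(1) for i in hits}
        denom_hit = Fraction(n_hit)
    miss_step = Fraction(1, N - n_hit) if n_hit < N else Fraction(0)
    running = Fraction(0)
    curve = []
    for i in range(N):
        if i in hits:
            running += weights[i] / denom_hit
        else:
            running -= miss_step
        curve.append(running)
    return curve


def brute_force_es(scores: np.ndarray, hit_positions, p: float):
    """ES and first-occurrence 1-based peak from the exact rational curve."""
    curve = brute_force_running_sum(scores, hit_positions, p)
    max_abs = max(abs(v) for v in curve)
    peak = next(i for i, v in enumerate(curve) if abs(v) == max_abs)
    return float(curve[peak]), peak + 1


def hypergeom_logrank(time, event, in_group_a):
    """Independent log-rank oracle built from scipy's hypergeometric moments.

    At each distinct event time the number of group-A deaths is, under the
    null, hypergeometric (population = at risk, successes = at risk in A,
    draws = total deaths); the chi-square accumulates observed-minus-mean
    over summed variances. Also returns the O/E hazard ratio.
    """
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    a = np.asarray(in_group_a, bool)
    O_a = E_a = V = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n, n_a = int(at_risk.sum()), int((at_risk & a).sum())
        d = int(((time == t) & (event == 1)).sum())
        d_a = int(((time == t) & (event == 1) & a).sum())
        hg = stats.hypergeom(M=n, n=n_a, N=d)
        O_a += d_a
        E_a += hg.mean()
        if d < n:  # everyone-at-risk-dies tables carry zero variance
            V += hg.var()
    chi2 = (O_a - E_a) ** 2 / V if V > 0 else 0.0
    p = float(stats.chi2.sf(chi2, 1)) if V > 0 else 1.0
    O_b = event.sum() - O_a
    E_b = event.sum() - E_a
    hr = (O_a / E_a) / (O_b / E_b) if min(O_b, E_a, E_b) > 0 else np.nan
    return chi2, p, hr


# ---------------------------------------------------------------- fixtures

@pytest.fixture(scope="session")
def small_ranked() -> RankedGeneList:
    """10 genes with scores 10..1, deterministic order g0..g9."""
    return RankedGeneList(
        pd.Series(np.arange(10, 0, -1, dtype=float), index=[f"g{i}" for i in range(10)])
    )


@pytest.fixture(scope="session")
def planted_matrix() -> pg.PrognosticScoreMatrix:
    """2,000 genes x 5 types with a 50-gene +3z module in every type."""
    module = pg.PlantedModule(tuple(range(50)), 3.0, ("T1", "T2", "T3", "T4", "T5"))
    cfg = pg.ZScoreSimConfig(
        n_genes=2000, cancer_types=("T1", "T2", "T3", "T4", "T5"),
        planted_modules=(module,), seed=42,
    )
    return pg.generate_zscore_matrix(cfg)


@pytest.fixture(scope="session")
def planted_collection(planted_matrix) -> pg.GeneSetCollection:
    universe = list(planted_matrix.gene_ids)
    return pg.generate_geneset_collection(
        50, (25, 100), universe, planted={"PLANTED": universe[:50]}, seed=7
    )


@pytest.fixture(scope="session")
def planted_cohort() -> pg.SurvivalCohort:
    """250 samples, 60-gene signature, planted hazard ratio 2.5."""
    cfg = pg.CohortSimConfig(
        n_samples=250, n_genes=300, signature_indices=tuple(range(60)),
        hazard_ratio=2.5, expression_shift=1.0, censor_rate=0.3, seed=11,
    )
    return pg.generate_survival_cohort(cfg)


@pytest.fixture(scope="session")
def signature_genes() -> list[str]:
    return [f"G{i + 1:06d}" for i in range(60)]


@pytest.fixture()
def gene_set_factory():
    def make(name: str, genes) -> GeneSet:
        return GeneSet(name, frozenset(genes))
    return make
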