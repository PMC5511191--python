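"""Survival arm: eligibility, LOOCV risk classification, KM, log-rank, HR.

A cohort is screened as follows: eligibility filters (enough annotated
cases, enough signature genes on the platform, death rate not extreme);
leave-one-out nearest-centroid classification of each sample into a high- or
low-risk group from its signature-gene expression (centroids are the mean
profiles of the deceased and surviving training samples); Kaplan–Meier
estimation per group; a two-group log-rank test with the hazard ratio taken
from the observed/expected event counts. A rank-sum comparison of cohort
sizes between significant and non-significant datasets quantifies the
cohort-size effect on statistical power.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import SurvivalCohort

__all__ = [
    "EligibilityRule",
    "EligibilityResult",
    "RiskClassification",
    "LogRankResult",
    "check_eligibility",
    "loocv_nearest_centroid",
    "kaplan_meier",
    "logrank_test",
    "cohort_size_effect",
    "run_survival_screen",
]

HIGH, LOW = "high_risk", "low_risk"
_EPS = 1e-12


@dataclass(frozen=True)
class EligibilityRule:
    """Dataset filters applied before any survival analysis.

    Defaults: at least 50 annotated cases, at least 25 signature genes
    measured, and a death rate inside [10%, 90%] (endpoints pass; only
    strictly more extreme rates fail).
    """

    min_samples: int = 50
    min_signature_genes: int = 25
    death_rate_bounds: tuple[float, float] = (0.10, 0.90)

    def __post_init__(self) -> None:
        lo, hi = self.death_rate_bounds
        if not 0 <= lo < hi <= 1:
            raise ValueError("death_rate_bounds must satisfy 0 <= lower < upper <= 1")


@dataclass(frozen=True)
class EligibilityResult:
    passed: bool
    reasons: tuple[str, ...]
    n_samples: int
    n_signature_genes: int
    death_rate: float


@dataclass(frozen=True)
class RiskClassification:
    """Per-sample risk labels with the distances that produced them."""

    labels: pd.Series  # "high_risk" / "low_risk" per sample
    distances: pd.DataFrame  # columns d_high, d_low
    n_ties: int = 0

    @property
    def high_risk_mask(self) -> pd.Series:
        return self.labels == HIGH


@dataclass(frozen=True)
class LogRankResult:
    chi_square: float
    p_value: float
    hazard_ratio: float
    observed: dict[str, float]
    expected: dict[str, float]


def check_eligibility(
    cohort: SurvivalCohort,
    signature_genes: "set[str] | frozenset[str] | list[str]",
    rule: EligibilityRule = EligibilityRule(),
) -> EligibilityResult:
    """Report (never raise) whether a cohort passes the screening filters."""
    n = cohort.n_samples
    n_sig = len(set(signature_genes) & set(cohort.gene_ids))
    dr = cohort.death_rate
    reasons = []
    if n < rule.min_samples:
        reasons.append("min_samples")
    if n_sig < rule.min_signature_genes:
        reasons.append("min_signature_genes")
    lo, hi = rule.death_rate_bounds
    if dr < lo or dr > hi:
        reasons.append("death_rate")
    return EligibilityResult(not reasons, tuple(reasons), n, n_sig, dr)


def _row_pearson_distance(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """1 - Pearson correlation between paired rows of a and b."""
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    na = np.linalg.norm(ac, axis=1)
    nb = np.linalg.norm(bc, axis=1)
    denom = na * nb
    corr = np.where(denom > _EPS, (ac * bc).sum(axis=1) / np.where(denom > _EPS, denom, 1.0), 0.0)
    return 1.0 - corr


def loocv_nearest_centroid(
    cohort: SurvivalCohort,
    signature_genes: "set[str] | frozenset[str] | list[str]",
    distance: str = "euclidean",
) -> RiskClassification:
    """Leave-one-out nearest-centroid risk labels from signature expression.

    For every sample, the per-gene means of the deceased (event = 1) and
    surviving (event = 0) *other* samples form two centroids over the
    signature genes; expression is z-scored per gene within that training
    remainder (refit at every fold, so the held-out sample never leaks into
    the standardisation), and the sample is labelled high-risk when it is
    nearer — under Euclidean (default), 1 − Pearson, or 1 − Spearman — to
    the deceased centroid. Distance ties go to low-risk. The Euclidean
    default acts on the z-scored profiles, so it is already insensitive to
    per-gene scale; the correlation metrics additionally discard any shift
    common to all signature genes, which can erase genuinely shared
    regulation.
    """
    if distance not in ("pearson", "euclidean", "spearman"):
        raise ValueError(f"unknown distance {distance!r}")
    genes = [g for g in cohort.gene_ids if g in set(signature_genes)]
    if not genes:
        raise ValueError("no signature gene present in the cohort expression matrix")
    X = cohort.expression[genes].to_numpy()
    n, g = X.shape
    ev = cohort.event.to_numpy().astype(float)
    n1, n0 = ev.sum(), (1 - ev).sum()
    if n1 < 2 or n0 < 2:
        raise ValueError(
            "cohort too small or unbalanced: every leave-one-out remainder needs "
            "at least one event and one non-event sample"
        )

    # remainder statistics for every fold at once
    S, Q = X.sum(axis=0), (X**2).sum(axis=0)
    M = (S - X) / (n - 1)  # remainder mean, per fold x gene
    V = (Q - X**2) / (n - 1) - M**2
    sd = np.sqrt(np.clip(V, 0.0, None))
    sd = np.where(sd > _EPS, sd, 1.0)  # constant gene in remainder: leave unscaled

    S1 = (X * ev[:, None]).sum(axis=0)
    S0 = S - S1
    C1 = (S1 - ev[:, None] * X) / (n1 - ev)[:, None]
    C0 = (S0 - (1 - ev)[:, None] * X) / (n0 - (1 - ev))[:, None]

    Z = (X - M) / sd
    Z1 = (C1 - M) / sd
    Z0 = (C0 - M) / sd

    if distance == "euclidean":
        # squared distance minus the centroid sampling-variance term g/m_k:
        # an unbiased estimate of the distance to the class *mean*, so a
        # sample's own class size (which depends on its event status through
        # the leave-one-out exclusion) does not bias its label
        m1 = n1 - ev
        m0 = n0 - (1 - ev)
        d1 = ((Z - Z1) ** 2).sum(axis=1) - g / m1
        d0 = ((Z - Z0) ** 2).sum(axis=1) - g / m0
    else:
        if distance == "spearman":
            Z = stats.rankdata(Z, axis=1)
            Z1 = stats.rankdata(Z1, axis=1)
            Z0 = stats.rankdata(Z0, axis=1)
        d1 = _row_pearson_distance(Z, Z1)
        d0 = _row_pearson_distance(Z, Z0)

    high = d1 < d0  # ties -> low risk (conservative)
    n_ties = int((d1 == d0).sum())
    labels = pd.Series(np.where(high, HIGH, LOW), index=cohort.sample_ids, name="risk")
    dist = pd.DataFrame({"d_high": d1, "d_low": d0}, index=cohort.sample_ids)
    return RiskClassification(labels, dist, n_ties)


def kaplan_meier(time, event) -> pd.DataFrame:
    """Kaplan–Meier estimate of the survival function.

    Returns one row per distinct event time with columns ``n_at_risk``,
    ``n_events``, ``n_censored`` (censorings in (previous, current] leave
    the risk set) and ``survival`` = prod(1 - d_i/n_i). With no censoring
    this equals the empirical survival function exactly.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if np.any(time <= 0):
        raise ValueError("follow-up times must be positive")
    if event.sum() == 0:
        warnings.warn("no events observed: survival estimate is identically 1", stacklevel=2)
        return pd.DataFrame(
            columns=["time", "n_at_risk", "n_events", "n_censored", "survival"]
        ).astype({"time": float, "survival": float})
    order = np.argsort(time, kind="mergesort")
    t, e = time[order], event[order]
    event_times = np.unique(t[e == 1])
    rows = []
    surv = 1.0
    for et in event_times:
        at_risk = int((t >= et).sum())
        d = int(((t == et) & (e == 1)).sum())
        c = int(((t == et) & (e == 0)).sum())
        surv *= 1.0 - d / at_risk
        rows.append((et, at_risk, d, c, surv))
    return pd.DataFrame(rows, columns=["time", "n_at_risk", "n_events", "n_censored", "survival"])


def logrank_test(time, event, labels, high_label: str = HIGH) -> LogRankResult:
    """Two-group log-rank test with an O/E hazard ratio.

    At each distinct event time a 2x2 risk table contributes the high-risk
    group's observed and (hypergeometric) expected event counts and
    variance; chi-square = (O - E)^2 / Var with 1 df. The hazard ratio is
    (O_high/E_high)/(O_low/E_low), the classical O/E estimate.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    labels = np.asarray(labels)
    groups = pd.unique(labels)
    if len(groups) != 2:
        raise ValueError(f"exactly two non-empty groups required, got {list(groups)}")
    if high_label not in groups:
        raise ValueError(f"label {high_label!r} absent from groups {list(groups)}")
    in_high = labels == high_label

    event_times = np.unique(time[event == 1])
    O_h = E_h = var = 0.0
    for et in event_times:
        at_risk = time >= et
        n_j = at_risk.sum()
        n_hj = (at_risk & in_high).sum()
        dying = (time == et) & (event == 1)
        d_j = dying.sum()
        d_hj = (dying & in_high).sum()
        O_h += d_hj
        E_h += d_j * n_hj / n_j
        if n_j > 1:
            var += d_j * (n_hj / n_j) * (1 - n_hj / n_j) * (n_j - d_j) / (n_j - 1)
    O_total = float(event.sum())
    O_l = O_total - O_h
    E_l = O_total - E_h

    if var > 0:
        chi2 = (O_h - E_h) ** 2 / var
        p = float(stats.chi2.sf(chi2, df=1))
    else:
        chi2, p = 0.0, 1.0
    if O_l > 0 and E_h > 0 and E_l > 0:
        hr = (O_h / E_h) / (O_l / E_l)
    elif O_h == 0 and O_l == 0:
        hr = 1.0
    else:
        hr = np.inf if O_l == 0 or E_h == 0 else 0.0
    return LogRankResult(
        float(chi2), p, float(hr),
        observed={HIGH: float(O_h), LOW: float(O_l)},
        expected={HIGH: float(E_h), LOW: float(E_l)},
    )


def cohort_size_effect(per_dataset: "list[tuple[int, float]]", alpha: float = 0.05):
    """Rank-sum comparison of cohort sizes, significant vs not.

    ``per_dataset`` holds (n_samples, log-rank p) pairs. Returns the
    two-sided Wilcoxon rank-sum p-value (exact for combined n <= 20 without
    ties, otherwise normal approximation with tie correction) for a shift in
    cohort size between datasets with p < alpha and the rest.
    """
    sizes = np.array([n for n, _ in per_dataset], dtype=float)
    pvals = np.array([p for _, p in per_dataset], dtype=float)
    sig = sizes[pvals < alpha]
    non = sizes[pvals >= alpha]
    if sig.size == 0 or non.size == 0:
        raise ValueError("both significant and non-significant datasets are required")
    n_comb = sig.size + non.size
    has_ties = len(np.unique(np.concatenate([sig, non]))) < n_comb
    method = "exact" if (n_comb <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        sig, non, alternative="two-sided", method=method, use_continuity=False
    )
    return float(res.pvalue)


def run_survival_screen(
    datasets: "list[SurvivalCohort]",
    signature_genes: "set[str] | frozenset[str] | list[str]",
    rule: EligibilityRule = EligibilityRule(),
    alpha: float = 0.05,
    distance: str = "euclidean",
    size_thresholds: tuple[int, ...] = (0, 100, 150, 200),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full eligibility → LOOCV → log-rank chain over many cohorts.

    Per-dataset failures (ineligibility, infeasible LOOCV) are recorded in
    the screen table, never raised. Returns ``(screen, summary)``: one row
    per dataset (eligible, n, death_rate, p, HR, significant, note) and the
    count/proportion of significant datasets at each cohort-size threshold.
    """
    rows = []
    for cohort in datasets:
        elig = check_eligibility(cohort, signature_genes, rule)
        row = dict(
            dataset=cohort.name, eligible=elig.passed, n=elig.n_samples,
            death_rate=elig.death_rate, p=np.nan, hazard_ratio=np.nan,
            significant=False, note=";".join(elig.reasons),
        )
        if elig.passed:
            try:
                risk = loocv_nearest_centroid(cohort, signature_genes, distance)
                if risk.labels.nunique() < 2:
                    row["note"] = "single_risk_group"
                else:
                    lr = logrank_test(cohort.time, cohort.event, risk.labels)
                    row.update(p=lr.p_value, hazard_ratio=lr.hazard_ratio,
                               significant=bool(lr.p_value < alpha))
            except ValueError as exc:
                row["note"] = f"loocv_failed:{exc}"
        rows.append(row)
    screen = pd.DataFrame(rows)

    tested = screen[screen["eligible"] & screen["p"].notna()]
    summary_rows = []
    for thr in size_thresholds:
        sub = tested[tested["n"] >= thr]
        n_t, n_s = len(sub), int(sub["significant"].sum())
        summary_rows.append(dict(
            min_n=thr, n_datasets=n_t, n_significant=n_s,
            proportion=(n_s / n_t) if n_t else np.nan,
        ))
    summary = pd.DataFrame(summary_rows)
    return screen, summary
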