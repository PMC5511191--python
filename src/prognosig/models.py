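"""Model/Results facades over the functional pipeline.

Two estimators in the statsmodels mould: construct a model from data, call
``fit()``, get a results object carrying the estimates and a ``summary()``
table, with plotting hanging off the results.

``PrerankedGSEA`` scores a gene-set collection against one ranking column of
a prognostic z-score matrix. ``SignatureSurvivalModel`` classifies a cohort
into risk groups from a signature's expression and tests the survival
difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import enrichment as _enr
from . import ranking as _rank
from . import robustness as _rob
from . import survival as _surv
from .containers import GeneSetCollection, PrognosticScoreMatrix, SurvivalCohort

__all__ = ["PrerankedGSEA", "EnrichmentResults", "SignatureSurvivalModel", "SurvivalResults"]


class PrerankedGSEA:
    """Preranked gene-set enrichment of a collection against one ranking.

    Parameters
    ----------
    matrix
        Prognostic z-score matrix (genes x cancer types + meta_z).
    collection
        Gene sets to score.
    column
        Ranking column: a cancer type or ``"meta_z"`` (default).
    config
        Permutation count, weight exponent, filters, seed.
    """

    def __init__(
        self,
        matrix: PrognosticScoreMatrix,
        collection: GeneSetCollection,
        column: str = "meta_z",
        config: _enr.EnrichmentRunConfig | None = None,
    ):
        self.matrix = matrix
        self.collection = collection
        self.column = column
        self.config = config or _enr.EnrichmentRunConfig()

    def fit(self) -> "EnrichmentResults":
        table = _enr.run_preranked(self.matrix, self.collection, self.column, self.config)
        return EnrichmentResults(self, table)

    @classmethod
    def from_files(cls, scores_path, gmt_path, column: str = "meta_z", **config_kwargs):
        from . import io
        config = _enr.EnrichmentRunConfig(**config_kwargs) if config_kwargs else None
        return cls(io.read_score_matrix(scores_path), io.read_gmt(gmt_path), column, config)


@dataclass
class EnrichmentResults:
    """Fitted enrichment run: one row per surviving gene set."""

    model: PrerankedGSEA
    table: pd.DataFrame

    @property
    def n_filtered(self) -> int:
        return self.table.attrs.get("n_filtered", 0)

    def significant(self, alpha: float | None = None) -> pd.DataFrame:
        alpha = alpha if alpha is not None else self.model.config.significance_alpha
        return self.table[self.table["p_fwer"] < alpha]

    def rank_signatures(self, alpha: float | None = None) -> pd.DataFrame:
        alpha = alpha if alpha is not None else self.model.config.significance_alpha
        return _rank.rank_signatures(self.table, alpha)

    def summary(self, top: int = 20) -> str:
        cfg = self.model.config
        head = self.table.sort_values("NES", ascending=False).head(top)
        lines = [
            "Preranked enrichment results",
            "=" * 60,
            f"ranking column:     {self.model.column}",
            f"ranked genes (N):   {self.table.attrs.get('N', 'n/a')}",
            f"sets scored:        {len(self.table)}"
            f"  (filtered out: {self.n_filtered} below {cfg.min_known_genes} known genes)",
            f"permutations:       {cfg.n_permutations} (seed {cfg.seed}, p = {cfg.weight_exponent})",
            f"significant (FWER < {cfg.significance_alpha}): {len(self.significant())}",
            "",
            head[["n_known", "ES", "NES", "p_fwer", "tag", "list", "signal"]]
            .to_string(float_format=lambda v: f"{v:.4f}"),
        ]
        return "\n".join(lines)

    def plot_enrichment(self, set_name: str, ax=None):
        """Running-sum enrichment curve for one gene set."""
        import matplotlib.pyplot as plt

        ranked = _enr.build_ranked_list(self.model.matrix, self.model.column)
        gs = self.model.collection[set_name]
        es, peak, curve = _enr.enrichment_score(ranked, gs, self.model.config.weight_exponent)
        if ax is None:
            _, ax = plt.subplots(figsize=(6, 3))
        ax.plot(np.arange(1, ranked.N + 1), curve, color="green")
        ax.axhline(0.0, color="grey", lw=0.5)
        ax.axvline(peak, color="red", ls="--", lw=0.8)
        hits = ranked.positions_of(gs.genes) + 1
        ax.plot(hits, np.full(hits.size, curve.min() - 0.02), "|", color="black", ms=6)
        ax.set_xlabel("rank in gene list")
        ax.set_ylabel("running enrichment score")
        ax.set_title(f"{set_name}: ES={es:.3f}, peak={peak}")
        return ax


class SignatureSurvivalModel:
    """Risk stratification of one cohort by one signature's expression.

    ``fit()`` runs eligibility checks, leave-one-out nearest-centroid
    classification and the two-group log-rank test; the results object
    carries the labels, KM curves, chi-square, p and O/E hazard ratio.
    """

    def __init__(
        self,
        cohort: SurvivalCohort,
        signature_genes: "set[str] | list[str]",
        distance: str = "euclidean",
        rule: _surv.EligibilityRule = _surv.EligibilityRule(),
    ):
        self.cohort = cohort
        self.signature_genes = frozenset(signature_genes)
        self.distance = distance
        self.rule = rule

    @classmethod
    def from_files(cls, expr_path, clinical_path, signature_path, **kwargs):
        from . import io
        cohort = io.read_cohort(expr_path, clinical_path)
        return cls(cohort, io.read_signature(signature_path), **kwargs)

    def fit(self, enforce_eligibility: bool = True) -> "SurvivalResults":
        elig = _surv.check_eligibility(self.cohort, self.signature_genes, self.rule)
        if enforce_eligibility and not elig.passed:
            raise ValueError(
                f"cohort {self.cohort.name!r} fails eligibility: {', '.join(elig.reasons)}"
            )
        risk = _surv.loocv_nearest_centroid(self.cohort, self.signature_genes, self.distance)
        logrank = _surv.logrank_test(self.cohort.time, self.cohort.event, risk.labels)
        return SurvivalResults(self, elig, risk, logrank)


@dataclass
class SurvivalResults:
    """Fitted survival stratification for one cohort."""

    model: SignatureSurvivalModel
    eligibility: _surv.EligibilityResult
    risk: _surv.RiskClassification
    logrank: _surv.LogRankResult

    @property
    def p_value(self) -> float:
        return self.logrank.p_value

    @property
    def hazard_ratio(self) -> float:
        return self.logrank.hazard_ratio

    def km_curves(self) -> dict[str, pd.DataFrame]:
        out = {}
        for label in (_surv.HIGH, _surv.LOW):
            mask = (self.risk.labels == label).to_numpy()
            if mask.any():
                out[label] = _surv.kaplan_meier(
                    self.model.cohort.time[mask], self.model.cohort.event[mask]
                )
        return out

    def robustness(self, config: _rob.RobustnessConfig | None = None) -> pd.DataFrame:
        return _rob.robustness_analysis(
            self.model.cohort, self.model.signature_genes,
            config or _rob.RobustnessConfig(distance=self.model.distance),
        )

    def summary(self) -> str:
        n_high = int(self.risk.high_risk_mask.sum())
        n = self.model.cohort.n_samples
        lines = [
            "Signature survival stratification",
            "=" * 60,
            f"cohort:            {self.model.cohort.name} (n = {n})",
            f"signature genes:   {self.eligibility.n_signature_genes} present",
            f"death rate:        {self.eligibility.death_rate:.3f}",
            f"eligible:          {self.eligibility.passed}"
            + (f" (failed: {', '.join(self.eligibility.reasons)})"
               if self.eligibility.reasons else ""),
            f"risk groups:       high = {n_high}, low = {n - n_high}"
            + (f" ({self.risk.n_ties} distance ties -> low risk)" if self.risk.n_ties else ""),
            f"log-rank chi2:     {self.logrank.chi_square:.4f}",
            f"log-rank p:        {self.logrank.p_value:.4g}",
            f"hazard ratio (O/E): {self.logrank.hazard_ratio:.4f}",
            f"observed events:   high = {self.logrank.observed['high_risk']:.0f}, "
            f"low = {self.logrank.observed['low_risk']:.0f}",
            f"expected events:   high = {self.logrank.expected['high_risk']:.2f}, "
            f"low = {self.logrank.expected['low_risk']:.2f}",
        ]
        return "\n".join(lines)

    def plot_km(self, ax=None):
        """Kaplan–Meier curves for the two risk groups."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 4))
        colors = {_surv.HIGH: "tab:red", _surv.LOW: "tab:blue"}
        for label, km in self.km_curves().items():
            t = np.concatenate([[0.0], km["time"].to_numpy()])
            s = np.concatenate([[1.0], km["survival"].to_numpy()])
            ax.step(t, s, where="post", label=label, color=colors[label])
        ax.set_xlabel("time")
        ax.set_ylabel("survival probability")
        ax.set_ylim(0, 1.02)
        ax.legend()
        ax.set_title(
            f"{self.model.cohort.name}: p = {self.p_value:.3g}, HR = {self.hazard_ratio:.2f}"
        )
        return ax
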