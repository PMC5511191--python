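"""Ranking competing signatures and counting per-type coverage.

Among the significantly enriched sets of one run, each signature is ranked
on four metrics — NES (descending), tag (descending; sensitivity), list
(ascending; lower list means purer enrichment), signal (descending) — and
scored by the arithmetic mean of the four ranks. Coverage counts, for one
signature, the cancer types in which it is significantly enriched, split by
whether the type itself has many or few outcome-associated genes.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .containers import PrognosticScoreMatrix

__all__ = [
    "mean_rank_score",
    "rank_signatures",
    "count_outcome_genes",
    "split_types_by_content",
    "type_coverage",
]

METRIC_ORIENTATION = {"NES": False, "tag": False, "list": True, "signal": False}


def mean_rank_score(ranks: "list[float] | tuple[float, ...] | np.ndarray") -> float:
    """Arithmetic mean of a signature's four per-metric ranks."""
    return float(np.mean(np.asarray(ranks, dtype=float)))


def rank_signatures(results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Leaderboard of significantly enriched sets by mean metric rank.

    Restricts to sets with ``p_fwer < alpha``, ranks each of NES/tag/list/
    signal (min-rank on ties, i.e. competition ranking), and orders by the
    mean of the four ranks. Returns columns rank_nes, rank_tag, rank_list,
    rank_signal, mean_rank_score, overall_rank; empty (with a warning) when
    nothing is significant.
    """
    sig = results[results["p_fwer"] < alpha].copy()
    sig = sig[~sig["NES"].isna()]
    if sig.empty:
        warnings.warn(f"no set significant at FWER < {alpha}", stacklevel=2)
        return pd.DataFrame(
            columns=["rank_nes", "rank_tag", "rank_list", "rank_signal",
                     "mean_rank_score", "overall_rank"]
        )
    out = pd.DataFrame(index=sig.index)
    for metric, ascending in METRIC_ORIENTATION.items():
        out[f"rank_{metric.lower()}"] = (
            sig[metric].rank(method="min", ascending=ascending).astype(int)
        )
    out.rename(columns={"rank_nes": "rank_nes"}, inplace=True)
    out["mean_rank_score"] = out[
        ["rank_nes", "rank_tag", "rank_list", "rank_signal"]
    ].mean(axis=1)
    out = out.sort_values(["mean_rank_score", "rank_nes"], kind="mergesort")
    out["overall_rank"] = (
        out["mean_rank_score"].rank(method="min", ascending=True).astype(int)
    )
    return out


def count_outcome_genes(
    scores: pd.Series, q_threshold: float = 0.05
) -> int:
    """Number of outcome-associated genes in one z-score column.

    Converts each z to a two-sided normal p-value, applies Benjamini–
    Hochberg, and counts genes with adjusted Q below the threshold. Missing
    z-scores (genes not evaluated in that type) are skipped.
    """
    z = scores.dropna().to_numpy(dtype=float)
    if z.size == 0:
        return 0
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    q = stats.false_discovery_control(pvals, method="bh")
    return int((q < q_threshold).sum())


def split_types_by_content(
    matrix: PrognosticScoreMatrix,
    gene_count_threshold: int = 10,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Partition cancer types by their outcome-associated gene content.

    Types with at least ``gene_count_threshold`` genes at Q < q_threshold
    are labelled ``high_content``, the rest ``low_content``. Returns a
    DataFrame indexed by type with columns ``n_outcome_genes`` and ``group``.
    """
    rows = {}
    for t in matrix.cancer_types:
        n = count_outcome_genes(matrix.column(t), q_threshold)
        rows[t] = {"n_outcome_genes": n,
                   "group": "high_content" if n >= gene_count_threshold else "low_content"}
    return pd.DataFrame.from_dict(rows, orient="index")


def type_coverage(
    per_type_results: dict[str, pd.DataFrame],
    signature_name: str,
    alpha: float = 0.05,
    content_groups: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-cancer-type enrichment flags for one signature.

    ``per_type_results`` maps each cancer type to the result table of a
    preranked run on that type's column. A type is covered when the
    signature's FWER p there is below ``alpha``. Returns a DataFrame indexed
    by type with columns ``enriched`` (bool), ``p_fwer`` and, when
    ``content_groups`` is given, the type's content ``group``; the covered
    count is in ``df.attrs["covered_types"]``.
    """
    rows = {}
    for t in sorted(per_type_results):
        table = per_type_results[t]
        if signature_name not in table.index:
            raise KeyError(
                f"signature {signature_name!r} absent from the enrichment run for type {t!r}"
            )
        p = float(table.loc[signature_name, "p_fwer"])
        rows[t] = {"enriched": bool(p < alpha), "p_fwer": p}
    out = pd.DataFrame.from_dict(rows, orient="index")
    if content_groups is not None:
        missing = set(out.index) - set(content_groups.index)
        if missing:
            raise KeyError(f"types missing from content grouping: {sorted(missing)}")
        out["group"] = content_groups.loc[out.index, "group"]
    out.attrs["covered_types"] = int(out["enriched"].sum())
    out.attrs["signature"] = signature_name
    return out
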