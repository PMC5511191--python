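"""Core data containers shared across the pipeline.

Thin, validated wrappers around pandas objects: a prognostic z-score matrix
(genes x cancer types plus a meta-z column), a named gene-set collection, a
ranked gene list, and an expression + survival cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PrognosticScoreMatrix",
    "GeneSet",
    "GeneSetCollection",
    "RankedGeneList",
    "SurvivalCohort",
]

META_Z = "meta_z"


class PrognosticScoreMatrix:
    """Genes x cancer-type prognostic z-scores with a meta-z column.

    Rows are genes (unique labels), columns are cancer types plus the
    reserved ``meta_z`` column. Positive z means higher expression associates
    with poorer outcome in that type (this artifact's sign convention).
    Missing values are permitted (a gene not evaluated in some type) and are
    excluded when a ranking is built.
    """

    def __init__(self, scores: pd.DataFrame):
        if scores.index.has_duplicates:
            dupes = scores.index[scores.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dupes[:5]}")
        if scores.shape[1] < 1:
            raise ValueError("at least one score column is required")
        with np.errstate(invalid="ignore"):
            if np.isinf(scores.to_numpy(dtype=float, na_value=np.nan)).any():
                raise ValueError("scores must be finite (NaN allowed for missing)")
        self._scores = scores.astype(float)
        self._scores.index.name = "gene"

    @property
    def gene_ids(self) -> pd.Index:
        return self._scores.index

    @property
    def cancer_types(self) -> list[str]:
        return [c for c in self._scores.columns if c != META_Z]

    @property
    def columns(self) -> list[str]:
        return list(self._scores.columns)

    @property
    def frame(self) -> pd.DataFrame:
        return self._scores

    def column(self, name: str) -> pd.Series:
        if name not in self._scores.columns:
            raise KeyError(
                f"unknown score column {name!r}; available: {list(self._scores.columns)}"
            )
        return self._scores[name]

    def __repr__(self) -> str:
        return (
            f"PrognosticScoreMatrix({len(self.gene_ids)} genes x "
            f"{len(self.cancer_types)} types, meta_z={'yes' if META_Z in self._scores else 'no'})"
        )


@dataclass(frozen=True)
class GeneSet:
    """A named gene set with provenance."""

    name: str
    genes: frozenset[str]
    source: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", frozenset(self.genes))
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.genes)


class GeneSetCollection:
    """An ordered collection of uniquely named gene sets (GMT-backed)."""

    def __init__(
        self,
        sets: Mapping[str, Sequence[str]],
        descriptions: Mapping[str, str] | None = None,
    ):
        self._sets: dict[str, GeneSet] = {}
        descriptions = descriptions or {}
        for name, genes in sets.items():
            if name in self._sets:
                raise ValueError(f"duplicate gene set name {name!r}")
            self._sets[name] = GeneSet(name, frozenset(genes), descriptions.get(name, ""))

    def __len__(self) -> int:
        return len(self._sets)

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self._sets.values())

    def __contains__(self, name: str) -> bool:
        return name in self._sets

    def __getitem__(self, name: str) -> GeneSet:
        return self._sets[name]

    @property
    def names(self) -> list[str]:
        return list(self._sets)

    def subset(self, names: Sequence[str]) -> "GeneSetCollection":
        return GeneSetCollection(
            {n: sorted(self._sets[n].genes) for n in names},
            {n: self._sets[n].source for n in names},
        )


class RankedGeneList:
    """Genes ordered by decreasing score.

    Ties are broken by gene label (lexicographic, ascending) so the ranking
    is fully deterministic across platforms. Genes with missing scores are
    excluded at construction and recorded in ``dropped``.
    """

    def __init__(self, scores: pd.Series, *, _presorted: bool = False):
        scores = scores.astype(float)
        dropped = scores.index[scores.isna()]
        scores = scores.dropna()
        if scores.index.has_duplicates:
            raise ValueError("duplicate gene ids in ranking input")
        if not _presorted:
            order = pd.DataFrame({"s": -scores.to_numpy(), "g": scores.index})
            idx = order.sort_values(["s", "g"], kind="mergesort").index
            scores = scores.iloc[idx]
        self._scores = scores
        self.dropped: list[str] = list(dropped)

    @property
    def gene_ids(self) -> pd.Index:
        return self._scores.index

    @property
    def scores(self) -> np.ndarray:
        return self._scores.to_numpy()

    @property
    def N(self) -> int:
        return len(self._scores)

    def positions_of(self, genes: frozenset[str] | set[str]) -> np.ndarray:
        """0-based rank positions of the given genes present in the list, sorted."""
        mask = self._scores.index.isin(genes)
        return np.flatnonzero(mask)

    def __len__(self) -> int:
        return self.N

    def __repr__(self) -> str:
        return f"RankedGeneList(N={self.N}, top={self._scores.index[0]!r})"


class SurvivalCohort:
    """Expression matrix plus per-sample survival records.

    ``expression`` is samples x genes; ``time`` (positive follow-up times)
    and ``event`` (1 = death/metastasis, 0 = censored) are aligned to the
    expression index.
    """

    def __init__(
        self,
        expression: pd.DataFrame,
        time: pd.Series,
        event: pd.Series,
        name: str = "cohort",
        extras: dict | None = None,
    ):
        if expression.index.has_duplicates:
            raise ValueError("duplicate sample ids")
        if not (len(expression) == len(time) == len(event)):
            raise ValueError("expression, time and event must have equal length")
        if not (expression.index.equals(time.index) and expression.index.equals(event.index)):
            raise ValueError("time/event index must match expression sample ids")
        if not np.isfinite(expression.to_numpy(dtype=float)).all():
            raise ValueError("expression must be finite")
        time = time.astype(float)
        if not ((time > 0) & np.isfinite(time)).all():
            raise ValueError("follow-up times must be positive and finite")
        ev = event.astype(float)
        if not np.isin(ev.to_numpy(), (0.0, 1.0)).all():
            raise ValueError("event indicator must be 0 or 1")
        self.expression = expression.astype(float)
        self.expression.index.name = "sample_id"
        self.time = time
        self.event = ev.astype(int)
        self.name = name
        self.extras = extras or {}

    @property
    def sample_ids(self) -> pd.Index:
        return self.expression.index

    @property
    def gene_ids(self) -> pd.Index:
        return self.expression.columns

    @property
    def n_samples(self) -> int:
        return len(self.expression)

    @property
    def death_rate(self) -> float:
        return float(self.event.mean())

    def select_samples(self, sample_ids: Sequence[str], name: str | None = None) -> "SurvivalCohort":
        idx = pd.Index(sample_ids)
        return SurvivalCohort(
            self.expression.loc[idx],
            self.time.loc[idx],
            self.event.loc[idx],
            name=name or self.name,
        )

    def __repr__(self) -> str:
        return (
            f"SurvivalCohort({self.name!r}: {self.n_samples} samples x "
            f"{len(self.gene_ids)} genes, death rate {self.death_rate:.2f})"
        )
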