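"""Readers and writers for the pipeline's plain-text formats.

GMT for gene-set collections, RNK for ranked lists, TSV for score matrices,
expression matrices, clinical tables and result reports. Floats are
serialised with 17 significant digits (``repr``-exact) so every write/read
round-trip is lossless.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time as _time
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import GeneSetCollection, PrognosticScoreMatrix, RankedGeneList, SurvivalCohort

__all__ = [
    "read_gmt", "write_gmt",
    "read_score_matrix", "write_score_matrix",
    "read_cohort", "write_cohort",
    "read_rnk", "write_rnk",
    "read_signature", "write_table",
    "RunManifest",
]

log = logging.getLogger("prognosig")

FLOAT_FMT = "%.17g"


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: one set per line — name, description, genes.

    Duplicate genes within a set are deduplicated with a warning; duplicate
    set names are an error.
    """
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields "
                    f"(name, description, genes), got {len(fields)}"
                )
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            unique = list(dict.fromkeys(genes))
            if len(unique) < len(genes):
                log.warning(
                    "%s:%d: set %r has %d duplicate gene entries (deduplicated)",
                    path, lineno, name, len(genes) - len(unique),
                )
            sets[name] = unique
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for gs in collection:
            fh.write("\t".join([gs.name, gs.source or "na", *sorted(gs.genes)]) + "\n")


def write_score_matrix(matrix: PrognosticScoreMatrix, path) -> None:
    matrix.frame.to_csv(path, sep="\t", index_label="gene", float_format=FLOAT_FMT)


def read_score_matrix(path) -> PrognosticScoreMatrix:
    df = pd.read_csv(path, sep="\t", index_col="gene", float_precision="round_trip")
    return PrognosticScoreMatrix(df)


def write_rnk(ranked: RankedGeneList, path) -> None:
    pd.Series(ranked.scores, index=ranked.gene_ids).to_csv(
        path, sep="\t", header=False, float_format=FLOAT_FMT
    )


def read_rnk(path) -> RankedGeneList:
    s = pd.read_csv(path, sep="\t", header=None, index_col=0, float_precision="round_trip").iloc[:, 0]
    s.index.name = "gene"
    return RankedGeneList(s)


def write_cohort(cohort: SurvivalCohort, expr_path, clinical_path) -> None:
    cohort.expression.to_csv(
        expr_path, sep="\t", index_label="sample_id", float_format=FLOAT_FMT
    )
    clin = pd.DataFrame({
        "sample_id": cohort.sample_ids,
        "time": cohort.time.to_numpy(),
        "event": cohort.event.to_numpy(),
    })
    clin.to_csv(clinical_path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_cohort(expr_path, clinical_path, name: str | None = None) -> SurvivalCohort:
    """Load and align an expression TSV with its clinical table.

    Samples present in only one of the two files are dropped with a log
    message; missing/invalid clinical values are errors.
    """
    expr = pd.read_csv(expr_path, sep="\t", index_col="sample_id", float_precision="round_trip")
    clin = pd.read_csv(clinical_path, sep="\t", float_precision="round_trip")
    required = {"sample_id", "time", "event"}
    missing = required - set(clin.columns)
    if missing:
        raise ValueError(f"{clinical_path}: missing clinical columns {sorted(missing)}")
    clin = clin.set_index("sample_id")
    if clin[["time", "event"]].isna().any().any():
        raise ValueError(f"{clinical_path}: missing values in time/event are not permitted")
    if not pd.api.types.is_numeric_dtype(clin["time"]):
        raise ValueError(f"{clinical_path}: non-numeric time column")
    if not np.isin(clin["event"].to_numpy(), (0, 1)).all():
        raise ValueError(f"{clinical_path}: event indicator must be 0 or 1")
    common = expr.index.intersection(clin.index)
    if len(common) == 0:
        raise ValueError("no sample id shared between expression and clinical tables")
    dropped = len(expr.index.symmetric_difference(clin.index))
    if dropped:
        log.info("read_cohort: dropped %d samples present in only one file", dropped)
    common = expr.index[expr.index.isin(common)]  # preserve expression order
    return SurvivalCohort(
        expr.loc[common],
        clin.loc[common, "time"].astype(float),
        clin.loc[common, "event"].astype(int),
        name=name or Path(str(expr_path)).stem,
    )


def read_signature(path) -> list[str]:
    """One-column gene list (one gene per line, blanks ignored)."""
    with open(path) as fh:
        genes = [line.strip() for line in fh if line.strip()]
    if not genes:
        raise ValueError(f"{path}: empty signature file")
    return list(dict.fromkeys(genes))


def write_table(df: pd.DataFrame, path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FMT)


class RunManifest:
    """Reproducibility record for one pipeline run.

    Captures the full configuration snapshot (thresholds, seeds, metric
    choices), SHA-256 digests of every input file, the package version and a
    timestamp — enough to re-run any stage byte-identically.
    """

    def __init__(self, config: dict, version: str):
        self.config = config
        self.version = version
        self.inputs: dict[str, str] = {}
        self.timestamp = _time.strftime("%Y-%m-%dT%H:%M:%S%z")

    def add_input(self, label: str, path) -> None:
        digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()
        self.inputs[label] = f"sha256:{digest}"

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "timestamp": self.timestamp,
            "config": self.config,
            "inputs": self.inputs,
        }

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")
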