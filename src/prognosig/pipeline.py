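"""End-to-end pipeline: config in, TSV reports + manifest out.

Stages: (optional) synthetic input generation → preranked enrichment on the
meta-z ranking → signature leaderboard → per-type enrichment and coverage →
per-cohort survival screening → subsampling robustness for qualifying
cohorts. Any stage error aborts with the stage name; outputs written by
earlier stages are preserved.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, io, ranking, simulate, survival
from .enrichment import EnrichmentRunConfig
from .models import PrerankedGSEA, SignatureSurvivalModel
from .robustness import RobustnessConfig, robustness_analysis

__all__ = ["full_pipeline", "PipelineError", "load_config"]

log = logging.getLogger("prognosig")

REQUIRED_KEYS = ("seed", "alpha", "signature")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def load_config(path) -> dict:
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def _require(cfg: dict, keys=REQUIRED_KEYS) -> None:
    missing = [k for k in keys if k not in cfg]
    if missing:
        raise KeyError(f"config missing required key(s): {', '.join(missing)}")


def _simulate_inputs(sim: dict, seed: int, indir: Path) -> dict:
    """Generate synthetic scores/gene sets/signature/cohorts into ``indir``."""
    indir.mkdir(parents=True, exist_ok=True)
    n_genes = int(sim.get("n_genes", 1000))
    types = list(sim.get("cancer_types", [f"TYPE{i+1}" for i in range(5)]))
    module_size = int(sim.get("module_size", 60))
    module_shift = float(sim.get("module_shift", 2.5))
    module_types = sim.get("module_types", types)
    module = simulate.PlantedModule(tuple(range(module_size)), module_shift, tuple(module_types))
    zcfg = simulate.ZScoreSimConfig(
        n_genes=n_genes, cancer_types=tuple(types),
        planted_modules=(module,), seed=seed,
    )
    matrix = simulate.generate_zscore_matrix(zcfg)
    io.write_score_matrix(matrix, indir / "scores.tsv")

    universe = list(matrix.gene_ids)
    sig_name = sim.get("signature_name", "PLANTED_SIG")
    sig_genes = [universe[i] for i in module.gene_indices]
    coll = simulate.generate_geneset_collection(
        n_sets=int(sim.get("n_sets", 50)),
        size_range=tuple(sim.get("set_size_range", (25, 100))),
        universe=universe,
        planted={sig_name: sig_genes},
        seed=seed + 1,
    )
    io.write_gmt(coll, indir / "sets.gmt")
    (indir / "signature.txt").write_text("\n".join(sig_genes) + "\n")

    cohort_paths = []
    for i, c in enumerate(sim.get("cohorts", [])):
        ccfg = simulate.CohortSimConfig(
            n_samples=int(c.get("n_samples", 150)),
            n_genes=n_genes,
            signature_indices=module.gene_indices,
            hazard_ratio=float(c.get("hazard_ratio", 2.0)),
            expression_shift=float(c.get("expression_shift", 1.0)),
            censor_rate=float(c.get("censor_rate", 0.3)),
            seed=seed + 100 + i,
        )
        cohort = simulate.generate_survival_cohort(ccfg)
        expr, clin = indir / f"cohort{i+1}_expr.tsv", indir / f"cohort{i+1}_clinical.tsv"
        io.write_cohort(cohort, expr, clin)
        cohort_paths.append({"expr": str(expr), "clinical": str(clin)})
    return {
        "scores": str(indir / "scores.tsv"),
        "gmt": str(indir / "sets.gmt"),
        "signature": sig_name,
        "cohorts": cohort_paths,
    }


def full_pipeline(config, outdir=None) -> dict:
    """Run every stage described by a YAML/JSON config (path or dict).

    Returns a dict of output paths; writes a JSON run manifest alongside.
    """
    cfg = load_config(config) if not isinstance(config, dict) else dict(config)
    _require(cfg)
    out = Path(outdir or cfg.get("outdir", "prognosig_out"))
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    alpha = float(cfg["alpha"])
    manifest = io.RunManifest(config=cfg, version=__version__)
    outputs: dict[str, str] = {}

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return deco

    @stage("simulate")
    def _sim():
        if "simulate" in cfg:
            generated = _simulate_inputs(cfg["simulate"], seed, out / "inputs")
            cfg.setdefault("scores", generated["scores"])
            cfg.setdefault("gmt", generated["gmt"])
            if cfg.get("signature") == "auto":
                cfg["signature"] = generated["signature"]
            cfg.setdefault("cohorts", generated["cohorts"])

    @stage("load")
    def _loaded():
        _require(cfg, ("scores", "gmt"))
        matrix = io.read_score_matrix(cfg["scores"])
        collection = io.read_gmt(cfg["gmt"])
        manifest.add_input("scores", cfg["scores"])
        manifest.add_input("gmt", cfg["gmt"])
        sig = cfg["signature"]
        if sig in collection:
            sig_name, sig_genes = sig, sorted(collection[sig].genes)
        else:
            sig_genes = io.read_signature(sig)
            sig_name = Path(sig).stem
            manifest.add_input("signature", sig)
        return matrix, collection, sig_name, sig_genes

    matrix, collection, sig_name, sig_genes = _loaded

    enr_cfg = EnrichmentRunConfig(seed=seed, significance_alpha=alpha,
                                  **cfg.get("enrichment", {}))

    @stage("enrichment")
    def _enriched():
        res = PrerankedGSEA(matrix, collection, "meta_z", enr_cfg).fit()
        io.write_table(res.table, out / "enrichment_meta_z.tsv")
        outputs["enrichment"] = str(out / "enrichment_meta_z.tsv")
        log.info("enrichment: %d sets scored, %d filtered (<%d known genes), %d significant",
                 len(res.table), res.n_filtered, enr_cfg.min_known_genes,
                 len(res.significant()))
        return res

    @stage("ranking")
    def _leaderboard():
        board = _enriched.rank_signatures(alpha)
        io.write_table(board, out / "leaderboard.tsv")
        outputs["leaderboard"] = str(out / "leaderboard.tsv")
        return board

    @stage("coverage")
    def _coverage():
        if not cfg.get("per_type", True):
            return None
        per_type = {}
        for j, t in enumerate(matrix.cancer_types):
            tcfg = EnrichmentRunConfig(
                seed=seed + 1000 + j, significance_alpha=alpha,
                **cfg.get("enrichment", {}),
            )
            per_type[t] = PrerankedGSEA(matrix, collection, t, tcfg).fit().table
        content = ranking.split_types_by_content(
            matrix, int(cfg.get("type_gene_threshold", 10)), alpha)
        cov = ranking.type_coverage(per_type, sig_name, alpha, content)
        io.write_table(cov, out / "coverage.tsv")
        outputs["coverage"] = str(out / "coverage.tsv")
        log.info("coverage: %s enriched in %d/%d types",
                 sig_name, cov.attrs["covered_types"], len(cov))
        return cov

    @stage("survival")
    def _screen():
        cohort_specs = cfg.get("cohorts", [])
        if not cohort_specs:
            return None
        rule = survival.EligibilityRule(**cfg.get("survival", {}))
        cohorts = []
        for spec in cohort_specs:
            cohorts.append(io.read_cohort(spec["expr"], spec["clinical"]))
            manifest.add_input(f"cohort:{cohorts[-1].name}", spec["expr"])
        screen, summary = survival.run_survival_screen(
            cohorts, sig_genes, rule, alpha,
            distance=cfg.get("distance", "euclidean"),
        )
        io.write_table(screen, out / "survival_screen.tsv", index=False)
        io.write_table(summary, out / "survival_summary.tsv", index=False)
        outputs["survival_screen"] = str(out / "survival_screen.tsv")
        outputs["survival_summary"] = str(out / "survival_summary.tsv")
        return cohorts, screen

    @stage("robustness")
    def _robust():
        if _screen is None or "robustness" not in cfg:
            return None
        cohorts, screen = _screen
        rcfg = RobustnessConfig(seed=seed, distance=cfg.get("distance", "euclidean"),
                                alpha=alpha, **cfg["robustness"])
        for cohort, (_, row) in zip(cohorts, screen.iterrows()):
            if not (row["significant"] and row["n"] >= rcfg.min_cohort_size):
                continue
            report = robustness_analysis(cohort, sig_genes, rcfg)
            path = out / f"robustness_{cohort.name}.tsv"
            io.write_table(report, path, index=False)
            outputs[f"robustness:{cohort.name}"] = str(path)

    manifest.write(out / "manifest.json")
    outputs["manifest"] = str(out / "manifest.json")
    return outputs
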