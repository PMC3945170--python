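"""End-to-end orchestration: preprocess → DE → DM → match → tabulate →
interaction → enrichment → report, with a structured run log.

Every stage writes its output table before the next stage runs; empty
intermediate results propagate as valid empty tables, never as absent
files.  All randomness flows from the single config seed, so a rerun
with the same config produces byte-identical CSVs.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import pandas as pd

from . import differential, enrichment, integrate, interaction, preprocess, report
from .annotation import read_manifest
from .config import PipelineConfig
from .preprocess import SampleDesign
from .synthetic import SimConfig, PlantedGeneSpec, simulate_dataset

__all__ = ["run_all", "analyze", "PipelineError", "ARTIFACTS"]

ARTIFACTS = [
    "de.csv", "dm.csv", "pairs.csv", "table_direction.csv",
    "table_gene_context.csv", "table_island_context.csv", "interaction.csv",
    "enrichment.csv", "pca.csv", "density.csv", "scatter_counts.json",
    "heatmap.csv", "tree.json", "runlog.json",
]


def analyze(records, beta, detection, expr, probe_map, design,
            case: str = "OSIS", control: str = "EIUM",
            treatment: str | None = None, thresholds=None) -> dict:
    """In-memory pipeline core: preprocess → DE → DM → match → interaction.

    Takes the raw tables (e.g. straight from
    :func:`methexpress.synthetic.simulate_dataset`) and returns a dict of
    result frames: ``de`` (collapsed transcripts), ``de_sig``, ``dm``,
    ``pairs`` (with ρ and correlation class), ``tables`` (direction /
    gene-context / island-context tabulations) and ``interaction``.
    :func:`run_all` adds file I/O, stage logging and reporting on top.
    """
    from .config import Thresholds
    thr = thresholds or Thresholds()
    kept, _removed = preprocess.exclude_probes(records)
    keep_ids = [r.probe_id for r in kept if r.probe_id in beta.index]
    beta = beta.loc[keep_ids]
    retained, present, _counts = preprocess.presence_filter(
        detection.loc[keep_ids], design, p_threshold=thr.det_p,
        min_present=thr.min_present)
    beta, present = beta.loc[retained], present.loc[retained]
    expr_norm = preprocess.quantile_normalize(preprocess.vst_expression(expr))
    _params, de_table = differential.de_two_group(
        expr_norm, design, case=case, control=control, treatment=treatment)
    de = differential.collapse_to_transcripts(de_table, probe_map)
    de_sig = de[de["p_adj"] < thr.de_alpha]
    dm = differential.call_dm(beta, present, design, case=case, control=control,
                              treatment=treatment, delta=thr.delta_beta)
    samples = (design.samples(phenotype=control, treatment=treatment)
               + design.samples(phenotype=case, treatment=treatment))
    pairs = integrate.match(dm, set(de_sig["transcript_id"]), kept)
    pairs = integrate.add_correlations(
        pairs, beta, expr_norm, de_sig[["transcript_id", "probe_id"]], samples,
        present=present)
    tables = {strat: integrate.tabulate_by_context(pairs, stratify=strat)
              for strat in ("direction", "gene", "island")}
    groups = dict(zip(design.frame["sample_id"], design.frame["phenotype"]))
    anova = interaction.run_interaction_analysis(
        pairs, beta, samples, present=present, alpha=thr.anova_alpha,
        sample_groups=groups)
    return {"de": de, "de_sig": de_sig, "dm": dm, "pairs": pairs,
            "tables": tables, "interaction": anova, "beta": beta,
            "present": present, "expr_norm": expr_norm}


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name for context."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


class _RunLog:
    def __init__(self) -> None:
        self.stages: list[dict] = []

    def record(self, stage: str, n_in: int, n_out: int, **params) -> None:
        self.stages.append({
            "stage": stage, "input_count": int(n_in), "output_count": int(n_out),
            "parameters": params, "wall_time": time.time(),
        })

    def write(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump({"stages": self.stages}, fh, indent=1)


def _read_matrix(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="probe_id")


def _plants_from_config(sim_cfg: dict) -> list[PlantedGeneSpec]:
    plants = []
    for item in sim_cfg.get("plants", []):
        item = dict(item)
        if "promoter_effect" in item:
            from .synthetic import plant_interaction_gene
            plants.append(plant_interaction_gene(
                item["gene_id"], item["promoter_effect"], item["body_effect"],
                logfc=item.get("logfc", 2.0)))
        else:
            plants.append(PlantedGeneSpec(**item))
    return plants


def run_all(config: PipelineConfig) -> Path:
    """Run the whole pipeline; returns the artifact directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = _RunLog()
    thr = config.thresholds
    paths = dict(config.paths)

    try:
        if config.simulate is not None:
            sim_cfg = dict(config.simulate)
            plants = _plants_from_config(sim_cfg)
            sim_cfg.pop("plants", None)
            sim_cfg.setdefault("seed", config.seed)
            dataset = simulate_dataset(SimConfig(**sim_cfg), plants)
            sim_paths = dataset.write(out / "sim")
            for key, name in [("manifest", "manifest"), ("beta", "beta"),
                              ("beta_detection", "beta.detection"),
                              ("expr", "expr"), ("expr_detection", "expr.detection"),
                              ("probe_map", "probe_map"), ("design", "design"),
                              ("categories", "categories")]:
                paths.setdefault(key, sim_paths[name])
            log.record("simulate", 0, len(dataset.beta),
                       seed=sim_cfg.get("seed"), n_plants=len(plants))
    except Exception as exc:  # noqa: BLE001 - stage context is the point
        raise PipelineError("simulate", exc) from exc

    def stage(name):
        def wrap(fn):
            try:
                return fn()
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001
                raise PipelineError(name, exc) from exc
        return wrap

    records = stage("read_manifest")(lambda: read_manifest(paths["manifest"]))
    design = stage("read_design")(lambda: SampleDesign.read_csv(paths["design"]))
    contrast = config.contrast
    samples = (design.samples(phenotype=contrast.control, treatment=contrast.treatment)
               + design.samples(phenotype=contrast.case, treatment=contrast.treatment))

    def _methylation():
        n_in = len(records)
        kept, removed = preprocess.exclude_probes(records)
        log.record("exclude_probes", n_in, len(kept), **removed)
        if "beta" in paths:
            beta = _read_matrix(paths["beta"])
        else:
            m = preprocess.quantile_normalize(_read_matrix(paths["meth_m"]))
            u = preprocess.quantile_normalize(_read_matrix(paths["meth_u"]))
            beta = preprocess.compute_beta(m, u)
        detection = _read_matrix(paths["beta_detection"])
        keep_ids = [r.probe_id for r in kept if r.probe_id in beta.index]
        beta = beta.loc[keep_ids]
        detection = detection.loc[keep_ids]
        retained, present, counts = preprocess.presence_filter(
            detection, design, p_threshold=thr.det_p, min_present=thr.min_present)
        log.record("presence_filter", len(beta), len(retained),
                   det_p=thr.det_p, min_present=thr.min_present)
        return kept, beta.loc[retained], present.loc[retained]

    kept_records, beta, present = stage("methylation_preprocess")(_methylation)

    def _expression():
        expr = _read_matrix(paths["expr"])
        probe_map = pd.read_csv(paths["probe_map"]).fillna("")
        tx_chrom = {}
        for rec in records:
            for tid, _ in rec.gene_links:
                tx_chrom.setdefault(tid, rec.chrom)
        sex_tx = {tid for tid, c in tx_chrom.items()
                  if preprocess.normalize_chrom(c) in ("X", "Y")}
        sex_probes = set(probe_map[probe_map["transcript_id"].isin(sex_tx)]["probe_id"])
        n_in = len(expr)
        expr = expr.loc[[p for p in expr.index if p not in sex_probes]]
        log.record("exclude_sex_expression", n_in, len(expr))
        expr = preprocess.quantile_normalize(preprocess.vst_expression(expr))
        return expr, probe_map

    expr, probe_map = stage("expression_preprocess")(_expression)

    def _de():
        params, table = differential.de_two_group(
            expr, design, case=contrast.case, control=contrast.control,
            treatment=contrast.treatment)
        collapsed = differential.collapse_to_transcripts(table, probe_map)
        collapsed.to_csv(out / "de.csv", index=False)
        log.record("differential_expression", len(expr), len(collapsed),
                   de_alpha=thr.de_alpha,
                   d0=getattr(params, "d0", None))
        return collapsed

    de = stage("differential_expression")(_de)
    de_sig = de[de["p_adj"] < thr.de_alpha]

    def _dm():
        dm = differential.call_dm(
            beta, present, design, case=contrast.case, control=contrast.control,
            treatment=contrast.treatment, delta=thr.delta_beta)
        dm.to_csv(out / "dm.csv", index=False)
        log.record("differential_methylation", len(beta), len(dm),
                   delta=thr.delta_beta)
        return dm

    dm = stage("differential_methylation")(_dm)

    def _match():
        pairs = integrate.match(dm, set(de_sig["transcript_id"]), kept_records)
        pairs = integrate.add_correlations(
            pairs, beta, expr, de_sig[["transcript_id", "probe_id"]], samples,
            present=present)
        pairs.to_csv(out / "pairs.csv", index=False)
        log.record("match", len(dm), len(pairs))
        return pairs

    pairs = stage("match")(_match)

    def _tabulate():
        for strat, name in (("direction", "table_direction.csv"),
                            ("gene", "table_gene_context.csv"),
                            ("island", "table_island_context.csv")):
            integrate.tabulate_by_context(pairs, stratify=strat) \
                .to_csv(out / name, index=False)
        log.record("tabulate", len(pairs), len(pairs))

    stage("tabulate")(_tabulate)

    def _interaction():
        groups = dict(zip(design.frame["sample_id"], design.frame["phenotype"]))
        table = interaction.run_interaction_analysis(
            pairs, beta, samples, present=present, alpha=thr.anova_alpha,
            sample_groups=groups)
        table.to_csv(out / "interaction.csv", index=False)
        log.record("interaction", len(pairs), len(table),
                   anova_alpha=thr.anova_alpha)
        return table

    anova = stage("interaction")(_interaction)

    def _enrichment():
        sig_genes = set(anova[anova["significant"] == True]["gene_id"])  # noqa: E712
        if "categories" in paths and sig_genes:
            categories = pd.read_csv(paths["categories"])
            background = config.background_size or categories["gene"].nunique()
            table = enrichment.ora(sig_genes & set(categories["gene"]),
                                   categories, background) \
                if sig_genes & set(categories["gene"]) else pd.DataFrame()
        else:
            table = pd.DataFrame()
        if table.empty:
            table = pd.DataFrame(columns=["category", "actual", "K", "n", "N",
                                          "expected", "ratio", "z", "p"])
        table.to_csv(out / "enrichment.csv", index=False)
        log.record("enrichment", len(sig_genes), len(table))

    stage("enrichment")(_enrichment)

    def _report():
        pca_beta = report.pca_summary(beta[samples])
        pca_expr = report.pca_summary(expr[samples])
        rows = []
        for layer, pca in (("methylation", pca_beta), ("expression", pca_expr)):
            for i, frac in enumerate(pca.variance_fraction):
                rows.append({"layer": layer, "component": i + 1,
                             "variance_fraction": float(frac)})
        pd.DataFrame(rows).to_csv(out / "pca.csv", index=False)
        tree = report.hclust(beta[samples])
        with open(out / "tree.json", "w") as fh:
            json.dump({"linkage": tree.linkage.tolist(),
                       "leaf_order": list(tree.leaf_order)}, fh, indent=1)
        report.beta_density(beta[samples]).to_csv(out / "density.csv", index=False)
        with open(out / "scatter_counts.json", "w") as fh:
            json.dump(report.dm_scatter_counts(dm), fh, indent=1)
        report.dm_heatmap_table(dm, beta, samples, kept_records) \
            .to_csv(out / "heatmap.csv")
        log.record("report", len(beta), len(beta))

    stage("report")(_report)
    log.write(out / "runlog.json")
    return out
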