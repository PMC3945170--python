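"""Synthetic two-group methylation + expression datasets with planted truth.

The generator emulates a 450K-style study design: two phenotypes
("EIUM" control vs "OSIS" case, 6 samples each by default), a probe
manifest whose CpGs carry both a gene context and a CGI context, a
bimodal β-value landscape (unmethylated islands, methylated open sea),
and an expression matrix coupled to methylation through planted
per-context Δβ effects and per-gene log fold-changes.  Every planted
effect is recorded in a truth table so calling, matching, correlation
and interaction stages can all be scored.

Geometry
--------
Each gene occupies a 100 kb slot: a + strand transcript with body
``[tss, tss+30kb]``, first exon ``[tss, tss+300]``, 5'UTR
``[tss, tss+500]`` and 3'UTR in the last kb; a promoter CGI
``[tss-500, tss+500]`` and an intragenic CGI ``[tss+10kb, tss+11kb]``
(intragenic islands are common on the real array and give gene bodies
all three island contexts).  CpG positions are drawn inside windows that
make the derived gene and island contexts exact by construction.

Baselines
---------
Unplanted CpGs sit at one of the two β modes, island CpGs mostly at the
unmethylated mode and open-sea CpGs mostly at the methylated mode, which
reproduces the pooled bimodal density of real arrays.  Planted
(differentially methylated) CpGs follow one of two baseline policies:

* ``context`` (default, realistic): CpGs that lose methylation start at
  the methylated mode; CpGs that gain methylation start at the
  unmethylated mode in islands and at intermediate levels in shores and
  open sea (aberrant gains concentrate on initially unmethylated CGIs).
  Combined with mixed-sign effects this produces the non-additive
  status×location cell structure the interaction ANOVA is designed to
  reward.
* ``uniform``: the two group means straddle 0.5 symmetrically for every
  planted CpG, so pooled cell means are identical everywhere — planted
  genes remain testable but carry **no** status×location interaction
  (the null configuration for calibrating the interaction test).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import (GENE_CONTEXTS, GenomicInterval, ProbeRecord,
                         TranscriptModel, write_manifest)
from .preprocess import SampleDesign

__all__ = [
    "SimConfig",
    "PlantedGeneSpec",
    "SimulatedDataset",
    "plant_interaction_gene",
    "simulate_dataset",
]

PROMOTER_CONTEXTS = ("TSS1500", "TSS200", "UTR5", "FirstExon")
BODY_CONTEXTS = ("Body", "UTR3")

#: Per-island-context choice of compatible gene contexts and weights.
_CONTEXT_MENU = {
    "Island": (("TSS200", 0.30), ("FirstExon", 0.25), ("UTR5", 0.15), ("Body", 0.30)),
    "Shore": (("TSS1500", 0.40), ("Body", 0.60)),
    "OpenSea": (("Body", 0.70), ("UTR3", 0.30)),
}

#: Probability that an unplanted CpG sits at the methylated mode.
_METHYLATED_PRIOR = {"Island": 0.15, "Shore": 0.50, "OpenSea": 0.85}

#: Baseline (control-group) β mean for planted hypermethylation, by
#: island context, under the "context" baseline policy.
_HYPER_BASELINE_SHORE = 0.40
_HYPER_BASELINE_OPENSEA = 0.50

_CATEGORY_CYCLE = ["transcription_factor", "kinase", "phosphatase", "receptor",
                   "enzyme", "ligand", "protease", "other", "other", "other"]


@dataclass
class SimConfig:
    """Study-condition knobs for the generator.

    Defaults reproduce the emulated design: 6+6 samples, ~2000 CpGs over
    200 genes, β modes 0.10/0.85 with beta-distributed noise at
    precision 100 (per-sample β s.d. ≈ 0.02–0.05 depending on the mean,
    typical of replicate arrays), expression on a log2-like scale with
    s.d. 0.5 residual noise, and 1% detection dropout.
    """

    seed: int = 0
    n_genes: int = 200
    cpgs_per_gene: tuple[int, int] = (6, 14)
    island_mix: tuple[float, float, float] = (0.30, 0.25, 0.45)
    samples_per_group: int = 6
    beta_precision: float = 100.0
    unmethylated_mode: float = 0.10
    methylated_mode: float = 0.85
    expr_baseline_mean: float = 8.0
    expr_baseline_sd: float = 1.5
    expr_noise_sd: float = 0.5
    detection_dropout_rate: float = 0.01
    planted_baseline_policy: str = "context"
    phenotypes: tuple[str, str] = ("EIUM", "OSIS")  # (control, case)
    include_intensities: bool = False

    def __post_init__(self) -> None:
        if abs(sum(self.island_mix) - 1.0) > 1e-9:
            raise ValueError("island_mix proportions must sum to 1")
        for mode in (self.unmethylated_mode, self.methylated_mode):
            if not (0.0 < mode < 1.0):
                raise ValueError("β modes must lie in (0, 1)")
        if self.samples_per_group < 2:
            raise ValueError("need at least 2 samples per group")
        if self.cpgs_per_gene[0] < 1 or self.cpgs_per_gene[0] > self.cpgs_per_gene[1]:
            raise ValueError("cpgs_per_gene must be a nondecreasing positive pair")
        if self.planted_baseline_policy not in ("context", "uniform"):
            raise ValueError("planted_baseline_policy must be 'context' or 'uniform'")
        if not (0.0 <= self.detection_dropout_rate < 1.0):
            raise ValueError("detection_dropout_rate must be in [0, 1)")


@dataclass
class PlantedGeneSpec:
    """Planted per-context Δβ effects and expression fold-change for one gene.

    ``effects`` maps gene contexts to signed Δβ (case − control); a
    context absent from the map (or with effect 0) stays at its null
    baseline.  ``correlation_sign`` ('+'/'-'), when given, orients the
    sign of ``logfc`` so the expected Spearman correlation between the
    planted CpGs and the gene's expression has the requested sign.
    ``is_interaction_gene`` may be true only when effects of both signs
    or unequal magnitudes are present.  Genes whose effects span both
    signs get guaranteed context coverage: their first CpGs are placed
    so that both statuses occur in both island and shore locations,
    the pattern (an NR5A1-like gene) the interaction test targets.
    """

    gene_id: str
    effects: dict[str, float] = field(default_factory=dict)
    logfc: float = 0.0
    correlation_sign: str | None = None
    is_interaction_gene: bool = False

    def __post_init__(self) -> None:
        for ctx, eff in self.effects.items():
            if ctx not in GENE_CONTEXTS:
                raise ValueError(f"unknown gene context {ctx!r}")
            if abs(eff) >= 1.0:
                raise ValueError(f"|Δβ| must be < 1, got {eff}")
        if self.correlation_sign not in (None, "+", "-"):
            raise ValueError("correlation_sign must be '+', '-' or None")
        nonzero = [e for e in self.effects.values() if e != 0.0]
        if self.is_interaction_gene:
            if not nonzero:
                raise ValueError("interaction gene needs nonzero effects")
            signs = {math.copysign(1, e) for e in nonzero}
            magnitudes = {abs(e) for e in nonzero}
            one_sided = any(e == 0.0 for e in self.effects.values())
            if len(signs) < 2 and len(magnitudes) < 2 and not one_sided:
                raise ValueError(
                    "is_interaction_gene requires effects of both signs or "
                    "context-varying magnitudes")

    @property
    def mixed_signs(self) -> bool:
        nonzero = [e for e in self.effects.values() if e != 0.0]
        return len({math.copysign(1, e) for e in nonzero}) == 2


def plant_interaction_gene(gene_id: str, promoter_effect: float,
                           body_effect: float, logfc: float = 2.0,
                           contexts=None) -> PlantedGeneSpec:
    """Build an interaction-gene spec from promoter and body Δβ effects.

    The promoter effect applies to TSS1500/TSS200/5'UTR/first-exon CpGs
    and the body effect to body/3'UTR CpGs.  Opposite-direction or
    unequal effects mark the gene as an interaction gene; identical
    effects (a uniform shift) do not.  When the gene's available
    ``contexts`` are supplied they must span at least two gene contexts.
    """
    if contexts is not None and len(set(contexts)) < 2:
        raise ValueError(f"gene {gene_id} has a single context; "
                         "an interaction needs CpGs in at least two")
    effects = {ctx: promoter_effect for ctx in PROMOTER_CONTEXTS}
    effects.update({ctx: body_effect for ctx in BODY_CONTEXTS})
    is_interaction = (promoter_effect != body_effect)
    return PlantedGeneSpec(gene_id=gene_id, effects=effects, logfc=logfc,
                           is_interaction_gene=is_interaction)


@dataclass
class SimulatedDataset:
    """All artifacts of one simulation run, as in-memory tables."""

    config: SimConfig
    manifest: list
    transcripts: list
    islands: list
    beta: pd.DataFrame
    detection: pd.DataFrame
    expr: pd.DataFrame
    expr_detection: pd.DataFrame
    probe_map: pd.DataFrame
    design: SampleDesign
    truth_cpgs: pd.DataFrame
    truth_genes: pd.DataFrame
    categories: pd.DataFrame
    meth_m: pd.DataFrame | None = None
    meth_u: pd.DataFrame | None = None

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        paths["manifest"] = outdir / "manifest.csv"
        write_manifest(self.manifest, paths["manifest"])
        for name, frame in [("beta", self.beta), ("beta.detection", self.detection),
                            ("expr", self.expr),
                            ("expr.detection", self.expr_detection)]:
            paths[name] = outdir / f"{name}.tsv"
            frame.to_csv(paths[name], sep="\t", index_label="probe_id")
        if self.meth_m is not None:
            for name, frame in [("meth_m", self.meth_m), ("meth_u", self.meth_u)]:
                paths[name] = outdir / f"{name}.tsv"
                frame.to_csv(paths[name], sep="\t", index_label="probe_id")
        for name, frame in [("probe_map", self.probe_map),
                            ("design", self.design.frame),
                            ("truth_cpgs", self.truth_cpgs),
                            ("truth_genes", self.truth_genes),
                            ("categories", self.categories)]:
            paths[name] = outdir / f"{name}.csv"
            frame.to_csv(paths[name], index=False)
        return paths


def _gene_geometry(g: int):
    """Deterministic transcript + CGI layout for gene index ``g``."""
    chrom = f"chr{1 + g % 22}"
    slot_start = 1 + (g // 22) * 100_000
    tss = slot_start + 20_000
    tx = TranscriptModel(
        transcript_id=f"NM_{g:05d}", chrom=chrom, strand="+", tss=tss,
        first_exon=GenomicInterval(chrom, tss, tss + 300),
        body=GenomicInterval(chrom, tss, tss + 30_000),
        utr5=GenomicInterval(chrom, tss, tss + 500),
        utr3=GenomicInterval(chrom, tss + 29_000, tss + 30_000),
    )
    islands = [GenomicInterval(chrom, tss - 500, tss + 500),
               GenomicInterval(chrom, tss + 10_000, tss + 11_000)]
    return tx, islands


def _position_window(gene_context: str, island_context: str, tss: int):
    """The bp window on which (gene_context, island_context) both hold."""
    windows = {
        ("TSS200", "Island"): (tss - 200, tss - 1),
        ("FirstExon", "Island"): (tss + 1, tss + 300),
        ("UTR5", "Island"): (tss + 301, tss + 500),
        ("Body", "Island"): (tss + 10_000, tss + 11_000),
        ("TSS1500", "Shore"): (tss - 1500, tss - 501),
        ("Body", "Shore"): (tss + 501, tss + 4500),
        ("Body", "OpenSea"): (tss + 15_001, tss + 28_999),
        ("UTR3", "OpenSea"): (tss + 29_000, tss + 30_000),
    }
    return windows[(gene_context, island_context)]


#: (gene context, island context) cells guaranteed for mixed-sign plants:
#: both statuses present in both the Island and the Shore location.
_COVERAGE_CELLS = [("TSS200", "Island"), ("TSS1500", "Shore"),
                   ("Body", "Island"), ("Body", "Shore")]


def _draw_context(rng, island_mix):
    island = rng.choice(len(island_mix), p=island_mix)
    island_label = ("Island", "Shore", "OpenSea")[island]
    menu = _CONTEXT_MENU[island_label]
    weights = np.array([w for _, w in menu])
    gene_label = menu[rng.choice(len(menu), p=weights / weights.sum())][0]
    return gene_label, island_label


def simulate_dataset(config: SimConfig,
                     plants: list[PlantedGeneSpec] | None = None) -> SimulatedDataset:
    """Generate a full dataset; bitwise-reproducible from ``config.seed``."""
    plants = list(plants or [])
    ss = np.random.SeedSequence(config.seed)
    rng_geom, rng_beta, rng_det, rng_expr, rng_edet, rng_int = (
        np.random.default_rng(child) for child in ss.spawn(6))

    plant_by_gene = {p.gene_id: p for p in plants}
    gene_ids = [f"NM_{g:05d}" for g in range(config.n_genes)]
    unknown = set(plant_by_gene) - set(gene_ids)
    if unknown:
        raise ValueError(f"planted gene ids not in generated manifest: "
                         f"{sorted(unknown)}")

    n_ctrl = n_case = config.samples_per_group
    control, case = config.phenotypes
    samples = ([f"{control[0]}{i+1}" for i in range(n_ctrl)]
               + [f"{case[0]}{i+1}" for i in range(n_case)])
    is_case = np.array([0] * n_ctrl + [1] * n_case)
    design = SampleDesign(pd.DataFrame({
        "sample_id": samples,
        "phenotype": [control] * n_ctrl + [case] * n_case,
        "treatment": ["control"] * (n_ctrl + n_case),
    }))

    records: list[ProbeRecord] = []
    transcripts, islands = [], []
    truth_rows = []
    mean_ctrl_rows, mean_case_rows = [], []
    probe_counter = 0
    for g, gene_id in enumerate(gene_ids):
        tx, gene_islands = _gene_geometry(g)
        transcripts.append(tx)
        islands.extend(gene_islands)
        plant = plant_by_gene.get(gene_id)
        n_cpgs = int(rng_geom.integers(config.cpgs_per_gene[0],
                                       config.cpgs_per_gene[1] + 1))
        forced = []
        if plant is not None and plant.mixed_signs:
            forced = _COVERAGE_CELLS
            n_cpgs = max(n_cpgs, len(forced))
        for k in range(n_cpgs):
            if k < len(forced):
                gene_ctx, island_ctx = forced[k]
            else:
                gene_ctx, island_ctx = _draw_context(rng_geom, config.island_mix)
            lo, hi = _position_window(gene_ctx, island_ctx, tx.tss)
            pos = int(rng_geom.integers(lo, hi + 1))
            probe_id = f"cg{probe_counter:07d}"
            probe_counter += 1
            records.append(ProbeRecord(
                probe_id=probe_id, chrom=tx.chrom, pos=pos,
                island_context=island_ctx,
                gene_links=[(tx.transcript_id, gene_ctx)], is_cpg=True))
            effect = 0.0
            if plant is not None:
                effect = float(plant.effects.get(gene_ctx, 0.0))
            if effect == 0.0:
                methylated = rng_geom.random() < _METHYLATED_PRIOR[island_ctx]
                m_ctrl = (config.methylated_mode if methylated
                          else config.unmethylated_mode)
                m_case = m_ctrl
            else:
                if config.planted_baseline_policy == "uniform":
                    m_ctrl = 0.5 - effect / 2.0
                elif effect < 0:
                    m_ctrl = config.methylated_mode
                else:
                    m_ctrl = {"Island": config.unmethylated_mode,
                              "Shore": _HYPER_BASELINE_SHORE,
                              "OpenSea": _HYPER_BASELINE_OPENSEA}[island_ctx]
                m_case = m_ctrl + effect
                if not (0.0 < m_ctrl < 1.0 and 0.0 < m_case < 1.0):
                    raise ValueError(
                        f"planted effect {effect} at {gene_id}/{gene_ctx} pushes "
                        f"a group β mean outside (0, 1): {m_ctrl} -> {m_case}")
            mean_ctrl_rows.append(m_ctrl)
            mean_case_rows.append(m_case)
            truth_rows.append({
                "probe_id": probe_id, "gene_id": gene_id,
                "gene_context": gene_ctx, "island_context": island_ctx,
                "true_direction": ("null" if effect == 0.0
                                   else ("hyper" if effect > 0 else "hypo")),
                "effect": effect,
            })

    n_probes = len(records)
    probe_ids = [r.probe_id for r in records]
    means = np.where(is_case[None, :].astype(bool),
                     np.array(mean_case_rows)[:, None],
                     np.array(mean_ctrl_rows)[:, None])
    phi = config.beta_precision
    beta_vals = rng_beta.beta(means * phi, (1.0 - means) * phi)
    beta = pd.DataFrame(beta_vals, index=probe_ids, columns=samples)

    dropout = rng_det.random((n_probes, len(samples))) < config.detection_dropout_rate
    det = np.where(dropout,
                   rng_det.uniform(0.05, 0.5, size=(n_probes, len(samples))),
                   rng_det.uniform(0.0, 0.005, size=(n_probes, len(samples))))
    detection = pd.DataFrame(det, index=probe_ids, columns=samples)

    # Expression: one probe per transcript, a second probe for every 10th
    # gene (exercises the collapse-to-transcript rule) and a few
    # unmapped probes (discarded by it).
    expr_rows, map_rows, expr_ids = [], [], []
    truth_gene_rows = []
    for g, gene_id in enumerate(gene_ids):
        plant = plant_by_gene.get(gene_id)
        logfc = float(plant.logfc) if plant is not None else 0.0
        if plant is not None and plant.correlation_sign is not None and logfc != 0:
            nonzero = [e for e in plant.effects.values() if e != 0.0]
            dominant = np.sign(sum(nonzero)) if nonzero else 1.0
            want = 1.0 if plant.correlation_sign == "+" else -1.0
            if dominant != 0 and np.sign(logfc) * dominant != want:
                logfc = -logfc
        baseline = rng_expr.normal(config.expr_baseline_mean, config.expr_baseline_sd)
        n_probes_gene = 2 if g % 10 == 0 else 1
        for rep in range(n_probes_gene):
            pid = f"ep{g:05d}" + ("b" if rep else "")
            vals = (baseline + logfc * is_case
                    + rng_expr.normal(0.0, config.expr_noise_sd, len(samples)))
            # emitted as raw-scale intensities; the VST recovers the log2 scale
            expr_rows.append(np.exp2(vals))
            expr_ids.append(pid)
            map_rows.append({"probe_id": pid, "transcript_id": gene_id})
        truth_gene_rows.append({
            "gene_id": gene_id,
            "true_de": logfc != 0.0,
            "logfc": logfc,
            "true_interaction": bool(plant.is_interaction_gene) if plant else False,
            "correlation_sign": (plant.correlation_sign or "") if plant else "",
        })
    for j in range(5):
        pid = f"ep_unmapped{j}"
        expr_rows.append(np.exp2(
            rng_expr.normal(config.expr_baseline_mean, config.expr_baseline_sd)
            + rng_expr.normal(0.0, config.expr_noise_sd, len(samples))))
        expr_ids.append(pid)
        map_rows.append({"probe_id": pid, "transcript_id": ""})
    expr = pd.DataFrame(np.vstack(expr_rows), index=expr_ids, columns=samples)
    e_dropout = (rng_edet.random(expr.shape) < config.detection_dropout_rate)
    expr_detection = pd.DataFrame(
        np.where(e_dropout, rng_edet.uniform(0.05, 0.5, expr.shape),
                 rng_edet.uniform(0.0, 0.005, expr.shape)),
        index=expr_ids, columns=samples)

    categories = pd.DataFrame({
        "gene": gene_ids,
        "category": [_CATEGORY_CYCLE[g % len(_CATEGORY_CYCLE)]
                     for g in range(config.n_genes)],
    })

    meth_m = meth_u = None
    if config.include_intensities:
        total = rng_int.uniform(1000.0, 5000.0, size=beta_vals.shape)
        # β = M/(M+U+100) requires total ≥ 100·β/(1−β); lift where violated
        total = np.maximum(total, 100.0 * beta_vals / (1.0 - beta_vals) * 1.05)
        m_int = beta_vals * (total + 100.0)
        u_int = (1.0 - beta_vals) * (total + 100.0) - 100.0
        meth_m = pd.DataFrame(m_int, index=probe_ids, columns=samples)
        meth_u = pd.DataFrame(u_int, index=probe_ids, columns=samples)

    return SimulatedDataset(
        config=config, manifest=records, transcripts=transcripts,
        islands=islands, beta=beta, detection=detection, expr=expr,
        expr_detection=expr_detection,
        probe_map=pd.DataFrame(map_rows), design=design,
        truth_cpgs=pd.DataFrame(truth_rows),
        truth_genes=pd.DataFrame(truth_gene_rows),
        categories=categories, meth_m=meth_m, meth_u=meth_u)
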