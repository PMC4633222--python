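"""End-to-end orchestration: simulate -> preprocess -> diffmeth -> annotate ->
enrich -> integrate, with a run manifest for bitwise reproducibility.

One master seed drives the whole run; per-stage child seeds are derived
deterministically with numpy's SeedSequence so any stage is individually
reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .annotate import annotate_probes, enrichment_by_class
from .assay import (
    AssayConfig,
    ProbeDefinition,
    derive_probes,
    digest,
    random_annotations,
    random_genome,
    simulate_assay,
    simulate_methylomes,
)
from .concordance import classify_concordance, filter_degs, map_dmr_to_gene
from .config import PipelineConfig
from .design import build_design
from .diffmeth import call_dmrs, fit_contrast, partition_dmr_sets
from .preprocess import ArraySet, preprocess_arrays

log = logging.getLogger(__name__)

_STAGES = ("simulate", "preprocess", "diffmeth", "annotate", "enrich", "integrate")


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    row_counts: dict[str, int] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True)


def stage_rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STAGES))
    return {name: np.random.default_rng(ss) for name, ss in zip(_STAGES, children)}


@dataclass
class PipelineResult:
    manifest: RunManifest
    design: pd.DataFrame
    probes: list[ProbeDefinition]
    truth: object
    m_matrix: pd.DataFrame
    stats: dict[str, pd.DataFrame]
    dmrs: dict[str, pd.DataFrame]
    contexts: pd.DataFrame
    enrichment: dict[str, pd.DataFrame]
    partition: object
    concordance: dict[str, object]


def run_pipeline(
    config: PipelineConfig,
    outdir: str | Path | None = None,
    deg_table: pd.DataFrame | None = None,
) -> PipelineResult:
    """Run the full simulated-experiment pipeline.

    When ``deg_table`` is None a synthetic differential-expression table is
    generated with planted inverse methylation-expression coupling for half
    of the DMR-bearing genes, so the concordance stage has known truth.
    """
    rngs = stage_rngs(config.seed)
    manifest = RunManifest(config.digest(), config.seed, __version__)

    # --- simulate ------------------------------------------------------
    rng = rngs["simulate"]
    genome = random_genome(rng, config.genome_chroms, config.genome_length,
                           config.genome_gc)
    annotations = random_annotations(genome, rng)
    fragments = [f for rec in genome.values() for f in digest(rec)]
    assay_cfg = AssayConfig(
        seed=config.seed,
        groups=config.groups,
        reference=config.reference,
        replicates=config.replicates,
        amplifiable_range=config.amplifiable_range,
        noise_sd=config.noise_sd,
        dye_bias=config.dye_bias,
        dmr_fraction=config.dmr_fraction,
        effect_size=config.effect_size,
    )
    probes = derive_probes(fragments, config=assay_cfg)
    truth = simulate_methylomes(probes, assay_cfg, rng)
    design = build_design(config.groups, config.replicates, config.reference)
    intensities, spikeins = simulate_assay(probes, truth, assay_cfg, design, rng)
    arrays = ArraySet(intensities, design)
    manifest.row_counts["probes"] = len(probes)
    manifest.row_counts["arrays"] = len(design)

    # --- preprocess ----------------------------------------------------
    m_matrix, detected = preprocess_arrays(
        arrays,
        sd_multiplier=config.sd_multiplier,
        floor=config.intensity_floor,
        span=config.loess_span,
        quantile_mode=config.quantile_mode,
    )
    manifest.row_counts["detected_probes"] = len(m_matrix)

    # --- diffmeth ------------------------------------------------------
    stats, dmrs = {}, {}
    for group in config.groups:
        cols = design.loc[design["group"] == group, "array_id"]
        stats[group] = fit_contrast(m_matrix[list(cols)])
        dmrs[group] = call_dmrs(
            stats[group],
            config.fc_threshold,
            config.p_threshold,
            threshold_is_log2=config.threshold_is_log2,
        )
        manifest.row_counts[f"dmrs_{group}"] = len(dmrs[group])
    partition = partition_dmr_sets({g: set(d.index) for g, d in dmrs.items()})

    # --- annotate ------------------------------------------------------
    probe_intervals = {p.probe_id: p.fragment.interval for p in probes}
    contexts = annotate_probes(
        {pid: probe_intervals[pid] for pid in m_matrix.index},
        annotations,
        shore_max=config.shore_max,
        shelf_max=config.shelf_max,
        tiers=config.promoter_tiers,
    )
    manifest.row_counts["annotated_probes"] = len(contexts)

    # --- enrich --------------------------------------------------------
    enrich_rng = rngs["enrich"]
    enrichment = {}
    for group, dmr_df in dmrs.items():
        if dmr_df.empty:
            enrichment[group] = pd.DataFrame()
            continue
        ctx = contexts.reindex(dmr_df.index)
        enrichment[group] = enrichment_by_class(
            dmr_df["direction"],
            ctx["genomic_region"],
            seed=int(enrich_rng.integers(0, 2**31 - 1)),
        )

    # --- integrate -----------------------------------------------------
    if deg_table is None:
        deg_table = synthetic_deg_table(dmrs, contexts, rngs["integrate"])
    degs = filter_degs(deg_table, config.deg_fc_threshold,
                       config.deg_p_threshold, config.deg_fdr_threshold)
    universe = set(deg_table["gene_id"])
    concordance = {}
    for group, dmr_df in dmrs.items():
        mapped = map_dmr_to_gene(dmr_df, contexts)
        pairs, summary = classify_concordance(mapped, degs, universe)
        concordance[group] = summary
        manifest.row_counts[f"concordant_pairs_{group}"] = summary.n_deg_overlap

    result = PipelineResult(
        manifest, design, probes, truth, m_matrix, stats, dmrs, contexts,
        enrichment, partition, concordance,
    )
    if outdir is not None:
        _write_outputs(result, Path(outdir), config)
    return result


def synthetic_deg_table(
    dmrs: dict[str, pd.DataFrame],
    contexts: pd.DataFrame,
    rng: np.random.Generator,
    inverse_fraction: float = 0.5,
) -> pd.DataFrame:
    """Expression table with planted coupling to the called DMRs.

    Each gene owning a DMR becomes a DEG with probability ``inverse_fraction``
    with expression opposite to the methylation direction (inverse pairs);
    otherwise it is left non-significant. Non-DMR genes get null statistics.
    """
    gene_direction: dict[str, str] = {}
    for dmr_df in dmrs.values():
        ctx = contexts.reindex(dmr_df.index)
        for probe_id, row in dmr_df.iterrows():
            gene = ctx.loc[probe_id, "gene_id"]
            if isinstance(gene, str) and gene not in gene_direction:
                gene_direction[gene] = row["direction"]
    all_genes = sorted({g for g in contexts["gene_id"].dropna().unique()})
    rows = []
    for gene in all_genes:
        direction = gene_direction.get(gene)
        if direction is not None and rng.random() < inverse_fraction:
            sign = -1.0 if direction == "hyper" else 1.0
            rows.append((gene, sign * rng.uniform(0.7, 2.0),
                         rng.uniform(0.0001, 0.01), rng.uniform(0.01, 0.2)))
        else:
            rows.append((gene, rng.normal(0.0, 0.2),
                         rng.uniform(0.2, 1.0), rng.uniform(0.5, 1.0)))
    return pd.DataFrame(rows, columns=["gene_id", "expr_log2fc", "p", "fdr"])


def _write_outputs(result: PipelineResult, outdir: Path,
                   config: PipelineConfig) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    tag = result.manifest.config_hash
    result.m_matrix.to_csv(outdir / "normalized_m.tsv", sep="\t")
    for group, dmr_df in result.dmrs.items():
        dmr_df.to_csv(outdir / f"dmrs_{group}.tsv", sep="\t")
    result.contexts.to_csv(outdir / "probe_contexts.tsv", sep="\t")
    for group, enr in result.enrichment.items():
        if not enr.empty:
            enr.to_csv(outdir / f"enrichment_{group}.tsv", sep="\t", index=False)
    result.partition.counts().to_csv(outdir / "dmr_partition.tsv", sep="\t",
                                     index=False)
    summary = {
        "config_hash": tag,
        "concordance": {
            g: {
                "n_in_transcriptome": s.n_in_transcriptome,
                "n_deg_overlap": s.n_deg_overlap,
                "n_inverse": s.n_inverse,
                "n_positive": s.n_positive,
                "percent_inverse_of_transcriptome":
                    s.percent_inverse_of_transcriptome,
                "percent_inverse_of_degs": s.percent_inverse_of_degs,
            }
            for g, s in result.concordance.items()
        },
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, allow_nan=True)
    config.to_yaml(outdir / "config.yaml")
    result.manifest.to_json(outdir / "manifest.json")


def output_digest(outdir: str | Path) -> str:
    """Digest over all text outputs of a run, for reproducibility checks."""
    h = hashlib.sha256()
    for path in sorted(Path(outdir).glob("*")):
        if path.is_file():
            h.update(path.name.encode())
            h.update(path.read_bytes())
    return h.hexdigest()
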