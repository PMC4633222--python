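"""Methylome-transcriptome concordance.

DMRs in gene bodies or promoter regions (proximal or promoter tier) are
mapped to their owning/nearest gene and joined to a differential-expression
table. A pair is *inverse* when methylation and expression move in opposite
directions (hyper + down, hypo + up), *positive* when they move together, and
*unchanged* when the gene is not differentially expressed. The paper-style
summary reports percentages under both denominators in use: DMRs overlapping
the transcriptome universe, and DMRs overlapping the DEG set.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

MAPPABLE_REGIONS = {"exon", "intron", "proximal_promoter", "promoter"}


def filter_degs(
    deg_table: pd.DataFrame,
    fc_threshold: float = 1.5,
    p_threshold: float = 0.05,
    fdr_threshold: float = 0.3,
) -> pd.DataFrame:
    """Differentially expressed genes: |FC| >= 1.5, p < 0.05, FDR < 0.3."""
    import math

    needed = {"gene_id", "expr_log2fc", "p", "fdr"}
    if not needed <= set(deg_table.columns):
        raise ValueError(f"DEG table missing columns {needed - set(deg_table.columns)}")
    keep = (
        (deg_table["expr_log2fc"].abs() >= math.log2(fc_threshold))
        & (deg_table["p"] < p_threshold)
        & (deg_table["fdr"] < fdr_threshold)
    )
    out = deg_table[keep].copy()
    if out["gene_id"].duplicated().any():
        dups = sorted(out.loc[out["gene_id"].duplicated(), "gene_id"].unique())
        raise ValueError(f"duplicate genes in DEG table (ambiguous direction): {dups}")
    return out


def map_dmr_to_gene(
    dmrs: pd.DataFrame, contexts: pd.DataFrame
) -> pd.DataFrame:
    """Join DMRs to genes through their probe context.

    Only gene-body and promoter/proximal-promoter probes map; distal-promoter
    and no-nearby-gene DMRs are unmapped and dropped. Expects the DMR frame
    indexed by probe_id with ``log2fc`` and ``direction`` columns.
    """
    ctx = contexts.reindex(dmrs.index)
    mapped = ctx["genomic_region"].isin(MAPPABLE_REGIONS) & ctx["gene_id"].notna()
    out = dmrs[mapped].copy()
    out["gene_id"] = ctx.loc[mapped, "gene_id"]
    out["genomic_region"] = ctx.loc[mapped, "genomic_region"]
    return out


@dataclass
class ConcordanceSummary:
    n_dmrs: int
    n_mapped: int
    n_in_transcriptome: int
    n_deg_overlap: int
    n_inverse: int
    n_positive: int

    @property
    def percent_inverse_of_transcriptome(self) -> float:
        if self.n_in_transcriptome == 0:
            return float("nan")
        return 100.0 * self.n_inverse / self.n_in_transcriptome

    @property
    def percent_inverse_of_degs(self) -> float:
        if self.n_deg_overlap == 0:
            return float("nan")
        return 100.0 * self.n_inverse / self.n_deg_overlap

    @property
    def percent_deg_overlap_of_transcriptome(self) -> float:
        if self.n_in_transcriptome == 0:
            return float("nan")
        return 100.0 * self.n_deg_overlap / self.n_in_transcriptome


def classify_concordance(
    mapped_dmrs: pd.DataFrame,
    degs: pd.DataFrame,
    transcriptome_universe: set[str] | None = None,
) -> tuple[pd.DataFrame, ConcordanceSummary]:
    """Assign inverse / positive / unchanged to every mapped DMR-gene pair.

    ``transcriptome_universe`` is the set of genes measured on the expression
    platform; DMRs whose gene is absent from it are excluded from the
    percentage denominators. Defaults to the DEG table's genes.
    """
    deg_dir = dict(zip(degs["gene_id"], degs["expr_log2fc"]))
    universe = (
        transcriptome_universe
        if transcriptome_universe is not None
        else set(deg_dir)
    )
    relations = []
    for probe_id, row in mapped_dmrs.iterrows():
        gene = row["gene_id"]
        if gene not in universe:
            relation = "not_measured"
        elif gene not in deg_dir:
            relation = "unchanged"
        else:
            hyper = row["direction"] == "hyper"
            up = deg_dir[gene] > 0
            relation = "inverse" if hyper != up else "positive"
        relations.append(relation)
    pairs = mapped_dmrs.copy()
    pairs["relation"] = relations
    in_tx = pairs["relation"] != "not_measured"
    n_inverse = int((pairs["relation"] == "inverse").sum())
    n_positive = int((pairs["relation"] == "positive").sum())
    summary = ConcordanceSummary(
        n_dmrs=len(mapped_dmrs),
        n_mapped=len(mapped_dmrs),
        n_in_transcriptome=int(in_tx.sum()),
        n_deg_overlap=n_inverse + n_positive,
        n_inverse=n_inverse,
        n_positive=n_positive,
    )
    return pairs, summary
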