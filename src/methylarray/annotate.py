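"""Genomic-context classification of probes and direction enrichment.

Probes are labelled by four independent context families:

* island length class — bottom-20th / top-80th nearest-rank percentiles of
  the differentially methylated island length distribution split short /
  intermediate / long;
* island distance context — island (overlap), shore (0-2 kb), shelf
  (2-4 kb), open sea (> 4 kb from the nearest island);
* gene region — exon / intron (gene body takes precedence), then strand-aware
  promoter tiers upstream of the nearest TSS: proximal promoter (<= 1 kb),
  promoter (<= 5 kb), distal promoter (<= 50 kb), else no nearby gene;
* repeat classes — multi-label overlap with SINE / LINE / LTR /
  low-complexity / simple repeats.

The direction enrichment per class is a log2 ratio of hyper-to-hypo odds in
the class against the overall odds, with half-unit pseudocounts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import AnnotationSet, GenomicInterval, nearest_island_distance

ISLAND_CONTEXTS = ("island", "shore", "shelf", "open_sea", "undefined")
GENOMIC_REGIONS = (
    "exon",
    "intron",
    "proximal_promoter",
    "promoter",
    "distal_promoter",
    "no_nearby_gene",
)


def classify_island_length(
    lengths: "pd.Series | np.ndarray | list[int]",
    lower_percentile: float = 20.0,
    upper_percentile: float = 80.0,
) -> list[str]:
    """Short / intermediate / long by nearest-rank percentiles.

    Nearest-rank: the p-th percentile of n sorted lengths is the value at
    1-based rank ceil(p/100 * n). Lengths <= P_low are short, >= P_high long,
    with the boundary tie (a length qualifying as both) resolved to
    intermediate, as is the degenerate all-equal case.
    """
    arr = np.asarray(lengths, dtype=float)
    if arr.size == 0:
        raise ValueError("need >= 1 island length")
    ordered = np.sort(arr)
    n = arr.size

    def nearest_rank(p: float) -> float:
        rank = max(1, math.ceil(p / 100.0 * n))
        return float(ordered[rank - 1])

    p_low = nearest_rank(lower_percentile)
    p_high = nearest_rank(upper_percentile)
    labels = []
    for length in arr:
        short = length <= p_low
        long_ = length >= p_high
        if short and long_:
            labels.append("intermediate")
        elif short:
            labels.append("short")
        elif long_:
            labels.append("long")
        else:
            labels.append("intermediate")
    return labels


def classify_island_context(
    distance: int | None,
    shore_max: int = 2000,
    shelf_max: int = 4000,
) -> str:
    """Bin a nearest-island distance; bins are half-open above: (0, 2000]
    shore, (2000, 4000] shelf, > 4000 open sea; overlap (0) is island."""
    if distance is None:
        return "undefined"
    if distance == 0:
        return "island"
    if distance <= shore_max:
        return "shore"
    if distance <= shelf_max:
        return "shelf"
    return "open_sea"


def classify_genomic_region(
    probe: GenomicInterval,
    annotations: AnnotationSet,
    tiers: tuple[int, int, int] = (1000, 5000, 50000),
) -> tuple[str, str | None]:
    """Label a probe's gene context by its fragment midpoint.

    Returns (label, gene_id). Gene-body assignment (exon, then intron) takes
    precedence over promoter tiers. Promoter tiers measure the strand-aware
    distance upstream of the nearest TSS; beyond the distal tier, or
    downstream of every gene, the probe has no nearby gene.
    """
    mid = probe.midpoint
    point = GenomicInterval(probe.chrom, mid, mid + 1)
    for gene in annotations.overlapping_genes(point):
        for exon in gene.exons:
            if exon.start <= mid < exon.end:
                return "exon", gene.gene_id
        return "intron", gene.gene_id
    proximal, promoter, distal = tiers
    best: tuple[int, str] | None = None
    for gene in annotations.genes:
        if gene.chrom != probe.chrom:
            continue
        upstream = gene.tss - mid if gene.strand == "+" else mid - gene.tss
        if upstream <= 0 or upstream > distal:
            continue
        if best is None or upstream < best[0]:
            best = (upstream, gene.gene_id)
    if best is None:
        return "no_nearby_gene", None
    dist, gene_id = best
    if dist <= proximal:
        return "proximal_promoter", gene_id
    if dist <= promoter:
        return "promoter", gene_id
    return "distal_promoter", gene_id


def classify_repeat(
    probe: GenomicInterval, annotations: AnnotationSet
) -> set[str]:
    """Repeat classes whose elements overlap the probe fragment (multi-label)."""
    return {rep.repeat_class for rep in annotations.overlapping_repeats(probe)}


def annotate_probes(
    probe_intervals: dict[str, GenomicInterval],
    annotations: AnnotationSet,
    *,
    shore_max: int = 2000,
    shelf_max: int = 4000,
    tiers: tuple[int, int, int] = (1000, 5000, 50000),
) -> pd.DataFrame:
    """One context row per probe: island overlap and distance context, gene
    region and owning/nearest gene, repeat classes."""
    rows = []
    for probe_id, iv in probe_intervals.items():
        overlaps = annotations.overlapping_islands(iv)
        overlap_bases = 0
        for isl in overlaps:
            overlap_bases += max(
                0, min(iv.end, isl.interval.end) - max(iv.start, isl.interval.start)
            )
        dist = nearest_island_distance(iv, annotations)
        region, gene_id = classify_genomic_region(iv, annotations, tiers)
        rows.append(
            {
                "probe_id": probe_id,
                "in_island": bool(overlaps),
                "island_overlap_bases": overlap_bases,
                "island_context": classify_island_context(dist, shore_max, shelf_max),
                "island_distance": -1 if dist is None else dist,
                "genomic_region": region,
                "gene_id": gene_id,
                "repeat_classes": ",".join(sorted(classify_repeat(iv, annotations))),
            }
        )
    return pd.DataFrame(rows).set_index("probe_id")


@dataclass(frozen=True)
class EnrichmentResult:
    class_label: str
    n_hyper: int
    n_hypo: int
    log2_enrichment: float
    ci_low: float
    ci_high: float
    low_support: bool = False


def _log2_odds(h: int, y: int, h_all: int, y_all: int) -> float:
    return math.log2((h + 0.5) / (y + 0.5)) - math.log2((h_all + 0.5) / (y_all + 0.5))


def enrichment_log2(
    directions: pd.Series,
    in_class: pd.Series,
    class_label: str,
    n_boot: int = 1000,
    seed: int = 0,
) -> EnrichmentResult:
    """Hyper-vs-hypo log2 enrichment of a context class among DMRs.

    ``directions`` holds 'hyper'/'hypo' per DMR; ``in_class`` is a boolean
    membership vector over the same index. The bootstrap resamples DMRs with
    replacement under a fixed seed; a class with no DMRs is flagged
    low-support.
    """
    directions = directions.astype(str)
    in_class = in_class.reindex(directions.index).fillna(False).astype(bool)
    hyper = directions == "hyper"
    h_all, y_all = int(hyper.sum()), int((~hyper).sum())
    h_c = int((hyper & in_class).sum())
    y_c = int((~hyper & in_class).sum())
    point = _log2_odds(h_c, y_c, h_all, y_all)
    low_support = (h_c + y_c) == 0
    rng = np.random.default_rng(seed)
    n = len(directions)
    hy = hyper.to_numpy()
    ic = in_class.to_numpy()
    boots = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        bh, bi = hy[idx], ic[idx]
        boots[b] = _log2_odds(
            int((bh & bi).sum()),
            int((~bh & bi).sum()),
            int(bh.sum()),
            int((~bh).sum()),
        )
    lo, hi = np.percentile(boots, [2.5, 97.5])
    lo, hi = min(lo, point), max(hi, point)
    return EnrichmentResult(class_label, h_c, y_c, point, float(lo), float(hi), low_support)


def enrichment_by_class(
    dmr_directions: pd.Series,
    class_labels: pd.Series,
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Enrichment for every distinct value of a single-label class column."""
    rows = []
    for label in sorted(class_labels.dropna().unique()):
        res = enrichment_log2(
            dmr_directions, class_labels == label, str(label), n_boot, seed
        )
        rows.append(res.__dict__)
    return pd.DataFrame(rows)
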