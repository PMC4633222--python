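"""In-silico methyl-sensitive restriction-enzyme assay.

Emulates the physical assay end to end: the genome is fragmented by a
frequent cutter (MseI, T^TAA), fragments carrying at least one
methyl-sensitive site (HpaII C^CGG, HinP1I G^CGC, AciI C^CGC scanned on both
strands) and an amplifiable length become probes, unmethylated sites are
cleaved and destroy amplifiability, and surviving fragments produce
two-channel log intensities with replicate noise, dye bias and dye swaps.

Sites are treated as independent: a molecule survives digestion only if every
sensitive site it carries is methylated, so the expected survival of a probe
is the product of its per-site methylation probabilities. Planted hyper/hypo
probes scale the disfavoured group's site probabilities *down*, which keeps
probabilities in (0, 1] and makes the expected log2 survival ratio equal the
planted effect exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import (
    REPEAT_CLASSES,
    AnnotationSet,
    CpGIsland,
    GeneModel,
    GenomicInterval,
    RepeatElement,
    SequenceRecord,
)

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class RestrictionEnzyme:
    name: str
    recognition: str
    cut_offset: int
    #: Scan the reverse-complement word too (non-palindromic recognition).
    double_strand_scan: bool = False

    def __post_init__(self) -> None:
        if len(self.recognition) < 4:
            raise ValueError("recognition word must be >= 4 bases")
        if not (0 <= self.cut_offset <= len(self.recognition)):
            raise ValueError("cut_offset outside recognition word")


MSEI = RestrictionEnzyme("MseI", "TTAA", 1)
HPAII = RestrictionEnzyme("HpaII", "CCGG", 1)
HINP1I = RestrictionEnzyme("HinP1I", "GCGC", 1)
ACII = RestrictionEnzyme("AciI", "CCGC", 1, double_strand_scan=True)

#: The three methyl-sensitive enzymes applied after adapter ligation.
METHYL_SENSITIVE_ENZYMES = (HPAII, HINP1I, ACII)


@dataclass(frozen=True)
class Fragment:
    parent: str
    interval: GenomicInterval
    residues: str

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class ProbeDefinition:
    probe_id: str
    fragment: Fragment
    site_counts: tuple[tuple[str, int], ...]

    @property
    def total_sites(self) -> int:
        return sum(n for _, n in self.site_counts)

    def site_count_map(self) -> dict[str, int]:
        return dict(self.site_counts)


@dataclass(frozen=True)
class SpikeInControl:
    control_id: str
    protected: bool
    ct_digested: float
    ct_undigested: float

    def __post_init__(self) -> None:
        if self.ct_digested <= 0 or self.ct_undigested <= 0:
            raise ValueError("Ct values must be > 0")


@dataclass
class AssayConfig:
    """Study conditions of the simulated experiment.

    Defaults mirror the hybridization design: four treatment groups, four
    biological replicates each, against a common in-vivo reference, with
    alternating dye swaps.
    """

    seed: int = 0
    groups: tuple[str, ...] = ("ZY", "4C", "16C", "IVP")
    reference: str = "VO"
    replicates: int = 4
    amplifiable_range: tuple[int, int] = (50, 1500)
    #: Per-channel log2 intensity noise.
    noise_sd: float = 0.2
    #: Constant log2 bias added to the Cy5 channel (cancelled by dye swaps).
    dye_bias: float = 0.1
    dmr_fraction: float = 0.05
    #: Planted |log2 survival ratio| for hyper/hypo probes.
    effect_size: float = 1.0
    #: Intensity scale of a fully surviving probe and background level.
    signal_scale: float = 5000.0
    background: float = 50.0
    n_negative_controls: int = 200

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0.0 <= self.dmr_fraction <= 1.0):
            raise ValueError("dmr_fraction must be in [0, 1]")
        if self.reference in self.groups:
            raise ValueError("reference group must be distinct from treatment groups")


@dataclass
class MethylationTruth:
    """Planted ground truth: per-group site methylation and DMR labels."""

    probe_ids: list[str]
    #: probe -> group -> per-site methylation probabilities
    site_probs: dict[str, dict[str, np.ndarray]]
    #: DataFrame indexed by probe, one column per treatment group with
    #: values 'hyper' / 'hypo' / 'null'.
    dmr_flags: pd.DataFrame
    #: Planted log2 survival ratio (treatment over reference) per probe/group.
    effects: pd.DataFrame

    def survival(self, probe_id: str, group: str) -> float:
        return float(np.prod(self.site_probs[probe_id][group]))


# ---------------------------------------------------------------------------
# Digestion and probe derivation


def digest(seq: SequenceRecord, enzyme: RestrictionEnzyme = MSEI) -> list[Fragment]:
    """Digest a linear sequence, scanning recognition sites left to right.

    Overlapping occurrences are resolved non-overlapping: after a cut the
    scan resumes at the cut position. N bases never match. Fragments tile the
    input without gaps.
    """
    s = seq.residues
    if not s:
        raise ValueError("cannot digest an empty sequence")
    cuts = []
    pos = 0
    word = enzyme.recognition
    while True:
        hit = s.find(word, pos)
        if hit == -1:
            break
        cut = hit + enzyme.cut_offset
        if cut > 0 and cut < len(s):
            cuts.append(cut)
        pos = cut if cut > pos else hit + 1
    fragments = []
    boundaries = [0] + cuts + [len(s)]
    for a, b in zip(boundaries, boundaries[1:]):
        fragments.append(
            Fragment(seq.id, GenomicInterval(seq.id, a, b), s[a:b])
        )
    return fragments


def count_word_occurrences(s: str, word: str) -> int:
    """Overlapping occurrence count (every genomic site is a cleavage site)."""
    count = 0
    start = 0
    while True:
        hit = s.find(word, start)
        if hit == -1:
            return count
        count += 1
        start = hit + 1


def count_sensitive_sites(
    fragment: Fragment | str,
    enzymes: tuple[RestrictionEnzyme, ...] = METHYL_SENSITIVE_ENZYMES,
) -> dict[str, int]:
    s = fragment if isinstance(fragment, str) else fragment.residues
    counts: dict[str, int] = {}
    for enz in enzymes:
        n = count_word_occurrences(s, enz.recognition)
        if enz.double_strand_scan:
            rc = reverse_complement(enz.recognition)
            if rc != enz.recognition:
                n += count_word_occurrences(s, rc)
        counts[enz.name] = n
    return counts


def derive_probes(
    fragments: list[Fragment],
    enzymes: tuple[RestrictionEnzyme, ...] = METHYL_SENSITIVE_ENZYMES,
    config: AssayConfig | None = None,
) -> list[ProbeDefinition]:
    """Retain fragments with >= 1 sensitive site and amplifiable length."""
    config = config or AssayConfig()
    lo, hi = config.amplifiable_range
    probes = []
    for frag in fragments:
        if not (lo <= len(frag) <= hi):
            continue
        counts = count_sensitive_sites(frag, enzymes)
        if sum(counts.values()) == 0:
            continue
        probe_id = f"{frag.parent}_{frag.interval.start:09d}"
        probes.append(
            ProbeDefinition(probe_id, frag, tuple(sorted(counts.items())))
        )
    if not probes:
        log.warning("no fragments qualified as probes")
    return probes


# ---------------------------------------------------------------------------
# Planted methylomes and signal model


def simulate_methylomes(
    probes: list[ProbeDefinition],
    config: AssayConfig,
    rng: np.random.Generator | None = None,
) -> MethylationTruth:
    """Draw per-site methylation states and plant DMRs.

    Null probes carry identical site probabilities in every group. A planted
    hyper probe keeps the baseline in the treatment group and scales the
    reference group's sites down by 2^(-effect/n_sites); hypo is the mirror
    image. The planted log2 survival ratio is therefore exactly ±effect.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    probe_ids = [p.probe_id for p in probes]
    groups = list(config.groups)
    all_groups = groups + [config.reference]
    flags = pd.DataFrame("null", index=probe_ids, columns=groups)
    effects = pd.DataFrame(0.0, index=probe_ids, columns=groups)
    site_probs: dict[str, dict[str, np.ndarray]] = {}
    for probe in probes:
        n_sites = probe.total_sites
        base = rng.uniform(0.5, 0.95, size=n_sites)
        per_group = {g: base.copy() for g in all_groups}
        site_probs[probe.probe_id] = per_group
        for g in groups:
            if rng.random() >= config.dmr_fraction:
                continue
            direction = "hyper" if rng.random() < 0.5 else "hypo"
            flags.loc[probe.probe_id, g] = direction
            eff = config.effect_size
            scale = 2.0 ** (-eff / n_sites)
            if direction == "hyper":
                # reference survival reduced -> treatment/reference = 2^eff
                ref = base * scale
                per_group[g] = base.copy()
                per_group[config.reference + "@" + g] = ref
                effects.loc[probe.probe_id, g] = eff
            else:
                per_group[g] = base * scale
                effects.loc[probe.probe_id, g] = -eff
    return MethylationTruth(probe_ids, site_probs, flags, effects)


def _reference_probs(truth: MethylationTruth, probe_id: str, group: str,
                     reference: str) -> np.ndarray:
    """Per-contrast reference state: hyper planting perturbs the reference."""
    per_group = truth.site_probs[probe_id]
    return per_group.get(reference + "@" + group, per_group[reference])


def simulate_assay(
    probes: list[ProbeDefinition],
    truth: MethylationTruth,
    config: AssayConfig,
    design: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, list[SpikeInControl]]:
    """Generate two-channel intensities for every array in the design.

    Returns a long intensity table (probe_id, array_id, channel1, channel2,
    is_negative_control) — channel1 is Cy3, channel2 is Cy5; the treatment
    sample is in Cy5 unless the array is dye-swapped — plus spike-in QC
    records (one protected and one unprotected control per array).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    surv = {}
    for probe in probes:
        pid = probe.probe_id
        surv[pid] = {}
        for g in config.groups:
            surv[pid][(g, "T")] = float(np.prod(truth.site_probs[pid][g]))
            surv[pid][(g, "R")] = float(
                np.prod(_reference_probs(truth, pid, g, config.reference))
            )
    rows = []
    spikeins = []
    probe_ids = [p.probe_id for p in probes]
    neg_ids = [f"NEG_{i:05d}" for i in range(config.n_negative_controls)]
    for _, arr in design.iterrows():
        g = arr["group"]
        array_id = arr["array_id"]
        swapped = bool(arr["dye_swapped"])
        n = len(probe_ids)
        noise_t = rng.normal(0.0, config.noise_sd, size=n)
        noise_r = rng.normal(0.0, config.noise_sd, size=n)
        for pid, nt, nr in zip(probe_ids, noise_t, noise_r):
            sig_t = config.signal_scale * surv[pid][(g, "T")] * 2.0 ** nt
            sig_r = config.signal_scale * surv[pid][(g, "R")] * 2.0 ** nr
            # treatment dye: Cy5 unless swapped
            if swapped:
                cy3, cy5 = sig_t, sig_r
            else:
                cy3, cy5 = sig_r, sig_t
            cy5 = cy5 * 2.0 ** config.dye_bias
            rows.append((pid, array_id, max(cy3, 1e-3), max(cy5, 1e-3), False))
        neg_noise = rng.normal(0.0, config.noise_sd, size=(len(neg_ids), 2))
        for nid, (n3, n5) in zip(neg_ids, neg_noise):
            rows.append(
                (nid, array_id, config.background * 2.0 ** n3,
                 config.background * 2.0 ** (n5 + config.dye_bias), True)
            )
        ct_base = 18.0 + rng.normal(0.0, 0.3)
        spikeins.append(SpikeInControl(
            f"{array_id}_protected", True,
            ct_digested=ct_base + abs(rng.normal(0.0, 0.3)),
            ct_undigested=ct_base,
        ))
        spikeins.append(SpikeInControl(
            f"{array_id}_unprotected", False,
            ct_digested=ct_base + rng.normal(8.0, 0.8),
            ct_undigested=ct_base,
        ))
    intensities = pd.DataFrame(
        rows,
        columns=["probe_id", "array_id", "channel1", "channel2",
                 "is_negative_control"],
    )
    return intensities, spikeins


def spikein_qc(control: SpikeInControl, min_delta_ct: float = 5.0) -> str:
    """Cleavage QC: pass iff digested-vs-undigested ΔCt >= 5 cycles."""
    if control.ct_digested is None or control.ct_undigested is None:
        raise ValueError("missing Ct value")
    delta = control.ct_digested - control.ct_undigested
    return "pass" if delta >= min_delta_ct else "fail"


# ---------------------------------------------------------------------------
# Random genome helper used by the simulator and tests


def random_annotations(
    genome: dict[str, SequenceRecord],
    rng: np.random.Generator,
    islands_per_mb: float = 150.0,
    genes_per_mb: float = 60.0,
    repeats_per_mb: float = 300.0,
) -> AnnotationSet:
    """Random CpG islands, multi-exon genes and repeats over a genome.

    Densities are per megabase; feature placements are independent uniform,
    so features may overlap each other (as real annotations do). Island
    lengths are log-normal around a few hundred bases; genes carry 2-6 exons
    over a 2-20 kb span; repeats draw uniformly from the five repeat classes.
    """
    islands: list[CpGIsland] = []
    genes: list[GeneModel] = []
    repeats: list[RepeatElement] = []
    for chrom, rec in genome.items():
        length = len(rec)
        mb = length / 1e6
        for _ in range(rng.poisson(islands_per_mb * mb)):
            size = int(np.clip(rng.lognormal(6.0, 0.7), 200, 10_000))
            start = int(rng.integers(0, max(1, length - size)))
            islands.append(CpGIsland(GenomicInterval(chrom, start, start + size)))
        for gi in range(rng.poisson(genes_per_mb * mb)):
            span = int(rng.integers(2_000, 20_000))
            start = int(rng.integers(0, max(1, length - span)))
            strand = "+" if rng.random() < 0.5 else "-"
            n_exons = int(rng.integers(2, 7))
            bounds = np.sort(rng.choice(
                np.arange(1, span), size=2 * n_exons - 2, replace=False
            ))
            edges = [0, *bounds.tolist(), span]
            exons = tuple(
                GenomicInterval(chrom, start + edges[2 * k], start + edges[2 * k + 1],
                                strand)
                for k in range(n_exons)
            )
            tss = exons[0].start if strand == "+" else exons[-1].end - 1
            genes.append(GeneModel(f"gene_{chrom}_{gi:04d}", strand, tss, exons))
        for _ in range(rng.poisson(repeats_per_mb * mb)):
            size = int(rng.integers(100, 2_000))
            start = int(rng.integers(0, max(1, length - size)))
            repeats.append(RepeatElement(
                GenomicInterval(chrom, start, start + size),
                REPEAT_CLASSES[int(rng.integers(0, len(REPEAT_CLASSES)))],
            ))
    return AnnotationSet(islands=islands, genes=genes, repeats=repeats)


def random_genome(
    rng: np.random.Generator,
    n_chroms: int = 2,
    length: int = 100_000,
    gc: float = 0.5,
) -> dict[str, SequenceRecord]:
    """Random genome with i.i.d. bases at the given GC content."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    genome = {}
    for c in range(1, n_chroms + 1):
        bases = rng.choice(np.array(list("ACGT")), size=length, p=p)
        genome[str(c)] = SequenceRecord(str(c), "".join(bases))
    return genome
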