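# Methods

## The assay being modelled

The pipeline analyses a methyl-sensitive restriction-enzyme (MSRE) tiling
array of the kind used to profile bovine blastocyst methylomes. Genomic DNA
is fragmented by the frequent cutter MseI (T^TAA), adapters are ligated, and
the unmethylated CpG sites inside each MseI–MseI fragment are cleaved by
three methyl-sensitive enzymes — HpaII (C^CGG), HinP1I (G^CGC) and AciI
(C^CGC, non-palindromic, active on both strands). Cleaved fragments fail
ligation-mediated PCR, so a fragment's amplification signal reports whether
its sensitive sites were methylated. Each treatment sample (blastocyst
groups ZY, 4C, 16C, IVP — named for the stage up to which embryos were
cultured in vitro) is co-hybridized two-colour against a common in-vivo
reference (VO), four biological replicates per group with alternating dye
swaps: 4 groups × 4 replicates = 16 arrays.

## Signal model in the simulator

The generator (`methylarray.assay`) is first-class, tested code that defines
the study conditions used throughout the test suite.

* **Digestion.** Recognition sites are scanned left to right; after a cut the
  scan resumes at the cut position, so overlapping occurrences resolve
  non-overlapping, as on a linear molecule. `N` never matches a recognition
  word. Fragments tile the input exactly.
* **Probes.** A fragment becomes a probe iff it carries ≥ 1 sensitive site
  and its length is in the amplifiable range, default [50, 1500] bases —
  typical ligation-mediated-PCR amplicon sizes; configurable.
* **Survival.** Sites are independent and cleavage is all-or-nothing per
  molecule, so the expected surviving fraction of a probe is the product of
  its per-site methylation probabilities. Baseline site probabilities are
  drawn Uniform(0.5, 0.95).
* **Planted DMRs.** Each probe, independently per treatment group, is planted
  hyper- or hypomethylated (equal odds) with probability `dmr_fraction`
  (default 0.05, reflecting that differential probes are a small minority of
  a genome-scale array). Planting scales the *disfavoured* group's site
  probabilities down by 2^(−effect/n_sites) — the reference for hyper probes,
  the treatment for hypo probes — so probabilities stay in (0, 1] and the
  expected log2 survival ratio equals the planted effect exactly (default
  |log2 ratio| = 1, i.e. two-fold). Null probes are bitwise identical across
  groups.
* **Intensities.** Channel intensity is proportional to survival times
  2^ε with ε ~ Normal(0, `noise_sd`) per channel (default 0.2 log2 units), a
  constant `dye_bias` (default 0.1 log2 units) added to the Cy5 channel, and
  a floor keeping intensities positive. The treatment sample is in Cy5
  except on dye-swapped arrays. Negative-control probes receive
  background-level intensities; spike-in controls emulate the cleavage QC
  (unprotected templates gain ≈ 8 cycles after digestion, protected ones
  ≈ 0).

What the generator does **not** emulate: sequence-dependent hybridization
thermodynamics, PCR stochasticity, spatial artifacts, partial digestion, and
correlated methylation between neighbouring fragments. Passing tests
therefore demonstrate correctness of the analysis pipeline under an idealized
signal model, not performance on real arrays.

## Preprocessing

1. **Detection.** A probe is above background iff the mean of its two
   channels (natural scale) strictly exceeds mean + 4·SD of the
   negative controls (sample SD, n−1, because control sets are small).
   Downstream analysis uses probes detected on *all* arrays; per-array masks
   are also reported.
2. **M/A and dye swaps.** M = log2(treatment/reference),
   A = ½·log2(treatment·reference), after flooring intensities at 0.5.
   Dye-swapped arrays are handled by re-labelling channels before the ratio
   (not by flipping M afterwards), which keeps A meaningful.
3. **Loess.** M is replaced by residuals from a robust locally weighted
   regression of M on A (span 0.3, local-linear, 3 robustness iterations —
   common two-colour practice). Degenerate A falls back to subtracting the
   global mean, with a warning.
4. **Inter-array scale normalization** defaults to full quantile
   normalization of the normalized M vectors over the common probe set
   (idempotent, rank-preserving); a median-absolute-deviation scaling is
   available via `quantile_mode="mad"` for users who read "scale
   normalization" literally.

## Moderated differential test

Per probe and contrast, beta is the mean replicate M, s² the sample variance
with df = n−1 (missing replicates reduce df). The variance prior
(d0, s0²) is estimated by the method of moments on log s²: with
e = log s² − ψ(df/2) + log(df/2), the excess of Var(e) over the sampling
floor ψ′(df/2) identifies d0 through the trigamma inverse (Newton
iteration), and the mean of e identifies s0². When the observed spread does
not exceed the floor, d0 is capped at a large sentinel (10⁸) and s0² set to
the mean variance. The moderated variance is
s̃² = (d0·s0² + df·s²)/(d0 + df); t = beta/√(s̃²/n) is referred to a t
distribution with d0 + df degrees of freedom. At d0 = 0 this is exactly the
ordinary one-sample t (verified to 1e−12); calibration on null simulations
gives a type-I error of ≈ 0.05 at p < 0.05.

**DMR rule.** A probe is a DMR iff p < 0.05 and |log2FC| ≥ log2(1.5)
≈ 0.585. On this platform fold-changes indicate higher or lower odds of
methylation rather than a quantitative methylation difference, and published
DMR lists for this assay include |log2FC| values down to ≈ 0.59 — consistent
only with the fold-change-1.5 reading. The literal reading |log2FC| ≥ 1.5 is
available via `threshold_is_log2=True`. P-values are deliberately
unadjusted, matching the platform's stated rule; a Benjamini–Hochberg FDR
column is emitted alongside for transparency. Each array is one observation;
dye-swap pairs are not averaged before fitting.

Group DMR sets are partitioned into Venn cells (group-specific vs "stable" =
shared by ≥ 2 groups); cells are disjoint and union-complete by construction.

## Genomic context and enrichment

* **Island length classes** use nearest-rank percentiles of the
  differentially methylated island length distribution: ≤ P20 short,
  ≥ P80 long, else intermediate; boundary ties (P20 = P80) and the
  single-island case resolve to intermediate (deterministic and scale-free).
* **Island distance context** uses edge-to-edge gap distance (overlap ⇒ 0,
  "undefined" when a chromosome has no island — never silently 0). Bins are
  half-open above: island (0), shore (0, 2 kb], shelf (2, 4 kb], open sea
  > 4 kb. The 0–1 kb gap left between "island" and the 1–2 kb shore
  definition is merged into shore; both bin edges are configurable.
* **Gene regions** classify the fragment midpoint: exon, else intron for
  gene-body hits (gene body takes precedence over any other gene's promoter
  window), else the strand-aware distance upstream of the nearest TSS:
  proximal promoter ≤ 1 kb, promoter ≤ 5 kb, distal promoter ≤ 50 kb, else
  no nearby gene. Labels are exhaustive and mutually exclusive.
* **Repeats** are multi-label overlaps with the five-class set SINE, LINE,
  LTR, low-complexity, simple.
* **Direction enrichment** of a class c among DMRs is
  log2((h_c+½)/(y_c+½)) − log2((H+½)/(Y+½)), hyper/hypo counts in the class
  against overall, with half-unit pseudocounts; positive values mean the
  class is enriched for hypermethylation. The 95% interval comes from a
  seeded bootstrap over DMRs. The estimator is antisymmetric under direction
  swap and recovers a planted within-class bias when the class is a small
  share of all calls (for a large class the overall term absorbs part of the
  bias by construction).

## Methylome–transcriptome integration

DMRs in gene bodies or promoter/proximal-promoter tiers map to one gene
(the owning gene, or the nearest TSS for promoter probes; no multi-gene
fan-out). The differential-expression filter is |FC| ≥ 1.5, p < 0.05,
FDR < 0.3; duplicate genes in the expression table are an error (ambiguous
direction). Relations: inverse = (hyper ∧ down) ∨ (hypo ∧ up); positive =
same-direction; unchanged = gene measured but not differentially expressed.
Because percentage summaries for this assay are reported against two
different denominators in practice, both are emitted, clearly labelled:
percent of DMRs overlapping the transcriptome universe, and percent of
DMR–DEG overlaps. Counting is DMR-level: a gene with several DMRs
contributes one pair per DMR.

## Validation analytics

* **Bisulfite clones.** Equal-length clones are compared position-by-position
  to the amplicon reference (desk-scale model; gapped alignment is out of
  scope). CpG cytosines read C are methylated, T unmethylated, anything else
  ambiguous (excluded from that site's denominator). The conversion rate is
  the fraction of non-CpG cytosines read as T; clones below 0.95 — a common
  bisulfite QC threshold; configurable — are discarded before site
  percentages.
* **qPCR.** Comparative Ct: ΔCt = target − normalizer per replicate,
  ΔΔCt = mean ΔCt(group) − mean ΔCt(calibrator), relative expression
  2^−ΔΔCt; the calibrator is exactly 1 against itself.
* **Spike-in QC.** A sample passes cleavage QC iff the digested-vs-undigested
  ΔCt is ≥ 5 cycles; missing Ct values are an error, never a default pass.

## Numerical and I/O choices

* Internal coordinates are 0-based half-open; printed DMR tables ingest as
  1-based inclusive and export back identically. A printed end coordinate
  smaller than its start (a lost leading digit) is an error unless the
  explicit repair policy is enabled, which restores leading digits from the
  start coordinate and logs the repair — inputs are never silently altered.
* One master seed drives a run; per-stage child seeds come from numpy's
  `SeedSequence.spawn`, so any stage is individually reproducible and two
  runs with the same config are bitwise identical (hash-verified in tests).
* Problem sizes in tests and the acceptance script are desk-scale by design:
  simulated genomes of ~0.1–0.2 Mb yield several hundred probes, and the
  statistical recoveries use 10,000 simulated probes — large enough for the
  stated tolerances, small enough to run anywhere.

## Known limitations

Headline biological counts from the original bovine experiment (thousands of
group-specific DMRs, group-wise hypermethylation percentages, inverse
concordance of a few percent) depend on the deposited arrays and are not
reproducible from simulation; the pipeline reproduces the printed
fixture-level numbers and the statistical operating characteristics instead.
The exon/intron labels of the packaged tables are taken as given rather than
re-derived from a bovine annotation, which this package deliberately does
not ship.
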