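# Methods

This note records the models, conventions and numerical choices behind
`oriconflict`, and what the synthetic-data tests do and do not establish
about real data.

## Replication geometry

The chromosome is circular and replicated bidirectionally from a single
origin. The **right replichore** is defined as the set of positions reached
from the origin (inclusive) walking in increasing coordinate, wrapping at
the genome length, up to but not including the terminus; the origin itself
is therefore `right` and the terminus `left`, making the classification
total and deterministic. When no terminus is supplied it defaults to the
position halfway around the circle, `((origin − 1 + ⌊L/2⌋) mod L) + 1`; an
explicit terminus (e.g., a mapped *terC* site) overrides this, since real
termination regions are rarely exactly antipodal.

A gene is **codirectional (CD)** iff (strand = forward) ⇔ (replichore =
right), evaluated at the circular midpoint of its CDS. The midpoint rule is
a deliberate convention for genes straddling the replichore boundary or the
coordinate origin: it is order-independent, deterministic, and affects only
the handful of boundary genes; no biological claim hangs on it. The
strand-template map is forced by consistency: on the right replichore the
forward strand is the lagging-strand template (LGST) and the reverse strand
the leading-strand template (LDST), mirrored on the left. This is the
unique assignment under which every CD gene is transcribed off the LDST and
every HO gene off the LGST, which is the identity that lets a replicative
strand bias present as an orientation effect.

Coordinates are 1-based inclusive in all external files (GFF3 convention)
and converted to 0-based internally; the converters are exercised by
round-trip tests.

## Mutation catalogs

A catalog row is a base-pair substitution (BPS) or an indel of ≤ 4 bp on
forward-strand coordinates; longer indels are rejected with a count, since
the short-read calling these catalogs come from cannot see them reliably.
BPSs are collapsed to the six pair-class types (A·T→G·C, G·C→A·T
transitions; four transversion classes). Indels are left-normalized on
read — shifted to the leftmost equivalent position with the indel unit
rotated, stopping at coordinate 1 — which makes the attribution of indels
to mononucleotide runs deterministic regardless of how the caller placed
them. Strand interpretation is always derived from geometry, never stored.

## Feature mapping

* **CDS assignment**: a mutation is credited to every CDS containing its
  (left-normalized) position; multi-assignments are counted explicitly so
  unique + multi + intergenic always equals the catalog size. Promoter
  windows (TSS − 60 … TSS on the sense strand, 61 nt, circular wrap
  handled) are counted independently of CDSs: a mutation inside both
  appears in both feature tables, because the two analyses are reported
  separately.
* **Mononucleotide runs**: maximal homopolymer tracts; the census reports
  the fraction of nucleotides in runs of each length (length-weighted,
  summing to 1). Runs are reported by pair class (A·T vs G·C), merging A-
  and T-runs, since slipped-strand mispairing is strand-agnostic. An indel
  belongs to a run iff its base composition matches the run base and its
  position lies in the run or immediately 5′ of it (where a left-normalized
  extension lands).
* **Transition placement**: every transition is labeled by which strand
  carries the diagnostic base — the A of an A·T pair or the C of a G·C
  pair — and that strand's template role, giving the four classes
  {A, C} × {LGST, LDST}. These partition the transitions exactly.
* **−10 element scan**: the original identification of T−7 hits was done by
  eye; software needs an explicit rule. The scanner takes A·T transitions
  within 20 nt upstream of a TSS, requires the mutated sense-strand base to
  be a T, and scores the hexamer ending at it against TATAAT (≥ 4/6
  matches, hexamer 3′ end 5–9 nt upstream of the TSS). Both thresholds are
  arguments; a hexamer ending exactly 7 nt upstream is flagged as the
  classic T−7 position.

## Rates and confidence limits

Conditional rates are μ̂ = m/(G·N): m mutations of a class, G total
line-generations, N eligible base pairs (an A·T pair counts once, whichever
strand carries the A). The 95% limits use the exact Poisson (Garwood)
interval on m — χ²(α/2, 2m)/2 to χ²(1−α/2, 2m+2)/2 — divided by the
exposure; for m = 0 the upper limit is χ²(0.975, 2)/2 ≈ 3.689/exposure.
Pooled counts are treated as one Poisson draw, which is exact under the
generator's assumptions; a between-line bootstrap (resampling lines with
replacement) is available for data where between-line heterogeneity is
suspected, and outputs are labeled with the method used. A simulation test
checks ≥ 93% empirical coverage at λ ∈ {1, 10, 100}.

## Statistics

Test statistics are computed from their explicit formulas; scipy supplies
distribution functions only.

* Default two-sample test is the pooled-variance Student t (Welch by
  flag). Mann–Whitney enumerates its exact null (dynamic programming over
  doubled midranks, so ties are exact too) when n₁·n₂ ≤ 400 — large enough
  for every per-table comparison at desk scale while keeping the
  enumeration fast — and otherwise uses the normal approximation with tie
  and continuity corrections. The exact two-sided p is
  2·min(P(R ≤ r), P(R ≥ r)) capped at 1.
* Correlation p-values come from the two-tailed t transform with n − 2 df;
  Spearman is Pearson on midranks.
* Benjamini–Hochberg is the step-up adjustment; one family spans all
  p-values emitted in a report run (comparison and correlation tables
  alike), which approximates treating the whole study as one ledger of
  comparisons. Family scoping is a function argument; Holm is available as
  an alternative.
* Gaussian histogram fits use nonlinear least squares of bin counts on
  a·exp(−(x−μ)²/2σ²), initialized at (max count, weighted mean, weighted
  SD) with parameter tolerance 1e-10, requiring ≥ 5 nonzero bins; R² is
  reported on the binned counts. The Poisson reference curve uses the
  sample mean.
* Box statistics use the linear-interpolation (type-7) quantile
  convention; a value is an outlier iff it is ≥ Q3 + 1.5·IQR or
  ≤ Q1 − 1.5·IQR. When IQR = 0 the literal rule would flag every tied
  value, so only strictly outside values are flagged in that degenerate
  case.

ΔHO = 100·(mean_HO/mean_CD − 1) is computed from unrounded means; rounding
happens only at serialization. Its confidence interval uses the delta
method on the ratio of means. Rate-ratio CIs (placement summaries) use the
exact conditional-binomial (Clopper–Pearson) interval on the count split,
scaled by the site-target ratio.

## Synthetic MA generator

The generator emulates the accumulation phase of an MA experiment in an
MMR-deficient strain; the defaults are the study conditions for all
property tests.

* Genome: 500 kb, GC 0.5, 500 non-overlapping genes (lengths truncated
  normal, 900 ± 300 nt, ≥ 120) laid around the circle with random gaps —
  dense gene packing like a real bacterial chromosome. Strands are chosen
  so that 55% of genes are CD in expectation, the genome-wide fraction in
  *E. coli*. One promoter per gene, TSS 25 nt upstream.
* Exposure: 200 lines × 1,000 generations. Mutation counts per class are
  Poisson with exposure = generations; there is no within-line lineage
  structure and no selection, the regime a single-cell-bottleneck MA
  design approximates.
* Transitions: per-pair rates 2.0e-8 (A·T) and 1.2e-8 (G·C) per
  generation, multiplied by `strand_bias_rho` when the diagnostic base is
  on the LGST (ρ = 1 in the null scenario, 2 in `strand_bias`, matching
  the ~2-fold asymmetry seen in real MMR⁻ spectra). Transversions at
  1e-9/bp uniformly. These give a catalog whose transition:transversion
  balance and per-CDS means are in the observed range at desk scale.
* Indels: rate per run of length ℓ is μ₀·bᶜ with c = min(ℓ, 8) − 5,
  μ₀ = 1e-7 per run per generation and b = 10. The calibration point is
  the strongest observed hotspot class: an 8 bp G·C run accumulating ~95
  events over ~10⁶ run-generations implies ~1e-4 per run per generation,
  and dividing out b³ anchors μ₀ at the 5 bp reference length. The
  exponential is saturated at ℓ = 8 because on a random genome an
  unsaturated b = 10 law would hand the entire indel budget to the single
  longest run (length ~10–11 in 500 kb), a concentration real genomes do
  not show; saturation length and b are both configuration fields.
  Isolated sites get a 2e-10 background. Each event inserts or deletes one
  run base at the left-normalized run start.
* Expression: log₁₀ TPM per phase = gene effect N(0, 0.5) + phase noise
  N(0, 0.15) around mean 1.0. tRNA-flagged genes are pinned to the top
  stratum (mean + 2.5 total SD) in all phases, mirroring constitutive
  structural-RNA output. `expression_coupled` scales a gene's BPS rate by
  10^(κ·(log₁₀TPM − mean)), κ = 0.5 in the preset and 0 by default, since
  the null of no expression–mutation coupling is the reference case.
* `trna_artifact`: 40 tRNA-like genes, 20 CD / 20 HO, four of them an
  identical cassette carrying an 8 bp C run and a 5 bp G run on the sense
  strand, placed 3 HO / 1 CD. The even family split makes the expected
  naive HO/CD indel ratio ≈ 3 when the four hotspot genes mutate
  identically — the placement artifact the decomposition is built to
  expose. The plain cassette has no run over 3 nt.

Reproducibility: (config, seed) → byte-identical FASTA/GFF3/TSV outputs;
all randomness flows through one `numpy` generator seeded from the config.

## What the synthetic tests do and do not show

The generator reproduces the *statistical structure* the analysis relies
on — Poisson accumulation, strand-biased transitions, run-length indel
scaling, hotspot placement, expression strata — but not real genomic
sequence composition (codon structure, skews, repeat content), real
operonic expression, context effects beyond homopolymer length, or
selection. Passing property tests therefore establish that the pipeline
recovers known effect sizes and stays null under the null at realistic
scale; they do not certify numeric agreement with any real organism's
catalog. In particular, published real-data quantities of this analysis
type (length correlations around ρ ≈ 0.8, distribution-fit R² ≈ 0.995,
and all real P values) require the deposited experimental catalogs, which
are deliberately not bundled; the test suite verifies the machinery
structurally on synthetic data of matching shape instead.

## Degenerate inputs and tie-breaks

Zero-variance samples are flagged, not raised, in correlation/t paths that
reports traverse (empty orientation classes yield `NA` rows, matching how
such table cells are normally printed); direct misuse (empty exposure,
zero-length CDS, transversion passed to the placement classifier) raises.
Genes wholly containing the origin are handled by the wrapping-interval
convention; wrap-around left-normalization is not attempted (the slide
stops at coordinate 1) so that positions stay comparable across lines.

## Problem sizes

Default test and acceptance runs use the full study conditions (500 kb,
500 genes, 200 lines × 1,000 generations — about 10¹¹ site-generations),
which complete in seconds; unit tests use 40–100 kb genomes where the
property under test does not need the full scale.
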