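# Methods

`nlrcensus` reconstructs, as a tested pipeline, a transcriptome-scale
census of plant NLR (nucleotide-binding, leucine-rich-repeat) immune
receptors: motif-based subfamily classification, redundancy clustering,
RPW8-domain phylogenetic grouping, cross-species statistics, and a drought
RNA-seq differential-expression stage.  This note records the models, the
parameters that matter, the numerical choices, and what the synthetic data
do and do not establish.

## Subfamily classification

NLRs fall into subfamilies by their N-terminal domain: TIR (TNL),
coiled-coil (CNL), or RPW8 (RNL), plus a conifer-specific non-TIR variant
(CNL2).  Within the central NB-ARC domain, the P-loop, Kinase-2/3, RNBS-C
and GLPL motifs are conserved across subfamilies, while RNBS-A, RNBS-D and
the MHD motif vary with the N-terminal domain and carry the classification
signal.  The diagnostic residues encoded in the default motif
configuration are:

* RNBS-D nine-position frame with a conserved aspartate (D4) in all
  subfamilies; a cysteine at position 5 (CNL), 6 (CNL2) or 7 (TNL); a
  glycine at position 6 in RNL, whose consensus is `CFLDLGxFP`;
* MHD variants: `QHD` (RNL — the glutamine is strictly required), `VHD`
  (CNL2), `MHD` (CNL and TNL, indistinguishable at this motif);
* RNBS-A variants for TNL, CNL and RNL; the CNL2 RNBS-A is polymorphic and
  deliberately has no consensus entry, so CNL2 calls rest on RNBS-D + MHD.

Motif patterns are data (`data/motifs_default.yaml`), not code: each
position is an exact residue, `h` (hydrophobic, default set AVLIMFWY, the
Kyte–Doolittle-positive residues) or `x` (any).  *Discriminant* positions
must match exactly and are never relaxed; other positions tolerate
`max_mismatch` (default 1) mismatches.  `X` (masked) residues match
nothing, so heavily masked sequences fall through to UNDETERMINED rather
than being guessed.  The exact consensus strings for motifs that carry no
published text anchor (shared chain motifs, the TNL/CNL/RNL RNBS-A
variants, TIR1–5) are curated from the standard published NB-ARC consensus
literature; correcting them requires editing only the config.

`locate_nbarc` anchors the NB-ARC region as the minimum-mismatch chain
P-loop < Kinase-2 < GLPL < MHD in sequence order with inter-motif gaps of
20–180 residues (about an NB-ARC span; configurable), ties broken by
leftmost position — the procedure is deterministic.  RNBS-A is then read
between P-loop and Kinase-2, RNBS-D between GLPL and MHD; if variants of
two subfamilies tie at the minimal mismatch count the slot is `ambiguous`.

`call_category` combines domain hits (external hmmscan-style tables or
planted synthetic annotations) with the signature: sequences with no TIR,
RPW8 or NB-ARC evidence are EXCLUDED (CC-only and LRR-only sequences are
not credible NLRs); NB-ARC-less TIR or RPW8 sequences are truncated
TNL/RNL; an NB-ARC with a non-canonical extra domain (e.g. a kinase) is
ATYPICAL; otherwise a 2-of-3 majority over the three signature calls
decides, with N-terminal contradictions (TIR over an RNL signature)
routed to ATYPICAL and no-majority to UNDETERMINED.  The 2-of-3 rule and
the ATYPICAL routing are this package's operationalization of a category
system whose tie rules are not published; coiled-coil detection is
deliberately absent (the CC region is too polymorphic for a reliable
consensus), so CNL is defined negatively.

## Identity clustering

Redundant transcripts (alleles, splice variants) are collapsed at 0.97
identity; RPW8 representative selection uses 0.60 and within-group
structure 0.80.  Identity comes from full Needleman–Wunsch/Gotoh global
alignment (BLOSUM62; gap of length L costs 11 + L) with identity =
identical aligned pairs / shorter sequence length — the global-identity
convention of greedy incremental clusterers.  Records are processed
longest-first (ties by id) and join the first representative at or above
the cutoff; this deterministic order replaces the internal order of
heuristic tools.  No k-mer prefilter exists because inputs are desk-scale;
a length-ratio short-circuit was considered and rejected because, with the
shorter-sequence denominator, a short sequence can be 100% identical to a
much longer representative.  Traceback tie-breaks (diagonal, then
vertical, then horizontal) are fixed so match counts are reproducible;
gap states open from the match state only.

## RPW8 groups

Full-length RPW8 domains (strictly >100 aa) are extracted from annotated
hits.  Distances are 1 − global identity; trees are Saitou–Nei neighbor
joining with Q-matrix ties broken by the smallest index pair and negative
branch lengths clamped to zero with the deficit moved to the sibling
branch (preserving the pair's patristic sum).  NJ replaces
maximum-likelihood tree search deliberately: the downstream quantity is
the nearest-anchor group of each query, which is robust to this
substitution, and every output records the substitution.  NJ is exact on
additive matrices, which the tests exploit (patristic recovery to 1e-9 on
random trees).

Queries are assigned to RNL groups 1–4 by nearest anchor, either by
patristic distance on a joint NJ tree (default) or by raw alignment
distance; a query equidistant from two groups within 1e-12 is left
unassigned, and the margin to the second-best group is reported.  Group 2
is anchored by ADR1 and group 4 by NRG1/RPW8.1/RPW8.2; groups 1 and 3 are
Gymnosperm-specific and anchored by packaged exemplars.  The shipped
anchor FASTA contains deterministic synthetic stand-ins (labelled in the
filename and headers), not the real Angiosperm sequences; analyses of real
data should replace them with the true reference domains.  Figure-level
subgroup structure (e.g. a 1b subgroup) is not modelled.

## Census statistics

The census tabulates architecture rows per species (truncated forms count
within their related subfamily: RPW8-only under RNL-related, TIR-only and
TIR–LRR under TNL-related).  Ratios are 100·count/transcriptome-size
rounded half-up to two decimals; the distribution column is each
subfamily's share of all *assigned* sequences (CNL+CNL2+RNL+TNL, across
species) rounded half-up to integer.  These conventions reproduce the
packaged seven-conifer fixture's printed derived values exactly
(distribution 63/22/6/9; ratios 0.73–1.35%).  Homogeneity between species
uses Pearson's chi-square without continuity correction on subfamily
columns (the original contingency layout is unstated; degenerate tables
are rejected).  The RNL-on-TNL relationship is ordinary least squares with
intercept on raw counts, reported with R² and the F statistic on
(1, n−2) df; the same fit on independent CNL counts serves as the null
comparison.

## Drought differential expression

Genes are kept when their count exceeds 5 in at least two libraries
(strict inequality).  Normalization is median-of-ratios: the reference is
the per-gene geometric mean over libraries (zero-free genes only) and each
library's size factor is the median count/reference ratio.  The per-gene
test is a negative-binomial GLM likelihood-ratio test: full mean model =
day + treatment + treatment-specific day effects, reduced model = day
only, so the LRT (chi-square, df = 5 for the five-day design) asks whether
treatment changed expression anywhere along the time course.  Genotype can
be added to both models as a covariate via config.  Gene-wise dispersion
is a method-of-moments estimate on normalized counts (floor 1e-8); there
is no dispersion shrinkage, no outlier refitting and no independent
filtering — this simplification relative to full DE packages is stated in
the run metadata of every report.  Reported log2 fold change is drought
versus control at the final sampling day (day 22).  P-values are
Benjamini–Hochberg adjusted; significance is adjusted p < 0.05.

DE genes are grouped by hierarchical clustering of per-gene z-scored
log2(normalized count + 1) profiles with manhattan distance and the
Ward.D2 criterion (scipy's `ward` linkage on a precomputed condensed
distance matrix), cut into k = 14 groups by default; group labels follow
first appearance in the input so the partition is order-stable.

## Synthetic data: what it emulates, and what it does not

Generators define the study conditions and carry complete truth tables,
validated structurally on every run.

* Proteomes: sequences are template scaffolds — N-terminal domain, linker,
  NB-ARC with the subfamily-correct motif chain, LRR repeats — with
  matching planted domain-hit rows.  Spacers draw from a hydrophilic
  alphabet that cannot satisfy hydrophobic positions or chain
  discriminants, and degenerate motif positions avoid residues a sibling
  variant requires, so an unmutated proteome classifies perfectly by
  construction.  Point mutations use one uniform draw per position
  independent of the rate (common random numbers), making mutated sets
  nested across rates and classifier recall monotone in the rate by
  construction.  Discriminant positions are spared unless corruption is
  requested.  Truncated forms default to 30% of RNL/TNL; atypical and
  LRR-only decoy counts are explicit parameters.
* Species panels: 49 species (the cross-species regression size), TNL
  counts uniform on 20–400, RNL = max(0, round(0.1·TNL + N(0, 5))), CNL
  independent — slope 0.1 mirrors the reported 1:10 RNL:TNL ratio, and the
  noise level keeps per-species RNL counts in the observed single-digit to
  ~40 range.
* Count matrices: balanced 3-genotype × 2-treatment × 5-day × 2-replicate
  design (60 libraries), NB counts with lognormal baselines (median 100),
  dispersion 0.05, and planted effects that ramp in at day 14 (half
  effect) and reach |log2FC| at days 18–22 — mirroring the reported onset
  of expression changes after 14 days of water deprivation.
* RPW8 sets: substitution-only divergence from known parents, bounded so
  sibling identity stays at or above 1 − 2·max_divergence; with
  max_divergence 0.2 and cutoff 0.60 parent recovery is exact by
  construction.

None of this emulates indel evolution, domain shuffling, assembly
artifacts, sequencing-depth structure or real phylogenetic covariance.
Passing tests therefore establish that the implementation is correct under
its stated model, not that the biological conclusions transfer to real
transcriptomes; headline dataset-scale counts (thousands of NLRs, hundreds
of DE genes) require the deposited data and are intentionally out of
reach at desk scale.

## Problem sizes and numerical choices

Default verification sizes are chosen to keep a full run at interactive
scale: 50 sequences per category for recall grids, 300 domains from 45
parents for clustering, 200 random 4–8-leaf trees for NJ, 1000 null genes
and 60 planted DE genes for calibration.  The null rejection fraction of
the LRT sits near 0.035–0.05 (slightly conservative, a known property of
moment dispersion estimates with modest library counts).  All generators
take explicit seeds (package default 20190812); identical seeds give
byte-identical outputs.  Degenerate inputs are defined everywhere:
empty census → all-zero table; all-zero genes → excluded with a log
entry; constant genes → log2FC 0, p ≈ 1; fewer than 3 labels → NJ error;
cutoffs outside (0, 1] → error.
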