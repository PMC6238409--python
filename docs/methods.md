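# Methods

This package implements the computational workflow for mapping the miRNA
regulatory landscape of a single 3'UTR: annotating its 3'-end signals,
enumerating and classifying candidate miRNA recognition elements (MREs),
narrowing them through a conservation funnel, quantifying pull-down (miTRAP)
qPCR experiments, and laying the validated interactions out as a positional
landscape with cooperative-site clusters. This note records the models, the
parameters that matter, and the design decisions taken where the procedure
was genuinely open.

## Coordinates and alphabets

All genomic coordinates are 1-based and inclusive, with position 1 the first
nucleotide after the stop codon. RNA input is transcribed to the DNA
alphabet on read (U -> T); `N` never pairs and never matches. Interval file
writers (BED6, bedGraph) convert to 0-based half-open coordinates at the
boundary and nowhere else.

## Poly(A)-signal and cleavage annotation

The scanner reports every occurrence — overlapping ones included — of a
configurable hexamer set (default AATAAA, ATTAAA, TATAAA, AGTAAA; AGTAAA is
scanned but typically absent in regions of interest) with start positions up
to a configurable region end. Downstream of each signal, every CA
dinucleotide inside a search window is a cleavage candidate, annotated with
the U/G (= T/G on the coding strand) fraction of a 16-nt window beginning
17 nt after the C. Cleavage-site biology places the CA 15–30 nt downstream
of the signal, but observed functional CAs can sit closer (~9 nt); the
search window is therefore configurable and defaults to the full [1, 30] nt
from the hexamer start, with distance measured hexamer-start to C. Whether
reported hexamer positions index the start or the end of the motif is a
convention choice; this package indexes the start. Candidates whose U/G
window runs off the sequence end are flagged truncated, not dropped.

## Seed-match MRE model

A mature miRNA recognizes targets through its seed (nt 2–7). Four site
types are enumerated, ordered 8mer > 7mer-m8 > 7mer-A1 > 6mer:

* **6mer** — Watson–Crick pairing of the target to miRNA nt 2–7;
* **7mer-m8** — the 6mer core plus pairing at miRNA nt 8;
* **7mer-A1** — the 6mer core plus a target adenine opposite miRNA nt 1
  (the adenine counts regardless of the identity of miRNA nt 1; the A1
  position is not a pairing position and can carry neither wobble nor
  mismatch);
* **8mer** — both the m8 pairing and the A1 adenine.

Relaxed configurations tolerate at most one G:U wobble (target G opposite
miRNA U, or target U opposite miRNA G) and/or at most one mismatch among the
pairing positions of the evaluated type. Offset-6mer, 6mer-alpha, G-bulge
sites and 3'-supplementary pairing are out of scope, as is any
thermodynamic accessibility scoring: the scanner's job is exhaustive
combinatorial enumeration of the seed-match universe.

A site's `start` is its 5'-most target nucleotide, so 7mer-m8/8mer sites
start one nucleotide before their seed core. `(miRNA, start, type)` is the
unique-hit key; two miRNAs sharing a seed yield two distinct hits at the
same coordinates. Under strongest-only reporting exactly one type is
emitted per seed-core placement; under all-types reporting the full
containment chain is emitted (every 8mer locus also satisfies the three
weaker types). Windows at UTR edges are padded with a sentinel that can
satisfy no pairing requirement.

## Conservation funnel

The funnel narrows a hit universe in fixed stage order: (1) the input
universe; (2) drop hits with a seed mismatch; (3) drop 6mer hits with a G:U
wobble; (4) keep hits conserved in >= 85% (configurable) of clade orthologs;
(5) keep hits whose miRNA is annotated in every required species (default:
human). Stage counts are non-increasing by construction, and stages 2 and 3
commute.

"Conserved in an ortholog" is not self-defining; here it is operationalized
as: the alignment columns of the reference site, gap-stripped in the
ortholog, contain a site of equal-or-stronger type for the same miRNA (an
exact-sequence-identity mode is available for stricter analyses). Species
whose window exceeds a gap fraction cap (default 0.5) leave the denominator;
a site whose denominator is empty has undefined conservation, fails the
filter and is flagged in the report rather than silently dropped.

Surviving hits collapse to *unique MREs* by single-linkage merging of
footprints overlapping by >= 6 nt — the length of a shared seed core — and
the redundancy summary counts MREs targeted by multiple miRNAs and miRNAs
with multiple MREs. Published recounts of the 6mer+wobble exclusion stage
for the Pax6 3'UTR universe disagree (190 vs 191); every funnel report
carries that note verbatim instead of resolving it. Externally enumerated
universes can be imported through a documented TSV column contract
(`mirna, start, type, n_wobble, n_mismatch[, conservation, species_flags]`),
so the funnel runs on prediction tables without re-deriving the universe.

## qPCR quantification

* **Efficiency.** Amplification efficiency comes from a ten-fold dilution
  standard curve as `E = 10^(1/slope)`, slope from the least-squares
  regression of Ct on log10 fold-dilution. The bait (GFP) primer pair used
  for normalization has E = 1.952; TaqMan miRNA assays are taken at the
  ideal E = 2. An r² below 0.99 flags a warning, not an error.
* **QC.** In order: wells whose minus-RT control is within 10 cycles of the
  +RT Ct are excluded; technical replicate groups with Ct SD > 0.5 cycles
  are discarded; an assay is *detected* only when every wild-type pull-down
  replicate has Ct < 40; undetermined control-pull-down Cts of detected
  assays are substituted by 40 (every other undetermined value propagates
  as undefined, never as zero). Each discard carries its rule tag, the
  reasons partition the discarded set, and the filter is idempotent.
* **Quantities.** Expression relative to U6 is `2^(Ct_U6 − Ct_miRNA)`;
  efficiency-corrected fold differences are `E^(Ct_ref − Ct_test)`; the
  Pfaffl normalized relative quantity is
  `NRQ = 2^dCt_miRNA / 1.952^dCt_GFP` with `dCt = control − wild-type`
  contrasts named in configuration, never inferred. With both efficiencies
  at 2 the NRQ reduces to the classic 2^ddCt. The miTRAP ratio divides the
  pull-down relative abundance `1.952^meanCt[GFP] / 2^meanCt[miRNA]` by the
  lysate abundance relative to U6, measuring enrichment independent of
  cellular expression.
* **Classification.** The point NRQ over the four pull-down replicates is
  the geometric mean. The 95% CI is a t-interval on log2-transformed
  replicate NRQs, back-transformed; the upstream software used for the
  original analyses does not document its interval math, so the log-t
  interval is this package's stated stand-in. Categories: undetected ->
  `no_interaction`; NRQ <= 1 -> `non_specific` (threshold configurable);
  NRQ > 1 with CI low > 1 -> `high_confidence`; otherwise
  `low_confidence`.
* **Mann–Whitney.** The two-sided exact test enumerates every assignment of
  the pooled midranks to one group (the exact permutation null of U, which
  handles ties), reporting `p = 2 × min(tail probabilities)` capped at 1,
  plus both one-sided tails. Above 12 pooled observations it switches to a
  flagged normal approximation.

## Positional landscape

Each interacting miRNA contributes one peak per MRE: an interval of 25 nt
(configurable) on either side of the MRE position, at the height of the
miRNA's mean NRQ. The per-nucleotide track composites peaks with max, not
sum, so values remain interpretable as NRQs; stretches covered by two or
more peaks are reported separately as overlap intervals. Before peak
construction, all-types site lists are collapsed to one representative site
per miRNA per overlapping locus (strongest type wins) so a single locus is
never double-counted.

Site pairs spaced 8–50 nt apart (defaults; measured center-to-center, with
an edge-gap mode available) are *cooperative* candidates, excluding pairs
whose miRNAs share common or overlapping MREs — such miRNAs cannot occupy
the UTR simultaneously — and directly overlapping footprints. Peaks with
overlapping intervals merge by single linkage into maximal cluster regions,
each reporting whether it contains a cooperative pair. Cluster counts are
non-increasing in the peak half-width. No statistical test of cluster
significance is attempted.

## Synthetic data: what it emulates, and what it does not

The generators produce every input class the pipeline consumes, each
deterministic under a fixed seed and each with a truth table sufficient to
score downstream precision and recall:

* **miRNAs** — random 22-nt sequences with pairwise distinct seeds.
* **Planted UTRs** — background sequence at configurable GC content
  (default 0.45), *rejection-sampled* until it contains no spurious sites at
  the requested scan strictness, with target windows written per site type
  and with requested wobble/mismatch edits. Rejection (rather than masking)
  is used because masking would bias background composition around planted
  sites; the cost is that synthetic UTRs are not uniform-random sequences.
* **Ortholog alignments** — each non-reference species retains each planted
  site with its configured probability; disruption is a single seed
  substitution chosen to break both Watson–Crick and wobble pairing.
  Background positions substitute at rate 0.02 and gap at rate 0.01
  (deletions only, so the reference row stays ungapped). The species count
  parameter counts non-reference orthologs.
* **Ct plates** — `Ct = baseline − log(abundance)/log(E)` plus Gaussian
  replicate noise (defaults: bait baseline 18, miRNA baseline 24 cycles,
  noise SD 0 unless asked for; the noisy analyses here use SD 0.3 cycles,
  a realistic technical-replicate spread). Quadruplicate wild-type and
  control pull-downs, optional triplicate lysate wells, minus-RT wells
  offset +12 cycles, and undetermined-Ct dropout at the 40-cycle floor.
  With zero noise the pipeline NRQ inverts the generator exactly.
* **Dilution series** — `Ct_k = c0 + k/log10(E)` for ten-fold steps, so the
  efficiency estimator round-trips any configured E.
* **Poly(A) regions** — hexamers planted at given positions on a background
  scrubbed of all other variant occurrences; a synthetic stand-in for
  genomic reference sequence, not any actual locus.

Passing tests on these inputs demonstrate the arithmetic and the
bookkeeping, not biology: synthetic UTRs have no secondary structure or
compositional heterogeneity, synthetic alignments have no phylogenetic
correlation between species, and simulated Ct noise is i.i.d. Gaussian,
which real plates only approximate.

## Problem sizes

The bundled analyses use an 876-nt UTR, six miRNAs, 10–20-species
alignments, quadruplicate pull-downs, and 200–500-replicate calibration
simulations — sizes chosen so the whole chain (scripts and test suite) runs
in well under a minute on one core while every stage still exercises the
regime the statistics assume (small-n t-intervals, exact-test sample
sizes).

## Known limitations

* Conservation is a per-species presence fraction, not a branch-length
  weighted score; closely related orthologs are counted independently.
* The funnel consumes alignments, it does not build them.
* The exact Mann–Whitney switches to the normal approximation above 12
  pooled observations; the approximation is flagged but not continuity-
  matched against the exact tail beyond that point.
* The landscape treats every MRE of a miRNA at that miRNA's single mean
  NRQ; site-level binding contributions are not resolvable from pull-down
  data.
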