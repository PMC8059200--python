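# Methods

`trgscout` identifies taxonomically restricted gene families (TRGFs) in a
clade of annotated genomes and infers whether each was born de novo from
noncoding sequence. This note documents the models, the decision rules, the
synthetic validation data, and the numerical choices; it is the place where
genuinely open design decisions are recorded.

## The detection funnel

The pipeline runs eight stages in a fixed order; every input family receives
exactly one disposition and stage counts are non-increasing:

1. **Homology families.** All-vs-all protein comparison across the input
   proteomes. A pair is homologous when a local alignment is significant
   (E ≤ 1e-03) *and* the alignment covers at least 61% of the shorter
   protein (the *length tolerance ratio*; strictly below 61% is rejected,
   exactly 61% passes). Accepted pairs form a graph; families are its
   connected components; unlinked genes become singleton families. This is a
   declared simplification of full orthology inference (no witnesses of
   non-orthology, no tree reconciliation): downstream logic depends only on
   family membership patterns. Within-species pairs do not create links;
   paralogs join a family only through cross-species edges.
2. **Clade restriction.** Keep families with members in ≥ 2 *distinct* focal
   species and none outside the focal clade. Single-species families are
   excluded: without cross-species conservation there is insufficient
   evidence of function, and requiring two independently assembled and
   annotated genomes suppresses assembly/annotation artifacts.
3. **Protein screen.** Each member protein is searched against all outgroup
   proteins (E ≤ 1e-03, query coverage ≥ 50%, boundary inclusive). A family
   is removed only when *every* member has at least one qualifying outside
   hit — a diverged homolog outside the clade means an earlier origin.
4. **DNA homology.** For each member gene, both the whole gene sequence and
   the concatenated CDS are used as nucleotide queries against all genomes,
   both strands. Hits are filtered per query form (E ≤ 1e-03, coverage
   ≥ 50%), overlapping hits on the same region/strand are amalgamated (union
   interval, best E-value, coverage recomputed from the union of query
   spans), and when more than 1,000 hits survive only the five best per
   species are kept. The member gene's own locus is always present as the
   self-hit. Two curation rules that are usually manual are codified and
   deterministic: hits lying wholly inside an intron of an annotated
   non-member gene are dropped, and hits that end in the middle of the query
   gene are extended on the subject side by the missing query length (plus a
   30-nt indel allowance, bounded by 500 nt per side) so truncated
   homologous regions enter the alignment in full.
5. **Outgroup ORF filter.** The best region per species is star-aligned
   around the candidate row (see below). ORFs are called on each close
   outgroup row; if any outgroup ORF covers ≥ 50% of the candidate ORF's
   alignment columns (in ≥ 1 outgroup species; both thresholds inclusive and
   configurable), the family is removed as having an earlier origin.
6. **Continuity filter.** "Continuous alignment" is defined operationally:
   an outgroup row is continuous when it covers ≥ 80% of the candidate
   gene's alignment span with no gap block longer than 50 columns (both
   configurable, both declared rather than hidden). Families with no
   continuous close-outgroup row are set aside as *undetermined* — it cannot
   be known whether the region diverged beyond recognition, was rearranged,
   or is missing from the assembly.
7. **Annotation QC.** Codified consistency checks replace manual
   inspection: CDS must begin with ATG and end with a stop and contain no
   premature stop; splice signals must be canonical GT–AG (strand-aware);
   and across species the aligned start/stop codon columns and splice-site
   columns must coincide (column slack 0 by default). A candidate must have
   protein-coding annotation in ≥ 2 species.
8. **Origin inference.** See the decision table below.

## Origin evidence and classification

*Synteny.* For each species with an alignable region, the nearest three
annotated genes up- and downstream (and any host gene whose intron contains
the region) are mapped to families; synteny holds when at least one flanking
family is shared by all species with regions (quorum configurable). Shared
flanking context is the evidence that weakly conserved regions are truly
orthologous.

*Intron mod-3 test.* An intron whose length is not divisible by 3 likely
predates the ORF it interrupts: intronization of an existing ORF at a
non-multiple-of-3 length would have caused a frameshift. Lengths divisible
by 3 are *inconclusive* — they are not evidence of later intronization.

*Conserved-stop frame analysis.* The designated anchor start codon defines
the +1 frame; +2/+3 are the other frames on the same strand. A *conserved
stop* is a gap-free codon column triple that is a stop in every row. Each is
assigned a frame per row by counting that row's non-gap characters between
the anchor column and the codon, mod 3, so interior indels shift the frame
per row; when rows disagree the codon is reported frame-ambiguous and not
counted (ambiguity is propagated, never resolved). The "conserved in all
rows" quantifier is strict by default; a sub-unanimous quorum is available
but off.

*Distant-outgroup start check.* Where distant outgroups align, the presence
of an in-frame ATG within ±30 columns of the candidate's mapped start
weakens a de novo call (the region could be a pseudogenized ancestral gene);
absence supports it; no alignable region yields "unavailable" and the
classification falls back to ingroup evidence.

*Decision table.* (a) conserved outgroup ORF → `earlier_origin`; (b) no
continuous outgroup alignment → `undetermined`; (c) outgroup regions
alignable but noncoding (no covering ORF), synteny conserved, distant start
check absent or unavailable, no unexplained intragenomic duplicates of the
outgroup region → `de_novo`; (d) an outgroup row nearly identical to the
candidate (identity ≥ 0.9 by default) whose only conserved-stop-free frame
is the candidate's frame → `diverged_ancestor`. The frame pattern alone
cannot separate (c) from (d): a genuinely de novo ORF also leaves its
alternate-frame stops conserved in all species, so near-identity of the
outgroup row is the discriminator, mirroring the reasoning that an extremely
well-conserved "pseudogene" sharing the open frame indicates an ancestral
ORF. A "present" distant start codon always blocks `de_novo` (conservative
downgrade to `undetermined`).

## Alignment machinery

Local alignment is affine-gap Smith–Waterman, backed by Biopython's
`PairwiseAligner` (C implementation) behind the package's own interface.
Defaults: BLOSUM62 with gap open 11 / extend 1 for proteins; +1/−2 with gap
5/2 for nucleotides; a gap of length L costs open + extend·L. Significance
uses the Karlin–Altschul form E = K·m·n·e^(−λS) with tabulated gapped
constants (protein λ = 0.267, K = 0.041; nucleotide λ = 1.28, K = 0.46); an
ungapped formula applied to gapped scores is a standard approximation and
sufficient for the coarse 1e-03 threshold. For all-vs-all family building,
n is the total residue count of the protein database (search-against-a-
database semantics) — using only the pair's m×n would admit chance
low-identity alignments as "significant". Genome searches are seeded with
exact k-mers (k = 11 nucleotide, k = 4 protein), clustered by diagonal band,
and extended by windowed alignment; among co-optimal alignments the engine's
first (deterministic) traceback is reported.

The multiple alignment behind the RegionAlignment contract is a
deterministic reference-anchored star alignment: each region is aligned
semi-globally (free end gaps) to the candidate self-hit row and gap patterns
are merged into a master alignment. Any MSA engine could back the same
contract; what is normative is the invariant set — equal row lengths,
de-gapping a row reproduces its (strand-adjusted) genomic substring, and
column→coordinate maps strictly monotone over non-gap columns — which is
re-validated after every alignment.

## The synthetic clade generator

The generator is the package's study system: a five-species clade shaped
like the *Drosophila melanogaster* subgroup — a focal triplet (sim, sec,
mel) and a close outgroup pair (yak, ere) — with split times 0.5 / 1.4 /
3.3 time units (the outgroup pair splits at 1.1, read off the study
clade's tree between the 1.4 and 0.5 splits). Time maps to branch length at
0.02 substitutions/site per unit by default, chosen so that focal↔outgroup
noncoding identity stays ~85–90%: alignable in the close outgroups, marginal
further out, matching the situation the method is designed for. Both the
tree and the rate are free configuration.

The ancestral genome carries 50 two-exon protein-coding genes (CDS 100–200
codons, introns 50–80 nt with canonical GT–AG signals, random strand)
separated by 200–500 nt intergenic spacers. Evolution along each branch
applies Jukes–Cantor substitutions (vectorized; an arbitrary 4×4 rate
matrix is accepted and exponentiated) and Poisson indels at 0.1× the
substitution rate with geometric lengths of mean 3. Purifying selection on
annotated coding genes is emulated by rejection: substitutions that would
break a start/stop codon or splice dinucleotide, or create a premature stop,
are reverted to the parental base; indels are confined to unannotated
sequence. Pseudogenes and unannotated loci drift freely.

Planted events, each recorded in a truth table whose coordinates are checked
against the emitted annotations after every simulation:

- **De novo birth** — a noncoding progenitor locus is planted in the
  ancestor between conserved genes (so the synteny checker has signal): the
  future ORF sequence with its start codon broken and stop codons planted
  in all three frames every ~90 nt, the typical state of noncoding DNA, so
  no long ORF survives in any frame in non-bearing lineages. On the event
  branch the clean ORF (default 120 codons, with a 52-nt intron — not a
  multiple of 3 — carrying canonical splice signals) replaces the
  progenitor and is annotated; only bearing species carry the annotation,
  emulating the fact that real annotation pipelines only annotate the gene
  in the species where it exists.
- **Duplication + rapid divergence** — an existing gene is copied into
  intergenic sequence and evolves at a multiplied rate (default ×15) while
  remaining a valid protein. At this divergence the copies typically remain
  protein-detectable against the parent family and are removed at the clade
  filter (the realistic fate); the protein screen and the
  missing/ORF-bearing outgroup alignment catch the escapes. In no case can
  the copy be classified de novo.
- **Pseudogenization** — a premature stop ~25% into the CDS; the gene is
  rebadged `pseudogene` and released from purifying selection. Planted in a
  close outgroup by default, which removes the family at the clade filter.
- **Gene loss** — the gene span is deleted with coordinate lifting.

What the generator does *not* emulate: codon-level selection (dN/dS),
rate heterogeneity among sites, transposable elements and repeats, assembly
gaps and fragmentation (N handling exists but synthetic genomes are
N-free), multi-isoform annotation, and polymorphism. Passing the synthetic
recovery tests therefore shows the pipeline's logic is correct under clean,
realistic divergence — not that real-genome artifacts (mis-assembly,
repeat-induced spurious hits, annotation noise) are handled, which is
exactly why the QC and undetermined categories exist.

## Numerical and interface choices

- Coordinates are 0-based half-open internally; GFF3 I/O converts to/from
  1-based inclusive at the boundary only. One transcript per gene is
  modelled (longest CDS wins, logged); the analysis is gene-level.
- "Set of CDSs as a query" is implemented as the concatenated CDS as a
  single second query form; the coverage rule then applies per query form.
- ORF calls require both an ATG and a terminal stop, default minimum 50
  codons (the confirmed genes in the study system are 113–155 aa; shorter
  ORFs are too often conserved by chance); windows containing N are skipped
  and reported rather than guessed through.
- Exactly-at-threshold inputs pass every inclusive boundary: ratio 0.61,
  coverage 0.50, 1,000 hits (the cap triggers only when *exceeded*).
- All report writers emit sorted, deterministic output; identical config +
  seed give byte-identical funnel reports.
- The benchmark's confidence intervals are Clopper–Pearson.

## Problem sizes

Default validation runs use 5 species × ~45 kb genomes × ~50 genes, 20
replicates for recovery experiments and 200 replicates × 10 kb for the
substitution-model calibration; these sizes give stable rates (binomial SE
≈ 7 points at n = 20 for rates near 90%) while keeping a full validation
cycle to a few minutes on one CPU.

## Known limitations

- The star alignment is anchored on one candidate row; badly rearranged
  regions would need a true MSA engine behind the same contract.
- The diverged-ancestor rule keys on near-identity (≥ 0.9) of an outgroup
  row; a diverged ancestral ORF below that identity with all its alternate
  frames blocked would be called de novo if all other de novo conditions
  held. The conservative distant-outgroup start check is the main guard.
- Karlin–Altschul constants are tabulated, not fitted per scoring scheme;
  E-values are approximations adequate for the coarse thresholds used.
- OMA-style verified-pairs orthology and tree reconciliation are out of
  scope; families are connected components of significant pairs.
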