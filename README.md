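# trgscout

Conservative identification of **de novo-born taxonomically restricted gene
families (TRGFs)** in clades of annotated genomes, with a synthetic-clade
simulator that makes every stage of the analysis testable against known
ground truth.

## The problem

Taxonomically restricted genes — genes present in only one clade — are the
raw observations behind claims about de novo gene birth. But a gene with no
detectable homologs outside its clade is not necessarily new: it may be a
rapidly diverged copy of an old gene, a pseudogenized relic mistaken for a
gene, or an annotation artifact. Phylostratigraphy (dating genes by the
deepest clade with detectable protein homology) cannot tell these apart.
The only way to be confident a TRGF was born de novo is to find the
**homologous noncoding DNA** in outgroup species and show that it is truly
noncoding — disrupted by stop codons and frameshifts — while synteny
confirms the regions are orthologous and more distant outgroups rule out
pseudogenization scenarios.

`trgscout` implements this evidence chain as a deterministic pipeline for
researchers studying gene birth in compact, well-annotated clades (the
design target is a five-species *Drosophila melanogaster*-subgroup-like
setting: a focal triplet plus a close outgroup pair).

## The method

Candidate families flow through a funnel; every family gets exactly one
disposition and counts are non-increasing:

```
proteomes ─► homology families        all-vs-all local alignment; a pair is
                                      homologous iff E ≤ 1e-03 AND
                                      aln_len / min(len) ≥ 0.61
          ─► clade restriction        members in ≥2 focal species, none outside
          ─► protein screen           removed iff EVERY member hits an
                                      outgroup protein (E ≤ 1e-03, cov ≥ 50%)
          ─► DNA homology             gene + concatenated-CDS queries, both
                                      strands; hits merged, capped (1,000 → 5
                                      best/species), star-aligned with
                                      coordinate maps
          ─► outgroup ORF filter      removed iff an outgroup ORF covers
                                      ≥ 50% of the candidate ORF
          ─► continuity filter        outgroup row covers ≥ 80% of the
                                      candidate span, gap blocks ≤ 50 cols
          ─► annotation QC            ATG/stop present, GT–AG splice signals,
                                      starts/stops/splices aligned across species
          ─► origin inference         synteny context, intron mod-3 test,
                                      conserved-stop frame analysis, distant-
                                      outgroup start check
                                      → de_novo | earlier_origin |
                                        diverged_ancestor | undetermined
```

Key origin evidence, in the field's notation: an intron of length ≢ 0
(mod 3) predates its ORF (later intronization would have frameshifted it);
and with the candidate's start codon defining the +1 frame, stop codons
conserved across *all* species in the +2/+3 frames — with +1 the only frame
free of conserved stops — show which frame was ancestrally open.
Frame assignment tracks per-row cumulative indel offsets and reports
frame-ambiguous codons instead of guessing.

See `docs/methods.md` for the full model description, defaults, and
limitations.

## Worked example

Simulate a five-species clade with one planted de novo birth (on the
sim–sec stem), one rapidly diverging gene duplicate, and one
pseudogenization, then run the detection funnel blind:

```python
from trgscout import simulate_clade, run_pipeline, PipelineConfig
from trgscout.synthetic_clade import default_study_events
from trgscout.pipeline import classification_for_locus

genomes, truth = simulate_clade(events=default_study_events(), seed=1)
report = run_pipeline(genomes, PipelineConfig(seed=1))
print(report.stage_counts)
print(report.classifications)
print("planted de novo locus ->", classification_for_locus(report, "dn1"))
```

prints

```
{'families': 51, 'clade_restricted': 1, 'after_protein_screen': 1,
 'with_outgroup_alignment': 1, 'after_orf_filter': 1, 'after_continuity': 1,
 'after_qc': 1, 'classified': 1}
{'fam_1d63dbe452': 'de_novo'}
planted de novo locus -> de_novo
```

Reading this: the 50 conserved ancestral genes form 49 five-species
families plus the parent family that absorbed the diverged duplicate — all
rejected at the clade filter, as is the pseudogenized family which still has
an outgroup member. The single clade-restricted candidate is the planted
de novo family; it survives every validation stage, and the origin evidence
(outgroup regions alignable but stop-disrupted, flanking synteny conserved,
52-nt intron ≢ 0 mod 3) classifies it `de_novo`. The disposition record
carries the full rationale string per family.

The same is available from a shell:

```bash
trgscout simulate --seed 17 --out clade/          # FASTA+GFF3+truth.tsv
trgscout run --genomes clade/ --seed 17 --out report.json
trgscout benchmark --replicates 20 --seed 1 --out bench.tsv
```

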