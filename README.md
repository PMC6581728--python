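# splicevol

Comparative alternative-splicing (AS) evolution analysis as a tested,
reusable pipeline:

* **AS detection** — junction-evidence filtering (overhang ≥ 13 bp, intron
  length 41–50,000 bp), classification into intron retention (IR),
  alternative donor (AltD), alternative acceptor (AltA) and exon skipping
  (ES), and percent-spliced-in (PSI) quantification with the ≥ 10-read
  support rule.
* **Cross-species conservation** — one-to-one orthologs by reciprocal-best
  protein alignment, exon–exon junction (EEJ) matching by reciprocal-best
  six-frame translated alignment of 200-bp flank sequences (≥ 3 aa aligned
  on both flanks, ≥ 60 bp coverage, significance threshold), conserved /
  lost / gained / type-switch labels and the 5×5 transition spectrum.
* **PTC / NMD annotation** — longest-ORF finding and the 50-nt rule
  (stop ≥ 50 nt upstream of the final exon–exon boundary), AS±PTC event
  classification, and Fisher-exact conservation comparison.
* **Splice-site determinants** — 12-mer splice-site weight-matrix models
  and candidate-site scanning (match score > 2), distances to the nearest
  alternative site / internal GT-AG with frame flags, polypyrimidine and
  UA tract detection (> 85% composition, ≥ 5 nt), branch-site heptamer
  search, log2 odds-ratio effect sizes and hexamer enhancer/silencer
  enrichment.
* **Classifiers** — the splicing-code model (balanced alternative vs
  constitutive, 60/20/20 split, validation-AUC hyperparameter selection,
  permutation importance) and the conservation model (1:1:1 class
  balancing, best of 10 repeats by complete-dataset AUC).
* **Profiles** — PSI (0.05 < PSI < 0.95 filter) and binary AS matrices,
  Spearman/binary-distance correlation, and average-linkage clustering
  with bootstrap node support.
* **Synthetic data** — a seeded multi-species cohort generator that plants
  GT..AG introns, AS events with known PSI, ortholog pairs with controlled
  divergence and known conservation labels, PTC-generating isoforms, and
  distance-dependent AS signal, so every stage is testable offline.

## CLI

```bash
splicevol simulate --config cohort.json --seed 1 --out bundle/
splicevol detect --junctions bundle/sp0/junctions.tsv --gff bundle/sp0/genes.gff3 --out events.tsv
splicevol conserve --species-a bundle/sp0 --species-b bundle/sp1 --out cons/
splicevol ptc --gff bundle/sp0/genes.gff3 --fasta bundle/sp0/genome.fa --out ptc.tsv
splicevol features --junctions ... --gff ... --fasta ... --side AltA --out matrix.tsv
splicevol train-code --matrix matrix.tsv --seed 1 --out model/
splicevol train-conservation --pairs pairs.tsv --repeats 10 --out cmodel/
splicevol profile --matrix psi.tsv --mode psi --n-bootstrap 1000 --out clust/
```

The junction TSV dialect is `chrom, intron_start, intron_end, strand,
reads, min_overhang, intron_coverage` with 0-based half-open intron
intervals; gene models are standard GFF3 (1-based inclusive).

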