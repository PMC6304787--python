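# nixlocus

In-silico characterisation of the male-determining *Nix* locus of the Asian
tiger mosquito *Aedes albopictus*, as a reusable, tested Python pipeline.

In *Aedes* mosquitoes the sexes share three homomorphic chromosome pairs;
maleness is decided by a dominant M factor carried hemizygously on one
homologue of chromosome 1. The candidate factor *Nix* can be characterised
without a finished genome by purely sequence-level operations, and this
package implements that tool-chain end to end:

- **`walker`** — iterative composite assembly: a seed sequence is extended
  through genomic and transcriptome contig databases by *exact* (100%
  identity) end-overlaps, both strands, until no database extends it
  further, with an audited extension log.
- **`annotate`** — exon/intron gene-model inference by explaining a spliced
  cDNA as exact excisions from the genomic composite; splice-site
  classification against the canonical donor `AG^GTAAGT` and acceptor
  `TTNCAG^GT` consensus; longest-ORF CDS finding.
- **`isoforms`** — spliced and intron-retained (IR) isoform enumeration with
  protein products and truncation calls, plus IR-fraction estimation from
  length-classified amplicon pools (Wilson 95% CI on
  *f̂ = n_retained / n_total*).
- **`pcr`** — in-silico PCR (exact full-length primer matching, amplicons
  measured 5'-primer-end to 5'-primer-end) and the presence/absence sexing
  caller gated by an 18S rDNA amplification control.
- **`popscan`** — ungapped semi-global placement of partial resequenced
  fragments on the reference and polymorphism counting, with `-`/`N` as
  missing data.
- **`synthetic`** — a seeded generator that reproduces the locus
  architecture exactly: a 1580-nt composite; coding exons of 674 and 175 nt
  split by a 107-nt intron (donor `GTTTGT`, non-canonical; acceptor
  `TTTCAG`); a spliced CDS of 282 codons; an in-frame stop 26 nt into the
  intron so the IR isoform truncates to 233 aa; a 701-nt seed; genomic
  contigs of 379/257/315 nt and transcripts of 603/583/257/214 nt placed so
  the walk extends the seed by 174/145/560 nt.
- **`pipeline`** — one config, one seed, all stages, YAML summary.

## Worked example

```bash
python examples/01_composite_walk.py
```

```
seed: 701 nt
round 1 [genome] gA (forward): overlap 205 nt, extends five_prime by 174 nt -> 875 nt
round 1 [genome] gB (forward): overlap 112 nt, extends three_prime by 145 nt -> 1020 nt
round 2 [transcriptome] t1 (reverse): overlap 43 nt, extends three_prime by 560 nt -> 1580 nt
final composite: 1580 nt
```

Two genomic contigs extend the 701-nt seed to a 1020-nt composite (+174 nt
at the 5' end, +145 nt at the 3' end); one transcript then extends the 3'
end by 560 nt to the full 1580-nt locus; a further genomic round adds
nothing because the remaining contig is fully contained. The other
examples continue the analysis:

```
$ python examples/02_gene_model.py
exons:   ((101, 774), (882, 1056))  (lengths (674, 175))
introns: ((775, 881),)  (lengths (107,))
intron 1: donor AG^GTTTGT (canonical: False), acceptor TTTCAG^GT (canonical: True), GT..AG: True

$ python examples/03_intron_retention.py
spliced: transcript 849 nt, protein 282 aa, truncated: False (stop: cds_end)
intron_retained: transcript 956 nt, protein 233 aa, truncated: True (stop: intronic)
amplicon counts {309: 104, 202: 96}: IR fraction 0.520 (95% CI 0.451-0.588, true 0.5)

$ python examples/04_sexing_assay.py
         male_pupa: male          (nix_833=+, nix_309=+, nix_1121=+, control=+)
       female_pupa: female        (nix_833=-, nix_309=-, nix_1121=-, control=+)
 failed_extraction: indeterminate (nix_833=+, nix_309=+, nix_1121=+, control=-)

$ python examples/05_population_scan.py
unmutated cohort: 11 fragments (721-767 nt), 0 variable sites
mutated cohort: 2 injected variants, 2 variable sites recovered
```

The intron-spanning assays shrink by exactly the intron length on spliced
templates (833 → 726 nt and 309 → 202 nt), which is what makes the
309/202 pair a direct read-out of intron retention, and the locus assays
are male-only because the locus is hemizygous on the M homologue.

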