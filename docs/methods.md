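# Methods

## The problem and the model

A dominant male-determining factor (*Nix* in *Aedes* mosquitoes) sits
hemizygously on the M homologue of an otherwise homomorphic chromosome.
Characterising such a locus before a finished genome exists relies on a
chain of sequence-level inferences, each of which this package implements
as a separately testable operation:

1. **Composite assembly by exact end-overlap walking.** Starting from a
   seed sequence, contig databases are searched for contigs whose end
   overlaps an end of the growing composite at 100% identity (both
   orientations). The best available extension is applied greedily and
   the databases are cycled until a full cycle adds nothing. This mirrors
   BLASTN-style locus reconstruction where only perfect overlaps are
   trusted; it is deliberately not a general assembler (no graphs, no
   mismatches, no gaps).
2. **Gene-model inference from spliced evidence.** A spliced cDNA that
   matches the genomic composite in exact blocks is explained as the
   genomic sequence with internal blocks excised. Gaps at least
   `min_intron` long become introns; shorter gaps are flagged as putative
   deletions. The spliced/unspliced size difference of any assay spanning
   the intron equals the intron length exactly.
3. **Intron retention (IR) as a truncation mechanism.** Retaining the
   intron in the mature transcript exposes an in-frame stop codon inside
   the intron, truncating the product (282 aa spliced vs 233 aa
   retained on the canonical locus). The IR fraction of a transcript pool
   is estimated from discrete length-classified amplicon counts, not gel
   band intensities.
4. **Presence/absence sexing.** Because the locus is hemizygous on the M
   homologue, locus amplicons appear only in males. Calls are gated by an
   amplification control (an 18S rDNA fragment): no control product means
   the template failed and the call is indeterminate, never female.
5. **Polymorphism scanning.** Partial resequenced fragments are placed on
   the reference by ungapped semi-global alignment (free end-gaps on the
   reference) and substitutions are counted; `-` and `N` are missing
   data. The model is haploid, which is exact for a male-linked locus
   sequenced from single males.

## The canonical synthetic locus

The generator (`nixlocus.synthetic`) emits a locus whose *architecture*
is fixed and whose *background* is seeded random sequence:

| element | coordinates (1-based) | content |
| --- | --- | --- |
| 5' flank | 1–100 | random |
| exon 1 | 101–774 (674 nt) | CDS codons 1–224 + `AG` of the junction codon |
| intron | 775–881 (107 nt) | `GTTTGT` donor, in-frame `TAA` at offset 26, `TTTCAG` acceptor |
| exon 2 | 882–1056 (175 nt) | rest of the CDS, ends in the single stop |
| 3' flank | 1057–1580 | random |

The seed analog is the composite substring 175–875 (701 nt). Genomic
contigs are placed at 1–379, 764–1020 and 1100–1414 (so the walk gains
174 nt 5' and 145 nt 3', and the third contig is contained); transcripts
at 978–1580, 998–1580, 1100–1356 and 1200–1413 (the first extends the 3'
end by 560 nt; all lie 3' of the intron so they match the genomic
composite contiguously). Primer footprints are read off the composite at
173–192/986–1005 (833-nt product), 706–725/995–1014 (309 nt) and
36–55/1137–1156 (1121 nt spanning the whole coding region); the control
locus is an independent 1000-nt sequence with a 757-nt control amplicon.

The junction codon is pinned to `AGG` so that exon 1 ends `…AG` and
exon 2 begins `GT` — the same dinucleotides as the intron boundaries,
which deliberately creates the one-step boundary-slide ambiguity that the
annotator must resolve by the GT..AG rule. The retained-intron reading
frame enters the intron one base after the donor, so its in-frame codons
start at intron offsets 2, 5, …; offsets 2–25 are constrained stop-free
and offset 26 carries `TAA`, giving 224 + 1 + 8 = 233 residues.

**Self-validation.** A handful of fixture properties depend on the random
background: the seed must occur exactly once, each primer must bind
exactly once, and the longest ORF of the spliced transcript must be the
intended CDS. After construction the generator verifies all of them
(plus full gene-model recovery) and, in the rare case a draw violates
one, re-draws the background deterministically from a derived seed. The
architecture constants never change, and equal seeds give byte-identical
fixtures.

**What the generator does not emulate**: sequencing error and quality
scores, PCR stochasticity and band intensities, indel variation
(substitutions only), repeats (background is i.i.d. random, so overlap
detection never faces repeat-induced ambiguity), and diploid
heterozygosity. Passing tests therefore demonstrate the correctness of
the inference chain under clean-data assumptions, not robustness to
noisy reads or repeat-rich genomes.

## Parameters that matter

- `min_overlap` (walker, default 20 nt): minimum exact end-overlap. Random
  20-mer collisions are vanishingly unlikely (4^-20), while the smallest
  true overlap in the canonical layout is 43 nt. Decoys and the control
  locus are rejection-sampled to share no `min_overlap`-mer with the
  composite, making "decoys never extend" a hard guarantee.
- `min_intron` (annotator, default 30 nt): genomic gaps below this are
  reported as putative deletions, not introns. The canonical intron is
  107 nt.
- Splice consensus strings (defaults `AGGTAAGT` donor, `TTNCAGGT`
  acceptor, DNA alphabet, N wildcard): configuration values, not
  hard-coded biology.
- `max_product` (PCR, default 5000 nt): suppresses spurious distant
  primer pairings.
- Popscan identity guard (default 0.80): its only job is to reject
  wrong-locus input; fragments from the locus align at ~1.0 identity.
- Generator defaults: cDNA pool depth 200 templates, IR fraction 0.5
  (the roughly equimolar mid-embryogenesis condition), 11 population
  fragments of 720–767 nt with substitution rate 0.

## Numerical and design choices

- **Coordinates** are 1-based inclusive in every public value and in
  GFF3 output.
- **Walk tie-breaking**: longest extension, then longest overlap, then
  lexicographically smallest contig id; each contig is used at most once
  per round and may extend only one end. This makes the walk
  deterministic and, on the canonical fixture, invariant to contig order
  and strand.
- **Excision decomposition** is the most parsimonious one (fewest
  excised blocks), found by iterative deepening with an 8-nt resync
  anchor; without the parsimony requirement the problem is
  under-determined (any shorter sequence can be "explained" with enough
  one-base gaps). Exons shorter than the resync anchor that are
  immediately followed by another intron can in principle be missed; no
  realistic input in this problem class has 8-nt exons.
- **Boundary-slide ambiguity**: when the bases flanking an excision
  repeat, the excision can slide. The placement yielding a GT..AG intron
  is chosen; if none or several qualify, the 5'-most placement is used
  and the intron is flagged ambiguous.
- **Gene-model convention**: inferred exons are trimmed to the coding
  span (start codon to stop), so a two-exon gene with UTR evidence on
  both sides reports exons of 674 and 175 nt; `trim_to_cds=False`
  returns the raw matched blocks including UTRs.
- **Amplicon convention**: 5' end of the forward primer to 5' end of the
  reverse primer, inclusive — the convention under which the 833-nt
  product decomposes as 602 + 107 + 124 nt of exon 1, intron and exon 2.
  Primer matching is exact and full-length with zero mismatches.
- **Stop-source classification**: a stop codon inside a retained intron
  is `intronic` (the isoform is truncated); any other stop — including a
  frameshift stop in a downstream exon after retaining an intron whose
  length is not a multiple of three — is classified `cds_end`. The
  single-intron canonical locus never hits that edge.
- **Wilson interval** (via `scipy.stats.binomtest(...).proportion_ci`)
  rather than the Wald interval, for sane behaviour at small counts and
  fractions near 0 or 1.
- **Degenerate inputs**: empty FASTA, duplicate ids and non-A/C/G/T/N
  characters are format errors; ambiguity codes other than N are rejected
  because "100% identity" would otherwise be ill-defined; `N` never
  matches in overlaps or primers. Translation requires at least one codon
  and drops a trailing partial codon.

## Problem sizes

Everything runs at desk scale: the composite is 1.6 kb, databases hold
6–7 contigs, sexing cohorts are 100 samples, cDNA pools 200 templates,
IR-coverage checks use 200 pools per fraction, and the population scan
uses 11 fragments. The full test suite completes in a few seconds on one
CPU.

## Known limitations

- The walker trusts exact overlaps; a single sequencing error in a true
  overlap window hides the extension (reported as a conflicting-overlap
  warning, and the contig is skipped).
- The annotator requires exact block matches; noisy spliced alignments
  are out of scope.
- The popscan alignment is ungapped, so indel variants would appear as
  runs of substitutions; the substitution-only simulator matches this
  assumption.
- Multi-intron retention patterns are enumerated exhaustively only up to
  4 introns; larger models are refused rather than sampled.
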