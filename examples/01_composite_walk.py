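"""Assemble the locus from a seed by iterative exact end-overlap walking.

Builds the synthetic contig databases, walks the 701-nt seed through the
genomic then the transcriptome database, and prints every extension
event. The final composite should reach 1580 nt: +174 nt (5') and
+145 nt (3') from genomic contigs, then +560 nt (3') from a transcript.
"""

from nixlocus.synthetic import fragment_genome, make_canonical_fixture, make_transcript_db
from nixlocus.walker import walk

fixture = make_canonical_fixture(rng_seed=0)
genomic_db = fragment_genome(fixture, rng_seed=0)
transcript_db = make_transcript_db(fixture, rng_seed=0)

assembly = walk(
    fixture.seed, [("genome", genomic_db), ("transcriptome", transcript_db)]
)

print(f"seed: {len(fixture.seed)} nt")
for ev in assembly.log:
    print(
        f"round {ev.round_index} [{ev.database_name}] {ev.contig_id} "
        f"({ev.strand}): overlap {ev.overlap_len} nt, "
        f"extends {ev.side} by {ev.extension_len} nt -> {ev.new_length} nt"
    )
print(f"final composite: {len(assembly.composite)} nt")
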