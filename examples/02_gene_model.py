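"""Infer the exon/intron gene model and classify its splice sites.

Compares the 1580-nt genomic composite with its spliced cDNA evidence:
two coding exons (674 + 175 nt) split by a 107-nt intron whose donor is
non-canonical (AG^GTTTGT instead of AG^GTAAGT) while the acceptor
(TTTCAG^GT) matches the TTNCAG^GT consensus — the weak donor is the
mechanistic suspect for intron retention.
"""

from nixlocus.annotate import classify_splice_sites, infer_introns
from nixlocus.synthetic import make_canonical_fixture

fixture = make_canonical_fixture(rng_seed=0)
model = infer_introns(fixture.composite, fixture.spliced_transcript)

print(f"exons:   {model.exons}  (lengths {model.exon_lengths})")
print(f"introns: {model.introns}  (lengths {model.intron_lengths})")
for report in classify_splice_sites(fixture.composite, model):
    print(
        f"intron {report.intron_index}: donor {report.donor_context} "
        f"(canonical: {report.donor_canonical}), acceptor "
        f"{report.acceptor_context} (canonical: {report.acceptor_canonical}), "
        f"GT..AG: {report.gt_ag}"
    )
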