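"""Properties of the synthetic locus generator.

The generator is the ground truth for every downstream analysis, so its
structural guarantees (printed lengths, placements, seed containment,
hemizygous female pools, reproducibility) are checked directly here.
"""

import numpy as np
import pytest

from nixlocus.seqio import TO_FIRST_STOP, revcomp, translate
from nixlocus.synthetic import (
    CDNA,
    GENOMIC_DNA,
    Sample,
    _kmers,
    _shares_kmer,
    fragment_genome,
    make_canonical_fixture,
    make_sample_templates,
    make_transcript_db,
    simulate_population,
)


def _placement_on(composite: str, contig_seq: str) -> tuple[int, int]:
    """Locate a contig (either orientation) on the composite, 1-based."""
    for seq in (contig_seq, revcomp(contig_seq)):
        idx = composite.find(seq)
        if idx != -1:
            return idx + 1, idx + len(seq)
    raise AssertionError("contig not found on the composite")


@pytest.mark.parametrize("seed", [0, 1, 42])
def test_fixture_architecture_holds_for_any_seed(seed):
    fx = make_canonical_fixture(seed)
    arch = fx.architecture
    assert len(fx.composite) == 1580
    assert len(fx.spliced_transcript) == 1580 - 107 == 1473
    assert len(fx.seed) == 701
    assert fx.composite.seq.count(fx.seed.seq) == 1
    cds_start = arch.exon1[0]
    spliced_cds = fx.spliced_transcript.seq[cds_start - 1 : cds_start + 848]
    assert len(translate(spliced_cds, TO_FIRST_STOP)) == 282
    assert len(translate(fx.composite.seq[cds_start - 1 :], TO_FIRST_STOP)) == 233
    intron = fx.composite.subseq(*arch.intron)
    assert intron.startswith("GTTTGT") and intron.endswith("TTTCAG")
    assert intron[25:28] == "TAA"


def test_fixture_is_bit_reproducible():
    a = make_canonical_fixture(7)
    b = make_canonical_fixture(7)
    c = make_canonical_fixture(8)
    assert a.composite.seq == b.composite.seq
    assert a.control_locus.seq == b.control_locus.seq
    assert a.composite.seq != c.composite.seq


def test_genomic_contigs_reproduce_printed_placements(locus, genomic_db):
    comp = locus.composite.seq
    by_id = {r.id: r for r in genomic_db}
    assert [len(by_id[i]) for i in ("gA", "gB", "gC")] == [379, 257, 315]
    seed_lo, seed_hi = locus.architecture.seed_span
    spans = {i: _placement_on(comp, by_id[i].seq) for i in ("gA", "gB", "gC")}
    # overlap with the seed span, by direct interval intersection
    overlap = lambda s, e: max(0, min(e, seed_hi) - max(s, seed_lo) + 1)
    assert overlap(*spans["gA"]) == 205
    assert overlap(*spans["gB"]) == 112
    assert spans["gA"][0] == 1 and seed_lo - spans["gA"][0] == 174  # 5' extension
    assert spans["gB"][1] - seed_hi == 145  # 3' extension
    assert spans["gC"] == (1100, 1414)


def test_transcript_contigs_reproduce_printed_placements(locus, transcript_db):
    comp = locus.composite.seq
    by_id = {r.id: r for r in transcript_db}
    assert [len(by_id[i]) for i in ("t1", "t2", "t3", "t4")] == [603, 583, 257, 214]
    reach = max(_placement_on(comp, by_id[i].seq)[1] for i in ("t1", "t2", "t3", "t4"))
    assert reach == 1580


def test_decoys_share_no_kmer_with_the_composite(locus, genomic_db, transcript_db):
    kmer_set = _kmers(locus.composite.seq, 20)
    decoys = [r for r in genomic_db + transcript_db if "decoy" in r.id]
    assert len(decoys) == 6
    assert not any(_shares_kmer(d.seq, kmer_set, 20) for d in decoys)


def test_empty_layout_without_decoys_gives_empty_database(locus):
    assert fragment_genome(locus, layout=(), n_decoys=0) == []


def test_female_pools_carry_no_locus_sequence(locus):
    kmer_set = _kmers(locus.composite.seq, 20)
    for kind in (GENOMIC_DNA, CDNA):
        pool = make_sample_templates(
            locus, Sample("f1", "female", kind), depth=50, rng_seed=3
        )
        assert pool, "female pools still contain the control"
        assert not any(_shares_kmer(rec.seq, kmer_set, 20) for rec, _ in pool)


def test_cdna_pool_is_binomial_in_the_ir_fraction(locus):
    sample = Sample("m1", "male", CDNA, ir_fraction=0.5)
    fractions = []
    for i in range(1000):
        pool = make_sample_templates(locus, sample, depth=200, rng_seed=i)
        counts = {rec.id: n for rec, n in pool}
        retained = counts.get("nix_unspliced_mrna", 0)
        spliced = counts.get("nix_spliced_mrna", 0)
        assert retained + spliced == 200
        fractions.append(retained / 200)
    assert abs(np.mean(fractions) - 0.5) < 0.01


def test_ir_fraction_zero_gives_fully_spliced_pools(locus):
    pool = make_sample_templates(
        locus, Sample("m2", "male", CDNA, ir_fraction=0.0), depth=100, rng_seed=1
    )
    ids = {rec.id for rec, _ in pool}
    assert "nix_unspliced_mrna" not in ids and "nix_spliced_mrna" in ids


def test_sample_validation():
    with pytest.raises(ValueError, match="outside"):
        Sample("x", "male", CDNA, ir_fraction=1.5)
    with pytest.raises(ValueError, match="only for cDNA"):
        Sample("x", "male", GENOMIC_DNA, ir_fraction=0.5)


def test_population_fragments_match_reference_when_unmutated(locus):
    frags, truth = simulate_population(locus, n=11, mut_rate=0.0, rng_seed=5)
    assert truth == []
    comp = locus.composite.seq
    intron_s, intron_e = locus.architecture.intron
    for frag in frags:
        assert 720 <= len(frag) <= 767
        start = comp.find(frag.seq) + 1
        assert start > 0, "unmutated fragment must be a verbatim substring"
        assert start <= intron_s and start + len(frag) - 1 >= intron_e


def test_population_rejects_impossible_fragment_ranges(locus):
    with pytest.raises(ValueError, match="intron"):
        simulate_population(locus, n=2, frag_len_range=(50, 60))
    with pytest.raises(ValueError, match="within"):
        simulate_population(locus, n=2, frag_len_range=(700, 2000))
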