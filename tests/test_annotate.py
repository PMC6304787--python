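"""Gene-model inference, splice-site classification and ORF finding."""

import numpy as np
import pytest

from nixlocus.annotate import (
    STOP_CODONS,
    AnnotationError,
    classify_splice_sites,
    find_cds,
    infer_introns,
)
from nixlocus.seqio import SeqRecord


def test_canonical_gene_model(gene_model):
    assert gene_model.exon_lengths == (674, 175)
    assert gene_model.intron_lengths == (107,)
    assert gene_model.exons == ((101, 774), (882, 1056))
    assert gene_model.introns == ((775, 881),)
    assert gene_model.cds == (1, 849)
    assert gene_model.ambiguous_introns == ()


def test_round_trip_excision_reproduces_the_cdna(locus, gene_model):
    # excising the inferred introns from the genomic reproduces the cDNA
    g = locus.composite.seq
    kept = []
    pos = 1
    for s, e in gene_model.introns:
        kept.append(g[pos - 1 : s - 1])
        pos = e + 1
    kept.append(g[pos - 1 :])
    assert "".join(kept) == locus.spliced_transcript.seq


def test_identical_sequences_give_a_single_exon():
    rec = SeqRecord("g", "ACGT" * 50)
    model = infer_introns(rec, SeqRecord("c", rec.seq), trim_to_cds=False)
    assert model.exons == ((1, 200),) and model.introns == ()


def test_two_synthetic_excisions_are_recovered():
    rng = np.random.default_rng(3)
    bases = "ACGT"
    part = lambda n: "".join(bases[i] for i in rng.integers(0, 4, n))
    e1, e2, e3 = part(120), part(150), part(110)
    i1 = "GT" + part(76) + "AG"  # 80 nt, GT..AG so the placement is unambiguous
    i2 = "GT" + part(86) + "AG"  # 90 nt
    genomic = SeqRecord("g", e1 + i1 + e2 + i2 + e3)
    cdna = SeqRecord("c", e1 + e2 + e3)
    model = infer_introns(genomic, cdna, trim_to_cds=False)
    assert model.exon_lengths == (120, 150, 110)
    assert model.intron_lengths == (80, 90)


def test_short_gap_is_a_putative_deletion_not_an_intron():
    rng = np.random.default_rng(9)
    part = lambda n: "".join("ACGT"[i] for i in rng.integers(0, 4, n))
    e1, gap, e2 = part(100), part(12), part(100)
    model = infer_introns(
        SeqRecord("g", e1 + gap + e2), SeqRecord("c", e1 + e2),
        min_intron=30, trim_to_cds=False,
    )
    assert model.introns == ()
    assert model.putative_deletions == ((101, 112),)


def test_unexplainable_cdna_raises():
    with pytest.raises(AnnotationError, match="decomposition|longer"):
        infer_introns(SeqRecord("g", "A" * 50 + "C" * 50), SeqRecord("c", "G" * 60))


def _random_gt_ag_model(rng):
    part = lambda n: "".join("ACGT"[i] for i in rng.integers(0, 4, n))
    n_introns = int(rng.integers(1, 4))
    exons = [part(int(rng.integers(50, 300))) for _ in range(n_introns + 1)]
    introns = [
        "GT" + part(int(rng.integers(26, 116))) + "AG" for _ in range(n_introns)
    ]
    genomic, cdna, layout = "", "", []
    for i, ex in enumerate(exons):
        start = len(genomic) + 1
        genomic += ex
        layout.append((start, len(genomic)))
        cdna += ex
        if i < n_introns:
            genomic += introns[i]
    return genomic, cdna, layout


def test_random_gene_models_are_recovered_exactly():
    rng = np.random.default_rng(100)
    for _ in range(100):
        genomic, cdna, layout = _random_gt_ag_model(rng)
        model = infer_introns(
            SeqRecord("g", genomic), SeqRecord("c", cdna), trim_to_cds=False
        )
        assert list(model.exons) == layout
    # bookkeeping: exons plus introns tile the gene span
    span = model.exons[-1][1] - model.exons[0][0] + 1
    assert sum(model.exon_lengths) + sum(model.intron_lengths) == span


def test_splice_classification_of_the_canonical_intron(locus, gene_model):
    (report,) = classify_splice_sites(locus.composite, gene_model)
    assert report.donor_context == "AG^GTTTGT"
    assert report.acceptor_context == "TTTCAG^GT"
    assert not report.donor_canonical  # GTTTGT, not the canonical GTAAGT
    assert report.acceptor_canonical  # TTTCAG matches TTNCAG with N wildcard
    assert report.gt_ag


def test_splice_classification_synthetic_cases():
    from nixlocus.annotate import GeneModel

    # canonical donor AG^GTAAGT and acceptor TTTCAG^GT
    g = "CCATGGCAAG" + "GTAAGT" + "C" * 20 + "TTTCAG" + "GTCCCTAAGG"
    model = GeneModel("s", exons=((1, 10), (43, 52)), introns=((11, 42),))
    (rep,) = classify_splice_sites(SeqRecord("s", g), model)
    assert rep.donor_canonical and rep.acceptor_canonical and rep.gt_ag
    # non-GT start
    g2 = "CCATGGCAAG" + "CTAAGT" + "C" * 20 + "TTTCAG" + "GTCCCTAAGG"
    (rep2,) = classify_splice_sites(SeqRecord("s", g2), model)
    assert not rep2.gt_ag and not rep2.donor_canonical


def brute_force_cds(seq: str):
    best = None
    for i in range(len(seq) - 2):
        if seq[i : i + 3] != "ATG":
            continue
        for j in range(i + 3, len(seq) - 2, 3):
            if seq[j : j + 3] in STOP_CODONS:
                key = ((j - i) // 3, -i)
                if best is None or key > best[0]:
                    best = (key, (i + 1, j + 3))
                break
    return None if best is None else best[1]


def test_find_cds_canonical_and_hand_cases(locus):
    start, end, protein = find_cds(locus.spliced_transcript)
    assert (start, len(protein)) == (101, 282)
    assert find_cds("ATGTAA")[:2] == (1, 6)
    with pytest.raises(AnnotationError):
        find_cds("ATGAAA")  # no stop codon


def test_find_cds_prefers_the_longer_orf():
    short = "ATG" + "GCA" * 9 + "TAA"
    long = "ATG" + "GCA" * 49 + "TAG"
    seq = "CC" + short + "TT" + long + "AA"
    start, end, protein = find_cds(seq)
    assert len(protein) == 50 and start == 2 + len(short) + 2 + 1


def test_find_cds_agrees_with_brute_force_on_random_sequences():
    rng = np.random.default_rng(17)
    for _ in range(30):
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, int(rng.integers(100, 2000))))
        expected = brute_force_cds(seq)
        if expected is None:
            with pytest.raises(AnnotationError):
                find_cds(seq)
        else:
            start, end, _ = find_cds(seq)
            assert (start, end) == expected
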