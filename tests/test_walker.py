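"""Exact end-overlap detection and the iterative composite walk."""

import logging

import numpy as np
import pytest

from nixlocus.seqio import SeqRecord, revcomp
from nixlocus.walker import (
    CompositeAssembly,
    end_overlap,
    walk,
    walk_round,
)


def brute_force_overlap(a: str, b: str, min_overlap: int):
    """Independent oracle: enumerate every suffix/prefix shift in both
    orientations with character-by-character comparison; best by
    (overlap, extension). Returns None or (overlap, extension, contained)."""
    best = None
    for bs in (b, revcomp(b)):
        if "N" not in bs and any(
            all(x == y for x, y in zip(a[i:], bs)) and i + len(bs) <= len(a)
            for i in range(len(a) - len(bs) + 1)
        ):
            cand = (len(bs), 0, True)
            best = cand if best is None or cand[:2] > best[:2] else best
        for ov in range(min_overlap, min(len(a), len(bs) - 1) + 1):
            if "N" in bs[:ov] or "N" in bs[-ov:]:
                continue
            if all(x == y for x, y in zip(a[len(a) - ov :], bs[:ov])):
                cand = (ov, len(bs) - ov, False)
                best = cand if best is None or cand[:2] > best[:2] else best
            if all(x == y for x, y in zip(a[:ov], bs[len(bs) - ov :])):
                cand = (ov, len(bs) - ov, False)
                best = cand if best is None or cand[:2] > best[:2] else best
    return best


def test_end_overlap_hand_case():
    hit = end_overlap("AAAATTTT", "TTTTGGGG", min_overlap=4)
    assert (hit.side, hit.overlap_len, hit.extension_len) == ("three_prime", 4, 4)


def test_end_overlap_seed_vs_first_genomic_contig(locus, genomic_db):
    gA = next(r for r in genomic_db if r.id == "gA")
    hit = end_overlap(locus.seed.seq, gA.seq, 20, "gA")
    assert (hit.side, hit.overlap_len, hit.extension_len) == ("five_prime", 205, 174)


def test_end_overlap_detects_containment(locus, genomic_db):
    gC = next(r for r in genomic_db if r.id == "gC")
    hit = end_overlap(locus.composite.seq, gC.seq, 20, "gC")
    assert hit.contained and hit.extension_len == 0


def test_end_overlap_ignores_n_in_the_window():
    assert end_overlap("AAAATTNT", "TTNTGGGG", min_overlap=4) is None


def test_end_overlap_agrees_with_brute_force_on_random_pairs():
    rng = np.random.default_rng(2024)
    bases = np.array(list("ACGT"))
    checked_hits = 0
    for trial in range(300):
        la, lb = rng.integers(10, 200, size=2)
        a = "".join(rng.choice(bases, la))
        if trial % 2 == 0:
            b = "".join(rng.choice(bases, lb))
        else:  # plant a true overlap so hits are exercised, not just misses
            ov = int(rng.integers(4, min(la, lb)))
            tail = "".join(rng.choice(bases, int(lb) - ov))
            b = (a[-ov:] + tail) if rng.random() < 0.5 else (tail + a[:ov])
            if rng.random() < 0.5:
                b = revcomp(b)
        hit = end_overlap(a, b, min_overlap=4)
        oracle = brute_force_overlap(a, b, 4)
        if oracle is None:
            assert hit is None
        else:
            assert hit is not None
            assert (hit.overlap_len, hit.extension_len, hit.contained) == oracle
            checked_hits += 1
    assert checked_hits > 100


def test_walk_round_reproduces_the_genomic_extension(locus, genomic_db):
    composite, events = walk_round(locus.seed, genomic_db, 20)
    assert len(composite) == 1020
    assert [(e.side, e.extension_len) for e in events] == [
        ("five_prime", 174),
        ("three_prime", 145),
    ]


def test_walk_round_with_decoys_only_is_a_fixed_point(locus, genomic_db):
    decoys = [r for r in genomic_db if "decoy" in r.id]
    composite, events = walk_round(locus.seed, decoys, 20)
    assert composite.seq == locus.seed.seq and events == []


def test_walk_round_warns_on_conflicting_overlap(locus, caplog):
    # shares an internal 60-mer with the composite but neither end overlaps
    comp = locus.composite
    conflicted = SeqRecord("bad", "C" * 12 + comp.subseq(501, 560) + "G" * 12)
    with caplog.at_level(logging.WARNING, "nixlocus.walker"):
        composite, events = walk_round(comp, [conflicted], 20)
    assert composite.seq == comp.seq and events == []
    assert any("conflicting overlap" in r.message for r in caplog.records)


def test_full_walk_recovers_the_composite(locus, assembly):
    assert len(assembly.composite) == 1580
    assert assembly.composite.seq == locus.composite.seq
    assert [e.extension_len for e in assembly.log] == [174, 145, 560]
    # a full extra cycle ran and added nothing
    assert max(e.round_index for e in assembly.log) == 2
    assert len(assembly.composite) == len(locus.seed) + assembly.total_extension
    assert assembly.composite.seq.count(locus.seed.seq) == 1


def test_walk_is_order_and_strand_invariant(locus, genomic_db, transcript_db, assembly):
    rng = np.random.default_rng(11)
    gdb = [
        SeqRecord(r.id, revcomp(r.seq) if rng.random() < 0.5 else r.seq)
        for r in genomic_db
    ]
    tdb = [
        SeqRecord(r.id, revcomp(r.seq) if rng.random() < 0.5 else r.seq)
        for r in transcript_db
    ]
    rng.shuffle(gdb)
    rng.shuffle(tdb)
    shuffled = walk(locus.seed, [("genome", gdb), ("transcriptome", tdb)])
    assert shuffled.composite.seq == assembly.composite.seq


def test_walk_with_huge_min_overlap_leaves_the_seed(locus, genomic_db, transcript_db):
    out = walk(locus.seed, [("genome", genomic_db), ("transcriptome", transcript_db)], 600)
    assert out.composite.seq == locus.seed.seq and out.log == ()


def test_walk_on_a_seed_containing_every_contig_is_a_fixed_point(locus, genomic_db):
    out = walk(locus.composite, [("genome", genomic_db)], 20)
    assert out.composite.seq == locus.composite.seq and out.log == ()


def test_log_length_monotonicity_is_enforced():
    ev = dict(database_name="g", contig_id="c", strand="forward",
              side="three_prime", overlap_len=20, extension_len=5)
    from nixlocus.walker import ExtensionEvent

    good = (
        ExtensionEvent(round_index=1, new_length=100, **ev),
        ExtensionEvent(round_index=1, new_length=90, **ev),
    )
    with pytest.raises(ValueError, match="strictly increase"):
        CompositeAssembly(SeqRecord("x", "ACGT" * 30), good)
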