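"""Iterative composite assembly by exact end-overlap extension.

A seed sequence is grown through one or more contig databases: in each
round every unused contig is tested for a perfect (100% identity) overlap
between one of its ends and one end of the current composite, in both
orientations, and the best available extension is applied until the round
is exhausted. Databases are cycled until a complete cycle adds nothing.

This mirrors the seed-and-extend walk used to reconstruct a locus from
genome and transcriptome contig sets when only perfect overlaps are
trusted. It is deliberately not a general assembler: no graphs, no
mismatches, no gaps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

from .seqio import SeqRecord, revcomp

logger = logging.getLogger(__name__)

FIVE_PRIME = "five_prime"
THREE_PRIME = "three_prime"
FORWARD = "forward"
REVERSE = "reverse"

DEFAULT_MIN_OVERLAP = 20


@dataclass(frozen=True)
class OverlapHit:
    """A perfect end-overlap (or containment) of contig ``b`` against ``a``."""

    contig_id: str
    strand: str  # forward | reverse (orientation of b relative to a)
    overlap_len: int
    side: str | None  # five_prime | three_prime; None when contained
    extension_len: int
    contained: bool = False

    def __post_init__(self) -> None:
        if self.contained and self.extension_len != 0:
            raise ValueError("a contained contig cannot extend the composite")
        if self.extension_len < 0:
            raise ValueError("extension_len must be >= 0")


@dataclass(frozen=True)
class ExtensionEvent:
    round_index: int
    database_name: str
    contig_id: str
    strand: str
    side: str
    overlap_len: int
    extension_len: int
    new_length: int


@dataclass(frozen=True)
class CompositeAssembly:
    composite: SeqRecord
    log: tuple[ExtensionEvent, ...]

    def __post_init__(self) -> None:
        lengths = [ev.new_length for ev in self.log]
        if any(b <= a for a, b in zip(lengths, lengths[1:])):
            raise ValueError("composite length must strictly increase along the log")

    @property
    def total_extension(self) -> int:
        return sum(ev.extension_len for ev in self.log)


def _clean_window(window: str) -> bool:
    # N is treated as matching nothing, so an overlap containing N is invalid
    return "N" not in window


def end_overlap(
    a: str, b: str, min_overlap: int = DEFAULT_MIN_OVERLAP, contig_id: str = ""
) -> OverlapHit | None:
    """Best perfect end-overlap of ``b`` (either orientation) against ``a``.

    Returns the hit with the longest overlap in which a suffix of one
    sequence equals a prefix of the other at 100% identity, or a
    containment hit when ``b`` occurs inside ``a``; ``None`` when nothing
    reaches ``min_overlap``. N never matches.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    best: OverlapHit | None = None
    for strand, bs in ((FORWARD, b), (REVERSE, revcomp(b))):
        if bs in a and _clean_window(bs):
            hit = OverlapHit(contig_id, strand, len(bs), None, 0, contained=True)
            if best is None or hit.overlap_len > best.overlap_len:
                best = hit
            continue
        max_l = min(len(a), len(bs) - 1)
        for overlap in range(max_l, min_overlap - 1, -1):
            if a[-overlap:] == bs[:overlap] and _clean_window(bs[:overlap]):
                hit = OverlapHit(
                    contig_id, strand, overlap, THREE_PRIME, len(bs) - overlap
                )
                if best is None or _better_overlap(hit, best):
                    best = hit
                break
        for overlap in range(max_l, min_overlap - 1, -1):
            if bs[-overlap:] == a[:overlap] and _clean_window(a[:overlap]):
                hit = OverlapHit(
                    contig_id, strand, overlap, FIVE_PRIME, len(bs) - overlap
                )
                if best is None or _better_overlap(hit, best):
                    best = hit
                break
    return best


def _better_overlap(x: OverlapHit, y: OverlapHit) -> bool:
    return (x.overlap_len, x.extension_len) > (y.overlap_len, y.extension_len)


def _shares_kmer(a: str, b: str, k: int) -> bool:
    if len(a) < k or len(b) < k:
        return False
    kmers = {a[i : i + k] for i in range(len(a) - k + 1)}
    brc = revcomp(b)
    return any(
        s[i : i + k] in kmers for s in (b, brc) for i in range(len(s) - k + 1)
    )


def walk_round(
    current: SeqRecord,
    db: Sequence[SeqRecord],
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    round_index: int = 1,
    database_name: str = "db",
) -> tuple[SeqRecord, list[ExtensionEvent]]:
    """One extension round against a single database.

    The best available extension (longest extension, then longest overlap,
    then lexicographically smallest contig id) is applied repeatedly until
    no contig extends the composite. Each contig is used at most once per
    round and may extend only one end. Contigs that share sequence with
    the composite but present no perfect end-overlap are skipped with a
    warning (conflicting overlap).
    """
    if not db:
        raise ValueError("walk_round requires a non-empty database")
    seq = current.seq
    used: set[str] = set()
    events: list[ExtensionEvent] = []
    while True:
        candidates: list[OverlapHit] = []
        for contig in db:
            if contig.id in used:
                continue
            hit = end_overlap(seq, contig.seq, min_overlap, contig.id)
            if hit is not None and not hit.contained and hit.extension_len >= 1:
                candidates.append(hit)
        if not candidates:
            break
        best = sorted(
            candidates,
            key=lambda h: (-h.extension_len, -h.overlap_len, h.contig_id),
        )[0]
        contig = next(c for c in db if c.id == best.contig_id)
        oriented = contig.seq if best.strand == FORWARD else revcomp(contig.seq)
        if best.side == THREE_PRIME:
            seq = seq + oriented[best.overlap_len :]
        else:
            seq = oriented[: best.extension_len] + seq
        used.add(best.contig_id)
        events.append(
            ExtensionEvent(
                round_index=round_index,
                database_name=database_name,
                contig_id=best.contig_id,
                strand=best.strand,
                side=best.side,
                overlap_len=best.overlap_len,
                extension_len=best.extension_len,
                new_length=len(seq),
            )
        )
    for contig in db:
        if contig.id in used:
            continue
        hit = end_overlap(seq, contig.seq, min_overlap, contig.id)
        if hit is None and _shares_kmer(seq, contig.seq, min_overlap):
            logger.warning(
                "contig %s shares >=%d nt with the composite but has no perfect "
                "end-overlap; skipped (conflicting overlap)",
                contig.id,
                min_overlap,
            )
    return SeqRecord(current.id, seq, current.description), events


def walk(
    seed: SeqRecord,
    dbs: Sequence[tuple[str, Sequence[SeqRecord]]],
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> CompositeAssembly:
    """Full iterative walk: cycle the databases in order until a complete
    cycle yields no extension. Deterministic for fixed inputs."""
    if not dbs:
        raise ValueError("walk requires at least one database")
    current = SeqRecord(f"{seed.id}|composite", seed.seq, seed.description)
    events: list[ExtensionEvent] = []
    round_index = 0
    while True:
        extended = False
        for name, db in dbs:
            round_index += 1
            current, evs = walk_round(
                current, db, min_overlap, round_index=round_index, database_name=name
            )
            if evs:
                extended = True
            events.extend(evs)
        if not extended:
            break
    assembly = CompositeAssembly(composite=current, log=tuple(events))
    # conservation and substring-preservation invariants, asserted on every run
    if len(current.seq) != len(seed.seq) + assembly.total_extension:
        raise AssertionError("final length != seed length + sum of extensions")
    if seed.seq not in current.seq:
        raise AssertionError("seed lost from the composite during the walk")
    return assembly
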