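"""Polymorphism scan of partial resequenced fragments against a reference.

Fragments (e.g. direct Sanger reads of a PCR product) are placed on the
reference locus by ungapped semi-global alignment: the query slides along
the reference with free end-gaps on the reference, and the placement with
the most matching bases wins. Gap characters ('-') and N in the query are
missing data — they are neither matches nor variants. Positions outside a
fragment's span are uncovered. The model is haploid/hemizygous, which is
exact for a male-linked locus sequenced from single males.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from .seqio import SeqRecord

DEFAULT_MIN_IDENTITY = 0.8
MISSING_CHARS = frozenset("-N")


class UnalignableError(ValueError):
    """No placement reaches the identity guard (wrong-locus input)."""


class GappedRecord(NamedTuple):
    """A query that may contain '-' missing-data characters.

    :class:`nixlocus.seqio.SeqRecord` enforces a strict A/C/G/T/N
    alphabet; alignment inputs exported from alignment viewers often mark
    truncated ends with dashes, so the scan accepts this looser record
    (anything with ``id`` and ``seq`` attributes works).
    """

    id: str
    seq: str


class Variant(NamedTuple):
    position: int  # 1-based on the reference
    ref_base: str
    alt_base: str
    sequence_id: str


@dataclass(frozen=True)
class Placement:
    sequence_id: str
    start: int  # 1-based inclusive on the reference
    end: int
    n_matches: int
    n_informative: int  # aligned non-missing positions
    variants: tuple[Variant, ...]

    @property
    def identity(self) -> float:
        return self.n_matches / self.n_informative if self.n_informative else 0.0


@dataclass(frozen=True)
class PolymorphismReport:
    reference_id: str
    n_sequences: int
    placements: tuple[Placement, ...]
    variant_sites: tuple[Variant, ...]
    coverage: tuple[int, ...]  # per reference position, non-missing observations

    @property
    def n_variable_sites(self) -> int:
        return len({v.position for v in self.variant_sites})


def _to_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype="S1")


def anchor_align(
    query: SeqRecord,
    reference: SeqRecord,
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> Placement:
    """Place a query on the reference by ungapped semi-global alignment.

    The query may contain '-' or N as missing data. Among all offsets the
    placement maximising the number of matches is chosen (ties: leftmost).
    Raises :class:`UnalignableError` when the best placement's identity
    over informative positions falls below ``min_identity``.
    """
    q_raw = query.seq.upper()
    bad = set(q_raw) - set("ACGTN-")
    if bad:
        raise ValueError(f"query {query.id!r} contains invalid characters {sorted(bad)!r}")
    if len(q_raw) > len(reference.seq):
        raise UnalignableError(
            f"query {query.id!r} ({len(q_raw)} nt) longer than the reference "
            f"({len(reference.seq)} nt)"
        )
    q = _to_array(q_raw)
    r = _to_array(reference.seq)
    informative = ~np.isin(q, [b"-", b"N"])
    n_informative = int(informative.sum())
    if n_informative == 0:
        raise UnalignableError(f"query {query.id!r} has no informative bases")
    m = len(q)
    best_offset, best_matches = 0, -1
    for offset in range(len(r) - m + 1):
        matches = int(((r[offset : offset + m] == q) & informative).sum())
        if matches > best_matches:
            best_offset, best_matches = offset, matches
    identity = best_matches / n_informative
    if identity < min_identity:
        raise UnalignableError(
            f"query {query.id!r}: best placement identity {identity:.3f} "
            f"< {min_identity:.2f}"
        )
    window = r[best_offset : best_offset + m]
    mismatch_idx = np.nonzero((window != q) & informative)[0]
    variants = tuple(
        Variant(
            position=best_offset + int(i) + 1,
            ref_base=window[i].decode(),
            alt_base=q[i].decode(),
            sequence_id=query.id,
        )
        for i in mismatch_idx
    )
    return Placement(
        sequence_id=query.id,
        start=best_offset + 1,
        end=best_offset + m,
        n_matches=best_matches,
        n_informative=n_informative,
        variants=variants,
    )


def count_polymorphisms(
    queries: Sequence[SeqRecord],
    reference: SeqRecord,
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> PolymorphismReport:
    """Align every query and aggregate variant sites and coverage.

    Individually unalignable queries are excluded from the report; if all
    queries are unalignable the scan fails. The report is invariant to the
    input order of the queries.
    """
    if not queries:
        raise ValueError("count_polymorphisms requires at least one query")
    placements: list[Placement] = []
    failures: list[str] = []
    coverage = np.zeros(len(reference.seq), dtype=int)
    for query in sorted(queries, key=lambda rec: rec.id):
        try:
            placement = anchor_align(query, reference, min_identity)
        except UnalignableError:
            failures.append(query.id)
            continue
        placements.append(placement)
        q = _to_array(query.seq.upper())
        informative = ~np.isin(q, [b"-", b"N"])
        coverage[placement.start - 1 : placement.end] += informative
    if not placements:
        raise UnalignableError(
            f"all {len(failures)} queries were unalignable to {reference.id!r}"
        )
    variants = tuple(
        sorted(
            (v for p in placements for v in p.variants),
            key=lambda v: (v.position, v.sequence_id),
        )
    )
    return PolymorphismReport(
        reference_id=reference.id,
        n_sequences=len(placements),
        placements=tuple(placements),
        variant_sites=variants,
        coverage=tuple(int(c) for c in coverage),
    )
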