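"""Exon/intron gene-model inference and splice-site classification.

The gene model is inferred by explaining a spliced cDNA as the genomic
sequence with internal blocks excised at 100% identity — the situation
that arises when transcript evidence aligns perfectly to a composite
locus. Excision boundaries that can slide (because the bases flanking the
intron repeat) are resolved in favour of the placement that produces a
canonical GT..AG intron; failing that, the 5'-most placement is used and
flagged as ambiguous.

Splice-site contexts are compared against configurable consensus strings,
by default the Aedes aegypti donor AG^GTAAGT and acceptor TTNCAG^GT (DNA
alphabet, N = wildcard).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

from .seqio import SeqRecord, TO_FIRST_STOP, translate

DEFAULT_MIN_INTRON = 30
DONOR_CONSENSUS = "AGGTAAGT"  # 2 exonic + 6 intronic
ACCEPTOR_CONSENSUS = "TTNCAGGT"  # 6 intronic + 2 exonic

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


class AnnotationError(ValueError):
    """The cDNA cannot be explained as exact excisions from the genomic."""


@dataclass(frozen=True)
class GeneModel:
    """Exon/intron/CDS structure of a gene on its (forward-strand) sequence.

    ``exons`` and ``introns`` are 1-based inclusive genomic intervals;
    ``cds`` is a 1-based inclusive interval on the *spliced* transcript.
    Inter-exon gaps shorter than the intron threshold are recorded as
    ``putative_deletions`` rather than introns.
    """

    seq_id: str
    exons: tuple[tuple[int, int], ...]
    introns: tuple[tuple[int, int], ...] = ()
    cds: tuple[int, int] | None = None
    strand: str = "+"
    putative_deletions: tuple[tuple[int, int], ...] = ()
    ambiguous_introns: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError("a gene model needs at least one exon")
        for s, e in self.exons + self.introns + self.putative_deletions:
            if s > e or s < 1:
                raise ValueError(f"invalid interval {s}..{e}")
        if list(self.exons) != sorted(self.exons):
            raise ValueError("exons must be sorted")
        gaps = [
            (pe + 1, ns - 1)
            for (_, pe), (ns, _) in zip(self.exons, self.exons[1:])
        ]
        if any(g[0] > g[1] for g in gaps):
            raise ValueError("exons overlap or abut without a gap")
        if set(gaps) != set(self.introns) | set(self.putative_deletions):
            raise ValueError("introns/deletions must exactly fill inter-exon gaps")

    @property
    def exon_lengths(self) -> tuple[int, ...]:
        return tuple(e - s + 1 for s, e in self.exons)

    @property
    def intron_lengths(self) -> tuple[int, ...]:
        return tuple(e - s + 1 for s, e in self.introns)

    @property
    def spliced_length(self) -> int:
        return sum(self.exon_lengths)

    def spliced_seq(self, genomic: SeqRecord | str) -> str:
        seq = genomic.seq if isinstance(genomic, SeqRecord) else genomic
        return "".join(seq[s - 1 : e] for s, e in self.exons)


@dataclass(frozen=True)
class SpliceSiteReport:
    intron_index: int
    donor_context: str  # "EX^GTNNNN" — 2 exonic, caret, 6 intronic
    acceptor_context: str  # "NNNNAG^EX" — 6 intronic, caret, 2 exonic
    donor_canonical: bool
    acceptor_canonical: bool
    gt_ag: bool


def _lce(a: str, i: int, b: str, j: int) -> int:
    """Longest common extension of a[i:] and b[j:]."""
    k = 0
    n = min(len(a) - i, len(b) - j)
    while k < n and a[i + k] == b[j + k]:
        k += 1
    return k


_RESYNC_ANCHOR = 8
_MAX_GAPS = 16


def _decompose(g: str, c: str) -> list[tuple[int, int]] | None:
    """Explain cDNA ``c`` as genomic ``g`` with internal blocks excised.

    Returns 0-based (start, length) exon blocks. The decomposition is the
    most parsimonious one (fewest excised blocks), found by iterative
    deepening on the gap count; within a level each exon is taken as the
    maximal match (the rightmost of the equivalent slid placements) and
    gap lengths are searched smallest-first with an 8-nt resync anchor.
    None when no decomposition exists.
    """

    def solve(i: int, j: int, gaps_left: int) -> list[tuple[int, int]] | None:
        k = _lce(g, i, c, j)
        if j + k == len(c):
            return [(i, k)] if i + k == len(g) else None
        if k == 0 or gaps_left == 0:
            return None
        surplus = (len(g) - i) - (len(c) - j)
        rem = len(c) - (j + k)
        anchor = min(_RESYNC_ANCHOR, rem)
        target = c[j + k : j + k + anchor]
        for d in range(1, surplus + 1):
            if g[i + k + d : i + k + d + anchor] != target:
                continue
            rest = solve(i + k + d, j + k, gaps_left - 1)
            if rest is not None:
                return [(i, k)] + rest
        return None

    for max_gaps in range(_MAX_GAPS + 1):
        result = solve(0, 0, max_gaps)
        if result is not None:
            return result
    return None


def _slide_for_gt_ag(
    g: str, exons: list[tuple[int, int]], gap_index: int
) -> tuple[int, int]:
    """Shift the gap after ``exons[gap_index]`` left among equivalent
    placements to obtain a GT..AG intron if possible.

    Returns (shift, n_gt_ag): the chosen left-shift and how many of the
    equivalent placements were GT..AG (for ambiguity flagging).
    """
    s = exons[gap_index][1] + 1  # 1-based intron start (rightmost placement)
    e = exons[gap_index + 1][0] - 1
    max_left = 0
    prev_exon_start = exons[gap_index][0]
    while (
        s - 1 - max_left >= prev_exon_start + 1  # keep the upstream exon non-empty
        and g[s - 2 - max_left] == g[e - 1 - max_left]
    ):
        max_left += 1
    gt_ag_shifts = [
        t
        for t in range(max_left + 1)
        if g[s - 1 - t : s + 1 - t] == "GT" and g[e - 2 - t : e - t] == "AG"
    ]
    if len(gt_ag_shifts) == 1:
        return gt_ag_shifts[0], 1
    # none or several qualify: use the 5'-most placement, flag ambiguity
    return max_left, len(gt_ag_shifts)


def infer_introns(
    genomic: SeqRecord,
    cdna: SeqRecord,
    min_intron: int = DEFAULT_MIN_INTRON,
    trim_to_cds: bool = True,
) -> GeneModel:
    """Infer the exon/intron model from a genomic sequence and a spliced
    cDNA that matches it in exact blocks.

    Genomic gaps >= ``min_intron`` become introns; shorter gaps are
    reported as putative deletions. With ``trim_to_cds`` (the default)
    the model's exons are trimmed to the coding span — the convention
    under which a two-exon gene with 100-odd nt of UTR evidence on either
    side still reports its exons as start-codon-to-stop segments — and
    ``cds`` covers the whole model-spliced sequence. With
    ``trim_to_cds=False`` the exons are the raw matched blocks including
    UTRs. Raises :class:`AnnotationError` when the cDNA cannot be
    explained as exact internal excisions.
    """
    g, c = genomic.seq, cdna.seq
    if len(c) > len(g):
        raise AnnotationError(
            f"cDNA ({len(c)} nt) is longer than the genomic sequence ({len(g)} nt)"
        )
    blocks = _decompose(g, c)
    if blocks is None:
        raise AnnotationError(
            f"cDNA {cdna.id!r} cannot be explained as exact excisions from "
            f"{genomic.id!r}: no consistent decomposition"
        )
    exons = [(start + 1, start + length) for start, length in blocks]
    # resolve slide ambiguity at every gap (GT..AG rule)
    ambiguous: list[int] = []
    for idx in range(len(exons) - 1):
        shift, n_gt_ag = _slide_for_gt_ag(g, exons, idx)
        if shift:
            s, e = exons[idx]
            exons[idx] = (s, e - shift)
            ns, ne = exons[idx + 1]
            exons[idx + 1] = (ns - shift, ne)
        if n_gt_ag != 1:
            ambiguous.append(idx)
    # classify each gap: (interval, is_intron, is_ambiguous)
    gaps: list[tuple[tuple[int, int], bool, bool]] = []
    for idx, ((_, pe), (ns, _)) in enumerate(zip(exons, exons[1:])):
        gap = (pe + 1, ns - 1)
        gaps.append((gap, gap[1] - gap[0] + 1 >= min_intron, idx in ambiguous))
    spliced = "".join(g[s - 1 : e] for s, e in exons)
    if spliced != c:  # round-trip invariant, asserted on every inference
        raise AssertionError("excising the inferred introns does not reproduce the cDNA")
    cds = None
    try:
        start, end, _ = find_cds(spliced)
        cds = (start, end)
    except AnnotationError:
        pass
    if trim_to_cds and cds is not None:
        from .seqio import _spliced_to_genomic_segments

        exons = _spliced_to_genomic_segments(exons, cds[0], cds[1])
        gstart, gend = exons[0][0], exons[-1][1]
        gaps = [gp for gp in gaps if gstart < gp[0][0] and gp[0][1] < gend]
        cds = (1, sum(e - s + 1 for s, e in exons))
    intron_gaps = [gp for gp in gaps if gp[1]]
    introns = [iv for iv, _, _ in intron_gaps]
    deletions = [iv for iv, is_intron, _ in gaps if not is_intron]
    ambiguous_introns = tuple(i for i, (_, _, amb) in enumerate(intron_gaps) if amb)
    return GeneModel(
        seq_id=genomic.id,
        exons=tuple(exons),
        introns=tuple(introns),
        cds=cds,
        putative_deletions=tuple(deletions),
        ambiguous_introns=ambiguous_introns,
    )


def _matches_consensus(context: str, consensus: str) -> bool:
    return len(context) == len(consensus) and all(
        k == "N" or k == b for b, k in zip(context, consensus)
    )


def classify_splice_sites(
    genomic: SeqRecord,
    model: GeneModel,
    donor_consensus: str = DONOR_CONSENSUS,
    acceptor_consensus: str = ACCEPTOR_CONSENSUS,
) -> list[SpliceSiteReport]:
    """Classify every intron's donor/acceptor context against consensus.

    Donor context is 2 exonic + 6 intronic bases written ``EX^INTRON``;
    acceptor context is 6 intronic + 2 exonic bases written ``INTRON^EX``.
    """
    g = genomic.seq
    reports = []
    for idx, (s, e) in enumerate(model.introns, start=1):
        if e - s + 1 < 6:
            raise AnnotationError(f"intron {idx} shorter than 6 nt")
        if s < 3 or e + 2 > len(g):
            raise AnnotationError(f"intron {idx} too close to the sequence end")
        donor = g[s - 3 : s - 1] + g[s - 1 : s + 5]
        acceptor = g[e - 6 : e] + g[e : e + 2]
        reports.append(
            SpliceSiteReport(
                intron_index=idx,
                donor_context=f"{donor[:2]}^{donor[2:]}",
                acceptor_context=f"{acceptor[:6]}^{acceptor[6:]}",
                donor_canonical=_matches_consensus(donor, donor_consensus),
                acceptor_canonical=_matches_consensus(acceptor, acceptor_consensus),
                gt_ag=g[s - 1 : s + 1] == "GT" and g[e - 2 : e] == "AG",
            )
        )
    return reports


def find_cds(spliced: SeqRecord | str) -> tuple[int, int, str]:
    """Longest ATG-initiated forward-strand ORF terminating in a stop.

    Returns (start, end, protein) with 1-based inclusive coordinates on the
    spliced sequence; ``end`` is the last base of the stop codon and the
    protein excludes the stop. Ties are broken by the 5'-most start.
    """
    seq = spliced.seq if isinstance(spliced, SeqRecord) else spliced
    if len(seq) < 3:
        raise AnnotationError("sequence shorter than one codon")
    best: tuple[int, int] | None = None  # (protein_len, -start) maximised
    best_span: tuple[int, int] | None = None
    stops_by_frame: dict[int, list[int]] = {0: [], 1: [], 2: []}
    for i in range(len(seq) - 2):
        if seq[i : i + 3] in STOP_CODONS:
            stops_by_frame[i % 3].append(i)
    for i in range(len(seq) - 2):
        if seq[i : i + 3] != "ATG":
            continue
        stop = next((s for s in stops_by_frame[i % 3] if s >= i + 3), None)
        if stop is None:
            continue
        n_res = (stop - i) // 3
        key = (n_res, -i)
        if best is None or key > best:
            best = key
            best_span = (i + 1, stop + 3)
    if best_span is None:
        raise AnnotationError("no ATG-initiated ORF with a stop codon")
    start, end = best_span
    protein = translate(seq[start - 1 : end], TO_FIRST_STOP)
    return start, end, protein
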