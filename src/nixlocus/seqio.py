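"""Sequence I/O and elementary nucleotide operations.

FASTA reading and writing, reverse complement, translation under the
standard nuclear genetic code, and GFF3 export/import of gene models.
Biopython does the format heavy lifting; this module adds the strict
validation the downstream analyses rely on (restricted A/C/G/T/N alphabet,
unique record ids, case normalisation).

Every coordinate exposed by this package is 1-based and inclusive, matching
the GFF3 convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO as _SeqIO
from Bio.Seq import Seq as _Seq

NUCLEOTIDE_ALPHABET = frozenset("ACGTN")

RUN_THROUGH = "run_through"
TO_FIRST_STOP = "to_first_stop"


class FastaFormatError(ValueError):
    """Malformed or inconsistent FASTA input."""


class SequenceAlphabetError(ValueError):
    """A sequence contains characters outside A, C, G, T, N."""


class CoordinateError(ValueError):
    """Feature coordinates fall outside their sequence."""


def _validate_nucleotides(seq: str, context: str = "sequence") -> str:
    seq = seq.upper()
    bad = set(seq) - NUCLEOTIDE_ALPHABET
    if bad:
        raise SequenceAlphabetError(
            f"{context} contains non-A/C/G/T/N characters: {sorted(bad)!r}"
        )
    return seq


@dataclass(frozen=True)
class SeqRecord:
    """A named nucleotide sequence over the alphabet A, C, G, T, N."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("SeqRecord id must be non-empty")
        if not self.seq:
            raise ValueError(f"SeqRecord {self.id!r} has an empty sequence")
        object.__setattr__(self, "seq", _validate_nucleotides(self.seq, self.id))

    def __len__(self) -> int:
        return len(self.seq)

    def subseq(self, start: int, end: int) -> str:
        """Slice by 1-based inclusive coordinates."""
        if not (1 <= start <= end <= len(self.seq)):
            raise CoordinateError(
                f"span {start}..{end} outside 1..{len(self.seq)} of {self.id!r}"
            )
        return self.seq[start - 1 : end]


def read_fasta(path: str | Path) -> list[SeqRecord]:
    """Read a FASTA file into validated, upper-cased records (file order).

    Raises :class:`FastaFormatError` on an empty file, a duplicate id, or
    a character outside the A/C/G/T/N alphabet.
    """
    records: list[SeqRecord] = []
    seen: set[str] = set()
    for rec in _SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FastaFormatError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        try:
            records.append(SeqRecord(rec.id, str(rec.seq), rec.description))
        except SequenceAlphabetError as exc:
            raise FastaFormatError(str(exc)) from exc
        except ValueError as exc:
            raise FastaFormatError(str(exc)) from exc
    if not records:
        raise FastaFormatError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path, width: int = 70) -> None:
    """Write records as wrapped multi-FASTA."""
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def revcomp(seq: str) -> str:
    """Reverse complement; N maps to N. Involution by construction."""
    seq = _validate_nucleotides(seq)
    return str(_Seq(seq).reverse_complement())


def translate(seq: str, stop_policy: str = TO_FIRST_STOP) -> str:
    """Translate a nucleotide string under the standard nuclear code.

    The frame starts at the first position; a trailing partial codon is
    dropped. With ``to_first_stop`` the protein is truncated at (and
    excludes) the first stop codon; with ``run_through`` stops appear as
    ``*`` and translation continues to the end.
    """
    seq = _validate_nucleotides(seq)
    if len(seq) < 3:
        raise ValueError(f"cannot translate a sequence of length {len(seq)} (< 3)")
    if stop_policy not in (RUN_THROUGH, TO_FIRST_STOP):
        raise ValueError(f"unknown stop_policy {stop_policy!r}")
    trimmed = seq[: len(seq) - len(seq) % 3]
    aa = str(_Seq(trimmed).translate())
    if stop_policy == TO_FIRST_STOP:
        return aa.partition("*")[0]
    return aa


def _spliced_to_genomic_segments(
    exons: Sequence[tuple[int, int]], start: int, end: int
) -> list[tuple[int, int]]:
    """Map a spliced-coordinate interval onto genomic exon segments."""
    segments: list[tuple[int, int]] = []
    offset = 0  # spliced bases consumed before the current exon
    for es, ee in exons:
        elen = ee - es + 1
        lo = max(start, offset + 1)
        hi = min(end, offset + elen)
        if lo <= hi:
            segments.append((es + (lo - offset - 1), es + (hi - offset - 1)))
        offset += elen
    if not segments:
        raise CoordinateError(f"spliced span {start}..{end} maps to no exon")
    return segments


def write_gene_model_gff(model, path: str | Path, seq_len: int | None = None) -> None:
    """Write a gene model (exons, introns, CDS) as GFF3.

    ``model`` is a :class:`nixlocus.annotate.GeneModel`. When ``seq_len``
    is given, coordinates are bounds-checked against it and a
    ``##sequence-region`` pragma is emitted.
    """
    if not model.exons:
        raise CoordinateError("gene model has no exons")
    gstart = model.exons[0][0]
    gend = model.exons[-1][1]
    if seq_len is not None and not (1 <= gstart <= gend <= seq_len):
        raise CoordinateError(
            f"gene span {gstart}..{gend} outside 1..{seq_len} of {model.seq_id!r}"
        )
    gene_id = f"{model.seq_id}.gene"
    mrna_id = f"{model.seq_id}.mRNA"

    def line(ftype: str, start: int, end: int, attrs: str, phase: str = ".") -> str:
        return (
            f"{model.seq_id}\tnixlocus\t{ftype}\t{start}\t{end}\t.\t"
            f"{model.strand}\t{phase}\t{attrs}"
        )

    rows = [
        "##gff-version 3",
    ]
    if seq_len is not None:
        rows.append(f"##sequence-region {model.seq_id} 1 {seq_len}")
    rows.append(line("gene", gstart, gend, f"ID={gene_id}"))
    rows.append(line("mRNA", gstart, gend, f"ID={mrna_id};Parent={gene_id}"))
    for i, (es, ee) in enumerate(model.exons, start=1):
        rows.append(
            line("exon", es, ee, f"ID={mrna_id}.exon{i};Parent={mrna_id}")
        )
    for i, (s, e) in enumerate(model.introns, start=1):
        rows.append(
            line("intron", s, e, f"ID={mrna_id}.intron{i};Parent={mrna_id}")
        )
    if model.cds is not None:
        cs, ce = model.cds
        consumed = 0
        for j, (s, e) in enumerate(
            _spliced_to_genomic_segments(model.exons, cs, ce), start=1
        ):
            phase = str((3 - consumed % 3) % 3)
            rows.append(
                line("CDS", s, e, f"ID={mrna_id}.cds;Parent={mrna_id}", phase)
            )
            consumed += e - s + 1
    Path(path).write_text("\n".join(rows) + "\n")


def read_gene_model_gff(path: str | Path):
    """Read a GFF3 gene model written by :func:`write_gene_model_gff`."""
    import gffutils

    from .annotate import GeneModel

    db = gffutils.create_db(
        str(path), dbfn=":memory:", keep_order=True, merge_strategy="create_unique"
    )
    seq_id = None
    strand = "+"
    exons: list[tuple[int, int]] = []
    introns: list[tuple[int, int]] = []
    cds_segments: list[tuple[int, int]] = []
    for feat in db.all_features():
        if feat.featuretype == "exon":
            exons.append((feat.start, feat.end))
        elif feat.featuretype == "intron":
            introns.append((feat.start, feat.end))
        elif feat.featuretype == "CDS":
            cds_segments.append((feat.start, feat.end))
        if feat.featuretype == "gene":
            seq_id = feat.seqid
            strand = feat.strand
    if seq_id is None or not exons:
        raise FastaFormatError(f"no gene model found in {path}")
    exons.sort()
    introns.sort()
    cds = None
    if cds_segments:
        cds_segments.sort()
        # map genomic CDS bounds back onto spliced coordinates
        def to_spliced(gpos: int) -> int:
            offset = 0
            for es, ee in exons:
                if es <= gpos <= ee:
                    return offset + (gpos - es) + 1
                offset += ee - es + 1
            raise CoordinateError(f"CDS position {gpos} not inside any exon")

        cds = (to_spliced(cds_segments[0][0]), to_spliced(cds_segments[-1][1]))
    return GeneModel(
        seq_id=seq_id,
        exons=tuple(exons),
        introns=tuple(introns),
        cds=cds,
        strand=strand,
    )
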