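"""In-silico PCR and the presence/absence sexing assay.

Primer sites are exact, full-length, zero-mismatch matches: the forward
primer on the plus strand and the reverse primer on the minus strand (its
reverse complement on the plus strand), in both pairings so results are
invariant to template orientation. An amplicon runs from the 5' end of
the forward primer to the 5' end of the reverse primer, inclusive — the
convention under which an amplicon spanning an intron shrinks by exactly
the intron length on a spliced template.

The sexing caller implements a hemizygous marker assay: locus-specific
amplicons appear only in templates carrying the male-specific locus,
gated by an amplification control (an 18S rDNA fragment) for template
integrity. No control product means the call is indeterminate.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .seqio import SeqRecord, _validate_nucleotides, revcomp

DEFAULT_MAX_PRODUCT = 5000

MALE = "male"
FEMALE = "female"
INDETERMINATE = "indeterminate"

CONTROL_ASSAY = "control"


@dataclass(frozen=True)
class PrimerPair:
    name: str
    forward_seq: str  # 5'->3'
    reverse_seq: str  # 5'->3' on the reverse strand
    max_product: int = DEFAULT_MAX_PRODUCT

    def __post_init__(self) -> None:
        for label, seq in (("forward", self.forward_seq), ("reverse", self.reverse_seq)):
            seq = _validate_nucleotides(seq, f"{self.name} {label} primer")
            if not 15 <= len(seq) <= 35:
                raise ValueError(
                    f"{self.name} {label} primer length {len(seq)} outside 15..35"
                )
            object.__setattr__(self, f"{label}_seq", seq)
        if self.max_product < 1:
            raise ValueError("max_product must be positive")


@dataclass(frozen=True)
class Amplicon:
    template_id: str
    pair_name: str
    start: int  # 1-based inclusive, forward strand of the template
    end: int
    length: int

    def __post_init__(self) -> None:
        if self.length != self.end - self.start + 1:
            raise ValueError("amplicon length must equal end - start + 1")


@dataclass(frozen=True)
class Assay:
    """A primer pair plus the product length(s) that score as positive."""

    pair: PrimerPair
    expected_lengths: frozenset[int]


@dataclass(frozen=True)
class SexCall:
    sample_id: str
    call: str  # male | female | indeterminate
    evidence: Mapping[str, bool]  # per-assay presence flags


def _find_all(haystack: str, needle: str) -> list[int]:
    out: list[int] = []
    i = haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def find_primer_sites(template: SeqRecord, primer: str) -> list[tuple[int, str]]:
    """All exact full-length binding sites of a primer on a template.

    Returns (position, strand) tuples; the position is the 1-based
    leftmost template coordinate of the site on the forward strand.
    """
    primer = _validate_nucleotides(primer, "primer")
    sites = [(i + 1, "forward") for i in _find_all(template.seq, primer)]
    forward_positions = {pos for pos, _ in sites}
    sites += [
        (i + 1, "reverse")
        for i in _find_all(template.seq, revcomp(primer))
        # a palindromic primer shares its footprint on both strands;
        # report that site once, as forward
        if i + 1 not in forward_positions or primer != revcomp(primer)
    ]
    return sorted(sites)


def amplify(template: SeqRecord, pair: PrimerPair) -> list[Amplicon]:
    """Predict all products of a primer pair on a template.

    Every (plus-strand site of one primer, downstream minus-strand site of
    the other) combination with a product no longer than ``max_product``
    yields an amplicon. Both primer-role pairings are evaluated, so a
    reverse-complemented template gives the same product lengths.
    """
    seq = template.seq
    products: list[Amplicon] = []
    pairings = (
        (pair.forward_seq, pair.reverse_seq),
        (pair.reverse_seq, pair.forward_seq),
    )
    seen: set[tuple[int, int]] = set()
    for plus_primer, minus_primer in pairings:
        plus_sites = _find_all(seq, plus_primer)
        minus_sites = _find_all(seq, revcomp(minus_primer))
        for p in plus_sites:
            for q in minus_sites:
                if q < p + len(plus_primer):
                    continue  # reverse site must lie downstream of the forward primer
                start = p + 1
                end = q + len(minus_primer)  # 5' end of the reverse primer
                length = end - start + 1
                if length > pair.max_product or (start, end) in seen:
                    continue
                seen.add((start, end))
                products.append(
                    Amplicon(template.id, pair.name, start, end, length)
                )
    return sorted(products, key=lambda a: (a.start, a.end))


def assay_positive(
    templates: Iterable[tuple[SeqRecord, int]], assay: Assay
) -> bool:
    """True when any template in the pool yields a product of an expected length."""
    for record, count in templates:
        if count <= 0:
            continue
        if any(a.length in assay.expected_lengths for a in amplify(record, assay.pair)):
            return True
    return False


def sex_call(
    sample_id: str,
    templates: Sequence[tuple[SeqRecord, int]],
    panel: Mapping[str, Assay],
) -> SexCall:
    """Call the sex of a sample from its template pool.

    ``panel`` must contain a ``control`` assay; every other assay is
    treated as a male-specific locus marker. Male = control positive and
    any marker positive; female = control positive and all markers
    negative; indeterminate = control negative (failed template).
    """
    if CONTROL_ASSAY not in panel:
        raise ValueError("the assay panel must contain a 'control' assay")
    evidence = {name: assay_positive(templates, assay) for name, assay in panel.items()}
    if not evidence[CONTROL_ASSAY]:
        call = INDETERMINATE
    elif any(v for name, v in evidence.items() if name != CONTROL_ASSAY):
        call = MALE
    else:
        call = FEMALE
    return SexCall(sample_id=sample_id, call=call, evidence=evidence)


def write_primer_panel(panel: Mapping[str, Assay], path: str | Path) -> None:
    """Write a panel as TSV: name, forward, reverse, max_product, expected."""
    lines = ["name\tforward\treverse\tmax_product\texpected_lengths"]
    for name, assay in panel.items():
        expected = ",".join(str(x) for x in sorted(assay.expected_lengths))
        lines.append(
            f"{name}\t{assay.pair.forward_seq}\t{assay.pair.reverse_seq}\t"
            f"{assay.pair.max_product}\t{expected}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_primer_panel(path: str | Path) -> dict[str, Assay]:
    lines = Path(path).read_text().strip().splitlines()
    panel: dict[str, Assay] = {}
    for line in lines[1:]:
        name, fwd, rev, max_product, expected = line.split("\t")
        panel[name] = Assay(
            pair=PrimerPair(name, fwd, rev, int(max_product)),
            expected_lengths=frozenset(int(x) for x in expected.split(",")),
        )
    return panel
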