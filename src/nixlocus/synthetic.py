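"""Synthetic male-determining locus generator.

Generates a canonical fixture locus whose architecture reproduces, by
construction, the printed sequence arithmetic of the Aedes albopictus
Nix locus: a 1580-nt composite carrying a two-exon gene (674 + 175 nt)
split by a 107-nt intron with a non-canonical GTTTGT donor and a TTTCAG
acceptor; a spliced CDS encoding 282 residues; an in-frame stop at intron
offset 26 so the intron-retained isoform encodes 233 residues; a 701-nt
seed substring; genomic contigs of 379/257/315 nt placed so the overlap
walk extends the seed by 174/145 nt and transcript contigs of
603/583/257/214 nt extend it by a further 560 nt to the full 1580.

Everything else — UTR/flank background, decoy contigs, the independent
18S-rDNA-analog control locus — is seeded random sequence. Decoys and the
control locus are rejection-sampled to share no >= ``min_overlap``-nt
exact substring with the composite (either strand), so "no extension from
decoys" and "no locus product in females" are hard guarantees.

All generators are bit-reproducible given their integer seed. Because a
handful of global properties (unique seed occurrence, unique primer
sites, a longest ORF that is the intended CDS) depend on the random
background, the canonical fixture validates itself after construction and
deterministically re-draws the background in the rare case a constraint
is violated; the printed architecture constants never change.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .annotate import STOP_CODONS, find_cds, infer_introns
from .pcr import Assay, PrimerPair, amplify
from .popscan import Variant
from .seqio import RUN_THROUGH, TO_FIRST_STOP, SeqRecord, revcomp, translate

_BASES = "ACGT"
_NONSTOP_CODONS = [
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in STOP_CODONS
]

DEFAULT_MIN_OVERLAP = 20
_MAX_FIXTURE_ATTEMPTS = 64

# -- canonical architecture constants (1-based inclusive composite coords) --
UTR5_LEN = 100
EXON1_LEN = 674
INTRON_LEN = 107
EXON2_LEN = 175
UTR3_LEN = 524
COMPOSITE_LEN = UTR5_LEN + EXON1_LEN + INTRON_LEN + EXON2_LEN + UTR3_LEN  # 1580
SEED_SPAN = (175, 875)  # 701 nt
DONOR_HEXAMER = "GTTTGT"  # non-canonical donor (canonical is GTAAGT)
ACCEPTOR_HEXAMER = "TTTCAG"
INTRONIC_STOP_OFFSET = 26  # 1-based offset of the in-frame stop within the intron

CONTROL_LOCUS_LEN = 1000
CONTROL_AMPLICON = (101, 857)  # 757 nt, the 18S rDNA analog product

# primer footprints on the composite: (fwd_start, fwd_end, rev_start, rev_end)
PRIMER_COORDS = {
    "nix_833": (173, 192, 986, 1005),
    "nix_309": (706, 725, 995, 1014),
    "nix_1121": (36, 55, 1137, 1156),
}
# expected product lengths per assay: genomic/unspliced first, spliced second
ASSAY_EXPECTED = {
    "nix_833": frozenset({833, 726}),
    "nix_309": frozenset({309, 202}),
    "nix_1121": frozenset({1121, 1014}),
    "control": frozenset({757}),
}

GENOMIC_DNA = "genomic_dna"
CDNA = "cdna"


@dataclass(frozen=True)
class LocusArchitecture:
    composite_len: int = COMPOSITE_LEN
    exon1: tuple[int, int] = (UTR5_LEN + 1, UTR5_LEN + EXON1_LEN)
    intron: tuple[int, int] = (UTR5_LEN + EXON1_LEN + 1, UTR5_LEN + EXON1_LEN + INTRON_LEN)
    exon2: tuple[int, int] = (
        UTR5_LEN + EXON1_LEN + INTRON_LEN + 1,
        UTR5_LEN + EXON1_LEN + INTRON_LEN + EXON2_LEN,
    )
    donor_hexamer: str = DONOR_HEXAMER
    acceptor_hexamer: str = ACCEPTOR_HEXAMER
    intronic_stop_offset: int = INTRONIC_STOP_OFFSET
    seed_span: tuple[int, int] = SEED_SPAN
    utr5_len: int = UTR5_LEN
    utr3_len: int = UTR3_LEN

    def __post_init__(self) -> None:
        e1 = self.exon1[1] - self.exon1[0] + 1
        e2 = self.exon2[1] - self.exon2[0] + 1
        il = self.intron[1] - self.intron[0] + 1
        if e1 + e2 != 849 or (e1 + e2) % 3 != 0:
            raise ValueError("exon lengths must sum to the 849-nt CDS")
        if self.composite_len != self.utr5_len + e1 + il + e2 + self.utr3_len:
            raise ValueError("flanks, exons and intron must tile the composite")


@dataclass(frozen=True)
class LocusFixture:
    architecture: LocusArchitecture
    composite: SeqRecord  # 1580 nt genomic composite
    spliced_transcript: SeqRecord  # 1473 nt, intron excised
    seed: SeqRecord  # 701 nt seed analog
    control_locus: SeqRecord  # independent locus carrying the control amplicon
    rng_seed: int


@dataclass(frozen=True)
class ContigPlacement:
    contig_id: str
    start: int
    end: int
    source: Literal["genome", "transcriptome"]

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class Sample:
    sample_id: str
    sex: Literal["male", "female"]
    template_kind: Literal["genomic_dna", "cdna"]
    stage: str = "adult"
    ir_fraction: float | None = None  # cdna only
    control_present: bool = True

    def __post_init__(self) -> None:
        if self.template_kind == CDNA:
            frac = 0.0 if self.ir_fraction is None else self.ir_fraction
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"ir_fraction {frac} outside [0, 1]")
        elif self.ir_fraction is not None:
            raise ValueError("ir_fraction is defined only for cDNA samples")


DEFAULT_GENOMIC_LAYOUT = (
    ContigPlacement("gA", 1, 379, "genome"),  # overlaps the seed by 205, extends 5' 174
    ContigPlacement("gB", 764, 1020, "genome"),  # overlaps by 112, extends 3' 145
    ContigPlacement("gC", 1100, 1414, "genome"),  # fully contained, extends nothing
)

DEFAULT_TRANSCRIPT_LAYOUT = (
    ContigPlacement("t1", 978, 1580, "transcriptome"),  # extends 3' by 560
    ContigPlacement("t2", 998, 1580, "transcriptome"),
    ContigPlacement("t3", 1100, 1356, "transcriptome"),
    ContigPlacement("t4", 1200, 1413, "transcriptome"),
)


def _rng(seed: int, *extra: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *extra]))


def _random_bases(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=n))


def _random_nonstop_codons(rng: np.random.Generator, n: int) -> list[str]:
    return [_NONSTOP_CODONS[i] for i in rng.integers(0, len(_NONSTOP_CODONS), size=n)]


def _build_cds(rng: np.random.Generator) -> str:
    """The 849-nt spliced CDS: ATG + 281 internal codons + TAA.

    Codon 225 spans the exon1/exon2 junction and is pinned to AGG so that
    exon 1 ends ...AG and exon 2 begins GT (codon 226 starts with T).
    """
    codons = ["ATG"]
    codons += _random_nonstop_codons(rng, 223)  # codons 2..224
    codons.append("AGG")  # codon 225: exon1 "AG" + exon2 first base "G"
    while True:  # codon 226 must start with the pinned exon2 "T" and not be a stop
        tail = _random_bases(rng, 2)
        if "T" + tail not in STOP_CODONS:
            codons.append("T" + tail)
            break
    codons += _random_nonstop_codons(rng, 56)  # codons 227..282
    codons.append("TAA")
    cds = "".join(codons)
    assert len(cds) == 849 and cds[672:675] == "AGG"
    return cds


def _build_intron(rng: np.random.Generator) -> str:
    """The 107-nt intron: GTTTGT donor, TTTCAG acceptor, an in-frame TAA
    at offset 26 and no in-frame stop upstream of it.

    The retained-intron reading frame enters the intron after the AG|G
    junction codon, so in-frame intronic codons start at offsets 2, 5, …
    """
    head = DONOR_HEXAMER + _random_bases(rng, 1)  # offsets 1..7; codons 2-4 = TTT,
    # 5-7 = GT?: neither can be a stop
    mid = "".join(_random_nonstop_codons(rng, 6))  # offsets 8..25, in frame
    stop = "TAA"  # offsets 26..28
    tail_len = INTRON_LEN - len(head) - len(mid) - len(stop) - len(ACCEPTOR_HEXAMER)
    tail = _random_bases(rng, tail_len)  # offsets 29..101, after the stop
    intron = head + mid + stop + tail + ACCEPTOR_HEXAMER
    assert len(intron) == INTRON_LEN
    assert intron[INTRONIC_STOP_OFFSET - 1 : INTRONIC_STOP_OFFSET + 2] == "TAA"
    return intron


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def _shares_kmer(seq: str, kmer_set: set[str], k: int) -> bool:
    rc = revcomp(seq)
    return any(
        s[i : i + k] in kmer_set for s in (seq, rc) for i in range(len(s) - k + 1)
    )


def _rejection_sample(
    rng: np.random.Generator, length: int, kmer_set: set[str], k: int
) -> str:
    for _ in range(1000):
        candidate = _random_bases(rng, length)
        if not _shares_kmer(candidate, kmer_set, k):
            return candidate
    raise RuntimeError("rejection sampling failed (should be unreachable)")


def fixture_primer_panel(fixture: LocusFixture) -> dict[str, Assay]:
    """The fixture's assay panel, with primers read off the fixture itself.

    Three locus assays (nix_833, nix_309 spanning the intron; nix_1121
    spanning the whole CDS) plus the 757-nt control assay on the
    independent control locus.
    """
    comp = fixture.composite
    panel: dict[str, Assay] = {}
    for name, (fs, fe, rs, re_) in PRIMER_COORDS.items():
        panel[name] = Assay(
            pair=PrimerPair(name, comp.subseq(fs, fe), revcomp(comp.subseq(rs, re_))),
            expected_lengths=ASSAY_EXPECTED[name],
        )
    cs, ce = CONTROL_AMPLICON
    ctrl = fixture.control_locus
    panel["control"] = Assay(
        pair=PrimerPair(
            "control", ctrl.subseq(cs, cs + 19), revcomp(ctrl.subseq(ce - 19, ce))
        ),
        expected_lengths=ASSAY_EXPECTED["control"],
    )
    return panel


def _validate_fixture(fx: LocusFixture) -> None:
    arch = fx.architecture
    comp, spliced = fx.composite.seq, fx.spliced_transcript.seq
    cds_start = arch.exon1[0]
    spliced_cds = spliced[cds_start - 1 : cds_start - 1 + 849]
    if len(translate(spliced_cds, TO_FIRST_STOP)) != 282:
        raise ValueError("spliced CDS does not encode 282 residues")
    if "*" in translate(spliced_cds[:-3], RUN_THROUGH):
        raise ValueError("premature stop in the spliced CDS")
    retained = translate(comp[cds_start - 1 :], TO_FIRST_STOP)
    if len(retained) != 233:
        raise ValueError("intron-retained reading frame does not stop at 233 residues")
    start, _, protein = find_cds(SeqRecord("spliced", spliced))
    if (start, len(protein)) != (cds_start, 282):
        raise ValueError("longest ORF of the spliced transcript is not the intended CDS")
    seed = fx.seed.seq
    if comp.count(seed) != 1 or revcomp(seed) in comp:
        raise ValueError("seed must occur exactly once in the composite")
    model = infer_introns(fx.composite, fx.spliced_transcript)
    if model.exons != (arch.exon1, arch.exon2) or model.introns != (arch.intron,):
        raise ValueError("gene-model inference does not recover the architecture")
    panel = fixture_primer_panel(fx)
    expect = {
        ("nix_833", fx.composite): [833],
        ("nix_833", fx.spliced_transcript): [726],
        ("nix_309", fx.composite): [309],
        ("nix_309", fx.spliced_transcript): [202],
        ("nix_1121", fx.composite): [1121],
        ("control", fx.control_locus): [757],
    }
    for (name, template), lengths in expect.items():
        got = [a.length for a in amplify(template, panel[name].pair)]
        if got != lengths:
            raise ValueError(f"assay {name} on {template.id}: products {got} != {lengths}")
    for name, assay in panel.items():
        other = fx.composite if name == "control" else fx.control_locus
        if amplify(other, assay.pair):
            raise ValueError(f"assay {name} amplifies the wrong locus")


def make_canonical_fixture(rng_seed: int = 0) -> LocusFixture:
    """Build the canonical 1580-nt fixture locus, deterministically.

    Byte-identical for equal seeds. The architecture constants are fixed;
    only flank/decoy background varies with the seed, and the background
    is re-drawn (still deterministically) if it happens to violate one of
    the fixture's global uniqueness constraints.
    """
    arch = LocusArchitecture()
    last_error: Exception | None = None
    for attempt in range(_MAX_FIXTURE_ATTEMPTS):
        rng = _rng(rng_seed, 0, attempt)
        cds = _build_cds(rng)
        intron = _build_intron(rng)
        utr5 = _random_bases(rng, arch.utr5_len)
        utr3 = _random_bases(rng, arch.utr3_len)
        composite = utr5 + cds[:EXON1_LEN] + intron + cds[EXON1_LEN:] + utr3
        spliced = utr5 + cds + utr3
        seed = composite[arch.seed_span[0] - 1 : arch.seed_span[1]]
        control = _rejection_sample(
            rng, CONTROL_LOCUS_LEN, _kmers(composite, DEFAULT_MIN_OVERLAP),
            DEFAULT_MIN_OVERLAP,
        )
        fx = LocusFixture(
            architecture=arch,
            composite=SeqRecord("nix_composite", composite),
            spliced_transcript=SeqRecord("nix_spliced_mrna", spliced),
            seed=SeqRecord("nix_seed_701", seed),
            control_locus=SeqRecord("rdna18s_control", control),
            rng_seed=int(rng_seed),
        )
        try:
            _validate_fixture(fx)
        except ValueError as exc:  # pathological background: re-draw
            last_error = exc
            continue
        return fx
    raise RuntimeError(f"could not build a valid fixture: {last_error}")


def _emit_contigs(
    fixture: LocusFixture,
    layout: Sequence[ContigPlacement],
    n_decoys: int,
    rng: np.random.Generator,
    min_overlap: int,
    decoy_prefix: str = "decoy",
) -> list[SeqRecord]:
    comp = fixture.composite.seq
    records: list[SeqRecord] = []
    flip = rng.random(len(layout) + n_decoys) < 0.5  # strand test
    for i, placement in enumerate(layout):
        if not 1 <= placement.start <= placement.end <= len(comp):
            raise ValueError(
                f"placement {placement.contig_id} outside the composite"
            )
        seq = comp[placement.start - 1 : placement.end]
        records.append(
            SeqRecord(placement.contig_id, seq if not flip[i] else revcomp(seq))
        )
    kmer_set = _kmers(comp, min_overlap)
    decoy_lengths = rng.integers(200, 601, size=n_decoys)
    for j, length in enumerate(decoy_lengths, start=1):
        seq = _rejection_sample(rng, int(length), kmer_set, min_overlap)
        if flip[len(layout) + j - 1]:
            seq = revcomp(seq)
        records.append(SeqRecord(f"{decoy_prefix}_{j:02d}", seq))
    return records


def fragment_genome(
    fixture: LocusFixture,
    layout: Sequence[ContigPlacement] = DEFAULT_GENOMIC_LAYOUT,
    n_decoys: int = 3,
    rng_seed: int = 0,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> list[SeqRecord]:
    """Genomic contig database: the three locus contigs (379/257/315 nt by
    default) plus rejection-sampled decoys; a random subset is emitted
    reverse-complemented."""
    return _emit_contigs(
        fixture, layout, n_decoys, _rng(rng_seed, 1), min_overlap, "gdecoy"
    )


def make_transcript_db(
    fixture: LocusFixture,
    layout: Sequence[ContigPlacement] = DEFAULT_TRANSCRIPT_LAYOUT,
    n_decoys: int = 3,
    rng_seed: int = 0,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> list[SeqRecord]:
    """Transcript contig database (603/583/257/214 nt by default), all 3'
    of the intron so they match the genomic composite contiguously."""
    return _emit_contigs(
        fixture, layout, n_decoys, _rng(rng_seed, 2), min_overlap, "tdecoy"
    )


def make_sample_templates(
    fixture: LocusFixture,
    sample: Sample,
    depth: int = 200,
    rng_seed: int = 0,
) -> list[tuple[SeqRecord, int]]:
    """Per-sample template pool as (record, copy count) pairs.

    Male genomic DNA carries the locus (hemizygous) plus the control;
    female templates carry the control only. Male cDNA is a binomial
    mixture of intron-retaining (unspliced) and spliced transcripts at the
    sample's ``ir_fraction``. ``control_present=False`` simulates a failed
    extraction.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = _rng(rng_seed, 3)
    pool: list[tuple[SeqRecord, int]] = []
    if sample.sex == "male":
        if sample.template_kind == GENOMIC_DNA:
            pool.append((fixture.composite, 1))
        else:
            frac = sample.ir_fraction or 0.0
            n_retained = int(rng.binomial(depth, frac))
            if n_retained:
                pool.append(
                    (SeqRecord("nix_unspliced_mrna", fixture.composite.seq), n_retained)
                )
            if depth - n_retained:
                pool.append((fixture.spliced_transcript, depth - n_retained))
    if sample.control_present:
        pool.append((fixture.control_locus, 1))
    return pool


def simulate_population(
    fixture: LocusFixture,
    n: int = 11,
    mut_rate: float = 0.0,
    frag_len_range: tuple[int, int] = (720, 767),
    rng_seed: int = 0,
) -> tuple[list[SeqRecord], list[Variant]]:
    """Partial resequenced fragments of the 833-nt amplicon region.

    Each fragment is a sub-span of the locus amplicon region that always
    contains the intron, with i.i.d. per-site substitutions at
    ``mut_rate``. Returns the fragments and the injected-variant truth
    table (positions on the composite reference).
    """
    if not 0.0 <= mut_rate < 1.0:
        raise ValueError("mut_rate must be in [0, 1)")
    region_start, region_end = PRIMER_COORDS["nix_833"][0], PRIMER_COORDS["nix_833"][3]
    intron_s, intron_e = fixture.architecture.intron
    lo, hi = frag_len_range
    max_len = region_end - region_start + 1
    if not 1 <= lo <= hi <= max_len:
        raise ValueError(f"frag_len_range must lie within [1, {max_len}]")
    if lo < intron_e - intron_s + 1:
        raise ValueError(
            "fragments shorter than the intron cannot always contain it"
        )
    rng = _rng(rng_seed, 4)
    comp = fixture.composite.seq
    fragments: list[SeqRecord] = []
    truth: list[Variant] = []
    for i in range(1, n + 1):
        length = int(rng.integers(lo, hi + 1))
        start_lo = max(region_start, intron_e - length + 1)
        start_hi = min(intron_s, region_end - length + 1)
        if start_lo > start_hi:
            raise ValueError(
                f"fragment length {length} cannot contain the intron inside the region"
            )
        start = int(rng.integers(start_lo, start_hi + 1))
        frag_id = f"pop_{i:02d}"
        bases = list(comp[start - 1 : start - 1 + length])
        if mut_rate > 0:
            hits = np.nonzero(rng.random(length) < mut_rate)[0]
            for j in hits:
                ref = bases[j]
                alt = _BASES[(_BASES.index(ref) + int(rng.integers(1, 4))) % 4]
                bases[j] = alt
                truth.append(Variant(start + int(j), ref, alt, frag_id))
        fragments.append(SeqRecord(frag_id, "".join(bases)))
    return fragments, truth
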