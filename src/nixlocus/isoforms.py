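"""Spliced and intron-retained isoforms, their protein products, and
intron-retention fraction estimation from classified amplicon pools.

Intron retention (IR) keeps an intron in the mature transcript. When the
retained intron carries an in-frame stop codon, translation terminates
inside the intron and the product is a truncated protein — the mechanism
by which a retained 107-nt intron turns a 282-aa product into a 233-aa
one. The IR fraction of a transcript pool is estimated from the counts of
length-classified RT-PCR amplicons (retained vs spliced product lengths),
with a Wilson 95% confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

from scipy.stats import binomtest

from .annotate import GeneModel
from .seqio import RUN_THROUGH, SeqRecord, translate

MAX_ENUMERATED_INTRONS = 4

SPLICED = "spliced"
INTRON_RETAINED = "intron_retained"


class IsoformError(ValueError):
    pass


@dataclass(frozen=True)
class StopSource:
    kind: str  # "cds_end" | "intronic"
    intron_index: int | None = None  # 1-based, for intronic stops
    offset_in_intron: int | None = None  # 1-based nt offset of the stop codon


@dataclass(frozen=True)
class IsoformProduct:
    isoform: str  # spliced | intron_retained
    retained_introns: tuple[int, ...]  # 1-based intron indices
    transcript_len: int
    protein: str
    truncated: bool
    stop_source: StopSource | None

    def __post_init__(self) -> None:
        intronic = self.stop_source is not None and self.stop_source.kind == "intronic"
        if self.truncated != intronic:
            raise ValueError("truncated must mirror an intronic stop_source")


@dataclass(frozen=True)
class IRFractionEstimate:
    n_total: int
    n_retained: int
    fraction: float
    ci95: tuple[float, float]
    unclassified: dict[int, int]

    def __post_init__(self) -> None:
        lo, hi = self.ci95
        if not (0.0 <= lo <= self.fraction <= hi <= 1.0):
            raise ValueError("Wilson interval must bracket the point estimate")


def _retention_patterns(n_introns: int) -> list[tuple[int, ...]]:
    patterns: list[tuple[int, ...]] = []
    for k in range(n_introns + 1):
        patterns.extend(combinations(range(1, n_introns + 1), k))
    return patterns


def enumerate_isoforms(genomic: SeqRecord, model: GeneModel) -> list[IsoformProduct]:
    """All retention patterns of a gene model, translated to first stop.

    For a single-intron gene this is exactly the fully spliced and the
    fully intron-retained product. Multi-intron models are enumerated
    exhaustively up to 4 introns; larger models raise.
    """
    if model.cds is None:
        raise IsoformError("gene model has no CDS; cannot translate isoforms")
    k = len(model.introns)
    if k > MAX_ENUMERATED_INTRONS:
        raise IsoformError(
            f"{k} introns exceed the exhaustive enumeration limit of "
            f"{MAX_ENUMERATED_INTRONS}"
        )
    g = genomic.seq
    cds_start, _ = model.cds
    products: list[IsoformProduct] = []
    for pattern in _retention_patterns(k):
        # assemble the transcript: exons plus retained introns, genomic order
        parts: list[str] = []
        intron_tx_span: dict[int, tuple[int, int]] = {}
        pos = 0
        for i, (es, ee) in enumerate(model.exons):
            parts.append(g[es - 1 : ee])
            pos += ee - es + 1
            if i < len(model.introns) and (i + 1) in pattern:
                s, e = model.introns[i]
                parts.append(g[s - 1 : e])
                intron_tx_span[i + 1] = (pos + 1, pos + (e - s + 1))
                pos += e - s + 1
        transcript = "".join(parts)
        # CDS start shifts by every retained intron inserted upstream of it
        tx_cds_start = cds_start + sum(
            e - s + 1
            for idx, (s, e) in enumerate(model.introns, start=1)
            if idx in pattern and intron_tx_span[idx][0] <= cds_start
        )
        aa = translate(transcript[tx_cds_start - 1 :], RUN_THROUGH)
        protein, _, _ = aa.partition("*")
        stop_source: StopSource | None = None
        if "*" in aa:
            # 1-based transcript coordinate of the first base of the stop codon
            stop_pos = tx_cds_start + 3 * len(protein)
            for idx, (ts, te) in intron_tx_span.items():
                if ts <= stop_pos <= te:
                    stop_source = StopSource("intronic", idx, stop_pos - ts + 1)
                    break
            else:
                stop_source = StopSource("cds_end")
        products.append(
            IsoformProduct(
                isoform=INTRON_RETAINED if pattern else SPLICED,
                retained_introns=pattern,
                transcript_len=len(transcript),
                protein=protein,
                truncated=stop_source is not None and stop_source.kind == "intronic",
                stop_source=stop_source,
            )
        )
    return products


def classify_amplicon_pool(
    length_counts: dict[int, int], retained_len: int, spliced_len: int
) -> IRFractionEstimate:
    """Estimate the IR fraction from amplicon length counts.

    ``length_counts`` maps amplicon length to occurrence count. Lengths
    other than the two expected ones are reported as unclassified, never
    silently dropped. Raises on an empty classified pool.
    """
    if retained_len == spliced_len:
        raise IsoformError("retained and spliced lengths must differ")
    n_retained = length_counts.get(retained_len, 0)
    n_spliced = length_counts.get(spliced_len, 0)
    unclassified = {
        length: n
        for length, n in sorted(length_counts.items())
        if length not in (retained_len, spliced_len) and n > 0
    }
    n_total = n_retained + n_spliced
    if n_total == 0:
        raise IsoformError("no amplicons of the expected lengths to classify")
    ci = binomtest(n_retained, n_total).proportion_ci(
        confidence_level=0.95, method="wilson"
    )
    return IRFractionEstimate(
        n_total=n_total,
        n_retained=n_retained,
        fraction=n_retained / n_total,
        ci95=(float(ci.low), float(ci.high)),
        unclassified=unclassified,
    )
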