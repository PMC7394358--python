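"""DNA sequence primitives: genome records, gene annotations, reverse
complement, exact gene location, and flank-window extraction.

Coordinates in user-facing objects are 1-based inclusive (GFF convention);
internal slicing is 0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

log = logging.getLogger("irscan")

#: IUPAC nucleotide alphabet accepted after uppercase normalization.
IUPAC_ALPHABET = frozenset("ACGTNRYSWKMBDHV")

#: Unambiguous bases; only these may participate in a 100%-identity match.
UNAMBIGUOUS = frozenset("ACGT")

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")


class SequenceAlphabetError(ValueError):
    """A sequence contains a character outside the IUPAC nucleotide alphabet."""


class GeneNotFoundError(LookupError):
    """The gene sequence occurs nowhere in the genome on either strand."""


class AmbiguousLocationError(LookupError):
    """The gene sequence occurs more than once (counting both strands)."""

    def __init__(self, gene_id: str, occurrences):
        self.occurrences = list(occurrences)
        locs = ", ".join(
            f"{c}:{s}-{e}({st})" for c, s, e, st in self.occurrences
        )
        super().__init__(
            f"gene {gene_id!r} occurs {len(self.occurrences)} times: {locs}; "
            "disambiguate with an explicit annotation"
        )


def normalize_sequence(seq: str) -> str:
    """Uppercase ``seq`` and reject non-IUPAC characters.

    Raises
    ------
    SequenceAlphabetError
        Naming the 1-based position of the first offending character.
    """
    s = seq.upper()
    if not set(s) <= IUPAC_ALPHABET:
        for i, ch in enumerate(s):
            if ch not in IUPAC_ALPHABET:
                raise SequenceAlphabetError(
                    f"invalid nucleotide {ch!r} at position {i + 1}"
                )
    return s


def reverse_complement(seq: str) -> str:
    """Base-paired reverse of ``seq``; ambiguity codes map to their IUPAC
    complements (N -> N, R -> Y, ...). Involution: applying twice returns
    the normalized input."""
    return normalize_sequence(seq).translate(_COMPLEMENT)[::-1]


def complement_base(base: str) -> str:
    return base.translate(_COMPLEMENT)


@dataclass
class GenomeRecord:
    """A named contig sequence; the search substrate."""

    contig_id: str
    sequence: str

    def __post_init__(self) -> None:
        self.sequence = normalize_sequence(self.sequence)

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class GeneAnnotation:
    """A located gene: contig, 1-based inclusive interval, strand, name."""

    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str = "unknown"
    product_label: str | None = None

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"{self.gene_id}: require 1 <= start <= end, "
                f"got {self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "unknown"):
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")

    @property
    def span(self) -> int:
        return self.end - self.start + 1


@dataclass
class SearchConfig:
    """Parameters of the inverted-repeat search.

    min_ir_len
        Shortest reported repeat (bp). Repeats at or above this length have
        been shown to support homologous recombination between hsdS copies.
    window
        Flank searched on each side of the gene (bp): 30 kb keeps partner
        repeats within a single Type I locus rather than a neighboring one.
    tile_stagger
        Seed tile spacing (bp); 1 guarantees completeness, larger values
        trade sensitivity for speed.
    repeat_sense
        "reverse-complement" matches biological inversions; "reverse"
        matches the plain reversed string (fidelity testing only).
    include_gene_body
        When true, each flank window additionally covers the gene interval
        itself (self-palindrome searching).
    max_report_len
        Optional ceiling on reported repeat length; hits longer than the cap
        are truncated (keeping their 5' gene end).
    legacy_strand
        Asymmetric historical mode: minus-strand genes are treated as if
        annotated on the plus strand (gene-local hit coordinates and flank
        sides stay in the plus frame instead of coding orientation).
    """

    min_ir_len: int = 20
    window: int = 30000
    tile_stagger: int = 1
    repeat_sense: str = "reverse-complement"
    include_gene_body: bool = False
    max_report_len: int | None = None
    legacy_strand: bool = False

    def __post_init__(self) -> None:
        if self.min_ir_len < 1:
            raise ValueError("min_ir_len must be >= 1")
        if self.window < 0:
            raise ValueError("window must be >= 0")
        if self.tile_stagger < 1:
            raise ValueError("tile_stagger must be >= 1")
        if self.repeat_sense not in ("reverse-complement", "reverse"):
            raise ValueError(f"bad repeat_sense {self.repeat_sense!r}")
        if self.max_report_len is not None and self.max_report_len < self.min_ir_len:
            raise ValueError("max_report_len must be >= min_ir_len")


def _find_all(haystack: str, needle: str) -> list[int]:
    """0-based start offsets of every (possibly overlapping) occurrence."""
    out: list[int] = []
    i = haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def locate_gene(
    gene_seq: str, genome: GenomeRecord, gene_id: str = "gene"
) -> GeneAnnotation:
    """Locate an exact occurrence of ``gene_seq`` in ``genome`` on either
    strand and return its annotation in coding orientation.

    Raises GeneNotFoundError for zero occurrences and AmbiguousLocationError
    (listing all occurrences) when the gene occurs more than once counting
    both strands; a palindromic gene occupying one interval counts once.
    """
    if not gene_seq:
        raise ValueError("gene_seq must be non-empty")
    g = normalize_sequence(gene_seq)
    n = len(g)
    occ: dict[tuple[int, int], str] = {}
    for i in _find_all(genome.sequence, g):
        occ[(i + 1, i + n)] = "+"
    for i in _find_all(genome.sequence, reverse_complement(g)):
        occ.setdefault((i + 1, i + n), "-")
    if not occ:
        raise GeneNotFoundError(f"gene {gene_id!r} not found in {genome.contig_id}")
    if len(occ) > 1:
        raise AmbiguousLocationError(
            gene_id,
            [(genome.contig_id, s, e, st) for (s, e), st in sorted(occ.items())],
        )
    (start, end), strand = next(iter(occ.items()))
    return GeneAnnotation(gene_id, genome.contig_id, start, end, strand)


def gene_sequence(genome: GenomeRecord, gene: GeneAnnotation) -> str:
    """Extract the gene in coding orientation (reverse-complemented for
    minus-strand genes). Unknown strand is treated as plus."""
    if gene.contig_id != genome.contig_id:
        raise KeyError(
            f"gene {gene.gene_id} is on contig {gene.contig_id!r}, "
            f"not {genome.contig_id!r}"
        )
    if gene.end > genome.length:
        raise ValueError(
            f"gene {gene.gene_id} extends past the end of {genome.contig_id}"
        )
    plus = genome.sequence[gene.start - 1 : gene.end]
    return reverse_complement(plus) if gene.strand == "-" else plus


def extract_window(
    genome: GenomeRecord, gene: GeneAnnotation, config: SearchConfig
) -> tuple[str, str, tuple[int, int]]:
    """Flank windows around a gene: ``(upstream_seq, downstream_seq,
    (upstream_offset, downstream_offset))``.

    ``upstream`` is the low-coordinate flank ``genome[start-window ..
    start-1]`` and ``downstream`` is ``genome[end+1 .. end+window]``, both
    clamped at contig boundaries (clamping is logged). Offsets are the
    1-based genome coordinate of each window's first base. With
    ``include_gene_body`` each window additionally covers the gene interval.
    """
    if gene.contig_id != genome.contig_id:
        raise KeyError(
            f"gene {gene.gene_id} is on contig {gene.contig_id!r}, "
            f"not {genome.contig_id!r}"
        )
    L = genome.length
    w = config.window
    u0 = max(0, gene.start - 1 - w)
    u1 = gene.end if config.include_gene_body else gene.start - 1
    d0 = gene.start - 1 if config.include_gene_body else gene.end
    d1 = min(L, gene.end + w)
    if u0 == 0 and gene.start - 1 - w < 0 and w > 0:
        log.info(
            "upstream window of %s clamped at start of %s (%d bp instead of %d)",
            gene.gene_id, genome.contig_id, u1 - u0, w,
        )
    if d1 == L and gene.end + w > L and w > 0:
        log.info(
            "downstream window of %s clamped at end of %s (%d bp instead of %d)",
            gene.gene_id, genome.contig_id, d1 - d0, w,
        )
    return (
        genome.sequence[u0:u1],
        genome.sequence[d0:d1],
        (u0 + 1, d0 + 1),
    )


def reflect_annotation(gene: GeneAnnotation, contig_len: int) -> GeneAnnotation:
    """Annotation coordinates after reverse-complementing the whole contig:
    start' = L - end + 1, end' = L - start + 1, strand flipped."""
    flipped = {"+": "-", "-": "+", "unknown": "unknown"}[gene.strand]
    return GeneAnnotation(
        gene.gene_id,
        gene.contig_id,
        contig_len - gene.end + 1,
        contig_len - gene.start + 1,
        flipped,
        gene.product_label,
    )
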