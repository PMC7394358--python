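"""Deterministic synthetic genomes carrying an inverting Type I
restriction-modification locus, with ground truth for every planted repeat.

The generator emulates the canonical locus architecture: hsdR - hsdM -
hsdS (expressed) - hsdS' (silent, on the opposite strand) - recombinase.
Each hsdS copy is start codon + spacer + leader IR + 5'-TRD + mid IR +
3'-TRD + stop; the silent copy carries alternative TRD variants between
byte-identical copies of the same two repeats and starts with GTG instead of
ATG. Background sequence is i.i.d. at the requested GC content, so planted
repeats are the only expected signals. Single-base breaks are enforced at
every repeat junction (spacer last base and TRD boundary bases differ between
copies), which makes the maximal-match coordinates of every planted repeat
exact by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .sequence import (
    GeneAnnotation,
    GenomeRecord,
    complement_base,
    reflect_annotation,
    reverse_complement,
)

_BASES = "ACGT"
_GAP = 60
_HSDR_LEN = 900
_HSDM_LEN = 600
_RECOMB_LEN = 600

DECOY_KINDS = ("below_min_len", "mismatched", "beyond_window", "direct_repeat")


class LocusSizingError(ValueError):
    """The requested locus (plus decoys) does not fit in the genome."""


@dataclass
class SimulationParams:
    """Generator configuration.

    Defaults model the repeats reported for the SpnD39III locus (leader and
    mid IRs of 85 and 33 bp), a specificity gene of about 650 bp, a 40-kb
    contig (large enough for the full 30-kb downstream window plus a
    beyond-window decoy), and GC 0.40.
    """

    seed: int
    genome_len: int = 40000
    gc: float = 0.40
    ir_lengths: tuple[int, int] = (85, 33)
    trd5_len: int = 270
    trd3_len: int = 250
    n_trd5_variants: int = 2
    n_trd3_variants: int = 2
    gene_strand: str = "+"
    decoys: tuple[str, ...] = ()
    intergene_gap: int = 120
    contig_id: str = "sim_contig"
    locus_start: int = 2000
    spacer_len: int = 9
    min_ir_len: int = 20
    window: int = 30000

    def __post_init__(self) -> None:
        if self.seed < 0:
            raise ValueError("seed must be >= 0")
        if not 0.0 < self.gc < 1.0:
            raise ValueError("gc must be in (0, 1)")
        for name in ("genome_len", "trd5_len", "trd3_len", "intergene_gap",
                     "spacer_len", "min_ir_len", "window"):
            if getattr(self, name) < 0 or (name.endswith("len") and getattr(self, name) < 1):
                raise ValueError(f"{name} must be positive")
        if any(l < 1 for l in self.ir_lengths):
            raise ValueError("ir_lengths must be positive")
        if self.n_trd5_variants < 1 or self.n_trd3_variants < 1:
            raise ValueError("variant counts must be >= 1")
        if self.gene_strand not in ("+", "-"):
            raise ValueError("gene_strand must be + or -")
        unknown = set(self.decoys) - set(DECOY_KINDS)
        if unknown:
            raise ValueError(f"unknown decoy kinds: {sorted(unknown)}")


@dataclass(frozen=True)
class IrTruthRecord:
    """One planted repeat (or decoy): gene-local and genome coordinates,
    1-based inclusive, in coding orientation of the expressed gene."""

    kind: str
    side: str
    gene_start: int
    gene_end: int
    partner_start: int
    partner_end: int
    length: int
    expected_detected: bool


@dataclass
class PlantedTruth:
    records: list[IrTruthRecord]
    annotations: list[GeneAnnotation]
    trd5_variants: list[str] = field(default_factory=list)
    trd3_variants: list[str] = field(default_factory=list)


def _rand_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    idx = rng.choice(4, size=n, p=p)
    return bytes(np.frombuffer(b"ACGT", dtype=np.uint8)[idx]).decode("ascii")


def _diff_base(rng: np.random.Generator, not_base: str) -> str:
    choices = [b for b in _BASES if b != not_base]
    return choices[int(rng.integers(0, 3))]


def _with_endpoints(
    rng: np.random.Generator,
    seq: str,
    not_first: str | None = None,
    not_last: str | None = None,
) -> str:
    s = list(seq)
    if not_first is not None and s[0] == not_first:
        s[0] = _diff_base(rng, not_first)
    if not_last is not None and s[-1] == not_last:
        s[-1] = _diff_base(rng, not_last)
    return "".join(s)


_SWAP = {"A": "C", "C": "A", "G": "T", "T": "G"}


def _break_flank(genome: bytearray, pos: int, forbidden: str | None) -> None:
    """Ensure genome[pos] cannot extend a planted match (differs from the
    single base that would pair with the next gene base)."""
    if forbidden is None or not 0 <= pos < len(genome):
        return
    if genome[pos : pos + 1].decode() == forbidden:
        genome[pos] = ord(_SWAP[forbidden])


def _segments(start_codon: str, spacer: str, leader: str, trd5: str,
              mid: str, trd3: str) -> list[tuple[str, str]]:
    return [
        ("start", start_codon),
        ("spacer", spacer),
        ("leader", leader),
        ("trd5", trd5),
        ("mid", mid),
        ("trd3", trd3),
        ("stop", "TAA"),
    ]


def _offsets(segs: list[tuple[str, str]]) -> list[int]:
    out, cur = [], 0
    for _, s in segs:
        out.append(cur)
        cur += len(s)
    return out


def simulate_genome(
    params: SimulationParams,
) -> tuple[GenomeRecord, list[GeneAnnotation], PlantedTruth]:
    """Generate a genome with a planted inverting Type I locus.

    Returns the contig, its gene annotations (hsdR, hsdM, expressed hsdS,
    silent hsdS' copies, recombinase), and the ground-truth table of every
    planted repeat and decoy. Identical seeds give byte-identical output.
    ``max(n_trd5_variants, n_trd3_variants) - 1`` silent copies are planted,
    cycling through the non-expressed variants; when one axis has a single
    variant the shared TRD merges adjacent repeats into one longer planted
    repeat, which the truth table records as such.
    """
    rng = np.random.default_rng(params.seed)
    leader_len, mid_len = params.ir_lengths
    leader = _rand_seq(rng, leader_len, params.gc)
    mid = _rand_seq(rng, mid_len, params.gc)

    n5, n3 = params.n_trd5_variants, params.n_trd3_variants
    trd5s = [_rand_seq(rng, params.trd5_len, params.gc)]
    for _ in range(n5 - 1):
        trd5s.append(
            _with_endpoints(rng, _rand_seq(rng, params.trd5_len, params.gc),
                            not_first=trd5s[0][0], not_last=trd5s[0][-1])
        )
    trd3s = [_rand_seq(rng, params.trd3_len, params.gc)]
    for _ in range(n3 - 1):
        trd3s.append(
            _with_endpoints(rng, _rand_seq(rng, params.trd3_len, params.gc),
                            not_first=trd3s[0][0])
        )

    sp_expr = _rand_seq(rng, params.spacer_len, params.gc)
    n_silent = max(n5, n3) - 1
    silent_defs = []
    for j in range(n_silent):
        sp_j = _with_endpoints(rng, _rand_seq(rng, params.spacer_len, params.gc),
                               not_last=sp_expr[-1])
        t5 = trd5s[1 + (j % (n5 - 1))] if n5 > 1 else trd5s[0]
        t3 = trd3s[1 + (j % (n3 - 1))] if n3 > 1 else trd3s[0]
        silent_defs.append(_segments("GTG", sp_j, leader, t5, mid, t3))

    expr_segs = _segments("ATG", sp_expr, leader, trd5s[0], mid, trd3s[0])
    gene_seq = "".join(s for _, s in expr_segs)
    gene_len = len(gene_seq)

    # -- layout on the canonical plus orientation -------------------------
    genome = bytearray(_rand_seq(rng, params.genome_len, params.gc), "ascii")

    def paste(pos: int, seq: str) -> None:
        genome[pos : pos + len(seq)] = seq.encode("ascii")

    if params.locus_start < 1:
        raise LocusSizingError("locus_start must leave room before hsdR")
    cur = params.locus_start
    layout: dict[str, tuple[int, int]] = {}  # name -> 0-based half-open
    for name, length in (("hsdR", _HSDR_LEN), ("hsdM", _HSDM_LEN)):
        layout[name] = (cur, cur + length)
        cur += length + _GAP
    gs0 = cur
    layout["hsdS"] = (gs0, gs0 + gene_len)
    cur = gs0 + gene_len + params.intergene_gap
    silent_spans: list[tuple[int, int]] = []
    for segs in silent_defs:
        m = sum(len(s) for _, s in segs)
        silent_spans.append((cur, cur + m))
        cur += m + _GAP
    layout["recombinase"] = (cur, cur + _RECOMB_LEN)
    cur += _RECOMB_LEN

    decoy_zone = cur + 400
    ge1 = gs0 + gene_len  # 1-based inclusive end of the expressed gene
    if cur >= params.genome_len - 1:
        raise LocusSizingError(
            f"locus ends at {cur} but genome_len is {params.genome_len}"
        )

    paste(gs0, gene_seq)
    for (s0, _), segs in zip(silent_spans, silent_defs):
        paste(s0, reverse_complement("".join(s for _, s in segs)))
    for name in ("hsdR", "hsdM", "recombinase"):
        a, b = layout[name]
        paste(a, "ATG" + _rand_seq(rng, b - a - 6, params.gc) + "TAA")

    # -- truth for the planted repeats (segment walk handles merged runs) --
    expr_off = _offsets(expr_segs)
    records: list[IrTruthRecord] = []
    for (s0, _), segs in zip(silent_spans, silent_defs):
        sil_off = _offsets(segs)
        M = sum(len(s) for _, s in segs)
        equal = [e[1] == s[1] for e, s in zip(expr_segs, segs)]
        i = 0
        while i < len(segs):
            if not equal[i]:
                i += 1
                continue
            j = i
            while j + 1 < len(segs) and equal[j + 1]:
                j += 1
            names = {segs[t][0] for t in range(i, j + 1)}
            if names & {"leader", "mid"}:
                g0 = expr_off[i]
                g1 = expr_off[j] + len(expr_segs[j][1])
                c0 = sil_off[i]
                c1 = sil_off[j] + len(segs[j][1])
                p0 = s0 + (M - c1)  # silent region holds the reverse complement
                p1 = s0 + (M - c0)
                length = g1 - g0
                kind = (
                    "leader_ir" if names == {"leader"}
                    else "mid_ir" if names == {"mid"}
                    else "merged_ir"
                )
                detected = (
                    length >= params.min_ir_len and p1 <= ge1 + params.window
                )
                records.append(IrTruthRecord(
                    kind, "downstream", g0 + 1, g1, p0 + 1, p1, length, detected,
                ))
            i = j + 1

    # -- decoys ------------------------------------------------------------
    trd5_off = expr_off[3]  # gene-local 0-based start of the expressed 5'-TRD
    src = 10
    place = decoy_zone
    k = params.min_ir_len
    for kind in params.decoys:
        if kind == "below_min_len":
            L = k - 1
        elif kind in ("mismatched", "beyond_window"):
            L = k + 4
        else:  # direct_repeat
            L = k + 20
        a0 = trd5_off + src
        src += L + 15
        if src > params.trd5_len:
            raise LocusSizingError("trd5_len too short to source the requested decoys")
        sub = gene_seq[a0 : a0 + L]
        if kind == "beyond_window":
            p = ge1 + params.window + 1000
        else:
            p = place
            place += L + 300
        if p + L + 1 > params.genome_len:
            raise LocusSizingError(
                f"decoy {kind} at {p} does not fit in genome_len {params.genome_len}"
            )
        if place > ge1 + params.window - 100:
            raise LocusSizingError("in-window decoys overflow the search window")
        if kind == "direct_repeat":
            paste(p, sub)
        else:
            d = list(reverse_complement(sub))
            if kind == "mismatched":
                c = L // 2
                d[c] = _diff_base(rng, d[c])
            paste(p, "".join(d))
            after = gene_seq[a0 + L] if a0 + L < gene_len else None
            before = gene_seq[a0 - 1] if a0 > 0 else None
            _break_flank(genome, p - 1, complement_base(after) if after else None)
            _break_flank(genome, p + L, complement_base(before) if before else None)
        records.append(IrTruthRecord(
            kind, "downstream", a0 + 1, a0 + L, p + 1, p + L, L, False,
        ))

    # -- annotations -------------------------------------------------------
    annotations = [
        GeneAnnotation("hsdR", params.contig_id, layout["hsdR"][0] + 1,
                       layout["hsdR"][1], "+", "hsdR"),
        GeneAnnotation("hsdM", params.contig_id, layout["hsdM"][0] + 1,
                       layout["hsdM"][1], "+", "hsdM"),
        GeneAnnotation("hsdS", params.contig_id, gs0 + 1, ge1, "+", "hsdS"),
    ]
    for idx, (s0, s1) in enumerate(silent_spans, start=1):
        annotations.append(GeneAnnotation(
            f"hsdS_prime_{idx}", params.contig_id, s0 + 1, s1, "-", "hsdS"
        ))
    annotations.append(GeneAnnotation(
        "recombinase", params.contig_id, layout["recombinase"][0] + 1,
        layout["recombinase"][1], "+", "recombinase/integrase",
    ))

    sequence = genome.decode("ascii")
    if params.gene_strand == "-":
        L = len(sequence)
        sequence = reverse_complement(sequence)
        annotations = [reflect_annotation(a, L) for a in annotations]
        records = [
            IrTruthRecord(
                r.kind, r.side, r.gene_start, r.gene_end,
                L - r.partner_end + 1, L - r.partner_start + 1,
                r.length, r.expected_detected,
            )
            for r in records
        ]

    record = GenomeRecord(params.contig_id, sequence)
    truth = PlantedTruth(
        records=records,
        annotations=list(annotations),
        trd5_variants=trd5s,
        trd3_variants=trd3s,
    )
    return record, annotations, truth


def write_fixture(
    genome: GenomeRecord,
    annotations: list[GeneAnnotation],
    truth: PlantedTruth,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write genome FASTA, annotation GFF3, and truth TSV into ``out_dir``;
    the files round-trip losslessly through the package readers."""
    from . import io as _io

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": out / "genome.fasta",
        "annotations": out / "annotations.gff3",
        "truth": out / "truth.tsv",
    }
    _io.write_genome_fasta([genome], paths["genome"])
    _io.write_gff3(annotations, paths["annotations"])
    _io.write_truth_tsv(truth.records, paths["truth"])
    return paths
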