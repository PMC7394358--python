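"""Maximal 100%-identity inverted-repeat detection between a gene and its
flanking windows.

The detector seeds on exact k-mer tiles (k = ``min_ir_len``) of the gene,
extends every seed to a maximal exact match against the reverse complement of
the window, and deduplicates runs per diagonal. Only unambiguous bases
(A/C/G/T) may participate in a match, so any candidate overlapping an N (or
other ambiguity code) fails the 100%-identity criterion by definition.

``brute_force_inverted_repeats`` is an independent oracle: it enumerates
maximal diagonal runs of the full match matrix and is used to certify the
seeded detector in tests.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .sequence import (
    GeneAnnotation,
    GenomeRecord,
    SearchConfig,
    UNAMBIGUOUS,
    extract_window,
    gene_sequence,
    normalize_sequence,
    reverse_complement,
)


@dataclass(frozen=True, order=True)
class InvertedRepeatHit:
    """One maximal inverted repeat between a gene and a partner region.

    ``gene_start``/``gene_end`` are 1-based inclusive positions within the
    gene in coding orientation. Partner coordinates are 1-based inclusive:
    window-local (``partner_contig`` None) straight out of
    ``find_inverted_repeats``, genome coordinates after ``scan_gene``.
    ``distance`` is the count of bases between the gene boundary and the
    nearest partner boundary (0 = abutting).
    """

    gene_id: str
    gene_start: int
    gene_end: int
    partner_contig: str | None
    partner_start: int
    partner_end: int
    length: int
    side: str | None = None
    distance: int | None = None


def tile_fragments(gene_seq: str, k: int, stagger: int = 1) -> list[tuple[int, str]]:
    """Tiled k-bp fragments of the gene at offsets 1, 1+stagger, ...
    (1-based); fragment i covers bases [offset, offset+k-1]."""
    if k < 1 or stagger < 1:
        raise ValueError("k and stagger must be >= 1")
    s = normalize_sequence(gene_seq)
    return [(i + 1, s[i : i + k]) for i in range(0, len(s) - k + 1, stagger)]


def _match(a: str, b: str) -> bool:
    return a == b and a in UNAMBIGUOUS


def _maximal_matches(
    a: str, b: str, min_len: int, stagger: int = 1
) -> set[tuple[int, int, int]]:
    """Maximal exact common substrings (unambiguous bases only) of length
    >= min_len between ``a`` and ``b``; returns 0-based ``(i, j, length)``
    start pairs. Seeds are k-mers of ``a`` at the given stagger."""
    k = min_len
    n, m = len(a), len(b)
    out: set[tuple[int, int, int]] = set()
    if n < k or m < k:
        return out
    seeds: dict[str, list[int]] = {}
    for i in range(0, n - k + 1, stagger):
        w = a[i : i + k]
        if set(w) <= UNAMBIGUOUS:
            seeds.setdefault(w, []).append(i)
    if not seeds:
        return out
    covered: dict[int, int] = {}  # diagonal -> exclusive end in b of last run
    for j in range(0, m - k + 1):
        positions = seeds.get(b[j : j + k])
        if not positions:
            continue
        for i in positions:
            d = j - i
            if covered.get(d, -1) >= j + k:
                continue  # seed lies inside an already-emitted run
            ii, jj = i, j
            while ii > 0 and jj > 0 and _match(a[ii - 1], b[jj - 1]):
                ii -= 1
                jj -= 1
            ie, je = i + k, j + k
            while ie < n and je < m and _match(a[ie], b[je]):
                ie += 1
                je += 1
            covered[d] = je
            out.add((ii, jj, ie - ii))
    return out


def _oriented(window_seq: str, sense: str) -> str:
    if sense == "reverse-complement":
        return reverse_complement(window_seq)
    return window_seq[::-1]


def _to_hits(
    matches: set[tuple[int, int, int]],
    window_len: int,
    config: SearchConfig,
    gene_id: str = "",
) -> list[InvertedRepeatHit]:
    """Map 0-based (gene, reversed-window) match starts to 1-based gene-local
    and window-local hit coordinates."""
    cap = config.max_report_len
    hits = []
    for i, j, L in matches:
        if cap is not None and L > cap:
            L = cap  # reproduce a bounded-scan length ceiling, keeping the 5' end
        p0 = window_len - j - L
        hits.append(
            InvertedRepeatHit(
                gene_id=gene_id,
                gene_start=i + 1,
                gene_end=i + L,
                partner_contig=None,
                partner_start=p0 + 1,
                partner_end=p0 + L,
                length=L,
            )
        )
    hits.sort(key=lambda h: (h.gene_start, h.partner_start))
    return hits


def find_inverted_repeats(
    gene_seq: str, window_seq: str, config: SearchConfig | None = None
) -> list[InvertedRepeatHit]:
    """All maximal exact matches of length >= ``config.min_ir_len`` between
    the gene and the reverse complement of the window (window-local partner
    coordinates), sorted by (gene_start, partner_start)."""
    config = config or SearchConfig()
    g = normalize_sequence(gene_seq)
    w = normalize_sequence(window_seq)
    matches = _maximal_matches(
        g, _oriented(w, config.repeat_sense), config.min_ir_len, config.tile_stagger
    )
    return _to_hits(matches, len(w), config)


_BRUTE_FORCE_CELL_LIMIT = 16_000_000


def brute_force_inverted_repeats(
    gene_seq: str,
    window_seq: str,
    min_len: int,
    repeat_sense: str = "reverse-complement",
) -> list[InvertedRepeatHit]:
    """Dynamic-programming oracle: maximal diagonal runs of the full
    gene x reverse-complement(window) match matrix, filtered to >= min_len.

    Refuses inputs beyond a fixed cell budget; this oracle exists to certify
    ``find_inverted_repeats`` on small instances, not to replace it.
    """
    g = normalize_sequence(gene_seq)
    w = normalize_sequence(window_seq)
    r = _oriented(w, repeat_sense)
    n, m = len(g), len(r)
    if n * m > _BRUTE_FORCE_CELL_LIMIT:
        raise ValueError(
            f"input too large for the brute-force oracle ({n}x{m} cells)"
        )
    matches: set[tuple[int, int, int]] = set()
    if n >= min_len and m >= min_len:
        ga = np.frombuffer(g.encode("ascii"), dtype=np.uint8)
        ra = np.frombuffer(r.encode("ascii"), dtype=np.uint8)
        valid = np.frombuffer(b"ACGT", dtype=np.uint8)
        gv = np.isin(ga, valid)
        rv = np.isin(ra, valid)
        M = (ga[:, None] == ra[None, :]) & gv[:, None] & rv[None, :]
        for off in range(-(n - 1), m):
            diag = np.diagonal(M, offset=off)
            if not diag.any():
                continue
            padded = np.concatenate(([0], diag.view(np.int8), [0]))
            edges = np.diff(padded)
            starts = np.flatnonzero(edges == 1)
            ends = np.flatnonzero(edges == -1)
            for s, e in zip(starts, ends):
                L = int(e - s)
                if L < min_len:
                    continue
                if off >= 0:
                    matches.add((int(s), int(s) + off, L))
                else:
                    matches.add((int(s) - off, int(s), L))
    cfg = SearchConfig(min_ir_len=min_len, repeat_sense=repeat_sense)
    return _to_hits(matches, len(w), cfg)


def _contains(outer: InvertedRepeatHit, inner: InvertedRepeatHit) -> bool:
    return (
        outer.side == inner.side
        and outer.partner_contig == inner.partner_contig
        and outer.gene_start <= inner.gene_start
        and inner.gene_end <= outer.gene_end
        and outer.partner_start <= inner.partner_start
        and inner.partner_end <= outer.partner_end
    )


def filter_redundant(hits: list[InvertedRepeatHit]) -> list[InvertedRepeatHit]:
    """Remove hits whose gene interval AND partner interval are both contained
    in those of a longer hit; exact duplicates collapse to one. The result is
    an antichain under simultaneous containment."""
    unique = sorted(set(hits), key=lambda h: (-h.length, h.gene_start, h.partner_start))
    kept: list[InvertedRepeatHit] = []
    for h in unique:
        if not any(_contains(k, h) for k in kept):
            kept.append(h)
    kept.sort(key=lambda h: (h.side or "", h.gene_start, h.partner_start))
    return kept


def scan_gene(
    genome: GenomeRecord, gene: GeneAnnotation, config: SearchConfig | None = None
) -> list[InvertedRepeatHit]:
    """Scan both flanks of an annotated gene for inverted repeats and return
    redundancy-filtered hits with genome partner coordinates.

    Inversion is a relation in the genome frame (one region's plus-strand
    text is the reverse complement of the other's) and is symmetric under
    the gene's reading direction, so matching always runs on the gene's
    plus-strand slice against the reverse-complemented window. Gene-local
    hit coordinates are then reported in coding orientation, and ``side``
    relative to coding orientation (for a minus-strand gene the
    low-coordinate flank is its downstream side). With
    ``config.legacy_strand`` a minus-strand gene is instead treated as if
    annotated on the plus strand: gene-local coordinates and sides stay in
    the plus frame (asymmetric historical mode).
    """
    config = config or SearchConfig()
    if gene.strand == "unknown":
        raise ValueError(
            f"gene {gene.gene_id} has unknown strand; resolve with locate_gene first"
        )
    plus_slice = genome.sequence[gene.start - 1 : gene.end]
    glen = len(plus_slice)
    flip_gene_frame = gene.strand == "-" and not config.legacy_strand
    left_seq, right_seq, (left_off, right_off) = extract_window(genome, gene, config)
    if flip_gene_frame:
        sides = (("downstream", left_seq, left_off), ("upstream", right_seq, right_off))
    else:
        sides = (("upstream", left_seq, left_off), ("downstream", right_seq, right_off))
    out: list[InvertedRepeatHit] = []
    for side, wseq, off in sides:
        for h in find_inverted_repeats(plus_slice, wseq, config):
            if flip_gene_frame:
                gs = glen - h.gene_end + 1
                ge = glen - h.gene_start + 1
            else:
                gs, ge = h.gene_start, h.gene_end
            ps = off + h.partner_start - 1
            pe = off + h.partner_end - 1
            if pe < gene.start:
                dist = gene.start - 1 - pe
            elif ps > gene.end:
                dist = ps - gene.end - 1
            else:
                dist = 0  # partner overlaps the gene body (include_gene_body)
            out.append(
                replace(
                    h,
                    gene_id=gene.gene_id,
                    gene_start=gs,
                    gene_end=ge,
                    partner_contig=genome.contig_id,
                    partner_start=ps,
                    partner_end=pe,
                    side=side,
                    distance=dist,
                )
            )
    return filter_redundant(out)
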