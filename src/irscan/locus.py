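"""Locus-level interpretation of inverted-repeat hits: collation of identical
genes, inverting/incidental classification, TRD segmentation, allele and
population-state enumeration, and survey summaries.

An "inverting" Type I locus carries a silent duplicate specificity gene
(hsdS') whose alternative target recognition domains (TRDs) are flanked by
the same inverted repeats as the expressed copy; recombination between the
repeats swaps TRDs and switches methyltransferase specificity.
"""

from __future__ import annotations

import logging
import math
import string
import warnings
from dataclasses import dataclass, field
from decimal import Decimal

from .search import InvertedRepeatHit, scan_gene
from .sequence import (
    GeneAnnotation,
    GenomeRecord,
    SearchConfig,
    gene_sequence,
    normalize_sequence,
    reverse_complement,
)

log = logging.getLogger("irscan")


class UnsegmentableLocusError(ValueError):
    """The gene cannot be split into two TRDs by the supplied IR intervals."""


@dataclass
class LocusCall:
    """Per-gene classification: inverting, incidental_ir, or no_ir."""

    gene_id: str
    category: str
    hits: list[InvertedRepeatHit] = field(default_factory=list)
    partner_gene_id: str | None = None
    partner_is_silent: bool | None = None


@dataclass
class TrdSegmentation:
    """Gene intervals (1-based inclusive) of the two IRs and the two TRDs."""

    leader_ir: tuple[int, int]
    mid_ir: tuple[int, int]
    trd5: tuple[int, int]
    trd3: tuple[int, int]

    def extract(self, gene_seq: str) -> tuple[str, str]:
        """(trd5, trd3) sequences of a gene in coding orientation."""
        s = normalize_sequence(gene_seq)
        return (
            s[self.trd5[0] - 1 : self.trd5[1]],
            s[self.trd3[0] - 1 : self.trd3[1]],
        )


@dataclass
class AlleleSpace:
    """Combinatorial space of hsdS alleles from independent TRD variant sets.

    Alleles are labeled A, B, C, ... in row-major order over (sorted 5'-TRD
    variants) x (sorted 3'-TRD variants).
    """

    n5: int
    n3: int
    alleles: list[tuple[str, int, int]]  # (label, trd5 index, trd3 index)

    @property
    def n_alleles(self) -> int:
        return self.n5 * self.n3


@dataclass
class CollationGroup:
    representative: str
    gene_ids: list[str]
    sequence: str


def collate_identical_genes(
    genes: list[tuple[str, str]]
) -> list[CollationGroup]:
    """Partition genes by exact sequence equality. A REBASE-style survey
    counts every annotated copy of a gene; collation reduces those to
    distinct loci. Representative = lexicographically smallest gene_id;
    groups are returned sorted by representative."""
    by_seq: dict[str, list[str]] = {}
    for gid, seq in genes:
        by_seq.setdefault(normalize_sequence(seq), []).append(gid)
    groups = [
        CollationGroup(min(ids), sorted(ids), seq) for seq, ids in by_seq.items()
    ]
    groups.sort(key=lambda g: g.representative)
    return groups


def _is_hsds(label: str | None) -> bool:
    return label is not None and "hsds" in label.lower()


def _first_codon(genome: GenomeRecord, ann: GeneAnnotation) -> str:
    if ann.strand == "-":
        return reverse_complement(genome.sequence[ann.end - 3 : ann.end])
    return genome.sequence[ann.start - 1 : ann.start + 2]


def classify_locus(
    gene: GeneAnnotation,
    hits: list[InvertedRepeatHit],
    annotations_in_window: list[GeneAnnotation],
    genome: GenomeRecord | None = None,
) -> LocusCall:
    """Classify a gene by where its inverted repeats land.

    inverting      at least one hit's partner interval overlaps (>= 1 bp) a
                   second annotation labeled hsdS;
    incidental_ir  hits exist but none lie in a second hsdS;
    no_ir          no hits at all.

    ``partner_is_silent`` is True when the partner's first codon in annotated
    orientation is not ATG (requires ``genome``; None otherwise — promoter
    presence is not assessed).
    """
    if not hits:
        return LocusCall(gene.gene_id, "no_ir")
    candidates = [
        a
        for a in annotations_in_window
        if a.gene_id != gene.gene_id and a.contig_id == gene.contig_id
    ]
    if candidates and all(a.product_label is None for a in candidates):
        log.warning(
            "no product labels on annotations near %s; cannot recognize a "
            "second hsdS, classification degrades to incidental_ir",
            gene.gene_id,
        )
    best: tuple[int, GeneAnnotation] | None = None
    for h in hits:
        for a in candidates:
            if not _is_hsds(a.product_label):
                continue
            if h.partner_contig == a.contig_id and not (
                h.partner_end < a.start or h.partner_start > a.end
            ):
                if best is None or h.length > best[0]:
                    best = (h.length, a)
    if best is None:
        return LocusCall(gene.gene_id, "incidental_ir", list(hits))
    partner = best[1]
    silent = None
    if genome is not None:
        silent = _first_codon(genome, partner) != "ATG"
    return LocusCall(gene.gene_id, "inverting", list(hits), partner.gene_id, silent)


def segment_trds(
    gene_seq: str,
    leader_ir: tuple[int, int],
    mid_ir: tuple[int, int],
) -> TrdSegmentation:
    """Split a gene into its two TRDs given the intervals of the repeat
    before the 5'-TRD and the repeat between the TRDs (1-based, gene-local).

    trd5 = (leader_ir end + 1 .. mid_ir start - 1);
    trd3 = (mid_ir end + 1 .. gene end).
    """
    n = len(gene_seq)
    ls, le = leader_ir
    ms, me = mid_ir
    if not (1 <= ls <= le < ms <= me <= n):
        raise UnsegmentableLocusError(
            f"unsegmentable locus: IR intervals {leader_ir} and {mid_ir} are "
            f"overlapping, out of order, or outside the gene (length {n})"
        )
    if ms - 1 < le + 1:
        raise UnsegmentableLocusError("unsegmentable locus: empty 5'-TRD")
    if n < me + 1:
        raise UnsegmentableLocusError("unsegmentable locus: empty 3'-TRD")
    return TrdSegmentation(
        leader_ir=(ls, le),
        mid_ir=(ms, me),
        trd5=(le + 1, ms - 1),
        trd3=(me + 1, n),
    )


def _labels(n: int) -> list[str]:
    letters = string.ascii_uppercase
    out = []
    for i in range(n):
        label = ""
        j = i
        while True:
            label = letters[j % 26] + label
            j = j // 26 - 1
            if j < 0:
                break
        out.append(label)
    return out


def enumerate_alleles(
    trd5_variants: set[str] | list[str], trd3_variants: set[str] | list[str]
) -> AlleleSpace:
    """All hsdS coding sequences reachable by pairing any 5'-TRD variant with
    any 3'-TRD variant: n_alleles = |trd5| x |trd3|. Variants are distinct by
    exact sequence identity."""
    v5 = sorted({normalize_sequence(s) for s in trd5_variants})
    v3 = sorted({normalize_sequence(s) for s in trd3_variants})
    if not v5 or not v3:
        raise ValueError("variant sets must be non-empty")
    labels = _labels(len(v5) * len(v3))
    alleles = [
        (labels[i * len(v3) + j], i, j)
        for i in range(len(v5))
        for j in range(len(v3))
    ]
    return AlleleSpace(n5=len(v5), n3=len(v3), alleles=alleles)


def combinatorial_states(num_biphasic_mod: int, num_hsds_alleles: int) -> int:
    """Distinct methyltransferase-activity combinations in a population:
    each biphasic (ON/OFF) mod gene switches independently and each cell
    carries exactly one hsdS allele, giving 2**mods x alleles states."""
    if num_biphasic_mod < 0:
        raise ValueError("num_biphasic_mod must be >= 0")
    if num_hsds_alleles < 1:
        raise ValueError("num_hsds_alleles must be >= 1")
    return (2 ** num_biphasic_mod) * num_hsds_alleles


def truncate_percent(x: float) -> float:
    """Truncate (floor) a percentage to one decimal. A 1e-6 guard on the
    tenths scale absorbs binary-float representation dust so that e.g.
    2.0 + 7.9 + 3.9 prints 13.8, while 100*875/22107 = 3.958... prints 3.9."""
    return math.floor(x * 10 + 1e-6) / 10


def format_percent(x: float) -> str:
    return f"{truncate_percent(x):.1f}"


@dataclass
class SurveySummary:
    total_genes: int
    genes_with_ir: int
    collated_with_ir: int
    inverting: int
    percent_inverting_raw: float
    percent_inverting: str
    species_rollup: list[str] = field(default_factory=list)

    def lines(self) -> list[str]:
        out = [
            f"total hsdS genes\t{self.total_genes}",
            f"genes with >=1 IR\t{self.genes_with_ir}",
            f"collated loci with >=1 IR\t{self.collated_with_ir}",
            f"inverting\t{self.inverting}",
            f"percent inverting\t{self.percent_inverting}%"
            f"\t(raw {self.percent_inverting_raw!r})",
        ]
        out.extend(self.species_rollup)
        return out


def summarize_survey(
    per_gene_calls: list[LocusCall],
    collation: list[CollationGroup] | None = None,
    species_by_gene: dict[str, str] | None = None,
) -> SurveySummary:
    """Survey totals: genes analyzed, genes with >= 1 IR, collated
    (distinct-sequence) loci with >= 1 IR, inverting count, and the inverting
    percentage of all genes, truncated to one decimal (raw float alongside).
    With ``species_by_gene``, adds "k of n strains" rollup rows counting
    strains whose gene is classified inverting."""
    total = len(per_gene_calls)
    with_ir = sum(1 for c in per_gene_calls if c.hits)
    inverting = sum(1 for c in per_gene_calls if c.category == "inverting")
    collated_with_ir = 0
    if collation:
        ir_genes = {c.gene_id for c in per_gene_calls if c.hits}
        collated_with_ir = sum(
            1 for g in collation if any(gid in ir_genes for gid in g.gene_ids)
        )
    raw = 100.0 * inverting / total if total else 0.0
    rollup: list[str] = []
    if species_by_gene:
        per_species: dict[str, list[LocusCall]] = {}
        for c in per_gene_calls:
            sp = species_by_gene.get(c.gene_id)
            if sp:
                per_species.setdefault(sp, []).append(c)
        for sp in sorted(per_species):
            calls = per_species[sp]
            k = sum(1 for c in calls if c.category == "inverting")
            rollup.append(f"{sp}\t{k} of {len(calls)} strains")
    return SurveySummary(
        total_genes=total,
        genes_with_ir=with_ir,
        collated_with_ir=collated_with_ir,
        inverting=inverting,
        percent_inverting_raw=raw,
        percent_inverting=format_percent(raw),
        species_rollup=rollup,
    )


def derive_alleles_from_locus(
    genome: GenomeRecord,
    gene: GeneAnnotation,
    annotations: list[GeneAnnotation],
    config: SearchConfig | None = None,
) -> tuple[TrdSegmentation, AlleleSpace, LocusCall]:
    """Scan an annotated hsdS gene, segment it into TRDs using the two
    repeats found in its silent partner(s), and enumerate the allele space
    from the expressed and silent TRD variants.

    The expressed gene must carry exactly two repeats per partner (one before
    the 5'-TRD, one between the TRDs); anything else is unsegmentable.
    """
    hits = scan_gene(genome, gene, config)
    call = classify_locus(gene, hits, annotations, genome)
    if call.category != "inverting":
        raise UnsegmentableLocusError(
            f"unsegmentable locus: {gene.gene_id} is {call.category}, not inverting"
        )
    expressed = gene_sequence(genome, gene)
    partners = [
        a
        for a in annotations
        if a.gene_id != gene.gene_id
        and a.contig_id == gene.contig_id
        and _is_hsds(a.product_label)
        and any(
            not (h.partner_end < a.start or h.partner_start > a.end) for h in hits
        )
    ]
    primary = next(a for a in partners if a.gene_id == call.partner_gene_id)
    in_primary = sorted(
        (
            h for h in hits
            if not (h.partner_end < primary.start or h.partner_start > primary.end)
        ),
        key=lambda h: h.gene_start,
    )
    if len(in_primary) != 2:
        raise UnsegmentableLocusError(
            f"unsegmentable locus: expected 2 repeats in {primary.gene_id}, "
            f"found {len(in_primary)}"
        )
    leader, midr = in_primary
    seg = segment_trds(
        expressed, (leader.gene_start, leader.gene_end), (midr.gene_start, midr.gene_end)
    )
    t5_expr, t3_expr = seg.extract(expressed)
    leader_seq = expressed[leader.gene_start - 1 : leader.gene_end]
    mid_seq = expressed[midr.gene_start - 1 : midr.gene_end]
    trd5_vars = {t5_expr}
    trd3_vars = {t3_expr}
    for partner in partners:
        silent = gene_sequence(genome, partner)
        l = silent.find(leader_seq)
        m = silent.find(mid_seq, l + len(leader_seq)) if l != -1 else -1
        if l == -1 or m == -1:
            log.warning(
                "partner %s lacks a copy of both repeats; skipped", partner.gene_id
            )
            continue
        trd5_vars.add(silent[l + len(leader_seq) : m])
        trd3_vars.add(silent[m + len(mid_seq) :])
    return seg, enumerate_alleles(trd5_vars, trd3_vars), call


def combined_phase_variable_percentage(percents: list[float]) -> float:
    """Arithmetic sum of disjoint mechanism percentages (e.g. SSR-driven hsdM
    and hsdS switching plus IR-driven inversion), one-decimal result. Sums via
    Decimal so one-decimal inputs add exactly; warns above 100 (overlapping
    categories)."""
    for p in percents:
        if not 0.0 <= p <= 100.0:
            raise ValueError(f"percentage out of range: {p}")
    total = float(sum(Decimal(repr(p)) for p in percents))
    if total > 100.0:
        warnings.warn(
            f"combined percentage {total} exceeds 100; categories overlap",
            stacklevel=2,
        )
    return truncate_percent(total)
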