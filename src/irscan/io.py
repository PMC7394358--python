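"""Readers and writers for the standard formats the scanner consumes and
emits: FASTA (genomes and gene dumps), GFF3 and TSV annotations, hit tables
(TSV / BED6), truth tables, and locus-call tables."""

from __future__ import annotations

import logging
from pathlib import Path

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .locus import LocusCall
from .search import InvertedRepeatHit
from .sequence import GeneAnnotation, GenomeRecord
from .simulate import IrTruthRecord

log = logging.getLogger("irscan")

ANNOTATION_TSV_COLUMNS = ["gene_id", "contig_id", "start", "end", "strand"]
HIT_TSV_COLUMNS = [
    "gene_id", "side", "gene_start", "gene_end",
    "partner_contig", "partner_start", "partner_end", "length", "distance",
]
TRUTH_TSV_COLUMNS = [
    "side", "gene_start", "gene_end", "partner_start", "partner_end",
    "length", "kind", "expected_detected",
]
CALL_TSV_COLUMNS = [
    "organism", "strain", "gene_id", "category", "n_hits", "max_ir_len",
    "partner_gene_id", "partner_is_silent",
]


# -- FASTA -------------------------------------------------------------------

def read_genome_fasta(path: str | Path) -> dict[str, GenomeRecord]:
    """Multi-record genome FASTA -> {contig_id: GenomeRecord} (uppercased)."""
    records: dict[str, GenomeRecord] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        records[rec.id] = GenomeRecord(rec.id, str(rec.seq))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def read_gene_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Gene FASTA (REBASE-style dump: first header token is the gene id) ->
    ordered (gene_id, sequence) pairs."""
    out = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
    if not out:
        raise ValueError(f"no FASTA records in {path}")
    return out


def write_genome_fasta(genomes: list[GenomeRecord], path: str | Path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(g.sequence), id=g.contig_id, description="") for g in genomes],
        str(path),
        "fasta",
    )


# -- annotations -------------------------------------------------------------

def read_gff3(path: str | Path) -> list[GeneAnnotation]:
    """GFF3 gene features -> annotations. Strand '.'/'?' maps to unknown;
    gene id from ID (or Name), product label from the product attribute."""
    db = gffutils.create_db(
        str(path), dbfn=":memory:", keep_order=True, merge_strategy="create_unique"
    )
    anns: list[GeneAnnotation] = []
    for feat in db.all_features():
        if feat.featuretype != "gene":
            continue
        gid = feat.attributes.get("ID", feat.attributes.get("Name", [feat.id]))[0]
        product = feat.attributes.get("product", [None])[0]
        strand = feat.strand if feat.strand in "+-" else "unknown"
        anns.append(GeneAnnotation(gid, feat.seqid, feat.start, feat.end, strand, product))
    return anns


def write_gff3(annotations: list[GeneAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for a in annotations:
            strand = a.strand if a.strand in "+-" else "."
            attrs = f"ID={a.gene_id}"
            if a.product_label:
                attrs += f";product={a.product_label}"
            fh.write(
                f"{a.contig_id}\tirscan\tgene\t{a.start}\t{a.end}\t.\t{strand}\t.\t{attrs}\n"
            )


def read_annotation_tsv(path: str | Path) -> list[GeneAnnotation]:
    """TSV dialect with header gene_id/contig_id/start/end/strand (REBASE
    dumps lack strand: blank means unknown). An optional product_label column
    is honored; extra columns are ignored."""
    df = pd.read_csv(path, sep="\t", dtype={"strand": "string"})
    missing = set(ANNOTATION_TSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"annotation TSV {path} lacks columns: {sorted(missing)}")
    anns = []
    for row in df.itertuples(index=False):
        strand = getattr(row, "strand")
        strand = strand if isinstance(strand, str) and strand in "+-" else "unknown"
        product = getattr(row, "product_label", None)
        product = product if isinstance(product, str) and product else None
        anns.append(GeneAnnotation(
            str(row.gene_id), str(row.contig_id), int(row.start), int(row.end),
            strand, product,
        ))
    return anns


def write_annotation_tsv(annotations: list[GeneAnnotation], path: str | Path) -> None:
    rows = [
        {
            "gene_id": a.gene_id, "contig_id": a.contig_id, "start": a.start,
            "end": a.end, "strand": a.strand if a.strand in "+-" else "",
            "product_label": a.product_label or "",
        }
        for a in annotations
    ]
    pd.DataFrame(rows, columns=ANNOTATION_TSV_COLUMNS + ["product_label"]).to_csv(
        path, sep="\t", index=False
    )


# -- hits --------------------------------------------------------------------

def write_hits_tsv(hits: list[InvertedRepeatHit], path: str | Path) -> None:
    rows = [
        {
            "gene_id": h.gene_id, "side": h.side or "",
            "gene_start": h.gene_start, "gene_end": h.gene_end,
            "partner_contig": h.partner_contig or "",
            "partner_start": h.partner_start, "partner_end": h.partner_end,
            "length": h.length, "distance": -1 if h.distance is None else h.distance,
        }
        for h in hits
    ]
    pd.DataFrame(rows, columns=HIT_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


def read_hits_tsv(path: str | Path) -> list[InvertedRepeatHit]:
    df = pd.read_csv(path, sep="\t")
    hits = []
    for row in df.itertuples(index=False):
        hits.append(InvertedRepeatHit(
            gene_id=str(row.gene_id),
            gene_start=int(row.gene_start), gene_end=int(row.gene_end),
            partner_contig=str(row.partner_contig) if not pd.isna(row.partner_contig) else None,
            partner_start=int(row.partner_start), partner_end=int(row.partner_end),
            length=int(row.length),
            side=str(row.side) if not pd.isna(row.side) else None,
            distance=None if int(row.distance) < 0 else int(row.distance),
        ))
    return hits


def write_hits_bed(hits: list[InvertedRepeatHit], path: str | Path) -> None:
    """Partner intervals as BED6 (0-based half-open); name = gene_id:index,
    score = repeat length, strand '-' marks the inverted orientation."""
    with open(path, "w") as fh:
        for i, h in enumerate(hits, start=1):
            fh.write(
                f"{h.partner_contig or '.'}\t{h.partner_start - 1}\t{h.partner_end}"
                f"\t{h.gene_id}:{i}\t{h.length}\t-\n"
            )


# -- truth -------------------------------------------------------------------

def write_truth_tsv(records: list[IrTruthRecord], path: str | Path) -> None:
    rows = [
        {
            "side": r.side, "gene_start": r.gene_start, "gene_end": r.gene_end,
            "partner_start": r.partner_start, "partner_end": r.partner_end,
            "length": r.length, "kind": r.kind,
            "expected_detected": str(r.expected_detected).lower(),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=TRUTH_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


def read_truth_tsv(path: str | Path) -> list[IrTruthRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        IrTruthRecord(
            kind=str(row.kind), side=str(row.side),
            gene_start=int(row.gene_start), gene_end=int(row.gene_end),
            partner_start=int(row.partner_start), partner_end=int(row.partner_end),
            length=int(row.length),
            expected_detected=str(row.expected_detected).lower() == "true",
        )
        for row in df.itertuples(index=False)
    ]


# -- locus calls ---------------------------------------------------------------

def write_calls_tsv(
    calls: list[LocusCall],
    path: str | Path,
    organism_by_gene: dict[str, str] | None = None,
    strain_by_gene: dict[str, str] | None = None,
) -> None:
    rows = []
    for c in calls:
        rows.append({
            "organism": (organism_by_gene or {}).get(c.gene_id, ""),
            "strain": (strain_by_gene or {}).get(c.gene_id, ""),
            "gene_id": c.gene_id,
            "category": c.category,
            "n_hits": len(c.hits),
            "max_ir_len": max((h.length for h in c.hits), default=0),
            "partner_gene_id": c.partner_gene_id or "",
            "partner_is_silent": "" if c.partner_is_silent is None
            else str(c.partner_is_silent).lower(),
        })
    pd.DataFrame(rows, columns=CALL_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


def read_calls_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", keep_default_na=False)
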