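"""Readers and writers for the external formats the pipeline touches.

FASTA goes through Biopython, GFF3 through gffutils, tabular data
through pandas. GFF3's 1-based closed coordinates are converted to the
internal 0-based half-open convention here and nowhere else.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .records import (
    CollinearityBlock,
    CollinearityFile,
    ExpressionMatrix,
    FamilyRecord,
    FamilyTable,
    GeneModel,
    ProteinRecord,
    RecordError,
)

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_family_table",
    "write_family_table",
    "read_collinearity",
    "read_ct_table",
]


def read_fasta(path) -> list[ProteinRecord]:
    """Read a protein FASTA file into a list of :class:`ProteinRecord`.

    Sequences are whitespace-stripped and uppercased. Duplicate ids and
    empty files are errors.
    """
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise RecordError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = "".join(str(rec.seq).split()).upper()
        records.append(ProteinRecord(rec.id, seq))
    if not records:
        raise RecordError(f"no FASTA records found in {path}")
    return records


def write_fasta(records, path) -> None:
    seqs = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    SeqIO.write(seqs, str(path), "fasta")


def _interval_0based(feature) -> tuple[int, int]:
    # GFF3 is 1-based closed; internal convention is 0-based half-open.
    return feature.start - 1, feature.end


def read_gff3(path) -> list[GeneModel]:
    """Read gene models from a GFF3 file.

    One mRNA per gene is expected; when several isoforms are annotated
    the one with the longest total CDS is taken as the representative.
    CDS intervals are returned in transcription order. A CDS whose
    total length is not a multiple of three is kept but flagged.
    """
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    models = []
    for gene in db.features_of_type("gene"):
        mrnas = list(db.children(gene, featuretype="mRNA"))
        if not mrnas:
            raise RecordError(f"gene {gene.id!r}: no mRNA child (missing parent links?)")
        best, best_cds = None, None
        for mrna in mrnas:
            cds = [_interval_0based(f) for f in db.children(mrna, featuretype="CDS")]
            if not cds:
                continue
            if best is None or sum(e - s for s, e in cds) > sum(
                e - s for s, e in best_cds
            ):
                best, best_cds = mrna, cds
        if best is None:
            raise RecordError(f"gene {gene.id!r}: no CDS features")
        exons = [_interval_0based(f) for f in db.children(best, featuretype="exon")]
        if not exons:
            exons = list(best_cds)
        reverse = gene.strand == "-"
        exons = sorted(exons, reverse=reverse)
        cds = sorted(best_cds, reverse=reverse)
        model = GeneModel(
            gene_id=gene.id,
            chromosome=gene.seqid,
            strand=gene.strand,
            exons=exons,
            cds=cds,
        )
        if "cds_length_not_multiple_of_3" in model.flags:
            warnings.warn(
                f"gene {gene.id!r}: CDS length {model.cds_length} is not a "
                "multiple of 3; record flagged"
            )
        models.append(model)
    return models


def write_gff3(models, path, sequences: dict[str, str] | None = None) -> None:
    """Write gene models as GFF3 (gene/mRNA/exon/CDS features)."""
    lines = ["##gff-version 3"]
    for m in models:
        exons_genomic = sorted(m.exons)
        cds_genomic = sorted(m.cds)
        g0, g1 = exons_genomic[0][0], exons_genomic[-1][1]
        attrs = f"ID={m.gene_id}"
        lines.append(
            f"{m.chromosome}\tbzipkit\tgene\t{g0 + 1}\t{g1}\t.\t{m.strand}\t.\t{attrs}"
        )
        mrna_id = f"{m.gene_id}.1"
        lines.append(
            f"{m.chromosome}\tbzipkit\tmRNA\t{g0 + 1}\t{g1}\t.\t{m.strand}\t.\t"
            f"ID={mrna_id};Parent={m.gene_id}"
        )
        for s, e in exons_genomic:
            lines.append(
                f"{m.chromosome}\tbzipkit\texon\t{s + 1}\t{e}\t.\t{m.strand}\t.\t"
                f"Parent={mrna_id}"
            )
        # GFF3 phase column: number of bases to remove to reach a codon start
        cds_tx = cds_genomic if m.strand == "+" else list(reversed(cds_genomic))
        phases = {}
        c = 0
        for s, e in cds_tx:
            phases[(s, e)] = (3 - c % 3) % 3
            c += e - s
        for s, e in cds_genomic:
            lines.append(
                f"{m.chromosome}\tbzipkit\tCDS\t{s + 1}\t{e}\t.\t{m.strand}\t"
                f"{phases[(s, e)]}\tParent={mrna_id}"
            )
    Path(path).write_text("\n".join(lines) + "\n")
    if sequences:
        fasta_path = Path(path).with_suffix(".fa")
        with open(fasta_path, "w") as fh:
            for name, seq in sequences.items():
                fh.write(f">{name}\n{seq}\n")


def read_expression_matrix(path, log2_transform: bool = False) -> ExpressionMatrix:
    """Read a genes x samples TSV (first column gene ids, header samples).

    Values are assumed to be already log2-scaled; set ``log2_transform``
    when the file holds linear intensities.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.isnull().any() or any(
        str(c).startswith("Unnamed") for c in df.columns
    ):
        raise RecordError(f"{path}: missing gene id or sample header cell")
    for col in df.columns:
        bad = df[col][pd.to_numeric(df[col], errors="coerce").isnull()]
        if len(bad):
            raise RecordError(
                f"{path}: non-numeric value {bad.iloc[0]!r} at "
                f"gene {bad.index[0]!r}, sample {col!r}"
            )
    df = df.astype(float)
    if log2_transform:
        import numpy as np

        df = np.log2(df)
    return ExpressionMatrix.from_frame(df)


def write_expression_matrix(matrix: ExpressionMatrix, path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index_label="gene_id")


_FAMILY_COLUMNS = [
    "gene_id",
    "gene_accession",
    "group",
    "chromosome",
    "start",
    "end",
    "strand",
    "protein_length",
    "intron_count",
    "pattern",
    "ortholog_ids",
]


def read_family_table(path) -> FamilyTable:
    """Read a family member table from TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = set(_FAMILY_COLUMNS) - set(df.columns)
    if missing:
        raise RecordError(f"{path}: missing family table columns {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        orth = tuple(t for t in str(row["ortholog_ids"]).split(",") if t)
        records.append(
            FamilyRecord(
                gene_id=row["gene_id"],
                gene_accession=row["gene_accession"],
                group=row["group"],
                chromosome=row["chromosome"],
                start=int(row["start"]),
                end=int(row["end"]),
                strand=row["strand"],
                protein_length=int(row["protein_length"]),
                intron_count=int(row["intron_count"]),
                pattern=row["pattern"],
                ortholog_ids=orth,
            )
        )
    return FamilyTable(records)


def write_family_table(table: FamilyTable, path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)


def read_collinearity(path) -> CollinearityFile:
    """Parse an MCScanX-style .collinearity file.

    Block headers start with ``## Alignment``; anchor lines carry two
    gene ids (and optionally an e-value) after a ``<block>-<anchor>:``
    prefix. Other ``#`` lines are ignored.
    """
    blocks: list[CollinearityBlock] = []
    current: CollinearityBlock | None = None
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("## Alignment"):
            body = line[len("## Alignment") :].strip()
            block_id = body.split(":")[0].strip() or str(len(blocks))
            chroms = None
            for tok in body.split():
                if "&" in tok:
                    a, _, b = tok.partition("&")
                    chroms = (a, b)
            current = CollinearityBlock(block_id, [], chroms)
            blocks.append(current)
        elif line.startswith("#"):
            continue
        else:
            if current is None:
                raise RecordError(f"{path}: anchor line before any '## Alignment' header")
            fields = line.split(":", 1)[-1].split()
            if len(fields) < 2:
                raise RecordError(f"{path}: cannot parse anchor line {raw!r}")
            current.anchors.append((fields[0], fields[1]))
    return CollinearityFile(blocks)


def read_ct_table(path) -> pd.DataFrame:
    """Read a qRT-PCR Ct table.

    Expected TSV columns: gene_id, condition, bio_rep, tech_rep,
    ct_target, ct_reference.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "condition", "ct_target", "ct_reference"}
    missing = required - set(df.columns)
    if missing:
        raise RecordError(f"{path}: missing Ct table columns {sorted(missing)}")
    for col in ("bio_rep", "tech_rep"):
        if col not in df.columns:
            df[col] = 1
    if not ((df["ct_target"] > 0) & (df["ct_reference"] > 0)).all():
        raise RecordError(f"{path}: Ct values must be positive")
    return df
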