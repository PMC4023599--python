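"""Core record types shared across the pipeline.

All genomic coordinates are held internally as 0-based half-open
intervals; conversion from the 1-based closed GFF3 convention happens
only at the I/O boundary (:mod:`bzipkit.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
#: residues accepted in protein sequences (X = unknown)
PROTEIN_ALPHABET = AMINO_ACIDS | {"X"}

VALID_GROUPS = set("ABCDEFGHIJ") | {"UC"}
VALID_PATTERNS = set("abcdefghi")


class RecordError(ValueError):
    """Raised when an input record violates a type invariant."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with a unique identifier."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise RecordError("protein record requires a non-empty id")
        if not self.sequence:
            raise RecordError(f"protein {self.id!r}: empty sequence")
        bad = set(self.sequence) - PROTEIN_ALPHABET
        if bad:
            raise RecordError(
                f"protein {self.id!r}: invalid residues {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GeneModel:
    """A gene model: chromosome, strand and exon/CDS intervals.

    ``exons`` and ``cds`` are lists of (start, end) tuples, 0-based
    half-open in genome coordinates, sorted 5'->3' in *transcription*
    order (descending genomic coordinate on the minus strand).
    """

    gene_id: str
    chromosome: str
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]]
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise RecordError(f"gene {self.gene_id!r}: strand must be + or -")
        for name, ivals in (("exons", self.exons), ("cds", self.cds)):
            for s, e in ivals:
                if s >= e:
                    raise RecordError(
                        f"gene {self.gene_id!r}: empty {name} interval ({s}, {e})"
                    )
            ordered = sorted(ivals) if self.strand == "+" else sorted(ivals, reverse=True)
            if list(ivals) != ordered:
                raise RecordError(
                    f"gene {self.gene_id!r}: {name} not in transcription order"
                )
            genomic = sorted(ivals)
            for (s1, e1), (s2, e2) in zip(genomic, genomic[1:]):
                if s2 < e1:
                    raise RecordError(
                        f"gene {self.gene_id!r}: overlapping {name} intervals"
                    )
        if self.cds_length % 3 != 0 and "cds_length_not_multiple_of_3" not in self.flags:
            self.flags.append("cds_length_not_multiple_of_3")

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)

    @property
    def n_introns(self) -> int:
        """Number of introns interrupting the CDS."""
        return max(len(self.cds) - 1, 0)

    @property
    def start(self) -> int:
        return min(s for s, _ in self.exons or self.cds)

    @property
    def end(self) -> int:
        return max(e for _, e in self.exons or self.cds)


@dataclass(frozen=True)
class FamilyRecord:
    """One family member: identity, phylogenetic group, locus and structure."""

    gene_id: str
    gene_accession: str
    group: str
    chromosome: str
    start: int
    end: int
    strand: str
    protein_length: int
    intron_count: int
    pattern: str
    ortholog_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.group not in VALID_GROUPS:
            raise RecordError(f"{self.gene_id!r}: unknown group {self.group!r}")
        if self.pattern not in VALID_PATTERNS:
            raise RecordError(f"{self.gene_id!r}: unknown pattern {self.pattern!r}")
        if not self.start < self.end:
            raise RecordError(f"{self.gene_id!r}: start must precede end")
        if self.strand not in {"+", "-"}:
            raise RecordError(f"{self.gene_id!r}: strand must be + or -")


class FamilyTable:
    """An ordered collection of :class:`FamilyRecord` with unique gene ids."""

    def __init__(self, records: list[FamilyRecord]):
        ids = [r.gene_id for r in records]
        dupes = {g for g in ids if ids.count(g) > 1}
        if dupes:
            raise RecordError(f"duplicate gene ids in family table: {sorted(dupes)}")
        self.records = list(records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, gene_id: str) -> FamilyRecord:
        for r in self.records:
            if r.gene_id == gene_id:
                return r
        raise KeyError(gene_id)

    def gene_ids(self) -> list[str]:
        return [r.gene_id for r in self.records]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            d = r.__dict__.copy()
            d["ortholog_ids"] = ",".join(r.ortholog_ids)
            rows.append(d)
        return pd.DataFrame(rows)


class ExpressionMatrix:
    """Genes x samples matrix of log2 fluorescence intensities."""

    def __init__(self, gene_ids, sample_ids, values):
        values = np.asarray(values, dtype=float)
        gene_ids = list(gene_ids)
        sample_ids = list(sample_ids)
        if len(set(gene_ids)) != len(gene_ids):
            raise RecordError("duplicate gene ids in expression matrix")
        if len(set(sample_ids)) != len(sample_ids):
            raise RecordError("duplicate sample ids in expression matrix")
        if values.shape != (len(gene_ids), len(sample_ids)):
            raise RecordError(
                f"matrix shape {values.shape} does not match "
                f"{len(gene_ids)} genes x {len(sample_ids)} samples"
            )
        self.gene_ids = gene_ids
        self.sample_ids = sample_ids
        self.values = values

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def row(self, gene_id: str) -> np.ndarray:
        return self.values[self.gene_ids.index(gene_id)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float))


@dataclass
class CollinearityBlock:
    """One homologous block: a list of anchored gene pairs."""

    block_id: str
    anchors: list[tuple[str, str]]
    chromosomes: tuple[str, str] | None = None


@dataclass
class CollinearityFile:
    """Parsed MCScanX-style collinearity output."""

    blocks: list[CollinearityBlock]

    def all_anchors(self) -> list[tuple[str, str]]:
        return [a for b in self.blocks for a in b.anchors]
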