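"""Chromosome distribution, tandem arrays and collinearity summaries."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx

from .records import CollinearityFile, FamilyTable, RecordError

#: chromosome labels treated as unplaced scaffolds rather than linkage groups
UNPLACED_SUFFIX = "_random"
UNPLACED_LABELS = {"Un", "un", "chrUn"}

DEFAULT_CHROMOSOME_UNIVERSE = tuple(str(i) for i in range(1, 20))


@dataclass
class DistributionSummary:
    """Per-chromosome gene counts over a supplied chromosome universe."""

    counts: dict[str, int]
    percentages: dict[str, float]  # of mapped genes, 2 decimals
    empty_chromosomes: list[str]
    unmapped: int
    mapped_total: int

    @property
    def total(self) -> int:
        return sum(self.counts.values()) + self.unmapped


def _is_unplaced(label: str) -> bool:
    return label in UNPLACED_LABELS or label.endswith(UNPLACED_SUFFIX)


def chromosome_distribution(
    table: FamilyTable, universe: tuple[str, ...] = DEFAULT_CHROMOSOME_UNIVERSE
) -> DistributionSummary:
    """Count family genes per chromosome.

    Genes on unplaced scaffolds (``*_random``, ``Un``) are counted as
    unmapped; percentages use the mapped total as denominator. Labels
    outside the universe are counted under their literal label with a
    warning.
    """
    counts = {c: 0 for c in universe}
    unmapped = 0
    for rec in table:
        chrom = rec.chromosome
        if _is_unplaced(chrom):
            unmapped += 1
        elif chrom in counts:
            counts[chrom] += 1
        else:
            warnings.warn(
                f"gene {rec.gene_id!r}: chromosome label {chrom!r} outside the "
                "supplied universe; counted under its literal label"
            )
            counts[chrom] = counts.get(chrom, 0) + 1
    mapped_total = sum(counts.values())
    percentages = {
        c: round(100.0 * n / mapped_total, 2) if mapped_total else 0.0
        for c, n in counts.items()
    }
    empty = [c for c in universe if counts[c] == 0]
    return DistributionSummary(counts, percentages, empty, unmapped, mapped_total)


@dataclass
class TandemArray:
    """A maximal run of homologous family genes clustered on one chromosome."""

    chromosome: str
    gene_ids: list[str]


def detect_tandem(
    table: FamilyTable,
    homolog_pairs: set[tuple[str, str]],
    max_intervening: int | None = None,
    max_span: int = 100_000,
) -> list[TandemArray]:
    """Find tandem arrays of homologous family genes.

    Two homologs count as tandem-arranged when they sit on the same
    chromosome within ``max_span`` bp (start-to-start) and, if
    ``max_intervening`` is given, with at most that many other family
    genes between them. Qualifying pairs are merged transitively into
    maximal arrays.
    """
    ids = set(table.gene_ids())
    for a, b in homolog_pairs:
        if a not in ids or b not in ids:
            raise RecordError(f"homolog pair ({a!r}, {b!r}) references unknown gene")
    pairs = {frozenset(p) for p in homolog_pairs if p[0] != p[1]}
    by_chrom: dict[str, list] = {}
    for rec in table:
        by_chrom.setdefault(rec.chromosome, []).append(rec)
    g = nx.Graph()
    for chrom, recs in by_chrom.items():
        recs = sorted(recs, key=lambda r: r.start)
        for i, a in enumerate(recs):
            for j in range(i + 1, len(recs)):
                b = recs[j]
                if frozenset((a.gene_id, b.gene_id)) not in pairs:
                    continue
                if abs(b.start - a.start) > max_span:
                    continue
                if max_intervening is not None and j - i - 1 > max_intervening:
                    continue
                g.add_edge(a.gene_id, b.gene_id)
    arrays = []
    for comp in nx.connected_components(g):
        members = sorted(comp, key=lambda gid: table[gid].start)
        arrays.append(TandemArray(table[members[0]].chromosome, members))
    arrays.sort(key=lambda t: (t.chromosome, t.gene_ids))
    return arrays


@dataclass
class CollinearitySummary:
    """Family-restricted view of a collinearity file."""

    family_anchors: list[tuple[str, str]]
    family_blocks: list[str]  # block ids containing >=1 family anchor
    components: list[frozenset[str]] = field(default_factory=list)

    @property
    def n_blocks(self) -> int:
        return len(self.family_blocks)

    @property
    def pairs(self) -> list[frozenset[str]]:
        return [c for c in self.components if len(c) == 2]

    @property
    def triplets(self) -> list[frozenset[str]]:
        return [c for c in self.components if len(c) == 3]


def summarize_collinearity(
    coll: CollinearityFile, table: FamilyTable
) -> CollinearitySummary:
    """Restrict collinearity anchors to family members and summarize.

    Blocks are counted once if they contain at least one family-family
    anchor; connected components of the family homology graph expose
    duplicate pairs and triplets.
    """
    ids = set(table.gene_ids())
    anchors = []
    block_ids = []
    g = nx.Graph()
    for block in coll.blocks:
        hit = False
        for a, b in block.anchors:
            if a in ids and b in ids:
                anchors.append((a, b))
                g.add_edge(a, b)
                hit = True
        if hit:
            block_ids.append(block.block_id)
    components = sorted(
        (frozenset(c) for c in nx.connected_components(g)), key=lambda c: sorted(c)
    )
    return CollinearitySummary(anchors, block_ids, components)
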