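"""Synthetic inputs with planted ground truth, plus the packaged family table.

Every generator is bit-reproducible given its configuration and seed,
and its truth object predicts the pipeline output deterministically at
zero noise: proteins obeying the bZIP grammar with planted heptad
counts and substitutions, gene models with planted intron subregions
and phases, expression matrices with planted correlated blocks, and
qRT-PCR Ct tables with planted fold changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .grammar import (
    ZIPPER_RESIDUES,
    BzipDomainAnnotation,
    GrammarParams,
    annotate_bzip_domain,
)
from .records import (
    ExpressionMatrix,
    FamilyRecord,
    FamilyTable,
    GeneModel,
    ProteinRecord,
)

#: filler residues used inside the domain frame: everything that can
#: neither seed an anchor (N, R, K) nor read as a heptad repeat (LIVFM)
DOMAIN_FILLER = sorted(set("ACDEFGHIKLMNPQRSTVWY") - set("NRK") - ZIPPER_RESIDUES)
ALL_RESIDUES = sorted("ACDEFGHIKLMNPQRSTVWY")

#: one codon per amino acid for deterministic reverse translation
CODON_OF = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT",
    "M": "ATG", "N": "AAT", "P": "CCT", "Q": "CAA", "R": "CGT",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class ProteinTruth:
    """Planted structure of a generated bZIP protein."""

    protein_id: str
    group: str | None
    asn_index: int
    heptad_count: int
    substitutions: dict[int, str]  # frame position -> planted residue


def gen_bzip_protein(
    heptads: int,
    substitutions: dict[int, str] | None = None,
    group: str | None = None,
    seed: int = 0,
    protein_id: str | None = None,
) -> tuple[ProteinRecord, ProteinTruth]:
    """Generate a protein obeying the bZIP grammar with planted truth.

    The domain carries Asn at -18, Arg at -10 (unless substituted) and
    Leu at every heptad repeat position (unless substituted). Filler
    inside the domain frame avoids anchor and repeat residues so the
    planted anchor is the only one; flanking sequence outside the
    domain is uniform over all twenty residues, re-drawn in the rare
    case it creates a competing anchor.
    """
    if not 3 <= heptads <= 11:
        raise ValueError("heptads must lie in [3, 11]")
    substitutions = dict(substitutions or {})
    if -18 in substitutions:
        raise ValueError("the -18 Asn anchor cannot be substituted")
    if -10 in substitutions and substitutions[-10] not in {"R", "K"}:
        raise ValueError(
            "only R/K are accepted at -10 under the strict grammar; use the "
            "relaxed_basic annotation setting for other residues"
        )
    rng = np.random.default_rng(seed)
    pid = protein_id or f"syn{seed}"

    def filler(n: int) -> str:
        return "".join(rng.choice(DOMAIN_FILLER, size=n))

    domain = ["N", filler(7), substitutions.get(-10, "R"), filler(9)]
    for h in range(heptads):
        pos = 1 + 7 * h
        domain.append(substitutions.get(pos, "L"))
        if h < heptads - 1:
            domain.append(filler(6))
    core = "".join(domain)
    params = GrammarParams()
    # the planted count is checkable only when substituted repeat residues
    # still read as repeats under the grammar
    count_checkable = all(
        aa in ZIPPER_RESIDUES for pos, aa in substitutions.items() if pos > 0
    )
    for _ in range(100):
        n_term = "".join(rng.choice(ALL_RESIDUES, size=int(rng.integers(5, 31))))
        c_term = list(rng.choice(ALL_RESIDUES, size=int(rng.integers(25, 41))))
        # terminate the zipper: the next heptad-spaced positions after the
        # last planted repeat must not read as (tolerated) repeats
        for k in range(1, params.max_interruptions + 2):
            idx = 7 * k - 1
            if idx < len(c_term):
                c_term[idx] = rng.choice(DOMAIN_FILLER)
        seq = n_term + core + "".join(c_term)
        ann = annotate_bzip_domain(ProteinRecord(pid, seq), params)
        if (
            ann is not None
            and ann.asn_index == len(n_term)
            and (not count_checkable or ann.heptad_count == heptads)
        ):
            record = ProteinRecord(pid, seq)
            truth = ProteinTruth(pid, group, len(n_term), heptads, substitutions)
            return record, truth
    raise RuntimeError("could not place the domain free of competing anchors")


@dataclass(frozen=True)
class IntronPlan:
    """One planted intron: junction codon and splicing phase.

    The junction codon may be given directly (``codon_offset``), as a
    domain-frame position, or as a subregion name resolved to a default
    codon inside that subregion. ``flanks`` forces the two protein
    residues around a phase-0 junction.
    """

    phase: int
    subregion: str | None = None
    frame_position: int | None = None
    codon_offset: int | None = None
    flanks: tuple[str, str] | None = None


@dataclass
class GeneTruth:
    """Planted structure of a generated gene model."""

    gene_id: str
    introns: list[tuple[str, int, int]]  # (subregion, frame_position, phase)
    expected_pattern: str | None
    strand: str


def _resolve_codon(plan: IntronPlan, ann: BzipDomainAnnotation) -> int:
    if plan.codon_offset is not None:
        return plan.codon_offset
    if plan.frame_position is not None:
        return ann.index_of(plan.frame_position)
    defaults = {
        "basic": ann.asn_index + 4,
        "hinge": ann.basic_residue_index + 5,
        "zipper": ann.zipper_start_index + 3,
    }
    if plan.subregion not in defaults:
        raise ValueError(f"cannot resolve intron plan {plan}")
    return defaults[plan.subregion]


def gen_bzip_gene(
    protein: ProteinRecord,
    intron_plan: list[IntronPlan],
    seed: int = 0,
    strand: str = "+",
    chromosome: str = "chrS",
    expected_pattern: str | None = None,
    annotation: BzipDomainAnnotation | None = None,
) -> tuple[GeneModel, dict[str, str], ProteinRecord, GeneTruth]:
    """Build a gene model whose CDS translates to ``protein`` with
    planted introns.

    Each plan entry lands the intron at the requested codon boundary or
    offset with the requested phase; both strands are supported (the
    minus strand emits a reverse-complemented contig). Returns the
    model, a {chromosome: sequence} contig dict, the (possibly
    flank-adjusted) protein, and the planted truth.
    """
    rng = np.random.default_rng(seed)
    ann = annotation or annotate_bzip_domain(protein)
    if ann is None:
        raise ValueError(f"protein {protein.id!r} carries no detectable domain")
    seq = list(protein.sequence)
    cuts = []
    for plan in intron_plan:
        if plan.phase not in {0, 1, 2}:
            raise ValueError(f"invalid phase {plan.phase}")
        r = _resolve_codon(plan, ann)
        if plan.flanks is not None:
            before, after = plan.flanks
            if plan.phase == 0 and r >= 1:
                seq[r - 1] = before
            seq[r] = after
        cuts.append((3 * r + plan.phase, r, plan))
    protein = ProteinRecord(protein.id, "".join(seq))
    ann = annotate_bzip_domain(protein) or ann
    cds_nt = "".join(CODON_OF[aa] for aa in protein.sequence) + "TAA"
    codons_used = {r for _, r, _ in cuts}
    if len(codons_used) != len(cuts):
        raise ValueError("two introns planted in one codon")
    cuts.sort()
    for c, _, _ in cuts:
        if not 0 < c < len(cds_nt):
            raise ValueError(f"intron position {c} outside the CDS")
    # split CDS at the cut points and interleave random GT..AG introns
    pieces, prev = [], 0
    for c, _, _ in cuts:
        pieces.append(cds_nt[prev:c])
        prev = c
    pieces.append(cds_nt[prev:])
    introns = [
        "GT" + "".join(rng.choice(list("ACGT"), size=int(rng.integers(76, 196)))) + "AG"
        for _ in cuts
    ]
    left = "".join(rng.choice(list("ACGT"), size=int(rng.integers(50, 151))))
    right = "".join(rng.choice(list("ACGT"), size=int(rng.integers(50, 151))))
    contig, pos = [left], len(left)
    exon_ivals = []
    for i, piece in enumerate(pieces):
        exon_ivals.append((pos, pos + len(piece)))
        contig.append(piece)
        pos += len(piece)
        if i < len(introns):
            contig.append(introns[i])
            pos += len(introns[i])
    contig.append(right)
    forward = "".join(contig)
    if strand == "+":
        genome = forward
        ivals = exon_ivals
    else:
        genome = _revcomp(forward)
        n = len(forward)
        ivals = [(n - e, n - s) for s, e in exon_ivals]  # descending = tx order
    model = GeneModel(
        gene_id=protein.id,
        chromosome=chromosome,
        strand=strand,
        exons=list(ivals),
        cds=list(ivals),
    )
    truth = GeneTruth(
        gene_id=model.gene_id,
        introns=[
            (
                "basic"
                if r <= ann.basic_residue_index
                else ("hinge" if r < ann.zipper_start_index else "zipper"),
                ann.frame_position(r),
                plan.phase,
            )
            for _, r, plan in sorted(cuts)
            if ann.asn_index <= r < ann.zipper_span[1]
        ],
        expected_pattern=expected_pattern,
        strand=strand,
    )
    return model, {chromosome: genome}, protein, truth


def pattern_intron_plan(pattern: str, ann: BzipDomainAnnotation) -> list[IntronPlan]:
    """Intron plan realizing one of the nine structural patterns a-i."""
    z = ann.zipper_start_index
    plans = {
        "a": [IntronPlan(0, codon_offset=z + 3, flanks=("Q", "A"))],
        "b": [
            IntronPlan(0, codon_offset=ann.asn_index + 4),
            IntronPlan(0, codon_offset=ann.basic_residue_index + 5),
        ],
        "c": [IntronPlan(2, subregion="basic"), IntronPlan(0, codon_offset=z + 2)],
        "d": [IntronPlan(2, subregion="basic"), IntronPlan(0, codon_offset=z + 8)],
        "e": [IntronPlan(2, subregion="basic"), IntronPlan(0, codon_offset=z + 14)],
        "f": [IntronPlan(2, subregion="basic")],
        "g": [IntronPlan(1, subregion="basic")],
        "h": [IntronPlan(0, codon_offset=z + 3, flanks=("D", "E"))],
        "i": (
            [IntronPlan(0, codon_offset=2)] if ann.asn_index >= 3 else []
        ),  # an intron outside the domain must not affect the call
    }
    if pattern not in plans:
        raise ValueError(f"unknown pattern {pattern!r}")
    return plans[pattern]


@dataclass
class MatrixTruth:
    """Planted correlation structure of a generated expression matrix."""

    blocks: list[list[str]]
    r_target: float
    expected_r: float  # attenuated by extra measurement noise


def gen_expression_matrix(
    n_genes: int,
    n_samples: int = 54,
    blocks: list[list[int]] | None = None,
    r_target: float = 0.9,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[ExpressionMatrix, MatrixTruth]:
    """Generate a log2 expression matrix with planted correlated blocks.

    Members of a block share a latent per-sample profile mixed with
    independent noise so the population PCC within the block equals
    ``r_target``; background genes are independent. ``noise_sd`` adds
    extra measurement noise on top, attenuating the expected sample
    correlation to r / (1 + noise_sd^2). The default 54 samples mirror
    a whole-plant expression atlas, where the critical |r| at p = 0.01
    is about 0.35.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if not 0 <= r_target <= 1:
        raise ValueError("r_target must lie in [0, 1]")
    blocks = blocks or []
    flat = [g for b in blocks for g in b]
    if len(set(flat)) != len(flat):
        raise ValueError("blocks must be disjoint")
    rng = np.random.default_rng(seed)
    gene_ids = [f"g{i:03d}" for i in range(n_genes)]
    sample_ids = [f"s{j:02d}" for j in range(n_samples)]
    baselines = rng.normal(8.0, 2.0, size=n_genes)
    values = rng.normal(0.0, 1.0, size=(n_genes, n_samples))
    a = float(np.sqrt(r_target))
    b = float(np.sqrt(1.0 - r_target))
    for block in blocks:
        latent = rng.normal(0.0, 1.0, size=n_samples)
        for g in block:
            values[g] = a * latent + b * rng.normal(0.0, 1.0, size=n_samples)
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=values.shape)
    values = values + baselines[:, None]
    truth = MatrixTruth(
        blocks=[[gene_ids[g] for g in b] for b in blocks],
        r_target=r_target,
        expected_r=r_target / (1.0 + noise_sd**2),
    )
    return ExpressionMatrix(gene_ids, sample_ids, values), truth


@dataclass
class QpcrTruth:
    """Planted fold changes of a generated Ct table."""

    folds: dict[tuple[str, str], float]  # (gene, condition) -> fold
    control_condition: str


def gen_qpcr(
    genes: list[str],
    conditions: list[str],
    planted_folds: dict[tuple[str, str], float],
    control_condition: str,
    ct_noise_sd: float = 0.0,
    n_bio: int = 3,
    n_tech: int = 3,
    seed: int = 0,
) -> tuple[pd.DataFrame, QpcrTruth]:
    """Generate a qRT-PCR Ct table realizing planted fold changes.

    The reference-gene Ct is constant within each condition and the
    target Ct sits a per-gene dCt baseline above it, shifted down by
    log2(fold), so 2^-ddCt recovers the planted folds exactly at zero
    noise. Unlisted (gene, condition) pairs default to fold 1.
    """
    if any(f <= 0 for f in planted_folds.values()):
        raise ValueError("planted folds must be positive")
    rng = np.random.default_rng(seed)
    ref_ct = {c: float(rng.uniform(14.0, 16.0)) for c in conditions}
    baseline = {g: float(rng.uniform(2.0, 10.0)) for g in genes}
    rows = []
    folds = {}
    for g in genes:
        for c in conditions:
            fold = planted_folds.get((g, c), 1.0)
            if c == control_condition:
                fold = 1.0
            folds[(g, c)] = fold
            for b in range(1, n_bio + 1):
                for t in range(1, n_tech + 1):
                    noise = rng.normal(0.0, ct_noise_sd) if ct_noise_sd > 0 else 0.0
                    rows.append(
                        {
                            "gene_id": g,
                            "condition": c,
                            "bio_rep": b,
                            "tech_rep": t,
                            "ct_target": ref_ct[c]
                            + baseline[g]
                            - float(np.log2(fold))
                            + noise,
                            "ct_reference": ref_ct[c],
                        }
                    )
    return pd.DataFrame(rows), QpcrTruth(folds, control_condition)


_TABLE1_CACHE: dict[str, FamilyTable] = {}


def table1_frame() -> pd.DataFrame:
    """The packaged 55-member grapevine family table as a DataFrame.

    Carries both the published per-gene pattern letters (``pattern``)
    and the derived text-scheme letters (``pattern_text``), which
    differ only in labeling domain-intron-less genes ``i`` rather
    than ``h``.
    """
    with resources.files("bzipkit.data").joinpath("table1.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", dtype=str)


def table1_fixture(scheme: str = "table") -> FamilyTable:
    """The packaged family table as a validated :class:`FamilyTable`.

    ``scheme`` selects which pattern-letter column populates the
    ``pattern`` field: "table" for the letters as published per gene,
    "text" for the derived text-scheme letters.
    """
    if scheme not in {"table", "text"}:
        raise ValueError("scheme must be 'table' or 'text'")
    if scheme not in _TABLE1_CACHE:
        df = table1_frame()
        col = "pattern" if scheme == "table" else "pattern_text"
        records = [
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
                pattern=row[col],
                ortholog_ids=tuple(t for t in row["ortholog_ids"].split(",") if t),
            )
            for _, row in df.iterrows()
        ]
        _TABLE1_CACHE[scheme] = FamilyTable(records)
    return _TABLE1_CACHE[scheme]
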