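"""Grammar-based bZIP domain detection and annotation.

The bZIP domain is recognized structurally rather than by profile
search: a basic region with the consensus N-x7-R/K-x9 anchors the
domain, and a leucine zipper of heptad repeats (Leu, or another bulky
hydrophobic residue — Ile, Val, Phe, Met — at the repeat position)
follows immediately after.

Positions are reported in the conventional coiled-coil numbering frame:
the invariant Asn of the basic region is -18, the invariant Arg/Lys is
-10, and the first zipper repeat position is +1, with subsequent repeat
positions at +8, +15, ... There is no position 0; consecutive residues
advance the frame by one.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .records import ProteinRecord

#: residues accepted at a heptad repeat position
ZIPPER_RESIDUES = set("LIVFM")

#: offset from the Asn anchor to the basic Arg/Lys (N-x7-R/K)
BASIC_OFFSET = 8
#: offset from the Arg/Lys to the first zipper repeat (R/K-x9 then +1)
ZIPPER_OFFSET = 10

ROMAN = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX"]

#: canonical residues at the key DNA-binding frame positions
CANONICAL_KEY_RESIDUES = {-18: "N", -10: "R", 1: "L", 8: "L", 15: "L"}

PHOSPHO_MOTIFS = {
    "RK-xx-ST": re.compile(r"(?=([RK]..[ST]))"),
    "ST-xx-DE": re.compile(r"(?=([ST]..[DE]))"),
}


@dataclass(frozen=True)
class GrammarParams:
    """Tunable settings for domain detection.

    min_heptads:
        Minimum number of canonical heptad repeats for an anchor to
        qualify (observed zipper lengths run from 3 to 11 repeats).
    max_interruptions:
        Non-canonical repeat positions tolerated inside the zipper,
        provided a later canonical repeat follows (zippers interrupted
        by one or two spacer units are seen in real families).
    relaxed_basic:
        Accept any residue at the -10 position (admits the rare Ile
        substitution); relaxed hits are always flagged.
    heptad_counting:
        "canonical" counts only canonical repeats toward heptad_count;
        "all" also counts tolerated interruptions.
    """

    min_heptads: int = 3
    max_interruptions: int = 2
    relaxed_basic: bool = False
    heptad_counting: str = "canonical"

    def __post_init__(self) -> None:
        if self.min_heptads < 1:
            raise ValueError("min_heptads must be >= 1")
        if self.max_interruptions < 0:
            raise ValueError("max_interruptions must be >= 0")
        if self.heptad_counting not in {"canonical", "all"}:
            raise ValueError("heptad_counting must be 'canonical' or 'all'")


@dataclass
class BzipDomainAnnotation:
    """Coordinates and heptad structure of one detected bZIP domain.

    All indices are 0-based positions in the protein sequence. Spans
    are half-open [start, end) index intervals covering, in order, the
    basic region, the hinge, and the leucine zipper.
    """

    protein_id: str
    asn_index: int
    basic_residue_index: int
    zipper_start_index: int
    heptads: list[tuple[int, str, bool]]  # (frame_position, residue, canonical)
    heptad_count: int
    interruptions: int
    basic_span: tuple[int, int]
    hinge_span: tuple[int, int]
    zipper_span: tuple[int, int]
    relaxed_anchor: bool = False

    def frame_position(self, index: int) -> int:
        """Domain-frame position of a 0-based sequence index (no 0)."""
        d = index - self.zipper_start_index
        return d + 1 if d >= 0 else d

    def index_of(self, frame_position: int) -> int:
        """0-based sequence index of a domain-frame position."""
        if frame_position == 0:
            raise ValueError("the domain frame has no position 0")
        off = frame_position - 1 if frame_position > 0 else frame_position
        return self.zipper_start_index + off

    @property
    def domain_span(self) -> tuple[int, int]:
        return self.basic_span[0], self.zipper_span[1]


@dataclass
class SpecificityReport:
    """Residues at the key DNA-binding positions and their substitutions."""

    protein_id: str
    residues: dict[int, str | None]  # frame position -> residue (None = absent)
    substitutions: dict[int, bool]
    notes: list[str] = field(default_factory=list)

    @property
    def n_substitutions(self) -> int:
        return sum(self.substitutions.values())


@dataclass(frozen=True)
class PhosphoSiteHit:
    """A match of a phosphorylation-site motif."""

    protein_id: str
    motif: str
    start: int
    matched: str


def _extend_zipper(seq: str, start: int, params: GrammarParams):
    """Walk heptad positions from ``start``, tolerating interruptions.

    Returns (heptads, canonical_count, interruptions). A non-canonical
    repeat position is kept only when a later canonical repeat follows
    within the interruption budget; trailing non-canonical positions
    are discarded.
    """
    heptads: list[tuple[int, bool]] = []
    pending: list[int] = []
    interruptions = 0
    j = start
    while j < len(seq):
        if seq[j] in ZIPPER_RESIDUES:
            heptads.extend((p, False) for p in pending)
            interruptions += len(pending)
            pending = []
            heptads.append((j, True))
        else:
            pending.append(j)
            if len(pending) > params.max_interruptions:
                break
        j += 7
    canonical = sum(1 for _, ok in heptads if ok)
    return heptads, canonical, interruptions


def annotate_bzip_domain(
    protein: ProteinRecord, params: GrammarParams | None = None
) -> BzipDomainAnnotation | None:
    """Detect the bZIP domain in a protein, or return None.

    Every anchor (Asn at i with Arg/Lys at i+8) is scored by the number
    of canonical heptad repeats extending from i+18; the highest-scoring
    anchor wins, with ties broken by the leftmost anchor. Anchors with
    fewer than ``min_heptads`` canonical repeats do not qualify.
    """
    params = params or GrammarParams()
    seq = protein.sequence
    best = None  # (-score, anchor) so min() is (max score, leftmost)
    for i, aa in enumerate(seq):
        if aa != "N":
            continue
        basic_i = i + BASIC_OFFSET
        if basic_i >= len(seq):
            break
        basic_ok = seq[basic_i] in {"R", "K"}
        if not basic_ok and not params.relaxed_basic:
            continue
        zipper_i = basic_i + ZIPPER_OFFSET
        if zipper_i >= len(seq):
            continue
        heptads, canonical, interruptions = _extend_zipper(seq, zipper_i, params)
        if canonical < params.min_heptads:
            continue
        key = (-canonical, i)
        if best is None or key < best[0]:
            best = (key, i, heptads, canonical, interruptions, not basic_ok)
    if best is None:
        return None
    _, i, heptads, canonical, interruptions, relaxed = best
    basic_i = i + BASIC_OFFSET
    zipper_i = basic_i + ZIPPER_OFFSET
    last = heptads[-1][0]
    count = canonical if params.heptad_counting == "canonical" else len(heptads)
    ann = BzipDomainAnnotation(
        protein_id=protein.id,
        asn_index=i,
        basic_residue_index=basic_i,
        zipper_start_index=zipper_i,
        heptads=[],
        heptad_count=count,
        interruptions=interruptions,
        basic_span=(i, basic_i + 1),
        hinge_span=(basic_i + 1, zipper_i),
        zipper_span=(zipper_i, last + 1),
        relaxed_anchor=relaxed,
    )
    ann.heptads = [(ann.frame_position(j), seq[j], ok) for j, ok in heptads]
    return ann


def classify_zipper_gradient(annotation: BzipDomainAnnotation) -> str:
    """Map heptad count to the zipper-length gradient label I..IX.

    Three repeats map to gradient I and eleven to IX; counts outside
    [3, 11] yield an out-of-range label with a warning.
    """
    n = annotation.heptad_count
    if 3 <= n <= 11:
        return ROMAN[n - 3]
    import warnings

    warnings.warn(
        f"{annotation.protein_id}: heptad count {n} outside the 3-11 gradient range"
    )
    return f"out-of-range({n})"


def report_binding_specificity(
    annotation: BzipDomainAnnotation, protein: ProteinRecord
) -> SpecificityReport:
    """Report residues at frame -18, -10, +1, +8, +15 and flag substitutions.

    Canonical residues are Asn at -18, Arg at -10 and Leu at the three
    zipper positions; Lys at -10 is a known substitution (group F) and
    is flagged with a note.
    """
    residues: dict[int, str | None] = {}
    substitutions: dict[int, bool] = {}
    notes: list[str] = []
    for pos, canonical in CANONICAL_KEY_RESIDUES.items():
        idx = annotation.index_of(pos)
        if 0 <= idx < len(protein.sequence):
            aa = protein.sequence[idx]
            residues[pos] = aa
            substitutions[pos] = aa != canonical
            if pos == -10 and aa == "K":
                notes.append("-10 Arg->Lys (known basic-region substitution)")
        else:
            residues[pos] = None
            substitutions[pos] = False
            notes.append(f"frame position {pos:+d} beyond sequence end")
    return SpecificityReport(protein.id, residues, substitutions, notes)


def scan_phospho_sites(protein: ProteinRecord) -> list[PhosphoSiteHit]:
    """Find all R/KxxS/T and S/TxxD/E phosphorylation-site 4-mers.

    Overlapping matches are all reported, with 0-based start indices.
    """
    hits = []
    for motif, rx in PHOSPHO_MOTIFS.items():
        for m in rx.finditer(protein.sequence):
            hits.append(PhosphoSiteHit(protein.id, motif, m.start(), m.group(1)))
    hits.sort(key=lambda h: (h.start, h.motif))
    return hits
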