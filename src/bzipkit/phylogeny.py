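"""Domain-anchored alignment, distances, neighbor joining and grouping.

The fixed numbering frame of the bZIP domain (-18 for the invariant
Asn, +1 for the first zipper repeat) gives a natural gap-free anchor
for aligning family members without a progressive aligner: residues at
the same frame position are homologous by construction. Family groups
are assigned by proximity to labeled reference sequences on a
neighbor-joining tree built from p-distances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skbio import DistanceMatrix, TreeNode

from .grammar import BzipDomainAnnotation
from .records import ProteinRecord

GAP = "-"


@dataclass
class DomainAlignment:
    """Alignment of bZIP domains in the fixed numbering frame."""

    ids: list[str]
    frame_positions: list[int]  # strictly increasing, no 0
    rows: list[str]  # one per id, same length as frame_positions
    source: str = "grammar-anchored"

    def __post_init__(self) -> None:
        if any(len(r) != len(self.frame_positions) for r in self.rows):
            raise ValueError("alignment rows must match the number of columns")
        if sorted(self.frame_positions) != self.frame_positions or 0 in self.frame_positions:
            raise ValueError("frame positions must be strictly increasing and nonzero")

    @property
    def shape(self) -> tuple[int, int]:
        return len(self.rows), len(self.frame_positions)


def _frame_range(start: int, end_inclusive: int) -> list[int]:
    return [p for p in range(start, end_inclusive + 1) if p != 0]


def anchored_domain_alignment(
    annotations: dict[str, BzipDomainAnnotation],
    proteins: dict[str, ProteinRecord],
    extent: str = "max",
) -> DomainAlignment:
    """Align domains by placing residues at their frame positions.

    Columns run from -18 to the zipper end; with ``extent="max"`` the
    zipper end of the longest domain is used and shorter rows are
    gap-padded on the right, with ``extent="common"`` columns stop at
    the shortest domain's zipper end.
    """
    if extent not in {"max", "common"}:
        raise ValueError("extent must be 'max' or 'common'")
    ids = list(annotations)
    ends = [
        ann.frame_position(ann.zipper_span[1] - 1) for ann in annotations.values()
    ]
    end = max(ends) if extent == "max" else min(ends)
    positions = _frame_range(-18, end)
    rows = []
    for pid in ids:
        ann = annotations[pid]
        seq = proteins[pid].sequence
        own_end = ann.frame_position(ann.zipper_span[1] - 1)
        row = []
        for pos in positions:
            if pos > own_end:
                row.append(GAP)
                continue
            idx = ann.index_of(pos)
            row.append(seq[idx] if 0 <= idx < len(seq) else GAP)
        rows.append("".join(row))
    return DomainAlignment(ids, positions, rows)


def p_distance(aln: DomainAlignment) -> DistanceMatrix:
    """Pairwise p-distances with pairwise deletion of gap columns.

    d(i, j) = mismatches / compared columns over columns where neither
    row has a gap; a pair with no comparable column gets distance 1
    with a warning.
    """
    n = len(aln.rows)
    if n < 2:
        raise ValueError("p_distance requires at least 2 rows")
    arr = np.array([list(r) for r in aln.rows])
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = (arr[i] != GAP) & (arr[j] != GAP)
            m = int(ok.sum())
            if m == 0:
                warnings.warn(
                    f"no comparable columns between {aln.ids[i]!r} and "
                    f"{aln.ids[j]!r}; distance set to 1"
                )
                d[i, j] = d[j, i] = 1.0
            else:
                d[i, j] = d[j, i] = float((arr[i][ok] != arr[j][ok]).sum()) / m
    return DistanceMatrix(d, aln.ids)


def build_nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Neighbor joining by the Saitou-Nei Q-criterion.

    At each step the pair minimizing Q(i, j) = (n-2) d(i, j) - r_i -
    r_j is joined; ties break on the lexicographically smallest id
    pair. Branch lengths follow the standard formulas; a negative
    length is clamped to zero with the excess moved to the sister
    branch. The result is returned as an unrooted tree (trifurcating
    root where possible).
    """
    ids = list(dm.ids)
    if len(ids) < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    d = {
        frozenset((a, b)): dm[a, b] for i, a in enumerate(ids) for b in ids[i + 1 :]
    }
    nodes = {name: TreeNode(name=name) for name in ids}
    active = sorted(ids)

    def dist(a, b):
        return 0.0 if a == b else d[frozenset((a, b))]

    counter = 0
    while len(active) > 3:
        n = len(active)
        r = {a: sum(dist(a, b) for b in active) for a in active}
        best = None
        for i, a in enumerate(active):
            for b in active[i + 1 :]:
                q = (n - 2) * dist(a, b) - r[a] - r[b]
                key = (q, a, b)
                if best is None or key < best:
                    best = key
        _, a, b = best
        dab = dist(a, b)
        va = 0.5 * dab + (r[a] - r[b]) / (2 * (n - 2))
        vb = dab - va
        if va < 0:
            va, vb = 0.0, dab
        elif vb < 0:
            va, vb = dab, 0.0
        parent = TreeNode(name=f"_nj{counter}")
        counter += 1
        na, nb = nodes.pop(a), nodes.pop(b)
        na.length, nb.length = va, vb
        parent.extend([na, nb])
        u = parent.name
        for c in active:
            if c in (a, b):
                continue
            d[frozenset((u, c))] = 0.5 * (dist(a, c) + dist(b, c) - dab)
        active = sorted([c for c in active if c not in (a, b)] + [u])
        nodes[u] = parent
    # final three taxa: solve the three-point equations exactly
    a, b, c = active
    va = 0.5 * (dist(a, b) + dist(a, c) - dist(b, c))
    vb = 0.5 * (dist(a, b) + dist(b, c) - dist(a, c))
    vc = 0.5 * (dist(a, c) + dist(b, c) - dist(a, b))
    root = TreeNode(name="root")
    for name, v in ((a, va), (b, vb), (c, vc)):
        node = nodes.pop(name)
        node.length = max(v, 0.0)
        root.append(node)
    return root


@dataclass
class GroupAssignment:
    """Group labels for query sequences, with nearest-reference support."""

    labels: dict[str, str]
    support: dict[str, float]  # nearest-reference distance


def assign_groups(
    tree: TreeNode | None,
    reference_labels: dict[str, str],
    dm: DistanceMatrix | None = None,
    tie_margin: float = 0.02,
) -> GroupAssignment:
    """Assign each query the group of its nearest labeled reference.

    Distances are tree path lengths when a tree is given, otherwise raw
    distances from ``dm``. A query whose two nearest references carry
    different labels within ``tie_margin`` of each other is labeled UC.
    Reference input order never affects the result: ties on distance
    break on reference id.
    """
    if not reference_labels:
        raise ValueError("at least one labeled reference is required")
    if any(not v for v in reference_labels.values()):
        bad = sorted(k for k, v in reference_labels.items() if not v)
        raise ValueError(f"unlabeled references: {bad}")
    if tree is not None:
        td = tree.tip_tip_distances()
        ids = list(td.ids)
        get = lambda a, b: td[a, b]
    elif dm is not None:
        ids = list(dm.ids)
        get = lambda a, b: dm[a, b]
    else:
        raise ValueError("either a tree or a distance matrix is required")
    missing = set(reference_labels) - set(ids)
    if missing:
        raise ValueError(f"references absent from the tree/matrix: {sorted(missing)}")
    refs = sorted(reference_labels)
    labels, support = {}, {}
    for q in ids:
        if q in reference_labels:
            labels[q] = reference_labels[q]
            support[q] = 0.0
            continue
        ranked = sorted(refs, key=lambda r: (get(q, r), r))
        best = ranked[0]
        labels[q] = reference_labels[best]
        support[q] = get(q, best)
        if len(ranked) > 1:
            second = ranked[1]
            if (
                reference_labels[second] != reference_labels[best]
                and get(q, second) - get(q, best) < tie_margin
            ):
                labels[q] = "UC"
    return GroupAssignment(labels, support)


def bootstrap_trees(
    aln: DomainAlignment, n_replicates: int, seed: int
) -> list[TreeNode]:
    """Column-resampled NJ replicate trees (off by default downstream)."""
    rng = np.random.default_rng(seed)
    ncol = len(aln.frame_positions)
    trees = []
    for _ in range(n_replicates):
        cols = sorted(rng.integers(0, ncol, size=ncol).tolist())
        rows = ["".join(r[c] for c in cols) for r in aln.rows]
        rep = DomainAlignment(aln.ids, list(range(1, ncol + 1)), rows, source=aln.source)
        trees.append(build_nj_tree(p_distance(rep)))
    return trees
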