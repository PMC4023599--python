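"""Atlas co-expression, qRT-PCR relative expression and clustering.

Co-expression between family members is read off a log2 expression
atlas with Pearson's correlation; significance uses the exact
t-transform t = r sqrt((n-2) / (1-r^2)) with n-2 degrees of freedom
(two-tailed, no multiple-testing correction). Relative expression from
qRT-PCR follows the 2^-ddCt method with the reference gene's Ct
subtracted per condition and the control condition as baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .records import ExpressionMatrix, RecordError

#: default thresholds for atlas co-expression classes
ALPHA = 0.01
POSITIVE_PCC = 0.35
NEGATIVE_PCC = -0.35
STRONG_PCC = 0.9


@dataclass(frozen=True)
class CorrelationClassification:
    """PCC, p-value and co-expression class for one unordered gene pair."""

    gene_a: str
    gene_b: str
    pcc: float
    p_value: float
    klass: str  # significant-positive | significant-negative | strong-positive | not-significant


def pcc_pvalue(r: float, n: int) -> float:
    """Two-tailed p-value of a Pearson correlation from the t-transform."""
    if n < 3:
        raise ValueError("PCC significance requires n >= 3 samples")
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) == 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def _classify(r: float, p: float, alpha, pos, neg, strong) -> str:
    if p < alpha and r >= pos:
        return "strong-positive" if r > strong else "significant-positive"
    if p < alpha and r <= neg:
        return "significant-negative"
    return "not-significant"


def pairwise_pcc(
    m: ExpressionMatrix,
    alpha: float = ALPHA,
    pos: float = POSITIVE_PCC,
    neg: float = NEGATIVE_PCC,
    strong: float = STRONG_PCC,
) -> list[CorrelationClassification]:
    """Classify all unordered gene pairs by Pearson correlation.

    Thresholds are honored exactly at their boundaries: r = ``pos``
    with p < ``alpha`` is significant-positive; r must strictly exceed
    ``strong`` to be strong-positive (which is always also
    significant). Zero-variance genes are excluded with a warning.
    """
    n = len(m.sample_ids)
    if n < 3:
        raise ValueError("pairwise PCC requires at least 3 samples")
    keep, dropped = [], []
    for i, gid in enumerate(m.gene_ids):
        (dropped if np.ptp(m.values[i]) == 0 else keep).append(i)
    if dropped:
        warnings.warn(
            "zero-variance genes excluded from PCC: "
            + ", ".join(m.gene_ids[i] for i in dropped)
        )
    ids = [m.gene_ids[i] for i in keep]
    if len(ids) < 2:
        return []
    corr = np.corrcoef(m.values[keep])
    out = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            r = float(corr[i, j])
            p = pcc_pvalue(r, n)
            out.append(
                CorrelationClassification(
                    ids[i], ids[j], r, p, _classify(r, p, alpha, pos, neg, strong)
                )
            )
    return out


def ddct_relative_expression(
    records: pd.DataFrame, control_condition: str
) -> pd.DataFrame:
    """Fold change per gene x condition by the 2^-ddCt method.

    ``records`` needs columns gene_id, condition, ct_target,
    ct_reference and optionally bio_rep / tech_rep. Technical
    replicates are averaged at the Ct level within each biological
    replicate; biological replicates are averaged at the fold level.
    ddCt pairs each treatment biological replicate with the control
    dCt of the same replicate when present, otherwise with the mean
    control dCt. Folds for the control condition are exactly 1.
    """
    df = records.copy()
    for col in ("bio_rep", "tech_rep"):
        if col not in df.columns:
            df[col] = 1
    if df["ct_reference"].isnull().any():
        bad = df[df["ct_reference"].isnull()].iloc[0]
        raise RecordError(
            f"missing reference-gene Ct for gene {bad['gene_id']!r}, "
            f"condition {bad['condition']!r}"
        )
    # technical replicates -> one dCt per (gene, condition, bio_rep)
    agg = (
        df.groupby(["gene_id", "condition", "bio_rep"])[["ct_target", "ct_reference"]]
        .mean()
        .reset_index()
    )
    agg["dct"] = agg["ct_target"] - agg["ct_reference"]
    rows = []
    for gene, sub in agg.groupby("gene_id"):
        ctrl = sub[sub["condition"] == control_condition]
        if ctrl.empty:
            raise RecordError(f"gene {gene!r}: no control records ({control_condition!r})")
        ctrl_by_rep = dict(zip(ctrl["bio_rep"], ctrl["dct"]))
        ctrl_mean = float(ctrl["dct"].mean())
        for cond, csub in sub.groupby("condition"):
            folds = []
            for _, row in csub.iterrows():
                base = ctrl_by_rep.get(row["bio_rep"], ctrl_mean)
                folds.append(2.0 ** (-(row["dct"] - base)))
            rows.append({"gene_id": gene, "condition": cond, "fold": float(np.mean(folds))})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ResponderCall:
    """Direction of a gene's stress response relative to the control."""

    gene_id: str
    direction: str  # up | down | none
    max_fold: float
    min_fold: float


def classify_responders(
    folds: pd.DataFrame, threshold: float = 2.0, control_condition: str | None = None
) -> list[ResponderCall]:
    """Call up-/down-regulated genes from fold changes.

    A gene is up-regulated when any condition reaches ``threshold``
    fold (the boundary is inclusive: "at least two fold") and
    down-regulated when any condition drops to 1/``threshold``; a gene
    may receive both calls. The control condition is excluded.
    """
    if (folds["fold"] <= 0).any():
        raise ValueError("folds must be positive")
    sub = folds
    if control_condition is not None:
        sub = folds[folds["condition"] != control_condition]
    calls = []
    for gene, g in sub.groupby("gene_id", sort=False):
        mx, mn = float(g["fold"].max()), float(g["fold"].min())
        directions = []
        if mx >= threshold:
            directions.append("up")
        if mn <= 1.0 / threshold:
            directions.append("down")
        if not directions:
            directions = ["none"]
        for d in directions:
            calls.append(ResponderCall(gene, d, mx, mn))
    return calls


def cluster_expression(m: ExpressionMatrix, k: int = 4, seed: int | None = None) -> dict[str, int]:
    """Agglomerative clustering of genes, distance 1 - PCC, average linkage.

    The dendrogram is cut at ``k`` clusters. Constant rows cannot enter
    a correlation distance; they are clustered among the rest by
    nearest cluster centroid (Euclidean) with a warning. Deterministic
    for a given input order; ``seed`` is accepted for interface
    symmetry with the stochastic generators but unused.
    """
    if k > len(m.gene_ids):
        raise ValueError(f"k={k} exceeds the number of genes ({len(m.gene_ids)})")
    variable = [i for i in range(len(m.gene_ids)) if np.ptp(m.values[i]) > 0]
    constant = [i for i in range(len(m.gene_ids)) if i not in variable]
    if constant:
        warnings.warn(
            "constant expression rows assigned by Euclidean fallback: "
            + ", ".join(m.gene_ids[i] for i in constant)
        )
    labels: dict[str, int] = {}
    if len(variable) >= 2:
        corr = np.corrcoef(m.values[variable])
        dist = np.clip(1.0 - corr, 0.0, 2.0)
        np.fill_diagonal(dist, 0.0)
        z = linkage(squareform(dist, checks=False), method="average")
        flat = fcluster(z, t=min(k, len(variable)), criterion="maxclust")
        for i, lab in zip(variable, flat):
            labels[m.gene_ids[i]] = int(lab)
    elif variable:
        labels[m.gene_ids[variable[0]]] = 1
    if constant and labels:
        centroids = {}
        for lab in set(labels.values()):
            rows = [m.values[m.gene_ids.index(g)] for g, l in labels.items() if l == lab]
            centroids[lab] = np.mean(rows, axis=0)
        for i in constant:
            best = min(
                sorted(centroids),
                key=lambda lab: float(np.linalg.norm(m.values[i] - centroids[lab])),
            )
            labels[m.gene_ids[i]] = best
    elif constant:
        for i in constant:
            labels[m.gene_ids[i]] = 1
    return labels


def compare_qpcr_vs_atlas(
    qpcr: pd.DataFrame,
    atlas: ExpressionMatrix,
    sample_pairs: list[tuple[str, str]],
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Per-gene agreement between qRT-PCR profiles and the atlas.

    ``qpcr`` holds columns gene_id, condition, fold; ``sample_pairs``
    matches qPCR conditions to atlas samples. Genes with fewer than 3
    matched points are skipped with a warning; agreement is flagged at
    two-tailed p < ``alpha``.
    """
    rows = []
    for gene in qpcr["gene_id"].unique():
        sub = qpcr[qpcr["gene_id"] == gene].set_index("condition")["fold"]
        xs, ys = [], []
        for cond, sample in sample_pairs:
            if cond in sub.index and gene in atlas.gene_ids and sample in atlas.sample_ids:
                xs.append(float(sub[cond]))
                ys.append(float(atlas.row(gene)[atlas.sample_ids.index(sample)]))
        if len(xs) < 3:
            warnings.warn(f"gene {gene!r}: fewer than 3 matched samples; skipped")
            continue
        if np.ptp(xs) == 0 or np.ptp(ys) == 0:
            warnings.warn(f"gene {gene!r}: constant profile; skipped")
            continue
        r = float(np.corrcoef(xs, ys)[0, 1])
        p = pcc_pvalue(r, len(xs))
        rows.append(
            {"gene_id": gene, "pcc": r, "p_value": p, "n": len(xs), "agreement": p < alpha}
        )
    return pd.DataFrame(rows)
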