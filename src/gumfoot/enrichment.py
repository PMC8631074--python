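"""Glue-protein identification from label-free quantification (LFQ) tables.

The gumfoot line of a cobweb is sampled as two pools: the lower glue-bearing
portion ("GlueFiber") and the bare upper portion ("Fiber"). Proteins whose
LFQ abundance is significantly higher in GlueFiber than in Fiber are strong
candidates for aggregate-glue components. The pipeline applies confidence
filters (search score, PTM evidence, per-run detection support), inspects
sample structure by Spearman-distance hierarchical clustering, flags
poorly-correlated outlier samples, and tests each protein with a one-tailed
t-test followed by Benjamini-Hochberg FDR adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Literal

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GLUE_FIBER",
    "FIBER",
    "LFQMatrix",
    "SchemaError",
    "filter_high_confidence",
    "sample_distance_matrix",
    "cluster_samples",
    "linkage_to_newick",
    "detect_outlier_samples",
    "relative_difference",
    "enrichment_test",
    "bh_fdr",
    "classify_proteins",
    "run_enrichment",
]

GLUE_FIBER = "GlueFiber"
FIBER = "Fiber"


class SchemaError(ValueError):
    """An input table does not carry the documented columns/labels."""


@dataclass(frozen=True)
class LFQMatrix:
    """Proteins-by-samples LFQ values with sample and search metadata.

    values
        DataFrame indexed by protein id, one column per sample id; LFQ >= 0
        with 0 meaning not quantified in that sample.
    samples
        DataFrame indexed by sample id with columns ``sample_type``
        (``GlueFiber`` | ``Fiber``) and ``run`` (1 | 2).
    scores
        DataFrame indexed by protein id, one column per run label, holding
        the per-run search (MaxQuant-style) score.
    ptm_modified
        Optional boolean DataFrame (protein x sample): PTM evidence flags.
    ptm_scores
        Optional Series (protein): score in the PTM search.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    scores: pd.DataFrame
    ptm_modified: pd.DataFrame | None = None
    ptm_scores: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise SchemaError("duplicate protein ids in LFQ matrix")
        missing = {"sample_type", "run"} - set(self.samples.columns)
        if missing:
            raise SchemaError(f"sample table lacks columns: {sorted(missing)}")
        if set(self.values.columns) != set(self.samples.index):
            raise SchemaError("LFQ columns do not match the sample table")
        bad = set(self.samples["sample_type"]) - {GLUE_FIBER, FIBER}
        if bad:
            raise SchemaError(f"unknown sample types: {sorted(bad)}")
        if (np.asarray(self.values, dtype=float) < 0).any():
            raise SchemaError("LFQ values must be non-negative")

    @property
    def proteins(self) -> pd.Index:
        return self.values.index

    def sample_ids(self, sample_type: str | None = None) -> list[str]:
        meta = self.samples
        if sample_type is not None:
            meta = meta[meta["sample_type"] == sample_type]
        return list(meta.index)

    def subset(self, proteins: Iterable[str]) -> "LFQMatrix":
        idx = pd.Index(proteins)
        return replace(
            self,
            values=self.values.loc[idx],
            scores=self.scores.loc[idx],
            ptm_modified=None if self.ptm_modified is None else self.ptm_modified.loc[idx],
            ptm_scores=None if self.ptm_scores is None else self.ptm_scores.loc[idx],
        )

    def drop_samples(self, sample_ids: Iterable[str]) -> "LFQMatrix":
        drop = set(sample_ids)
        keep = [s for s in self.values.columns if s not in drop]
        return replace(
            self,
            values=self.values[keep],
            samples=self.samples.loc[keep],
            ptm_modified=None if self.ptm_modified is None else self.ptm_modified[
                [c for c in self.ptm_modified.columns if c not in drop]
            ],
        )


# ---------------------------------------------------------------------------
# confidence filtering
# ---------------------------------------------------------------------------


def filter_high_confidence(
    matrix: LFQMatrix,
    score_min: float = 50.0,
    min_ptm_samples: int = 5,
    min_samples_per_run: int = 2,
) -> LFQMatrix:
    """Retain proteins consistently and confidently identified.

    A protein is kept iff it satisfies
    (search score > ``score_min`` in at least one LFQ run) OR
    (PTM-modified in >= ``min_ptm_samples`` GlueFiber samples AND PTM-search
    score > ``score_min``), AND it has LFQ > 0 in at least
    ``min_samples_per_run`` samples from *each* run.  Idempotent.
    """
    if "run" not in matrix.samples.columns:
        raise SchemaError("sample table lacks run labels")

    score_ok = (matrix.scores > score_min).any(axis=1)

    if matrix.ptm_modified is not None and matrix.ptm_scores is not None:
        gf = matrix.sample_ids(GLUE_FIBER)
        gf_cols = [c for c in matrix.ptm_modified.columns if c in gf]
        n_mod = matrix.ptm_modified[gf_cols].sum(axis=1)
        ptm_ok = (n_mod >= min_ptm_samples) & (matrix.ptm_scores > score_min)
    else:
        ptm_ok = pd.Series(False, index=matrix.proteins)

    support_ok = pd.Series(True, index=matrix.proteins)
    for _, meta in matrix.samples.groupby("run"):
        nonzero = (matrix.values[list(meta.index)] > 0).sum(axis=1)
        support_ok &= nonzero >= min_samples_per_run

    keep = (score_ok | ptm_ok) & support_ok
    return matrix.subset(matrix.proteins[keep])


# ---------------------------------------------------------------------------
# sample structure
# ---------------------------------------------------------------------------


def _spearman_corr(values: pd.DataFrame) -> pd.DataFrame:
    corr = values.corr(method="spearman")
    # constant sample vectors have undefined rank correlation; treat as 0
    return corr.fillna(0.0)


def sample_distance_matrix(matrix: LFQMatrix) -> pd.DataFrame:
    """Pairwise sample distances d = 1 - Spearman rho over protein LFQ."""
    if matrix.values.shape[1] < 2:
        raise ValueError("need at least two samples")
    d = 1.0 - _spearman_corr(matrix.values)
    np.fill_diagonal(d.values, 0.0)
    return d


def cluster_samples(distances: pd.DataFrame, method: str = "average") -> np.ndarray:
    """Agglomerative clustering of the sample distance matrix.

    Returns the scipy linkage matrix; sample order follows
    ``distances.index``. Average linkage by default.
    """
    if distances.shape[0] != distances.shape[1]:
        raise ValueError("distance matrix must be square")
    if distances.shape[0] == 1:
        return np.empty((0, 4))
    condensed = squareform(distances.values, checks=False)
    return linkage(condensed, method=method)


def linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Serialize a scipy linkage matrix as a newick string."""
    if len(labels) == 1:
        return f"{labels[0]};"
    tree = to_tree(Z)

    def fmt(node, parent_dist: float) -> str:
        length = parent_dist - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = fmt(node.left, node.dist)
        right = fmt(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return f"({fmt(tree.left, tree.dist)},{fmt(tree.right, tree.dist)});"


def detect_outlier_samples(
    matrix: LFQMatrix, threshold: float = 0.5
) -> list[str]:
    """Flag samples that correlate poorly with their own sample type.

    A sample is flagged when its median Spearman correlation with the other
    samples of the same type falls below ``threshold``. Flagging is
    advisory: callers decide whether to drop the sample.
    """
    if matrix.values.shape[1] < 3:
        raise ValueError("need at least three samples to assess outliers")
    corr = _spearman_corr(matrix.values)
    flagged = []
    for sid in matrix.values.columns:
        stype = matrix.samples.loc[sid, "sample_type"]
        peers = [
            s
            for s in matrix.sample_ids(stype)
            if s != sid and s in corr.columns
        ]
        if not peers:
            continue
        if float(corr.loc[sid, peers].median()) < threshold:
            flagged.append(sid)
    return flagged


# ---------------------------------------------------------------------------
# per-protein enrichment statistics
# ---------------------------------------------------------------------------


def relative_difference(mean_fiber: float, mean_gluefiber: float) -> float:
    """Symmetric-mean-normalized difference of group means, in [-2, 2].

    ``(m_F - m_GF) / ((m_F + m_GF)/2)``; negative values indicate
    GlueFiber enrichment.
    """
    if mean_fiber < 0 or mean_gluefiber < 0:
        raise ValueError("means must be non-negative")
    denom = (mean_fiber + mean_gluefiber) / 2.0
    if denom == 0:
        raise ValueError("relative difference undefined when both means are zero")
    return (mean_fiber - mean_gluefiber) / denom


def enrichment_test(
    gluefiber: np.ndarray,
    fiber: np.ndarray,
    equal_var: bool = False,
    log_transform: bool = True,
) -> tuple[float, float]:
    """One-tailed t-test for mean(GlueFiber) > mean(Fiber).

    Welch's unequal-variance t by default (matching R's ``t.test``);
    ``equal_var=True`` gives the pooled-variance Student's form. By default
    values are tested on log10(x+1), the standard working scale for LFQ
    intensities; ``log_transform=False`` tests the raw scale.
    Returns ``(t, p)``; degenerate zero-variance inputs yield ``p = 1``.
    """
    a = np.asarray(gluefiber, dtype=float)
    b = np.asarray(fiber, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two values")
    if log_transform:
        a = np.log10(a + 1.0)
        b = np.log10(b + 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(a, b, equal_var=equal_var, alternative="greater")
    if np.isnan(p):
        return 0.0, 1.0
    return float(t), float(p)


def bh_fdr(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify_proteins(
    matrix: LFQMatrix,
    alpha: float = 0.05,
    equal_var: bool = False,
    log_transform: bool = True,
) -> pd.DataFrame:
    """Per-protein enrichment statistics and detection classes.

    Returns a DataFrame indexed by protein id with columns ``mean_gluefiber``,
    ``mean_fiber``, ``relative_difference``, ``t``, ``p``, ``q``,
    ``detection`` (both | glue_only | fiber_only | none) and ``enriched``
    (q < ``alpha``).
    """
    gf_cols = matrix.sample_ids(GLUE_FIBER)
    f_cols = matrix.sample_ids(FIBER)
    gf = matrix.values[gf_cols]
    fb = matrix.values[f_cols]

    mean_gf = gf.mean(axis=1)
    mean_f = fb.mean(axis=1)

    rows = []
    for pid in matrix.proteins:
        t, p = enrichment_test(
            gf.loc[pid].to_numpy(),
            fb.loc[pid].to_numpy(),
            equal_var=equal_var,
            log_transform=log_transform,
        )
        mg, mf = float(mean_gf[pid]), float(mean_f[pid])
        rd = np.nan if (mg == 0 and mf == 0) else relative_difference(mf, mg)
        in_gf = bool((gf.loc[pid] > 0).any())
        in_f = bool((fb.loc[pid] > 0).any())
        detection = (
            "both"
            if in_gf and in_f
            else "glue_only"
            if in_gf
            else "fiber_only"
            if in_f
            else "none"
        )
        rows.append((pid, mg, mf, rd, t, p, detection))
    out = pd.DataFrame(
        rows,
        columns=[
            "protein_id",
            "mean_gluefiber",
            "mean_fiber",
            "relative_difference",
            "t",
            "p",
            "detection",
        ],
    ).set_index("protein_id")
    out["q"] = bh_fdr(out["p"].to_numpy())
    out["enriched"] = out["q"] < alpha
    return out


def run_enrichment(
    matrix: LFQMatrix,
    alpha: float = 0.05,
    score_min: float = 50.0,
    min_ptm_samples: int = 5,
    outlier_threshold: float = 0.5,
    drop_outliers: bool = False,
    equal_var: bool = False,
    log_transform: bool = True,
) -> dict:
    """Full pipeline: filter, cluster, flag outliers, test, classify.

    Returns a dict with keys ``matrix`` (filtered), ``distances``,
    ``linkage``, ``newick``, ``outliers`` and ``results`` (the
    classification table).  Outlier samples are only removed when
    ``drop_outliers`` is set; flagging alone never silently deletes data.
    """
    filtered = filter_high_confidence(
        matrix, score_min=score_min, min_ptm_samples=min_ptm_samples
    )
    if filtered.values.shape[0] == 0:
        raise ValueError("no proteins survive the confidence filters")
    outliers = detect_outlier_samples(filtered, threshold=outlier_threshold)
    if drop_outliers and outliers:
        filtered = filtered.drop_samples(outliers)
    distances = sample_distance_matrix(filtered)
    Z = cluster_samples(distances)
    newick = linkage_to_newick(Z, list(distances.index))
    results = classify_proteins(
        filtered, alpha=alpha, equal_var=equal_var, log_transform=log_transform
    )
    return {
        "matrix": filtered,
        "distances": distances,
        "linkage": Z,
        "newick": newick,
        "outliers": outliers,
        "results": results,
    }
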