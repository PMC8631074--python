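"""Sequence-derived protein properties and distribution comparisons.

Glue proteins tend to be more hydrophilic than the background proteome, and
their isoelectric points are bimodally distributed — oppositely charged
proteins can interact electrostatically, a plausible contributor to glue
cohesion. This module computes mean Kyte-Doolittle hydropathy (GRAVY; lower
= more hydrophilic), an averaged isoelectric point, gland-expression
percentages from TPM vectors, the Possible-Glue classification, and
Wilcoxon rank-sum comparisons between protein groups.

The "averaged pI" follows the simple convention of averaging per-residue
isoelectric-point constants together with one N-terminus and one C-terminus
value per protein. The residue constants are the standard free amino acid
pI values; the terminus values are the glycine alpha-amino and
alpha-carboxyl pKa's. This is a descriptive summary statistic, not a
charge-neutrality pI; a Henderson-Hasselbalch solver is provided separately
as :func:`isoelectric_point_hh`.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "KYTE_DOOLITTLE",
    "RESIDUE_PI",
    "SequenceProperties",
    "RankSumResult",
    "mean_hydropathy",
    "average_isoelectric_point",
    "isoelectric_point_hh",
    "sequence_properties",
    "wilcoxon_rank_sum",
    "percent_gland_expression",
    "possible_glue_classification",
    "compare_property_distributions",
]

#: Kyte-Doolittle hydropathy scale (unitless; +4.5 Ile ... -4.5 Arg).
KYTE_DOOLITTLE: dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

#: Isoelectric points of the free amino acids (pH units).
RESIDUE_PI: dict[str, float] = {
    "A": 6.00, "R": 10.76, "N": 5.41, "D": 2.77, "C": 5.07,
    "Q": 5.65, "E": 3.22, "G": 5.97, "H": 7.59, "I": 6.02,
    "L": 5.98, "K": 9.74, "M": 5.74, "F": 5.48, "P": 6.30,
    "S": 5.68, "T": 5.60, "W": 5.89, "Y": 5.66, "V": 5.96,
}

#: Terminus contributions to the averaged pI: glycine alpha-amino and
#: alpha-carboxyl pKa values, one of each per protein.
N_TERMINUS_PI = 9.60
C_TERMINUS_PI = 2.34

# side-chain / termini pKa's for the Henderson-Hasselbalch solver (EMBOSS)
_PKA_POSITIVE = {"K": 10.8, "R": 12.5, "H": 6.5}
_PKA_NEGATIVE = {"D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1}
_PKA_NTERM = 8.6
_PKA_CTERM = 3.6

_AMBIGUOUS = set("XBZJUO*")


@dataclass(frozen=True)
class SequenceProperties:
    protein_id: str
    length: int
    mean_hydropathy: float
    average_pi: float


@dataclass(frozen=True)
class RankSumResult:
    """Wilcoxon rank-sum outcome, W in the Mann-Whitney-U convention of R."""

    W: float
    pvalue: float
    method: str  # "exact" | "normal"


def _clean(sequence: str) -> str:
    seq = sequence.strip().upper()
    unknown = [c for c in seq if c in _AMBIGUOUS]
    if unknown:
        warnings.warn(
            f"skipping {len(unknown)} ambiguous residue(s): "
            f"{sorted(set(unknown))}",
            stacklevel=3,
        )
    seq = "".join(c for c in seq if c in KYTE_DOOLITTLE)
    if not seq:
        raise ValueError("sequence has no standard residues")
    return seq


def mean_hydropathy(sequence: str) -> float:
    """Mean Kyte-Doolittle hydropathy (GRAVY) of a protein sequence.

    Ambiguous residues (X, B, Z, ...) are skipped with a warning.
    """
    seq = _clean(sequence)
    return sum(KYTE_DOOLITTLE[c] for c in seq) / len(seq)


def average_isoelectric_point(sequence: str) -> float:
    """Average of per-residue pI constants plus N- and C-terminus values."""
    seq = _clean(sequence)
    total = sum(RESIDUE_PI[c] for c in seq) + N_TERMINUS_PI + C_TERMINUS_PI
    return total / (len(seq) + 2)


def isoelectric_point_hh(sequence: str) -> float:
    """Charge-neutrality pI via Henderson-Hasselbalch titration (bisection).

    An alternative to :func:`average_isoelectric_point` using side-chain and
    terminus pKa's; the two are different statistics and are not
    interchangeable.
    """
    seq = _clean(sequence)

    def net_charge(ph: float) -> float:
        pos = 1.0 / (1.0 + 10 ** (ph - _PKA_NTERM))
        neg = 1.0 / (1.0 + 10 ** (_PKA_CTERM - ph))
        for c in seq:
            if c in _PKA_POSITIVE:
                pos += 1.0 / (1.0 + 10 ** (ph - _PKA_POSITIVE[c]))
            elif c in _PKA_NEGATIVE:
                neg += 1.0 / (1.0 + 10 ** (_PKA_NEGATIVE[c] - ph))
        return pos - neg

    lo, hi = 0.0, 14.0
    for _ in range(60):
        mid = (lo + hi) / 2.0
        if net_charge(mid) > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def sequence_properties(records: dict[str, str]) -> pd.DataFrame:
    """Property table (length, hydropathy, averaged pI) for id->sequence."""
    rows = [
        SequenceProperties(
            protein_id=pid,
            length=len(_clean(seq)),
            mean_hydropathy=mean_hydropathy(seq),
            average_pi=average_isoelectric_point(seq),
        )
        for pid, seq in records.items()
    ]
    return pd.DataFrame([r.__dict__ for r in rows]).set_index("protein_id")


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------


def _midranks(pooled: np.ndarray) -> np.ndarray:
    return stats.rankdata(pooled, method="average")


def wilcoxon_rank_sum(x, y, exact_limit: int = 12) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum test with midrank ties.

    ``W`` follows the convention of R's ``wilcox.test``: the rank sum of
    ``x`` minus ``n(n+1)/2`` (the Mann-Whitney U for x). For
    ``n + m <= exact_limit`` the p-value is computed by exact enumeration of
    all rank assignments (valid under ties because the pooled midranks are
    permuted); larger samples use the tie-corrected normal approximation
    with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = x.size, y.size
    if n == 0 or m == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    w_obs = float(ranks[:n].sum() - n * (n + 1) / 2.0)

    if n + m <= exact_limit:
        mu = n * m / 2.0
        dev_obs = abs(w_obs - mu)
        count = 0
        total = 0
        base = n * (n + 1) / 2.0
        for comb in itertools.combinations(range(n + m), n):
            w = float(ranks[list(comb)].sum() - base)
            if abs(w - mu) >= dev_obs - 1e-12:
                count += 1
            total += 1
        return RankSumResult(W=w_obs, pvalue=count / total, method="exact")

    mu = n * m / 2.0
    # tie correction on the variance
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    N = n + m
    var = n * m / 12.0 * ((N + 1) - tie_term / (N * (N - 1)))
    if var == 0:
        return RankSumResult(W=w_obs, pvalue=1.0, method="normal")
    z = (abs(w_obs - mu) - 0.5) / math.sqrt(var)
    p = 2.0 * stats.norm.sf(max(z, 0.0))
    return RankSumResult(W=w_obs, pvalue=min(p, 1.0), method="normal")


# ---------------------------------------------------------------------------
# expression and classification
# ---------------------------------------------------------------------------


def percent_gland_expression(tpm) -> pd.Series:
    """Percent of summed TPM attributable to each gland type (sums to 100)."""
    v = pd.Series(tpm, dtype=float)
    if (v < 0).any():
        raise ValueError("TPM values must be non-negative")
    total = float(v.sum())
    if total == 0:
        raise ValueError("percent expression undefined for an all-zero profile")
    return 100.0 * v / total


def possible_glue_classification(
    enriched: bool | None,
    modified_in_all_gf: bool | None,
    aggregate_expression_enriched: bool | None,
) -> str:
    """Classify a protein as ``PossibleGlue`` or ``Fiber``.

    PossibleGlue iff it is significantly more abundant in GlueFiber (FDR
    q < 0.05), OR PTM-modified in all GlueFiber samples, OR flagged as
    aggregate-gland expression-enriched by the (external) differential
    expression analysis. Missing evidence counts as negative.
    """
    flags = [
        bool(enriched) if enriched is not None else False,
        bool(modified_in_all_gf) if modified_in_all_gf is not None else False,
        (
            bool(aggregate_expression_enriched)
            if aggregate_expression_enriched is not None
            else False
        ),
    ]
    return "PossibleGlue" if any(flags) else "Fiber"


def compare_property_distributions(
    groups: dict[str, np.ndarray], bins: int = 30
) -> tuple[pd.DataFrame, dict[str, tuple[np.ndarray, np.ndarray]]]:
    """Pairwise rank-sum comparisons plus exportable histogram bins.

    ``groups`` maps a group name (e.g. PossibleGlue / Fiber / Proteome) to
    its property values. Returns (pairwise test table, per-group
    ``(counts, bin_edges)`` histograms on a common binning).
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    allv = np.concatenate([np.asarray(v, dtype=float) for v in groups.values()])
    edges = np.histogram_bin_edges(allv, bins=bins)
    hists = {
        name: np.histogram(np.asarray(v, dtype=float), bins=edges)
        for name, v in groups.items()
    }
    rows = []
    for (na, va), (nb, vb) in itertools.combinations(groups.items(), 2):
        res = wilcoxon_rank_sum(va, vb)
        rows.append(
            {
                "group_a": na,
                "group_b": nb,
                "W": res.W,
                "p": res.pvalue,
                "method": res.method,
            }
        )
    return pd.DataFrame(rows), hists
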