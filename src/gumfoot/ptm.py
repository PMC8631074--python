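"""Peptide-level post-translational modification (PTM) tabulation and tests.

Glue stickiness is thought to come largely from glycosylation (and, less
appreciated, phosphorylation) of the glue proteins. Peptides identified in
each sample type are pooled into four exclusive categories — unmodified,
glycosylated only, phosphorylated only, both — and modification enrichment
in GlueFiber versus Fiber is tested with Fisher's exact test on the
modified-vs-unmodified 2x2 table for each single modification. Peptides
carrying both modifications are excluded from each single-modification
table, which is what makes the odds ratios reproducible from the reported
category counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import contingency

__all__ = [
    "PTMCounts",
    "OddsRatioResult",
    "counts_from_table",
    "percent_modified",
    "fisher_exact_odds_ratio",
    "consistent_modification",
    "modification_report",
]


@dataclass(frozen=True)
class PTMCounts:
    """Pooled peptide counts for one sample type, four exclusive categories."""

    sample_type: str
    n_unmodified: int
    n_glycosylated: int
    n_phosphorylated: int
    n_both: int

    def __post_init__(self) -> None:
        for n in (
            self.n_unmodified,
            self.n_glycosylated,
            self.n_phosphorylated,
            self.n_both,
        ):
            if n < 0:
                raise ValueError("peptide counts must be non-negative")

    @property
    def total(self) -> int:
        return (
            self.n_unmodified
            + self.n_glycosylated
            + self.n_phosphorylated
            + self.n_both
        )


@dataclass(frozen=True)
class OddsRatioResult:
    """Fisher's exact test outcome for a 2x2 modified/unmodified table."""

    odds_ratio: float  # conditional MLE (exact-test convention)
    sample_odds_ratio: float  # cross-product ad/bc, for transparency
    pvalue: float  # two-sided exact p
    table: tuple[tuple[int, int], tuple[int, int]]


def counts_from_table(peptides: pd.DataFrame) -> dict[str, PTMCounts]:
    """Pool a per-sample peptide table into per-type category counts.

    ``peptides`` needs columns ``sample_type``, ``glycosylated``,
    ``phosphorylated`` (boolean). Counts pool peptides across samples of a
    type; each row is one observed peptide in one sample.
    """
    required = {"sample_type", "glycosylated", "phosphorylated"}
    missing = required - set(peptides.columns)
    if missing:
        raise ValueError(f"peptide table lacks columns: {sorted(missing)}")
    out = {}
    for stype, grp in peptides.groupby("sample_type"):
        g = grp["glycosylated"].astype(bool)
        p = grp["phosphorylated"].astype(bool)
        out[stype] = PTMCounts(
            sample_type=str(stype),
            n_unmodified=int((~g & ~p).sum()),
            n_glycosylated=int((g & ~p).sum()),
            n_phosphorylated=int((~g & p).sum()),
            n_both=int((g & p).sum()),
        )
    return out


def percent_modified(counts: PTMCounts) -> dict[str, float]:
    """Percentage of peptides in each modified category, of the pooled total.

    The denominator is the four-category total (unmodified + glycosylated +
    phosphorylated + both). Report tables round to one decimal.
    """
    if counts.total == 0:
        raise ValueError("percentages undefined for an empty peptide pool")
    t = counts.total
    return {
        "glycosylated": 100.0 * counts.n_glycosylated / t,
        "phosphorylated": 100.0 * counts.n_phosphorylated / t,
        "both": 100.0 * counts.n_both / t,
        "unmodified": 100.0 * counts.n_unmodified / t,
    }


def fisher_exact_odds_ratio(
    modified_gf: int,
    unmodified_gf: int,
    modified_f: int,
    unmodified_f: int,
) -> OddsRatioResult:
    """Fisher's exact test of modification enrichment in GlueFiber vs Fiber.

    The 2x2 table is [[modified_gf, unmodified_gf], [modified_f,
    unmodified_f]]. The reported odds ratio is the conditional maximum
    likelihood estimate under Fisher's noncentral hypergeometric model (the
    convention of R's ``fisher.test``); the sample (cross-product) OR is
    carried alongside.
    """
    table = np.array(
        [[modified_gf, unmodified_gf], [modified_f, unmodified_f]], dtype=int
    )
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("degenerate table: a zero margin")
    cond = contingency.odds_ratio(table, kind="conditional").statistic
    a, b = table[0]
    c, d = table[1]
    sample = np.inf if b * c == 0 else (a * d) / (b * c)
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return OddsRatioResult(
        odds_ratio=float(cond),
        sample_odds_ratio=float(sample),
        pvalue=float(p),
        table=((int(a), int(b)), (int(c), int(d))),
    )


def consistent_modification(flags, min_samples: int = 5) -> bool:
    """True iff a protein shows PTM evidence in >= ``min_samples`` GlueFiber
    samples (all six for the black widow design; at least five of six for
    the house spider design)."""
    flags = np.asarray(flags, dtype=bool)
    return int(flags.sum()) >= min_samples


def modification_report(counts: dict[str, PTMCounts]) -> pd.DataFrame:
    """Summary table mirroring the pooled-count report layout.

    One row per sample type: raw category counts with one-decimal rounded
    percentages of the pooled total.
    """
    rows = []
    for stype, c in counts.items():
        pct = percent_modified(c)
        rows.append(
            {
                "sample_type": stype,
                "unmodified": c.n_unmodified,
                "glycosylated": c.n_glycosylated,
                "glycosylated_pct": round(pct["glycosylated"], 1),
                "phosphorylated": c.n_phosphorylated,
                "phosphorylated_pct": round(pct["phosphorylated"], 1),
                "both": c.n_both,
                "both_pct": round(pct["both"], 1),
                "total": c.total,
            }
        )
    return pd.DataFrame(rows).set_index("sample_type")
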