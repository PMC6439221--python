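"""Post-processing of per-gene selection statistics.

Covers the statistics layer downstream of codon-model fitting: the
branch-site likelihood ratio test (model A versus the null with foreground
omega fixed at 1), Benjamini-Hochberg FDR adjustment, selection of pairwise
positively selected genes (omega > 1, adjusted p below alpha, not positively
selected in other lineages), and ranking of orthologs by between-lineage
divergence in omega, r = |log2(omega1 / omega2)|.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .msa_unique_residues import rank_top_fraction

__all__ = [
    "BranchSiteResult",
    "PairwiseOmegaRecord",
    "DivergenceRankRecord",
    "lrt_pvalue",
    "bh_adjust",
    "select_pairwise_psg",
    "branch_divergence_rank",
    "filter_by_alignment_length",
]


@dataclass(frozen=True)
class BranchSiteResult:
    """Null/alternative log-likelihoods of a branch-site test on one lineage."""

    gene_id: str
    lineage_id: str
    lnL_null: float
    lnL_alt: float
    df: int = 1


@dataclass(frozen=True)
class PairwiseOmegaRecord:
    """Pairwise dN/dS of a gene with optional raw and adjusted p-values."""

    gene_id: str
    omega: float
    p_raw: float | None = None
    p_adj: float | None = None


@dataclass(frozen=True)
class DivergenceRankRecord:
    """Per-gene omegas against a common outgroup for two sister lineages."""

    gene_id: str
    omega1: float  # focal vs outgroup
    omega2: float  # sister vs outgroup

    @property
    def r(self) -> float:
        return abs(math.log2(self.omega1 / self.omega2))


def lrt_pvalue(
    res: BranchSiteResult, *, mixture: bool = False
) -> float:
    """Upper-tail chi-square p-value of the likelihood ratio test.

    The statistic is 2 * max(0, lnL_alt - lnL_null); a negative delta (the
    alternative converged worse than the null) is clamped to 0, giving p = 1.
    With ``mixture=True`` the null is the 50:50 mixture of a point mass at 0
    and chi-square(df), halving the tail probability for positive statistics.
    """
    if not (math.isfinite(res.lnL_null) and math.isfinite(res.lnL_alt)):
        raise ValueError(f"non-finite log-likelihoods for {res.gene_id!r}")
    if res.df < 1:
        raise ValueError("df must be >= 1")
    stat = 2.0 * max(0.0, res.lnL_alt - res.lnL_null)
    if stat == 0.0:
        return 1.0
    p = float(stats.chi2.sf(stat, res.df))
    return 0.5 * p if mixture else p


def bh_adjust(p: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.size and (np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def select_pairwise_psg(
    records: Iterable[PairwiseOmegaRecord],
    alpha: float = 0.01,
    exclusion: Iterable[str] = (),
) -> list[str]:
    """Positively selected gene candidates from a pairwise omega screen.

    A gene is selected iff omega > 1, its BH-adjusted p is below ``alpha``,
    and it shows no sign of positive selection in other lineages
    (``exclusion`` holds gene ids positively selected elsewhere, typically at
    a looser alpha).
    """
    excl = set(exclusion)
    out = []
    for rec in records:
        if rec.p_adj is None:
            raise ValueError(f"record {rec.gene_id!r} lacks an adjusted p-value")
        if rec.omega > 1 and rec.p_adj < alpha and rec.gene_id not in excl:
            out.append(rec.gene_id)
    return out


def branch_divergence_rank(
    records: Iterable[DivergenceRankRecord],
    fraction: float = 0.05,
    *,
    require_focal_higher: bool = False,
    exclusion: Iterable[str] = (),
) -> list[str]:
    """Top fraction of genes by omega divergence r = |log2(omega1/omega2)|.

    Genes with a non-positive omega (log-ratio undefined, e.g. dS = 0 handled
    upstream) are skipped with a warning.  Ranking is descending in r with
    the deterministic ceil/tie rules of :func:`rank_top_fraction`.  With
    ``require_focal_higher`` the ranked cut is then restricted to genes with
    omega1 > omega2 and not in ``exclusion`` (cut first, subset second).
    """
    usable = []
    by_id = {}
    for rec in records:
        if rec.omega1 <= 0 or rec.omega2 <= 0:
            warnings.warn(
                f"gene {rec.gene_id!r} has non-positive omega; skipped",
                stacklevel=2,
            )
            continue
        usable.append((rec.gene_id, rec.r))
        by_id[rec.gene_id] = rec
    selected = rank_top_fraction(usable, fraction)
    if require_focal_higher:
        excl = set(exclusion)
        selected = [
            g
            for g in selected
            if by_id[g].omega1 > by_id[g].omega2 and g not in excl
        ]
    return selected


def filter_by_alignment_length(
    records: Iterable, lengths: dict[str, int], min_length: int = 150
) -> list:
    """Drop records whose codon alignment is shorter than ``min_length``.

    Mirrors the common practice of excluding short filtered alignments from
    dN/dS screens; records missing a length are kept.
    """
    return [
        r
        for r in records
        if lengths.get(r.gene_id) is None or lengths[r.gene_id] >= min_length
    ]
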