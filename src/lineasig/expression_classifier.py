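"""Threshold-based expression and differential-expression classification.

Designed for unreplicated RNA-seq tissue panels, where significance testing
is not possible and calls instead rest on stringent count thresholds:

* a gene is *expressed* in a tissue when its raw read count is at least
  ``expressed_min_reads`` (default 10);
* gonad contrast (testis vs ovary): differentially expressed when the raw
  count exceeds ``de_min_count`` (default 500) in one gonad, the gene is
  unexpressed in the other, and |log2FC| exceeds the gonad threshold;
* secretory-organ contrast (male vs female): differentially expressed when
  the raw count is at least ``de_min_count`` in either sample and |log2FC|
  exceeds the secretory threshold (no unexpressed requirement).

Fold changes are computed on median-of-ratios-normalized counts with a
pseudocount, an explicit stand-in for model-based normalization that keeps
the calls reproducible from the raw count matrix alone.  A four-set Venn
partition summarises expressed/DE gene sets across tissues.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "DEConfig",
    "DECall",
    "size_factors",
    "call_expressed",
    "log2fc",
    "de_calls",
    "venn_partition",
]


@dataclass(frozen=True)
class DEConfig:
    """Thresholds for expression and differential-expression calls.

    ``gonad_lfc_min`` defaults to 4; 10 reproduces the stricter variant used
    in some summaries of the gonad contrast.
    """

    expressed_min_reads: int = 10
    de_min_count: int = 500
    gonad_lfc_min: float = 4.0
    secretory_lfc_min: float = 4.0
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        for name in (
            "expressed_min_reads",
            "de_min_count",
            "gonad_lfc_min",
            "secretory_lfc_min",
            "pseudocount",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class DECall:
    """One differential-expression call within a two-tissue contrast."""

    gene_id: str
    contrast: str  # "gonad" | "secretory"
    direction: str  # "up_in_first" | "up_in_second"
    lfc: float


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factor per tissue column.

    Reference genes are those with nonzero counts in every tissue; each
    tissue's factor is the median over reference genes of the ratio of its
    count to the gene's geometric mean across tissues.  When no reference
    gene exists the factors fall back to library-size ratios (column sums
    scaled to geometric mean 1), with a warning.
    """
    mat = counts.to_numpy(dtype=float)
    ref = np.all(mat > 0, axis=1)
    if not ref.any():
        warnings.warn(
            "no gene has nonzero counts in all tissues; "
            "falling back to library-size factors",
            stacklevel=2,
        )
        libs = mat.sum(axis=0)
        if np.any(libs <= 0):
            raise ValueError("cannot compute size factors: empty library")
        factors = libs / np.exp(np.mean(np.log(libs)))
    else:
        refmat = mat[ref]
        geomean = np.exp(np.mean(np.log(refmat), axis=1))
        factors = np.median(refmat / geomean[:, None], axis=0)
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts divided column-wise by their median-of-ratios size factors."""
    return counts / size_factors(counts)


def call_expressed(
    counts: pd.DataFrame, cfg: DEConfig = DEConfig()
) -> pd.DataFrame:
    """Boolean gene x tissue matrix: raw count >= expressed_min_reads."""
    return counts >= cfg.expressed_min_reads


def log2fc(norm_a: float, norm_b: float, pseudocount: float = 1.0) -> float:
    """log2((a + pseudocount) / (b + pseudocount)) on normalized counts."""
    if norm_a < 0 or norm_b < 0:
        raise ValueError("normalized counts must be non-negative")
    return float(np.log2((norm_a + pseudocount) / (norm_b + pseudocount)))


def de_calls(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    contrast: str,
    cfg: DEConfig = DEConfig(),
) -> list[DECall]:
    """Differential-expression calls for a two-tissue contrast.

    ``counts`` is the raw gene x tissue matrix; ``meta`` is indexed by tissue
    id with a ``tissue_class`` column ("gonad" or "secretory").  Exactly two
    tissues of the requested class must exist; "first" and "second" follow
    their order in ``meta``.  Size factors are estimated from the full
    matrix, fold changes from the normalized pair with a pseudocount;
    the count and unexpressed thresholds apply to raw counts.
    """
    pair = [t for t in meta.index if meta.loc[t, "tissue_class"] == contrast]
    if len(pair) != 2:
        raise ValueError(
            f"contrast {contrast!r} needs exactly 2 tissues, found {len(pair)}"
        )
    a, b = pair
    norm = normalize(counts)
    calls = []
    for g in counts.index:
        ra, rb = counts.loc[g, a], counts.loc[g, b]
        lfc = log2fc(norm.loc[g, a], norm.loc[g, b], cfg.pseudocount)
        if contrast == "gonad":
            hit = (
                (ra > cfg.de_min_count and rb < cfg.expressed_min_reads)
                or (rb > cfg.de_min_count and ra < cfg.expressed_min_reads)
            ) and abs(lfc) > cfg.gonad_lfc_min
        elif contrast == "secretory":
            hit = (
                max(ra, rb) >= cfg.de_min_count
                and abs(lfc) > cfg.secretory_lfc_min
            )
        else:
            raise ValueError(f"unknown contrast {contrast!r}")
        if hit:
            direction = "up_in_first" if lfc > 0 else "up_in_second"
            calls.append(DECall(str(g), contrast, direction, lfc))
    return calls


def venn_partition(expressed_sets: Mapping[str, set]) -> dict[frozenset, int]:
    """Counts of the 15 nonempty-membership regions of four named sets.

    Keys are frozensets of set names (the region's exact membership); values
    sum to the size of the union.
    """
    names = list(expressed_sets)
    if len(names) != 4:
        raise ValueError(f"expected exactly 4 sets, got {len(names)}")
    regions = {
        frozenset(c): 0
        for k in range(1, 5)
        for c in itertools.combinations(names, k)
    }
    union = set().union(*expressed_sets.values())
    for g in union:
        member = frozenset(n for n in names if g in expressed_sets[n])
        regions[member] += 1
    return regions
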