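"""Sex-linked sequence discovery from alignment hit tables and RAD-tag matrices.

Under male heterogamety (XY) the Y-specific region of the genome is present
in the male assembly but absent from the female one.  This module implements
the comparative calls used to find it:

* filter pairwise local-alignment hits (PSL semantics) on match length,
  mismatch rate and query coverage;
* call a scaffold genome-specific when no retained hit from the other
  assembly covers it;
* sex-associate RAD-tags from a presence/absence matrix ("present in most
  of one sex, absent in most of the other"), optionally with a one-sided
  Fisher exact p-value;
* classify sex-associated tags by which scaffold class their best hits fall
  into;
* find autosomal paralogs of Y-candidate scaffolds from a
  specific-vs-remainder hit table;
* compute the repeat-masked percentage of a scaffold subset (Y-linked
  regions typically accumulate transposable elements).
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "AlignmentHit",
    "HitFilterConfig",
    "TagPresenceMatrix",
    "SpecificScaffoldSet",
    "filter_hits",
    "genome_specific_scaffolds",
    "sex_associated_tags",
    "classify_tag_hits",
    "paralog_candidates",
    "masked_fraction",
    "TAG_CATEGORIES",
]

TAG_CATEGORIES = (
    "male_specific_only",
    "male_specific_and_shared",
    "female_specific_only",
    "shared_only",
    "no_hit",
)


@dataclass(frozen=True)
class AlignmentHit:
    """One pairwise local-alignment record (PSL semantics, 0-based half-open)."""

    query_id: str
    target_id: str
    match_len: int
    mismatch_len: int
    query_size: int
    strand: str = "+"
    q_start: int = 0
    q_end: int = 0
    t_start: int = 0
    t_end: int = 0

    def __post_init__(self) -> None:
        if self.match_len < 0 or self.mismatch_len < 0:
            raise ValueError("match/mismatch lengths must be non-negative")
        if self.query_size <= 0:
            raise ValueError(f"query_size must be positive, got {self.query_size}")


@dataclass(frozen=True)
class HitFilterConfig:
    """Thresholds for hit retention.

    A hit is kept when match_len > min_match_len, mismatch_len / match_len <
    max_mismatch_rate, and match_len / query_size > min_coverage.
    """

    min_match_len: int = 100
    max_mismatch_rate: float = 0.03
    min_coverage: float = 0.10

    def __post_init__(self) -> None:
        if self.min_match_len <= 0:
            raise ValueError("min_match_len must be positive")
        if not 0 < self.max_mismatch_rate <= 1:
            raise ValueError("max_mismatch_rate must be in (0, 1]")
        if not 0 < self.min_coverage <= 1:
            raise ValueError("min_coverage must be in (0, 1]")


@dataclass(frozen=True)
class TagPresenceMatrix:
    """RAD-tag x sample boolean presence with per-sample sex labels."""

    tags: tuple[str, ...]
    samples: tuple[tuple[str, str], ...]  # (sample_id, "male" | "female")
    presence: np.ndarray  # bool, shape (n_tags, n_samples)

    def __post_init__(self) -> None:
        presence = np.asarray(self.presence, dtype=bool)
        object.__setattr__(self, "presence", presence)
        if presence.shape != (len(self.tags), len(self.samples)):
            raise ValueError(
                f"presence shape {presence.shape} inconsistent with "
                f"{len(self.tags)} tags x {len(self.samples)} samples"
            )
        sexes = {sex for _, sex in self.samples}
        if not sexes <= {"male", "female"}:
            raise ValueError(f"unknown sex labels: {sexes - {'male', 'female'}}")
        if sexes != {"male", "female"}:
            raise ValueError("need at least one sample of each sex")

    def sex_columns(self, sex: str) -> np.ndarray:
        return np.array([i for i, (_, s) in enumerate(self.samples) if s == sex])


@dataclass(frozen=True)
class SpecificScaffoldSet:
    """Scaffolds present in one assembly with no aligned counterpart in the other."""

    genome_label: str  # "male" | "female"
    scaffold_ids: frozenset[str]


def filter_hits(
    hits: Iterable[AlignmentHit],
    cfg: HitFilterConfig = HitFilterConfig(),
    *,
    literal_rate: bool = False,
) -> list[AlignmentHit]:
    """Retain hits passing the match-length / mismatch-rate / coverage filter.

    The mismatch rate is mismatch_len / match_len.  ``literal_rate=True``
    instead tests match_len / mismatch_len < max_mismatch_rate (the inverted
    reading; it retains almost nothing and exists for comparison only).
    Order is preserved.  A degenerate hit with match_len = 0 and
    mismatch_len > 0 is discarded with a warning rather than raising.
    """
    out = []
    for h in hits:
        if h.match_len == 0 and h.mismatch_len > 0:
            warnings.warn(
                f"hit {h.query_id}->{h.target_id} has zero match length; discarded",
                stacklevel=2,
            )
            continue
        if h.match_len <= cfg.min_match_len:
            continue
        if literal_rate:
            if h.mismatch_len == 0 or h.match_len / h.mismatch_len >= cfg.max_mismatch_rate:
                continue
        else:
            if h.mismatch_len / h.match_len >= cfg.max_mismatch_rate:
                continue
        if h.match_len / h.query_size <= cfg.min_coverage:
            continue
        out.append(h)
    return out


def _covered_fraction(hits: list[AlignmentHit], length: int) -> float:
    iv = sorted((h.t_start, h.t_end) for h in hits)
    total = 0
    cur_s, cur_e = None, None
    for s, e in iv:
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        total += cur_e - cur_s
    return total / length


def genome_specific_scaffolds(
    scaffolds: Mapping[str, int] | Iterable[str],
    retained_hits: Iterable[AlignmentHit],
    genome_label: str,
    *,
    min_covered_fraction: float | None = None,
) -> SpecificScaffoldSet:
    """Scaffolds of one assembly with no retained hit from the other covering them.

    ``scaffolds`` is the full scaffold set of the assembly under test (ids, or
    id -> length mapping); ``retained_hits`` are filtered hits from the OTHER
    assembly targeting this one.  By default "covered" means having at least
    one retained hit as target.  With ``min_covered_fraction`` set, a scaffold
    is instead non-specific only when the union of its hits' target intervals
    covers at least that fraction of its length (requires lengths).
    """
    if isinstance(scaffolds, Mapping):
        lengths = dict(scaffolds)
        ids = set(lengths)
    else:
        lengths = None
        ids = set(scaffolds)
    by_target: dict[str, list[AlignmentHit]] = {}
    for h in retained_hits:
        by_target.setdefault(h.target_id, []).append(h)
    if min_covered_fraction is None:
        specific = {s for s in ids if s not in by_target}
    else:
        if lengths is None:
            raise ValueError("min_covered_fraction requires scaffold lengths")
        specific = {
            s
            for s in ids
            if _covered_fraction(by_target.get(s, []), lengths[s])
            < min_covered_fraction
        }
    return SpecificScaffoldSet(genome_label, frozenset(specific))


def _fisher_one_sided(k_in: int, n_in: int, k_out: int, n_out: int) -> float:
    """One-sided Fisher exact p for enrichment of presence in the in-sex."""
    table = [[k_in, n_in - k_in], [k_out, n_out - k_out]]
    return float(stats.fisher_exact(table, alternative="greater")[1])


def sex_associated_tags(
    m: TagPresenceMatrix,
    min_in: int | None = None,
    max_out: int | None = None,
    *,
    test: bool = False,
) -> list[tuple[str, str, float | None]]:
    """Tags present in most samples of one sex and almost no samples of the other.

    A tag is male-associated when present in >= ``min_in`` males and <=
    ``max_out`` females (female-associated symmetrically).  Defaults are
    min_in = ceil(0.8 * n_sex) and max_out = floor(0.08 * n_other_sex),
    chosen so a 25 + 25 design calls tags present in >= 20 of one sex and
    <= 2 of the other.  With ``test=True`` each call carries a one-sided
    Fisher exact p-value from its 2x2 presence table.

    Returns (tag_id, "male" | "female", p or None) in tag order.
    """
    males = m.sex_columns("male")
    females = m.sex_columns("female")
    n_m, n_f = len(males), len(females)

    def bounds(n_in: int, n_out: int) -> tuple[int, int]:
        lo = math.ceil(0.8 * n_in) if min_in is None else min_in
        hi = math.floor(0.08 * n_out) if max_out is None else max_out
        if lo > n_in:
            raise ValueError(f"min_in={lo} exceeds {n_in} samples of that sex")
        if hi < 0:
            raise ValueError("max_out must be >= 0")
        return lo, hi

    lo_m, hi_m = bounds(n_m, n_f)
    lo_f, hi_f = bounds(n_f, n_m)

    in_m = m.presence[:, males].sum(axis=1)
    in_f = m.presence[:, females].sum(axis=1)
    out = []
    for t, km, kf in zip(m.tags, in_m, in_f):
        if km >= lo_m and kf <= hi_m:
            p = _fisher_one_sided(int(km), n_m, int(kf), n_f) if test else None
            out.append((t, "male", p))
        elif kf >= lo_f and km <= hi_f:
            p = _fisher_one_sided(int(kf), n_f, int(km), n_m) if test else None
            out.append((t, "female", p))
    return out


def classify_tag_hits(
    tag_best_hits: Mapping[str, Iterable[str]],
    male_specific: Iterable[str],
    female_specific: Iterable[str] = (),
) -> tuple[dict[str, str], Counter]:
    """Assign each tag one of five categories from the scaffolds its best hits reach.

    Categories: male_specific_only, male_specific_and_shared,
    female_specific_only, shared_only, no_hit.  A tag reaching both a
    male-specific scaffold and any other scaffold is
    male_specific_and_shared.
    """
    ms = set(male_specific)
    fs = set(female_specific)
    categories: dict[str, str] = {}
    for tag, targets in tag_best_hits.items():
        targets = set(targets)
        if not targets:
            cat = "no_hit"
        else:
            hit_m = bool(targets & ms)
            hit_other = bool(targets - ms)
            if hit_m and hit_other:
                cat = "male_specific_and_shared"
            elif hit_m:
                cat = "male_specific_only"
            elif targets <= fs:
                cat = "female_specific_only"
            else:
                cat = "shared_only"
        categories[tag] = cat
    return categories, Counter(categories.values())


def paralog_candidates(
    hits: Iterable[AlignmentHit],
) -> tuple[list[tuple[str, str, int]], list[str]]:
    """Best autosomal paralog per Y-candidate scaffold.

    ``hits`` align male-specific scaffolds (queries) against the remainder of
    the male assembly (targets), already filtered.  For each query the
    best-scoring hit (maximal match_len, ties by ascending target id) is
    kept.  Returns (pairs, deduplicated target list); pairs are
    (y_scaffold, paralog_scaffold, match_len) sorted by y_scaffold.
    """
    best: dict[str, AlignmentHit] = {}
    for h in hits:
        cur = best.get(h.query_id)
        if (
            cur is None
            or h.match_len > cur.match_len
            or (h.match_len == cur.match_len and h.target_id < cur.target_id)
        ):
            best[h.query_id] = h
    pairs = sorted(
        (q, h.target_id, h.match_len) for q, h in best.items()
    )
    targets = sorted({t for _, t, _ in pairs})
    return pairs, targets


def masked_fraction(
    repeat_intervals: Mapping[str, Sequence[tuple[int, int]]],
    scaffold_lengths: Mapping[str, int],
    scaffold_subset: Iterable[str],
) -> float:
    """Percentage of a scaffold subset covered by repeat intervals.

    Intervals are 0-based half-open per scaffold; overlaps are merged so each
    base is counted once.  Returns 100 * union_length / total_subset_length.
    """
    subset = list(scaffold_subset)
    total = 0
    masked = 0
    for s in subset:
        length = scaffold_lengths[s]
        total += length
        iv = sorted(tuple(x) for x in repeat_intervals.get(s, ()))
        cur_s = cur_e = None
        for a, b in iv:
            if not (0 <= a <= b <= length):
                raise ValueError(
                    f"interval [{a}, {b}) out of bounds for {s!r} (length {length})"
                )
            if cur_e is None or a > cur_e:
                if cur_e is not None:
                    masked += cur_e - cur_s
                cur_s, cur_e = a, b
            else:
                cur_e = max(cur_e, b)
        if cur_e is not None:
            masked += cur_e - cur_s
    if total == 0:
        raise ValueError("empty scaffold subset")
    return 100.0 * masked / total
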