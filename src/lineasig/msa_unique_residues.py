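"""Detection and conservation-weighted scoring of lineage-unique residues.

Given a gap-free multiple protein alignment with one designated focal taxon,
a *unique residue* is an alignment column where the focal taxon's amino acid
occurs in no other row.  Each unique residue at 0-based column ``p`` receives
a score built from the per-column variability ``V_i`` (number of distinct
residue letters in column ``i``) over a +/-25-column window::

    S(p) = sum_{i in W(p)} V_i * (|i - p| / 10 + 1)^(-2),
    W(p) = [max(0, p - 25), min(l - 1, p + 25)]

where ``l`` is the alignment length.  The window term at ``i = p`` has weight
exactly 1.  A protein's score is the sum of its unique-residue scores divided
by ``l``.  Residue and protein lists are ranked in descending score order and
the top fraction retained.

As printed, the score grows with flanking variability.  The accompanying
narrative interpretation is the opposite — conserved flanks should make a
unique substitution more notable — so every scoring entry point accepts
``conservation_transform=True``, which substitutes ``n_rows - V_i + 1`` for
``V_i`` (a column where all rows agree then contributes the most).  The
default is the literal formula.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Alignment",
    "ResidueScore",
    "ProteinScoreRecord",
    "InsufficientTaxaError",
    "NoUngappedColumnsError",
    "WINDOW_RADIUS",
    "remove_gap_columns",
    "column_variability",
    "find_unique_residues",
    "score_residue",
    "score_protein",
    "rank_top_fraction",
]

#: half-width of the scoring window, in alignment columns
WINDOW_RADIUS = 25

#: characters treated as alignment gaps
GAP_CHARS = frozenset("-.")


class InsufficientTaxaError(ValueError):
    """Raised when an alignment has too few rows for unique-residue calling."""


class NoUngappedColumnsError(ValueError):
    """Raised when gap removal would discard every column."""


@dataclass(frozen=True)
class Alignment:
    """A multiple protein alignment with one designated focal row.

    Parameters
    ----------
    protein_id : str
        Identifier of the homolog group / protein.
    rows : sequence of (taxon_id, sequence)
        Ordered alignment rows; all sequences must have equal length and
        exactly one ``taxon_id`` must equal ``focal_taxon``.
    focal_taxon : str
        The lineage whose unique residues are sought.
    """

    protein_id: str
    rows: tuple[tuple[str, str], ...]
    focal_taxon: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "rows", tuple((t, s.upper()) for t, s in self.rows))
        if not self.rows:
            raise ValueError("alignment has no rows")
        lengths = {len(s) for _, s in self.rows}
        if len(lengths) != 1:
            raise ValueError(f"rows have unequal lengths: {sorted(lengths)}")
        n_focal = sum(1 for t, _ in self.rows if t == self.focal_taxon)
        if n_focal != 1:
            raise ValueError(
                f"expected exactly one row for focal taxon {self.focal_taxon!r}, found {n_focal}"
            )

    @property
    def l(self) -> int:
        """Alignment length (number of columns)."""
        return len(self.rows[0][1])

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def focal_sequence(self) -> str:
        return next(s for t, s in self.rows if t == self.focal_taxon)

    def column(self, i: int) -> str:
        return "".join(s[i] for _, s in self.rows)

    def has_gaps(self) -> bool:
        return any(any(c in GAP_CHARS for c in s) for _, s in self.rows)

    def _require_gap_free(self) -> None:
        if self.has_gaps():
            raise ValueError(
                f"alignment {self.protein_id!r} contains gap characters; "
                "run remove_gap_columns first"
            )


@dataclass(frozen=True)
class ResidueScore:
    """Score of a single focal-unique residue at 0-based column ``p``."""

    protein_id: str
    p: int
    focal_residue: str
    score: float


@dataclass(frozen=True)
class ProteinScoreRecord:
    """Per-protein summary: unique residues and the length-normalized score S."""

    protein_id: str
    residue_scores: tuple[ResidueScore, ...]
    S: float

    @property
    def n_unique(self) -> int:
        return len(self.residue_scores)


def remove_gap_columns(aln: Alignment, mode: str = "any") -> Alignment:
    """Drop gapped columns from an alignment.

    mode="any" (default) drops every column containing a gap character in any
    row; mode="focal" drops only columns gapped in the focal row.
    """
    if mode not in ("any", "focal"):
        raise ValueError(f"unknown gap-removal mode {mode!r}")
    seqs = [s for _, s in aln.rows]
    if mode == "any":
        keep = [
            i for i in range(aln.l) if not any(s[i] in GAP_CHARS for s in seqs)
        ]
    else:
        focal = aln.focal_sequence
        keep = [i for i in range(aln.l) if focal[i] not in GAP_CHARS]
    if not keep:
        raise NoUngappedColumnsError(
            f"alignment {aln.protein_id!r} has no ungapped columns"
        )
    rows = tuple(
        (t, "".join(s[i] for i in keep)) for t, s in aln.rows
    )
    return Alignment(aln.protein_id, rows, aln.focal_taxon)


def column_variability(aln: Alignment) -> np.ndarray:
    """Number of distinct residue letters in each column (vector V, length l)."""
    aln._require_gap_free()
    arr = np.array([list(s) for _, s in aln.rows])
    return np.array([len(set(arr[:, i])) for i in range(arr.shape[1])], dtype=int)


def find_unique_residues(aln: Alignment) -> list[tuple[int, str]]:
    """Columns where the focal letter occurs in no other row.

    Returns a list of (p, focal_residue), p 0-based ascending.  Other rows
    need not agree with each other.  Requires at least three rows: with two
    rows every difference is trivially "unique" in both directions and the
    notion of a lineage-specific substitution is meaningless.
    """
    aln._require_gap_free()
    if aln.n_rows < 3:
        raise InsufficientTaxaError(
            f"alignment {aln.protein_id!r} has {aln.n_rows} rows; need >= 3"
        )
    focal = aln.focal_sequence
    others = [s for t, s in aln.rows if t != aln.focal_taxon]
    out = []
    for p in range(aln.l):
        c = focal[p]
        if all(s[p] != c for s in others):
            out.append((p, c))
    return out


def _window_weights(p: int, l: int) -> tuple[int, int, np.ndarray]:
    lo = max(0, p - WINDOW_RADIUS)
    hi = min(l - 1, p + WINDOW_RADIUS)
    i = np.arange(lo, hi + 1)
    w = (np.abs(i - p) / 10.0 + 1.0) ** -2
    return lo, hi, w


def score_residue(
    variability: Sequence[int] | np.ndarray,
    p: int,
    *,
    conservation_transform: bool = False,
    n_rows: int | None = None,
) -> float:
    """Conservation-weighted score S(p) of a residue at column ``p``.

    Parameters
    ----------
    variability : array of int
        Per-column distinct-letter counts V, length l.
    p : int
        0-based column index, 0 <= p < l.
    conservation_transform : bool
        If True, score with ``n_rows - V_i + 1`` in place of ``V_i`` so that
        conserved flanks raise the score; requires ``n_rows``.
    """
    V = np.asarray(variability, dtype=float)
    l = V.shape[0]
    if not 0 <= p < l:
        raise IndexError(f"column index {p} out of range for length {l}")
    if conservation_transform:
        if n_rows is None:
            raise ValueError("conservation_transform requires n_rows")
        V = n_rows - V + 1
    lo, hi, w = _window_weights(p, l)
    return float(np.dot(V[lo : hi + 1], w))


def score_protein(
    aln: Alignment, *, conservation_transform: bool = False
) -> ProteinScoreRecord:
    """Score a protein: S = sum of its unique-residue scores S(p), divided by l.

    A protein with no unique residues gets S = 0.
    """
    V = column_variability(aln)
    unique = find_unique_residues(aln)
    scores = tuple(
        ResidueScore(
            aln.protein_id,
            p,
            res,
            score_residue(
                V,
                p,
                conservation_transform=conservation_transform,
                n_rows=aln.n_rows,
            ),
        )
        for p, res in unique
    )
    S = sum(r.score for r in scores) / aln.l
    return ProteinScoreRecord(aln.protein_id, scores, S)


def rank_top_fraction(
    items: Iterable[tuple[str, float]], fraction: float
) -> list[str]:
    """Keep the ids of the top ``ceil(fraction * n)`` items by descending score.

    Ties at the cutoff are broken by ascending id so the selection is
    deterministic and invariant under input order.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    items = list(items)
    if not items:
        return []
    for _id, score in items:
        if not math.isfinite(score):
            raise ValueError(f"non-finite score for {_id!r}")
    k = math.ceil(fraction * len(items))
    ranked = sorted(items, key=lambda t: (-t[1], t[0]))
    return [i for i, _ in ranked[:k]]
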