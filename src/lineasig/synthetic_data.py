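"""Seeded generators of benchmark inputs with known ground truth.

Each generator emulates one input of the comparative-genomics pipeline and
returns, along with the data, a :class:`SimTruth` recording exactly what was
planted, so recovery can be measured:

* :func:`simulate_msa` — a 12-taxon gap-free protein alignment with
  focal-unique residues planted at chosen columns and a per-column
  variability profile elsewhere;
* :func:`simulate_genome_pair` — a male/female assembly pair sharing
  autosomal scaffolds (with per-base divergence) plus planted sex-only
  scaffolds, and the reciprocal alignment hit tables the construction
  implies (no aligner is run: hit match/mismatch lengths are written from
  the realized mutations);
* :func:`simulate_radtag_matrix` — RAD-tag presence/absence under an XY
  model with dropout and a female leak-through error rate;
* :func:`simulate_count_table` — negative-binomial gene x tissue counts
  with planted sex-biased or sex-exclusive genes.

One integer seed drives a named per-generator substream (the seed sequence
is keyed on the generator name), so adding a generator never perturbs the
output of the others, and the same seed always yields byte-identical
artifacts.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .msa_unique_residues import Alignment
from .sexlink_discovery import AlignmentHit, TagPresenceMatrix

__all__ = [
    "SimTruth",
    "simulate_msa",
    "simulate_genome_pair",
    "simulate_radtag_matrix",
    "simulate_count_table",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
NUCLEOTIDES = "ACGT"


@dataclass(frozen=True)
class SimTruth:
    """Ground truth of one simulated dataset."""

    seed: int
    planted_unique_positions: dict[str, tuple[int, ...]] = field(default_factory=dict)
    planted_male_scaffold_ids: tuple[str, ...] = ()
    planted_female_scaffold_ids: tuple[str, ...] = ()
    planted_ylinked_tag_ids: tuple[str, ...] = ()
    planted_de_gene_ids: dict[str, float] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _rng(seed: int, stream: str) -> np.random.Generator:
    """Named substream: generator keyed on (seed, crc32(stream name))."""
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, zlib.crc32(stream.encode())])


def simulate_msa(
    n_taxa: int = 12,
    length: int = 500,
    flank_variability_profile: int | Sequence[int] = 1,
    planted_positions: Sequence[int] = (),
    seed: int = 0,
    *,
    protein_id: str = "sim_prot",
    focal_taxon: str = "focal",
) -> tuple[Alignment, SimTruth]:
    """Gap-free protein alignment with focal-unique residues planted.

    At each planted column the focal row carries a letter absent from every
    other row.  At other columns the requested number of distinct letters is
    realized and, whenever that number is below ``n_taxa``, the focal letter
    is guaranteed to occur in at least one other row (so the column is not
    unique).  A column whose profile value equals ``n_taxa`` necessarily has
    all rows distinct, making the focal letter unique there as well; profiles
    at ``n_taxa`` are therefore only meaningful for column-census checks.

    The profile is an integer (uniform) or a length-``length`` sequence of
    per-column distinct-letter targets; planted columns realize
    profile-value + 1 distinct letters when the profile is 1 (conserved
    flanks), and in general min(profile, n_taxa - 1) letters among the
    non-focal rows plus the focal's private letter.
    """
    if n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    if n_taxa > len(AMINO_ACIDS):
        raise ValueError(f"n_taxa must be <= {len(AMINO_ACIDS)}")
    profile = np.broadcast_to(
        np.asarray(flank_variability_profile, dtype=int), (length,)
    ).copy()
    if np.any(profile < 1) or np.any(profile > len(AMINO_ACIDS)):
        raise ValueError(
            f"variability profile values must be in [1, {len(AMINO_ACIDS)}]"
        )
    if np.any(profile > n_taxa):
        raise ValueError("profile cannot demand more distinct letters than taxa")
    planted = sorted(set(int(p) for p in planted_positions))
    if planted and not (0 <= planted[0] and planted[-1] < length):
        raise ValueError("planted positions must lie in [0, length)")

    rng = _rng(seed, "msa")
    aa = np.array(list(AMINO_ACIDS))
    n_other = n_taxa - 1
    planted_set = set(planted)
    cols = np.empty((length, n_taxa), dtype="<U1")
    for i in range(length):
        v = int(profile[i])
        if i in planted_set:
            # focal gets a private letter; others realize min(v, n_taxa-1) letters
            v_other = min(v, n_other)
            letters = rng.choice(len(aa), size=v_other + 1, replace=False)
            focal_letter = letters[0]
            other_letters = letters[1:]
            col_other = _fill_column(rng, other_letters, n_other)
            cols[i] = np.concatenate(([aa[focal_letter]], aa[col_other]))
        else:
            letters = rng.choice(len(aa), size=v, replace=False)
            if v < n_taxa:
                # focal shares letters[0]; one other row forced to letters[0]
                col_other = _fill_column(rng, letters, n_other, force_first=True)
                cols[i] = np.concatenate(([aa[letters[0]]], aa[col_other]))
            else:
                # all rows distinct: uniqueness unavoidable
                perm = rng.permutation(letters)
                cols[i] = aa[perm]
    taxa = [focal_taxon] + [f"taxon_{j:02d}" for j in range(1, n_taxa)]
    rows = tuple(
        (taxa[j], "".join(cols[:, j])) for j in range(n_taxa)
    )
    aln = Alignment(protein_id, rows, focal_taxon)
    truth = SimTruth(
        seed=seed,
        planted_unique_positions={protein_id: tuple(planted)},
    )
    return aln, truth


def _fill_column(
    rng: np.random.Generator,
    letters: np.ndarray,
    n_rows: int,
    *,
    force_first: bool = False,
) -> np.ndarray:
    """Assign len(letters) distinct letter indices across n_rows rows.

    Every letter appears at least once; with force_first, letters[0] is
    additionally guaranteed (it already is by the former rule).
    """
    v = len(letters)
    if v > n_rows:
        raise ValueError("more letters than rows")
    col = np.empty(n_rows, dtype=letters.dtype)
    # one slot per letter, remaining slots drawn uniformly from the letters
    slots = rng.permutation(n_rows)
    col[slots[:v]] = letters
    if n_rows > v:
        col[slots[v:]] = rng.choice(letters, size=n_rows - v, replace=True)
    if force_first and not np.any(col == letters[0]):  # pragma: no cover
        col[slots[0]] = letters[0]
    return col


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list(NUCLEOTIDES))[rng.integers(0, 4, size=length)])


def _mutate(rng: np.random.Generator, seq: str, divergence: float) -> tuple[str, int]:
    """Per-base substitution with probability ``divergence``; returns (seq, n_mut)."""
    if divergence == 0:
        return seq, 0
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < divergence
    n = int(hit.sum())
    if n:
        for i in np.flatnonzero(hit):
            choices = [c for c in NUCLEOTIDES if c != arr[i]]
            arr[i] = choices[rng.integers(0, 3)]
    return "".join(arr), n


def simulate_genome_pair(
    n_shared: int = 100,
    shared_len: int = 1000,
    divergence: float = 0.0,
    n_male_only: int = 12,
    n_female_only: int = 0,
    seed: int = 0,
) -> tuple[dict[str, str], dict[str, str], list[AlignmentHit], list[AlignmentHit], SimTruth]:
    """Male/female assembly pair with shared autosomes and planted sex-only scaffolds.

    Shared scaffolds are per-base mutated copies between the assemblies;
    sex-only scaffolds are independent random sequence present in one
    assembly only.  Returns (male_scaffolds, female_scaffolds,
    hits_female_onto_male, hits_male_onto_female, truth).  Each shared pair
    contributes one full-length hit per direction whose match/mismatch
    lengths reflect the realized substitutions; sex-only scaffolds appear in
    no hit.
    """
    if not 0 <= divergence <= 0.2:
        raise ValueError("divergence must be in [0, 0.2]")
    rng = _rng(seed, "genome_pair")
    male: dict[str, str] = {}
    female: dict[str, str] = {}
    hits_f2m: list[AlignmentHit] = []  # queries female, targets male
    hits_m2f: list[AlignmentHit] = []
    for i in range(n_shared):
        f_id, m_id = f"f_scf_{i:04d}", f"m_scf_{i:04d}"
        f_seq = _random_seq(rng, shared_len)
        m_seq, n_mut = _mutate(rng, f_seq, divergence)
        female[f_id] = f_seq
        male[m_id] = m_seq
        match = shared_len - n_mut
        common = dict(
            match_len=match,
            mismatch_len=n_mut,
            query_size=shared_len,
            strand="+",
            q_start=0,
            q_end=shared_len,
            t_start=0,
            t_end=shared_len,
        )
        hits_f2m.append(AlignmentHit(f_id, m_id, **common))
        hits_m2f.append(AlignmentHit(m_id, f_id, **common))
    male_only = tuple(f"m_y_{i:04d}" for i in range(n_male_only))
    for s in male_only:
        male[s] = _random_seq(rng, shared_len)
    female_only = tuple(f"f_w_{i:04d}" for i in range(n_female_only))
    for s in female_only:
        female[s] = _random_seq(rng, shared_len)
    truth = SimTruth(
        seed=seed,
        planted_male_scaffold_ids=male_only,
        planted_female_scaffold_ids=female_only,
    )
    return male, female, hits_f2m, hits_m2f, truth


def simulate_radtag_matrix(
    n_tags: int = 10_000,
    n_males: int = 25,
    n_females: int = 25,
    n_ylinked: int = 30,
    dropout: float = 0.0,
    error: float = 0.0,
    seed: int = 0,
) -> tuple[TagPresenceMatrix, SimTruth]:
    """RAD-tag presence/absence under an XY model.

    Y-linked tags are present in each male with probability 1 - dropout and
    in each female with probability ``error``; autosomal tags are present in
    every sample with probability 1 - dropout.
    """
    if not (0 <= dropout < 1 and 0 <= error < 1):
        raise ValueError("rates must be in [0, 1)")
    if n_ylinked > n_tags:
        raise ValueError("n_ylinked cannot exceed n_tags")
    rng = _rng(seed, "radtags")
    n_samples = n_males + n_females
    tags = tuple(f"tag_{i:06d}" for i in range(n_tags))
    samples = tuple(
        [(f"male_{i:02d}", "male") for i in range(n_males)]
        + [(f"female_{i:02d}", "female") for i in range(n_females)]
    )
    presence = rng.random((n_tags, n_samples)) < (1.0 - dropout)
    y_idx = np.arange(n_ylinked)  # first n_ylinked tags are Y-linked
    female_cols = np.arange(n_males, n_samples)
    presence[np.ix_(y_idx, female_cols)] = (
        rng.random((n_ylinked, n_females)) < error
    )
    truth = SimTruth(
        seed=seed, planted_ylinked_tag_ids=tuple(tags[i] for i in y_idx)
    )
    return TagPresenceMatrix(tags, samples, presence), truth


DEFAULT_TISSUE_DESIGN: tuple[tuple[str, str, str], ...] = (
    ("testis", "gonad", "male"),
    ("ovary", "gonad", "female"),
    ("secretory_male", "secretory", "male"),
    ("secretory_female", "secretory", "female"),
)


def simulate_count_table(
    n_genes: int = 2000,
    tissue_design: Sequence[tuple[str, str, str]] = DEFAULT_TISSUE_DESIGN,
    planted_de: Mapping[str, tuple[str, float]] | None = None,
    nb_dispersion: float = 0.05,
    library_sizes: Mapping[str, float] | None = None,
    base_mean: float = 100.0,
    seed: int = 0,
):
    """Negative-binomial gene x tissue count matrix with planted sex-biased genes.

    ``tissue_design`` lists (tissue_id, tissue_class, sex).  ``planted_de``
    maps a gene id (``gene_000000`` style, within range) to (up_tissue,
    fold); fold = inf plants an exclusive gene — mean ``base_mean * 10`` in
    the up tissue and exactly 0 in the paired tissue of the same class and
    opposite sex.  Finite folds scale the up tissue's mean by ``fold``.
    Counts are Gamma-Poisson with variance mu + dispersion * mu^2;
    dispersion 0 degenerates to Poisson.  ``library_sizes`` multiplies each
    tissue's means.

    Returns (counts DataFrame, meta DataFrame indexed by tissue with
    tissue_class and sex columns, SimTruth).
    """
    import pandas as pd

    if nb_dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    planted_de = dict(planted_de or {})
    rng = _rng(seed, "counts")
    tissues = [t for t, _, _ in tissue_design]
    meta = pd.DataFrame(
        {
            "tissue_class": [c for _, c, _ in tissue_design],
            "sex": [s for _, _, s in tissue_design],
        },
        index=pd.Index(tissues, name="tissue"),
    )
    genes = [f"gene_{i:06d}" for i in range(n_genes)]
    gene_pos = {g: i for i, g in enumerate(genes)}
    lib = np.array([(library_sizes or {}).get(t, 1.0) for t in tissues])

    partner = {}
    for t, c, s in tissue_design:
        mates = [t2 for t2, c2, s2 in tissue_design if c2 == c and t2 != t]
        partner[t] = mates[0] if len(mates) == 1 else None

    mu = np.full((n_genes, len(tissues)), base_mean, dtype=float)
    truth_fc: dict[str, float] = {}
    for g, (up_tissue, fold) in planted_de.items():
        if g not in gene_pos:
            raise ValueError(f"planted gene {g!r} not in matrix")
        if fold <= 0:
            raise ValueError("fold changes must be > 0")
        i = gene_pos[g]
        j = tissues.index(up_tissue)
        if np.isinf(fold):
            mu[i, j] = base_mean * 10
            mate = partner[up_tissue]
            if mate is not None:
                mu[i, tissues.index(mate)] = 0.0
        else:
            mu[i, j] = base_mean * fold
        truth_fc[g] = float(fold)
    mu = mu * lib[None, :]

    if nb_dispersion == 0:
        counts = rng.poisson(mu)
    else:
        shape = 1.0 / nb_dispersion
        lam = np.zeros_like(mu)
        pos = mu > 0
        lam[pos] = rng.gamma(shape, mu[pos] / shape)
        counts = rng.poisson(lam)
    df = pd.DataFrame(counts, index=pd.Index(genes, name="gene"), columns=tissues)
    truth = SimTruth(seed=seed, planted_de_gene_ids=truth_fc)
    return df, meta, truth
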