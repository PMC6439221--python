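"""Readers and writers for the tabular and sequence formats the pipeline consumes.

FASTA goes through Biopython; PSL (blat's 21-column pairwise-alignment
table, with or without the psLayout header) is parsed directly; everything
else is header-bearing TSV via pandas.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .msa_unique_residues import Alignment
from .sexlink_discovery import AlignmentHit, TagPresenceMatrix

__all__ = [
    "read_alignment_fasta",
    "write_alignment_fasta",
    "write_genome_fasta",
    "read_psl",
    "write_psl",
    "read_scaffold_lengths",
    "read_tag_matrix",
    "write_tag_matrix",
    "read_counts",
    "read_tissue_meta",
    "read_intervals_bed",
    "read_intervals_rmout",
]

PSL_COLUMNS = 21


def read_alignment_fasta(
    path: str | os.PathLike, focal_taxon: str, protein_id: str | None = None
) -> Alignment:
    """Read one aligned FASTA file as an :class:`Alignment`.

    Record ids are taxon ids; the protein id defaults to the file stem.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no sequences in {path}")
    if protein_id is None:
        protein_id = os.path.splitext(os.path.basename(str(path)))[0]
    rows = tuple((r.id, str(r.seq)) for r in records)
    return Alignment(protein_id, rows, focal_taxon)


def write_alignment_fasta(aln: Alignment, path: str | os.PathLike) -> None:
    records = [
        SeqRecord(Seq(s), id=t, description="") for t, s in aln.rows
    ]
    SeqIO.write(records, str(path), "fasta")


def write_genome_fasta(scaffolds: Mapping[str, str], path: str | os.PathLike) -> None:
    records = [
        SeqRecord(Seq(s), id=name, description="")
        for name, s in scaffolds.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_psl(path: str | os.PathLike) -> list[AlignmentHit]:
    """Parse a PSL file (blat dialect), skipping a psLayout header if present."""
    hits = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 17:
                continue  # header / separator lines
            try:
                matches = int(parts[0])
            except ValueError:
                continue  # psLayout column-name lines
            hits.append(
                AlignmentHit(
                    query_id=parts[9],
                    target_id=parts[13],
                    match_len=matches,
                    mismatch_len=int(parts[1]),
                    query_size=int(parts[10]),
                    strand=parts[8],
                    q_start=int(parts[11]),
                    q_end=int(parts[12]),
                    t_start=int(parts[15]),
                    t_end=int(parts[16]),
                )
            )
    return hits


def write_psl(
    hits: Iterable[AlignmentHit],
    path: str | os.PathLike,
    target_sizes: Mapping[str, int] | None = None,
) -> None:
    """Write hits as headerless 21-column PSL (single-block records)."""
    with open(path, "w") as fh:
        for h in hits:
            tsize = (target_sizes or {}).get(h.target_id, h.t_end)
            block = h.q_end - h.q_start
            fields = [
                h.match_len, h.mismatch_len, 0, 0, 0, 0, 0, 0,
                h.strand, h.query_id, h.query_size, h.q_start, h.q_end,
                h.target_id, tsize, h.t_start, h.t_end,
                1, f"{block},", f"{h.q_start},", f"{h.t_start},",
            ]
            fh.write("\t".join(str(f) for f in fields) + "\n")


def read_scaffold_lengths(path: str | os.PathLike) -> dict[str, int]:
    """Scaffold lengths from a two-column TSV or a samtools .fai index."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    return dict(zip(df[0].astype(str), df[1].astype(int)))


def read_tag_matrix(
    matrix_path: str | os.PathLike, sex_map_path: str | os.PathLike
) -> TagPresenceMatrix:
    """Tag x sample 0/1 TSV (first column tag id) plus sample->sex map TSV."""
    df = pd.read_csv(matrix_path, sep="\t", index_col=0)
    sex_map = pd.read_csv(sex_map_path, sep="\t", index_col=0).iloc[:, 0]
    samples = tuple((str(s), str(sex_map[s])) for s in df.columns)
    return TagPresenceMatrix(
        tuple(str(t) for t in df.index), samples, df.to_numpy(dtype=bool)
    )


def write_tag_matrix(
    m: TagPresenceMatrix,
    matrix_path: str | os.PathLike,
    sex_map_path: str | os.PathLike,
) -> None:
    df = pd.DataFrame(
        m.presence.astype(int),
        index=pd.Index(m.tags, name="tag_id"),
        columns=[s for s, _ in m.samples],
    )
    df.to_csv(matrix_path, sep="\t")
    pd.DataFrame(
        {"sex": [sex for _, sex in m.samples]},
        index=pd.Index([s for s, _ in m.samples], name="sample_id"),
    ).to_csv(sex_map_path, sep="\t")


def read_counts(path: str | os.PathLike) -> pd.DataFrame:
    """Gene x tissue raw count matrix (TSV, first column gene id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    return df


def read_tissue_meta(path: str | os.PathLike) -> pd.DataFrame:
    """Tissue metadata TSV indexed by tissue id, with tissue_class and sex."""
    meta = pd.read_csv(path, sep="\t", index_col=0)
    missing = {"tissue_class", "sex"} - set(meta.columns)
    if missing:
        raise ValueError(f"tissue metadata lacks columns: {sorted(missing)}")
    return meta


def read_intervals_bed(path: str | os.PathLike) -> dict[str, list[tuple[int, int]]]:
    """Per-scaffold 0-based half-open intervals from BED3+."""
    out: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            out.setdefault(parts[0], []).append((int(parts[1]), int(parts[2])))
    return out


def read_intervals_rmout(path: str | os.PathLike) -> dict[str, list[tuple[int, int]]]:
    """Per-scaffold intervals from a RepeatMasker .out table (1-based inclusive)."""
    out: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) < 7 or not parts[0].isdigit():
                continue  # header lines start with 'SW'/'score' or are blank
            scaffold, begin, end = parts[4], int(parts[5]), int(parts[6])
            out.setdefault(scaffold, []).append((begin - 1, end))
    return out
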