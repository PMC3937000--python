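"""File formats: FASTA genomes, TSV feature tables and distance matrices,
Newick dendrograms.

TSV is used throughout (UTF-8, '.' decimal); distance matrices are written
as labeled square tables whose header row and first column carry the same
sample order, and symmetry is validated on read.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .insilico_gp import PreSpiddo
from .pass_distance import DistanceMatrix
from .spiddos import GenomeProfile

__all__ = [
    "read_fasta", "write_fasta",
    "read_raw_profiles_tsv", "write_raw_profiles_tsv",
    "read_spiddos_tsv", "write_spiddos_tsv",
    "read_dg_tsv", "write_dg_tsv",
    "read_pairs_tsv", "write_matrix_tsv",
]

_BASES = frozenset("ACGT")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Multi-FASTA as (label, sequence) pairs; sequences uppercased and
    validated against the ACGT alphabet."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        bad = set(seq) - _BASES
        if bad:
            raise ValueError(
                f"record {rec.id!r}: non-ACGT characters {sorted(bad)}"
            )
        out.append((rec.id, seq))
    return out


def write_fasta(seqs: Sequence[tuple[str, str]], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=label, description="") for label, s in seqs]
    SeqIO.write(records, str(path), "fasta")


def write_raw_profiles_tsv(
    profiles: dict[str, Sequence[PreSpiddo]], path: str | Path
) -> None:
    rows = [
        {
            "sample": sample,
            "point_id": p.source,
            "mobility_raw": p.mobility_raw,
            "temp_raw": p.temp_raw,
            "is_reference": int(p.is_reference),
        }
        for sample, points in profiles.items()
        for p in points
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_raw_profiles_tsv(path: str | Path) -> dict[str, list[PreSpiddo]]:
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "point_id", "mobility_raw", "temp_raw", "is_reference"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"raw profile TSV missing columns: {sorted(missing)}")
    out: dict[str, list[PreSpiddo]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.sample), []).append(
            PreSpiddo(float(row.mobility_raw), float(row.temp_raw),
                      bool(row.is_reference), str(row.point_id))
        )
    return out


def write_spiddos_tsv(profiles: Sequence[GenomeProfile], path: str | Path) -> None:
    rows = [
        {
            "sample": prof.sample_label,
            "point_id": i,
            "mobility_norm": prof.spiddos[i, 0],
            "temp_norm": prof.spiddos[i, 1],
        }
        for prof in profiles
        for i in range(prof.n)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_spiddos_tsv(path: str | Path) -> list[GenomeProfile]:
    """Spiddos interchange TSV (also the entry point for digitized real
    gel data): columns sample, point_id, mobility_norm, temp_norm."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "mobility_norm", "temp_norm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"spiddos TSV missing columns: {sorted(missing)}")
    profiles = []
    for sample, grp in df.groupby("sample", sort=True):
        pts = grp[["mobility_norm", "temp_norm"]].to_numpy(dtype=np.float64)
        profiles.append(GenomeProfile(str(sample), pts))
    return profiles


def write_matrix_tsv(labels: Sequence[str], values: np.ndarray,
                     path: str | Path) -> None:
    pd.DataFrame(values, index=list(labels), columns=list(labels)).to_csv(
        path, sep="\t"
    )


def write_dg_tsv(d: DistanceMatrix, path: str | Path) -> None:
    write_matrix_tsv(d.labels, d.values, path)


def read_dg_tsv(path: str | Path) -> DistanceMatrix:
    """Labeled square dG matrix; header row and index column must agree
    and the matrix must be symmetric to 1e-9."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] != df.shape[1]:
        raise ValueError("distance matrix must be square")
    if list(df.index.astype(str)) != list(df.columns.astype(str)):
        raise ValueError("distance matrix row and column labels differ")
    values = df.to_numpy(dtype=np.float64)
    if not np.allclose(values, values.T, atol=1e-9):
        raise ValueError("distance matrix is not symmetric (tolerance 1e-9)")
    values = (values + values.T) / 2.0
    np.fill_diagonal(values, 0.0)
    return DistanceMatrix([str(c) for c in df.columns], values)


def read_pairs_tsv(path: str | Path) -> list[tuple[float, float]]:
    """(generations, count) table for rate estimation."""
    df = pd.read_csv(path, sep="\t")
    missing = {"generations", "count"} - set(df.columns)
    if missing:
        raise ValueError(f"pairs TSV missing columns: {sorted(missing)}")
    return [(float(g), float(c)) for g, c in zip(df["generations"], df["count"])]
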