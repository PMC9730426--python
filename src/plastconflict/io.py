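"""Readers and writers for the formats the pipeline touches.

FASTA parsing goes through Biopython; partition files use the RAxML-style
``DNA, locus = start-end`` convention with 1-based inclusive coordinates.
Tabular outputs are plain TSV via pandas.
"""

from __future__ import annotations

import os
from typing import Iterable

import pandas as pd
from Bio import SeqIO

from plastconflict.core import (
    Alphabet,
    ConcatenatedMatrix,
    LocusAlignment,
    LocusCategory,
)


def read_locus_fasta(
    path,
    locus_id: str,
    category: LocusCategory = LocusCategory.OTHER,
    alphabet: Alphabet = Alphabet.NT,
) -> LocusAlignment:
    """Read one aligned locus from FASTA.

    Requires at least two records, unique headers, and equal lengths;
    sequences are upper-cased on read.
    """
    seqs: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seqs:
            raise ValueError(f"{path}: duplicate header {record.id!r}")
        seqs[record.id] = str(record.seq)
    if len(seqs) < 2:
        raise ValueError(f"{path}: need at least 2 records, found {len(seqs)}")
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) != 1:
        raise ValueError(f"{path}: ragged alignment, lengths {sorted(lengths)}")
    return LocusAlignment(
        locus_id=locus_id, category=category, seqs=seqs, alphabet=alphabet
    )


def write_locus_fasta(locus: LocusAlignment, path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for taxon, seq in locus.seqs.items():
            fh.write(f">{taxon}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_matrix_fasta(matrix: ConcatenatedMatrix, path, width: int = 80) -> str:
    """Write a supermatrix as wrapped FASTA plus a companion partition file.

    The partition file sits next to the FASTA with extension ``.partitions``
    and uses 1-based inclusive coordinates. Returns the partition file path.
    """
    path = str(path)
    with open(path, "w") as fh:
        for taxon in matrix.taxa:
            fh.write(f">{taxon}\n")
            seq = matrix.rows[taxon]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
    part_path = os.path.splitext(path)[0] + ".partitions"
    dtype = "DNA" if matrix.alphabet == Alphabet.NT else "PROT"
    with open(part_path, "w") as fh:
        for locus, (start, end) in matrix.partitions.items():
            fh.write(f"{dtype}, {locus} = {start + 1}-{end}\n")
    return part_path


def read_matrix_fasta(
    path, partition_path=None, alphabet: Alphabet = Alphabet.NT
) -> ConcatenatedMatrix:
    """Read a supermatrix FASTA (+ optional partition file) back."""
    rows: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in rows:
            raise ValueError(f"{path}: duplicate header {record.id!r}")
        rows[record.id] = str(record.seq).upper()
    if not rows:
        raise ValueError(f"{path}: empty FASTA")
    L = len(next(iter(rows.values())))
    if partition_path is None:
        guess = os.path.splitext(str(path))[0] + ".partitions"
        partition_path = guess if os.path.exists(guess) else None
    if partition_path is not None:
        partitions = read_partition_file(partition_path)
    else:
        partitions = {"all": (0, L)}
    return ConcatenatedMatrix(
        taxa=list(rows), rows=rows, partitions=partitions, alphabet=alphabet
    )


def read_partition_file(path) -> dict[str, tuple[int, int]]:
    """Parse RAxML-style partition lines into 0-based half-open intervals."""
    partitions: dict[str, tuple[int, int]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            # "DNA, name = 1-400"
            _, rest = line.split(",", 1)
            name, span = rest.split("=")
            start, end = span.strip().split("-")
            partitions[name.strip()] = (int(start) - 1, int(end))
    return partitions


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_manifest(path) -> pd.DataFrame:
    """Read a locus manifest TSV with columns locus_id, category, path."""
    df = pd.read_csv(path, sep="\t")
    required = {"locus_id", "category", "path"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing column(s): {sorted(missing)}")
    return df


def load_loci_from_manifest(manifest: pd.DataFrame, base_dir=None) -> list[LocusAlignment]:
    loci = []
    for row in manifest.itertuples():
        path = row.path
        if base_dir is not None and not os.path.isabs(path):
            path = os.path.join(str(base_dir), path)
        loci.append(
            read_locus_fasta(path, row.locus_id, LocusCategory(row.category))
        )
    return loci


def write_sls_tsv(tables: dict[str, Iterable[float]], path) -> None:
    """Write per-site ln-likelihoods, one row per column, one field per topology."""
    df = pd.DataFrame({label: list(sls) for label, sls in tables.items()})
    df.insert(0, "site", range(1, len(df) + 1))
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_sls_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return df.drop(columns=["site"], errors="ignore")
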