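"""Shared domain types: locus alignments, concatenated supermatrices,
site-likelihood tables, and candidate-topology sets.

Coordinates are 0-based half-open everywhere inside the package; 1-based
inclusive coordinates appear only in the RAxML-style partition files written
by :mod:`plastconflict.io`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterator

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from plastconflict.substmodel import SubstitutionModel
    from plastconflict.tree import PhyloTree


class Alphabet(str, enum.Enum):
    """Sequence alphabet of an alignment."""

    NT = "NT"
    AA = "AA"


class LocusCategory(str, enum.Enum):
    """Functional category of a plastome locus."""

    CDS = "CDS"
    IGS = "IGS"
    OTHER = "OTHER"


#: Canonical state orderings used by the likelihood engine.
NT_STATES = "ACGT"
AA_STATES = "ARNDCQEGHILKMFPSTWYV"

#: Characters treated as fully ambiguous (all-ones partial likelihood).
NT_AMBIGUOUS = {"N", "-", "?"}
AA_AMBIGUOUS = {"X", "-", "?"}


def states_for(alphabet: Alphabet) -> str:
    return NT_STATES if alphabet == Alphabet.NT else AA_STATES


def ambiguous_for(alphabet: Alphabet) -> set[str]:
    return NT_AMBIGUOUS if alphabet == Alphabet.NT else AA_AMBIGUOUS


def _validate_seq(seq: str, alphabet: Alphabet, label: str) -> str:
    seq = seq.upper()
    allowed = set(states_for(alphabet)) | ambiguous_for(alphabet)
    bad = set(seq) - allowed
    if bad:
        raise ValueError(
            f"illegal character(s) {sorted(bad)} in sequence {label!r} "
            f"for alphabet {alphabet.value}"
        )
    return seq


@dataclass
class LocusAlignment:
    """One aligned locus (CDS or IGS) over a set of taxa.

    All sequences share the same length; taxon labels are unique; characters
    are stored upper-case and restricted to the declared alphabet plus its
    ambiguity codes.
    """

    locus_id: str
    category: LocusCategory
    seqs: dict[str, str]
    alphabet: Alphabet = Alphabet.NT

    def __post_init__(self) -> None:
        if not self.seqs:
            raise ValueError(f"locus {self.locus_id!r}: empty alignment")
        self.seqs = {
            taxon: _validate_seq(seq, self.alphabet, taxon)
            for taxon, seq in self.seqs.items()
        }
        lengths = {len(s) for s in self.seqs.values()}
        if len(lengths) != 1:
            raise ValueError(
                f"locus {self.locus_id!r}: ragged alignment, lengths {sorted(lengths)}"
            )
        if lengths == {0}:
            raise ValueError(f"locus {self.locus_id!r}: zero-length alignment")

    @property
    def length(self) -> int:
        return len(next(iter(self.seqs.values())))

    @property
    def taxa(self) -> list[str]:
        return list(self.seqs)

    def n_taxa_with_data(self) -> int:
        """Taxa carrying at least one unambiguous residue."""
        amb = ambiguous_for(self.alphabet)
        return sum(
            1 for s in self.seqs.values() if any(c not in amb for c in s)
        )


@dataclass
class ConcatenatedMatrix:
    """Supermatrix over an ordered taxon set with a partition map.

    ``partitions`` maps locus_id to a half-open 0-based column interval
    ``(start, end)``; the intervals are disjoint, contiguous, and tile
    ``[0, L)``. Taxa absent from a locus are padded with ``'-'`` across that
    locus's interval. ``provenance`` records the strategy labels that
    produced the matrix.
    """

    taxa: list[str]
    rows: dict[str, str]
    partitions: dict[str, tuple[int, int]]
    alphabet: Alphabet = Alphabet.NT
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.taxa:
            raise ValueError("empty matrix: no taxa")
        if set(self.taxa) != set(self.rows):
            raise ValueError("taxa list and row keys disagree")
        L = self.length
        for taxon in self.taxa:
            if len(self.rows[taxon]) != L:
                raise ValueError(f"row {taxon!r} has length {len(self.rows[taxon])} != {L}")
        pos = 0
        for locus, (start, end) in self.partitions.items():
            if start != pos or end <= start:
                raise ValueError(
                    f"partition {locus!r} interval [{start},{end}) does not tile the matrix"
                )
            pos = end
        if pos != L:
            raise ValueError(f"partitions cover [0,{pos}) but matrix length is {L}")

    @property
    def length(self) -> int:
        return len(self.rows[self.taxa[0]])

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def locus_ids(self) -> list[str]:
        return list(self.partitions)

    def locus_columns(self, locus_id: str) -> tuple[int, int]:
        return self.partitions[locus_id]

    def iter_loci(self) -> Iterator[tuple[str, int, int]]:
        for locus, (start, end) in self.partitions.items():
            yield locus, start, end

    def to_codes(self) -> np.ndarray:
        """Integer-encode the matrix: states 0..S-1, ambiguity = -1.

        Returns an ``(n_taxa, L)`` int8 array in ``self.taxa`` order.
        """
        states = states_for(self.alphabet)
        lut = np.full(128, -1, dtype=np.int8)
        for i, s in enumerate(states):
            lut[ord(s)] = i
        arr = np.empty((len(self.taxa), self.length), dtype=np.int8)
        for i, taxon in enumerate(self.taxa):
            row = np.frombuffer(self.rows[taxon].encode("ascii"), dtype=np.uint8)
            arr[i] = lut[row]
        return arr

    def with_provenance(self, label: str) -> "ConcatenatedMatrix":
        return ConcatenatedMatrix(
            taxa=list(self.taxa),
            rows=dict(self.rows),
            partitions=dict(self.partitions),
            alphabet=self.alphabet,
            provenance=[*self.provenance, label],
        )

    def select_columns(self, keep: np.ndarray) -> tuple["ConcatenatedMatrix", np.ndarray]:
        """Return a new matrix with only the columns flagged in ``keep``.

        ``keep`` is a boolean mask of length L. Partitions are rescaled;
        loci whose columns all vanish are dropped. Also returns the indices
        of the kept columns.
        """
        keep = np.asarray(keep, dtype=bool)
        if keep.shape != (self.length,):
            raise ValueError("keep mask has wrong length")
        idx = np.flatnonzero(keep)
        new_partitions: dict[str, tuple[int, int]] = {}
        pos = 0
        for locus, (start, end) in self.partitions.items():
            n_kept = int(keep[start:end].sum())
            if n_kept > 0:
                new_partitions[locus] = (pos, pos + n_kept)
                pos += n_kept
        new_rows = {}
        for taxon in self.taxa:
            row = np.frombuffer(self.rows[taxon].encode("ascii"), dtype=np.uint8)
            new_rows[taxon] = row[idx].tobytes().decode("ascii")
        if pos == 0:
            raise EmptyMatrixError("all columns removed")
        mat = ConcatenatedMatrix(
            taxa=list(self.taxa),
            rows=new_rows,
            partitions=new_partitions,
            alphabet=self.alphabet,
            provenance=list(self.provenance),
        )
        return mat, idx


class EmptyMatrixError(ValueError):
    """Raised when an operation removes every column or locus."""


@dataclass
class SiteLikelihoodTable:
    """Per-column ln-likelihoods of one matrix under one fixed topology."""

    topology_id: str
    sls: np.ndarray
    tree_used: "PhyloTree"
    model_used: "SubstitutionModel"

    def __post_init__(self) -> None:
        self.sls = np.asarray(self.sls, dtype=float)
        if not np.all(np.isfinite(self.sls)):
            raise ValueError("non-finite site log-likelihood")
        if np.any(self.sls > 0):
            raise ValueError("positive site log-likelihood for discrete states")

    @property
    def total(self) -> float:
        return float(self.sls.sum())

    def __len__(self) -> int:
        return len(self.sls)


@dataclass
class TopologySet:
    """Candidate topologies (T1, T2, T3, ...) over a common leaf set."""

    trees: dict[str, "PhyloTree"]

    def __post_init__(self) -> None:
        if len(self.trees) < 2:
            raise ValueError("need at least two candidate topologies")
        leafsets = {label: frozenset(t.leaf_labels()) for label, t in self.trees.items()}
        if len(set(leafsets.values())) != 1:
            raise ValueError("candidate topologies have different leaf sets")
        bips = {label: t.bipartitions() for label, t in self.trees.items()}
        labels = list(self.trees)
        for i, a in enumerate(labels):
            for b in labels[i + 1 :]:
                if bips[a] == bips[b]:
                    raise ValueError(f"topologies {a} and {b} are identical")

    def labels(self) -> list[str]:
        return list(self.trees)

    def __getitem__(self, label: str) -> "PhyloTree":
        return self.trees[label]

    def items(self):
        return self.trees.items()
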