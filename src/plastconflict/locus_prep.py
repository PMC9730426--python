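"""Locus filtering, concatenation, block trimming, codon operations, and the
30-matrix strategy grid.

The grid reproduces the six matrix-construction strategies used to probe
conflicting plastome signal: conserved-block trimming at three gap modes,
long-branch / saturation-slope / saturation-R² / mean-support locus filters,
signal-outlier removal, and (for protein-coding loci) codon-frame datasets
with and without third positions. Default thresholds are the CDS/IGS density
"shoulder" values adopted by the original study.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from plastconflict.core import (
    Alphabet,
    ConcatenatedMatrix,
    EmptyMatrixError,
    LocusAlignment,
    LocusCategory,
)
from plastconflict.signal import outlier_bounds


# ------------------------------------------------------------------ filters


def filter_loci(
    loci: list[LocusAlignment],
    n_taxa_total: int,
    min_coverage: float = 0.55,
    min_len_cds: int = 100,
    min_len_igs: int = 50,
) -> tuple[list[LocusAlignment], pd.DataFrame]:
    """Drop loci with poor taxon coverage or short alignments.

    A locus is kept iff the fraction of taxa with at least one unambiguous
    residue is >= ``min_coverage`` and its aligned length meets the
    category minimum (CDS 100 bp, IGS 50 bp by default). Returns the kept
    loci and a rejection report (locus_id, reason, value).
    """
    if not loci:
        raise ValueError("empty locus list")
    max_present = max(len(l.taxa) for l in loci)
    if n_taxa_total < max_present:
        raise ValueError("n_taxa_total smaller than taxa present in a locus")
    kept: list[LocusAlignment] = []
    rows = []
    for locus in loci:
        coverage = locus.n_taxa_with_data() / n_taxa_total
        min_len = min_len_cds if locus.category == LocusCategory.CDS else min_len_igs
        if coverage < min_coverage:
            rows.append((locus.locus_id, "coverage", coverage))
        elif locus.length < min_len:
            rows.append((locus.locus_id, "length", locus.length))
        else:
            kept.append(locus)
    report = pd.DataFrame(rows, columns=["locus_id", "reason", "value"])
    return kept, report


def concatenate(loci: list[LocusAlignment]) -> ConcatenatedMatrix:
    """Concatenate loci into a supermatrix, padding absent taxa with '-'.

    Taxon order is lexicographic; partitions follow input locus order.
    """
    if not loci:
        raise ValueError("no loci to concatenate")
    alphabets = {l.alphabet for l in loci}
    if len(alphabets) != 1:
        raise ValueError("cannot concatenate mixed NT/AA loci")
    taxa = sorted(set().union(*(set(l.taxa) for l in loci)))
    chunks: dict[str, list[str]] = {t: [] for t in taxa}
    partitions: dict[str, tuple[int, int]] = {}
    pos = 0
    for locus in loci:
        L = locus.length
        for t in taxa:
            chunks[t].append(locus.seqs.get(t, "-" * L))
        partitions[locus.locus_id] = (pos, pos + L)
        pos += L
    rows = {t: "".join(chunks[t]) for t in taxa}
    return ConcatenatedMatrix(
        taxa=taxa,
        rows=rows,
        partitions=partitions,
        alphabet=alphabets.pop(),
        provenance=["concatenate"],
    )


# ----------------------------------------------------------- block trimming


def trim_conserved_blocks(
    matrix: ConcatenatedMatrix,
    gap_mode: str = "none",
    is_frac: float = 0.5,
    fs_frac: float = 0.85,
    max_nonconserved: int = 8,
    min_block: int = 10,
) -> tuple[ConcatenatedMatrix, np.ndarray]:
    """Conserved-block trimming in the style of Gblocks.

    Column classification: a column is *conserved* when its majority residue
    frequency (over all rows) is >= ``is_frac`` and *highly conserved* when
    >= ``fs_frac``; a column violating the gap rule is non-conserved
    regardless (``none``: any gap; ``half``: > 50% gaps; ``all``: no limit).
    Gap-rule violations are removed outright. Runs of more than
    ``max_nonconserved`` contiguous non-conserved columns are cut; surviving
    blocks are trimmed back to highly conserved flanks and dropped when
    shorter than ``min_block``. Returns the trimmed matrix (provenance
    ``GB-<mode>``) and the kept-column indices.
    """
    if gap_mode not in ("all", "half", "none"):
        raise ValueError(f"unknown gap mode {gap_mode!r}")
    codes = matrix.to_codes()
    n_taxa, L = codes.shape
    gaps = np.array(
        [
            np.frombuffer(matrix.rows[t].encode("ascii"), dtype=np.uint8) == ord("-")
            for t in matrix.taxa
        ]
    )
    gap_frac = gaps.mean(axis=0)
    n_states = 4 if matrix.alphabet == Alphabet.NT else 20
    maj = np.zeros(L)
    for s in range(n_states):
        maj = np.maximum(maj, (codes == s).sum(axis=0))
    maj_frac = maj / n_taxa

    conserved = maj_frac >= is_frac
    highly = maj_frac >= fs_frac
    if gap_mode == "none":
        bad_gap = gap_frac > 0
    elif gap_mode == "half":
        bad_gap = gap_frac > 0.5
    else:
        bad_gap = np.zeros(L, dtype=bool)
    conserved &= ~bad_gap
    highly &= ~bad_gap

    keep = np.ones(L, dtype=bool)
    # cut long non-conserved runs
    i = 0
    while i < L:
        if not conserved[i]:
            j = i
            while j < L and not conserved[j]:
                j += 1
            if j - i > max_nonconserved:
                keep[i:j] = False
            i = j
        else:
            i += 1
    keep &= ~bad_gap
    # trim blocks to highly conserved flanks, then enforce minimum length
    final = np.zeros(L, dtype=bool)
    i = 0
    while i < L:
        if keep[i]:
            j = i
            while j < L and keep[j]:
                j += 1
            hc = np.flatnonzero(highly[i:j])
            if hc.size:
                lo, hi = i + hc[0], i + hc[-1] + 1
                if hi - lo >= min_block:
                    final[lo:hi] = True
            i = j
        else:
            i += 1

    if not final.any():
        warnings.warn("block trimming removed every column")
        empty = ConcatenatedMatrix(
            taxa=list(matrix.taxa),
            rows={t: "-" for t in matrix.taxa},
            partitions={"empty": (0, 1)},
            alphabet=matrix.alphabet,
            provenance=[*matrix.provenance, f"GB-{gap_mode}", "empty"],
        )
        return empty, np.array([], dtype=int)
    trimmed, idx = matrix.select_columns(final)
    return trimmed.with_provenance(f"GB-{gap_mode}"), idx


# -------------------------------------------------------------- codon tools


def remove_third_codon(matrix: ConcatenatedMatrix) -> ConcatenatedMatrix:
    """Drop every third codon position in each partition (codon-aligned NT)."""
    if matrix.alphabet != Alphabet.NT:
        raise ValueError("third-codon removal requires nucleotide data")
    keep = np.ones(matrix.length, dtype=bool)
    for locus, (start, end) in matrix.partitions.items():
        if (end - start) % 3 != 0:
            raise ValueError(f"partition {locus!r} length {end - start} breaks frame")
        keep[start + 2 : end : 3] = False
    out, _ = matrix.select_columns(keep)
    return out.with_provenance("rm3")


def translate_cds(matrix: ConcatenatedMatrix, table: int = 1) -> ConcatenatedMatrix:
    """Translate a codon-aligned nucleotide matrix to amino acids.

    Gap codons ('---') become '-'; codons containing any ambiguity or gap
    become 'X'; stop codons become 'X' and are counted per locus in a
    warning.
    """
    if matrix.alphabet != Alphabet.NT:
        raise ValueError("translation requires nucleotide data")
    code = CodonTable.unambiguous_dna_by_id[table]
    fwd = dict(code.forward_table)
    stops = set(code.stop_codons)
    new_partitions: dict[str, tuple[int, int]] = {}
    pos = 0
    stop_counts: dict[str, int] = {}
    segments: dict[str, list[str]] = {t: [] for t in matrix.taxa}
    for locus, (start, end) in matrix.partitions.items():
        if (end - start) % 3 != 0:
            raise ValueError(f"partition {locus!r} length {end - start} breaks frame")
        n_aa = (end - start) // 3
        new_partitions[locus] = (pos, pos + n_aa)
        pos += n_aa
        for taxon in matrix.taxa:
            nt = matrix.rows[taxon][start:end]
            aa = []
            for i in range(0, len(nt), 3):
                codon = nt[i : i + 3]
                if codon == "---":
                    aa.append("-")
                elif codon in stops:
                    aa.append("X")
                    stop_counts[locus] = stop_counts.get(locus, 0) + 1
                elif codon in fwd:
                    aa.append(fwd[codon])
                else:
                    aa.append("X")
            segments[taxon].append("".join(aa))
    if stop_counts:
        warnings.warn(f"internal stop codons translated to X: {stop_counts}")
    rows = {t: "".join(segments[t]) for t in matrix.taxa}
    return ConcatenatedMatrix(
        taxa=list(matrix.taxa),
        rows=rows,
        partitions=new_partitions,
        alphabet=Alphabet.AA,
        provenance=[*matrix.provenance, "translate"],
    )


def enforce_codon_frame(locus: LocusAlignment) -> pd.DataFrame:
    """Report codon-frame violations without modifying the locus.

    Checks that the alignment length is divisible by 3 and that every gap
    run in every sequence has a length divisible by 3.
    """
    rows = []
    if locus.length == 0:
        rows.append((locus.locus_id, "*", -1, "empty"))
    if locus.length % 3 != 0:
        rows.append((locus.locus_id, "*", locus.length, "length_not_multiple_of_3"))
    for taxon, seq in locus.seqs.items():
        i = 0
        while i < len(seq):
            if seq[i] == "-":
                j = i
                while j < len(seq) and seq[j] == "-":
                    j += 1
                if (j - i) % 3 != 0:
                    rows.append((locus.locus_id, taxon, i, "gap_run_breaks_frame"))
                i = j
            else:
                i += 1
    return pd.DataFrame(rows, columns=["locus_id", "taxon", "column", "violation"])


# ------------------------------------------------------------ strategy grid


@dataclass
class StrategyGridConfig:
    """Thresholds and switches for the 30-matrix strategy grid.

    Defaults are the density-plot shoulder values adopted for the plastome
    study: saturation slope 0.104 (CDS) / 0.30 (IGS), saturation R² 0.50
    (CDS) / 0.344 (IGS), and a 75% mean-bootstrap-support floor. Long-branch
    heterogeneity here is the standard deviation of percent-scale LB scores,
    so the corresponding shoulders are 45 (CDS) / 90 (IGS) on that scale.
    """

    gap_modes: tuple[str, ...] = ("all", "half", "none")
    lb_threshold: dict = field(default_factory=lambda: {"CDS": 45.0, "IGS": 90.0})
    slope_threshold: dict = field(default_factory=lambda: {"CDS": 0.104, "IGS": 0.30})
    r2_threshold: dict = field(default_factory=lambda: {"CDS": 0.50, "IGS": 0.344})
    bs_threshold: float = 75.0
    include_codon_datasets: bool = True
    include_block_dataset: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.bs_threshold <= 100):
            raise ValueError("bs_threshold must lie in (0, 100]")
        for d in (self.lb_threshold, self.slope_threshold, self.r2_threshold):
            if any(v <= 0 for v in d.values()):
                raise ValueError("thresholds must be positive")


def _category_filter(
    loci: list[LocusAlignment],
    diagnostics: pd.DataFrame,
    metric: str,
    thresholds: dict | float,
    direction: str,
) -> list[LocusAlignment]:
    """Apply a diagnostics threshold per locus category; ties are kept."""
    diag = diagnostics.set_index("locus_id")
    kept = []
    for locus in loci:
        value = diag.loc[locus.locus_id, metric]
        thr = (
            thresholds
            if np.isscalar(thresholds)
            else thresholds.get(locus.category.value, next(iter(thresholds.values())))
        )
        if direction == "remove_above":
            if not value > thr:
                kept.append(locus)
        else:
            if not value < thr:
                kept.append(locus)
    return kept


def build_strategy_grid(
    cds_loci: list[LocusAlignment],
    igs_loci: list[LocusAlignment],
    diagnostics: pd.DataFrame,
    signal: pd.DataFrame,
    config: StrategyGridConfig | None = None,
) -> dict[str, ConcatenatedMatrix]:
    """Emit the named grid of concatenated matrices (30 with defaults).

    ``diagnostics`` must provide locus_id, lb_heterogeneity, slope, r2,
    mean_support for every locus. ``signal`` provides per base dataset the
    mean ΔGLS of each locus (columns: dataset ∈ {CDS, IGS, All}, locus_id,
    mean_delta); outlier flags are recomputed per dataset with the μ±3σ
    rule. ``All-Homblock`` is strict block trimming of the whole
    concatenation, standing in for collinear-block mining.
    """
    config = config or StrategyGridConfig()
    all_loci = list(cds_loci) + list(igs_loci)
    families = {"CDS": cds_loci, "IGS": igs_loci, "All": all_loci}
    need = {l.locus_id for l in all_loci}
    have = set(diagnostics["locus_id"])
    if need - have:
        raise ValueError(f"diagnostics missing loci: {sorted(need - have)}")

    grid: dict[str, ConcatenatedMatrix] = {}

    def emit(label: str, loci: list[LocusAlignment]) -> None:
        if not loci:
            raise EmptyMatrixError(f"strategy {label!r} removed every locus")
        grid[label] = concatenate(loci).with_provenance(label)

    for family, loci in families.items():
        emit(family, loci)
        for mode in config.gap_modes:
            trimmed, _ = trim_conserved_blocks(grid[family], gap_mode=mode)
            grid[f"{family}-GB-{mode}"] = trimmed.with_provenance(f"{family}-GB-{mode}")
        emit(
            f"{family}-BS75",
            _category_filter(
                loci, diagnostics, "mean_support", config.bs_threshold, "remove_below"
            ),
        )
        emit(
            f"{family}-LB",
            _category_filter(
                loci, diagnostics, "lb_heterogeneity", config.lb_threshold, "remove_above"
            ),
        )
        emit(
            f"{family}-Slope",
            _category_filter(
                loci, diagnostics, "slope", config.slope_threshold, "remove_below"
            ),
        )
        emit(
            f"{family}-R2",
            _category_filter(loci, diagnostics, "r2", config.r2_threshold, "remove_below"),
        )
        sub = signal[signal["dataset"] == family]
        flags = dict(
            zip(sub["locus_id"], outlier_bounds(sub["mean_delta"].to_numpy()).flags)
        )
        emit(
            f"{family}-no-outlier",
            [l for l in loci if not flags.get(l.locus_id, False)],
        )

    if config.include_codon_datasets:
        codon = concatenate(cds_loci).with_provenance("CDS-codon-align")
        grid["CDS-codon-align"] = codon
        grid["CDS-codon-align-rm3"] = remove_third_codon(codon).with_provenance(
            "CDS-codon-align-rm3"
        )
    if config.include_block_dataset:
        homblock, _ = trim_conserved_blocks(grid["All"], gap_mode="none")
        grid["All-Homblock"] = homblock.with_provenance("All-Homblock")
    return grid
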