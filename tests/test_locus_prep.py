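import numpy as np
import pandas as pd
import pytest

from plastconflict.core import (
    Alphabet,
    ConcatenatedMatrix,
    EmptyMatrixError,
    LocusAlignment,
    LocusCategory,
)
from plastconflict.locus_prep import (
    StrategyGridConfig,
    build_strategy_grid,
    concatenate,
    enforce_codon_frame,
    filter_loci,
    remove_third_codon,
    translate_cds,
    trim_conserved_blocks,
)


def locus(locus_id, seqs, category=LocusCategory.CDS):
    return LocusAlignment(locus_id=locus_id, category=category, seqs=seqs)


class TestFilterLoci:
    def test_low_coverage_rejected(self):
        lc = locus("a", {f"t{i}": "A" * 200 for i in range(5)})
        kept, report = filter_loci([lc], n_taxa_total=10)
        assert not kept
        assert report.iloc[0]["reason"] == "coverage"

    def test_category_length_minima(self):
        short_cds = locus("cds", {f"t{i}": "A" * 99 for i in range(9)})
        ok_igs = locus(
            "igs", {f"t{i}": "A" * 50 for i in range(9)}, LocusCategory.IGS
        )
        kept, report = filter_loci([short_cds, ok_igs], n_taxa_total=10)
        assert [l.locus_id for l in kept] == ["igs"]
        assert report.iloc[0]["reason"] == "length"

    def test_passing_locus_kept(self):
        lc = locus("ok", {f"t{i}": "A" * 200 for i in range(6)})
        kept, report = filter_loci([lc], n_taxa_total=10)
        assert kept and report.empty

    def test_all_gap_taxa_do_not_count_as_covered(self):
        seqs = {f"t{i}": "A" * 200 for i in range(5)}
        seqs.update({f"g{i}": "-" * 200 for i in range(4)})
        lc = locus("gappy", seqs)
        kept, _ = filter_loci([lc], n_taxa_total=10)
        assert not kept

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            filter_loci([], 10)


class TestConcatenate:
    def test_partitions_and_padding(self):
        a = locus("a", {"x": "ACGT", "y": "ACGT"})
        b = locus("b", {"y": "AACCGG", "z": "AACCGG"})
        m = concatenate([a, b])
        assert m.partitions == {"a": (0, 4), "b": (4, 10)}
        assert m.rows["z"] == "----AACCGG"
        assert m.rows["x"] == "ACGT------"
        assert m.taxa == sorted(m.taxa)

    def test_single_locus_identity(self):
        a = locus("a", {"x": "ACGT", "y": "AC-T"})
        m = concatenate([a])
        assert m.rows == {"x": "ACGT", "y": "AC-T"}

    def test_mixed_alphabets_rejected(self):
        a = locus("a", {"x": "ACGT", "y": "ACGT"})
        b = LocusAlignment(
            locus_id="b",
            category=LocusCategory.CDS,
            seqs={"x": "MF", "y": "MF"},
            alphabet=Alphabet.AA,
        )
        with pytest.raises(ValueError, match="mixed"):
            concatenate([a, b])


def column_matrix(cols, taxa=None):
    """Build a matrix from a list of column strings (one char per taxon)."""
    n = len(cols[0])
    taxa = taxa or [f"t{i}" for i in range(n)]
    rows = {t: "".join(col[i] for col in cols) for i, t in enumerate(taxa)}
    return ConcatenatedMatrix(
        taxa=taxa, rows=rows, partitions={"locus": (0, len(cols))}
    )


class TestTrimConservedBlocks:
    def test_fully_conserved_matrix_kept_under_every_mode(self):
        m = column_matrix(["AAAA"] * 20)
        for mode in ("all", "half", "none"):
            trimmed, idx = trim_conserved_blocks(m, mode)
            assert trimmed.length == 20

    def test_gap_column_rules(self):
        # one 60%-gap column in the middle of conserved context
        cols = ["AAAAA"] * 12 + ["AA---"] + ["AAAAA"] * 12
        m = column_matrix(cols)
        kept_none, _ = trim_conserved_blocks(m, "none")
        kept_half, _ = trim_conserved_blocks(m, "half")
        kept_all, _ = trim_conserved_blocks(m, "all")
        assert kept_none.length == 24
        assert kept_half.length == 24
        assert kept_all.length == 25

    @pytest.mark.parametrize("seed", range(6))
    def test_gap_mode_outputs_are_nested(self, seed):
        rng = np.random.default_rng(seed)
        cols = []
        for _ in range(30):
            if rng.random() < 0.5:
                col = [rng.choice(list("ACGT"))] * 6
            else:
                col = list(rng.choice(list("ACGT-"), 6))
            cols.append("".join(col))
        m = column_matrix(cols)
        kept = {}
        for mode in ("all", "half", "none"):
            _, idx = trim_conserved_blocks(m, mode, min_block=3, max_nonconserved=4)
            kept[mode] = set(idx.tolist())
        assert kept["none"] <= kept["half"] <= kept["all"]

    def test_everything_removed_warns_and_stays_valid(self):
        m = column_matrix(["ACGTAC"] * 5)  # nothing conserved
        with pytest.warns(UserWarning, match="every column"):
            trimmed, idx = trim_conserved_blocks(m, "none")
        assert idx.size == 0
        assert "empty" in trimmed.provenance


class TestCodonOperations:
    def test_remove_third_codon_positions(self):
        m = ConcatenatedMatrix(
            taxa=["x", "y"],
            rows={"x": "ATGAAATTT", "y": "ATGAAATTT"},
            partitions={"a": (0, 9)},
        )
        out = remove_third_codon(m)
        assert out.rows["x"] == "ATAATT"
        assert out.partitions == {"a": (0, 6)}

    def test_frame_violation_rejected(self):
        m = ConcatenatedMatrix(
            taxa=["x", "y"],
            rows={"x": "A" * 10, "y": "A" * 10},
            partitions={"a": (0, 10)},
        )
        with pytest.raises(ValueError, match="frame"):
            remove_third_codon(m)

    def test_double_application_is_recorded_and_not_identity(self):
        m = ConcatenatedMatrix(
            taxa=["x", "y"],
            rows={"x": "ATGAAATTT", "y": "ATGAAATTT"},
            partitions={"a": (0, 9)},
        )
        once = remove_third_codon(m)
        twice = remove_third_codon(once)
        assert twice.length == 4
        assert once.provenance.count("rm3") == 1
        assert twice.provenance.count("rm3") == 2

    def test_translate_standard_code(self):
        m = ConcatenatedMatrix(
            taxa=["x", "y"],
            rows={"x": "ATGTTT", "y": "---ATG"},
            partitions={"a": (0, 6)},
        )
        aa = translate_cds(m)
        assert aa.rows["x"] == "MF"
        assert aa.rows["y"] == "-M"
        assert aa.alphabet == Alphabet.AA
        assert aa.partitions == {"a": (0, 2)}

    def test_internal_stop_becomes_x_with_warning(self):
        m = ConcatenatedMatrix(
            taxa=["x", "y"],
            rows={"x": "TAAATG", "y": "ATGATG"},
            partitions={"a": (0, 6)},
        )
        with pytest.warns(UserWarning, match="stop"):
            aa = translate_cds(m)
        assert aa.rows["x"] == "XM"

    def test_ambiguous_codon_becomes_x(self):
        m = ConcatenatedMatrix(
            taxa=["x", "y"],
            rows={"x": "A-GATG", "y": "ATNATG"},
            partitions={"a": (0, 6)},
        )
        aa = translate_cds(m)
        assert aa.rows["x"] == "XM"
        assert aa.rows["y"] == "XM"

    def test_frame_check_report(self):
        good = locus("g", {"x": "ATG---AAA", "y": "ATGAAAAAA"})
        assert enforce_codon_frame(good).empty
        bad = locus("b", {"x": "ATG--AAAT", "y": "ATGAAAAAT"})
        report = enforce_codon_frame(bad)
        assert (report["violation"] == "gap_run_breaks_frame").any()
        assert report.iloc[0]["column"] == 3


def grid_inputs(n_cds=4, n_igs=3, n_taxa=6, seed=0):
    rng = np.random.default_rng(seed)
    taxa = [f"t{i}" for i in range(n_taxa)]
    cds = [
        locus(f"cds_{i}", {t: "".join(rng.choice(list("ACGT"), 120)) for t in taxa})
        for i in range(n_cds)
    ]
    igs = [
        locus(
            f"igs_{i}",
            {t: "".join(rng.choice(list("ACGT"), 80)) for t in taxa},
            LocusCategory.IGS,
        )
        for i in range(n_igs)
    ]
    ids = [l.locus_id for l in cds + igs]
    diagnostics = pd.DataFrame(
        {
            "locus_id": ids,
            "lb_heterogeneity": 10.0,
            "slope": 0.8,
            "r2": 0.95,
            "mean_support": 90.0,
        }
    )
    rows = []
    for fam, fam_loci in (("CDS", cds), ("IGS", igs), ("All", cds + igs)):
        for i, l in enumerate(fam_loci):
            rows.append(
                {"dataset": fam, "locus_id": l.locus_id, "mean_delta": float(i)}
            )
    signal = pd.DataFrame(rows)
    return cds, igs, diagnostics, signal


class TestStrategyGrid:
    def test_default_grid_has_thirty_matrices(self):
        cds, igs, diag, sig = grid_inputs()
        grid = build_strategy_grid(cds, igs, diag, sig)
        assert len(grid) == 30
        families = {"CDS": 0, "IGS": 0, "All": 0}
        for label in grid:
            families[label.split("-")[0]] += 1
        assert families == {"CDS": 11, "IGS": 9, "All": 10}

    def test_without_codon_datasets_28_matrices(self):
        cds, igs, diag, sig = grid_inputs()
        grid = build_strategy_grid(
            cds, igs, diag, sig, StrategyGridConfig(include_codon_datasets=False)
        )
        assert len(grid) == 28
        assert "CDS-codon-align" not in grid

    def test_passing_diagnostics_make_filters_no_ops(self):
        cds, igs, diag, sig = grid_inputs()
        grid = build_strategy_grid(cds, igs, diag, sig)
        assert grid["CDS-LB"].rows == grid["CDS"].rows
        assert grid["CDS-BS75"].rows == grid["CDS"].rows

    def test_filter_removing_everything_is_an_error(self):
        cds, igs, diag, sig = grid_inputs()
        diag["mean_support"] = 10.0
        with pytest.raises(EmptyMatrixError, match="BS75"):
            build_strategy_grid(cds, igs, diag, sig)

    def test_filters_remove_whole_loci_only(self):
        cds, igs, diag, sig = grid_inputs()
        diag.loc[diag.locus_id == "cds_1", "slope"] = 0.01
        grid = build_strategy_grid(cds, igs, diag, sig)
        assert set(grid["CDS-Slope"].partitions) == {
            "cds_0",
            "cds_2",
            "cds_3",
        }
        for locus_id, (start, end) in grid["CDS-Slope"].partitions.items():
            assert end - start == 120
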