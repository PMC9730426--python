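import numpy as np
import pytest

from plastconflict.core import ConcatenatedMatrix
from plastconflict.likelihood import (
    CompressedAlignment,
    OptimizationSettings,
    PruningEngine,
    bootstrap_support,
    fit_model,
    nni_search,
    optimize_branch_lengths,
    site_loglik,
)
from plastconflict.simulate import default_simulation_model, simulate_locus
from plastconflict.substmodel import SubstitutionModel
from plastconflict.tree import PhyloTree
from plastconflict.locus_prep import concatenate

from conftest import brute_force_loglik, random_matrix


def two_taxon_matrix(seq_a, seq_b):
    return ConcatenatedMatrix(
        taxa=["A", "B"],
        rows={"A": seq_a, "B": seq_b},
        partitions={"locus": (0, len(seq_a))},
    )


class TestPruning:
    def test_identical_states_short_branch_limit(self, jc1):
        m = two_taxon_matrix("A", "A")
        t = PhyloTree.from_newick("(A:1e-9,B:1e-9);")
        assert site_loglik(m, t, jc1).total == pytest.approx(np.log(0.25), abs=1e-6)

    def test_saturation_limit(self, jc1):
        m = two_taxon_matrix("A", "C")
        t = PhyloTree.from_newick("(A:6,B:6);")
        assert site_loglik(m, t, jc1).total == pytest.approx(np.log(1 / 16), abs=1e-4)

    @pytest.mark.parametrize("n_taxa,seed", [(4, 0), (4, 1), (5, 2)])
    def test_matches_exhaustive_enumeration(self, gtr_gi, n_taxa, seed):
        rng = np.random.default_rng(seed)
        taxa = [f"t{i}" for i in range(n_taxa)]
        m = random_matrix(taxa, 5, rng)
        if n_taxa == 4:
            nwk = "((t0:0.3,t1:0.2):0.15,t2:0.4,t3:0.1);"
        else:
            nwk = "((t0:0.3,t1:0.2):0.15,(t2:0.4,t4:0.33):0.21,t3:0.1);"
        tree = PhyloTree.from_newick(nwk)
        ours = site_loglik(m, tree, gtr_gi).total
        oracle = brute_force_loglik(m, tree, gtr_gi)
        assert abs(ours - oracle) < 1e-10

    def test_ambiguous_states_match_enumeration(self, gtr_gi):
        m = ConcatenatedMatrix(
            taxa=["t0", "t1", "t2", "t3"],
            rows={"t0": "ANG-T", "t1": "ACGTT", "t2": "-CGTA", "t3": "ACNTA"},
            partitions={"locus": (0, 5)},
        )
        tree = PhyloTree.from_newick("((t0:0.3,t1:0.2):0.15,t2:0.4,t3:0.1);")
        ours = site_loglik(m, tree, gtr_gi).total
        assert abs(ours - brute_force_loglik(m, tree, gtr_gi)) < 1e-10

    def test_rerooting_invariance(self, gtr_gi):
        rng = np.random.default_rng(3)
        m = random_matrix([f"t{i}" for i in range(5)], 40, rng)
        rootings = [
            "((t0:0.3,t1:0.2):0.15,(t2:0.4,t4:0.33):0.21,t3:0.1);",
            "(t2:0.4,t4:0.33,((t0:0.3,t1:0.2):0.15,t3:0.1):0.21);",
            "(t0:0.3,t1:0.2,((t2:0.4,t4:0.33):0.21,t3:0.1):0.15);",
            # a degree-2 rooting along the central edge; derooted on read
            "((t0:0.3,t1:0.2):0.05,((t2:0.4,t4:0.33):0.21,t3:0.1):0.10);",
        ]
        values = [site_loglik(m, PhyloTree.from_newick(r), gtr_gi).total for r in rootings]
        assert max(values) - min(values) < 1e-8

    def test_site_loglik_sums_to_total(self, gtr_gi):
        rng = np.random.default_rng(4)
        m = random_matrix([f"t{i}" for i in range(6)], 200, rng)
        tree, lnl = nni_search(
            m,
            PhyloTree.from_newick(
                "((t0:0.2,t1:0.2):0.1,(t2:0.2,(t4:0.2,t5:0.2):0.1):0.1,t3:0.2);"
            ),
            gtr_gi,
            restarts=0,
        )
        table = site_loglik(m, tree, gtr_gi)
        assert abs(table.total - lnl) < 1e-8

    def test_gamma_limit_equals_single_rate(self):
        # short branches keep the rate-curvature term well below tolerance
        rng = np.random.default_rng(5)
        m = random_matrix([f"t{i}" for i in range(4)], 12, rng)
        tree = PhyloTree.from_newick("((t0:0.05,t1:0.04):0.03,t2:0.05,t3:0.02);")
        flat = SubstitutionModel.jc(alpha=1e6, n_categories=4)
        single = SubstitutionModel.jc(n_categories=1)
        a = site_loglik(m, tree, flat).total
        b = site_loglik(m, tree, single).total
        assert abs(a - b) < 1e-6

    def test_taxon_mismatch_rejected(self, jc1):
        m = two_taxon_matrix("ACGT", "ACGT")
        t = PhyloTree.from_newick("(A:1,C:1);")
        with pytest.raises(ValueError, match="absent|differ"):
            site_loglik(m, t, jc1)


class TestBranchOptimization:
    def test_two_taxon_jc_mle_matches_closed_form(self, jc1):
        # 100 sites, 10 differences: t_hat = -(3/4) ln(1 - 4p/3)
        m = two_taxon_matrix("A" * 100, "C" * 10 + "A" * 90)
        t = PhyloTree.from_newick("(A:0.05,B:0.05);")
        opt, _ = optimize_branch_lengths(m, t, jc1)
        total = sum(n.length for n in opt.postorder() if n is not opt.root)
        expected = -0.75 * np.log(1 - 4 * 0.10 / 3)
        assert total == pytest.approx(expected, abs=1e-6)

    def test_identical_sequences_hit_lower_bound(self, jc1):
        m = ConcatenatedMatrix(
            taxa=["A", "B", "C"],
            rows={t: "ACGT" * 10 for t in "ABC"},
            partitions={"locus": (0, 40)},
        )
        t = PhyloTree.from_newick("(A:0.1,B:0.1,C:0.1);")
        settings = OptimizationSettings()
        opt, _ = optimize_branch_lengths(m, t, jc1, settings)
        for node in opt.postorder():
            if node is not opt.root:
                assert node.length <= settings.bl_min * 10

    def test_lnl_never_decreases_from_start(self, gtr_gi):
        rng = np.random.default_rng(6)
        m = random_matrix([f"t{i}" for i in range(5)], 150, rng)
        tree = PhyloTree.from_newick(
            "((t0:0.9,t1:0.01):0.5,(t2:0.2,t4:1.5):0.01,t3:0.3);"
        )
        before = site_loglik(m, tree, gtr_gi).total
        opt, after = optimize_branch_lengths(m, tree, gtr_gi)
        assert after >= before

    def test_restart_from_optimum_is_stable(self, jc1):
        m = two_taxon_matrix("A" * 80 + "C" * 20, "A" * 100)
        t = PhyloTree.from_newick("(A:0.1,B:0.1);")
        opt, lnl1 = optimize_branch_lengths(m, t, jc1)
        opt2, lnl2 = optimize_branch_lengths(m, opt, jc1)
        assert lnl2 == pytest.approx(lnl1, abs=1e-3)


class TestFitModel:
    def test_jc_data_recovers_near_equal_exchangeabilities(self):
        tree = PhyloTree.from_newick(
            "((t0:0.2,t1:0.2):0.1,(t2:0.2,t3:0.2):0.1,t4:0.3);"
        )
        truth = SubstitutionModel.jc(n_categories=1)
        locus = simulate_locus(tree, truth, 5000, seed=11, locus_id="sim")
        m = concatenate([locus])
        template = SubstitutionModel.gtr(
            np.ones(6), np.full(4, 0.25), alpha=1.0, n_categories=1
        )
        model, _, _ = fit_model(m, tree, template, fit_alpha=False)
        rates = model.gtr_rates()
        assert np.all(rates > 0.8) and np.all(rates < 1.25)

    def test_alpha_recovery_within_band(self):
        tree = PhyloTree.from_newick(
            "((t0:0.2,t1:0.2):0.1,(t2:0.2,t3:0.2):0.1,t4:0.3);"
        )
        truth = default_simulation_model(alpha=0.5)
        hits = 0
        for rep in range(5):
            locus = simulate_locus(tree, truth, 5000, seed=100 + rep, locus_id="sim")
            m = concatenate([locus])
            model, _, _ = fit_model(
                m, tree, truth.replace(alpha=1.0), fit_exchangeabilities=False
            )
            if 0.35 <= model.alpha <= 0.7:
                hits += 1
        assert hits >= 4

    def test_invariant_alignment_takes_warning_path(self):
        m = ConcatenatedMatrix(
            taxa=["A", "B", "C"],
            rows={t: "AAAA" for t in "ABC"},
            partitions={"locus": (0, 4)},
        )
        tree = PhyloTree.from_newick("(A:0.1,B:0.1,C:0.1);")
        template = SubstitutionModel.jc(alpha=2.0, n_categories=4)
        with pytest.warns(UserWarning, match="no variable site"):
            model, _, _ = fit_model(m, tree, template, fit_exchangeabilities=False)
        assert model.alpha == 1.0


class TestNNISearch:
    def test_quartet_recovers_true_split_from_wrong_start(self, jc1):
        # sites overwhelmingly supporting AB|CD
        cols_ab = ["AACC"] * 60 + ["CCAA"] * 60 + ["ACGT"] * 5
        rows = {t: "".join(c[i] for c in cols_ab) for i, t in enumerate("ABCD")}
        m = ConcatenatedMatrix(
            taxa=list("ABCD"), rows=rows, partitions={"locus": (0, len(cols_ab))}
        )
        start = PhyloTree.from_newick("((A:0.1,C:0.1):0.1,B:0.1,D:0.1);")
        best, _ = nni_search(m, start, jc1, restarts=0)
        want = PhyloTree.from_newick("((A:1,B:1):1,C:1,D:1);")
        assert best.same_topology(want)

    def test_quartet_beats_both_alternatives_by_exhaustion(self, jc1):
        cols = ["AACC"] * 40 + ["CCAA"] * 40 + ["ACAC"] * 6 + ["ACCA"] * 6
        rows = {t: "".join(c[i] for c in cols) for i, t in enumerate("ABCD")}
        m = ConcatenatedMatrix(
            taxa=list("ABCD"), rows=rows, partitions={"locus": (0, len(cols))}
        )
        scores = {}
        for nwk in (
            "((A:0.1,B:0.1):0.1,C:0.1,D:0.1);",
            "((A:0.1,C:0.1):0.1,B:0.1,D:0.1);",
            "((A:0.1,D:0.1):0.1,B:0.1,C:0.1);",
        ):
            _, lnl = nni_search(m, PhyloTree.from_newick(nwk), jc1, restarts=0)
            scores[nwk] = lnl
        best, _ = nni_search(
            m, PhyloTree.from_newick("((A:0.1,C:0.1):0.1,B:0.1,D:0.1);"), jc1, restarts=2, seed=0
        )
        assert max(scores.values()) == pytest.approx(
            nni_search(m, best, jc1, restarts=0)[1], abs=1e-3
        )

    def test_fixed_point_at_optimum(self, gtr_gi):
        rng = np.random.default_rng(8)
        m = random_matrix([f"t{i}" for i in range(6)], 300, rng)
        start = PhyloTree.from_newick(
            "((t0:0.2,t1:0.2):0.1,(t2:0.2,(t4:0.2,t5:0.2):0.1):0.1,t3:0.2);"
        )
        best, lnl = nni_search(m, start, gtr_gi, restarts=0)
        again, lnl2 = nni_search(m, best, gtr_gi, restarts=0)
        assert again.bipartitions() == best.bipartitions()

    def test_under_four_taxa_returns_start(self, jc1):
        m = ConcatenatedMatrix(
            taxa=["A", "B", "C"],
            rows={"A": "ACGT", "B": "ACGA", "C": "ACTT"},
            partitions={"locus": (0, 4)},
        )
        start = PhyloTree.from_newick("(A:0.1,B:0.1,C:0.1);")
        tree, _ = nni_search(m, start, jc1)
        assert tree.same_topology(start)

    def test_topology_recovery_on_simulated_data(self):
        truth_model = default_simulation_model(alpha=1.0)
        rng = np.random.default_rng(42)
        hits = 0
        for rep in range(5):
            from plastconflict.tree import assign_branch_lengths, random_topology

            true_tree = random_topology([f"t{i}" for i in range(8)], rng)
            assign_branch_lengths(true_tree, lambda: float(rng.exponential(0.12)))
            locus = simulate_locus(
                true_tree, truth_model, 1500, rng=rng, locus_id="sim"
            )
            m = concatenate([locus])
            start = random_topology([f"t{i}" for i in range(8)], rng)
            assign_branch_lengths(start, lambda: 0.1)
            est, _ = nni_search(m, start, truth_model, seed=rep, restarts=2)
            if est.same_topology(true_tree):
                hits += 1
        assert hits >= 4


class TestBootstrap:
    def test_same_seed_identical_supports(self, jc1):
        rng = np.random.default_rng(9)
        m = random_matrix([f"t{i}" for i in range(5)], 120, rng)
        tree = PhyloTree.from_newick(
            "((t0:0.2,t1:0.2):0.1,(t2:0.2,t4:0.2):0.1,t3:0.2);"
        )
        a = bootstrap_support(m, tree, jc1, b=5, seed=123)
        b = bootstrap_support(m, tree, jc1, b=5, seed=123)
        assert a.to_newick() == b.to_newick()

    def test_single_replicate_supports_are_zero_or_hundred(self, jc1):
        rng = np.random.default_rng(10)
        m = random_matrix([f"t{i}" for i in range(5)], 120, rng)
        tree = PhyloTree.from_newick(
            "((t0:0.2,t1:0.2):0.1,(t2:0.2,t4:0.2):0.1,t3:0.2);"
        )
        out = bootstrap_support(m, tree, jc1, b=1, seed=1)
        sups = [n.support for n in out.postorder() if n.support is not None]
        assert sups and all(s in (0.0, 100.0) for s in sups)

    def test_strong_signal_gives_high_support(self):
        model = default_simulation_model(alpha=1.0)
        tree = PhyloTree.from_newick(
            "((t0:0.15,t1:0.15):0.08,(t2:0.15,(t3:0.15,t4:0.15):0.08):0.08,t5:0.2);"
        )
        locus = simulate_locus(tree, model, 1200, seed=21, locus_id="sim")
        m = concatenate([locus])
        out = bootstrap_support(m, tree, model, b=30, seed=2)
        sups = [n.support for n in out.postorder() if n.support is not None]
        assert sups and min(sups) >= 80.0
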