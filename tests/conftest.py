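import itertools

import numpy as np
import pytest

from plastconflict.core import Alphabet, ConcatenatedMatrix
from plastconflict.pipeline import RunConfig, run_pipeline
from plastconflict.simulate import SimulationConfig, simulate_study
from plastconflict.substmodel import SubstitutionModel


@pytest.fixture
def jc1():
    """Jukes-Cantor with a single rate category."""
    return SubstitutionModel.jc(n_categories=1)


@pytest.fixture
def gtr_gi():
    """A skewed GTR+Γ+I model exercising every mixture component."""
    return SubstitutionModel.gtr(
        [1.2, 3.0, 0.8, 1.1, 2.5, 1.0],
        [0.3, 0.2, 0.2, 0.3],
        alpha=0.7,
        n_categories=4,
        p_inv=0.1,
    )


def random_matrix(taxa, length, rng, partitions=None):
    rows = {t: "".join(rng.choice(list("ACGT"), length)) for t in taxa}
    if partitions is None:
        partitions = {"locus": (0, length)}
    return ConcatenatedMatrix(taxa=list(taxa), rows=rows, partitions=partitions)


def brute_force_loglik(matrix, tree, model):
    """Exhaustive sum over all internal-state assignments; oracle for pruning.

    Only feasible for a handful of taxa; mirrors the likelihood definition
    directly, independent of the pruning recursion.
    """
    codes = matrix.to_codes()
    idx = {t: i for i, t in enumerate(matrix.taxa)}
    rates, w = model.category_rates, model.category_weights
    pi = model.frequencies
    s = model.n_states
    nodes = tree.postorder()
    internal = [n for n in nodes if not n.is_leaf]
    vals, a, b = model._eigen
    total = 0.0
    for site in range(matrix.length):
        lik = 0.0
        for k, r in enumerate(rates):
            pmats = {}
            for n in nodes:
                if n is not tree.root:
                    if r == 0:
                        pmats[id(n)] = np.eye(s)
                    else:
                        pmats[id(n)] = (a * np.exp(vals * n.length * r)[None, :]) @ b
            cat_lik = 0.0
            for assign in itertools.product(range(s), repeat=len(internal)):
                amap = {id(n): st for n, st in zip(internal, assign)}
                p = pi[amap[id(tree.root)]]
                for n in nodes:
                    if n is tree.root:
                        continue
                    ps = amap[id(n.parent)]
                    pm = pmats[id(n)]
                    if n.is_leaf:
                        c = codes[idx[n.label], site]
                        p *= pm[ps].sum() if c < 0 else pm[ps, c]
                    else:
                        p *= pm[ps, amap[id(n)]]
                cat_lik += p
            lik += w[k] * cat_lik
        total += np.log(lik)
    return total


SMALL_STUDY = SimulationConfig(
    seed=7, n_taxa=10, n_clean=12, n_conflict=3, n_saturated=2, n_outlier=1
)


@pytest.fixture(scope="session")
def small_study():
    """A scaled-down synthetic study shared across the suite."""
    return simulate_study(SMALL_STUDY)


@pytest.fixture(scope="session")
def pipeline_artifacts(small_study, tmp_path_factory):
    """One full pipeline run on the small study, shared by every consumer."""
    loci, truth, topologies = small_study
    outdir = tmp_path_factory.mktemp("pipeline_run")
    config = RunConfig(outdir=str(outdir), seed=7, test_b=500, bootstrap_b=10)
    artifacts = run_pipeline(loci, topologies, config, return_artifacts=True)
    artifacts["outdir"] = outdir
    artifacts["config"] = config
    artifacts["truth"] = truth
    artifacts["topologies"] = topologies
    artifacts["loci"] = loci
    return artifacts
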