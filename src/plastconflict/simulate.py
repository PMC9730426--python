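"""Seeded generator of multi-locus datasets with the statistical structure
of a plastome-scale phylogenomic study.

The generator produces a candidate topology set (a base tree plus two
single-NNI rearrangements around one focal internal edge), then simulates
loci along those trees under a GTR+Γ model: a majority of "clean" loci on
the base topology, a minority of conflicting loci whose history follows an
alternative topology, a saturated subset evolving at a large rate multiple,
and a few long strongly-conflicting outlier loci. CDS-like loci are slower
and emitted in frame; IGS-like loci are shorter and faster. Each locus
independently loses taxa with a configurable probability, emulating
incomplete coverage (gaps arise only this way; indels are not simulated).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from plastconflict.core import (
    Alphabet,
    LocusAlignment,
    LocusCategory,
    TopologySet,
)
from plastconflict.io import write_locus_fasta, write_tsv
from plastconflict.substmodel import SubstitutionModel
from plastconflict.tree import PhyloTree, assign_branch_lengths, random_topology

#: Default simulation model: AT-rich plastome-like composition with a
#: transition/transversion asymmetry and moderate rate heterogeneity.
DEFAULT_GTR_RATES = (1.3, 3.0, 0.6, 1.1, 3.5, 1.0)
DEFAULT_FREQUENCIES = (0.31, 0.18, 0.19, 0.32)


def default_simulation_model(alpha: float = 0.8) -> SubstitutionModel:
    return SubstitutionModel.gtr(
        DEFAULT_GTR_RATES, DEFAULT_FREQUENCIES, alpha=alpha, n_categories=4
    )


@dataclass
class SimulationConfig:
    """Study-design parameters of the synthetic generator.

    Locus counts follow the planted-structure design: ``n_clean`` loci on
    the base topology T1, ``n_conflict`` on the alternatives (alternating
    T2/T3), ``n_saturated`` on T1 at ``saturation_multiplier`` times the
    rate, and ``n_outlier`` strongly conflicting loci on T2 at double
    length. Per-locus rates are lognormal with median 1; IGS-like loci run
    ``igs_rate_factor`` times faster than CDS-like ones.
    """

    seed: int
    n_taxa: int = 12
    n_clean: int = 30
    n_conflict: int = 6
    n_saturated: int = 6
    n_outlier: int = 3
    cds_length_range: tuple[int, int] = (300, 1500)
    igs_length_range: tuple[int, int] = (100, 800)
    rate_sigma: float = 0.4
    igs_rate_factor: float = 2.0
    saturation_multiplier: float = 10.0
    alpha: float = 0.8
    missing_prob: float = 0.2
    min_taxon_fraction: float = 0.6

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        counts = (self.n_clean, self.n_conflict, self.n_saturated, self.n_outlier)
        if any(c < 0 for c in counts):
            raise ValueError("locus counts must be non-negative")
        if sum(counts) == 0:
            raise ValueError("at least one locus must be simulated")
        if self.cds_length_range[0] % 3 or self.cds_length_range[1] % 3:
            raise ValueError("CDS length bounds must be multiples of 3")


def make_topology_set(n_taxa: int, seed: int) -> TopologySet:
    """Base topology T1 plus two single-NNI rearrangements T2 and T3.

    The base tree is a random unrooted binary topology with branch lengths
    drawn from Exponential(rate=10); T2 and T3 are the two NNI alternatives
    around one randomly chosen focal internal edge, so RF(T1,T2) =
    RF(T1,T3) = 2.
    """
    if n_taxa < 6:
        raise ValueError("need at least 6 taxa for a meaningful topology set")
    rng = np.random.default_rng(seed)
    labels = [f"taxon{i + 1:02d}" for i in range(n_taxa)]
    t1 = random_topology(labels, rng)
    assign_branch_lengths(t1, lambda: rng.exponential(0.1))
    edges = t1.internal_edges()
    focal = int(rng.integers(len(edges)))
    t2 = t1.apply_nni(focal, 0)
    t3 = t1.apply_nni(focal, 1)
    return TopologySet(trees={"T1": t1, "T2": t2, "T3": t3})


def simulate_locus(
    tree: PhyloTree,
    model: SubstitutionModel,
    length: int,
    rate_multiplier: float = 1.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    locus_id: str = "locus",
    category: LocusCategory = LocusCategory.OTHER,
) -> LocusAlignment:
    """Simulate one alignment along a tree under the model's Γ mixture.

    Ancestral states are drawn from the stationary frequencies; each site is
    assigned a mixture rate category and evolved along every branch with the
    corresponding transition matrix scaled by ``rate_multiplier``.
    """
    if length <= 0:
        raise ValueError("length must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)
    s = model.n_states
    pi = model.frequencies
    rates = model.category_rates
    weights = model.category_weights
    cat = rng.choice(len(rates), size=length, p=weights)
    states: dict[int, np.ndarray] = {}
    root = tree.root
    states[id(root)] = rng.choice(s, size=length, p=pi)
    for node in tree.preorder():
        if node is root:
            continue
        parent_states = states[id(node.parent)]
        child = np.empty(length, dtype=np.int64)
        for k in range(len(rates)):
            mask = cat == k
            if not mask.any():
                continue
            t = node.length * rate_multiplier * rates[k]
            if t == 0:
                child[mask] = parent_states[mask]
                continue
            vals, a, b = model._eigen
            pmat = (a * np.exp(vals * t)[None, :]) @ b
            pmat = np.clip(pmat, 0, 1)
            pmat /= pmat.sum(axis=1, keepdims=True)
            cum = np.cumsum(pmat, axis=1)
            u = rng.random(int(mask.sum()))
            child[mask] = (u[:, None] > cum[parent_states[mask]]).sum(axis=1)
        states[id(node)] = child
    alpha_chars = "ACGT" if model.alphabet == Alphabet.NT else None
    if alpha_chars is None:
        from plastconflict.core import AA_STATES

        alpha_chars = AA_STATES
    seqs = {}
    for leaf in tree.leaves():
        arr = states[id(leaf)]
        seqs[leaf.label] = "".join(alpha_chars[x] for x in arr)
    return LocusAlignment(
        locus_id=locus_id,
        category=category,
        seqs=seqs,
        alphabet=model.alphabet,
    )


def _drop_taxa(
    locus: LocusAlignment, rng: np.random.Generator, missing_prob: float, min_frac: float
) -> LocusAlignment:
    taxa = locus.taxa
    keep = [t for t in taxa if rng.random() >= missing_prob]
    min_keep = max(4, int(np.ceil(min_frac * len(taxa))))
    if len(keep) < min_keep:
        dropped = [t for t in taxa if t not in keep]
        rng.shuffle(dropped)
        keep = keep + dropped[: min_keep - len(keep)]
    keep_set = set(keep)
    return LocusAlignment(
        locus_id=locus.locus_id,
        category=locus.category,
        seqs={t: s for t, s in locus.seqs.items() if t in keep_set},
        alphabet=locus.alphabet,
    )


def simulate_study(
    config: SimulationConfig,
) -> tuple[list[LocusAlignment], pd.DataFrame, TopologySet]:
    """Simulate the full planted-structure study.

    Returns the loci, a truth table (locus_id, category, class, topology,
    rate multiplier, length, taxa retained), and the candidate topology set.
    """
    rng = np.random.default_rng(config.seed)
    topo_seed = int(rng.integers(2**31 - 1))
    topologies = make_topology_set(config.n_taxa, topo_seed)
    model = default_simulation_model(alpha=config.alpha)

    plan: list[tuple[str, str, float, float]] = []  # (class, topology, rate_factor, len_factor)
    for i in range(config.n_clean):
        plan.append(("clean", "T1", 1.0, 1.0))
    for i in range(config.n_conflict):
        plan.append(("conflict", "T2" if i % 2 == 0 else "T3", 1.0, 1.0))
    for i in range(config.n_saturated):
        plan.append(("saturated", "T1", config.saturation_multiplier, 1.0))
    for i in range(config.n_outlier):
        plan.append(("outlier", "T2", 1.0, 2.0))

    loci: list[LocusAlignment] = []
    rows = []
    counters = {"CDS": 0, "IGS": 0}
    for idx, (klass, topo, rate_factor, len_factor) in enumerate(plan):
        category = LocusCategory.CDS if idx % 2 == 0 else LocusCategory.IGS
        if category == LocusCategory.CDS:
            lo, hi = config.cds_length_range
            length = int(rng.integers(lo // 3, hi // 3 + 1)) * 3
        else:
            lo, hi = config.igs_length_range
            length = int(rng.integers(lo, hi + 1))
        length = int(length * len_factor)
        if category == LocusCategory.CDS:
            length -= length % 3
        multiplier = float(np.exp(rng.normal(0.0, config.rate_sigma)))
        multiplier *= rate_factor
        if category == LocusCategory.IGS:
            multiplier *= config.igs_rate_factor
        counters[category.value] += 1
        locus_id = f"{category.value.lower()}_{counters[category.value]:03d}"
        locus = simulate_locus(
            topologies[topo],
            model,
            length,
            rate_multiplier=multiplier,
            rng=rng,
            locus_id=locus_id,
            category=category,
        )
        locus = _drop_taxa(locus, rng, config.missing_prob, config.min_taxon_fraction)
        loci.append(locus)
        rows.append(
            {
                "locus_id": locus_id,
                "category": category.value,
                "class": klass,
                "topology": topo,
                "rate_multiplier": multiplier,
                "length": length,
                "n_taxa": len(locus.taxa),
            }
        )
    truth = pd.DataFrame(rows)
    return loci, truth, topologies


def write_study(
    loci: list[LocusAlignment],
    truth: pd.DataFrame,
    topologies: TopologySet,
    outdir,
) -> None:
    """Write per-locus FASTA, a manifest TSV, the truth table, and Newick
    topologies under ``outdir``."""
    outdir = str(outdir)
    locus_dir = os.path.join(outdir, "loci")
    os.makedirs(locus_dir, exist_ok=True)
    manifest_rows = []
    for locus in loci:
        path = os.path.join("loci", f"{locus.locus_id}.fasta")
        write_locus_fasta(locus, os.path.join(outdir, path))
        manifest_rows.append(
            {"locus_id": locus.locus_id, "category": locus.category.value, "path": path}
        )
    write_tsv(pd.DataFrame(manifest_rows), os.path.join(outdir, "manifest.tsv"))
    write_tsv(truth, os.path.join(outdir, "truth.tsv"))
    for label, tree in topologies.items():
        tree.write(os.path.join(outdir, f"{label}.nwk"), with_support=False)
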