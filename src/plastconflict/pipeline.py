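"""End-to-end pipeline: filter → diagnostics → strategy grid → per-matrix
site likelihoods → signal → topology tests → summary table.

Every random stage is seeded from the run seed, so a rerun with the same
configuration is byte-identical. Every locus removal is logged with its
reason. The summary table has one row per grid matrix, mirroring a
meta-analysis over the dataset strategies: which topology each matrix
supports, the supported-locus proportions, and all five test p-values per
candidate topology.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from plastconflict import io as pio
from plastconflict.core import (
    ConcatenatedMatrix,
    LocusAlignment,
    LocusCategory,
    SiteLikelihoodTable,
    TopologySet,
)
from plastconflict.diagnostics import diagnose_locus, diagnostics_table
from plastconflict.likelihood import (
    OptimizationSettings,
    bootstrap_support,
    fit_model,
    nni_search,
    optimize_branch_lengths,
    site_loglik,
)
from plastconflict.locus_prep import (
    StrategyGridConfig,
    build_strategy_grid,
    concatenate,
    filter_loci,
)
from plastconflict.signal import gene_wise_gls, signal_table, support_proportions
from plastconflict.substmodel import SubstitutionModel
from plastconflict.topo_tests import DEFAULT_SCALES, run_topology_tests

logger = logging.getLogger("plastconflict")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    outdir: str
    seed: int
    min_coverage: float = 0.55
    min_len_cds: int = 100
    min_len_igs: int = 50
    grid: StrategyGridConfig = field(default_factory=StrategyGridConfig)
    collapse_threshold: float = 10.0
    bootstrap_b: int = 25
    genetree_restarts: int = 1
    model_alpha0: float = 0.5
    gamma_categories: int = 4
    use_p_inv: bool = False
    test_b: int = 10000
    test_scales: tuple = DEFAULT_SCALES
    optimization: OptimizationSettings = field(default_factory=OptimizationSettings)

    def model_template(self) -> SubstitutionModel:
        return SubstitutionModel.gtr(
            np.ones(6),
            np.full(4, 0.25),
            alpha=self.model_alpha0,
            n_categories=self.gamma_categories,
            p_inv=0.2 if self.use_p_inv else 0.0,
        )


def compute_diagnostics(
    loci: list[LocusAlignment],
    topologies: TopologySet,
    model: SubstitutionModel,
    config: RunConfig,
) -> tuple[pd.DataFrame, dict[str, object]]:
    """Infer a gene tree per locus (NNI from the base topology, bootstrap
    support, low-support collapse for export) and compute its diagnostics."""
    base = topologies["T1"]
    records = []
    gene_trees: dict[str, object] = {}
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    for locus in loci:
        matrix = concatenate([locus])
        start = base.pruned_to(matrix.taxa)
        seed = int(rng.integers(2**31 - 1))
        tree, lnl = nni_search(
            matrix,
            start,
            model,
            config.optimization,
            seed=seed,
            restarts=config.genetree_restarts,
        )
        supported = bootstrap_support(
            matrix, tree, model, b=config.bootstrap_b, seed=seed + 1,
            settings=config.optimization,
        )
        records.append(diagnose_locus(locus, supported))
        gene_trees[locus.locus_id] = supported.collapse_low_support(
            config.collapse_threshold
        )
        logger.info(
            "gene tree %s: lnL=%.3f mean_support=%.1f",
            locus.locus_id,
            lnl,
            records[-1].mean_support,
        )
    return diagnostics_table(records), gene_trees


def analyze_matrix(
    matrix: ConcatenatedMatrix,
    topologies: TopologySet,
    model_template: SubstitutionModel,
    config: RunConfig,
    label: str = "",
    seed: int | None = None,
) -> dict:
    """Fixed-topology likelihood analysis of one matrix.

    The substitution model is fitted once (on the first topology) and shared
    across candidates, matching the convention of evaluating ΔGLS "under the
    same model"; branch lengths are re-optimised per topology. Returns the
    site-likelihood tables, signal records, supported-topology proportions,
    and topology-test table.
    """
    labels = topologies.labels()
    trees = {t: topologies[t].pruned_to(matrix.taxa) for t in labels}
    first = labels[0]
    model, tree0, lnl0 = fit_model(
        matrix, trees[first], model_template, config.optimization
    )
    tables: dict[str, SiteLikelihoodTable] = {}
    totals: dict[str, float] = {}
    for t in labels:
        if t == first:
            opt_tree, lnl = tree0, lnl0
        else:
            opt_tree, lnl = optimize_branch_lengths(
                matrix, trees[t], model, config.optimization
            )
        tables[t] = site_loglik(matrix, opt_tree, model, topology_id=t)
        totals[t] = lnl
    records = gene_wise_gls(tables, matrix.partitions)
    proportions = support_proportions(records)
    sls = {t: tables[t].sls for t in labels}
    _, tests = run_topology_tests(
        sls, b=config.test_b, scales=config.test_scales, seed=seed
    )
    logger.info(
        "matrix %s: L=%d loci=%d lnL=%s",
        label,
        matrix.length,
        len(matrix.partitions),
        {t: round(v, 3) for t, v in totals.items()},
    )
    return {
        "label": label,
        "matrix": matrix,
        "model": model,
        "tables": tables,
        "totals": totals,
        "records": records,
        "proportions": proportions,
        "tests": tests,
    }


def base_signal_table(
    cds_loci: list[LocusAlignment],
    igs_loci: list[LocusAlignment],
    topologies: TopologySet,
    model_template: SubstitutionModel,
    config: RunConfig,
) -> tuple[pd.DataFrame, dict[str, dict]]:
    """Signal (mean ΔGLS per locus) on the three base matrices.

    Returns a tidy table (dataset, locus_id, mean_delta, supported) used by
    the strategy grid's no-outlier datasets, plus the full per-dataset
    analysis payloads.
    """
    families = {
        "CDS": cds_loci,
        "IGS": igs_loci,
        "All": list(cds_loci) + list(igs_loci),
    }
    rows = []
    payloads = {}
    for name, loci in families.items():
        if not loci:
            continue
        matrix = concatenate(loci).with_provenance(name)
        payload = analyze_matrix(
            matrix, topologies, model_template, config, label=name,
            seed=config.seed + 101,
        )
        payloads[name] = payload
        for rec in payload["records"]:
            rows.append(
                {
                    "dataset": name,
                    "locus_id": rec.locus_id,
                    "mean_delta": rec.mean_delta,
                    "supported": rec.supported,
                }
            )
    return pd.DataFrame(rows), payloads


def run_pipeline(
    loci: list[LocusAlignment],
    topologies: TopologySet,
    config: RunConfig,
    n_taxa_total: int | None = None,
    return_artifacts: bool = False,
) -> pd.DataFrame | dict:
    """Execute every stage and write results under ``config.outdir``.

    Returns the summary table (one row per non-empty grid matrix), or, with
    ``return_artifacts``, a dict carrying the summary plus the intermediate
    grid, diagnostics, signal table, and per-matrix payloads.
    """
    outdir = config.outdir
    for sub in ("matrices", "trees", "tables", "logs"):
        os.makedirs(os.path.join(outdir, sub), exist_ok=True)
    handler = logging.FileHandler(os.path.join(outdir, "logs", "run.log"), mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        artifacts = _run(loci, topologies, config, n_taxa_total)
    finally:
        logger.removeHandler(handler)
        handler.close()
    return artifacts if return_artifacts else artifacts["summary"]


def _run(loci, topologies, config, n_taxa_total) -> dict:
    outdir = config.outdir
    if n_taxa_total is None:
        n_taxa_total = len(topologies[topologies.labels()[0]].leaf_labels())

    # stage 1: locus filters
    kept, rejections = filter_loci(
        loci,
        n_taxa_total,
        min_coverage=config.min_coverage,
        min_len_cds=config.min_len_cds,
        min_len_igs=config.min_len_igs,
    )
    for row in rejections.itertuples():
        logger.info("locus %s rejected: %s (%s)", row.locus_id, row.reason, row.value)
    pio.write_tsv(rejections, os.path.join(outdir, "tables", "rejections.tsv"))
    cds = [l for l in kept if l.category == LocusCategory.CDS]
    igs = [l for l in kept if l.category != LocusCategory.CDS]

    template = config.model_template()

    # stage 2: global model on the full concatenation, reused for gene trees
    all_matrix = concatenate(kept)
    base_tree = topologies["T1"].pruned_to(all_matrix.taxa)
    global_model, _, _ = fit_model(all_matrix, base_tree, template, config.optimization)

    # stage 3: per-locus gene trees and diagnostics
    diag, gene_trees = compute_diagnostics(kept, topologies, global_model, config)
    pio.write_tsv(diag, os.path.join(outdir, "tables", "diagnostics.tsv"))
    for locus_id, tree in gene_trees.items():
        tree.write(os.path.join(outdir, "trees", f"{locus_id}.nwk"))

    # stage 4: signal on base matrices (feeds no-outlier datasets)
    signal_df, base_payloads = base_signal_table(
        cds, igs, topologies, global_model, config
    )
    pio.write_tsv(signal_df, os.path.join(outdir, "tables", "base_signal.tsv"))

    # stage 5: strategy grid
    grid = build_strategy_grid(cds, igs, diag, signal_df, config.grid)
    logger.info("strategy grid: %d matrices", len(grid))

    # stage 6: per-matrix analysis and summary
    rows = []
    payloads = {}
    labels = topologies.labels()
    for i, (name, matrix) in enumerate(grid.items()):
        pio.write_matrix_fasta(
            matrix, os.path.join(outdir, "matrices", f"{name}.fasta")
        )
        if "empty" in matrix.provenance:
            logger.warning("matrix %s is empty after trimming; skipped", name)
            continue
        payload = analyze_matrix(
            matrix, topologies, global_model, config, label=name,
            seed=config.seed + 1000 + i,
        )
        payloads[name] = payload
        pio.write_sls_tsv(
            {t: payload["tables"][t].sls for t in labels},
            os.path.join(outdir, "tables", f"sls_{name}.tsv"),
        )
        pio.write_tsv(
            signal_table(payload["records"]),
            os.path.join(outdir, "tables", f"signal_{name}.tsv"),
        )
        row = {
            "matrix": name,
            "n_loci": len(matrix.partitions),
            "n_sites": matrix.length,
        }
        best = max(payload["totals"], key=payload["totals"].get)
        row["best_topology"] = best
        for t in labels:
            row[f"lnl_{t}"] = payload["totals"][t]
            row[f"pct_{t}"] = payload["proportions"][t]
        row["pct_ambiguous"] = payload["proportions"]["ambiguous"]
        tests = payload["tests"].set_index("topology")
        for t in labels:
            for col in ("p_au", "p_kh", "p_sh", "p_wkh", "p_wsh"):
                row[f"{col}_{t}"] = float(tests.loc[t, col])
        rows.append(row)
    summary = pd.DataFrame(rows)
    pio.write_tsv(summary, os.path.join(outdir, "tables", "summary.tsv"))
    return {
        "summary": summary,
        "grid": grid,
        "diagnostics": diag,
        "signal": signal_df,
        "payloads": payloads,
        "rejections": rejections,
    }
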