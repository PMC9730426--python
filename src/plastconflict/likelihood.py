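"""Felsenstein pruning engine with site-pattern compression, branch-length
and model optimisation, NNI tree search, and nonparametric bootstrap.

The engine is alphabet-generic (4 or 20 states) and evaluates the discrete
Γ(+I) mixture with per-pattern log-scaling, so likelihoods stay finite at
any taxon count. Branch lengths are optimised one edge at a time by bounded
scalar search on the exact single-edge likelihood, using cached "inside"
(subtree) and "outside" (rest-of-tree) conditional vectors; the inside
cache is refreshed on the way back up the traversal, so every single-edge
optimisation is exact given the current remaining lengths and the total
log-likelihood never decreases.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize, minimize_scalar

from plastconflict.core import ConcatenatedMatrix, SiteLikelihoodTable
from plastconflict.substmodel import SubstitutionModel
from plastconflict.tree import Node, PhyloTree, assign_branch_lengths, random_topology

_TINY = 1e-300


def _colmax(arr: np.ndarray) -> np.ndarray:
    """Per-pattern max of a (K, P, S) partial; contiguous reductions only."""
    return arr.max(axis=2).max(axis=0)


@dataclass
class OptimizationSettings:
    """Knobs for branch-length and model optimisation."""

    bl_min: float = 1e-8
    bl_max: float = 10.0
    tolerance: float = 1e-4
    max_iterations: int = 50
    brent_xatol: float = 1e-6
    model_rounds: int = 2
    nni_restarts: int = 5


class CompressedAlignment:
    """Integer-coded alignment collapsed to unique site patterns."""

    def __init__(self, matrix: ConcatenatedMatrix, taxa: list[str] | None = None):
        self.taxa = list(taxa) if taxa is not None else list(matrix.taxa)
        missing = set(self.taxa) - set(matrix.taxa)
        if missing:
            raise ValueError(f"taxa absent from matrix: {sorted(missing)}")
        codes = matrix.to_codes()
        rows = [matrix.taxa.index(t) for t in self.taxa]
        codes = codes[rows]
        self.n_states = 4 if matrix.alphabet.value == "NT" else 20
        patterns, inverse, counts = np.unique(
            codes, axis=1, return_inverse=True, return_counts=True
        )
        self.patterns = patterns  # (n_taxa, n_patterns)
        self.pattern_index = inverse.ravel()  # original column -> pattern
        self.weights = counts.astype(float)
        self.n_sites = codes.shape[1]
        self.n_patterns = patterns.shape[1]
        # one-hot tip partials; ambiguity (-1) becomes all-ones
        self._tips: dict[str, np.ndarray] = {}
        eye = np.eye(self.n_states)
        for i, taxon in enumerate(self.taxa):
            col = self.patterns[i]
            tip = np.where(col[:, None] >= 0, eye[np.clip(col, 0, None)], 1.0)
            self._tips[taxon] = tip  # (n_patterns, S)

    def tip_partial(self, taxon: str) -> np.ndarray:
        return self._tips[taxon]

    def empirical_frequencies(self, pseudocount: float = 0.5) -> np.ndarray:
        flat = self.patterns.ravel()
        counts = np.bincount(
            flat[flat >= 0],
            weights=np.tile(self.weights, len(self.taxa))[flat >= 0],
            minlength=self.n_states,
        )
        counts = counts + pseudocount
        return counts / counts.sum()


class PruningEngine:
    """Likelihood of one compressed alignment under one tree and model.

    The engine mutates the tree's branch lengths in place during
    optimisation; topology is fixed.
    """

    def __init__(
        self,
        data: CompressedAlignment,
        tree: PhyloTree,
        model: SubstitutionModel,
    ):
        leafset = set(tree.leaf_labels())
        dataset = set(data.taxa)
        if leafset != dataset:
            raise ValueError(
                "tree leaves and alignment taxa differ: "
                f"only-in-tree={sorted(leafset - dataset)}, "
                f"only-in-data={sorted(dataset - leafset)}"
            )
        self.data = data
        self.tree = tree
        self.model = model
        self._down: dict[int, np.ndarray] = {}
        self._down_logsc: dict[int, np.ndarray] = {}

    # ------------------------------------------------------------ internals

    def _pmats(self, t: float) -> np.ndarray:
        return self.model.transition_matrices(t)

    def _contrib(self, node: Node) -> tuple[np.ndarray, np.ndarray]:
        """Message from ``node`` to its parent through the edge above it."""
        pmat_t = self._pmats(node.length).transpose(0, 2, 1)
        if node.is_leaf:
            arr = np.matmul(self.data.tip_partial(node.label), pmat_t)
            logsc = np.zeros(self.data.n_patterns)
        else:
            arr = np.matmul(self._down[id(node)], pmat_t)
            logsc = self._down_logsc[id(node)]
        return arr, logsc

    def _refresh_down(self, node: Node) -> None:
        arr = None
        logsc = None
        for child in node.children:
            c_arr, c_logsc = self._contrib(child)
            if arr is None:
                arr = c_arr  # matmul output, safe to mutate
                logsc = np.array(c_logsc, copy=True)
            else:
                arr *= c_arr
                logsc += c_logsc
        scale = np.maximum(_colmax(arr), _TINY)
        arr /= scale[None, :, None]
        self._down[id(node)] = arr
        self._down_logsc[id(node)] = logsc + np.log(scale)

    def _compute_down(self) -> None:
        self._down.clear()
        self._down_logsc.clear()
        for node in self.tree.postorder():
            if not node.is_leaf:
                self._refresh_down(node)

    def _pattern_loglik(self) -> np.ndarray:
        root = self.tree.root
        if root.is_leaf:  # degenerate single-leaf tree
            raise ValueError("tree has no internal structure")
        arr = self._down[id(root)]
        w = self.model.category_weights
        pi = self.model.frequencies
        site = np.tensordot(w, arr @ pi, axes=(0, 0))
        site = np.maximum(site, _TINY)
        return np.log(site) + self._down_logsc[id(root)]

    # ----------------------------------------------------------- public API

    def loglik(self) -> float:
        self._compute_down()
        per_pattern = self._pattern_loglik()
        total = float(np.dot(self.data.weights, per_pattern))
        if not np.isfinite(total):
            raise ValueError("non-finite log-likelihood")
        return total

    def site_loglik(self) -> np.ndarray:
        """Per-original-column ln-likelihoods (pattern values expanded)."""
        self._compute_down()
        per_pattern = self._pattern_loglik()
        sls = per_pattern[self.data.pattern_index]
        return np.minimum(sls, 0.0)

    def _outside(self, node: Node) -> tuple[np.ndarray, np.ndarray]:
        """Outside (rest-of-tree) partial at the parent of ``node``.

        Requires fresh inside partials (``_compute_down``)."""
        path: list[Node] = []
        cur = node
        while cur.parent is not None:
            path.append(cur)
            cur = cur.parent
        path.reverse()
        pi = self.model.frequencies
        k = len(self.model.category_rates)
        out = np.broadcast_to(
            pi[None, None, :], (k, self.data.n_patterns, self.data.n_states)
        ).copy()
        logsc = np.zeros(self.data.n_patterns)
        parent = self.tree.root
        for step in path:
            if parent is not self.tree.root:
                out = np.matmul(out, self._pmats(parent.length))
            for other in parent.children:
                if other is not step:
                    arr, sc = self._contrib(other)
                    out *= arr
                    logsc += sc
            scale = np.maximum(_colmax(out), _TINY)
            out /= scale[None, :, None]
            logsc += np.log(scale)
            parent = step
        return out, logsc

    def optimize_single_edge(
        self, node: Node, settings: "OptimizationSettings | None" = None
    ) -> float:
        """Exactly optimise one branch, all others fixed; returns total lnL."""
        settings = settings or OptimizationSettings()
        self._compute_down()
        out, logsc = self._outside(node)
        self._optimize_edge(node, out, logsc, settings)
        return self._edge_loglik_fn(node, out, logsc)(node.length)

    # --------------------------------------------------- branch optimisation

    def _edge_loglik_fn(self, node: Node, out: np.ndarray, out_logsc: np.ndarray):
        """Return f(t) = total lnL as a function of the edge above ``node``."""
        if node.is_leaf:
            below = self.data.tip_partial(node.label)
            below_logsc = 0.0
        else:
            below = self._down[id(node)]
            below_logsc = self._down_logsc[id(node)]
        w = self.model.category_weights
        weights = self.data.weights
        # project both partials into the eigenbasis once; each evaluation
        # then only touches the spectral coordinates:
        # P(t r_k) = A diag(exp(lam t r_k)) B, so
        # sum_xy out_x P_xy below_y = sum_e exp(lam_e t r_k) (out A)_e (B below)_e
        vals, a, b = self.model._eigen
        rates = self.model.category_rates
        g = np.matmul(out, a) * np.matmul(below, b.T)  # (K, P, S)
        gw = g * w[:, None, None]
        const = out_logsc + below_logsc

        def f(t: float) -> float:
            e = np.exp(np.outer(rates, vals) * t)  # (K, S)
            site = gw[0] @ e[0]
            for k in range(1, len(rates)):
                site += gw[k] @ e[k]
            np.maximum(site, _TINY, out=site)
            lnl = np.log(site)
            lnl += const
            return float(np.dot(weights, lnl))

        return f

    def _optimize_edge(
        self, node: Node, out: np.ndarray, out_logsc: np.ndarray, settings
    ) -> None:
        f = self._edge_loglik_fn(node, out, out_logsc)
        current = f(node.length)
        res = minimize_scalar(
            lambda t: -f(t),
            bounds=(settings.bl_min, settings.bl_max),
            method="bounded",
            options={"xatol": settings.brent_xatol},
        )
        best_t, best_f = node.length, current
        if -res.fun > best_f:
            best_t, best_f = float(res.x), -res.fun
        # snap to the lower bound when the likelihood is flat there
        if best_t < 1e-4 and f(settings.bl_min) >= best_f - 1e-10:
            best_t = settings.bl_min
        node.length = best_t

    def optimize_branch_lengths(
        self, settings: OptimizationSettings | None = None, max_sweeps: int | None = None
    ) -> float:
        """Round-robin single-edge optimisation until lnL gain < tolerance.

        Returns the final total log-likelihood; lnL is non-decreasing
        across sweeps.
        """
        settings = settings or OptimizationSettings()
        sweeps = max_sweeps if max_sweeps is not None else settings.max_iterations
        self._compute_down()
        pi = self.model.frequencies
        k = len(self.model.category_rates)
        prev = float(np.dot(self.data.weights, self._pattern_loglik()))
        for sweep in range(sweeps):
            self._sweep(settings, pi, k)
            self._compute_down()
            lnl = float(np.dot(self.data.weights, self._pattern_loglik()))
            if lnl - prev < settings.tolerance:
                prev = max(lnl, prev)
                break
            prev = lnl
        else:
            if sweeps >= settings.max_iterations:
                warnings.warn("branch-length optimisation hit max iterations")
        return prev

    def _sweep(self, settings, pi, k) -> None:
        root = self.tree.root

        def visit(node: Node, out: np.ndarray, out_logsc: np.ndarray) -> None:
            self._optimize_edge(node, out, out_logsc, settings)
            if node.is_leaf:
                return
            for child in node.children:
                contribs = {}
                sc = {}
                for other in node.children:
                    if other is not child:
                        contribs[id(other)], sc[id(other)] = self._contrib(other)
                trans = np.matmul(out, self._pmats(node.length))
                child_out = trans
                child_logsc = out_logsc.copy()
                for other in node.children:
                    if other is not child:
                        child_out = child_out * contribs[id(other)]
                        child_logsc = child_logsc + sc[id(other)]
                scale = np.maximum(_colmax(child_out), _TINY)
                child_out = child_out / scale[None, :, None]
                child_logsc = child_logsc + np.log(scale)
                visit(child, child_out, child_logsc)
                if not child.is_leaf:
                    self._refresh_down(child)

        base_out = np.broadcast_to(
            pi[None, None, :], (k, self.data.n_patterns, self.data.n_states)
        )
        zero = np.zeros(self.data.n_patterns)
        for child in root.children:
            out = np.array(base_out)
            logsc = zero.copy()
            for other in root.children:
                if other is not child:
                    arr, s = self._contrib(other)
                    out = out * arr
                    logsc = logsc + s
            scale = np.maximum(_colmax(out), _TINY)
            out = out / scale[None, :, None]
            logsc = logsc + np.log(scale)
            visit(child, out, logsc)
            if not child.is_leaf:
                self._refresh_down(child)


# --------------------------------------------------------------- operations


def site_loglik(
    matrix: ConcatenatedMatrix,
    tree: PhyloTree,
    model: SubstitutionModel,
    topology_id: str = "T",
) -> SiteLikelihoodTable:
    """Per-column ln-likelihoods of ``matrix`` under a fixed tree and model."""
    data = CompressedAlignment(matrix, tree.leaf_labels())
    engine = PruningEngine(data, tree, model)
    sls = engine.site_loglik()
    return SiteLikelihoodTable(
        topology_id=topology_id, sls=sls, tree_used=tree, model_used=model
    )


def optimize_branch_lengths(
    matrix: ConcatenatedMatrix,
    tree: PhyloTree,
    model: SubstitutionModel,
    settings: OptimizationSettings | None = None,
) -> tuple[PhyloTree, float]:
    """Optimise branch lengths on a fixed topology; returns (tree, lnL)."""
    tree = tree.copy()
    data = CompressedAlignment(matrix, tree.leaf_labels())
    engine = PruningEngine(data, tree, model)
    lnl = engine.optimize_branch_lengths(settings)
    return tree, lnl


def fit_model(
    matrix: ConcatenatedMatrix,
    tree: PhyloTree,
    model_template: SubstitutionModel,
    settings: OptimizationSettings | None = None,
    fit_exchangeabilities: bool | None = None,
    fit_alpha: bool = True,
) -> tuple[SubstitutionModel, PhyloTree, float]:
    """Fit free model parameters by coordinate ascent with branch lengths.

    Nucleotide models free the 5 relative GTR exchangeabilities; amino-acid
    models keep the supplied exchangeability matrix fixed. Frequencies are
    empirical counts. Γ shape (and p_inv, when the template enables it) are
    optimised numerically. lnL is non-decreasing across rounds.
    """
    settings = settings or OptimizationSettings()
    tree = tree.copy()
    data = CompressedAlignment(matrix, tree.leaf_labels())
    freqs = data.empirical_frequencies()
    model = model_template.replace(frequencies=freqs)
    if fit_exchangeabilities is None:
        fit_exchangeabilities = model.n_states == 4

    # degenerate alignment: no variable pattern -> alpha unidentifiable
    variable = np.any(
        [
            len({c for c in col if c >= 0}) > 1
            for col in data.patterns.T
        ]
    )
    if not variable and fit_alpha:
        warnings.warn("alignment has no variable site; fixing gamma shape at 1")
        model = model.replace(alpha=1.0)
        fit_alpha = False

    engine = PruningEngine(data, tree, model)
    lnl = engine.optimize_branch_lengths(settings)

    fit_pinv = model_template.p_inv > 0
    for _ in range(settings.model_rounds):
        theta0, unpack = _pack_params(model, fit_exchangeabilities, fit_alpha, fit_pinv)
        if len(theta0) == 0:
            break

        def objective(theta):
            trial = unpack(theta)
            eng = PruningEngine(data, tree, trial)
            try:
                return -eng.loglik()
            except (ValueError, FloatingPointError):
                return 1e12

        res = minimize(
            objective,
            theta0,
            method="L-BFGS-B",
            options={"maxiter": 20, "ftol": 1e-7},
        )
        candidate = unpack(res.x)
        eng = PruningEngine(data, tree, candidate)
        if eng.loglik() >= lnl - 1e-9:
            model = candidate
            engine = PruningEngine(data, tree, model)
        new_lnl = engine.optimize_branch_lengths(settings)
        if new_lnl - lnl < settings.tolerance:
            lnl = max(new_lnl, lnl)
            break
        lnl = new_lnl
    return model, tree, lnl


def _pack_params(model, fit_ex, fit_alpha, fit_pinv):
    """Map free parameters to an unconstrained vector and back."""
    parts = []
    if fit_ex:
        rates = model.gtr_rates()[:-1]
        parts.append(np.log(np.maximum(rates, 1e-8)))
    if fit_alpha:
        parts.append([np.log(model.alpha)])
    if fit_pinv:
        p = np.clip(model.p_inv, 1e-4, 0.98)
        parts.append([np.log(p / (1 - p))])
    theta0 = np.concatenate(parts) if parts else np.array([])

    def unpack(theta):
        i = 0
        kwargs = {}
        if fit_ex:
            rates = np.exp(np.clip(theta[i : i + 5], -10, 10))
            full = np.concatenate([rates, [1.0]])
            ex = np.zeros((4, 4))
            ex[np.triu_indices(4, 1)] = full
            kwargs["exchangeabilities"] = ex + ex.T
            i += 5
        if fit_alpha:
            kwargs["alpha"] = float(np.exp(np.clip(theta[i], -5, 7)))
            i += 1
        if fit_pinv:
            kwargs["p_inv"] = float(1 / (1 + np.exp(-np.clip(theta[i], -12, 6))))
            i += 1
        return model.replace(**kwargs)

    return theta0, unpack


def nni_search(
    matrix: ConcatenatedMatrix,
    start: PhyloTree,
    model: SubstitutionModel,
    settings: OptimizationSettings | None = None,
    seed: int | None = None,
    restarts: int | None = None,
) -> tuple[PhyloTree, float]:
    """Hill-climbing NNI search with seeded random restarts.

    Candidate neighbours are scored after a single branch-length sweep; the
    best improving move is accepted and fully re-optimised. With fewer than
    4 taxa the start tree is returned unchanged.
    """
    settings = settings or OptimizationSettings()
    if restarts is None:
        restarts = settings.nni_restarts
    labels = start.leaf_labels()
    data = CompressedAlignment(matrix, labels)
    if len(labels) < 4:
        tree = start.copy()
        lnl = PruningEngine(data, tree, model).optimize_branch_lengths(settings)
        return tree, lnl

    rng = np.random.default_rng(seed)
    best_tree, best_lnl = _hill_climb(data, start.copy(), model, settings)
    for _ in range(restarts):
        rand = random_topology(labels, rng)
        assign_branch_lengths(rand, lambda: rng.exponential(0.1))
        tree, lnl = _hill_climb(data, rand, model, settings)
        if lnl > best_lnl:
            best_tree, best_lnl = tree, lnl
    return best_tree, best_lnl


def _hill_climb(data, tree, model, settings) -> tuple[PhyloTree, float]:
    engine = PruningEngine(data, tree, model)
    best_lnl = engine.optimize_branch_lengths(settings)
    while True:
        best_cand = None
        cand_lnl = best_lnl
        n_edges = len(tree.internal_edges())
        for edge_idx in range(n_edges):
            for which in (0, 1):
                cand, central = tree.apply_nni(edge_idx, which, return_edge=True)
                eng = PruningEngine(data, cand, model)
                lnl = eng.optimize_single_edge(central, settings)
                if lnl > cand_lnl + 1e-6:
                    best_cand, cand_lnl = cand, lnl
        if best_cand is None:
            return tree, best_lnl
        tree = best_cand
        engine = PruningEngine(data, tree, model)
        best_lnl = engine.optimize_branch_lengths(settings)


def bootstrap_support(
    matrix: ConcatenatedMatrix,
    tree: PhyloTree,
    model: SubstitutionModel,
    b: int = 100,
    seed: int | None = None,
    settings: OptimizationSettings | None = None,
) -> PhyloTree:
    """Nonparametric bootstrap: resample columns, re-search from ``tree``,
    and annotate each internal edge with the percentage of replicates whose
    tree contains that bipartition."""
    if b < 1:
        raise ValueError("need at least one bootstrap replicate")
    settings = settings or OptimizationSettings()
    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {}
    L = matrix.length
    for _ in range(b):
        cols = rng.integers(0, L, size=L)
        rep = _resample_columns(matrix, cols)
        rep_tree, _ = nni_search(rep, tree, model, settings, seed=None, restarts=0)
        for split in rep_tree.bipartitions():
            counts[split] = counts.get(split, 0) + 1
    out = tree.copy()
    all_leaves = frozenset(out.leaf_labels())
    ref = min(all_leaves)
    below: dict[int, frozenset] = {}
    for node in out.postorder():
        if node.is_leaf:
            below[id(node)] = frozenset([node.label])
        else:
            clade = frozenset().union(*(below[id(c)] for c in node.children))
            below[id(node)] = clade
            if node is not out.root and 1 < len(clade) < len(all_leaves) - 1:
                side = clade if ref not in clade else all_leaves - clade
                node.support = 100.0 * counts.get(side, 0) / b
    return out


def _resample_columns(matrix: ConcatenatedMatrix, cols: np.ndarray) -> ConcatenatedMatrix:
    rows = {}
    for taxon in matrix.taxa:
        row = np.frombuffer(matrix.rows[taxon].encode("ascii"), dtype=np.uint8)
        rows[taxon] = row[cols].tobytes().decode("ascii")
    return ConcatenatedMatrix(
        taxa=list(matrix.taxa),
        rows=rows,
        partitions={"resampled": (0, len(cols))},
        alphabet=matrix.alphabet,
        provenance=[*matrix.provenance, "bootstrap"],
    )
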