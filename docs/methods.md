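# Methods

## The model

All likelihood computations assume a stationary, time-reversible Markov
substitution process on an unrooted tree. The rate matrix is built from a
symmetric exchangeability matrix and stationary frequencies, scaled to one
expected substitution per site at stationarity. Rate heterogeneity across
sites uses the discrete-Γ approximation with K = 4 equal-probability
categories whose rates are the exact conditional means of the Γ(α, 1/α)
bins (computed through the incomplete-gamma identity), optionally extended
with an invariant-sites category of weight p_inv; category rates are scaled
so the weighted mean rate is 1. For shapes α ≥ 10⁵ the relative rate spread
across categories falls below 0.5% and the categories are collapsed to a
single rate — the mixture is numerically rate-homogeneous there, and the
collapse makes the large-α limit agree exactly with the single-rate model.

Nucleotide analyses use the GTR family (5 free exchangeabilities,
empirical frequencies); amino-acid analyses fix the exchangeability matrix
— equal rates (Poisson) by default, or any PAML-format empirical matrix
(LG, JTT, WAG, …) supplied as a file — with empirical frequencies. Gap and
ambiguity characters (`-`, `N`, `X`, `?`) contribute an all-ones partial
likelihood; `-` is distinguished from `N` only by coverage and trimming
statistics, not by the likelihood.

## Likelihood engine

Site patterns are collapsed before any computation; all per-site outputs
are expanded back to columns afterwards. Partial likelihood vectors are
rescaled per pattern with log-scale accumulators at every internal node, so
log-likelihoods stay finite at any taxon count. Transition matrices come
from the symmetrised eigendecomposition of the rate matrix, clamped to
[0, 1].

Branch lengths are optimised one edge at a time by bounded scalar search
(bounds [1e-8, 10], default convergence tolerance 1e-4 on lnL, at most 50
sweeps). For each edge, the inside (subtree) and outside (rest-of-tree)
conditional vectors are projected into the eigenbasis once, after which the
single-edge likelihood is an explicit function of exp(λ_e r_k t) — each
trial length costs a handful of small matrix-vector products. The outside
vectors are recomputed during the pre-order traversal and the inside cache
is refreshed on the way back up, so every single-edge optimisation is exact
given the current remaining lengths, which makes the total lnL
non-decreasing across the sweep. A branch whose likelihood is flat at the
lower bound is snapped to the bound.

Model fitting interleaves branch-length sweeps with L-BFGS-B over
log-exchangeabilities, log-α, and (when enabled) logit-p_inv, with
empirical base frequencies; alignments without a single variable site fix
α = 1 with a warning, since the shape is unidentifiable there.

Gene trees are inferred by NNI hill-climbing: each of the two neighbours
per internal edge is scored after exactly re-optimising the central edge of
the rearrangement (inside/outside caches make this one cheap pass), the
best improving move is accepted and fully re-optimised, and the search
restarts from seeded random topologies (default 5 restarts at the library
level; the pipeline default is 1 restart on top of a start tree pruned from
the base candidate topology, which on desk-scale data reaches the same
optima at a fraction of the cost). Nonparametric bootstrap resamples
columns with replacement and re-searches from the input tree; support is
the percentage of replicates containing each bipartition, and edges below
10% support are collapsed before any gene-tree export.

## Dataset strategies

Locus filters: a locus is kept when at least 55% of the study's taxa carry
at least one unambiguous residue and the aligned length is ≥ 100 bp (CDS) /
≥ 50 bp (IGS). Concatenation pads absent taxa with `-` and fixes taxon
order lexicographically.

Conserved-block trimming re-implements the Gblocks procedure rather than
shelling out to it: a column is conserved when its majority-residue
frequency is ≥ 0.5 (highly conserved ≥ 0.85) over all rows; the gap mode
(`all` / `half` / `none`) removes columns with more than 50% gaps or any
gap at all; runs of more than 8 non-conserved columns are cut, blocks are
trimmed back to highly conserved flanks, and blocks shorter than 10 columns
are dropped. Only the gap mode is varied across the grid. The kept sets are
nested: none ⊆ half ⊆ all. A matrix whose columns are all removed is a
valid (empty-flagged) grid member: with whole-locus taxon dropout even a
single missing taxon gaps every column of a locus, so the strict mode can
legitimately empty a gap-rich family.

Diagnostic filters remove whole loci by per-locus statistics computed from
their gene trees: the long-branch (LB) score of a taxon is the percent
deviation of its mean patristic distance from the tree-wide mean pairwise
distance, summarised per locus as the sample standard deviation of taxon LB
scores (removal above 45 for CDS, 90 for IGS, on the percent scale of that
definition); substitution saturation is the zero-intercept OLS of
uncorrected p-distance on patristic distance (removal below slope
0.104 / 0.30 and below R² 0.50 / 0.344 for CDS / IGS); and mean bootstrap
support below 75% removes a locus. Ties at a threshold are kept; filters
are idempotent. Threshold selection is deliberately not automated — the
values are config inputs chosen from the density of each statistic, and the
defaults above are the shoulder values appropriate to plastome-scale data.
For the synthetic saturation study the analogous shoulder is slope 0.15 for
both categories: the generator's saturated class runs at 10× the clean
rate, so saturated slopes cluster well below clean ones (95th percentile
≈ 0.12 versus a clean 5th percentile ≈ 0.20 in the pooled synthetic slope
density), and 0.15 is the midpoint of the empty valley between the
clusters; the filter's behaviour is identical for any cut in 0.13–0.16.

The full grid comprises 30 matrices — 11 CDS-family, 9 IGS-family, 10
All-family — including `CDS-codon-align` (frame-checked CDS concatenation),
`CDS-codon-align-rm3` (third codon positions removed), and `All-Homblock`,
which applies the strict block trimmer to the whole concatenation in place
of collinear-block mining.

## Signal and outliers

Site-wise log-likelihoods are computed under each candidate topology with
one shared substitution model per matrix (fitted on the first candidate,
branch lengths re-optimised per candidate), so ΔGLS differences reflect
topology, not model drift. GLS partition sums reproduce each topology's
total lnL exactly (tested to 1e-6). A locus supports the candidate with the
highest GLS; ties within 1e-9 are "ambiguous" rather than resolved by
order. The per-locus outlier statistic is the mean of the three oriented
pairwise ΔGLS values; loci outside μ ± 3σ (sample standard deviation) are
flagged, and the reported envelope is additionally capped at the observed
min/max, which never changes the flags.

A known property of this detector, inherited from its definition: a
*cluster* of k equal-magnitude outliers among n loci self-masks once
k/n exceeds (n−1)/(10n−1) ≈ 9.7% at n = 30, because the outliers inflate σ
proportionally to their own deviation. It reliably isolates scattered
extreme loci at ≤ ~7% contamination (the regime of real plastome studies,
where ~4–6% of loci were flagged) but cannot flag three equal planted
outliers among thirty — a limitation measured and documented rather than
patched, since the μ ± 3σ rule itself is part of the method under study.

## Topology tests

RELL resampling draws ⌈scale·L⌉ sites with replacement and sums per-site
log-likelihoods; it is implemented as a multinomial draw over unique
site-pattern columns, which is distributionally identical to index
resampling and much faster at large L. KH follows the one-sided
replicate-mean-centering convention (the ML topology gets p = 1); SH
compares against the replicate-wise maximum, so p_SH ≥ p_KH on the same
replicates; the weighted variants standardise each pairwise difference by
its replicate standard deviation. The AU test computes bootstrap
proportions at scales 0.5–1.4 (step 0.1) and fits BP(r) = 1 − Φ(d√r + c/√r)
by weighted least squares on the probit scale with binomial weights
(continuity correction 1/(2B) at degenerate proportions; with fewer than
two non-degenerate scales the p-value is set by the degenerate side with a
warning); p_AU = 1 − Φ(d − c). Default B is 10,000 per scale for real runs;
the test suite uses 2,000.

## Synthetic data generator

The generator emulates the structure of a plastome-scale multi-locus
study; its defaults are the study conditions of every simulation-based
check. Twelve taxa; a random base topology T1 with branch lengths from
Exponential(rate 10) (mean 0.1 substitutions/site), and T2/T3 the two NNI
alternatives around one random focal internal edge. The substitution model
is AT-rich GTR (frequencies 0.31/0.18/0.19/0.32, exchangeabilities
1.3/3.0/0.6/1.1/3.5/1.0) with Γ shape α = 0.8 — plastome-like composition,
transition bias, and moderate rate heterogeneity. Locus classes: 30 clean
loci on T1, 6 conflicting loci alternating T2/T3, 6 saturated loci on T1 at
10× rate, and 3 outlier loci on T2 at doubled length (the length, not the
rate, is what strengthens a locus's aggregate ΔGLS; extra rate is absorbed
by branch-length re-optimisation and eroded by saturation). Loci alternate
CDS-like (300–1,500 bp, multiples of 3, emitted in frame) and IGS-like
(100–800 bp, 2× faster); per-locus rate multipliers are lognormal with
median 1 and σ = 0.4; each locus independently drops each taxon with
probability 0.2, floored at 60% of taxa retained.

What the generator does **not** emulate: indels (gaps arise only from
whole-taxon dropout), codon structure beyond frame (no selection on
synonymous positions, so third-codon removal is exercised structurally, not
biologically), within-locus recombination or heteroplasmy, alignment error,
and base-composition heterogeneity across lineages. Passing tests therefore
demonstrate that the pipeline's statistics behave as designed under their
own model assumptions — not that those assumptions hold for any particular
real plastome dataset.

## Numerical and design choices

* Coordinates are 0-based half-open internally; 1-based inclusive only in
  RAxML-style partition files.
* Taxon order in matrices is lexicographic; all random stages take explicit
  seeds and every pipeline stage derives its streams from the run seed, so
  reruns are byte-identical.
* Site log-likelihoods are clipped at 0 from above (a discrete-state
  likelihood cannot exceed 1; the clip only removes float round-off).
* Gene trees for per-locus diagnostics start from the base candidate
  topology pruned to the locus's taxa; the saturation regression then uses
  the gene tree's own patristic distances.
* Problem sizes in the test suite and acceptance script are desk-scale by
  design: 8–12 taxa, tens of loci, B = 2,000 RELL replicates, bootstrap
  B = 10–25 for gene-tree support, and a reduced model-fitting effort
  (Γ shape on empirical frequencies) in the replicated recovery studies.
  The pipeline defaults (full GTR fit, B = 10,000) are what a real analysis
  would use.

## Known limitations

* One substitution model per matrix (no per-locus partitioned models) and
  no model selection; the model family is fixed GTR+Γ(+I).
* NNI hill-climbing with random restarts replaces full tree searches; it is
  adequate for the synthetic studies but is not a general-purpose tree
  inference engine.
* The AU fit uses probit-scale weighted least squares rather than the full
  maximum-likelihood fit; adequate at B = 10,000.
* The μ ± 3σ outlier rule self-masks clustered contamination above ~10%
  (see above).
* `All-Homblock` approximates collinear-block mining by strict trimming of
  the whole concatenation.
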