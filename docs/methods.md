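# Methods

This note documents the model conventions, numerical choices and the
synthetic study conditions behind `tihs`, in the spirit of a statistical
software methods appendix. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Network construction

The resistance network is the subgraph of the supplied interaction
catalogue induced on the significant genes (defaults: |log₂FC| ≥ 1.0
inclusive, adjusted *p* < 0.05 strict, edge confidence ≥ 0.7 inclusive —
the inequality directions follow the conventional DEG and STRING
high-confidence definitions). Gene symbols are upper-cased before any
matching. Duplicate DEG rows collapse to the entry with the largest
|log₂FC| (ties: smaller adjusted *p*, then first occurrence), preserving
the strongest resistance signal. Reciprocal/duplicate edges merge keeping
the maximum confidence; self-loops are removed. STRING's integer
`combined_score` dialect is auto-detected from the score range (any score
> 1 ⇒ divide by 1000); a file whose scores already lie in [0, 1] is never
rescaled.

By default only the largest connected component is analysed
(`restrict_to_lcc=True`), because eigenvector centrality is ill-defined
across disconnected components; the flag exposes the full-graph
alternative. Ties between equal-sized components go to the component
containing the alphabetically first node. Isolated DEGs are excluded from
topology (centralities are degenerate for them) and reported separately.

## Centralities

Raw, unnormalised values are used throughout: degree as edge count,
betweenness as unnormalised shortest-path betweenness on the unweighted
graph (each unordered pair counted once), eigenvector centrality as the
L2-normalised principal eigenvector of the binary adjacency matrix, MCC as
Σ_{C ∋ v} (|C|−1)! over exactly enumerated maximal cliques, and EPC as the
Monte-Carlo average reachable fraction under global edge percolation.

Numerical conventions:

* **Eigenvector** — power iteration on A + I (same eigenvectors as A, but
  the principal eigenvalue is strictly dominant even on bipartite graphs,
  where iteration on A oscillates); uniform start, tolerance 1e-10, cap
  10,000 iterations, non-convergence is an error.
* **MCC** — Bron–Kerbosch maximal-clique enumeration with a configurable
  safety cap (default 10⁶ cliques) against factorial blow-up.
* **EPC** — per realisation a single global threshold t ~ U(0,1) is drawn
  and every edge with confidence < t (strict) is deleted, so a
  confidence-1.0 edge never dies; the node score is the reachable fraction
  of |V| including the node itself, averaged over realisations (default
  1000), deterministic under the supplied seed. Internally realisations
  are processed in decreasing threshold order with an incremental
  union–find, so the sweep unites each edge exactly once; the result is
  identical to naive per-realisation reconstruction (tested).
* Using raw rather than normalised metric values is provably
  inconsequential: Z-scoring absorbs any positive affine per-column
  transform, and the scale-invariance of the final composite is itself a
  regression test.

## Normalisation, weights, TIHS

Z-scores use the population (n) standard deviation; the choice is a pure
convention and cannot affect rankings. Degenerate columns (σ = 0) get
Z ≡ 0. The positivity shift is implemented as Z′ = Z − min(Z) + 0.001,
i.e. every column's minimum is exactly 0.001 — the only reading under
which a shift can "avoid negative values" for columns whose minimum
Z-score is negative.

Two weight modes are provided, both returning simplex vectors:

* `std_share`: W_j = σ_j / Σ_k σ_k with σ_j taken on min–max-rescaled raw
  columns. Rescaling is essential: on Z columns every σ is 1 (forcing
  equal weights), and on raw columns the factorially scaled MCC would
  dominate by units alone. The rescaled share is the only unit-free
  variance share that can produce stable, non-equal weights.
* `pca_loading`: absolute PC1 loadings of the Z matrix, renormalised to
  sum 1. PC1 is sign-aligned so its largest-|loading| metric is positive,
  pinning the eigenvector sign ambiguity for reproducibility.

Because the two modes answer slightly different questions ("which metric
varies most" vs "which metric carries the dominant joint axis"), outputs
record the mode used. Weight vectors from several training datasets may be
averaged (arithmetic mean, renormalised) and then locked for
application-stage runs; cosine similarity against the averaged vector,
computed on unit-normalised vectors with 0.98 as the conventional
stability flag, quantifies cross-dataset concordance.

TIHS_i = Σ_j W_j Z′_ij is strictly positive by construction; output
ordering is descending score with alphabetical tie-break.

## Drug scoring and filtering

Drug targets match network nodes by upper-cased symbol; targets outside
the network contribute nothing ("topological targets" only) but are
counted. Multiple activity measurements per (drug, target) aggregate by
median nM before scoring (configurable: geometric mean, minimum) for
robustness to assay outliers. The per-metric accumulation
Σ_t Σ_j (log₂FC_t/activity_t)·Z′_tj·100·W_j and its factored form
100·Σ_t (log₂FC_t/activity_t)·TIHS_t are both computed and asserted equal
at every call — a live guard on weight/shift bookkeeping.

Mechanism strings map to the effect multiplier by case-insensitive
keywords, inhibitory set checked first so "antagonist" never falls through
to the "agonist" substring; unmapped mechanisms leave the drug *excluded*
rather than defaulted (+1), since a wrong sign is worse than a missing
candidate. Ranking is by descending sensitivity score, ties by more
matched targets then name.

Tier 3's pharmacokinetic check compares the mean matched-target potency
(as the available potency proxy, labelled as such) against the drug's
Cmax; drugs missing from the Cmax table pass that check with a warning.
The expression check requires every matched target to reach the
detectability floor (default 1.0 in the caller's expression units). All
tier flags are annotations — no rows are silently dropped.

## Statistical suite

* McNemar is implemented in its exact one-sided binomial form on the
  discordant counts (p = Σ_{k≥n10} C(n,k)/2ⁿ): with n01 = 0 the p-value
  is exactly 0.5^n10, the only form consistent with the reference values
  the tests pin (3.05×10⁻⁵ at n10 = 15, 9.54×10⁻⁷ at n10 = 20).
* Permutation p-values use the add-one estimator (1+b)/(m+1), which is
  never zero and keeps the test valid; calibration (super-uniformity under
  a simulated uniform null) is property-tested.
* Bootstrap CIs are percentile intervals from full-length resampling,
  seeded.
* The χ² tests on weight vectors need counts; proportions are scaled by a
  caller-supplied pseudo-n (reported alongside the statistic). The
  statistic is linear in pseudo-n, so these are descriptive unless the
  caller has a principled count basis — the implementation flags expected
  counts below 5.

## Heterogeneity module

The shift matrix uses the intersection of model gene sets (no imputation),
genes sorted for determinism. PCA treats models as observations with
centred, unscaled gene columns (prcomp-style); components are sign-aligned
to the largest-|loading| gene. Clustering is complete linkage on 1 − r.
The gene bootstrap (default 500 iterations) resamples rows with
replacement and re-aligns each bootstrap component's sign against the
*reference* embedding (maximising score agreement); without this, random
eigenvector sign flips would scramble the coordinate clouds into
artificial mirror-image lobes — the alignment is itself tested on a
one-cluster input.

## Synthetic study conditions

Defaults (the conditions under which the recovery properties are asserted):
300 genes, 8 planted hubs each additionally wired to 30% of all nodes over
an Erdős–Rényi background at edge probability 0.02 (mean background degree
≈ 6, just above the connectivity threshold), edge confidences
U(0.70, 1.0); background log₂FC ~ N(0, 0.6) with adjusted *p* ~ U(0,1),
planted hubs at log₂FC = +2.0 with *p* ~ U(0, 0.01); 72 drugs of which 6
planted sensitive (inhibitors of 2–3 hubs at 10–100 nM), 6 planted
resistant (agonists of hubs, same potency) and 60 decoys (inhibitors of
1–3 non-hub genes at 1–10 µM). Hub over-attachment (rather than
preferential attachment) keeps hub identity an exactly known quantity, so
recovery assertions are crisp; hubs are upregulated so that inhibitor
scores come out positive.

The generator emulates the statistical *shape* of a resistance study, not
any real cohort: log₂FC and adjusted p are independent in the background
(in real DE output they are strongly dependent), potencies are uniform
rather than assay-distributed, and the network is ER-plus-hubs rather than
a protein-interaction degree distribution. Passing recovery tests
therefore demonstrate internal correctness and sensitivity of the scoring
chain, not field performance on real cohorts.

The end-to-end recovery analysis builds its network over the full
simulated gene universe (significance filters disabled at the network
step). With the background's uniform adjusted-p, a thresholded network
would contain essentially only the planted hubs, making "hubs occupy the
top decile" vacuous by pigeonhole; over the full 300-gene universe the
statement is substantive and is asserted over 20 seeds, alongside the
tier-1 recovery of planted sensitive drugs against the 10% null. The
planted-hub significance guarantee is still verified at the conventional
thresholds separately.

## Validation scale

Oracle-equivalence tests run degree, betweenness, MCC and eigenvector
against independent brute-force oracles (all-shortest-path enumeration,
exhaustive subset cliques, dense eigendecomposition) on **every** connected
labeled graph with ≤ 5 nodes (771 graphs) plus a seeded random sample of
one hundred 6–7-node graphs; exhaustive labeled enumeration at 6–7 nodes
(2¹⁵–2²¹ graphs) buys no additional structural coverage worth its cost in
pure Python. EPC is checked against closed-form expectations on one- to
three-edge graphs at 10,000 realisations within three Monte-Carlo standard
errors, and against a naive per-realisation reconstruction for exact
agreement. The end-to-end recovery experiment uses 20 seeds at the default
study conditions (~10 s total), keeping the full suite well inside an
interactive budget.

## Known limitations

* The weight-derivation basis (which σ enters W_j) is a modelling choice;
  the two implemented modes will generally produce different (both valid)
  weight vectors, and neither is claimed to reproduce any particular
  published per-dataset weights.
* Tier 3 uses mean matched-target potency as an IC50 proxy; with a
  measured cellular IC50 available, callers should filter on that instead.
* The χ² weight tests depend on an arbitrary pseudo-count basis (see
  above).
* No approximate betweenness: networks of ~5k nodes / ~25k edges are
  exact-computable in minutes on one CPU, which covers the intended scale;
  much larger graphs would need sampling strategies out of scope here.
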