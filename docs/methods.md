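# Methods

## Model and procedure

`switchtfi` treats each baseline-GRN edge *e* = (TF *i*, target *j*) as
the unit of analysis. The premise: if the edge is mechanistically
involved in a progenitor → offspring transition, the joint expression of
TF and target separates the two states, so a univariate split of the
cells by TF expression — chosen to predict the target — should align
with the state annotation.

Stages, in order:

1. **Imputation** (optional, on by default). A row-stochastic diffusion
   operator M is built on the cells and the matrix is replaced by
   M<sup>t</sup>X with t = 1, the most conservative depth: each value
   becomes a convex combination of the gene's expression over the cell's
   immediate graph neighborhood. Zeros are preserved exactly where a
   gene is unexpressed across the whole neighborhood, so imputation
   cannot invent expression out of nothing.
2. **Cell selection.** Per edge, only cells with strictly positive
   (imputed) expression of both genes are used; an edge co-expressed in
   fewer than `min_coexpression_fraction` (default 0.20) of *all* cells
   is excluded and reported, because weights fit on few cells are
   unstable.
3. **Weight fitting.** A depth-1 regression tree of target on TF
   expression is fit by exhaustive search over candidate boundaries;
   the induced split {L<sub>e</sub>, R<sub>e</sub>} is compared with
   {P, O} (restricted to the cells used) by the block-matched average
   Jaccard similarity w<sub>e</sub> ∈ [0.25, 1]. The range bound is
   exact and is verified by exhaustive enumeration in the test suite.
4. **Significance.** Single-step Westfall–Young max-T: q label
   permutations of the full cell set, shared across edges to preserve
   the dependence structure, each restricted to an edge's cell subset;
   P<sub>e</sub> = (1/q)#{k : w<sub>max</sub><sup>(k)</sup> ≥
   w<sub>e</sub>}. Pruning at P<sub>e</sub> ≤ α controls the FWER at
   level α over the tested family — i.e., over the edges that survived
   stage 2; excluded edges are not tested and make no FWER claim.
5. **Ranking.** PageRank on the edge-reversed unweighted transition GRN
   (normalized over all nodes, then restricted to TFs), and/or weighted
   outdegree of the edge scores s<sub>e</sub> = −log₁₀(max(P<sub>e</sub>,
   1/q)) · w<sub>e</sub>.
6. **Network validation.** Connectivity score CS = Σ (|C<sub>r</sub>|/|V|)²
   over weakly connected components, compared against q random
   edge-induced subnetworks of the baseline GRN with the same edge
   count; empirical P with a +1 pseudocount so it is never zero.

## Assumptions

* The two states are given, trusted, and exhaustive: every cell is
  labeled P or O, both nonempty.
* Under an edge's null hypothesis the state labels are exchangeable with
  respect to that edge's expression — the basis of permutation validity.
* The baseline GRN is taken at face value; its own inference weights are
  carried through as metadata but never used in computation.
* A "TF" is defined structurally as a node with at least one outgoing
  edge; a gene may be both TF and target.

## Parameters that matter

| parameter | default | meaning / why |
|---|---|---|
| `impute.t` | 1 | diffusion depth; 1 is the most conservative smoothing and keeps neighborhood zeros exact |
| `impute.k` | min(15, n/2) | kNN size; 15 follows common diffusion-imputation practice, halved automatically on tiny inputs; an explicit k is honored as given |
| `impute.ka` | 4 | adaptive-kernel bandwidth index (distance to the ka-th neighbor), capped at k |
| `impute.decay` | 2 | kernel decay exponent exp(−(d/σ)^decay) |
| `impute.n_pca` | 20 | PCA depth before kNN; skipped below 50 genes where it would not denoise |
| `weight.min_coexpression_fraction` | 0.20 | exclusion threshold for sparsely co-expressed edges, denominated in all cells |
| `test.n_permutations` | 1000 | q; gives P-value resolution 1/q = 0.001 |
| `test.alpha` | 0.05 | FWER level; only affects transition-GRN size, not the weight fit |
| `test.empty_class_policy` | omit | permutations leaving an edge's subset single-state contribute nothing to that permutation's maximum; `conservative` counts them as weight 1 |
| `rank.damping` | 0.85 | canonical PageRank damping |
| `validate.n_samples` | 1000 | null subnetworks for the connectivity test |

## Numerical choices

* **Stump candidates** are the midpoints between consecutive distinct
  sorted TF values — these realize every achievable bipartition — plus
  the degenerate all-on-one-side split at the maximum. MSE ties are
  broken toward the smallest boundary, which makes fits on discrete
  imputed values deterministic. Because splitting never increases the
  within-leaf sum of squares, the degenerate candidate can only tie,
  never strictly win.
* **Observed and permuted weights use identical count-based
  arithmetic**, so the identity permutation reproduces w<sub>e</sub>
  bit-for-bit and the comparison w<sub>max</sub> ≥ w<sub>e</sub> is
  exact rather than tolerance-based.
* **P-values may be exactly 0** when the observed weight exceeds every
  permutation maximum; the 1/q floor is applied only inside the edge
  score, not in storage or pruning. The adjusted-P formula is used as
  stated, without adding the identity permutation to the permutation
  set; the exact size of the resulting min-P test under a global null is
  (⌊αq⌋+1)/(q+1), e.g. ≈ 0.052 at α = 0.05, q = 500 — the global-null
  simulation in the acceptance suite bounds the empirical FWER by
  α + 2 binomial SE accordingly.
* **Degenerate inputs**: constant TF over the cell subset (no split
  exists) and subsets containing only one state (Jaccard terms
  undefined) exclude the edge, with the reason recorded in the
  exclusion report. An empty transition GRN is a valid result and a
  warning, not an error.
* Duplicate cells at distance 0 receive kernel affinity 1, so the
  operator stays well-defined when the bandwidth collapses.

## Synthetic benchmark

The generator produces the minimal structure the pipeline must resolve:
a GRN that is a union of regulons (`n_tfs` × `targets_per_tf` edges), a
cell bipartition, and counts in which driver regulons shift their
log-mean expression by ±`effect_size`/2 per state (coherently within a
regulon, random direction per regulon) while the rest is
state-independent. Counts follow lognormal latent means (baseline
log-mean log 5 ± 0.5) → Poisson sampling → independent dropout masking
with probability `dropout_rate · exp(−μ/μ₀)`, biased toward low-mean
transcripts. Defaults (300 cells, 10 TFs × 5 targets, 30% driver TFs,
effect 1.5, within-state SD 0.4, dropout 0.2, balanced states) describe
a mid-sized, moderately noisy experiment in which recovery is good but
not trivial.

What the generator deliberately does **not** emulate: continuous
pseudotime (the state switch is binary), gene-specific overdispersion
beyond Poisson, batch effects, doublets, or correlated noise between
regulons. Passing recovery tests therefore demonstrates that the
algorithm extracts planted switch-like signals under zero inflation and
sampling noise — not that it is robust to every artifact of real
scRNA-seq chemistry. With `effect_size = 0` the ground-truth driver sets
are empty: a "driver" with no effect is not a driver, and such runs
serve as global-null calibration data.

Problem sizes used by the automated checks — 200-replicate global null
at 200 cells / 50 edges / 500 permutations; recovery at 400 cells with
effect 3 and no dropout; exhaustive weight enumeration up to 8 cells —
were chosen so each property is measured at the scale where it is
informative: the null study needs replicate count (binomial resolution),
not cell count; the recovery study needs a cleanly separable regime; the
enumeration is complete by construction.

## Design choices where the design was open

* **Shared global permutations.** One label permutation per replicate is
  applied to the full cell set and then restricted per edge, rather than
  permuting each edge's subset independently: max-T FWER control rests
  on evaluating all statistics under the *same* permutation to respect
  their dependence.
* **Restriction symmetry.** P and O are restricted to the edge's cell
  subset both when computing the observed weight and under permutation,
  so the two are directly comparable.
* **Imputation runs on the full gene set**, not only GRN genes:
  neighborhoods should reflect the whole transcriptome.
* **Co-expression filtering happens after imputation**, consistent with
  imputation being the dropout mitigation that precedes weight fitting.
* **Baseline-GRN edges with endpoints missing from the matrix are
  dropped with a warning** instead of failing: externally inferred GRNs
  routinely contain extra genes.

## Known limitations

* Testing after kNN-graph imputation is mildly liberal at the gene
  level: smoothing over state-coherent neighborhoods can lift borderline
  null edges past the threshold (visible in the README example, where
  the no-imputation run is exactly precise). The permutation null
  conditions on the observed splits and does not account for the
  smoothing step itself.
* FWER is controlled over the *tested* family; edges excluded by the
  co-expression filter are outside any error guarantee.
* The stump considers one TF at a time; combinatorial regulation and
  activation/repression signs are out of scope.
* P-value resolution is 1/q; edges tied at P = 0 are ordered by weight
  through the score, not by evidence beyond the permutation limit.
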