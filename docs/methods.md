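# Methods

## Model and assumptions

The pipeline treats disease-associated co-regulation as a network signal:
genes whose pairwise co-expression is both strong and group-dependent form
a differential expression network (DEN) inside a curated interaction
network, and tightly connected neighbourhoods of that DEN should separate
cases from controls when used as classifier features. The method assumes a
normalized, log-scale expression matrix with no missing values, a binary
group design with at least two samples per group, and an undirected
weighted interaction network whose identifiers match the expression rows
exactly (no alias resolution is attempted).

## Edge scoring and the differential network

Every background edge (i, j) carries two statistics:

- the pooled Pearson correlation r_ij over all samples, and
- a one-sided two-sample t-test on per-sample co-expression
  contributions c_s = z̃_i(s)·z̃_j(s), where z̃ is the gene's expression
  standardized over all samples.

Retention requires |r_ij| ≥ `pcc` (default 0.8, inclusive) and
p < `edge_p` (default 0.05, strict).

Two design points deserve emphasis:

**Pooled-variance Student t by default.** Under the null hypothesis the
two groups are exchangeable, so the contribution variances are equal and
the pooled-variance test is exactly sized; empirically its null p-values
are uniform (KS p ≈ 0.5 at 20,000 null edges) while being markedly more
powerful than the Welch variant when one group is small (a 6-sample
control arm is common in this setting). `method="welch_products"` and
`method="fisher_z"` (difference of per-group correlations via Fisher's
transformation) are available alternatives.

**Direction "minority" by default.** With pooled standardization, an edge
whose genes shift between groups concentrates its coordinated deviation
from the pooled mean in the *smaller* group: the minority group sits
farther from the pooled mean, so its standardized cross-products are
systematically larger for exactly the edges the DEN is meant to capture.
A one-sided alternative aimed at the majority group has essentially no
power against such edges, and with co-expression present in both groups
neither fixed direction does. The default therefore aims the test at the
minority group; `direction="cases"` or `"controls"` fix it explicitly.
For balanced designs the minority rule falls back to cases.

No multiple-testing correction is applied at the edge level; the |PCC|
threshold, not the p-value, is the dominant filter in practice.

## Topology score and ego genes

On the DEN with weighted adjacency W (weights |r_ij|), degree matrix
D = diag(d_i), and symmetric normalized adjacency A = D^(−1/2) W D^(−1/2),
the topology score of gene i is

    f_i = Σ_{j ∈ N(i)} A_ij · s_j

with s_j the absolute Welch t-statistic of gene j's case-vs-control
differential expression. The score rises with the number, importance and
connection strength of a gene's neighbours, and is invariant to a global
rescaling of edge weights. f is standardized to z-scores over DEN nodes
(sample SD, n−1); the top max(1, ⌊0.05·n⌋) genes are ego genes, ties at
the cut broken by higher weighted degree, then gene id. The floor rule
pins the reference behaviour: a 149-node DEN yields exactly 7 ego genes.

If all f are equal (e.g. a vertex-transitive DEN) the z-scores are set to
0 with a warning, and selection falls back to the tie-breaks.

## Module growth and AUC

The classification value of a gene set is its leave-one-out
cross-validated AUC: per fold a linear soft-margin SVM (C = 1.0) is
trained on the module genes, features standardized with training-fold
statistics (zero-variance features left centred); held-out decision
values are pooled and the AUC computed by the rank-sum (Mann–Whitney)
formulation, ties counted half. LOOCV is chosen because at a few dozen
samples it is deterministic and maximally data-efficient; no
hyperparameter search is performed.

Greedy expansion starts at the ego gene and repeatedly evaluates every
DEN neighbour of the current module, adding the one with the largest AUC
change (ties: higher topology z, then gene id). Growth stops when the
module's accuracy would drop — judged at the resolution of the estimate:
with n1 cases and n0 controls the LOOCV AUC moves in steps of 1/(n1·n0),
and a decrease of a single ranking inversion is indistinguishable from
cross-validation noise, so only a larger drop stops growth
(`drop_tol_pairs`, default 1; 0 restores a strict decrease rule). Without
this tolerance, expansion on strongly separating data stalls at two or
three genes because the AUC saturates and every further (redundant)
neighbour loses one inversion by chance. A size cap (default 30) bounds
pathological growth. Candidates with AUC ≥ 0.8 and at least 4 genes
(both inclusive) are ego modules.

Two AUC caveats worth knowing: the retrained SVM is symmetric in the two
classes, so flipping all labels leaves the module AUC unchanged (the
1−AUC flip holds only for fixed decision values); and on null data LOOCV
decision values are anti-correlated with the held-out label (the
classic leave-one-out flipping artifact), so null AUCs centre below 0.5.
The permutation test is unaffected because the same artifact applies
under every relabelling.

## Permutation significance

Each ego module's observed AUC is compared with B = 1000 uniform label
permutations (module genes fixed — the null of interest is "no
association between this gene set's expression and the grouping", not a
random gene set). The add-one estimate p = (#{AUC_perm ≥ AUC_obs}+1)/(B+1)
is strictly positive and depends only on the exceedance count.
Benjamini–Hochberg adjustment is applied across modules and adjusted
p < 0.05 (strict) is called significant.

## Pathway enrichment

Pathways are intersected with the analysis universe (background PPIN gene
set — not the whole genome, since only measured, connected genes could
have entered a module) and kept when the intersection holds 5–100 genes
inclusive. Per module, each background pathway gets a one-sided Fisher's
exact p on the 2×2 table [[k, m−k], [K−k, N−K−m+k]] — the hypergeometric
tail P(X ≥ k) — with BH adjustment within the module across the pathways
tested; adjusted p < 0.05 flags an ego pathway. Per-module adjustment
(rather than one global family) keeps each module's calls interpretable
in isolation; the count of tested pathways is logged.

## Synthetic data

The generator emulates the pipeline's intended inputs at desk scale:

- a scale-free interaction graph (preferential attachment, m = 2) —
  PPI degree distributions are heavy-tailed, and hubs exercise the
  degree-normalization code path; an Erdős–Rényi alternative exists;
- a planted module of `planted_module_size` genes (default 6) wired as a
  star around a hub plus chords between consecutive spokes; spokes are
  drawn away from the earliest preferential-attachment nodes, which are
  densely interconnected and would blur the hub's star-centre role;
- planted expression from a single shared latent factor,
  x_g = noise_sd·(√ρ·z + √(1−ρ)·ε_g) + effect_size·noise_sd·1[case],
  giving expected within-group pairwise correlation ρ (default 0.9) and a
  standardized between-group shift of `effect_size` (default 3.0) per
  gene; all other genes are independent noise;
- group sizes default to 19 cases / 6 controls, a realistic small
  two-group design;
- a GMT collection (default 40 sets) whose first pathway overlaps the
  planted module in `planted_pathway_overlap` genes (default 5), padded
  to 10 genes with random non-planted genes.

Everything derives from one integer seed; equal seeds give byte-identical
fixture files. The generator does **not** model probe-level artifacts,
batch effects, platform normalization, correlated background modules, or
missing values — so passing recovery tests demonstrates that the
algorithmic chain works under its own statistical assumptions, not that
it is robust to real microarray pathologies.

## Numerical choices

- Zero-variance genes: PCC 0 and p 1 on their edges, t-statistic 0, with
  logged warnings — they can never drive a result.
- Degenerate zero-variance t-test contributions fall back to comparing
  means directly.
- All intermediate files are written at full float precision
  (shortest-round-trip repr) and parsed with round-trip parsing, and the
  expression matrix is forced C-contiguous, so stage-wise (file-based)
  and in-memory pipeline runs are byte-identical.
- Seeds fan out from the global seed through `numpy` SeedSequence so
  stages and permutation tests are independently reproducible.
- BH adjustment delegates to statsmodels; Fisher's exact test to scipy.

## Problem sizes in the test-suite

Statistical checks run at reduced scale chosen to keep the full suite in
the minutes range while leaving clear margins: null calibration uses 200
four-gene modules with B = 49 permutations (the add-one p-value grid is
then 0.02-spaced, far below the KS band at n = 200); recovery uses 100
seeds for hub selection, 50 for expansion Jaccard, and 50 for pathway
flagging. The acceptance script averages the planted-module AUC over 8
generator replicates.

## Known limitations

- The one-sided edge test entangles mean shift and co-expression through
  pooled standardization; the `fisher_z` method is the cleaner pure
  co-expression contrast but has little power with very small groups.
- Greedy expansion with a drop tolerance can absorb neutral genes inside
  the ego's DEN component; on sparse DENs this is the desired behaviour
  (the ego's neighbourhood), on dense DENs the size cap is the only brake.
- Binary outcomes only; no survival or multi-class support.
- Exact-string gene identifiers; duplicate expression rows are collapsed
  by maximum mean as a stand-in for upstream probe summarization.
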