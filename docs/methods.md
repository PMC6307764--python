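# Methods

This note documents the statistical model behind `fflscan`, the choices the
implementation makes where the procedure admits more than one reading, and
what the synthetic benchmark does and does not establish.

## Candidate loops

A candidate feed-forward loop (FFL) is a triple (miRNA, TF, gene) such that
the miRNA and TF are linked by at least one regulator edge (miRNA→TF and/or
TF→miRNA) and both regulate the gene.  Loops are typed by the master
regulator — miRNA-FFL (miRNA→TF), TF-FFL (TF→miRNA), composite-FFL (both,
four edges) — with composite taking precedence so the three classes
partition the candidate set.  The TF universe is declared explicitly via
the feature-class map, and a symbol classified as TF never occupies the
gene slot, which prevents one physical TF–target pair from being counted
both as a TF→gene and a gene-level interaction.  Interaction sources are
consumed as plain TSV edge lists; set-union semantics deduplicate pairs
that occur in several source databases.

## Node scores

Differential expression is computed once per study.  The default is a
self-contained empirical-Bayes moderated t: per-feature pooled variances
are shrunk toward a common prior whose scale and degrees of freedom are
estimated by moment matching on log variances (digamma/trigamma moments of
the scaled-F marginal; the trigamma inverse is solved by safeguarded Newton
iteration).  When the observed spread of log variances does not exceed pure
chi-square noise the prior degrees of freedom go to infinity and the test
reduces to a z-test at the common variance.  Welch's unequal-variance t is
available as `method="welch_t"` and is the variant checked against an
independent scalar oracle in the tests.  Expression values are assumed to
be on the log2 scale, so the fold change is `FC = 2^(mean_case −
mean_ctrl)`; this assumption is the usual convention for microarray
intensity matrices and is deliberate, not inferred from data.  The SDE
(significantly differentially expressed) rule is two-sided: p < 0.01 and
max(FC, 1/FC) > 1.2, so down-regulation passes symmetrically.

The node magnitude `Diff = (−log10 p)·|log2 FC|` is mapped through
`S = Φ⁻¹(2Φ(Diff) − 1)`, a fold of the two-sided normal tail onto a
one-sided z-score.  The transform diverges at its boundaries (Diff = 0 maps
to −∞), so scores are clamped to ±8: beyond |z| = 8 the double-precision
normal CDF is saturated and larger values carry no ranking information.
p-values are floored at 1e−300 before taking −log10 for the same reason.
Features constant in both groups are assigned p = 1 and flagged rather than
erroring, so one flat probe cannot abort a run.

## Edge scores

Within each sample group the Spearman correlation of an edge's endpoints is
computed with midranks; its two-sided significance uses the t
approximation `t = r·sqrt((n−2)/(1−r²))` with n−2 degrees of freedom
(p = 0 at |r| = 1; exact permutation enumeration is available behind a flag
for groups of at most 8 samples, where the full n! ≤ 40 320 permutation set
is enumerated).  The differential co-expression statistic

    X = [F(r_case)(−log10 p_case) − F(r_ctrl)(−log10 p_ctrl)]
        / sqrt(1.06/(n_case−3) + 1.06/(n_ctrl−3))

uses the Fisher transformation F with 1.06/(n−3), the classical variance
inflation for Fisher-z applied to a Spearman rather than Pearson
correlation.  The p-values entering X are the correlation significances of
each group — the reading consistent with the differential-co-expression
lineage of the statistic.  X is antisymmetric under swapping the groups;
the edge score `S_edge = Φ⁻¹(2Φ(|X|) − 1)` depends on |X| only and is
clamped like the node score.  Both sample groups must have at least 4
samples, since the variance term divides by n − 3.

## Loop score and significance

`S_FFL = α·mean(S_node) + (1−α)·mean(S_edge)` with α = 0.5 by default, the
node mean over the three members and the edge mean over the loop's typed
edges — 3 for single-regulator loops, 4 for composite loops, where the two
antiparallel miRNA↔TF links count separately (they share one score value
because the correlation statistic is symmetric in the pair).

The empirical p-value compares the observed score against `n_random`
(default 10 000) random loops assembled by drawing a miRNA, a TF and a gene
uniformly and independently per iteration.  Three choices here are
implementation decisions:

* **Universe.** Random molecules are drawn from the molecules appearing in
  the candidate loop set (`universe="candidate"`, the default) — the
  conservative choice, since those molecules share the detection
  characteristics of the loops under test — or from all profiled molecules
  (`universe="profiled"`).
* **Topology.** Random loops inherit the 3- vs 4-edge topology of the loop
  under test so the edge-score means are comparable.
* **Tail rule.** p is the *strict* exceedance proportion with no
  pseudocount, so p = 0 is possible; a corrected `(k+1)/(n+1)` value is
  emitted alongside for consumers that need positive p-values.

Loops with p < 0.01 are called dysregulated.  Node scores are cached per
feature, edge scores per unordered feature pair, and for the permutation
engine dense class-pair edge-score matrices over the universe are
precomputed from standardized rank vectors (one matrix product per group),
making each loop's 10 000 permutations a vectorised table lookup; scoring
200 candidates at 10 000 permutations takes well under a minute on one CPU.
Per-loop random streams are spawned from a single seed via
`SeedSequence.spawn`, so results are deterministic given (inputs, seed) and
independent of evaluation order.

Annotation enrichment of selected molecule sets uses the upper-tail
hypergeometric test P(X ≥ k).

## Network topology

Dysregulated loops are merged by set union: nodes and typed links
deduplicate, so a link shared by many loops counts once.  A node's degree
counts the typed links incident to it — a mutual miRNA↔TF pair contributes
two — which makes the per-class degree sums equal the per-type link counts
and the grand total equal twice the link count; this is the convention
under which published per-class mean degrees follow directly from a
network's composition table.  Betweenness centrality uses Brandes' exact
algorithm on the collapsed undirected simple graph, normalized by
(n−1)(n−2)/2.  The degree distribution is fit by least squares on
(log10 k, log10 count(k)) over observed degrees with positive counts — the
fit implied when a slope is reported together with an R²; it requires at
least three distinct degree values, and a flat count profile is reported as
slope 0 with R² = 1 (the flat line fits exactly).  Hubs are either the
top-k nodes per class by degree (default k = 4; ties broken by betweenness,
then name) or the nodes above class mean + 2 SD; the method used is
recorded in the report.  Top-betweenness selection takes the
ceil(fraction·class size) highest-BC nodes per class (default 5%).
Flagged-vs-background comparisons of degree or BC use the two-sided
Wilcoxon rank-sum test.

## Biomarker panels

All 2^k − 1 non-empty subsets of up to 20 candidate regulators are
evaluated as panels (beyond 20 the enumeration guard advises a heuristic
search).  Each panel trains a linear SVM (C = 1.0) under stratified 5-fold
cross-validation — stratification matters because with strongly unbalanced
designs plain k-fold can produce folds without controls.  Accuracy is the
mean over folds.  AUC is reported twice: pooled continuous decision values
over all test folds (headline) and the mean of per-fold AUCs; a panel whose
feature matrix has zero variance is reported at AUC 0.5, since fold
intercepts would otherwise impose a spurious ordering on pooled decision
values.  The optimal panel is the smallest one whose accuracy is within a
tolerance (default 0.0, i.e. strict maximum) of the best observed, ties
resolved by higher AUC then lexicographic feature list — the only reading
of "balance accuracy against panel size" that is deterministic.

## Synthetic benchmark

The generator emulates the statistical structure the scoring model assumes:
log2-scale intensities with a common baseline (default 8.0), independent
Gaussian background features with no group effect, and planted loops whose
three members receive (i) a mean shift `de_shift` (default 1.0) in cases
and (ii) pairwise co-expression `corr_case` in cases vs `corr_control` in
controls (defaults 0.7 vs 0.0).  Correlations are produced by a Gaussian
copula: the target Spearman value is converted to a latent Pearson
correlation via ρ = 2·sin(π·r_s/6), a 3×3 equi-correlated latent matrix is
built per loop and group (eigenvalue-clipped to the nearest
positive-definite matrix, erroring if the repair moves any entry by more
than 0.05), and the latent normals are mapped affinely onto the expression
scale — a monotone map, so the Spearman target is preserved exactly in
distribution.  Planted loops occupy disjoint molecules.

Decoy candidate loops are added one triple at a time under incremental loop
accounting that rejects any triple whose edges would create more or fewer
than one new candidate, so the candidate count equals the configured target
exactly; additional miRNA→gene noise edges are accepted only if they close
no loop.  Default study design is 106 cases vs 20 controls with 80 miRNAs,
150 genes and 40 TFs and 200 candidate loops, 5 of them planted — a scale
at which the full pipeline (enumeration, scoring, 10 000 permutations per
loop) runs in seconds and planted effects are comfortably but not trivially
detectable.

What the benchmark does **not** emulate: microarray platform artifacts,
batch effects, heavy-tailed intensity distributions, correlated background
(co-regulated gene modules), or incomplete/biased interaction catalogs.
Passing the planted-recovery and calibration tests therefore demonstrates
the correctness and statistical calibration of the machinery, not its
sensitivity on real tissue profiles.

## Degenerate inputs and numerical conventions

* Duplicate probe rows collapse by arithmetic mean at load; load-then-test
  equals test-on-precollapsed (verified property).
* Constant expression vectors: correlation r = 0, p = 1, flagged.
* |r| = 1 in the Fisher transform is clamped to ±(1 − 1e−15).
* Empirical p times n_random is always an integer; mixing records with
  different n_random in one selection is an error.
* All tables are TSV with headers; the network also exports GraphML.

## Known limitations

* The moderated t is a moment-matching approximation, not a re-implementation
  of any particular package; its p-values agree with the shrinkage family of
  tests in calibration but not digit-for-digit with other tools.
* The permutation null resamples molecules, not sample labels; it therefore
  measures how extreme a loop's score is against random molecule triples
  under the same data, not against a no-disease-effect world.
* The exhaustive panel search is limited to 20 candidates by design.
* Betweenness on the undirected collapsed graph discards edge direction;
  directed exports are available for external analysis.
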