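# Methods

## The analysis model

`micronet` treats a soil microbial community as an ASV × sample count
table per ecosystem and asks two questions: (i) which taxa co-vary
strongly enough, across that ecosystem's samples, to be joined in a
co-occurrence network, and (ii) how the resulting network's topology
relates to the ecosystem's soil chemistry.

Co-occurrence is defined by Spearman rank correlation, computed as the
Pearson correlation of average-rank vectors (ties get fractional ranks).
An edge requires |r| > 0.6 **and** two-sided p < 0.05; both thresholds are
parameters, recorded in the network's metadata. The p-value uses the t
approximation t = r·√((n−2)/(1−r²)) on n−2 degrees of freedom. This
approximation is anti-conservative in the extreme tails for very small n;
ecosystems with 6–9 samples cannot in fact reach p < 0.05 at modest |r|
under it, so an exact option (`p_method="exact"`, full enumeration of all
n! orderings, n ≤ 9) is provided. No multiple-testing correction is
applied by default — the edge rule is a fixed dual threshold, not an
error-rate guarantee — but a Benjamini–Hochberg switch (`fdr=True`)
exists and its use should be reported as a deviation. Pairs involving a
constant ASV have undefined correlation; they are flagged, set to NaN and
excluded, with a warning.

Rank correlation makes the edge set invariant to any per-sample monotone
rescaling of the data, which is why total-sum scaling (relative abundance)
is the only depth correction used; no rarefaction. Compositional closure
still induces weak negative correlation between unrelated taxa
(≈ −1/(p−1) for p taxa); the method does not attempt SparCC-style
compositionality correction, which is out of scope.

## Inclusion filter

An ASV enters the analysis when its mean relative abundance across the
ecosystem's samples exceeds `min_rel_abund` (default 0.001) and its raw
count is non-zero in at least `min_prevalence` samples (default 3, i.e.
"present in more than two"). The abundance clause is deliberately the
*mean* across samples — stable on sparse tables — with
`abundance_rule="any_sample"` as the alternative reading. Prevalence is
counted on raw counts, not proportions. Filters are applied per ecosystem,
because each ecosystem's network is an independent community. The filter
is idempotent and monotone in both thresholds (property-tested).

## Topology

All metrics run on the unweighted, unsigned edge skeleton — negative edges
count as edges — matching common practice in network tools' defaults;
`positive_subgraph` supports sensitivity analysis. Average path length is
the mean BFS distance over *reachable* unordered pairs (pairs in different
components are excluded and logged), which keeps the statistic defined for
the fragmented graphs that strong thresholds produce; the diameter is the
largest finite distance. Nodes of degree < 2 contribute 0 to the mean
clustering coefficient.

Community structure uses the Louvain multilevel algorithm as implemented
in igraph (C backend), run over 5 restarts with seeds derived
deterministically from the caller's seed; the partition with the highest
Newman modularity Q (evaluated independently via networkx) is kept. Nodes
are processed in lexicographic order so repeated runs agree bit-for-bit.
Resolution is fixed at 1.0 by default. Singleton communities count toward
the module number; an edgeless graph has undefined Q, reported as NaN.
On small graphs (≤ 8 nodes) the returned Q is verified in the test suite
against exhaustive partition enumeration, with equality on disjoint-clique
graphs where the optimum has the closed form Q = 1 − 1/K.

## Chemistry link

Soil traits follow the conventional units: texture in g/kg, pH unitless,
EC in dS/m, limestone/OC/TN in g/kg, P₂O₅ in mg/kg, CEC in meq/100 g.
C/N = OC/TN is derived, never measured. Replicate records are aggregated
by arithmetic mean per ecosystem. The ecosystem × feature matrix joins the
topology summary, per-domain mean Shannon diversity, and chemistry (the
default feature set: modularity, module count, diameter, path length,
clustering, edges, nodes, average degree, bacterial and fungal H′, pH, TN,
OC, P₂O₅).

The ordination is PCA on column-wise z-scores (ddof = 1) — equivalently an
eigen-decomposition of the correlation matrix — because topology counts
and chemistry concentrations differ by orders of magnitude; a
raw-covariance mode exists behind `standardize=False`. Each component's
sign is fixed so its largest-magnitude loading is positive, making outputs
comparable across runs. Constant columns cannot be z-scored and raise
(named) in the estimator; the pipeline drops them with a warning first,
since a constant feature carries no ordination information.

## Synthetic data

The generator emulates ecosystem-level amplicon surveys: 6–36 samples per
ecosystem, hundreds of ASVs tagged bacterial/fungal, fixed sequencing
depth. Structure is planted by a Gaussian copula: ASVs are assigned
round-robin to K modules; a block latent correlation matrix (module_rho
within, background_rho between, validated PSD) generates latent normals;
each ASV's latent value passes through a monotone log-normal marginal
whose per-ASV scale is itself log-normal with sigma `abundance_shape`
(default 1.5 — few dominant, many rare taxa, as in real surveys); counts
are one multinomial draw per sample at depth `depth` (default 50,000
reads), so columns sum exactly to the depth. The within-ASV log-scale
dispersion is fixed at 1.0 natural-log unit, a typical sample-to-sample
variation for amplicon counts; it sets the signal-to-multinomial-noise
ratio but not the planted rank structure.

Because the marginal map is monotone, counted data inherit the planted
rank structure: within a module, the large-sample Spearman approaches
(6/π)·arcsin(module_rho/2). Two effects perturb this at realistic sizes,
and both are *features* of the emulation, not bugs: multinomial
discretisation ties rare ASVs at zero, and compositional closure couples
taxa through the per-sample normaliser. The closure effect shrinks as the
ASV count grows, so the copula identity is checked with 200 ASVs in
modules of 10, depth 5·10⁵ and a mild dominance profile
(abundance_shape = 0.5) — conditions chosen to approximate the continuous
limit — where the empirical within-module Spearman lands within 0.02 of
the identity.

Chemistry records are truncated-normal draws around per-ecosystem means
(pH truncated to [3, 10], mass/charge traits to non-negative), with
sd = cv·mean; cv = 0 reproduces the means exactly. The default means are
the package's built-in reference table for a twelve-ecosystem land-use
gradient; the noisy texture triple (sand/loam/clay) is rescaled back to
the ecosystem's texture total so it never exceeds 1000 g/kg.

What passing tests on these data do **not** show: robustness to real
amplicon artefacts the generator deliberately omits — sequencing error and
chimeras, taxonomy mis-assignment, batch effects, overdispersion beyond
the log-normal latent, and genuinely compositional interactions. The
generator plants *rank* structure only; methods sensitive to
compositionality would need different benchmarks.

## Benchmarks the package carries

The standard planted-recovery benchmark is 4 modules × 15 ASVs,
module_rho = 0.85, 30 samples, depth 50,000 — sizes a desk machine
processes in under a second per community. Pushed through
filter → network → topology, the pipeline recovers the 4 modules with Q
near the disjoint-clique limit 0.75 in 85–100% of seeds; the failures
are seeds where closure-induced cross-module edges genuinely merge two
modules in the thresholded graph (truth-partition Q ≈ 0.5 on those
graphs), i.e. the information loss happens before community detection.
The null benchmark (module_rho = 0, 200 ASVs, 30 samples) compares the
observed edge rate at the (0.6, 0.05) thresholds with a permutation
oracle — row-wise shuffled copies of the same table, which preserves each
ASV's marginal and tie structure — and stays within a factor 2 of it
(~10⁻³ per pair).

## Numerical choices and degenerate inputs

- Spearman needs ≥ 4 samples (p-values are meaningless below) and ≥ 2 ASVs.
- An all-zero sample column cannot be normalised and raises, naming the
  sample; a filter that removes every ASV raises and advises threshold
  review; an empty *network* after thresholding is a warning, not an error.
- Ties in ranks use average ranks throughout.
- Determinism: every stochastic step (generation, Louvain restarts,
  chemistry noise) flows from explicit seeds; identical config + seed
  gives byte-identical pipeline outputs, and per-ecosystem Louvain seeds
  are derived via CRC32 of the ecosystem name so runs do not perturb each
  other.
- The exact-permutation p-value conditions on the observed tie pattern by
  permuting one ranked vector over all n! orderings; it is limited to
  n ≤ 9 (9! ≈ 3.6·10⁵ orderings).

## Known limitations

- The t-approximation p-values make edges unattainable for n < 10 at the
  default thresholds unless the exact option is used.
- Spearman networks are not compositionality-aware; closure induces a weak
  negative background correlation that strong thresholds mostly, but not
  entirely, suppress.
- Topology on the unsigned skeleton conflates positive and negative
  associations; use `positive_subgraph` to separate them.
- The PCA is descriptive ordination, not causal analysis of
  chemistry → topology.
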