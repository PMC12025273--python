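# Methods

This note documents the models, defaults and design decisions behind
`dims`, in the order the pipeline runs them.

## Synthetic study design

The generator (`dims.simulate`) emulates a four-arm drug-combination
experiment on a log2-scale expression platform plus an interaction network,
with every planted feature recorded in a `GroundTruth` object.

**Expression.** Each module *m* is a one-factor Gaussian block: member gene
*j* in group *g* and sample *s* has

x_js = baseline_j + noise_sd · ( r_mg · e_ms + √(1 − r_mg²) · ε_js ) + δ_g(j)

with the module factor e_ms and the residual ε_js independent standard
normal draws. The one-factor form was chosen because it is the simplest
generator whose within-module correlation is controllable analytically
(population correlation = r², so r = 0.9 implies 0.81) and because every
Zsummary component is correlation- or eigengene-based — this is the minimal
structure those statistics respond to. A *disruption* replaces the loading
r by `r_disrupted` (default 0) in the named group only; membership labels
therefore stay meaningful across groups, unlike a gene-shuffling scheme.
DEG effects δ are additive log2 mean shifts. Per-gene baselines
(N(8, 2²), shared across groups) give realistic absolute levels without
affecting correlations or fold changes.

Defaults: 200 genes, 20 samples per group, five modules of 30 genes with
loading 0.9, residual scale `noise_sd = 0.2` (so a planted log2(1.5) shift
is comfortably detectable at n = 10–20, as on a good microarray), planted
DEGs of log2(1.5) on ten noise genes per single drug and their union under
the combination. The default disruption map makes module 1 intact only
under drug A, module 2 only under drug B, module 3 only under the
combination, and modules 4–5 intact everywhere — so each drug induces its
own co-expression programme, the combination induces a unique one (the
planted synergy module), and the Sy rule has exactly one correct answer.

**Network.** A Barabási–Albert scaffold (n = 500, m = 3 by default; a
configuration-model alternative is available) carries two planted target
sets wired as spokes of community hubs. In `separated` mode the two sets
hang off hubs of two disjoint scale-free communities joined only through
`n_bridges` planted bridge nodes, so every cross-set shortest path
traverses a bridge and S_AB ≥ +1 by construction. In `overlapping` mode
both sets hang off one hub and share a stated fraction f of nodes, giving
S_AB = −2f exactly. Planting members as spokes rather than as scaffold
members is deliberate: it fixes the sign of S_AB by construction, which is
what the sign-recovery guarantees are about; the cost is that target genes
have degree 1, which is not realistic and is irrelevant to the distance
arithmetic being validated. Bridge nodes exist only in separated mode; in
overlapping mode the bridge list is empty. In the combined study
(`simulate_study`), the network target sets are the genes of modules 1 and
2, so the expression-level On modules and the network-level target sets
refer to the same genes.

All randomness flows from a single seed through named `numpy` sub-streams,
so a fixed config reproduces matrices and graphs byte for byte.

**What the generator does not emulate:** probe/batch effects, heavy-tailed
expression noise, correlated residuals outside modules, weighted or
directed interactions, degree-realistic target placement. Passing tests
demonstrate that the algorithms recover planted structure under the stated
model, not that they would behave identically on any particular microarray
or PPI snapshot.

## Co-expression modules

Unsigned WGCNA-style construction: adjacency a_ij = |cor(x_i, x_j)|^β
(Pearson, complete matrices required; zero-variance genes are the caller's
responsibility), topological overlap
TOM_ij = (L_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij), dissimilarity
1 − TOM, average-linkage hierarchical clustering. The unsigned form is the
conventional default and matches the unsigned use of the preservation
statistics.

**Soft threshold.** The scale-free fit index bins connectivity into ten
equal-width bins and regresses log10 frequency on log10 mean connectivity;
the index is reported as 0 for non-negative slopes. The smallest power
reaching the 0.8 target is chosen, with a warning fallback to the best
fitting power. On small latent-factor fixtures the criterion over-selects
high powers (block-structured data is not scale-free), so the pipeline
defaults to the conventional unsigned power β = 6 and treats scale-free
selection as opt-in (`auto_beta`); published per-dataset powers can always
be passed explicitly.

**Tree cut.** Modules are harvested top-down from the dendrogram: a subtree
is accepted when it holds ≥ `min_size` genes (default 3), is separated from
its sibling by ≥ `min_branch_gap` (default 0.02 of the tree height) and has
mean internal dissimilarity below `max_core_scatter` (default 0.92 of the
tree height); otherwise its children are examined. Accepted branches are
then pruned: members whose mean adjacency to the rest falls below
`prune_rel` (default 0.25) times the median member attachment return to the
grey pool. This is a deliberately transparent stand-in for the dynamic
hybrid tree cut: the gap criterion plays the role of the split sensitivity,
the scatter bound rejects loose noise branches, and the pruning step plays
the role of the kME-based assignment stage. It is deterministic and
invariant to gene ordering. Labels are renumbered by decreasing size with 0
as the unassigned ("grey") label.

## Module preservation and the Sy rule

`module_preservation(ref, test, modules, ...)` evaluates modules *defined
in the reference dataset* (the treatment whose modules are being named)
*inside the test dataset* (the comparator: sham or a single drug). The
direction matters and is an explicit argument order, never inferred. Seven
statistics are computed as documented in the module docstring; eigengenes
come from the first eigenvector of the within-module correlation matrix
(kME_g = √λ₁ · v₁g for row-standardized data), with the sign fixed so mean
kME is non-negative. The permutation null draws `n_perm` (default 200;
minimum 50) random gene sets of the module's size from the full gene
universe of the test dataset without replacement; the same draws provide
the connectivity-side null, which is equivalent to permuting module labels.
A mandatory seed makes runs reproducible; a zero null standard deviation
yields Z = 0 with a warning. Because the universe contains other intact
modules, random sets carry residual co-expression, which is what pushes a
truly disrupted module's Z below zero rather than merely to zero.

Classification: Zsummary < 0 → `on`, Zsummary ≥ 2 (inclusive) →
`conserved`, the band between → `indeterminate` (excluded from both sets).
The Sy rule is
`sy = (On(combo vs drug A) ∪ On(combo vs drug B)) ∩ On(combo vs sham)`,
with per-module provenance recorded.

## DEG screen

Per-gene Welch two-sample *t* on log2 values; fold change 2^|Δmean| with
the direction stored separately; Bonferroni column always reported;
defaults FC > 1.2 and raw p < 0.05 with Bonferroni one flag away. A
moderated-variance option (shrinkage of per-gene variances toward their
mean, weight 0.2) is available but off by default — the default is a plain,
fully specified test rather than an empirical-Bayes pipeline. Overlap
summaries report pairwise and all-way intersections with percentages
against both the pair union and the global union, since overlap-percentage
conventions differ between reports.

## Network proximity and drivers

All distances are unweighted breadth-first; computations restrict to the
largest connected component by default (with a warning) and genes absent
from the network are dropped with a named warning. Disconnected pairs are
skipped and counted rather than given a pseudo-distance, keeping means
interpretable. Separation follows the closest measure exactly as printed
above; shared nodes contribute zero to d_AB; singleton mapped sets are an
error because d_AA is undefined. Flow centrality counts shortest paths by
BFS sigma-accumulation from each target-set member; for a candidate v,
pairs with v as an endpoint are skipped and the normalized value divides by
the per-candidate usable-pair count, so fc_norm ∈ [0, 1]. Both fc_norm
(faithful to the 1/(|A||B|) definition) and the raw pair sum fc_raw are
reported; ranking defaults to fc_raw, matching the magnitude convention of
published driver tables. The per-gene distance score is the summed distance
to every reachable member of A ∪ B — one reconstruction of a "per-gene
shortest distance" column among several possible; it is labelled as such.

Drivers: top-k (default 10) by ascending total distance and by descending
flow centrality; drivers = union, common = intersection, so
|drivers| = 2k − |common| always. Ties break by score then lexicographic
gene id, making the output deterministic and order-invariant. The candidate
pool defaults to all network nodes, since bridge-like drivers need not
belong to either target module.

## Enrichment

A plain one-sided Fisher/hypergeometric over-representation test against
GMT annotations with Bonferroni or Benjamini–Hochberg adjustment. It is a
local stand-in for web-service enrichment tools and makes no attempt to
replicate any modified (EASE-style) statistic. The background defaults to
all genes of the expression matrix.

## Pipeline

`run_pipeline(RunConfig)` executes the seven stages (data, modules,
preservation, DEGs, separation, drivers, enrichment) with group roles named
explicitly in the config, writes every artifact as TSV/JSON, and records a
manifest with sha256 checksums; the config-to-outputs map is a pure
function of the seed. The separation/driver stages use the union of each
single drug's On-module genes as the target sets A and B, which in the
default synthetic study coincide with the planted network sets.

## Problem sizes and numerical choices

The shipped validation workloads use 200-gene, 20-sample studies, 500-node
networks, 100 permutations and 10–20 replicates: large enough for the
planted effects to dominate sampling noise, small enough that the whole
suite runs in about a minute. The end-to-end synthetic fixture detects
modules at a minimum size of 10 (a third of the planted module size)
rather than the library default of 3: at 20 samples, chance triplets of
mutually correlated noise genes are expected, and a minimum size
commensurate with the module scale of the data is the standard guard.
Floating-point policy: correlations are clipped to [−1, 1], TOM division
guards against empty neighbourhoods, p-values are clipped away from zero,
and exact assertions are reserved for genuinely exact identities (set
arithmetic, TOM of a perfect pair, the Zsummary composite).

## Known limitations

- The tree cut is a transparent reimplementation of the dynamic-hybrid
  idea, not a port; on real genome-scale data its defaults may need tuning
  and it offers no PAM stage beyond attachment pruning.
- Preservation implements the seven-statistic Zsummary composite only, not
  the full battery of preservation statistics or medianRank.
- The scale-free fit criterion is meaningful only for data whose
  connectivity actually follows a power law; the synthetic fixtures do not,
  which is why the pipeline pins β by default.
- Enrichment ignores ontology structure (no term propagation).
- Networks are unweighted and undirected throughout.
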