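# Methods

This note records the models, conventions and design choices behind
`rhizostab`, in the order the pipeline runs.

## Count tables and preprocessing

Rarefaction draws without replacement (multivariate hypergeometric), so
rarefying a sample to its own total is the identity and retained column
sums equal the target depth exactly. Samples shallower than the depth
are dropped (and reported), never padded. The rare-taxon screen retains
zOTUs whose **mean** relative abundance across the analysis dataset's
samples is strictly greater than the threshold (default 0.01%); the
mean-across-samples convention, applied per analysis dataset (one
compartment × treatment), is the common practice and is logged with
each run. Shannon diversity uses the natural logarithm.

## Co-occurrence networks

One network per compartment × treatment, pooling growth stages and
replicates (15 samples at the reference design). Edges require Spearman
|ρ| > 0.8 **and** Benjamini–Hochberg adjusted *P* < 0.05, adjusted over
the pairs actually tested within that network. Isolated retained taxa
are excluded from the node set (logged); constant taxa yield undefined
correlations and are never promoted to edges.

**P-values.** The classical *t* approximation for Spearman's ρ is
accurate near the centre but anti-conservative by a factor of 2–5 in
the far tail at n ≈ 15 — exactly the region that decides whether the
smallest p-value survives BH. The default is therefore an exact-tail
scheme: full enumeration of the tie-free permutation null for n ≤ 8,
and a large (2 × 10⁶ draw) shared Monte-Carlo sample of the permutation
null for 8 < n ≤ 30 (the null distribution is universal for tie-free
data given n, so the table is computed once per sample size from a
fixed internal seed and cached). Beyond n = 30 the *t* approximation is
used; it can always be requested explicitly. With ties the permutation
null is an approximation (tied data are rare for count tables at
realistic depth; a log message flags them in the exact-enumeration
path).

**False positives and compositional closure.** With valid p-values,
the probability that a structure-free table yields *any* edge equals
the BH level (≈5%, the Simes identity) — that is the floor, not an
implementation artefact. Relative abundances add a second, genuine
signal: when one taxon dominates a community (≳30% of reads), its
fluctuations suppress everything else through the shared denominator,
creating real negative correlations with — and positive correlations
among — the remaining taxa. A correlation network rightly detects
these. The package's null fixture (`null_design`) therefore uses an
even community; analyses of real tables with hyperdominant taxa should
expect closure-driven edges.

## Topology

Closeness centrality uses the component-scaled (Wasserman–Faust)
convention, so values are in [0, 1] network-wide even when the graph is
disconnected and the hub threshold (closeness > 0.25, degree > 40, both
strict) is meaningful. Modules come from Louvain modularity
maximisation with a fixed seed and sorted node order (stable
tie-breaks); relative modularity compares observed modularity with
degree-preserving Maslov–Sneppen rewirings (10·|E| double-edge swaps,
100 null graphs by default), falling back to an Erdős–Rényi null with
matched n and |E| when rewiring is impossible (e.g. stars). Degree is
unweighted; correlation strengths remain as edge attributes.

## Stability battery

*Natural connectivity* is λ̄ = ln((1/N) Σ e^{λᵢ}) over the unweighted
adjacency spectrum, computed with a log-sum-exp so dense graphs cannot
overflow; an edgeless graph gives exactly 0. Robustness curves remove
round(f·N) random nodes (induced subgraph) for f = 0…0.8 in steps of
0.05, 100 repetitions, reporting mean ± sd of λ̄ and average degree.

*Cohesion*: a taxon's connectedness is the **mean** of its significant
positive (resp. negative) correlations — the convention of the index's
source method; the package also offers the sum (`agg="sum"`). Per
sample, positive/negative cohesion is the abundance-weighted sum of
connectedness. Abundances are the community-wide relative abundances,
so taxa outside the network contribute zero and cohesion scales with
how much of the community the network engages; a `renormalize=True`
variant restricts and renormalises weights over network taxa, which
makes cohesion a pure mean-correlation summary that is invariant to
network coverage (and therefore cannot express coverage differences
between treatments). No null-model correction is applied to
connectedness.

*AVD* is the grand mean of |x − mean| / sd over taxa and replicates
(sample sd; zero-variance taxa contribute 0 but still count in the
denominator), with the three growth stages' replicates pooled within a
treatment. *Vulnerability* is the maximum relative drop in global
efficiency (unreachable pairs contribute zero) over single-node
removals, computed on the whole graph rather than the giant component.

## Zi–Pi, SPEC-OCCU and the core screen

Zi is the within-module degree z-score (sample sd over the module's
members; sd = 0 gives Zi = 0); Pi = 1 − Σ (k_t/k)² over modules
(degree-0 nodes get Pi = 0). The printed role rules overlap at the
corner, so precedence is fixed: network hub (Zi ≥ 2.5 and Pi ≥ 0.62)
first, then module hub (Zi > 2.5, Pi ≤ 0.62), then connector
(Zi ≤ 2.5, Pi > 0.62), else peripheral. Specialists require
specificity > 0.7 and occupancy > 0.7 (both strict) among a habitat's
500 most abundant zOTUs ranked by mean relative abundance; habitats are
the treatments. "Present" means count > 0 in the table at hand, with
no minimum-count threshold. Shared zOTUs must survive the network-level
abundance filter and be detected within every treatment group. The
core set is the three-way intersection, with keystone status taken as
the union over all compartment × treatment networks: a connector's
edges at 15 samples per network appear stochastically, so any single
network understates keystone membership while the union over the study
design's nine networks is reliable (measured below).

## NTI

MNTD is presence-based (unweighted). The null shuffles taxon labels on
the distance matrix — equivalently, draws uniform same-size subsets of
the pool — with 999 randomisations by default; NTI is the negated
standardised effect size, set to 0 (and flagged) when the null is
degenerate (e.g. the community is the whole pool). NTI > 2 is annotated
as phylogenetic clustering.

## The synthetic-community generator

The generator exists so every downstream stage can be scored against a
known truth; its defaults are the study conditions used throughout the
tests.

**Latent model.** A Gaussian copula over log-normal abundances: block
members load √ρ on a shared factor (pairwise latent correlation ρ),
anti-correlated pairs take loadings of opposite sign (all-negative
blocks larger than pairs are not positive semi-definite), and
attachment taxa load evenly on several factors. Counts are multinomial
per sample at log-normally drawn depths (mean 50,000, σ = 0.2).
Because ranks are invariant to monotone per-sample transforms, a pair's
population Spearman correlation follows ρ_s = (6/π)·asin(r/2) from its
latent Pearson r.

**Abundances.** Unplanted taxa draw base log-abundance from N(0, 1.5²)
(a broad community distribution); planted taxa from N(−1, 0.3²),
roughly 0.1–0.4% relative abundance each. Two constraints pin this
level: planted taxa must sit far enough above count noise that ~50-read
fluctuations cannot scramble ranks, yet the co-fluctuating planted
guild must stay a small share of the community — a correlated guild
above roughly 10% of reads visibly attenuates every correlation through
compositional closure (the per-sample total swings with the guild's
common factor). Enriched taxa (30-fold in severe drought) start from
the same planted baseline, so even enriched they hold only a few
percent of reads.

**Core taxa as connectors.** Each planted core rides the common factor
of its own cluster of eight six-member blocks (block ρ = 0.95, factor
correlation 0.72 — the positive-semi-definiteness minimum for the
attachment strength 0.865). The geometry here is a hard constraint: a
taxon cannot be strongly correlated with several *weakly* coupled
groups (the attachment ceiling is √((1+(k−1)r)/k)), so connector
attachments necessarily sit just below the detection threshold and
appear as a handful of cross-module edges per 15-sample network — the
Zi–Pi signature of a connector, realised stochastically. Measured over
30 seeds, the nine-network union recovers planted cores with recall
≈ 0.88 and no spurious core calls; planted edges are recovered with
precision ≈ 0.98 and recall ≈ 0.89.

**Edge ground truth uses a decision band.** Strictly planted edges are
pairs whose latent Spearman correlation exceeds the network threshold
by a margin (0.85 for the 0.8 threshold): recall is scored against this
set. Pairs with genuine planted correlation in the band (latent |ρ_s|
between 0.5 and 0.85) are detected with probability near one half *by
construction*; they count in favour of precision (they are not false
positives) but not against recall. This is the standard indeterminate-
band treatment when scoring a thresholded detector.

**Replicate instability and AVD.** For purely log-normal replicate
noise, AVD *decreases* as dispersion grows: the per-taxon statistic
|x − mean|/sd is scale-free, and more dispersed log-normal replicates
are more skewed, which lowers it. Real replicate instability, however,
also manifests as sporadic blooms of conditionally rare taxa (CRT).
The generator therefore carries a large CRT pool (375 taxa by default)
far below the abundance filter (base log-abundance −12), each cell of
which blooms to ~0.03% relative abundance with probability
0.1 × noise_sd. Blooms dominate the fraction of non-constant taxa, so
AVD rises monotonically with the instability parameter (≈0.47 / 0.52 /
0.56 at noise 0.7 / 1.0 / 1.3), matching the index's intended reading,
while the CRT never enter the networks.

**Directional scenarios.** Two scenarios mirror a niche contrast in
which stability rises (root-like) or falls (rhizosphere-like) across
CK → MD → SD. Each treatment owns disjoint planted structure at one of
three intensity levels: blocks of 5/6/8 taxa at ρ 0.93/0.93/0.96,
chained by 1/2/4 bridge taxa per junction plus 0/1/4 ring-closing
bridges (parallel and ring bridges provide path redundancy, which is
what lowers vulnerability), 1/4/8 abundant anti-correlated competitor
pairs (graded to baseline/~1%/~2.5% abundance so negative cohesion mass
tracks the level; a competitor pair's *sum* is stable, so these add no
closure distortion), and replicate instability 1.3/1.0/0.7. Under
these conditions all five indices (natural connectivity, total
cohesion, |negative|/positive cohesion ratio, AVD, vulnerability) order
monotonically with the planted direction in both scenarios (20-seed
means).

**What the generator does not emulate.** Real sequencing data add
taxonomic misassignment, chimeras, batch effects, spatial structure and
phylogenetically conserved niche responses; the generator's taxa are
exchangeable apart from their planted roles, its tree (for NTI testing)
is random rather than trait-linked, and growth stages carry no stage
effect. Passing tests therefore certify the statistical machinery and
its directional behaviour under known truth, not performance on any
particular real dataset.

## Problem sizes

The reference design uses 170 persistent plus 375 conditionally-rare
taxa across three kingdoms, 3 compartments × 3 treatments × 15 samples,
depth 50,000; recovery statistics average 20 seeds and directional
scenarios 20 seeds, sizes chosen so the full validation runs in about a
minute while keeping Monte-Carlo error well below the decision margins.

## Known limitations

- Thresholded Spearman networks are not compositionally aware
  (SparCC/SPIEC-EASI are out of scope by design); closure effects are
  real correlations on the relative-abundance scale and are documented
  above rather than corrected.
- Exact-tail p-values assume tie-free data; heavy zero-inflation among
  retained taxa would make them approximate.
- The any-edge false-positive rate on null data cannot fall below the
  BH level (~5%); tests asserting "≤5 of 100 seeds" sit at that
  boundary by construction.
- Vulnerability is O(N²·E); for networks beyond a few thousand nodes it
  becomes the pipeline's bottleneck.
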