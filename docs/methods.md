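# Methods

This note documents the models, conventions, and design choices behind
osteonet, in the order the pipelines run them.

## Interaction network construction

The analyzed object is a simple undirected graph: protein symbols as nodes,
STRING-style combined confidence scores in [0, 1] on edges. The parser
accepts both score dialects (0–1 reals and 0–1000 integers, the latter
divided by 1000; the decision is made per file from the column maximum),
collapses duplicate unordered pairs to the maximum score, and skips
self-loop rows with a warning. Identifiers are case-sensitive and
whitespace-trimmed.

**Confidence filter.** `filter_by_confidence` keeps edges with
`score >= threshold` (default 0.9, the conventional "very high confidence"
level). The comparison is inclusive because the threshold names the
confidence level itself. Nodes isolated by filtering are retained and
reported (`isolated_nodes`) rather than silently dropped — downstream
consumers decide their fate.

**Connected-core reduction.** Interactive database front-ends let an
analyst re-query with progressively fewer allowed interactors until the
seed proteins form one uninterrupted chain. That manual process is not
reproducible, so the package substitutes a deterministic greedy rule:
remove non-seed nodes in increasing current-degree order (lexicographic
tie-break), skipping any removal that would disconnect the graph or
orphan a seed, until at most `max_partners` non-seed nodes remain or
nothing further can go. The output is always connected and seed-complete;
seeds spread over several components are an error, reported by name.

## Topological indices

All distances are hop counts: scores gate which edges exist, after which
edges are unweighted — the default of common network-analysis tools and
the convention assumed by the index definitions.

- Betweenness is computed with Brandes' accumulation algorithm and
  reported **unnormalized** (sum of pair fractions); a normalized variant
  (divisor `(n−1)(n−2)/2`) is emitted alongside since tool conventions
  vary. The test suite checks both the fast implementation against a naive
  oracle that enumerates every shortest path explicitly (10⁴ random
  connected graphs on ≤ 7 nodes, agreement to 1e-9) and against networkx.
- Eccentricity and closeness are per-component; an isolated node gets
  Ecc = 0 and CC = 0 and every node carries a component index so consumers
  can exclude stragglers. The harmonic-closeness alternative for
  disconnected graphs is deliberately not used.
- Local clustering of a degree-<2 node counts as 0 in the average. This
  matters: it lowers Acc relative to conventions that exclude such nodes
  from the mean, and is documented for that reason.
- All iteration is over sorted identifiers, so results are independent of
  node insertion order (asserted by a relabeling-invariance test).

## Role classification

Hubs are the top decile by degree, bottlenecks the top decile by
betweenness, the backbone their union. Two conventions are fixed
deliberately:

- **Decile size rounds up** (`ceil(0.10 N)`, so 3 of 24) and every node
  tied with the cutoff value is included. Rounding down would make a
  three-way hub call on a 24-node network impossible.
- **Upstream signal.** A node can be hub-grade in degree yet peripheral:
  BC below the network median, Ecc strictly above the median, CC strictly
  below. Such a node behaves as an early/initial activator feeding the
  backbone rather than a relay inside it, and is excluded from the
  backbone (the flags are mutually exclusive). The qualitative pattern is
  operationalized as strict median comparisons; the decile fraction is a
  parameter.

Ranks use competition ranking (ties share the better rank).

## Colony morphometry

**Segmentation** is fixed-threshold foreground (default 0.5), hole
filling, 8-connected labeling, and a minimum-area speckle filter (default
50 px). All parameters are exposed in the run config.

**Geometry.** Area is the mask pixel count; circularity is the
isoperimetric quotient `4πA/P²`. The perimeter estimator is the length of
the subpixel 0.5-level contour (marching squares) smoothed with a circular
5-point moving average of its vertices. The smoothing is essential: a raw
pixel-chain perimeter (axis steps 1, diagonal steps √2) overestimates a
smooth boundary by ~5% on average orientation, which deflates a rasterized
disk's circularity to ≈ 0.90; after smoothing the r = 50 disk measures
0.994, a 100-px square 0.801 (ideal π/4 ≈ 0.785), and a 2:1 ellipse 0.836
(Ramanujan ideal ≈ 0.844). Residual discretization error is within about
±0.03 for shapes tens of pixels across, and values may exceed 1 by up to
~0.02; tests and documentation carry these tolerances. Reported
circularity is rounded to 4 decimals.

**Classification.** An aggregate is a colony only above 14 cells (> 1.75
doublings at the replication kinetics of these cells at subconfluence);
exactly 14 is *not* a colony. Sparse vs dense is driven by an explicit
nuclei-countability flag — how two human observers operationalized
countability is not recoverable, so it is an input, supplied by the
synthetic generator's ground truth in tests.

**Counts and scores.** CFE = colonies per 10⁵ seeded cells, computed per
condition; the control/differentiated comparison is the ratio of the two
CFE values. Grid proportions pool positives over fields
(`Σ pos / Σ total`) and also return per-field fractions. The ordinal
staining scale is `-` below 25%, `+` for 25–50%, `++` for >50–75%, `+++`
above 75%; the printed convention leaves a gap between 50% and 51%, closed
here by assigning exactly 0.50 to `+`. Quadrant counts partition the field
by its midlines with points on a dividing line assigned to the left/top
quadrant, so totals are conserved.

## Statistics

One-way fixed-effects ANOVA by direct sum-of-squares decomposition
(degenerate zero-variance inputs: F = 0, p = 1 for equal means; F = ∞,
p = 0 otherwise). The SNK post hoc orders group means and tests contiguous
stretches outward-in against `q(r, df_within, α)·√(MSW/n_h)`; a
non-significant stretch blocks all nested comparisons (coherence), and
unequal group sizes use the harmonic mean n_h (Kramer adjustment — the
original procedure does not fix a convention). Critical values come from
scipy's studentized-range distribution (numerical integration, no lookup
tables) and are validated against published table entries; under the
complete null the family-wise error equals the nominal α of the first
(full-range) step, which the Monte-Carlo calibration test confirms.

The chi-squared test on 2×2 proportion tables is the Pearson statistic
without continuity correction by default (Yates available by flag), with
zero margins rejected.

**Sample-size helper.** `anova_n_per_group` returns the smallest per-group
n whose one-way noncentral-F power (λ = f²·k·n, df = (k−1, k(n−1))) reaches
the target; with Cohen's f = 0.50, α = 0.05, power = 0.80 and two groups it
gives n = 17. Published designs sometimes quote much smaller n from
repeated-measures configurations whose correlation structure and
measurement counts are rarely reported; this helper sizes the one-way
design only and makes no claim to reproduce such numbers.

## Synthetic data

The generators define the conditions under which the package is exercised;
all are deterministic per seed with one RNG stream per call.

**Planted graphs** (default 24 nodes, 42 edges, 14 seeds, scores uniform
in [0.9, 1.0], matching the dimensions of the interactome the pipeline is
built for): two dense blocks joined only through a bridge node X (two
gateway edges per side), a hub H wired to all of its block, a random
spanning tree in the other block, and random intra-block extra edges that
are never allowed to raise another node to the hub's degree. Every
cross-block shortest path passes X, so X's betweenness dominates; the
construction is verified after generation (connected, hub strictly max
degree, X strictly max betweenness) and deterministically re-drawn from
the same stream in the rare case an extra edge spoils the ordering. Role
recovery across 100 seeds is 100/100 in the shipped configuration.

**Culture fields** (default 512×512, colonies of radius 18–40 px,
non-overlapping, Gaussian pixel noise σ = 0.02): shapes are disks,
area-preserving ellipses (axis ratio 1.4–2.2), or radially perturbed blobs;
each colony's exact rasterized area and the analytic circularity of its
continuous outline go into the ground-truth table. Dense colonies render
as near-confluent bright texture, sparse ones as a moderate base with
bright resolvable nucleus dots — mirroring the countability criterion.
The `control` preset draws larger, more irregular colonies
(radius 26–40 px, ellipse/blob-heavy); the `differentiated` preset plants
the post-induction effect — smaller (16–26 px), disk-heavy, hence more
circular. What passing tests show is that the measurement chain recovers
planted geometry and direction-of-effect; the generator does not emulate
uneven illumination, touching colonies, debris, or focus drift, so
real-image performance depends on threshold/min-area tuning that synthetic
results cannot certify.

**Group data**: seeded normal draws per group, used by the null
calibrations (ANOVA rejection ≈ α; SNK family-wise error within
Monte-Carlo error of α over 2000 simulations of 4 equal-mean groups,
n = 10).

## Pipelines and determinism

Both pipelines validate a flat config (defaults: min_score 0.9, decile
0.10, alpha 0.05), run fixed stage orders, and write reports that embed
the resolved config, its hash, the package version, and the seed — and no
timestamps, so a rerun on the same inputs is bit-identical (asserted by
checksum in tests). A failing stage removes partial outputs and re-raises
tagged with the stage name.

## Known limitations

- The hub/bottleneck tie expansion can return more than `ceil(0.10 N)`
  nodes on graphs with many tied degrees; this is by design but worth
  remembering when comparing set sizes across networks.
- The perimeter estimator is tuned for convex-ish blobs tens of pixels
  across; very small masks (< ~10 px diameter) and highly concave shapes
  carry larger circularity error than the stated ±0.03.
- Cell counts per colony are inputs (or generator truth), not estimated
  from pixels; nucleus-level instance segmentation is out of scope.
- The average clustering coefficient depends on the degree-<2 convention
  (counted as 0 here); comparisons against tools that exclude such nodes
  must adjust.
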