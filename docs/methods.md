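# Methods

This note documents the models, conventions, and numerical choices behind
`nichewebs`, and what the synthetic-data validation does and does not show
about real amplicon surveys.

## Niche breadth and classification

Levins' breadth B_j = 1/Σ_i P(i,j)² is computed per ASV after row-wise
normalization, so B lies in [1, N] for N samples regardless of sequencing
depth. The shares P(i,j) are taken by default from per-sample relative
abundances (removing depth artifacts before asking how evenly a taxon
spreads over samples); raw counts are available through `use="counts"`
because published workflows are often silent about this step and the
choice can matter for unevenly sequenced designs.

Inclusion filters run before classification: mean relative abundance
≥ 2×10⁻⁵ and prevalence ≥ 25 samples, both boundaries inclusive.
Extremely rare taxa otherwise masquerade as specialists. Classification is
strict outside the cutoffs (generalist B > upper, specialist B < lower;
both cutoffs themselves fall to "common"). Fixed defaults 78/22 suit a
225-sample design; `suggest_thresholds` derives data-driven cutoffs as the
Tukey fence Q3 + 1.5·IQR (upper) and the lower quartile Q1 (lower) using
linear-interpolation ("type 7") quantiles, the R default. At least 4
values are required — the minimum for quartiles to be defined.

A structural consequence of the Q1 rule: it can never label more than a
quarter of the included taxa as specialists, so datasets (real or
simulated) whose true specialist fraction exceeds 25% cannot be fully
recovered with data-driven cutoffs. The synthetic defaults keep the
specialist fraction near 23% for this reason.

## Association networks

All pairwise Spearman correlations use midranks for ties; p-values come
from the t approximation t = ρ√((n−2)/(1−ρ²)) on n−2 degrees of freedom
(standard at n in the hundreds), with |ρ| = 1 mapped to p = 0. Zero-
variance variables get undefined (NaN) correlations and never form edges.
Missing covariate values are handled pairwise-complete with the per-pair n
recorded; pairs with fewer than 10 complete observations are not tested.

Benjamini–Hochberg correction is applied once over all tested pairs in the
network under construction — ASV–ASV, ASV–environment, and
environment–environment as a single family. This is the conservative
reading when a published workflow says only that q-values were computed
"to account for multiple testing". Edge retention is strict:
ρ > 0.5 and p < 0.001 and q < 0.001 (a pair at exactly ρ = 0.5 is
rejected). Negative correlations are excluded by default
(`positive_only`), environment–environment edges are kept but flagged
`env_env`, and isolated nodes are dropped from exported graphs.

## Topology, nulls, and small-worldness

Observed metrics follow the Cytoscape NetworkAnalyzer conventions:
density 2m/n(n−1); mean degree 2m/n; mean clustering with degree-<2 nodes
contributing 0 (not excluded); L and diameter over connected pairs only
(these networks are disconnected; a largest-component-only variant is
available); heterogeneity √var(k)/mean(k); centralization
(n/(n−2))(max(k)/(n−1) − density). One published bookkeeping quirk is
documented rather than emulated: a "average number of neighbours" row that
does not equal 2m/n for the printed node and edge counts, presumably
because the plugin excluded some node class; this package always reports
2m/n.

The null model is G(n, m) — uniform over simple graphs with exactly the
observed node and edge counts, per "same number of nodes and links" — not
G(n, p). Default 100 replicates; per-metric means and standard errors are
reported, and each replicate's modularity comes from a seeded Louvain run.
SW = (C/C_R)/(L/L_R). For a pure ER graph SW ≈ 1; note that a single
n = 200, m = 800 draw has roughly 5–10% sampling noise in C, so sanity
checks of SW ≈ 1 average several observed draws.

Louvain uses networkx's seeded implementation; communities are renumbered
by their smallest node label so a fixed seed gives bit-reproducible module
ids. The reported Q always equals the package's own Newman modularity
Q = Σ_s (e_s/m − (d_s/2m)²) on the returned partition, and matches
brute-force maximum-modularity enumeration on small test graphs.

## Node roles

Zi is the z-score of within-module degree over the node's module, using
the population standard deviation (Guimerà–Amaral convention); singleton
and zero-variance modules get Zi = 0, where the statistic is otherwise
undefined. Pi = 1 − Σ_s (k_is/k_i)², 0 for isolated nodes. Role classes
split at Zi = 2.5 and Pi = 0.62, boundaries belonging to the peripheral
side. Closeness is (reachable count)/(distance sum) within a component
(a harmonic variant is available), betweenness is unnormalized by default,
and environment nodes are excluded from role statistics unless requested —
roles describe microbes. Group comparisons across niche categories use
two-sided Mann–Whitney tests by default (a t-test is available); the
choice is a package default because published figures of this kind often
show significance stars without naming the test, and no multiple-
comparison correction is applied beyond the per-pair test.

## Module patterns

A module's distribution pattern is the per-sample mean of its member ASVs'
min–max-scaled relative abundances; environment nodes never contribute.
Constant profiles scale to zeros with a warning. Patterns are clustered
with Ward's method on Euclidean distances — scipy's `ward`, equivalent to
hclust's `ward.D2`; a `ward.D` variant (the classic Lance–Williams update
applied to the distances as given) is provided since hclust users may have
used either. Major modules are those with at least max(5, 2% of nodes)
members — a tunable default, since published analyses typically report
major-module counts and coverage without stating the rule; the reported
coverage makes the consequence of the rule visible. Inter-module
connectivity uses within-density e_s/(n_s(n_s−1)/2) and between-density
e_st/(n_s·n_t), displayed as percentages rounded half-away-from-zero to
one decimal. Environment subnetworks induce the graph on environment nodes
plus their direct ASV neighbors, excluding ASV–ASV edges among the
selected neighbors by default (flag to include).

## Synthetic communities

The generator emulates a three-belt elevation survey: 225 samples split
75/75/75 across belts with elevations drawn at 162 ± 43 m (low),
251 ± 21 m (mid), and 302 ± 39 m (high). About 15 covariates are linear in
standardized elevation plus Gaussian noise, with field-realistic signs:
moisture, vascular cover, C/N, EC, and litter depth decrease with
elevation; temperature, cryptogam cover, rock cover, dry/wet ratio, and
respiration increase; pH is flat. A latent vegetation variable is driven
by (negative) elevation and moisture and indicated by vascular-plant and
cryptogam cover, mirroring the causal structure the analysis is meant to
probe: vegetation → generalists → common taxa → specialists, with cascade
coefficients of 0.3–0.5 log-units per latent standard deviation.

Each ASV's expected abundance is log-linear: a category baseline, a
Gaussian niche response along elevation, and a shared per-module latent
factor that plants co-occurrence blocks (modules are correlation blocks,
not taxonomic groups). Counts are negative binomial (size 10) at a
lognormal sequencing depth (median 20,000, log-sd 0.25), then implicitly
compositional through relative-abundance normalization downstream.

Default effect sizes are chosen for recoverability — the ability of the
downstream pipeline to identify what was planted — not to reproduce any
particular field dataset, which supplies no usable effect sizes. The
defaults that matter:

* niche widths 1000 / 60 / 14 m (generalist / common / specialist): the
  generalist response is flat over the sampled range; the specialist
  response confines most abundance to one belt;
* module loadings 0.2 / 1.1 / 1.1: weak for generalists (one loosely
  coherent block, consistent with generalist networks being the least
  modular), strong for common and specialist blocks;
* category baselines 4.4 / 2.8 / 4.2 log-units. The low common baseline
  is deliberate: because relative abundances share a compositional
  denominator, a high-abundance block's latent factor partially cancels in
  its own members' proportions while adding variance to everyone else's.
  Keeping the common block's community share modest preserves both its own
  planted correlation structure and the generalists' high, tightly
  clustered B values;
* 40 generalists, 130 common, 50 specialists (≈23% specialists, see the
  Q1 constraint above) in six modules: one generalist block, two common
  blocks centered mid-gradient (215 and 270 m), three specialist blocks at
  the belt centers. Mid-gradient common centers keep common profiles
  non-monotone in elevation; monotone profiles rank-correlate strongly
  with specialist profiles at the gradient ends and blur the planted
  blocks.

What passing recovery tests shows: under these conditions the classifier
recovers planted generalists and specialists at ≥ 80% with data-driven
cutoffs, and Louvain on the built network recovers the planted blocks at
ARI ≥ 0.8 (10 seeds). What it does not show: performance on real
communities with thousands of rare taxa, phylogenetically structured
correlation, spatial autocorrelation beyond the elevation axis, or
taxon-specific amplification bias — none of which the generator emulates.
The synthetic networks are also denser and more cleanly clustered
(C ≈ 0.95) than field networks.

## Pipeline and reproducibility

`run_all` executes simulate/load → low-count filter (total ≥ 4, removing
singletons through tripletons) → rarefaction (to the minimum depth, single
draw — replicate-averaged rarefaction is not attempted) and Shannon
diversity (natural log, as in vegan) → niche classification → four
networks (one per category plus total, all from the same filtered pool,
with environment nodes) → topology with nulls → roles on the total
network → module patterns. Every stochastic stage draws its seed from the
run seed, and identical configurations produce byte-identical TSV outputs.
On a simulated scenario the pipeline defaults to data-driven B cutoffs,
since the fixed 78/22 values are calibrated to a particular 225-sample
field design's B distribution, not to arbitrary simulated ones; fixed
cutoffs apply when `auto_thresholds` is off.

Problem sizes used in the validation suite — 220-ASV scenarios, 100-replicate
nulls at n ≤ 250, 10-seed recovery averages — are chosen so the full suite
and the acceptance script each complete in minutes on a single CPU while
keeping the Monte-Carlo error of every checked quantity well inside its
test tolerance.

## Known limitations

* The p-value approximation is the t form only; exact permutation p-values
  and the F alternative are not implemented.
* Compositionality-aware association methods (SparCC, SPIEC-EASI) are out
  of scope; Spearman on relative abundances inherits their known biases.
* Weighted-edge topology and degree-preserving (configuration-model) nulls
  are not implemented.
* BIOM/HDF5 input is not supported; TSV is canonical.
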