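# nichewebs

Niche-breadth classification and co-occurrence network analysis for
microbial communities sampled along environmental gradients.

`nichewebs` is aimed at microbial ecologists working with amplicon (16S
rRNA ASV) surveys who want to ask: *which taxa are habitat generalists and
which are specialists, how do those groups wire the community's
co-occurrence network, and which environmental factors line up with the
network's modules?* The package bundles the full analysis chain — feature
table handling, Levins' niche breadth, Spearman association networks with
FDR control, Erdős–Rényi null models and small-world coefficients, Zi/Pi
node roles, and module distribution patterns — together with a synthetic
elevation-gradient community generator that carries complete ground truth,
so every stage of the pipeline can be validated without external data.

## The statistics at the core

**Levins' niche breadth.** For taxon *j* with abundance share *P(i,j)* in
sample *i* (normalized so the shares sum to 1 over samples),

    B_j = 1 / Σ_i P(i,j)²

*B* ranges from 1 (confined to one sample) to *N* (perfectly even over *N*
samples). Taxa with *B* above an upper cutoff are generalists, below a
lower cutoff specialists, and common taxa in between. Cutoffs are either
fixed (defaults 78/22, appropriate for 225-sample designs) or data-driven:
the Tukey fence Q3 + 1.5·IQR for generalists and the lower quartile Q1 for
specialists. Rare taxa (mean relative abundance < 2×10⁻⁵ or prevalence
< 25 samples) are excluded before classification.

**Co-occurrence networks.** Edges connect variables (ASVs, and optionally
environmental covariates) with Spearman ρ > 0.5 and both p and
Benjamini–Hochberg q below 0.001 (p from the t approximation
t = ρ·√((n−2)/(1−ρ²))). Whole-network topology is normalized by a G(n, m)
Erdős–Rényi null with the same node and edge counts; the small-world
coefficient is SW = (C/C_R)/(L/L_R) with C the mean clustering
coefficient, L the characteristic path length, and subscript R the null
means. Modules come from seeded Louvain; each node gets a within-module
degree z-score (Zi) and a participation coefficient
Pi = 1 − Σ_s (k_is/k_i)², classifying it as peripheral, connector, module
hub, or network hub at the conventional thresholds Zi = 2.5 and Pi = 0.62.

## Worked example

Run the whole pipeline on the default synthetic scenario (225 samples in
three elevation belts, 220 ASVs: 40 generalists, 130 common, 50
specialists, six planted co-occurrence modules):

```python
from nichewebs.pipeline import RunConfig, run_all, report
from nichewebs.simulate import ScenarioConfig

cfg = RunConfig(scenario=ScenarioConfig(), seed=1, outdir="out", null_reps=100)
res = run_all(cfg)
print(report(res.manifest))
```

prints

```
nichewebs 0.1.0 run (seed 1, config 75e748e2)

input: 220 ASVs x 225 samples
after low-count filter (total >= 4): 220 ASVs
niche classification (B cutoffs 85.0/129.6): 220 included
  generalist  40
  common      125
  specialist  55

network      nodes   edges      C      L      SW      Q
generalist      54     775   0.95   1.06    2.43   0.09
common         139    3884   0.99   1.17    3.33   0.51
specialist      69     641   0.92   1.61    3.65   0.63
total          234    5536   0.98   1.88    4.59   0.69
```

Reading the output: the data-driven B cutoffs (129.6 for generalists, 85.0
for specialists) recover the planted 40 generalists exactly; the four
networks (one per niche category plus the total) all have SW > 1, i.e.
they are more clustered than an Erdős–Rényi graph of the same size at a
comparable path length, and modularity Q is highest for the specialist
network — specialists form tight, elevation-specific modules while
generalists form one loosely modular block. Stage outputs (niche profiles,
edge/node tables, GraphML, module patterns, a Ward dendrogram in Newick
form, and a JSON manifest of all stage counts) land in `out/`.

The same pipeline is available from the shell:

```sh
nichewebs run --seed 1 --outdir out
nichewebs simulate --seed 1 --outdir data
nichewebs niche --input data/feature_table.tsv --output profiles.tsv --auto-thresholds
```

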