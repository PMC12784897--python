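# fishdiv

Multidimensional diversity analysis for reservoir fish assemblages.

Dam impoundment turns a flowing river into a lentic gradient: habitat
conditions homogenize toward the dam, widespread (often introduced) species
spread across sites, and community composition converges. `fishdiv`
quantifies that process on a site × species survey (counts + biomass), a
dated phylogeny of the species pool, an environmental table and river
distances, asking three questions:

1. **How diverse is each site?** Taxonomic α-diversity (Margalef richness
   `D = (S−1)/ln N`, Shannon `H′`, Pielou evenness `J = H′/ln S`, Hellinger
   distance-to-centroid divergence) and phylogenetic α-diversity (Faith PD,
   abundance-weighted MPD and VPD), the latter standardized against a
   tip-shuffle ("taxa labels") null:
   `SES = (obs − mean(null)) / sd(null)` over 999 permutations.
2. **How different are sites, and why?** Pairwise Sørensen dissimilarity,
   Baselga-partitioned into turnover and nestedness at both levels,

   ```
   βsor = (b+c)/(2a+b+c),  βturn = min(b,c)/(a+min(b,c)),  βnes = βsor − βturn
   ```

   where (a, b, c) are shared/unique species counts (taxonomic) or
   shared/unique branch lengths of the communities' spanning subtrees
   (phylogenetic). The two levels are contrasted with the beta deviation
   `(βtax − βphy)/βtax` and Cohen's d.
3. **Which species dominate?** The index of relative importance,
   `IRI = 10000 · Fi · (Ni + Wi)` (occurrence frequency × the summed shares
   of individuals and biomass), with >500 dominant, 100–500 common,
   <100 rare.

Driver attribution then regresses each β component on pairwise
environmental distance and river distance (distance decay, with a
Mantel-style permutation check), splits the joint R² by hierarchical
partitioning ("average shared variance"), screens α-diversity drivers with
BH-adjusted Spearman correlations, and fits penalized-spline (GAM) trends
of each environmental variable against distance-to-dam.

A fully parameterized synthetic-data module generates surveys with
independently tunable turnover and nestedness structure, Yule trees,
trended environmental gradients and river geometry, so the whole pipeline
is testable end to end without field data.

## Worked example

```python
from fishdiv.tables import RunConfig
from fishdiv.pipeline import run_pipeline

res = run_pipeline(RunConfig(seed=42, out_dir="results/demo"))
print(res["beta_summary"].round(4))
```

```
              n_pairs  mean_sor  mean_turn  mean_nes  turnover_share  nestedness_share  beta_dev
level
taxonomic          36    0.5114     0.4044    0.1071         79.0632           20.9368     0.605
phylogenetic       36    0.2020     0.1209    0.0811         59.8547           40.1453     0.605
```

On this synthetic survey (9 sites, 23 species, default scenario) total
taxonomic dissimilarity (mean βsor = 0.51) is dominated by turnover (79%
of total β), phylogenetic dissimilarity is lower (0.20) — a positive beta
deviation of 0.61, i.e. sites swap phylogenetically close species — and the
hierarchical partition attributes more of the pairwise-dissimilarity
variance to river distance than to environmental distance:

```
                  environment  spatial  joint  full_r2  residual
taxonomic_sor           0.188    0.511  0.331    0.700     0.300
phylogenetic_sor        0.121    0.383  0.160    0.504     0.496
```

Per-site α-diversity from the same run (first rows of
`alpha_taxonomic.csv`):

```
       S    N  margalef  shannon  pielou  hellinger_div
S1    11  197     1.893    2.160   0.901          0.731
S2    12  296     1.933    2.218   0.893          0.704
```

The same workflow is scriptable from the shell:

```sh
fishdiv simulate --seed 42 --out inputs/       # write the four input files
fishdiv all --seed 42 --out results/demo       # alpha, beta, drivers, log
```

Each verb (`simulate`, `alpha`, `beta`, `drivers`, `all`) accepts
`--config` (YAML mirroring `RunConfig`), `--seed` and `--out`. Outputs are
plain CSV plus `run.log` recording the master seed, per-stage derived seeds
and library versions; a rerun with the same seed is byte-identical.

The dominance worked example ships with the package: the published
Dongfeng Reservoir composition table (23 species, printed OF/RA/RB
marginals) is bundled, and

```python
from fishdiv.datasets import reservoir_iri
reservoir_iri()["iri"].head(3)
```

reproduces the printed IRI column (e.g. *Lepomis cyanellus* 6006.0 vs
printed 6006.23 — the residual is rounding of the 2-dp printed inputs)
and classifies exactly five species as dominant.

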