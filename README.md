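# phylocascade

Partitioning microbial community turnover into assembly processes along
cascades of connected habitats.

When water flows through a chain of reservoirs, the bacteria in each
reservoir are shaped simultaneously by **local** environmental filtering
(selection), by **regional** exchange of organisms (dispersal — either
homogenizing the communities or, when restricted, letting them diverge),
and by pure demographic **drift**. `phylocascade` implements the two-stage
phylogenetic null-model framework that disentangles these processes from an
OTU table and a phylogeny, plus the ordination and permutation statistics
that usually accompany such an analysis. It is written for microbial
ecologists working with 16S rRNA OTU tables across structured sampling
designs (here: reservoirs × sampling events × seasons), and it ships a
synthetic-data generator so every stage can be exercised and validated
without sequence data.

## The method

For two communities A and B, the abundance-weighted beta mean nearest taxon
distance is

    βMNTD(A,B) = ½ [ Σ_{i∈A} f_i · min_{j∈B} d(i,j) + Σ_{j∈B} f_j · min_{i∈A} d(i,j) ]

with f the within-sample relative abundances and d the patristic distance
between tips of the phylogeny. Shuffling taxon identities across the tips
gives a null distribution, and

    βNTI = (βMNTD_obs − mean_null) / sd_null .

|βNTI| > 2 assigns the pair to **selection (S)**. Remaining pairs go through
an abundance-based Raup-Crick null that reassembles each community
preserving its richness (taxa drawn by occupancy) and total abundance
(individuals placed by metacommunity relative abundance); with
α the fraction of null Bray-Curtis values below the observed one (ties at
half weight), RC_bray = 2α − 1 ∈ [−1, 1]:

* RC_bray < −0.95 → **homogenizing dispersal (HD)**
* RC_bray > +0.95 → **dispersal limitation (DL)**
* otherwise → **drift (D)**

Labels for cascade-adjacent reservoir pairs are aggregated into
Local (= S) / Regional (= HD + DL) / Stochastic (= D) percentages per
season. See `docs/methods.md` for the full model description, parameter
table and calibration analysis.

## Worked example

Simulate a four-reservoir, six-event study and run the full analysis:

```bash
phylocascade simulate --seed 42 --out-dir demo/sim
cat > demo/run.cfg <<EOF
otu_table: demo/sim/otu_table.tsv
tree: demo/sim/tree.nwk
metadata: demo/sim/metadata.tsv
env_table: demo/sim/env.tsv
n_iter_bnti: 999
n_iter_rc: 999
seed: 42
EOF
phylocascade run-all --config demo/run.cfg --out-dir demo/out
```

`demo/out/table1.tsv` holds the per-pair process labels (rows are adjacent
reservoir pairs in cascade order, columns are sampling events):

```
pair     D1  D2  D3  R1  R2  R3
BB - Pr  DL  S   D   HD  HD  D
Pr - NA  S   S   S   HD  D   D
NA - TI  DL  D   S   HD  HD  HD
```

and `demo/out/summary.json` aggregates them:

```
dry:    local 56%   regional 22%   stochastic 22%   (9 pairs)
rainy:  local  0%   regional 67%   stochastic 33%   (9 pairs)
total:  local 28%   regional 44%   stochastic 28%   (18 pairs)
```

The generator builds dry-season communities under strong reservoir-specific
environmental filtering and rainy-season communities from a well-mixed
common pool, and the pipeline reads that back: selection dominates the dry
season, homogenizing dispersal the rainy season. `demo/out/stats.json`
carries the supporting statistics — here PERMANOVA finds reservoirs highly
distinct within the dry season (R² = 1.00, p = 0.001; NMDS stress 0.004)
but not within the rainy season (R² = 0.30, p = 0.38), and the PCA of the
environmental table puts 61.7% of the variance on the trophic-gradient axis
and 36.8% on the seasonal axis.

Every stage is also callable on its own (`rarefy`, `turnover`, `nulls`,
`classify`, `summarize`, `stats`) and from Python:

```python
import phylocascade as pc

ds = pc.generate_cascade_study(seed=42)
dist = pc.cophenetic_distances(ds.tree)
nti = pc.beta_nti(ds.table, dist, n_iter=999, seed=1)      # per-pair βNTI
rc  = pc.raup_crick_bray(ds.table, n_iter=999, seed=1)     # per-pair RC_bray
```

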