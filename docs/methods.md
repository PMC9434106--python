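# Methods

## The model

`phylocascade` partitions the turnover of microbial communities between pairs
of connected habitats into four assembly processes — selection (S),
homogenizing dispersal (HD), dispersal limitation (DL) and drift (D) — using
a two-stage phylogenetic null-model framework, and supplies the supporting
ordination and permutation statistics.

The framework rests on one ecological assumption: habitat preference is
phylogenetically conserved, so closely related taxa occupy similar niches.
Under that assumption the *phylogenetic* turnover between two communities
carries a signal of environmental filtering that taxonomic turnover alone
does not.

### Stage 1 — βMNTD and βNTI

For communities A and B with within-sample relative abundances *f* and
patristic (cophenetic) tip-to-tip distances *d* on a rooted phylogeny,

    βMNTD(A, B) = ½ [ Σ_{i∈A} f_i · min_{j∈B} d(i, j)
                    + Σ_{j∈B} f_j · min_{i∈A} d(i, j) ],

the abundance-weighted mean distance from each taxon to its nearest relative
in the opposite community. A taxon present in both communities matches
itself at distance zero, so βMNTD(A, A) = 0. The null model shuffles taxon
identities across the tips of the phylogeny (equivalently, permutes the rows
and columns of the patristic matrix) and recomputes βMNTD; by default one
permutation per iteration is shared by every sample pair, which keeps nulls
consistent across pairs and is much faster (a per-pair shuffle is available
behind a flag). The z-score

    βNTI = (βMNTD_obs − mean_null) / sd_null

flags selection when |βNTI| > 2: greater-than-null turnover (βNTI > 2)
indicates divergent filtering, less-than-null (βNTI < −2) homogeneous
filtering. Both are reported as S; the sign is retained for diagnostics. If
the null distribution has zero spread (e.g. both communities contain every
taxon, so every permutation yields βMNTD = 0), βNTI is undefined and the
pair is forwarded to stage 2 with a warning.

### Stage 2 — abundance-based Raup-Crick (RC_bray)

Pairs not attributed to selection are tested against a null that reassembles
each community while preserving its observed richness and total abundance.
Per iteration, each sample draws its observed number of taxa without
replacement with probability proportional to occupancy across the analyzed
table, seeds each drawn taxon with one individual, and distributes the
remaining individuals multinomially with probability proportional to
metacommunity relative abundance. With Bray-Curtis dissimilarity
BC = Σ|x−y| / Σ(x+y),

    α = [ #(BC_null < BC_obs) + ½·#(BC_null = BC_obs) ] / n_iter,
    RC_bray = 2α − 1  ∈  [−1, 1].

RC_bray < −0.95 → HD (pair more similar than chance), RC_bray > 0.95 → DL
(more dissimilar than chance), otherwise D. All threshold inequalities are
strict; boundary values fall to the less specific process. Bray-Curtis ties
use a 1e-12 tolerance to avoid floating-point false ties.

**The analyzed table defines the metacommunity.** Occupancy and abundance
weights come from all samples of the table handed to the RC stage — in the
pipeline, the season subset of the study. This matters: the null is only
informative when the table contains more than the focal pair.

### Cascade design and aggregation

Process labels are computed for directly connected (cascade-adjacent)
reservoir pairs within each sampling event — for a four-reservoir chain and
three events per season, 9 comparisons per season. Aggregation reports
Local = S, Regional = HD + DL and Stochastic = D percentages per season and
in total, with integer display values rounded half-away-from-zero; raw
fractions are retained.

### Supporting statistics

* **PERMANOVA** — one-factor partition of squared dissimilarities
  (pseudo-F), p = (1 + #{F_perm ≥ F_obs}) / (1 + n_perm), free label
  permutation, 999 permutations by default. βMNTD is not Euclidean, so the
  raw between-group component can be negative; reported R² is floored into
  [0, 1] (the permutation test itself uses the raw partition). The study
  design motivates two groupings: season over all samples, and reservoir
  within each season.
* **NMDS** — non-metric MDS minimizing Kruskal stress-1, 20 random restarts,
  convergence at stress improvement < 1e-6 or 500 iterations (SMACOF with
  isotonic regression, via scikit-learn). Run for groupings significant in
  PERMANOVA.
* **PCA** — on z-scored environmental variables (correlation structure).
  Sign convention: each component's largest-magnitude loading is positive.
  Constant variables are rejected by name.

## Tunable parameters

| Parameter | Default | Meaning |
|---|---|---|
| `n_iter` (βNTI, RC) | 999 | null iterations; the convention of this framework |
| `bnti_cut` | 2 | selection threshold on the z-like score |
| `rc_cut` | 0.95 | dispersal thresholds on RC_bray |
| rarefaction depth | min sample total | common depth for subsampling without replacement |
| `n_perm` (PERMANOVA) | 999 | label permutations |
| NMDS restarts | 20 | random initializations; best stress kept |

Randomness is governed by one master seed; per-sample (rarefaction) and
per-pair (RC) substreams are derived from stable CRC32 hashes of the ids, so
results do not depend on evaluation order and dropping a sample never
perturbs another sample's draws.

## The synthetic-data generator

The generator emulates the study layout this pipeline targets: four
reservoirs in a flow-connected chain with a decreasing trophic gradient,
sampled at three dry-season and three rainy-season events, one subcommunity
per sample. Its parts:

* **Phylogeny** — pure-birth (Yule) trees with exponential waiting times,
  unit birth rate, tips extended to the present (ultrametric, positive
  branch lengths).
* **Niche traits** — Brownian motion along branches
  (child = parent + N(0, σ²·length)), then standardized. This is the minimal
  mechanism producing the phylogenetically conserved habitat preference the
  framework assumes.
* **Assembly** — a community of J individuals is a multinomial draw with
  probability ∝ pool_i · exp(−(trait_i − env)²/(2σ²)); σ = ∞ disables the
  filter. Species-abundance pools are lognormal (log-sd 1.5, a typical
  microbial skew) except where noted.

Scenario constructions and their strong-effect defaults (n_taxa = 200,
J = 2000, filter width σ = 0.5, environmental offset Δ = 3 trait-sd units,
pool overlap 0.1):

* **selection** — a shared pool filtered at env = ±Δ/2 with width σ. The
  trait filter selects clades, so the pair's βMNTD exceeds the tip-shuffle
  null (expected βNTI > 2).
* **homogenizing dispersal** — two draws of J ≥ 10·n_taxa from one
  identical pool, embedded in eight context samples from independent pools
  (a heterogeneous landscape). Against that metacommunity the pair is far
  more similar than the RC null expects (RC → −1).
* **dispersal limitation** — mostly disjoint, phylogenetically random
  species pools (overlap 0.1). Bray-Curtis is near 1 while βNTI stays null
  (RC → +1).
* **drift** — independent moderate draws (4 individuals per pool taxon,
  J = 800 at defaults) from one *even* pool (lognormal log-sd 0.5), with
  eight same-pool context samples. Observed dissimilarity sits inside the
  null spread (|RC| < 0.95, |βNTI| ≤ 2).

Two drift choices deserve explanation because they are where the null
model's mechanics bite:

1. *Even pool.* Under a strongly skewed pool, finite same-pool draws each
   miss a random rare tail; the richness-resampling null scatters supports
   more than iid draws do, and any such pair looks more similar than chance
   (RC → −1) — a homogenizing-dispersal signature. With an even pool
   essentially every taxon occurs in every sample, the support channel is
   inactive, and the null's generative process matches the observed one.
2. *Moderate J.* The null seeds every drawn taxon with one individual
   before the multinomial fill, so null communities carry slightly less
   sampling noise than iid draws of the same total; as J grows this biases
   neutral RC positive. Measured medians over replicate neutral pairs place
   the balance near 4 individuals per taxon, which is where the drift draw
   size is fixed.

The cascade study assembles dry-season communities through strong
reservoir-specific filters along the gradient (true adjacent-pair process:
selection) and rainy-season communities as large draws from a well-mixed
common event pool (true process: homogenizing dispersal); an environmental
table (trophic state, residence time, temperature, DOC, total nitrogen) is
emitted alongside, with trophic state strictly monotone along the cascade
within every event.

### What the generator does not emulate

Sequencing artifacts (chimeras, read errors, compositional bias of
amplicon counts), temporal autocorrelation between events, partial overlap
of processes within one pair, and taxon-specific dispersal traits. Passing
recovery tests therefore show that the inference machinery identifies each
process *when it acts alone under its favorable regime* — they do not bound
its error on real sequence data, where βNTI/RC magnitudes depend on
phylogenetic signal strength and metacommunity breadth.

## Calibration results the test-suite recomputes

The `experiments` module re-measures, from scratch: the βNTI false-positive
rate on phylogeny-agnostic neutral pairs (≤ 10% at n_iter = 999, 100
replicates), the neutral RC_bray median (|median| < 0.3), RC_bray = −1 for
an identical pair inside a varied metacommunity, per-process recovery ≥ 80%
over 50 replicate pairs at n_iter = 999, 9 classified pairs per season for
the cascade study, and PERMANOVA type-I error of 5% ± 2% at α = 0.05 under
exchangeable nulls (1,000 simulations, 199 permutations each). Problem
sizes (50–100 replicates, 999 iterations, a 100-taxon cascade for the
integration check) were chosen to give stable estimates at desk scale.

## Numerical and degenerate-input choices

* Rarefaction uses multivariate hypergeometric draws (exact sampling
  without replacement); samples below depth are dropped with a warning,
  all-zero taxon columns removed.
* Weighted sampling without replacement in the RC null uses Gumbel-key
  (Efraimidis-Spirakis) top-k selection.
* βNTI uses the sample standard deviation (ddof = 1) of the null draws.
* Taxa present in the table but absent from the tree are an error by
  default; `--prune-to-tree` drops them with a logged count, because silent
  pruning hides upstream mistakes.
* Sample ids and reservoir codes are read verbatim ("NA" is a reservoir,
  never a missing value).
* A pair classified at the thresholds exactly (|βNTI| = 2, |RC| = 0.95)
  goes to the less specific process, as the strict inequalities dictate.

## Known limitations

* The HD/D distinction depends on metacommunity context: with a two-sample
  table the RC null is nearly degenerate and the labels are unreliable;
  supply the full season table (the pipeline does).
* Published percentage tables for this design (k/9 and k/18 cells) admit a
  single rounding rule only approximately; this package reports
  round-half-away-from-zero integers and keeps raw fractions.
* PERMANOVA assumes exchangeability under the null; with strong
  heteroscedasticity between groups the test confounds location and
  dispersion effects, as all distance-based PERMANOVAs do.
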