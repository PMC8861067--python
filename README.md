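# stopover

Analysis of migrant passerine composition at stopover islands: variance-based
beta diversity partitioned into spatial and temporal components, permutation
inference on composition, constrained ordination against island descriptors,
per-species count models with effort offsets, and phylogenetically corrected
wing-shape comparisons. Written for community ecologists working with
multi-site, multi-year ringing (banding) campaigns — or any island-year ×
species count design — who want these analyses as a tested, reproducible
Python pipeline rather than a patchwork of scripts.

## The statistics at its core

Counts of newly ringed birds are arranged as an island-year × species matrix
and chord-transformed, `y'_rj = y_rj / sqrt(Σ_j y_rj²)`, so each sample row
has unit norm and Euclidean distances equal chord distances. With `y_ijk` the
transformed abundance of species *j* on island *i* in year *k*, `ȳ_ij` its
island mean over years and `ȳ_j` its grand mean:

    SS_Total  = Σ_ijk (y_ijk − ȳ_j)²        BD_I,T = SS_Total / (N − 1)
    SS_I      = Σ_ij  (ȳ_ij − ȳ_j)²         BD_I   = SS_I / (n − 1)
    SS_Temp   = Σ_ijk (y_ijk − ȳ_ij)²       BD_T   = SS_Temp / (Y − n)
    SS_Temp,i = Σ_jk  (y_ijk − ȳ_ij)²       BD_Ti  = SS_Temp,i / (Y_i − 1)

where `N = Y` is the number of island-year samples, `n` the number of islands
and `Y_i` the years sampled on island *i*. `BD_I,T` lies in [0, 1] under the
chord transform. Local and species contributions are
`LCBD_r = SS_r / SS_Total` and `SCBD_j = SS_j / SS_Total`; each set sums
to 1. The exact decomposition
`SS_Total = SS_Temp + Σ_i Y_i Σ_j (ȳ_ij − ȳ_j)²` is verified on every run.

Around that core: PERMANOVA and a multivariate dispersion test with
small-sample bias adjustment (permutation p-values with the observed
statistic in the reference set), pairwise contrasts under
Benjamini–Hochberg FDR; redundancy analysis (RDA) with iterative VIF
screening, permutation forward selection, Ezekiel-adjusted R² and two-block
variance partitioning; per-species GLMs (Poisson, nbinom1, nbinom2) with log
effort offsets and AICc model selection; and PGLS with Pagel's λ estimated
by profile maximum likelihood, with a likelihood-ratio test against λ = 0.

Because raw multi-island ringing data are rarely public, a first-class
synthetic-data generator reproduces the statistical structure of such
campaigns — 9 islands on the real descriptor layout, 5–16 years each, 35
species spanning three orders of continental abundance, log-linear responses
to island area and distance-to-southern-land linked to wing pointedness —
so every stage is testable end to end with known truth.

## Worked example

```python
import stopover as st

cfg = st.SyntheticConfig(seed=42)
captures, effort, truth = st.simulate_ringing(cfg)
filtered, dropped = st.filter_species(captures)   # >=5 years OR >=5 islands
tm = st.chord_transform(st.pivot(filtered))
part = st.partition_beta(tm)
print(part.bd_total, part.bd_island, part.bd_temp)
```

Running `python examples/01_beta_partition.py` (this exact computation)
prints:

```
samples: 86 island-years, 9 islands
BD_total (I,T) = 0.1270   # total beta diversity, in [0,1]
BD_I           = 0.1407   # between-island component
BD_T           = 0.0014   # pooled temporal component
decomposition residual = -1.78e-15  (exact identity)
```

Total beta diversity ~0.13 means migrant composition is far from its
possible maximum of 1: the same widespread species dominate everywhere
(their continental abundance drives counts on all islands), yet the
between-island component shows each island still carries its own
composition signature. The near-zero temporal component reflects the
default generator's Poisson-only year-to-year noise (see
`docs/methods.md`). The other examples cover the published island-table
correlations, permutation tests, ordination and variance partitioning,
species response models against planted truth, and the wing-shape PGLS.

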