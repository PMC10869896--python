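# funcniche

Intraspecific functional-niche analysis for trait-based ecology.

`funcniche` quantifies how demographic groups *within* a species —
juveniles, males, and females of a lizard population, in the motivating
use case — partition a functional trait space, and which microhabitat
variables drive both their spatial distribution and their trait
variation. It bundles the complete workflow that this kind of study
runs, as a tested, scriptable Python package:

1. **Traits** — nine unitless eco-morphological traits from ten linear
   morphometrics (mm) and body mass (g): `Mass = log10(M+1)`,
   eye position `IO/HW`, mouth shape `MW/HW`, head size
   `(HW·HL·HH)^(1/3)`, relative fore-/hindlimb length `FLL/SVL`,
   `HLL/SVL`, limb ratio `FLL/HLL`, relative tail length `TAL/SVL`, and
   relative abdominal width `AMW/SVL`; all z-scored to mean 0, SD 1.
2. **Functional space** — PCA of the trait correlation matrix; axes
   with eigenvalues > 1 (Kaiser rule) span the functional space, and
   trait–axis Pearson correlations describe what each axis means.
3. **Niche metrics** — per group:
   * *FIde* (functional identity): mean position on each axis,
   * *FRic* (functional richness): convex-hull volume as % of the
     pooled hull,
   * *FOve* (functional overlap): Jaccard ratio of two hulls,
     `V(A∩B) / (V(A) + V(B) − V(A∩B))`, with the intersection computed
     exactly via pooled facet half-spaces, an LP Chebyshev interior
     point, and Qhull vertex enumeration.
   Sample-size bias is handled by subsampling every group to a common
   *n* (10,000 replicates by default) for percentile CIs; group
   position differences are tested by one-way PERMANOVA
   (pseudo-F on Euclidean distances, permutation p with the add-one
   convention).
4. **Habitat models** — Shapiro–Wilk normality screen, then pairwise
   Spearman/Pearson collinearity screening (|r| ≥ 0.9 collapses a pair);
   per-group counts over transects are modelled with log-link Poisson
   GLMs over **all predictor subsets**, ranked by AICc
   (`−2logL + 2k + 2k(k+1)/(n−k−1)`); a single best model is declared
   only when the runner-up trails by ΔAICc > 2, otherwise Akaike-weighted
   full model averaging with Burnham–Anderson unconditional SEs is
   reported; hierarchical partitioning (Chevan–Sutherland / Shapley)
   decomposes the full model's deviance explained into per-predictor
   independent contributions.
5. **Ordination** — a DCA axis-1 gradient-length gate (< 3 SD → linear
   response model) followed by RDA of standardized traits on
   standardized microhabitat variables, with a 999-permutation test and
   forward selection of the significant arrows.

A synthetic-data generator (`funcniche.synthetic`) emulates the study
design the analysis assumes — 40 juveniles / 30 males / 41 females over
11 transects, group trait centroids separated by a configurable number
of SD, an environment correlation structure with r = 0.958 between the
two temperature variables and r = −0.907 between the two ground-cover
variables, and Poisson counts driven by log-linear habitat preferences —
so the entire pipeline is testable without any field data.

## Worked example

Simulate a study and run the niche and ordination stages:

```bash
$ funcniche simulate --seed 11 --out-dir demo
wrote 111 individuals, 11 transects to demo

$ funcniche niche demo/individuals.csv --n-perm 999 --seed 11
FRic[juvenile] = 43.26%
FRic[male] = 33.06%
FRic[female] = 37.26%
FOve[female,juvenile] = 14.86%
FOve[female,male] = 27.10%
FOve[juvenile,male] = 28.51%
PERMANOVA pseudo-F = 11.372, p = 0.0010 (999 permutations)

$ funcniche ordinate demo/individuals.csv demo/transects.csv --seed 11
DCA axis-1 gradient length = 1.16 SD -> RDA
canonical axes explain 6.08% (first two) of trait variance
permutation test: F = 1.045, p = 0.3630
```

Reading the output: each group's convex hull fills 33–43% of the pooled
trait space; pairwise overlaps are modest (15–29%), and PERMANOVA
rejects equality of group centroids decisively (p = 0.001) — the three
groups occupy distinct functional positions, as the generator's 2-SD
centroid shift intends. The DCA gradient is well under 3 SD, so the
linear (RDA) model is appropriate; in this synthetic population traits
are driven by group membership rather than by transect environment, so
the trait–environment constraint is weak and non-significant.

The same stages are available as library calls (`compute_traits`,
`standardize`, `build_space`, `fric`, `fove`, `permanova`,
`all_subsets`, `model_average`, `hierarchical_partition`,
`dca_gradient_length`, `rda`, ...), and `funcniche pipeline` runs
everything in order, writing a JSON summary plus CSV tables.

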