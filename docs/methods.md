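# Methods

## The inferential model

The pipeline compares three species-level distance structures: a
morphological one (size-normalised worker characters, nest means), a
phylogenetic proxy (binary AFLP bands), and an ecological proxy (climatic
and soil variables per species–locality combination). All three are built
the same way: optional PCA reduction, Euclidean distances among entities,
then arithmetic means of within- and between-species pairwise distances
with self-comparisons excluded. Only the between-species (off-diagonal)
means enter the matrix tests; within-species means are reported as
diagnostics because a Mantel statistic has no diagonal.

**Mantel test.** The statistic is the Pearson correlation of the
vectorised strict upper triangles. The null distribution permutes one
matrix's rows and columns jointly. Monte-Carlo p-values use the add-one
estimator (1 + b)/(1 + m) — never zero, unbiased for the exceedance
probability, with the identity permutation's role played by the added
pseudo-count rather than forced into the sample. Whenever n! fits within
the permutation budget the test silently enumerates all permutations and
reports the exact fraction (`exhaustive=True`); with the 9–10 species
typical here, `--exhaustive` makes that affordable explicitly.

**Partial Mantel test.** First-order partial correlation
r_AB·C = (r_AB − r_AC·r_BC)/√((1 − r_AC²)(1 − r_BC²)) over upper
triangles, permuting the first matrix (A) and recomputing the full
statistic each time, so r_AB and r_AC vary under the null while r_BC is
fixed. Permuting the raw matrix (rather than residualising it first) is
the simpler of the two classic conventions; the residual-permutation
variant is a known alternative and is deliberately not implemented.
A control matrix collinear with a tested one (|r| = 1) makes the
statistic undefined and raises an error rather than returning ±∞.

**Tail convention.** Two-sided by default: a positive relation
(stasis / concerted evolution) and a negative one (convergence /
character displacement) are both live hypotheses, and r's sign is always
reported so direction is never lost. One-sided tails are configurable.

**Multiple testing.** The single-character family within each battery is
corrected by Holm's step-down procedure (adjusted
p_(i) = max running (m − i + 1)·p_(i), capped at 1); the all-character
test stands alone outside the family. Because Holm can be conservative,
each battery also reports the exact binomial probability of at least k of
n single characters reaching p ≤ 0.05 by chance, evaluated with rational
arithmetic (`fractions.Fraction`) so tail values of order 10⁻⁸ carry no
floating-point underflow. For n = 29, k = 3 this gives 0.175; for
n = 29, k = 11 the exact sum is ≈ 7.3 × 10⁻⁸ — note that a bound of
"< 10⁻⁸" sometimes quoted for this configuration is stricter than the
formula's exact value, which is what the implementation reports.

**Crypsis scores.** The score of a nest is the discriminant posterior of
its a-priori species: pooled within-species covariance (unbiased, n − k
denominator), posterior_s ∝ prior_s · exp(−½·Mahalanobis²(x, mean_s)).
Priors default to equal (configurable to proportional); scoring defaults
to resubstitution with leave-one-out refits available; a typicality
variant (χ² tail of the Mahalanobis distance to the own-species mean) is
available behind a flag but is not the default reading of an
"identification p-value". Scores are regressed by ordinary least squares
on |altitude| and |latitude| (absolute values so hemispheres do not
cancel; identity transform available), reporting signed r, slope,
intercept and the two-sided t-test p with n − 2 degrees of freedom.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `cumulative_variance_threshold` | 0.80 | smallest k components with cumulative explained variance ≥ threshold |
| `correlation_prune_threshold` | 0.8 | \|Pearson r\| at which one of a character pair is dropped (seeded draw; pairs processed alphabetically; a dropped character triggers no further drops) |
| `n_permutations` | 100 000 | Monte-Carlo permutations per test |
| `alpha` | 0.05 | level for Holm rejection and the k counts |
| `pca_scaling_*` | covariance (morphology, AFLP), correlation (ecology) | covariance when variables share a scale (dimensionless ratios, 0/1 bands), correlation for heterogeneous units |

PCA scaling is configurable per block because the historical analyses do
not record which convention their software used; the report's provenance
block echoes the choice. Sign/rotation indeterminacy of PCA cannot affect
any downstream number: Euclidean distances are rotation-invariant, which
the test suite verifies by comparing full-variance PCA distances with
plain Euclidean distances on centred data.

## The synthetic generator

No raw data of the motivating kind are publicly deposited, so the
generator is the package's test bed. It emulates:

* an ultrametric species tree (Kingman coalescent, depth normalised to 1
  so rates are per unit depth);
* latent shape ratios per character evolving on the tree — Brownian
  (`stasis_bm`), tree-mirrored via classical-MDS embedding of
  max(P) − P so trait distance anti-correlates with patristic distance
  (`convergence_mirror`), or tree-independent (`null_independent`) —
  with nest-level and worker-level Gaussian noise below;
* raw measurements re-assembled so the classic normalisation hazard is
  present: CS = (CL + CW)/2 per worker, hence CL/CS and CW/CS are exactly
  complementary, and SPST tracks MPSP closely — the two near-collinear
  pairs the pruning stage must find (two characters are emitted as small
  integer counts and analysed as numeric);
* AFLP bands as Brownian liabilities per locus clamped to [0.05, 0.95],
  drawn independently per individual;
* a 2-axis latent niche space (axis sd 1.0 and 0.5 — empirical niche
  ordinations are anisotropic) imaged affinely into the 28 ecological
  variables with per-variable offsets and scales mimicking mixed units;
  altitudes drawn per locality from species-specific ranges spanning
  lowland (~100 m) to alpine (~2000 m) profiles, with the spread set to a
  third of the distance to the nearer range limit so realised species
  means sit close to their targets;
* optional couplings: selected characters' species means shifted by
  `eco_coupling_strength × niche axis 1`, and among-nest sd inflated by
  `altitude_variance_slope` per km.

Default dimensions mirror a full study (10 species, ~460 nests, ~920
workers, 890 loci on ~270 individuals, ~1100 species–locality rows); the
replicated Monte-Carlo suites use the `_DESK` presets (6–8 nests per
species, 150 loci, 8 localities per species) so 200 replicates of the
full pipeline run in minutes.

The default drift rate is deliberately small (`bm_rate = 4e-4`, i.e.
between-species sd equal to the among-nest sd): that is what "cryptic"
means operationally, and it keeps nest-mean character correlations from
collapsing onto the handful of species means (which would create spurious
collinearity prunings). The strong-signal presets
(`scenario_stasis`/`scenario_convergence`, `bm_rate = 0.01`) override it
where a clearly detectable signal is the point.

What the generator does **not** emulate: spatial autocorrelation of
localities, gene flow or hybridisation between species, non-Gaussian
measurement error, missing data, and any real covariance structure among
morphometric characters beyond the two engineered collinear pairs.
Passing recovery tests therefore show the statistics detect the modelled
signals at the modelled noise levels — not that real data meet those
assumptions.

## A note on resubstitution optimism

During development the altitude-variance scenario exposed a genuine
pitfall: with few nests per species, resubstitution discriminant scores
*increase* with within-species variance, because each nest drags its own
species mean toward itself and the resulting (2/n)·|x − mean|² term in
the posterior log-odds grows with the very variance that should make the
nest harder to classify. At 8 nests per species this reverses the
expected negative altitude relation (measured r ≈ +0.39 resubstitution
vs −0.26 leave-one-out on identical data). The altitude-recovery suite
therefore scores with `lda_mode="leave_one_out"`; resubstitution remains
the package default for ordinary scoring because it is what the classic
statistics packages print, but users regressing scores on anything
correlated with group variance should prefer leave-one-out.

## Numerical choices and degenerate inputs

* Permutation comparisons use a 10⁻¹² tolerance so ties with the observed
  statistic count as exceedances (conservative).
* Distance matrices are validated for symmetry, zero diagonal and
  finiteness on construction, then symmetrised to machine precision.
* PCA component retention takes the smallest k whose cumulative fraction
  reaches the threshold minus 10⁻¹² (so an exact 80% boundary is
  included). Constant variables are dropped with a warning under
  correlation scaling; an all-constant block is an error — except an
  AFLP matrix with *no* band variation at all, which legitimately means
  "no information" and yields all-zero distances.
* Zero variance in a distance triangle (a constant character at species
  level) makes the Mantel statistic undefined and raises, rather than
  returning NaN.
* Holm adjusted p-values are computed with running maxima and capped at
  1; rejections always form a prefix of the rank order.
* Species with one entity get NaN within-species means and are flagged,
  never silently averaged.
* The discriminant stage refuses more characters than residual degrees of
  freedom (n − k < d) or a singular pooled covariance, with an error
  directing the user to prune or project first — the pipeline runs it on
  the pruned character set for exactly that reason.

## Limitations

* The Partial Mantel permutation scheme (raw-matrix permutation) is one
  of several conventions; p-values can differ slightly from
  residual-permutation implementations.
* Species-level Mantel tests with ~10 species rest on 45 distance pairs;
  power is intrinsically modest and the exhaustive option only reaches
  p ≥ 1/n!.
* The binomial exceedance treats the 29 single-character tests as
  independent Bernoulli trials, which characters on one body are not; it
  is a heuristic complement to Holm, not a calibrated test.
* Ecological distances assume one pooled PCA over all species–locality
  rows; per-species ordinations are out of scope.
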