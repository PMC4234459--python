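# Methods

## Fractionation

Isotopic enrichment of a wax compound relative to its source water is
computed in ratio space:

    eps = ((dD_wax + 1000) / (dD_source + 1000) - 1) * 1000   [permil]

All inputs and outputs are per mil vs VSMOW; the +1000 offset converts a
delta value to a (scaled) isotope ratio. The computation is exact — no
sub-per-mil rounding is applied before or after. Source water is the
measured xylem water when available; plants without usable xylem samples
(ferns and lycopods, whose green stems hold evaporatively enriched
water) fall back to the mean-annual-precipitation value carried in the
table (−57 ‰ by default), and each fallback is recorded in the output
metadata so the affected rows can be audited. Missing wax measurements
stay missing through every stage; nothing is imputed.

Lipid-abundance summaries follow the standard definitions: ACL is the
abundance-weighted mean carbon number of a homolog series, and R is the
total n-acid to total n-alkane mass ratio.

## Multi-compound integration (VAST scaling)

The seven compound ε series are strongly correlated across species but
carry systematic offsets between compound classes and chain lengths, so
raw averaging would mix those offsets into the biological signal. The
integration procedure is:

1. **Center** each compound column on its mean over observed species.
2. **Autoscale** (divide by the column sd) and **weight** each compound
   by its variable-stability weight: for compound c with lineage classes
   j = 1..n, w_c = (1/n) Σ_j |x̄_jc| / σ_jc, the mean over classes of the
   class-mean-to-class-sd ratio. Compounds that separate lineages
   consistently (large class means, small within-class scatter) are
   up-weighted. Because the columns are centered first, signed class
   means can cancel; we therefore take absolute class means by default
   (`vast_mode="abs_mean_over_sd"`), with the signed variant available
   for comparison. The mean/sd ratio is scale-invariant, so computing it
   before or after autoscaling is equivalent.
3. **Grand-normalize**: divide every cell by the mean absolute value of
   all non-missing cells (`grand_norm="mean_abs"`). Dividing by the raw
   mean of centered data would be division by ≈0, so the raw-mean and
   identity options exist only as explicit alternatives. With the
   default, results are invariant to whether the input ε is expressed in
   per mil or as a fraction.
4. **Integrate**: per plant, the unweighted mean of available scaled
   acid values and, separately, of available scaled alkane values. The
   two series (ε\*_acid, ε\*_alkane) are never merged: principal-component
   analysis of the compound matrix places acids and alkanes on opposite
   sides of the second component, indicating a class-specific factor
   that averaging across classes would fold into noise.

Each class must contribute at least two observations per compound and
nonzero within-class variance, otherwise scaling aborts with the class
and compound named. The per-compound means, sds, weights and the global
normalizer are all exported for audit. Inter-compound regressions use
pairwise-complete observations (mirroring uneven compound coverage in
real surveys), with pairs under three shared points flagged
not-estimable.

## Phylogenetic comparative models

Trees are rooted with non-negative branch lengths; polytomies and
zero-length branches are accepted as-is, and a Newick branch without a
length defaults to 1 (the all-ones, topology-only convention). Both
time-calibrated and unit-branch-length trees are plain inputs — the
package takes no stance on dating.

**Brownian motion.** Tip values are multivariate normal with mean z0·1
and covariance σ²C, where C_ij is the root-to-MRCA shared path length.
The GLS root state and ML rate have closed forms; k = 2. With only two
tips the fit is still exact but AICc (which needs n > k + 1) is reported
as undefined with a flag.

**Pagel's λ.** C_λ multiplies off-diagonal covariances by λ ∈ [0, 1].
λ̂ maximizes the profile BM likelihood by bounded 1-D optimization
(tolerance 1e-6, with the bounds 0 and 1 checked explicitly so boundary
optima are never missed). Significance uses tip-label permutation: the
observed likelihood improvement of λ̂ over λ = 0 is compared with the
same statistic on B permuted datasets, p = (1 + #{LR_perm ≥ LR_obs}) /
(B + 1). A χ²(1) likelihood-ratio p-value is reported alongside; it is
approximate at the λ = 0 boundary and serves only as a cross-check.

**Multi-regime OU (Hansen model).** A regime painting assigns every
branch an optimum index; clade specs paint the MRCA subtree including
the stem branch, with nested clades overriding their parents (applied
largest-first, so the spec order is irrelevant). Tip expectations are

    E[x_i] = e^{-alpha T_i} z0 + sum_r theta_r sum_{segments in r}
             (e^{-alpha (T_i - t_b)} - e^{-alpha (T_i - t_a)})

over the regime-r segments [t_a, t_b] of the root-to-tip path (rows of
the design sum to 1 by telescoping), and covariances use the general
non-ultrametric form

    V_ij = sigma2/(2 alpha) e^{-alpha(T_i + T_j - 2 t_a)}(1 - e^{-2 alpha t_a}).

At fixed α the optima solve GLS normal equations and σ² is profiled in
closed form; α is maximized over a 60-point log grid on
[1e-6, 100]/tree-height followed by bounded local refinement —
deterministic, no random restarts. A grid-boundary maximum is flagged.
By default the root state equals the root regime's optimum (the
convention of the standard multi-regime OU software), giving
k = 2 + #regimes (3/4/5 for one/two/three optima); `root_mode=
"estimated"` frees it at k = 3 + #regimes. A regime that lies on no
observed tip's root path is structurally non-identifiable and rejected;
α values at which a regime's exponential window underflows are simply
discarded as candidates. Model comparison uses
AICc = −2lnL + 2k + 2k(k+1)/(n−k−1) with n = the number of trait
entries actually used in the fit (recorded in the output, since surveys
rarely state it).

**Ancestral states.** Under the fitted BM model, internal-node values
are the GLS/ML estimates obtained by conditioning the joint
tip/ancestor normal on the observed tips; they are exported as a node
table and as a Newick with bracketed comment values for branch coloring
(branch color interpolates linearly between node values).

**Simulation.** BM and OU tip values are simulated by preorder
recursion with the exact branch transition distributions; `expm1` keeps
the OU branch variance accurate for small α·t.

## Synthetic studies

The generator emulates a common-garden survey: 100 tips on a Yule tree
(birth rate 1, ultrametric; expected height ≈ Σ_{k=2..n} 1/k ≈ 4.5),
a monocot clade (~30% of tips) with nested Poales (~20%) and BEP (~12%)
clades, and non-monocot tips split into grade-like blocks (lycopods,
ferns, gymnosperms, magnoliids, eudicots) in tree order. The latent
integrated trait evolves under a three-optimum OU with α = 2 (α × height
≈ 9, near-stationary), σ² = 200 (stationary within-regime sd ≈ 7) and
optima (16.31, −27.82, −56.44) in scaled units — paper-scale effect
sizes, so recovery tests run at realistic signal-to-noise. Each
compound reads the latent trait through its own affine channel
(slopes 0.85–1.10, intercepts −118 to −134 ‰, noise sd 8.5–10.5 ‰),
plus a per-species compound-class factor (sd 5 ‰, +u on acids, −u on
alkanes) that gives the acid/alkane split on the second principal
component. These defaults put pairwise compound R² mostly in the
0.6–0.95 band. Xylem water is N(−57, 3) ‰; ferns and lycopods get no
xylem value, exercising the fallback path. Leaf water is source + 15 ‰
evaporative enrichment, + 12 ‰ extra for graminoids. C4 (only on
non-BEP grass analogs) and CAM (a few eudicots) shift per-compound ε by
+20 and +10 ‰ respectively — fractionation smaller in absolute value,
as observed for these pathways. Wax δD is back-computed by inverting
the ε equation against the same source the pipeline will resolve, so at
zero noise the pipeline reproduces the generator's ε exactly (this
invertibility is asserted to 1e-9).

Growth forms other than graminoid are assigned independently of the
tree, so the growth-form ANOVA is significant only through the
graminoid ⊂ monocot confound — removing graminoids removes the effect
while the lineage effect persists, which is the study design the
package exists to interrogate.

One global seed expands into independent per-stage streams (tree,
structure, trait, compounds, water, missingness) via
`SeedSequence(seed, spawn_key=(stage,))`; each stage is reproducible in
isolation and the whole study is byte-deterministic under a fixed seed.

What the generator does **not** emulate: analytical chemistry error
structure (beyond Gaussian noise), within-species replication,
environmental gradients, non-stationary root effects, missing-data
mechanisms correlated with abundance, or real clade ages — so passing
tests demonstrate correctness of the estimators under the stated model,
not field performance.

## Group statistics

One-way fixed-effects ANOVA is computed from the sums-of-squares
decomposition (SS_total = SS_between + SS_within is asserted to 1e-9
relative); all-zero within-group variance reports F = ∞ with p = 0
flagged. The post hoc default is Tukey HSD on the studentized range
with the Tukey–Kramer unequal-n adjustment (groups of size 1 are
excluded); unadjusted and Bonferroni pairwise t-tests are available,
and unadjusted p-values are never larger than Tukey's. Pathway
contrasts report per-lineage mean differences vs C3 with seeded
2000-resample bootstrap percentile CIs; singleton cells report the
difference with the CI flagged undefined. Acid and alkane entries are
analyzed as separate response series by default, with pooling available
where a single per-plant test is wanted.

## Problem sizes and numerical tolerances

The test suite validates likelihoods against dense multivariate-normal
oracles on 100 random trees of ≤ 8 tips (1e-8), OU means/covariances
against numeric path integration (1e-9/1e-10), λ behavior over 20 seeds
at 100 tips with 200 permutations, and three-optimum recovery over 20
seeds at 150 tips — sizes chosen to give stable pass/fail behavior on a
single CPU in minutes. ANOVA calibration uses 1000 label permutations
(KS < 0.05 against uniform). The acceptance script runs the full
pipeline at the default 100-tip study size.

## Known limitations

- Single-trait models only; acid and alkane series are fitted
  separately, never jointly.
- The λ permutation test permutes tips globally; no stratified or
  phylogenetically constrained permutation is offered.
- OU fitting assumes the painting is known; no reversible-jump or
  painting search is provided.
- The χ²(1) λ likelihood-ratio p is boundary-biased (conservative
  mixture not applied); the permutation p is the primary inference.
- Grade-style lineage blocks in the generator are contiguous in tree
  order but not strict clades, matching how paraphyletic groups like
  "ferns" function as labels rather than clades.
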