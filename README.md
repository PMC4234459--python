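# waxphylo

Phylogenetic comparative analysis of hydrogen-isotope fractionation in
vascular-plant leaf waxes.

## The problem

Sedimentary leaf-wax δD is a workhorse proxy for past precipitation, but
the apparent fractionation between a plant's source water and its wax
lipids varies by tens of per mil across species. Is that variation
organized by *growth form* (tree, shrub, grass...), as older
compilations suggested, or by *evolutionary lineage*? The two are badly
confounded in nature — "graminoid" is a growth form that exists only
inside one monocot clade — so answering the question needs explicit
phylogenetic models, not just group means.

`waxphylo` implements the full analysis chain for a common-garden
survey of ~100 species spanning lycopods through grasses:

1. **Fractionation.** For each of seven wax compounds (n-C24/26/28/30
   alkanoic acids, n-C27/29/31 alkanes),
   ε = ((δD_wax + 1000)/(δD_source + 1000) − 1) × 1000 ‰, against
   measured xylem water, falling back to mean precipitation (−57 ‰) for
   plants whose green stems preclude xylem sampling.
2. **Integration.** The seven correlated-but-offset ε series are
   centered per compound, autoscaled, weighted by variable-stability
   (VAST) weights w_c = (1/n)Σ_j |x̄_j|/σ_j over lineage classes,
   divided by a global normalizer, and averaged within compound class,
   giving one integrated acid entry and one alkane entry (ε\*) per plant.
3. **Comparative models.** Pagel's λ (bounded ML plus tip-permutation
   test) measures phylogenetic signal in ε\*; Brownian motion and
   multi-optimum Ornstein–Uhlenbeck (Hansen) models — one optimum,
   monocots vs rest, and BEP grasses vs other monocots vs rest — are
   compared by AICc. Ancestral states under BM color the tree.
4. **Group statistics.** One-way ANOVA and Tukey HSD post hoc matrices
   across lineages, growth forms and C3/C4/CAM pathways, including the
   demonstration that the growth-form "effect" vanishes once graminoids
   are removed.

Because no real trait table or tree ships with the package, a
first-class synthetic generator (`waxphylo.synthetic`) produces complete
studies — Yule tree, nested monocot/BEP clades, a latent ε\* evolving
under a three-optimum OU process, per-compound affine read-outs, water
values and pathway offsets — with the full generating truth retained, so
every stage is testable end to end.

## Worked example

```python
import numpy as np
import waxphylo as wp
from waxphylo.comparative import single_regime_painting

ds = wp.simulate_study(wp.SyntheticConfig(n_tips=100, seed=1))
m = wp.build_fractionation_matrix(ds.samples)          # species x compound, permil
scaled = wp.scale_matrix(m, m.labels["lineage"])       # centered + VAST-scaled
entries = wp.integrate_entries(scaled)                 # eps* per plant
x = entries["eps_star_acid"]

sig = wp.fit_lambda(ds.tree, x, n_randomizations=200, seed=2)
print(f"lambda = {sig.lambda_hat:.3f}  p = {sig.p_value:.4f}")

mono = wp.RegimePainting(np.minimum(ds.painting.node_regime, 1), 0, 2)
fits = [wp.fit_brownian(ds.tree, x),
        wp.fit_ou(ds.tree, x, single_regime_painting(ds.tree)),
        wp.fit_ou(ds.tree, x, mono),
        wp.fit_ou(ds.tree, x, ds.painting)]
print(wp.compare_models(fits)[["model", "lnL", "k", "aicc", "delta_aicc"]]
      .round(2).to_string(index=False))
```

prints

```
lambda = 0.793  p = 0.0050
model     lnL  k   aicc  delta_aicc
  OU3  -59.69  5 130.02        0.00
  OU2  -87.15  4 182.72       52.70
  OU1 -109.90  3 226.04       96.02
   BM -118.67  2 241.46      111.43
```

The integrated acid entries carry strong phylogenetic signal
(λ ≈ 0.79, permutation p = 1/201), and the three-optimum OU model —
distinct optima for BEP grasses, other monocots, and everything else —
beats the two-optimum, single-optimum and Brownian alternatives by a
wide AICc margin, with fitted optima in the expected rank order
(θ̂ ≈ 0.72 > −0.93 > −2.52 in scaled units).

The same analysis runs from the shell:

```sh
waxphylo run-all --n-tips 100 --seed 1 --out report/
```

writing the fractionation matrix, ε\* tables, λ report, model-comparison
table, post hoc matrix, group summaries and an ancestral-state annotated
tree.

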