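# karstrad

**Diagnosing adaptive radiation on time-calibrated phylogenies.**

An adaptive radiation leaves three coupled signatures on a clade: a burst
of lineage accumulation, a burst of ecological (habitat) diversification,
and a burst of morphological disparification — ideally synchronous, and
often repeated independently in subclades that then converge on similar
adaptive peaks.  `karstrad` implements the full diagnostic battery for a
dated phylogeny (a chronogram, branch lengths in My) plus species-level
habitat, morphometric and coordinate tables:

* **Lineage accumulation** — LTT curves and the γ statistic with
  Monte-Carlo pure-birth nulls,

  γ = [ (n−2)⁻¹ Σᵢ₌₂ⁿ⁻¹ Σₖ₌₂ⁱ k·gₖ − T/2 ] / ( T·√(1/(12(n−2))) ),

  where gₖ is the time with k lineages and T = Σ k·gₖ; γ ≪ 0 flags an
  early burst with slowdown.
* **Diversification model selection** — ML fitting of birth–death models
  with diversity dependence, λ(N) = max(0, λ₀ − (λ₀−μ)N/K), and shifts in
  λ, μ, K at an estimated age t*, compared by Akaike weights
  wᵢ = exp(−Δᵢ/2)/Σⱼexp(−Δⱼ/2).
* **Ecological diversification** — Mk models on habitat categories,
  stochastic character maps, changes-through-time (CTT) curves tested
  against fitted-model nulls with the rank envelope test.
* **Morphological disparification** — phylogenetic size correction
  (PGLS residuals), disparity-through-time (DTT) curves against
  multivariate Brownian nulls, the MDI (integrated observed−null
  difference), node height tests, phylogenetic PCA, Ward morphotypes,
  and multivariate BM/EB/OU models with a fixed-time mode shift.
* **Convergence** — SURFACE-style stepwise Hansen (multi-peak OU) search
  with forward shift addition and backward peak merging.
* **Ancestral geography** — Brownian motion on sphere-embedded
  coordinates with exact conditional-Gaussian sampling and 95%
  centroid-trimmed credible regions.

A first-class synthetic-data module generates a study-dimensioned
reference bundle (377 tips, crown age 47 My, a speciation-rate shift at
15.7 My, six focal clades, partially missing habitat/trait data) so the
whole pipeline is testable without any external download.

## Worked example

```python
import karstrad as kr
from karstrad.diversification import DiversificationModel, compare_models, birth_death_model_family

bundle = kr.make_reference_dataset(seed=1)

g = kr.gamma_test(bundle.tree, n_null=1000, seed=2)
print(g.summary())

fits = [DiversificationModel(bundle.tree, s).fit() for s in birth_death_model_family(pure_birth=True)]
table = compare_models(fits)
print(table[["model", "AIC", "dAIC", "AICw", "t_shift"]].head(3).to_string(index=False))
```

prints (seeds as above):

```
gamma = -8.0466, one-sided p = 0.000999 (1000 pure-birth nulls, n = 377)
                                                model         AIC     dAIC     AICw  t_shift
                             shift in speciation rate 2208.682733 0.000000 0.584032    15.85
       shift in speciation rate and carrying capacity 2210.747725 2.064992 0.207984    15.85
shift in speciation, extinction and carrying capacity 2210.747725 2.064992 0.207984    15.85
```

The tree-wide γ of −8.05 (p ≈ 0.001) rejects constant rates in favour of
an early burst with slowdown, and among the birth–death family the
best-supported model (Akaike weight 0.58) places a speciation-rate shift
at 15.85 My — recovering the 15.7-My shift the generator planted.  The
same objects feed the rest of the battery, e.g.

```python
res = kr.dtt_test(bundle.tree, bundle.traits.dropna(), n_sims=500, seed=3)
print(res.summary())
```

```
DTT: 256 points, MDI=-0.0172 (p2=0.866, p>=0.555), rank envelope p-interval [0.0020, 0.0579]
```

— an overall MDI near zero (the early low-disparity phase cancels the
late burst in the integral) while the global rank envelope test still
flags the curve as unusual: exactly the situation the two statistics are
designed to disentangle.

A `karstrad` command-line interface wraps each stage (`karstrad gamma`,
`ddfit`, `ctt`, `dtt`, `traits`, `traitmodels`, `surface`, `geo`) and
`karstrad run --config cfg.yaml --out report/` drives the full pipeline,
including the per-clade battery, into tab-separated report tables.

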