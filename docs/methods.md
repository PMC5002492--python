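# Methods

## Compositional geometry

A specimen's tissue analysis is treated as a composition on the scale
κ = 1000 g kg⁻¹ dry mass. Analyzed nutrients (N, P, K, Ca, Mg, S in g kg⁻¹;
B in mg kg⁻¹, divided by 1000 at ingestion) are completed by a filling
value `Fv = κ − Σ analyzed`, which absorbs everything unanalyzed — C, H, O
and the micronutrients excluded from the design. No attempt is made to
subtract measured carbon from `Fv`; the filling value is defined relative
to the *analyzed* parts only. Output tables re-report boron in mg kg⁻¹.

Balances are ilr coordinates of a sequential binary partition (SBP). The
sign convention is `[denominator | numerator]` with the numerator group
positive: a coordinate grows when the numerator geometric mean grows. SBP
validation is order-free: rows may be printed fine-to-coarse (as published
balance tables usually are), and a table is accepted whenever the nonzero
sets of any two rows are disjoint or nested inside one side of the coarser
split (a laminar family). A table with D−1 rows satisfying that condition
is necessarily a full binary hierarchy, which is what completeness means
here; completeness is required for the inverse transform, compositional
means, Aitchison distances and the Monte-Carlo stage, because a partial
basis leaves the back-transform underdetermined.

The packaged default design uses seven balances over
(N, P, K, Ca, Mg, S, B, Fv). Six of them are the classic agronomic
contrasts (protein-synthesis vs energy `[P|N]`, cation competition
`[Mg|K]`, mobile pairs `[N,P|K,Mg]`, sulfur vs mobile macros
`[S|N,P,K,Mg]`, `[B|Ca]`, and nutrient accumulation vs dilution
`[Fv|nutrients]`); the seventh, `[Ca,B | N,P,K,Mg,S]`, contrasts the
relatively immobile nutrients with the mobile ones and completes the
hierarchy. The six-row variant is also accepted (forward transform only).

Numerical choices: closure enforces the sum invariant to the last ulp;
orthonormality is checked to 1e−10 and the ilr/inverse round trip to 1e−8
relative — double-precision tolerances, not statistical ones. The SBP
count D!·(D−1)!/2^(D−1) is computed in exact integer arithmetic.

## Budget balance sheets

Inputs: organic amendments contribute dose (Mg dry matter ha⁻¹) × content
(g kg⁻¹ dry); fresh-waste doses are dry-matter equivalents. The packaged
mineral standard supplies 229 kg N, 12.5 kg P, 71.4 kg K, 31.5 kg Ca and
19 kg S ha⁻¹ (no Mg, no micronutrients). Removals: fresh fruit yield ×
dry-matter fraction (default 0.11) × fruit concentration on a dry basis;
when several fruit analyses exist their centroid is the ilr mean
back-transformed (equivalently the closed geometric mean), not the
arithmetic mean of concentrations. Budgets are inputs − removals summed
over cycles; negative = deficit. Pruning-residue returns are not modelled —
they can be supplied as an extra input stream, but ash-fraction arithmetic
is out of scope.

The kg ha⁻¹ → mmol_c dm⁻³ conversion uses a soil volume of 10⁶ dm³ ha⁻¹
(one hectare mixed to 0.1 m); the depth convention is exposed as a
parameter since practice varies. Base saturation is
100·(K+Ca+Mg)/CEC with CEC the sum of cationic species including (H+Al).

## Diagnosis

Yields are discretized at a user-chosen cutoff (ties go to *high*). The
cutoff is deliberately a required parameter: any default would smuggle in
a local economic judgement. The synthetic workflow uses the dataset median.

The classifier is weighted knn on ilr coordinates with Minkowski exponent
`p` (default 4, with Euclidean `p = 2` in the default tuning grid),
`k = 10` neighbours by default, and one of three kernels: rectangular
(equal votes), triangular (1 − d/d₍ₖ₊₁₎), or "optimal" — Samworth-type
rank weights `wᵢ ∝ 1 + d/2 − d/(2k^{2/d})·(i^{1+2/d} − (i−1)^{1+2/d})`,
clipped at zero, with d the coordinate dimension. Neighbour search is
exact (scikit-learn `NearestNeighbors`); vote ties are broken by a class
order drawn once from the configured seed, making predictions fully
reproducible. Hyperparameters are tuned by stratified 10-fold
cross-validation over a small grid; ties prefer smaller `k`, then smaller
`p`. Whole-set prediction (used for the confusion partition) includes each
specimen among its own potential neighbours, so its accuracy is a
resubstitution figure; the cross-validated accuracy is the honest
generalization estimate and is the one used in recovery checks.

Undefined diagnostic ratios (zero denominators) are reported as NaN, never
as 0.

## Concentration ranges

Each balance of a group gets a two-sided Student-t interval
`mean ± t₍₁₋α/2, n−1₎·s/√n` (α = 0.05). The intervals define an
axis-aligned box in ilr space; 100 000 vectors are drawn with independent
uniform coordinates on that box, each is back-transformed and closed, and
per-nutrient extremes over the draws become the concentration range, with
the back-transformed interval means as the centroid. Sampling the box
rather than the joint confidence ellipsoid is a deliberate simplification:
the box is exactly what the per-balance interval summary defines. Draws
use common uniforms affinely mapped to the intervals, so nested boxes give
nested draws (monotone ranges) under a fixed seed. Because draw extremes
creep outward with `n_draws`, a quantile option (e.g. 0.5 %/99.5 %) is
provided; the default reports extremes. The centroid is clipped into the
range so containment holds exactly even under quantile trimming.

Critical values: where the TN and TP ranges of a nutrient are disjoint,
the default critical value is the midpoint of the gap between the facing
bounds; the facing TN bound itself is available via `rule="facing"`. No
rule is canonical in the literature, so both are exposed; overlap yields
`None`, a valid outcome.

## Synthetic orchard generator

The generator emulates a long-term factorial fertilization trial:
4 blocks × 7 treatments (dry-waste doses 0/9/18/27/36 Mg ha⁻¹ yr⁻¹, fresh
waste at 18 Mg dry-matter equivalent, and the mineral standard) over
5 years — 140 specimens. Defaults, chosen once as field-realistic values:

* **Yield**: Mitscherlich plateau `y = 60 − 20·exp(−dose/3)` Mg ha⁻¹, so
  the response is essentially saturated at the 9 Mg ha⁻¹ dose; the mineral
  treatment is assigned a 9 Mg dose-equivalent. Gaussian noise SD
  8 Mg ha⁻¹ — explicitly a tuning choice placing the default diagnosis in
  a realistic accuracy regime (neither trivial nor hopeless), not a
  measured value.
* **Foliar composition**: logistic-normal — multivariate normal in ilr
  space, diagonal covariance with per-balance SD 0.15, back-transformed to
  κ = 1000. The high-yield centroid sits at the midpoints of literature
  foliar sufficiency ranges for guava; the low-yield class is shifted by
  δ = −0.30 on `[P|N]` and +0.30 on `[S|N,P,K,Mg]` (excess P, deficient S
  relative to the mobile macros), echoing the nutrients for which TN/TP
  ranges typically separate.
* **Fruit composition**: fixed centroid (N 8, P 1.1, K 14, Ca 0.8, Mg 0.9,
  S 0.8 g kg⁻¹; B 10 mg kg⁻¹) with ilr noise SD 0.10. Fruit K of
  14 g kg⁻¹ keeps harvest K export ahead of waste K returns at every dose,
  reproducing the structural potassium deficit such balance sheets show.
* **Waste batches**: yearly draws around the packaged dry/fresh analysis
  means with their reported SDs, truncated positive.

What the generator does *not* emulate: climate-driven year effects and
their correlations with balances, spatial block effects, fruit–leaf
nutrient proportionality, soil-stock dynamics, and non-Gaussian ilr tails.
Passing recovery tests therefore shows the pipeline is correct and well
calibrated under its own distributional assumptions, not that real
orchards satisfy them.

`recover_parameters` runs the full pipeline (ilr → knn tuning → confusion
partition → TN ranges) on a generated dataset and scores it against the
stored truth: cross-validated class-recovery accuracy, estimated vs true
high-class centroids, and whether each nutrient's TN range contains the
true high-class centroid. Problem sizes in the shipped checks — 140
specimens per orchard, a 4-point tuning grid with 10 folds, 100 000 draws
per range, 100 replicates for coverage — keep a full recovery study in the
tens of seconds while leaving Monte-Carlo error well inside the asserted
margins.

## Known limitations

* Marginal (per-balance) intervals ignore balance correlations; the box
  overstates joint uncertainty in correlated directions.
* Draw-extreme ranges depend (slowly) on `n_draws`; use the quantile
  option for n-stable bounds.
* The knn "optimal" kernel uses rank-based Samworth weights; other
  implementations scale ranks by a bandwidth-inflated neighbour count and
  will differ slightly in small samples.
* Budget sheets track only measured streams: leaching, volatilization,
  mineralization kinetics and internal cycling are out of scope.
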