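# Methods

This note records the models implemented in `faunarange`, their
assumptions, the tunable parameters that matter, and the numerical and
design choices made where the underlying mapping protocol is silent.

## Periodization and inclusion rule

Three periods partition the record: Holocene (11,700 BP–AD 1900),
historical (AD 1900–2000) and modern (post-2000). Pre-modern evidence
is presence-only point localities; modern evidence is expert-drawn
range polygons. A species enters the comparative analysis only when it
is recorded from at least `min_sites` (default 10) *distinct* Holocene
sites — sites, not specimens: repeated finds at one site count once.
The threshold trades robustness of the reconstructed polygon against
discarding species; it is a config value, and the filter is monotone in
it (raising the threshold never adds species).

## Cumulative range reconstruction

Ranges are extents of occurrence built backwards in time, so by
construction modern ⊆ historical ⊆ Holocene and per-species areas can
only grow into the past. The assumption doing the work is that species
ranges did not undergo major natural expansions or shifts after early
Holocene climates stabilised, so an older record outside the younger
range marks *lost* range rather than a range shift.

For a locality point outside the baseline polygon, the two nearest
admissible features are found among (i) the other locality points of
the same species and layer that fall outside the baseline, (ii) the
nearest part of the baseline polygon (anchored at the closest boundary
point). When fewer than two such features exist, the study-region
border supplies the missing anchor at the foot of the perpendicular —
the border stands in for unobserved extralimital range, which is the
weakest assumption available when no out-of-region data exist. Ties
break deterministically: distance, then feature kind
(point < polygon < border), then feature id.

A straight-line connection bounds no area, so each connection pair is
realised as the **triangle** (point, anchor₁, anchor₂) — the
smallest-area polygon consistent with connecting the point to both
features, keeping reconstructions conservative. Degenerate (collinear)
triangles are replaced by the two segments buffered by ε, with
ε = `epsilon_fraction` (default 10⁻⁶) of the border's bounding-box
diagonal, so every retained connection contributes positive area.
All attachments are computed against the *original* baseline, not the
incrementally grown geometry; since the result is a union, the output
is independent of point order (asserted by test). The union is clipped
to the border and dissolved: interior rings are dropped, since a
polygon contained in a larger one carries no extra extent.

Species whose modern map has parts flagged as no-longer-occupied have
those parts removed from the modern layer and unioned into the
historical baseline before point attachment.

### Projection

All areas are measured in a Lambert cylindrical equal-area projection:
spherical earth R = 6371.0072 km, standard parallel 0°, central
meridian defaulting to the border's centroid longitude (105° E for a
China-like region). On the sphere the projection is exactly equal-area;
polygon areas measured in the plane deviate from the spherical
closed-form R²·Δλ·Δ(sin φ) only through chord-vs-arc discretisation of
polygon edges (tested < 0.5% for 1° cells). Geometry spanning the
antimeridian opposite the central meridian is rejected rather than
silently cut; move the central meridian instead.

### Loss accounting

Per species, p_lost(old → new) = (A_old − A_new)/A_old ∈ [0, 1]; a zero
Holocene area makes the fraction undefined and flags the species. The
two era responses used by the trait models put both losses on the
Holocene base — y_pre = (A_hol − A_hist)/A_hol and
y_post = (A_hist − A_mod)/A_hol — so they sum to the total Holocene
loss. Pooled percentages sum areas across species before dividing.

Displayed percent-remaining values are rounded to one decimal with an
endpoint convention: a species with any nonzero loss never displays
100%, and one with any nonzero remainder never displays 0% — values
that would round across those endpoints clamp to 99.9 / 0.1. This keeps
the printed figure faithful to whether loss occurred at all.

## Richness grids and per-cell loss

The grid (default 100 km cells) is anchored at the lower-left corner of
the projected border's bounding box; partial edge cells are kept and
cells that miss the border entirely are dropped — a deterministic
tiling. Presence in a cell is any positive-area overlap of the range
polygon (not a centroid rule): it is the least surprising reading and
is monotone under range nesting, so per-cell richness is non-increasing
through time. Per interval, p_cell = n_lost/n_old over the older
period's occupants, computed **only** for cells containing at least one
older-period locality record; in unsampled cells the absence of records
cannot be told from absence of species, and including them would bias
regional loss downward. The empirical logit
ln((p + a)/(1 − p + a)), a = 0.5/n, is provided for the linear-model
response mode.

## Trait models (PGLS)

The model is y = Xβ + ε with ε ~ N(0, σ²V(λ)); V(λ) multiplies the
off-diagonal entries of the Brownian covariance C (Cᵢⱼ = shared
root-to-MRCA branch length) by Pagel's λ ∈ [0, 1]. β is the GLS
estimator via Cholesky whitening; σ² is profiled by maximum likelihood;
λ is ML-profiled per model by default (a bounded scalar search with the
interval endpoints checked explicitly), or fixed by config. ML-λ per
model means log-likelihoods need not be monotone along nested formula
chains — adding a predictor can lower the ML log-likelihood when λ
moves — which is the observed behaviour of per-model-λ PGLS rankings.

Choices where the protocol is open, all config-exposed:

- body mass enters as log₁₀ kg (the fauna spans ~0.25–3300 kg);
- trophic level is an unordered 3-level categorical with herbivore as
  reference (a numeric coding exists for sensitivity); unused levels
  are dropped from the design, as for factors in R model matrices;
- the AICc parameter count k = coefficients + 1 (σ²) + 1 when λ is
  ML-estimated; the published convention for k in comparable tables is
  ambiguous, so the convention here is explicit and configurable;
- responses are fitted as untransformed proportions (a logit-response
  mode exists).

AICc = −2LL + 2k + 2k(k+1)/(n−k−1); models within 2 of the best are
"well supported", with the looser threshold of 6 reported alongside.
Standard errors use the unbiased σ̂² = RSS_w/(n−p) and t(n−p)
intervals; adjusted r² is computed against the intercept-only GLS fit
on the same V. Near-singular V (effectively duplicated tips) receives
an escalating relative diagonal jitter (10⁻¹² … 10⁻⁸) before
factorization; exact fits floor σ̂²_ML to keep the likelihood finite.

## Spatial models (binomial GLMs)

Each analysed cell contributes the count pair (n_lost, n_retained),
fitted with a logit-link binomial GLM (IRLS to 10⁻⁸, 100 iterations;
statsmodels backend). This weights cells by their older-period
richness, which is the point of the count-pair response; the
empirical-logit ordinary linear model is available as a sensitivity
mode. Predictors are z-standardized internally and coefficients
reported on both scales. Complete separation is detected and logged.
Goodness of fit is 1 − (residual deviance)/(null deviance), reported as
a proportion in [0, 1]. The ten a-priori formulas (a–j) encode
hypotheses about climatic (Rain/Temp/AET/PET), anthropogenic (HFI) and
physical (Elev) drivers, with the collinear pairs Temp–Rain and AET–PET
never reduced below one representative; a failing member is recorded
and the suite continues. HFI is a current-day composite applied to past
eras; no temporal correction is attempted.

## Synthetic study systems

The generator's defaults emulate the empirical setting: 34 species;
10–111 Holocene and 5–249 historical sites per species; log₁₀ masses
uniform on (−0.6, 3.5); a China-sized quadrangle (90–120° E, 20–45° N);
smooth Gaussian-random-field predictor surfaces with Temp–Rain and
AET–PET correlations of 0.8; a pure-birth phylogeny rescaled to unit
depth with terminal branches floored at 0.02 (a vanishing terminal
branch makes the Brownian covariance singular, which neither real
faunas nor GLS tolerate). Era contractions are inverse-logit linear in
centred log₁₀ mass and trophic level plus a λ-scaled Brownian deviate
(defaults: pre-1900 base rate ≈ 15%, mass slope 0.8, trophic slope
−0.5 so herbivores lose more; post-1900 weakly structured), and the
post-1900 loss is applied to the range remaining after 1900 so the two
era fractions cannot exceed 1. True ranges are discs in the equal-area
plane eroded about their centre to each era's area, so nesting holds by
construction; locality points are sampled uniformly inside the true era
range (an optional low-elevation accessibility bias is available, off
by default). Per-cell loss counts for GLM validation are drawn directly
from the logistic model with known coefficients (defaults: intercept
−1; Elev −0.8, HFI +0.9, Temp +0.5, AET +0.6, Rain −0.4, PET −0.5,
matching the directions reported for pre-1900 losses). All randomness
descends from one seed through fixed substreams.

What the generator does **not** emulate: taphonomic and dating error,
gazetteer/georeferencing noise, spatially autocorrelated sampling
effort, non-disc range shapes, and range shifts (as opposed to
contractions). Passing recovery tests therefore show that the
estimators are calibrated when their assumptions hold — not that those
assumptions hold for any particular empirical archive.

## Validation and problem sizes

- Geometry: attachment and union areas on ≤ 5-point cases against the
  shoelace formula and a 4 × 10⁵-sample Monte-Carlo rejection oracle
  (1% tolerance); projection against the spherical band closed form
  (0.5%); nesting asserted on every synthetic run.
- Statistics: identity-covariance PGLS equals OLS to 10⁻⁸; a 3-taxon
  GLS example verified by hand matrix algebra (intercept 0, slope
  0.625); AICc closed form; the saturated two-group binomial slope
  logit(0.8) − logit(0.2) = 2.7726.
- Calibration: 200 replicates each — PGLS 95% CI coverage of the trait
  effects on a 64-tip tree (≥ 90% required per coefficient), GLM
  estimates within 2 SE of the true logistic coefficients on 200-cell
  tables (≥ 90%), and elevation-only truth placing an
  elevation-containing model in the ΔAICc < 2 set (≥ 80%).
- End to end: a 30-species system at 30 Holocene sites per species is
  simulated, written to disk in the interchange formats, re-read and
  fully re-analysed; estimated Holocene–modern loss fractions must
  correlate with truth at Spearman ρ ≥ 0.8.

Reconstruction from finite presence-only samples is conservative: the
reconstructed polygon is contained in the true range (up to border
triangles), so absolute loss fractions are biased toward the modern
baseline while their ranking across species is preserved — hence the
rank-correlation criterion for the end-to-end check, and the shrinking
of the area deficit with sampling intensity asserted as a property.

## Known limitations

- Attachment triangles are one realisation of "connect to the two
  nearest features"; any areal realisation is a modelling choice, and
  absolute reconstructed areas inherit it.
- No spatial autocorrelation structure is fitted in the cell-level
  GLMs; neighbouring cells are treated as independent.
- Topographic exclusions (unsuitable-habitat masks) are consumed as
  user-supplied data; no algorithmic habitat rule is applied.
- Masses and trophic levels are point values; trait uncertainty is not
  propagated.
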