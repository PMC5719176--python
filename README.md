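# faunarange

Reconstruction and analysis of Holocene-to-modern geographic range
contraction across a regional mammal fauna, from presence-only
zooarchaeological and historical locality archives.

Modern conservation data describe faunas that have already passed
through an *extinction filter*: the species and landscapes most
vulnerable to human pressure were lost first, long before systematic
surveys began. Quantifying how much range each species has lost since
the early Holocene — and whether the correlates of that loss have
changed through time — requires stitching together three very different
evidence layers: expert-drawn current-day range polygons,
twentieth-century locality records, and Holocene archaeological /
palaeontological site records. `faunarange` implements that whole chain
as a tested, reproducible pipeline, for anyone analysing long-term
range dynamics from sparse presence-only archives (the worked setting
is the mammal fauna of China across three periods: Holocene
11,700 BP–AD 1900, historical AD 1900–2000, modern post-2000).

## What it computes

**Cumulative extent-of-occurrence reconstruction.** Each species'
modern polygon is the baseline for its historical range; the completed
historical range is the baseline for its Holocene range. An older
locality point outside the baseline is connected to its two nearest
admissible features (other outside points, the nearest baseline
polygon, or — when fewer than two such features exist — the study-region
border at the foot of the perpendicular), and each connection is
realised as the triangle spanned by the point and its anchors. Unioning
baseline and triangles, dissolving contained polygons, and clipping to
the border gives the period range. Areas are measured in a Lambert
cylindrical equal-area projection (spherical earth, R = 6371.0072 km),
so ranges are exactly nested and per-species loss fractions

p_lost = (A_old − A_new) / A_old

are well defined for the Holocene–historical, historical–modern and
Holocene–modern intervals.

**Gridded regional loss.** A 100 × 100 km equal-area grid over the
region yields per-period species richness and, per cell, the proportion
of the older period's occupants no longer present — computed only for
cells that actually contain an older-period record, so non-sampling is
never mistaken for absence.

**Trait selectivity (PGLS).** Per-species loss fractions are regressed
on log₁₀ body mass and trophic level (herbivore / omnivore / carnivore)
under phylogenetic generalized least squares, y = Xβ + ε with
ε ~ N(0, σ²V(λ)), V(λ) the Pagel's-λ-scaled Brownian covariance of the
phylogeny. The four candidate models {mass}, {mass + trophic},
{mass + trophic + interaction}, {trophic} are ranked by AICc with the
ΔAICc < 2 support rule (ΔAICc < 6 reported alongside).

**Spatial selectivity (binomial GLMs).** Per-cell loss counts
(n_lost, n_retained) are fitted with logit-link binomial GLMs against
six environmental surfaces — elevation, Human Footprint Index, annual
precipitation, annual temperature, AET and PET — over ten a-priori
predictor combinations (models a–j), ranked by AICc and scored by the
proportion of null deviance explained.

**Synthetic study systems.** A generator simulates the full input set
(border, correlated predictor surfaces, birth–death phylogeny,
trait-driven nested range histories, presence-only locality sampling)
with every ground-truth quantity recorded, so the estimators can be
validated by parameter recovery.

## Worked example

```python
>>> import faunarange as fr
>>> fauna = fr.load_china_mammal_ranges()   # 34 species x 3 period areas (km^2)
>>> fr.proportion_lost(fauna.loc["Ailuropoda melanoleuca", "area_hol_km2"],
...                    fauna.loc["Ailuropoda melanoleuca", "area_mod_km2"])
0.9782807013229489
>>> s = fr.aggregate_summary(fauna)
>>> round(s.pct_total_lost, 1), round(s.pct_lost_pre1900, 1), round(s.pct_lost_post1900, 1)
(22.8, 15.0, 7.8)
>>> round(s.pct_species_lost_lt50, 1)
73.5
```

The giant panda retains 2.2% of its Holocene range; pooled over the
34-species fauna, 22.8% of combined Holocene range has been lost
(15.0% before AD 1900, 7.8% after), yet 73.5% of species still hold
more than half of their Holocene range.

A complete synthetic run from the shell:

```sh
faunarange simulate --seed 1 --outdir data/
faunarange all --config config.yaml --outdir out/
```

which writes the per-species areas table, per-cell loss tables, the
PGLS and GLM model rankings for both eras, and a run manifest with
input/output checksums (reruns are byte-identical).

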