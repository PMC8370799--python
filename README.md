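# seepbef

Biodiversity–ecosystem functioning (BEF) analysis for benthic macrofaunal
communities along a chemosynthetic resource gradient — from raw abundance
tables to habitat-stratified additive models and relationship-shape calls.

## The problem

Methane seeps are deep-sea trophic hotspots: chemosynthetic production
supports dense, dominance-skewed macrofaunal communities in "active" seep
sediment, grading through a transitional "chemotone" into photosynthetically
fuelled background sediment. Whether more biodiverse communities deliver
more ecosystem functioning — and whether that relationship changes shape
along the resource gradient — is a question for community ecologists and
deep-sea conservation planners. This package implements the full analysis
chain for push-core survey designs of that kind (tens of samples, two
pooled cores per sample, three habitat categories) and pairs it with a
synthetic community generator whose ground-truth BEF relationship is known,
so that the inference machinery can be power-tested and calibrated.

## What it computes

**Functioning proxies** (per sample): faunal density and wet standing stock
per m² of seafloor; community bioturbation potential

> BP<sub>c</sub> = Σᵢ (Bᵢ/Aᵢ) · Aᵢ · Mᵢ · Rᵢ

over families *i* with abundance *Aᵢ*, mobility *Mᵢ* and sediment-reworking
*Rᵢ* scores, with *Bᵢ/Aᵢ* replaced by the sample-wide mean individual
biomass (a `sqrt` variant of the index is also provided); and an
abundance-weighted calcification degree Σ score<sub>f</sub> · A<sub>f</sub>.

**Biodiversity** (per sample): richness, Shannon *H* = −Σ pᵢ ln pᵢ and
Pielou *J* = *H*/ln *S*, computed on the species matrix and on the
trait-weighted matrix (32 functional traits in 7 groupings, scored 0–5 per
family and multiplied by abundance).

**Environment**: IDW/nearest interpolation of point measurements onto the
bathymetry grid; annual NPP; depth-attenuated export flux
NPP·(prd·e^(−z/rld) + prr); slope (Horn), terrain ruggedness (Wilson TRI)
and topographic position (TPI) from the ESRI-ASCII bathymetry raster.

**Inference**: variables are z-scored, missing values 0-imputed, reduced by
per-grouping PCA (functioning 2 PCs, taxonomic and trait biodiversity 2
each, oceanographic 2, terrain 1, TPI raw), then modelled as

> g(E[functioning PC]) = factor(habitat) + s(BiodivPC1, by habitat)
> + s(BiodivPC2, by habitat) + s(OceanPC1) + s(OceanPC2) + s(TerrainPC1) + s(TPI)

with penalized cubic regression splines, GCV-selected smoothing, AIC-based
family/link and knot selection, and backward stepwise term removal. Each
habitat's fitted biodiversity smooth is classified as *null*, *monotone*,
*unimodal* (with the interior peak located) or *complex* from its
derivative and pointwise intervals.

## Worked example

```bash
python examples/04_fit_bef_gam.py
```

```
variance captured by functioning PC1+PC2: 99.0%

retained terms (adjusted R^2 = 0.86):
                                term    edf       F      p
s(taxonomic_biodiversity_PC1):active 2.2790 12.2523 0.0000
s(taxonomic_biodiversity_PC2):active 2.9222 14.5493 0.0000
                s(oceanographic_PC1) 1.0000  1.8518 0.1601

per-habitat BEF shape calls (taxonomic biodiversity PC1):
      active: unimodal, peak at PC1 = -2.17
  background: null
  transition: null

(ground truth was active: unimodal, transition/background: null)
```

The four functioning proxies co-vary strongly, so their first two principal
components carry ~99% of the variance; after backward selection only the
active-habitat biodiversity smooths survive (edf ≈ 2–3: curved, not linear),
and the shape classifier recovers exactly the generating pattern — a
functioning peak at intermediate biodiversity in the seep habitat, no
relationship elsewhere. Other examples cover dataset simulation (`01`),
the index arithmetic on a tiny community (`02`), terrain/export-flux
derivations (`03`) and the file-based pipeline with its reproducibility
manifest (`05`).

The same workflow is scriptable from a shell:

```bash
seepbef simulate -o data_dir --seed 42
seepbef validate data_dir
seepbef run -i data_dir -o out_dir
```

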