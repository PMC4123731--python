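# photomat

Photosynthetic parameter imaging and structure–function analysis of
cyanobacterial mat cross-sections.

Cyanobacterial mats are compact, vertically stratified microbial
ecosystems whose photosynthetic activity is concentrated in a thin,
chlorophyll-rich top layer. Variable chlorophyll fluorescence (PAM)
imaging of a vertical section resolves the photophysiology of that layer
at sub-millimeter scale; reflectance imaging adds a chlorophyll-a proxy;
and community fingerprinting (ARISA) characterises who lives there. This
package implements the complete computational chain from those raw
measurements to maps of photosynthetic parameters, multi-scale spatial
variability statistics, and a permutation test of the concordance between
community composition and photosynthetic function. Because such imaging
surveys rarely deposit raw image stacks, the package ships a first-class
forward simulator with known ground truth, so every estimator is
validated by recovery.

## The model

For each pixel, a rapid light curve (RLC) records the effective PSII
quantum yield Y = (Fm′ − F′)/Fm′ at an increasing actinic irradiance
ladder I, plus the dark-adapted yield Y₀ = (Fm − Fo)/Fm. In
cyanobacterial mats Y(I) is non-monotone: it rises from Y₀ to a maximum
Y_max at a small irradiance I_max before decaying. The
photosynthesis–irradiance model is a Webb-type exponential saturation
minus an irradiance-weighted suppression term,

    P(I) = P_max [1 − exp(−I/I_k)] − (δY/α) · I · exp(−I/I_m),

which, with Y = αP/I and I_m ≪ I_k, gives the yield–irradiance form

    Y(I) ≈ Y_m (I_k/I) [1 − exp(−I/I_k)] − δY exp(−I/I_max),

with Y_m = Y_max/(1 − I_max/I_k) and δY = Y_m − Y₀. Estimation pins Y₀,
Y_max and I_max directly from the measured curve, then fits the single
remaining parameter — the light-acclimation irradiance I_k — by bounded
1-D least squares over the curve points beyond I_max. Chlorophyll-a
absorptivity is the band ratio A_chl = (R_nir − R_r)/R_nir (two-band) or
(R₇₅₀ − R₆₇₅)/R₇₅₀ (hyperspectral). Downstream, the package computes
within-mat / within-site / global variability, a two-factor
(depth × horizontal) variance decomposition, site ANOVA with Tukey rank
groups, Bray–Curtis + NMDS + ANOSIM on Hellinger-transformed consensus
ARISA profiles, and symmetric Procrustes concordance between the
community and physiology ordinations.

## Worked example

Simulate a small two-site study, fit every pixel, and test the
structure–function link:

```python
from photomat import SimConfig
from photomat.pipeline import run_study

cfg = SimConfig(shape=(20, 20), layer_rows=16, mats_per_site=4)
res = run_study(cfg, seed=0)
print(f"ANOSIM R = {res.anosim_community.r:.3f} (p = {res.anosim_community.p})")
print(f"Procrustes r = {res.procrustes.r:.2f} (p = {res.procrustes.p})")
print(f"NMDS stress = {res.nmds.stress:.3f}")
print(f"ubiquitous OTUs: {res.shared_otus['ubiquitous_pct']:.1f}%")
```

prints

```
ANOSIM R = 0.996 (p = 0.001)
Procrustes r = 0.70 (p = 0.001)
NMDS stress = 0.000
ubiquitous OTUs: 25.7%
```

i.e. the communities cluster by site (ANOSIM R near 1, permutation
p = 0.001), the community ordination and the physiology ordination agree
far better than chance (Procrustes r = 0.70, p = 0.001), the 2-D NMDS
embedding preserves the dissimilarity rank order essentially perfectly
(stress ≈ 0 for these four tight clusters), and about a quarter of the
OTUs occur at every site.

The numbered scripts under `analysis/` run the same chain at full survey
scale (4 sites, 25 mats, 48 × 48 cross-sections) and write their tables
under `results/`:

```bash
python analysis/01_simulate_study.py      # truth fields + PAM stacks
python analysis/02_fit_parameter_maps.py  # per-pixel RLC fits
python analysis/03_absorptivity_maps.py   # two-band vs hyperspectral A_chl
python analysis/04_spatial_variability.py # three scales + ANOVA
python analysis/05_community_fingerprints.py
python analysis/06_structure_function_link.py
```

A `photomat` command-line interface wraps the same steps
(`photomat simulate|fit|absorptivity|spatialstats|community|run`).

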