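# Methods

This note documents the models, estimators, simulator and design choices
behind `photomat`, and what the passing tests do and do not establish.

## Yield–irradiance model and the pin-and-fit estimator

The package models the rate of photosynthesis against actinic irradiance
as a Webb-type exponential saturation minus an irradiance-weighted
suppression term,

    P(I) = P_max [1 − exp(−I/I_k)] − (δY/α) · I · exp(−I/I_m),

and works throughout with the derived yield–irradiance form (valid when
I_m ≪ I_k)

    Y(I) = Y_m (I_k/I) [1 − exp(−I/I_k)] − δY exp(−I/I_max),

with Y_m = Y_max/(1 − I_max/I_k), δY = Y_m − Y₀, and Y(I→0⁺) = Y₀ by
construction. α and P_max are carried for forward simulation only and
never fitted (only yield ratios are measured). The saturation factor is
computed with `expm1`: the naive `1 − exp(−I/I_k)` loses ~5 significant
digits as I → 0 and visibly violates the dark-limit identity.

Estimation per pixel:

1. Y₀ from the dark pair, Y from each (F′, Fm′) pair. Pixels whose Fm
   falls below a noise floor (default 5% of the image's 99th-percentile
   Fm) are masked from everything downstream; the floor guards the ratio
   against division blow-ups and mimics the restriction of all statistics
   to the cyanobacterial layer.
2. (Y_max, I_max) pinned as the maximum of the measured curve, dark point
   included, ties broken toward the smaller irradiance. A monotone
   decreasing ("plant-like") curve therefore pins (Y₀, 0); the I_max = 0
   suppression exponent is defined by its limit (0 for I > 0), making
   that case a continuous special case.
3. I_k by bounded Brent search on (1.01·max(I_max, first light step),
   5000] µmol photons m⁻² s⁻¹ with absolute tolerance 10⁻³, minimising
   the sum of squared yield residuals over the curve points strictly
   beyond I_max (points at or below I_max serve only for pinning). Y_m
   and δY are re-derived from the trial I_k at every step, so the search
   is genuinely one-dimensional. A fit is flagged invalid when fewer than
   3 points lie beyond I_max, the pinned maximum is non-positive, or the
   minimiser lands on a search bound; invalid pixels carry NaN and are
   excluded from statistics. Least squares is used as the residual
   criterion; the measured curve is not smoothed before pinning (an
   optional 3-point median filter exists behind a flag, default off).

## Irradiance ladder

Instruments vary, so the ladder is always explicit configuration. The
default is a dark step plus 12 light steps, 1 → 1700 µmol photons
m⁻² s⁻¹, roughly geometric with a dense low end (1, 2, 5, 10, 21, 44,
90, 186, 383, 788, 1300, 1700): small I_max values (a few µmol m⁻² s⁻¹)
are only identifiable if the ladder samples that range.

## Absorptivity

A_chl = (R_nir − R_r)/R_nir from the two-band camera, or
(R₇₅₀ − R₆₇₅)/R₇₅₀ from a hyperspectral cube after a single
multiplicative per-band normalisation against a gray reference standard
scan scaled to its nominal reflectance (40% by default). Band selection
is nearest-sampled-wavelength, recorded in the result; no interpolation.
Spectral QC requires a rising chlorophyll-a edge (mean slope over
700–720 nm > 0.002 reflectance units/nm) and a flat plateau (CV over
720–780 nm < 5%); both thresholds were calibrated on simulated spectra
and are configurable. Being ratios, both estimators are invariant to a
positive rescaling of the spectrum.

## Spatial statistics

Within-mat variability of a parameter image is reported three ways: SD
over all layer pixels (total), SD of the mean vertical profile, and SD of
the mean horizontal profile; the CV is total SD over the layer mean.
Within-site variability is the SD of the mat-level layer means per site
(undefined and flagged for single-mat sites); global variability is the
SD of the site means. All SDs use n − 1.

The two-factor variance decomposition treats depth (row) and horizontal
position (column) as crossed factors with one observation per cell, so
the interaction is the residual: SS_int = SS_total − SS_row − SS_col.
Because the irregular layer boundary would unbalance the factors, the
default operates on the largest full rectangle inscribed in the mask
(balanced design; exact SS bookkeeping), with a count-weighted
marginal-means variant behind a flag whose residual interaction can go
negative. Raw row/column indices are used as factor levels, without
binning.

Site differences of the layer means are tested by one-way ANOVA after a
Shapiro–Wilk normality check of the pooled residuals (reported, not
enforced), with Tukey HSD pairwise comparisons at α = 0.05 compacted into
bracket rank labels ([1] > [2]; [1-2] overlaps both). Rank clusters are
the maximal cliques of the not-significantly-different graph. Parameters
with strongly right-skewed mat means (I_max) are log-transformed before
testing; reported means and SDs stay on the original scale.

## Community fingerprints

Fragment profiles are binned into fixed consecutive 2-bp windows anchored
at 100 bp (anonymous OTU bins; the window is a config knob), relative
abundances taken per replicate, and PCR triplicates merged by a k-of-n
presence rule: a bin is kept iff nonzero in ≥ 2 of 3 replicates, with the
consensus abundance the mean of the nonzero replicates. The consensus
table is Hellinger-transformed (rows then have unit Euclidean norm) and
compared by Bray–Curtis. NMDS (SMACOF with isotonic regression, Kruskal
stress-1, best of 16 random starts by default) ordinates the matrix;
ANOSIM tests site structure with Clarke's R = (r̄_B − r̄_W)/(M/2),
M = n(n−1)/2 — the denominator that makes complete separation give
R = 1 — with seeded label permutations and the (1 + x)/(1 + N) p-value
convention (an exact enumeration mode covers all distinct relabelings for
small designs). The physiology side is classical metric MDS of
z-standardised (A_chl, Y_max, I_k, I_max) means — the parameters carry
incompatible units — and the two ordinations are compared by symmetric
Procrustes (both configurations centred and scaled to unit norm,
m₁₂² = 1 − (Σ singular values)², r = √(1 − m₁₂²), reflections allowed by
default) with a row-permutation Monte-Carlo test, 1000 permutations by
default.

## The simulator

The generator emulates a four-site mat survey. Defaults follow the
survey's structure: 13 + 8 + 2 + 2 mats across sites AD, AU, BR and SP,
with site-level mean parameters (e.g. Y_max 0.13–0.28, I_k 32–88
µmol m⁻² s⁻¹) and mat-level lognormal scatter at the within-site CVs.
Depth structure per mat: exponential decay for Y_max and I_k; A_chl a
decaying baseline plus a Gaussian subsurface bump; I_max a decaying,
patchy field. Horizontal structure multiplies the vertical profile by
(1 + a·g(x) + b·G(z, x)) with g a smoothed 1-D noise (column effect) and
G a smoothed 2-D noise with row/column means removed (pure interaction);
a is calibrated so the SD of the mean horizontal profile is half the SD
of the mean vertical profile — the 2:1 anisotropy the analysis should
recover — and G feeds the interaction variance without disturbing that
calibration.

Self-consistency of the forward map is deliberate: the pinning relation
Y_m = Y_max/(1 − I_max/I_k) is an approximation, so for arbitrary
(Y₀, Y_max, I_max, I_k) the simulated curve's sampled maximum is neither
at I_max nor equal to Y_max, and zero-noise recovery would be ill-posed.
The generator therefore (a) snaps truth I_max to the irradiance ladder —
consistent with I_max's operational definition as the measured irradiance
of the curve maximum; (b) caps I_max at 0.25·I_k, the model's own
I_m ≪ I_k operating regime; and (c) derives the dark yield Y₀ from
(Y_max, I_max, I_k) so that the curve passes through (I_max, Y_max)
exactly. Y₀ is therefore a derived truth field rather than an independent
profile. At zero noise the pin-and-fit estimator then recovers I_k to the
optimiser tolerance (~10⁻⁴ % in practice); at the default 2%
multiplicative yield noise the 32 × 32 map relative RMSE is ~12%.

Fm′ is kept equal to Fm (no quenching model): the yield is the only
quantity consumed downstream, so F′ = Fm′(1 − Y) defines the image pair.
Multiplicative Gaussian noise is applied to yields and mapped back to F′.
Reflectance: R_nir is a flat plateau (0.4), R_r = R_nir(1 − A_chl); the
hyperspectral cube has an absorption weight of 1 at 675 nm, a linear
700–720 nm edge and a flat plateau above 720 nm, multiplied by a smooth
lamp spectrum so that the reference-standard normalisation is exercised;
the noiseless band ratio returns A_chl exactly.

Communities: a pool of distinct integer fragment lengths (100–1000 bp,
400 OTUs by default) splits into a fraction shared by all sites (0.21)
and site-specific remainders; in linked mode, environmentally similar
site pairs (paired by their physiological Y_max level: AD–SP and AU–BR
under the survey defaults) additionally share 40% of their non-global
pools, which is what gives the community ordination a between-site
geometry that matches the physiology ordination — without it the site
pools are exchangeable, the four community clusters sit on a regular
simplex, and Procrustes concordance is weak even though ANOSIM is
maximal. Each mat carries a random 80% subset of its site pool with
lognormal abundances; each PCR replicate detects a mat OTU with
probability 0.9 and jitters its measured length by ±1 bp with probability
0.3. In unlinked mode the sites share one physiology level and
concordance vanishes by construction.

What the simulator does not emulate: optical cross-talk and
autofluorescence baselines, registration error between fluorescence and
reflectance images, non-multiplicative (e.g. shot-noise) error structure,
electropherogram peak-calling artifacts, and any taxonomic identity of
OTU bins. Passing recovery tests therefore demonstrate correctness of the
estimators under the stated error model, not robustness to instrument
systematics.

## Numerical and reproducibility choices

- All randomness flows from a single seed per entry point; permutation
  tests, NMDS restarts and simulation each receive an independent child
  seed. Identical configurations give identical outputs.
- Problem sizes in the test-suite and acceptance checks are scaled-down
  study conditions chosen to exercise every code path at desk scale:
  20 × 20 to 32 × 32 cross-sections, 4 mats per site for the linked
  study, 199–999 permutations, 1000 null datasets for the ANOSIM
  calibration and 500 seeds for the Procrustes null. The full-scale
  survey (25 mats, 48 × 48) is run by the `analysis/` scripts.
- Degenerate inputs are flagged, not fixed: inverted fluorescence pairs
  are counted in a QC table with values untouched; zero-variance ANOVA
  groups return an undefined p; an all-zero community row is an error
  naming the sample; two all-zero samples give a flagged undefined
  Bray–Curtis pair.

## Known limitations

- The pinned Y_max is the sampled curve maximum and is biased high under
  noise (max of noisy values); any estimator that pins the observed
  maximum inherits this.
- The exact-enumeration ANOSIM is feasible only for small designs (it
  enumerates all distinct relabelings).
- The balanced variance decomposition discards masked cells outside the
  inscribed rectangle; for very ragged layers the unbalanced variant is
  the better choice despite its residual interaction term.
- I_k and I_max are reported in instrument irradiance units; no
  absolute-quantum calibration (which would need α) is attempted.
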