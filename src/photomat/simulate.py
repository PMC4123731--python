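"""Forward simulation of PAM stacks, reflectance images and ARISA profiles.

Every downstream estimator in this package is tested by recovery against
the known ground truth produced here. The generator emulates the study
conditions of a multi-site mat survey:

* photophysiology fields over a mat cross-section whose column-mean
  vertical profiles decrease with depth (Y_max, I_k), a chlorophyll
  absorptivity field with a subsurface maximum, and a patchy I_max;
* about 2:1 vertical:horizontal within-mat variability, with an explicit
  interaction component (vertical profiles that vary along the horizontal);
* site-structured physiology (per-site mean parameter levels) and
  site-structured communities with a tunable fraction of OTUs shared by
  all sites, three PCR replicates per mat, per-replicate detection loss
  and +/-1 bp fragment-length jitter.

All randomness flows from a single seed; identical configurations produce
identical outputs.

A note on self-consistency: the yield-irradiance model relates the pinned
maximum to its underlying amplitude through Y_m = Y_max/(1 - I_max/I_k).
The generator takes Y_max, I_max (snapped to the irradiance ladder, where a
measured maximum must lie) and I_k as the free truth fields, and derives
the dark yield Y0 so that the simulated curve passes through (I_max, Y_max)
exactly. At zero noise the pin-and-fit estimator then recovers I_k to the
optimiser tolerance. This also requires I_max to stay well below I_k
(the model's own operating regime); the generator caps I_max at
``imax_cap_frac * I_k``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .datatypes import (
    LayerMask,
    ReflectanceSet,
    RLCStack,
    RLCStep,
    StudyDesign,
    TruthFields,
    ValidationError,
)

__all__ = [
    "DEFAULT_LADDER",
    "SITE_PARAMS",
    "SimConfig",
    "generate_truth",
    "simulate_rlc_stack",
    "simulate_reflectance",
    "simulate_community",
    "generate_study",
]

#: Default actinic irradiance ladder (µmol photons m⁻² s⁻¹): a dark step
#: plus 12 light steps rising to 1700, geometric-ish with a dense low end
#: so that small I_max values are resolvable.
DEFAULT_LADDER = (0.0, 1.0, 2.0, 5.0, 10.0, 21.0, 44.0, 90.0,
                  186.0, 383.0, 788.0, 1300.0, 1700.0)

#: Per-site mean layer-averaged parameter levels and the replicate counts
#: of the emulated survey (four sites; 13 + 8 + 2 + 2 mats).
SITE_PARAMS: dict[str, dict[str, float]] = {
    "AD": {"a_chl": 0.66, "y_max": 0.13, "i_k": 85.0, "i_max": 24.0, "n_mats": 13},
    "AU": {"a_chl": 0.80, "y_max": 0.25, "i_k": 88.0, "i_max": 5.0, "n_mats": 8},
    "BR": {"a_chl": 0.72, "y_max": 0.28, "i_k": 66.0, "i_max": 2.4, "n_mats": 2},
    "SP": {"a_chl": 0.57, "y_max": 0.13, "i_k": 32.0, "i_max": 6.0, "n_mats": 2},
}

#: Within-site coefficient of variation of the mat-level parameter means.
SITE_CV = {"a_chl": 0.09, "y_max": 0.15, "i_k": 0.20, "i_max": 0.40}


@dataclass
class SimConfig:
    """All knobs of the forward simulation, with survey-scale defaults."""

    shape: tuple[int, int] = (48, 48)
    layer_rows: int | None = None  # default: 5/6 of the image rows
    ladder: tuple[float, ...] = DEFAULT_LADDER
    # vertical profile descriptors (surface value, e-folding depth in rows)
    y_max_surface: float = 0.28
    y_max_decay: float = 45.0
    ik_surface: float = 130.0
    ik_decay: float = 45.0
    imax_surface: float = 12.0
    imax_decay: float = 80.0
    imax_patchiness: float = 0.4
    imax_cap_frac: float = 0.25
    achl_surface: float = 0.55
    achl_decay: float = 90.0
    achl_bump_amp: float = 0.25
    achl_bump_depth: float = 8.0
    achl_bump_width: float = 5.0
    # horizontal structure
    vertical_horizontal_ratio: float = 2.0
    roughness_amp: float = 1.0  # scales all horizontal/interaction structure
    interaction_rel: float = 1.0  # interaction amplitude relative to horizontal
    horizontal_corr: float = 6.0  # correlation length (pixels)
    # measurement noise
    noise_sd: float = 0.02  # multiplicative SD on yields
    fm_scale: float = 0.6
    r_nir_plateau: float = 0.4
    reflectance_noise_sd: float = 0.0
    wavelength_step: float = 5.0
    # community simulation
    sites: tuple[str, ...] = ("AD", "AU", "BR", "SP")
    mats_per_site: int | None = None  # None -> survey replicate counts
    total_otus: int = 400
    shared_fraction: float = 0.21
    pair_overlap: float = 0.4  # extra OTU sharing between similar site pairs
    mat_occupancy: float = 0.8
    detection_p: float = 0.9
    jitter_p: float = 0.3
    abundance_sigma: float = 1.0
    linked: bool = True  # site physiology levels follow SITE_PARAMS
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.shape) < 4:
            raise ValidationError("image dimensions must be >= 4")
        if self.layer_rows is None:
            self.layer_rows = max(4, round(self.shape[0] * 5 / 6))
        if not 1 <= self.layer_rows <= self.shape[0]:
            raise ValidationError("layer_rows out of range")
        ladder = np.asarray(self.ladder, dtype=float)
        if np.any(np.diff(ladder) <= 0):
            raise ValidationError("ladder must be strictly increasing")
        if self.noise_sd < 0 or self.reflectance_noise_sd < 0:
            raise ValidationError("noise SD must be >= 0")
        if not 0.0 <= self.shared_fraction <= 1.0:
            raise ValidationError("shared_fraction must lie in [0, 1]")
        if not 0.0 < self.detection_p <= 1.0:
            raise ValidationError("detection_p must lie in (0, 1]")

    def design(self) -> StudyDesign:
        if self.mats_per_site is None:
            counts = {s: int(SITE_PARAMS[s]["n_mats"]) if s in SITE_PARAMS else 2
                      for s in self.sites}
        else:
            counts = {s: int(self.mats_per_site) for s in self.sites}
        return StudyDesign.from_sites(counts)


def _smooth_noise(rng: np.random.Generator, shape, corr: float) -> np.ndarray:
    """Zero-mean, unit-SD correlated noise (uniform-filtered white noise)."""
    w = rng.standard_normal(shape)
    size = max(int(round(corr)), 1)
    g = ndimage.uniform_filter(w, size=size, mode="wrap")
    g -= g.mean()
    sd = g.std()
    return g / sd if sd > 0 else g


def _horizontal_modulations(cfg: SimConfig, rng: np.random.Generator):
    """Column effect g(x) and interaction field G(z, x), both unit scale.

    G has its row and column means removed so that it contributes (almost)
    pure interaction variance, leaving the 2:1 vertical:horizontal
    calibration of the marginal profiles intact.
    """
    nr, nc = cfg.shape
    g = _smooth_noise(rng, (nc,), cfg.horizontal_corr)
    G = _smooth_noise(rng, (nr, nc), cfg.horizontal_corr)
    G = G - G.mean(axis=0, keepdims=True) - G.mean(axis=1, keepdims=True) + G.mean()
    sd = G.std()
    if sd > 0:
        G = G / sd
    return g, G


def _structured_field(profile: np.ndarray, cfg: SimConfig, g: np.ndarray,
                      G: np.ndarray, layer_rows: int) -> np.ndarray:
    """Spread a vertical profile into 2-D with calibrated horizontal spread.

    The horizontal amplitude is set so that the SD of the mean horizontal
    profile is ``1/vertical_horizontal_ratio`` times the SD of the mean
    vertical profile; the interaction term has row/column means removed and
    does not disturb that calibration.
    """
    nr, nc = cfg.shape
    f = profile[:, None] * np.ones((1, nc))
    sd_v = profile[:layer_rows].std(ddof=1)
    mean_f = profile[:layer_rows].mean()
    if cfg.roughness_amp == 0 or mean_f == 0 or sd_v == 0:
        return f
    a = cfg.roughness_amp * (sd_v / cfg.vertical_horizontal_ratio) / mean_f
    b = a * cfg.interaction_rel
    return f * (1.0 + a * g[None, :] + b * G)


def _snap_to_ladder(values: np.ndarray, ladder: np.ndarray) -> np.ndarray:
    """Snap each value to the nearest ladder irradiance (0 included)."""
    cand = np.concatenate([[0.0], ladder[ladder > 0]])
    idx = np.argmin(np.abs(values[..., None] - cand[None, None, :]), axis=-1)
    return cand[idx]


def generate_truth(cfg: SimConfig, seed: int | None = None) -> TruthFields:
    """Generate ground-truth photophysiology fields for one mat.

    Column-mean Y_max and I_k profiles decrease with depth; A_chl has a
    subsurface maximum when ``achl_bump_amp > 0``; I_max is patchy, capped
    at ``imax_cap_frac * I_k`` and snapped to the irradiance ladder (a
    measured curve maximum can only occur at a ladder step). Y0 is derived
    from (Y_max, I_max, I_k) via the pinning-consistency relation (module
    docstring).
    """
    if seed is None:
        seed = cfg.seed
    rng = np.random.default_rng(seed)
    nr, nc = cfg.shape
    z = np.arange(nr, dtype=float)
    ladder = np.asarray(cfg.ladder, dtype=float)

    g, G = _horizontal_modulations(cfg, rng)

    y_max_prof = cfg.y_max_surface * np.exp(-z / cfg.y_max_decay)
    ik_prof = cfg.ik_surface * np.exp(-z / cfg.ik_decay)
    achl_prof = cfg.achl_surface * np.exp(-z / cfg.achl_decay)
    if cfg.achl_bump_amp > 0:
        achl_prof = achl_prof + cfg.achl_bump_amp * np.exp(
            -0.5 * ((z - cfg.achl_bump_depth) / cfg.achl_bump_width) ** 2
        )

    y_max = np.clip(_structured_field(y_max_prof, cfg, g, G, cfg.layer_rows),
                    1e-3, 0.95)
    i_k = np.clip(_structured_field(ik_prof, cfg, g, G, cfg.layer_rows),
                  5.0, None)
    a_chl = np.clip(_structured_field(achl_prof, cfg, g, G, cfg.layer_rows),
                    0.0, 1.0)

    imax_prof = cfg.imax_surface * np.exp(-z / cfg.imax_decay)
    i_max = imax_prof[:, None] * np.ones((1, nc))
    if cfg.imax_patchiness > 0:
        patch = _smooth_noise(rng, cfg.shape, cfg.horizontal_corr)
        i_max = i_max * np.clip(1.0 + cfg.imax_patchiness * patch, 0.1, None)
    i_max = np.clip(i_max, 0.0, cfg.imax_cap_frac * i_k)
    i_max = _snap_to_ladder(i_max, ladder)
    # snapping may overshoot the cap at the coarse end of the ladder
    over = i_max > cfg.imax_cap_frac * i_k
    while np.any(over):
        cand = np.concatenate([[0.0], ladder[ladder > 0]])
        pos = np.searchsorted(cand, i_max[over])
        i_max[over] = cand[np.maximum(pos - 1, 0)]
        over = i_max > cfg.imax_cap_frac * i_k

    x = np.divide(i_max, i_k)
    with np.errstate(invalid="ignore", divide="ignore"):
        A = np.where(x > 0, (1.0 - np.exp(-x)) / np.where(x > 0, x, 1.0), 1.0)
    y_m = np.where(x > 0, y_max / (1.0 - x), y_max)
    delta_y = np.where(x > 0, y_m * (A - 1.0 + x) / np.exp(-1.0), 0.0)
    y0 = y_m - delta_y

    mask = np.zeros(cfg.shape, dtype=bool)
    mask[: cfg.layer_rows, :] = True
    return TruthFields(
        y0=y0, y_max=y_max, i_max=i_max, i_k=i_k, a_chl=a_chl,
        layer=LayerMask(mask), seed=seed,
    )


def _model_yield_fields(truth: TruthFields, irradiance: float) -> np.ndarray:
    """Vectorised yield-irradiance model over the truth fields (i > 0)."""
    y_m = np.where(truth.i_max > 0,
                   truth.y_max / (1.0 - truth.i_max / truth.i_k), truth.y_max)
    dy = y_m - truth.y0
    t1 = y_m * (truth.i_k / irradiance) * (-np.expm1(-irradiance / truth.i_k))
    with np.errstate(divide="ignore"):
        expo = np.where(truth.i_max > 0,
                        np.exp(-irradiance / np.where(truth.i_max > 0,
                                                      truth.i_max, 1.0)), 0.0)
    return t1 - dy * expo


def simulate_rlc_stack(
    truth: TruthFields,
    ladder=None,
    noise_sd: float = 0.02,
    seed: int = 0,
    fm_scale: float = 0.6,
    mat_id: str = "mat",
    site_id: str = "",
) -> RLCStack:
    """Forward-simulate a PAM image stack from truth fields.

    The ladder must be strictly increasing with a leading 0 (the dark
    pair). Noiseless effective yields equal the model exactly;
    multiplicative Gaussian noise of SD ``noise_sd`` is applied to the
    yields and mapped back to F' (Fm' is kept equal to Fm: the yield is
    the only quantity consumed downstream). Pixels outside the layer are
    given a near-zero Fm so they fall below any sensible noise floor.
    """
    if ladder is None:
        ladder = DEFAULT_LADDER
    ladder = np.asarray(ladder, dtype=float)
    if noise_sd < 0:
        raise ValidationError("noise SD must be >= 0")
    if len(ladder) < 2 or ladder[0] != 0:
        raise ValidationError("ladder must start with the dark step I = 0")
    if np.any(np.diff(ladder) <= 0):
        raise ValidationError("ladder must be strictly increasing")
    rng = np.random.default_rng(seed)
    mask = truth.layer.mask

    fm = fm_scale * (0.4 + 0.6 * truth.a_chl)
    fm = np.where(mask, fm, 0.005 * fm_scale)

    def noisy(y: np.ndarray) -> np.ndarray:
        if noise_sd == 0:
            return y
        return np.clip(y * (1.0 + noise_sd * rng.standard_normal(y.shape)),
                       0.0, 0.999)

    y0 = noisy(np.where(mask, truth.y0, 0.0))
    fo = fm * (1.0 - y0)
    steps = []
    for irr in ladder[1:]:
        y = noisy(np.where(mask, _model_yield_fields(truth, irr), 0.0))
        fm_prime = fm.copy()
        f_prime = fm_prime * (1.0 - y)
        steps.append(RLCStep(irradiance=float(irr), f_prime=f_prime,
                             fm_prime=fm_prime))
    return RLCStack(fo=fo, fm=fm, steps=steps, mat_id=mat_id, site_id=site_id)


def simulate_reflectance(
    truth: TruthFields,
    noise_sd: float = 0.0,
    seed: int = 0,
    plateau: float = 0.4,
    with_cube: bool = True,
    wavelength_step: float = 5.0,
):
    """Forward-simulate two-band reflectance and a hyperspectral cube.

    Two-band: R_nir is a flat plateau, R_r = R_nir * (1 - A_chl). The cube
    spans 400-900 nm with a chlorophyll-a absorption weight that is 1 at
    675 nm, ramps down across the 700-720 nm edge and is 0 above 720 nm
    (flat plateau), so that (R750 - R675)/R750 returns A_chl exactly at
    zero noise. The cube is returned in raw camera units (reflectance times
    a smooth lamp spectrum); the matching 40%-gray reference scan is
    returned alongside for normalisation.

    Returns ``(ReflectanceSet, reference_spectrum)``.
    """
    if noise_sd < 0:
        raise ValidationError("noise SD must be >= 0")
    rng = np.random.default_rng(seed)
    a = truth.a_chl

    def noisy(img):
        if noise_sd == 0:
            return img
        return np.clip(img * (1.0 + noise_sd * rng.standard_normal(img.shape)),
                       0.0, None)

    r_nir = noisy(np.full(a.shape, plateau))
    r_r = noisy(plateau * (1.0 - a))

    cube = None
    wavelengths = None
    reference = None
    if with_cube:
        wavelengths = np.arange(400.0, 900.0 + 1e-9, wavelength_step)
        w = np.ones_like(wavelengths)
        edge = (wavelengths > 700) & (wavelengths < 720)
        w[edge] = (720.0 - wavelengths[edge]) / 20.0
        w[wavelengths >= 720] = 0.0
        refl = plateau * (1.0 - a[..., None] * w[None, None, :])
        # smooth halogen-lamp spectrum peaking toward the near infrared
        lamp = 0.5 + 0.5 * (wavelengths - 400.0) / 500.0
        cube = noisy(refl * lamp[None, None, :])
        reference = 0.4 * lamp
    return (
        ReflectanceSet(r_r=r_r, r_nir=r_nir, cube=cube, wavelengths=wavelengths),
        reference,
    )


def _site_levels(cfg: SimConfig, design: StudyDesign,
                 rng: np.random.Generator) -> dict[str, dict[str, float]]:
    """Per-mat target layer means for each physiology parameter.

    In linked mode the site means follow the survey levels (SITE_PARAMS,
    falling back to mid-range levels for unknown site ids) and mats scatter
    around them with the within-site CV. In unlinked mode all sites share
    one common level, leaving only mat-level scatter: community structure
    then carries no physiological signal.
    """
    fallback = {"a_chl": 0.70, "y_max": 0.20, "i_k": 70.0, "i_max": 8.0}
    levels: dict[str, dict[str, float]] = {}
    for mat in design.mats:
        site = design.site_of(mat)
        base = SITE_PARAMS.get(site, fallback) if cfg.linked else fallback
        levels[mat] = {
            p: base[p] * float(rng.lognormal(0.0, SITE_CV[p]))
            for p in ("a_chl", "y_max", "i_k", "i_max")
        }
    return levels


def generate_study(
    cfg: SimConfig, seed: int | None = None
) -> tuple[StudyDesign, dict[str, TruthFields]]:
    """Generate truth fields for every mat of the study design.

    Each mat's vertical-profile surface values are rescaled so that its
    layer-mean parameters land at the mat's target level (site level times
    mat-level lognormal scatter); I_max targets are approximate because of
    the ladder snap and the I_k cap.
    """
    if seed is None:
        seed = cfg.seed
    rng = np.random.default_rng(seed)
    design = cfg.design()
    levels = _site_levels(cfg, design, rng)
    truths: dict[str, TruthFields] = {}
    for mat in design.mats:
        lv = levels[mat]
        # mean of exp(-z/L) over the layer converts surface value <-> mean
        z = np.arange(cfg.layer_rows, dtype=float)

        def surf(mean_target: float, decay: float) -> float:
            return mean_target / float(np.exp(-z / decay).mean())

        mat_cfg = replace(
            cfg,
            y_max_surface=min(surf(lv["y_max"], cfg.y_max_decay), 0.9),
            ik_surface=surf(lv["i_k"], cfg.ik_decay),
            imax_surface=surf(lv["i_max"], cfg.imax_decay),
            achl_surface=max(
                (lv["a_chl"]
                 - cfg.achl_bump_amp
                 * float(np.exp(-0.5 * ((z - cfg.achl_bump_depth)
                                        / cfg.achl_bump_width) ** 2).mean()))
                / float(np.exp(-z / cfg.achl_decay).mean()),
                0.05,
            ),
        )
        truths[mat] = generate_truth(mat_cfg, seed=int(rng.integers(2**31 - 1)))
    return design, truths


def simulate_community(
    cfg: SimConfig, seed: int | None = None
) -> tuple[pd.DataFrame, dict]:
    """Simulate triplicate ARISA fragment profiles for the whole study.

    A pool of ``total_otus`` distinct integer fragment lengths (100-1000
    bp) is split into a fraction shared by all sites and site-specific
    remainders. Each mat carries a random subset of its site pool
    (``mat_occupancy``) with lognormal abundances; each of the 3 PCR
    replicates detects a mat OTU independently with ``detection_p`` and
    jitters its measured length by +/-1 bp with ``jitter_p``.

    Returns ``(profiles, truth)``: a long table with columns (sample,
    replicate, fragment_bp, intensity) and a dict with the true pools and
    per-mat memberships.
    """
    if seed is None:
        seed = cfg.seed
    rng = np.random.default_rng(seed)
    design = cfg.design()
    sites = design.sites
    if len(sites) < 2:
        raise ValidationError("need at least 2 sites")

    n_shared = int(round(cfg.shared_fraction * cfg.total_otus))
    lengths = rng.choice(np.arange(100, 1001), size=cfg.total_otus, replace=False)
    shared = lengths[:n_shared]
    rest = lengths[n_shared:]
    chunks = np.array_split(rest, len(sites))
    site_pools = {s: [shared, chunk] for s, chunk in zip(sites, chunks)}
    if cfg.linked and cfg.pair_overlap > 0:
        # environmentally similar site pairs share part of their non-global
        # pool, mirroring their similar physiology (low-y_max AD/SP vs
        # high-y_max AU/BR in the default survey); this graded between-site
        # similarity is what links community geometry to function
        ordered = sorted(
            sites, key=lambda s: SITE_PARAMS.get(s, {"y_max": 0.2})["y_max"]
        )
        pairs = [tuple(ordered[i: i + 2]) for i in range(0, len(ordered) - 1, 2)]
        for s1, s2 in pairs:
            for a, b in ((s1, s2), (s2, s1)):
                donor = site_pools[b][1]
                k = int(round(cfg.pair_overlap * len(donor)))
                site_pools[a].append(donor[:k])
    site_pools = {s: np.sort(np.concatenate(parts))
                  for s, parts in site_pools.items()}

    records = []
    membership: dict[str, np.ndarray] = {}
    for mat in design.mats:
        pool = site_pools[design.site_of(mat)]
        present = pool[rng.random(len(pool)) < cfg.mat_occupancy]
        if len(present) == 0:
            present = pool[:1]
        membership[mat] = present
        abund = rng.lognormal(0.0, cfg.abundance_sigma, size=len(present))
        for rep in (1, 2, 3):
            detected = rng.random(len(present)) < cfg.detection_p
            jitter = np.where(
                rng.random(len(present)) < cfg.jitter_p,
                rng.choice([-1, 1], size=len(present)),
                0,
            )
            intens = abund * rng.lognormal(0.0, 0.2, size=len(present))
            for L, a_, d in zip(present + jitter, intens, detected):
                if d:
                    records.append(
                        {"sample": mat, "replicate": rep,
                         "fragment_bp": int(L), "intensity": float(a_)}
                    )
    profiles = pd.DataFrame.from_records(
        records, columns=["sample", "replicate", "fragment_bp", "intensity"]
    )
    truth = {"site_pools": site_pools, "membership": membership,
             "shared": np.sort(shared), "design": design}
    return profiles, truth
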