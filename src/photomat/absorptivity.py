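"""Chlorophyll-a absorptivity maps from reflectance imaging.

A_chl is a band-ratio proxy for chlorophyll-a concentration: the relative
depression of red reflectance (maximal chl-a absorption, 675 nm) against a
chl-a-free reference band in the near infrared (750 nm). Two routes are
supported: the two-band camera form A_chl = (R_nir - R_r)/R_nir and the
hyperspectral form A_chl = (R750 - R675)/R750 after normalisation against
a gray reference standard. Being ratios, both are invariant to a positive
rescaling of the whole spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import ReflectanceSet, ValidationError

__all__ = [
    "AbsorptivityMap",
    "achl_two_band",
    "achl_hyperspectral",
    "spectral_qc",
    "QCResult",
]


@dataclass
class AbsorptivityMap:
    a_chl: np.ndarray
    method: str  # "two_band" | "hyperspectral"
    qc: np.ndarray  # True where the estimate is trustworthy
    bands: dict | None = None  # selected wavelengths (hyperspectral)


@dataclass
class QCResult:
    passed: bool
    edge_slope: float  # reflectance units / nm over 700-720 nm
    plateau_cv: float  # CV of reflectance over 720-780 nm
    diagnostics: list[str]


def achl_two_band(refl: ReflectanceSet, floor: float | None = None) -> AbsorptivityMap:
    """A_chl = (R_nir - R_r)/R_nir with low-signal pixels masked.

    Pixels whose near-infrared reflectance is at or below the noise floor
    (default: 5% of the image's 99th percentile) are NaN with qc False.
    """
    r_nir = refl.r_nir
    if floor is None:
        floor = 0.05 * float(np.nanpercentile(r_nir, 99))
    ok = r_nir > floor
    if not ok.any():
        raise ValidationError("all pixels below the R_nir noise floor")
    a = np.full(r_nir.shape, np.nan)
    a[ok] = (r_nir[ok] - refl.r_r[ok]) / r_nir[ok]
    return AbsorptivityMap(a_chl=a, method="two_band", qc=ok)


def _nearest_band(wavelengths: np.ndarray, target: float) -> int:
    return int(np.argmin(np.abs(wavelengths - target)))


def achl_hyperspectral(
    cube: np.ndarray,
    wavelengths,
    reference_spectrum=None,
    reference_reflectance: float = 0.4,
    floor: float | None = None,
) -> AbsorptivityMap:
    """A_chl from a hyperspectral cube via the 675/750 nm band ratio.

    The cube is first normalised by the reference-standard scan scaled to
    its nominal reflectance (a single multiplicative normalisation per
    band). Band selection is nearest sampled wavelength, recorded in the
    result metadata; no interpolation.
    """
    wavelengths = np.asarray(wavelengths, dtype=float)
    cube = np.asarray(cube, dtype=float)
    if wavelengths.min() > 675.0 or wavelengths.max() < 750.0:
        raise ValidationError("wavelength axis must cover 675 and 750 nm")
    if reference_spectrum is not None:
        reference_spectrum = np.asarray(reference_spectrum, dtype=float)
        norm = reference_spectrum / reference_reflectance
        cube = cube / norm[None, None, :]
    j675 = _nearest_band(wavelengths, 675.0)
    j750 = _nearest_band(wavelengths, 750.0)
    r675 = cube[:, :, j675]
    r750 = cube[:, :, j750]
    if floor is None:
        floor = 0.05 * float(np.nanpercentile(r750, 99))
    ok = r750 > floor
    if not ok.any():
        raise ValidationError("all pixels below the R750 noise floor")
    a = np.full(r750.shape, np.nan)
    a[ok] = (r750[ok] - r675[ok]) / r750[ok]
    return AbsorptivityMap(
        a_chl=a, method="hyperspectral", qc=ok,
        bands={"r675_nm": float(wavelengths[j675]),
               "r750_nm": float(wavelengths[j750])},
    )


def spectral_qc(
    wavelengths,
    spectrum,
    edge_slope_min: float = 0.002,
    plateau_cv_max: float = 0.05,
) -> QCResult:
    """Check a pixel spectrum for the chl-a signature.

    Pass requires (a) a rising chl-a edge: mean slope over 700-720 nm above
    ``edge_slope_min`` (reflectance units per nm), and (b) a flat plateau:
    coefficient of variation of reflectance over 720-780 nm below
    ``plateau_cv_max``. Thresholds were calibrated on simulated spectra
    and are configurable.
    """
    wavelengths = np.asarray(wavelengths, dtype=float)
    spectrum = np.asarray(spectrum, dtype=float)
    if wavelengths.min() > 650.0 or wavelengths.max() < 780.0:
        raise ValidationError("spectrum must cover 650-780 nm")
    edge = (wavelengths >= 700.0) & (wavelengths <= 720.0)
    plateau = (wavelengths >= 720.0) & (wavelengths <= 780.0)
    if edge.sum() < 2 or plateau.sum() < 2:
        raise ValidationError("insufficient sampling of the edge/plateau windows")
    slope = float(np.polyfit(wavelengths[edge], spectrum[edge], 1)[0])
    pm = float(spectrum[plateau].mean())
    cv = float(spectrum[plateau].std(ddof=1) / pm) if pm > 0 else np.inf
    diagnostics = []
    if slope <= edge_slope_min:
        diagnostics.append("no edge")
    if cv >= plateau_cv_max:
        diagnostics.append("not flat")
    return QCResult(passed=not diagnostics, edge_slope=slope, plateau_cv=cv,
                    diagnostics=diagnostics)
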