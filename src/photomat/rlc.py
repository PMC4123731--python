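"""Rapid-light-curve (RLC) model and per-pixel parameter estimation.

The PSII quantum yield of cyanobacterial mats is not a monotone function of
actinic irradiance I: it rises from the dark-adapted yield Y0 to a maximum
Y_max at a small irradiance I_max before saturating away. The
photosynthesis-irradiance model used here is a Webb-type exponential
saturation term minus an irradiance-weighted suppression term,

    P(I) = P_max [1 - exp(-I/I_k)] - (dY/alpha) I exp(-I/I_m),

and, with Y = alpha P / I and I_m << I_k, the yield-irradiance form

    Y(I) = Y_m (I_k/I) [1 - exp(-I/I_k)] - dY exp(-I/I_max),

with Y_m = Y_max / (1 - I_max/I_k) and dY = Y_m - Y0. The estimation
procedure pins Y0, Y_max and I_max directly from the measured curve and then
fits the single remaining parameter I_k by bounded 1-D least squares over
the curve points beyond I_max.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize_scalar

from .datatypes import (
    LayerMask,
    ModelConstants,
    ParameterMaps,
    RLCParams,
    RLCStack,
    ValidationError,
)

__all__ = [
    "dark_yield",
    "effective_yield",
    "model_P",
    "model_Y",
    "pin_curve_extrema",
    "fit_ik",
    "fit_stack",
    "default_noise_floor",
    "IK_SEARCH_MAX",
]

#: Upper bound of the bounded I_k search (µmol photons m⁻² s⁻¹).
IK_SEARCH_MAX = 5000.0
#: Absolute tolerance of the 1-D I_k minimisation (µmol photons m⁻² s⁻¹).
IK_XATOL = 1e-3


def default_noise_floor(fm: np.ndarray, fraction: float = 0.05) -> float:
    """Noise floor for maximum-fluorescence images.

    Pixels whose Fm (or Fm') falls below ``fraction`` of the image's 99th
    percentile carry no usable signal and are masked out of all statistics;
    the floor also guards the yield ratio against division blow-ups.
    """
    return fraction * float(np.nanpercentile(fm, 99))


def _yield_ratio(f_low: np.ndarray, f_high: np.ndarray, floor: float):
    f_low = np.asarray(f_low, dtype=float)
    f_high = np.asarray(f_high, dtype=float)
    ok = f_high > floor
    if not np.any(ok):
        raise ValidationError("all pixels below the noise floor")
    y = np.full(f_high.shape, np.nan)
    y[ok] = (f_high[ok] - f_low[ok]) / f_high[ok]
    return np.clip(y, 0.0, 1.0, out=y), ok


def dark_yield(fo, fm, floor: float | None = None):
    """Dark-adapted PSII yield Y0 = (Fm - Fo)/Fm.

    Returns ``(y0, valid)`` where pixels with Fm at or below the noise floor
    are NaN and marked invalid. Values are clipped to [0, 1] for reporting.
    """
    fm = np.asarray(fm, dtype=float)
    if floor is None:
        floor = default_noise_floor(fm)
    return _yield_ratio(fo, fm, floor)


def effective_yield(f_prime, fm_prime, floor: float | None = None):
    """Effective PSII yield under actinic light, Y = (Fm' - F')/Fm'."""
    fm_prime = np.asarray(fm_prime, dtype=float)
    if floor is None:
        floor = default_noise_floor(fm_prime)
    return _yield_ratio(f_prime, fm_prime, floor)


def model_P(i, params: RLCParams, constants: ModelConstants):
    """Photosynthesis rate P(I) of the saturation-minus-suppression model.

    Provided for completeness and forward simulation; alpha and P_max are
    never fitted. With dY = 0 the model reduces to the Webb saturation
    curve. I_m = 0 with dY != 0 is a domain error (the suppression term has
    no limit there for the rate form).
    """
    i = np.asarray(i, dtype=float)
    if np.any(i < 0):
        raise ValueError("irradiance must be nonnegative")
    if params.i_k <= 0:
        raise ValueError("i_k must be positive")
    webb = constants.p_max * (1.0 - np.exp(-i / params.i_k))
    if params.delta_y == 0:
        return webb
    if constants.i_m == 0:
        raise ValueError("i_m = 0 with delta_y != 0 is undefined")
    return webb - (params.delta_y / constants.alpha) * i * np.exp(-i / constants.i_m)


def model_Y(i, params: RLCParams):
    """Yield-irradiance model Y(I) for I > 0.

    The I_max = 0 case (plant-like monotone decrease) is taken as the
    continuous limit of the suppression exponential: 0 for I > 0. The dark
    value is Y0 by definition and must not be requested here (I <= 0 is a
    domain error); note Y(I -> 0+) = Y_m - dY = Y0.
    """
    i = np.asarray(i, dtype=float)
    if np.any(i <= 0):
        raise ValueError("model_Y is defined for i > 0; use y0 for the dark value")
    if not params.i_k > params.i_max:
        raise ValueError("need i_k > i_max")
    t1 = params.y_m * (params.i_k / i) * (-np.expm1(-i / params.i_k))
    if params.i_max > 0:
        t2 = params.delta_y * np.exp(-i / params.i_max)
    else:
        t2 = 0.0
    return t1 - t2


def pin_curve_extrema(irradiances, yields, y0: float) -> tuple[float, float]:
    """Pin (Y_max, I_max) as the maximum of the measured curve.

    The dark point (0, Y0) participates in the maximum search, so a plant-
    like monotone decreasing curve yields (Y0, 0). Ties are broken toward
    the smallest irradiance. Requires at least 4 curve points.
    """
    irradiances = np.asarray(irradiances, dtype=float)
    yields = np.asarray(yields, dtype=float)
    if len(irradiances) != len(yields):
        raise ValidationError("irradiances and yields lengths differ")
    if len(yields) < 4:
        raise ValidationError("need at least 4 curve points to pin extrema")
    all_i = np.concatenate([[0.0], irradiances])
    all_y = np.concatenate([[y0], yields])
    j = int(np.argmax(all_y))  # first occurrence = smallest irradiance on ties
    return float(all_y[j]), float(all_i[j])


def fit_ik(
    irradiances,
    yields,
    y0: float,
    y_max: float,
    i_max: float,
    ik_max: float = IK_SEARCH_MAX,
) -> RLCParams:
    """Fit the light-acclimation irradiance I_k with extrema pinned.

    After pinning, the model has a single free parameter: for each trial
    I_k, Y_m = Y_max/(1 - I_max/I_k) and dY = Y_m - Y0 are re-derived and
    the sum of squared yield residuals over the curve points with I > I_max
    is minimised by bounded Brent search on
    I_k in (1.01 * max(I_max, first ladder step), ik_max].

    ``valid`` is False when fewer than 3 points lie beyond I_max, when the
    pinned maximum is nonpositive, or when the minimiser lands on a bound.
    """
    irradiances = np.asarray(irradiances, dtype=float)
    yields = np.asarray(yields, dtype=float)
    sel = irradiances > i_max
    invalid = RLCParams(
        y0=y0, y_max=y_max, i_max=i_max, i_k=np.nan,
        y_m=np.nan, delta_y=np.nan, residual_rms=np.nan, valid=False,
    )
    if sel.sum() < 3 or not np.isfinite(y_max) or y_max <= 0:
        return invalid
    pts_i = irradiances[sel]
    pts_y = yields[sel]
    if not np.all(np.isfinite(pts_y)):
        return invalid
    lo = 1.01 * max(i_max, float(irradiances[0]))
    hi = float(ik_max)
    if lo >= hi:
        return invalid

    def ssr(ik: float) -> float:
        y_m = y_max / (1.0 - i_max / ik)
        dy = y_m - y0
        t1 = y_m * (ik / pts_i) * (-np.expm1(-pts_i / ik))
        t2 = dy * np.exp(-pts_i / i_max) if i_max > 0 else 0.0
        resid = t1 - t2 - pts_y
        return float(resid @ resid)

    res = minimize_scalar(ssr, bounds=(lo, hi), method="bounded",
                          options={"xatol": IK_XATOL})
    ik_hat = float(res.x)
    on_bound = ik_hat <= lo + 10 * IK_XATOL or ik_hat >= hi - 10 * IK_XATOL
    return RLCParams(
        y0=y0,
        y_max=y_max,
        i_max=i_max,
        i_k=ik_hat,
        residual_rms=float(np.sqrt(res.fun / sel.sum())),
        valid=not on_bound,
    )


def fit_stack(
    stack: RLCStack,
    layer: LayerMask,
    noise_floor: float | None = None,
    median_filter: bool = False,
) -> ParameterMaps:
    """Fit the RLC model at every masked pixel of a PAM stack.

    Applies dark_yield / effective_yield, pins the per-pixel curve extrema
    and runs the 1-D I_k fit. Pixels outside the layer, below the noise
    floor, or with a failed fit are NaN with ``valid`` False. The optional
    3-point median filter smooths each pixel's measured curve before
    pinning (off by default: the raw curve is what is pinned).
    """
    if layer.shape != stack.shape:
        raise ValidationError("layer mask shape differs from stack")
    if not layer.mask.any():
        raise ValidationError("empty layer mask")
    if noise_floor is None:
        noise_floor = default_noise_floor(stack.fm)

    y0_map, ok = dark_yield(stack.fo, stack.fm, floor=noise_floor)
    irr = stack.irradiances
    n_steps = len(stack.steps)
    yields = np.full((n_steps,) + stack.shape, np.nan)
    for j, step in enumerate(stack.steps):
        yj, okj = effective_yield(step.f_prime, step.fm_prime, floor=noise_floor)
        yields[j] = yj
        ok &= okj

    shape = stack.shape
    out = {k: np.full(shape, np.nan) for k in
           ("y0", "y_max", "i_max", "i_k", "residual_rms")}
    valid = np.zeros(shape, dtype=bool)
    rows, cols = np.nonzero(layer.mask & ok)
    if rows.size == 0:
        raise ValidationError("no valid pixel inside the layer mask")
    for r, c in zip(rows, cols):
        curve = yields[:, r, c]
        if median_filter and n_steps >= 3:
            padded = np.concatenate([curve[:1], curve, curve[-1:]])
            curve = np.median(
                np.stack([padded[:-2], padded[1:-1], padded[2:]]), axis=0
            )
        y0 = float(y0_map[r, c])
        y_max, i_max = pin_curve_extrema(irr, curve, y0)
        params = fit_ik(irr, curve, y0, y_max, i_max)
        out["y0"][r, c] = y0
        out["y_max"][r, c] = y_max
        out["i_max"][r, c] = i_max
        out["i_k"][r, c] = params.i_k
        out["residual_rms"][r, c] = params.residual_rms
        valid[r, c] = params.valid
    return ParameterMaps(valid=valid, mat_id=stack.mat_id, **out)
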