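"""Core data containers for mat cross-section imaging and community profiling.

Image convention: row 0 is the mat surface and the row index increases with
depth below the surface; columns index horizontal position along the section.
All fluorescence yields are stored as floating point values in [0, 1]
(instrument counts are normalised on read).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "RLCStep",
    "RLCStack",
    "ReflectanceSet",
    "LayerMask",
    "StudyDesign",
    "TruthFields",
    "RLCParams",
    "ModelConstants",
    "ParameterMaps",
    "ProfileStats",
    "VarianceDecomposition",
    "OrdinationResult",
    "ANOSIMResult",
    "ProcrustesResult",
]


class ValidationError(ValueError):
    """Raised when a container violates one of its declared invariants."""


def _as_2d(name: str, arr) -> np.ndarray:
    a = np.asarray(arr, dtype=float)
    if a.ndim != 2:
        raise ValidationError(f"{name} must be 2-D, got shape {a.shape}")
    return a


@dataclass
class RLCStep:
    """One rapid-light-curve step: actinic irradiance with its image pair."""

    irradiance: float  # µmol photons m⁻² s⁻¹
    f_prime: np.ndarray
    fm_prime: np.ndarray


@dataclass
class RLCStack:
    """A registered PAM image stack across an increasing irradiance ladder.

    ``fo``/``fm`` are the dark-adapted minimum/maximum fluorescence yield
    images; each step holds the (F', Fm') pair recorded under actinic light.
    Pixels where fm < fo (or fm' < f') are physically impossible and are
    flagged in :attr:`qc_flags` on validation but never altered.
    """

    fo: np.ndarray
    fm: np.ndarray
    steps: list[RLCStep]
    mat_id: str = "mat"
    site_id: str = ""
    qc_flags: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.fo = _as_2d("fo", self.fo)
        self.fm = _as_2d("fm", self.fm)
        self.validate()

    @property
    def shape(self) -> tuple[int, int]:
        return self.fo.shape

    @property
    def irradiances(self) -> np.ndarray:
        return np.array([s.irradiance for s in self.steps], dtype=float)

    def validate(self) -> pd.DataFrame:
        """Check invariants; return (and store) a QC table of flagged pixels.

        Validation never mutates pixel values: inverted yield pairs are
        counted and reported, not clipped.
        """
        if self.fm.shape != self.fo.shape:
            raise ValidationError("fo and fm shapes differ")
        irr = self.irradiances
        if len(irr) and np.any(np.diff(irr) <= 0):
            raise ValidationError(f"irradiance ladder not strictly increasing: {irr}")
        if len(irr) and irr[0] < 0:
            raise ValidationError("negative irradiance in ladder")
        records = []
        for s in self.steps:
            s.f_prime = _as_2d("f_prime", s.f_prime)
            s.fm_prime = _as_2d("fm_prime", s.fm_prime)
            if s.f_prime.shape != self.shape or s.fm_prime.shape != self.shape:
                raise ValidationError("step image shape differs from dark pair")
            records.append(
                {
                    "irradiance": s.irradiance,
                    "n_inverted": int(np.sum(s.fm_prime < s.f_prime)),
                    "n_negative": int(np.sum(s.f_prime < 0) + np.sum(s.fm_prime < 0)),
                }
            )
        records.insert(
            0,
            {
                "irradiance": np.nan,  # dark pair
                "n_inverted": int(np.sum(self.fm < self.fo)),
                "n_negative": int(np.sum(self.fo < 0) + np.sum(self.fm < 0)),
            },
        )
        self.qc_flags = pd.DataFrame.from_records(records)
        return self.qc_flags


@dataclass
class ReflectanceSet:
    """Red / near-infrared reflectance images, optionally with a cube.

    The hyperspectral cube is (row, column, wavelength) with the wavelength
    axis in nm, strictly increasing, nominally covering 400-900 nm.
    """

    r_r: np.ndarray
    r_nir: np.ndarray
    cube: np.ndarray | None = None
    wavelengths: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.r_r = _as_2d("r_r", self.r_r)
        self.r_nir = _as_2d("r_nir", self.r_nir)
        if self.r_r.shape != self.r_nir.shape:
            raise ValidationError("r_r and r_nir shapes differ")
        if np.any(self.r_r < 0) or np.any(self.r_nir < 0):
            raise ValidationError("reflectance must be nonnegative")
        if self.cube is not None:
            self.cube = np.asarray(self.cube, dtype=float)
            if self.wavelengths is None:
                raise ValidationError("cube requires a wavelength axis")
            self.wavelengths = np.asarray(self.wavelengths, dtype=float)
            if self.cube.ndim != 3 or self.cube.shape[2] != len(self.wavelengths):
                raise ValidationError("cube last axis must match wavelengths")
            if np.any(np.diff(self.wavelengths) <= 0):
                raise ValidationError("wavelengths not strictly increasing")


@dataclass
class LayerMask:
    """Boolean mask of the cyanobacterial layer.

    Each column's True pixels must form one contiguous vertical run: the
    layer is a connected band below the surface, possibly of varying
    thickness along the horizontal direction.
    """

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValidationError("mask must be 2-D")
        if not self.mask.any():
            raise ValidationError("mask has no True pixel")
        # column-wise contiguity
        for c in range(self.mask.shape[1]):
            col = self.mask[:, c]
            if col.any():
                idx = np.flatnonzero(col)
                if idx[-1] - idx[0] + 1 != len(idx):
                    raise ValidationError(f"column {c} mask not contiguous")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


@dataclass
class StudyDesign:
    """Mapping of mats to sites (one site per mat, unique mat ids)."""

    table: pd.DataFrame  # columns: mat_id, site_id, replicate

    def __post_init__(self) -> None:
        req = {"mat_id", "site_id"}
        if not req.issubset(self.table.columns):
            raise ValidationError(f"design table must have columns {sorted(req)}")
        if self.table["mat_id"].duplicated().any():
            raise ValidationError("duplicate mat_id in design")
        if "replicate" not in self.table.columns:
            t = self.table.copy()
            t["replicate"] = t.groupby("site_id").cumcount() + 1
            self.table = t

    @classmethod
    def from_sites(cls, sites: dict[str, int]) -> "StudyDesign":
        """Build a design from ``{site_id: n_mats}``."""
        rows = [
            {"mat_id": f"{s}{i + 1}", "site_id": s, "replicate": i + 1}
            for s, n in sites.items()
            for i in range(n)
        ]
        return cls(pd.DataFrame(rows))

    @property
    def sites(self) -> list[str]:
        return list(dict.fromkeys(self.table["site_id"]))

    @property
    def mats(self) -> list[str]:
        return list(self.table["mat_id"])

    def site_of(self, mat_id: str) -> str:
        row = self.table.loc[self.table["mat_id"] == mat_id, "site_id"]
        if row.empty:
            raise KeyError(mat_id)
        return str(row.iloc[0])


@dataclass
class TruthFields:
    """Ground-truth parameter fields behind a simulated mat cross-section."""

    y0: np.ndarray
    y_max: np.ndarray
    i_max: np.ndarray
    i_k: np.ndarray
    a_chl: np.ndarray
    layer: LayerMask
    seed: int = 0

    def __post_init__(self) -> None:
        m = self.layer.mask
        for name in ("y0", "y_max", "i_max", "i_k", "a_chl"):
            setattr(self, name, _as_2d(name, getattr(self, name)))
            if getattr(self, name).shape != m.shape:
                raise ValidationError(f"{name} shape differs from layer mask")
        if np.any(self.y0[m] < 0) or np.any(self.y0[m] > self.y_max[m] + 1e-12):
            raise ValidationError("need 0 <= y0 <= y_max in layer")
        if np.any(self.y_max[m] >= 1):
            raise ValidationError("y_max must be < 1")
        if np.any(self.i_max[m] < 0) or np.any(self.i_k[m] <= self.i_max[m]):
            raise ValidationError("need i_k > i_max >= 0 in layer")
        if np.any(self.a_chl[m] < 0) or np.any(self.a_chl[m] > 1):
            raise ValidationError("a_chl must lie in [0, 1]")


@dataclass
class RLCParams:
    """Fitted rapid-light-curve parameters for one pixel (or curve).

    ``y_m`` and ``delta_y`` are derived: y_m = y_max / (1 - i_max/i_k) and
    delta_y = y_m - y0. ``valid`` is False when the 1-D I_k search hit its
    bounds or the curve was degenerate.
    """

    y0: float
    y_max: float
    i_max: float
    i_k: float
    y_m: float = np.nan
    delta_y: float = np.nan
    residual_rms: float = np.nan
    valid: bool = True

    def __post_init__(self) -> None:
        if np.isnan(self.y_m) and self.i_k > self.i_max:
            self.y_m = self.y_max / (1.0 - self.i_max / self.i_k)
        if np.isnan(self.delta_y):
            self.delta_y = self.y_m - self.y0


@dataclass
class ModelConstants:
    """Constants of the photosynthesis-irradiance model.

    ``alpha`` links yield and photosynthesis rate (Y = alpha * P / I); its
    value is carried for simulation only and never fitted. ``i_m`` is the
    decay irradiance of the suppression term of the P-I model; under the
    i_m << i_k regime it coincides with the measured I_max.
    """

    p_max: float = 1.0
    alpha: float = 1.0
    i_m: float = 10.0

    def __post_init__(self) -> None:
        if self.p_max < 0 or self.alpha <= 0 or self.i_m < 0:
            raise ValidationError("need p_max >= 0, alpha > 0, i_m >= 0")


@dataclass
class ParameterMaps:
    """Per-pixel photophysiology maps with a shared validity mask.

    Invalid pixels carry NaN and are excluded from all statistics.
    """

    y0: np.ndarray
    y_max: np.ndarray
    i_max: np.ndarray
    i_k: np.ndarray
    residual_rms: np.ndarray
    valid: np.ndarray
    mat_id: str = "mat"

    def __post_init__(self) -> None:
        shape = np.asarray(self.y0).shape
        for name in ("y_max", "i_max", "i_k", "residual_rms", "valid"):
            if np.asarray(getattr(self, name)).shape != shape:
                raise ValidationError(f"{name} shape differs")
        self.valid = np.asarray(self.valid, dtype=bool)

    def as_dict(self) -> dict[str, np.ndarray]:
        return {
            "y0": self.y0,
            "y_max": self.y_max,
            "i_max": self.i_max,
            "i_k": self.i_k,
            "residual_rms": self.residual_rms,
        }

    def layer_means(self) -> dict[str, float]:
        """Mean of each parameter over valid pixels."""
        return {k: float(np.nanmean(v[self.valid])) for k, v in self.as_dict().items()}


@dataclass
class ProfileStats:
    """Mean depth (vertical) or lateral (horizontal) profile with spread."""

    axis: str  # "vertical" | "horizontal"
    positions: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n: np.ndarray

    def __post_init__(self) -> None:
        if self.axis not in ("vertical", "horizontal"):
            raise ValidationError("axis must be 'vertical' or 'horizontal'")
        if not (len(self.positions) == len(self.mean) == len(self.sd) == len(self.n)):
            raise ValidationError("profile arrays must share one length")


@dataclass
class VarianceDecomposition:
    """Two-factor (depth x horizontal position) variance split of one image."""

    ss_row: float
    ss_col: float
    ss_interaction: float
    ss_total: float
    defined: bool = True

    @property
    def pct_vertical(self) -> float:
        return 100.0 * self.ss_row / self.ss_total if self.defined else np.nan

    @property
    def pct_horizontal(self) -> float:
        return 100.0 * self.ss_col / self.ss_total if self.defined else np.nan

    @property
    def pct_interaction(self) -> float:
        return 100.0 * self.ss_interaction / self.ss_total if self.defined else np.nan


@dataclass
class OrdinationResult:
    """Low-dimensional sample coordinates with a goodness diagnostic."""

    coordinates: pd.DataFrame  # index = sample ids, columns = axis 1..k
    method: str  # "nmds" | "metric_mds"
    stress: float = np.nan  # Kruskal stress-1 (NMDS only)
    explained: np.ndarray | None = None  # eigenvalue fractions (metric MDS)
    restarts: int = 1
    seed: int | None = None

    def __post_init__(self) -> None:
        # centred coordinates by convention
        vals = self.coordinates.to_numpy(dtype=float)
        self.coordinates = pd.DataFrame(
            vals - vals.mean(axis=0),
            index=self.coordinates.index,
            columns=self.coordinates.columns,
        )


@dataclass
class ANOSIMResult:
    """Clarke's ANOSIM R with its permutation p-value."""

    r: float
    p: float
    n_permutations: int
    group_sizes: dict[str, int]

    def __post_init__(self) -> None:
        if not -1.0 - 1e-9 <= self.r <= 1.0 + 1e-9:
            raise ValidationError(f"R out of [-1, 1]: {self.r}")


@dataclass
class ProcrustesResult:
    """Symmetric Procrustes superimposition of two ordinations."""

    rotation: np.ndarray
    scale: float
    translation: np.ndarray
    m12_squared: float
    r: float
    p: float = np.nan
    n_permutations: int = 0

    def __post_init__(self) -> None:
        if not -1e-9 <= self.m12_squared <= 1.0 + 1e-9:
            raise ValidationError(f"m12^2 out of [0, 1]: {self.m12_squared}")
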