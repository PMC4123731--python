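"""File I/O: TIFF stacks, CSV tables, YAML configuration, result archives.

Stacks travel as multi-page grayscale TIFF (page 0 = Fo, page 1 = Fm, then
an (F', Fm') page pair per ladder step) with the irradiance ladder in a
sidecar CSV. Yield images are floating point in [0, 1]; integer-count
TIFFs are normalised by their dtype maximum on read. Ladder units are
fixed to µmol photons m⁻² s⁻¹ — no unit inference.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .datatypes import (
    LayerMask,
    ParameterMaps,
    RLCStack,
    RLCStep,
    StudyDesign,
    ValidationError,
)

__all__ = [
    "read_rlc_stack",
    "write_rlc_stack",
    "read_design",
    "write_design",
    "read_fragment_profiles",
    "write_fragment_profiles",
    "write_parameter_maps",
    "read_parameter_maps",
    "write_report",
    "load_config",
]

_MAP_ORDER = ("y0", "y_max", "i_max", "i_k", "residual_rms")


def _normalise_counts(page: np.ndarray) -> np.ndarray:
    if np.issubdtype(page.dtype, np.integer):
        return page.astype(float) / float(np.iinfo(page.dtype).max)
    return page.astype(float)


def read_rlc_stack(stack_path, ladder_path, mat_id: str | None = None,
                   site_id: str = "") -> RLCStack:
    """Read a PAM stack TIFF plus its irradiance-ladder CSV.

    The ladder CSV needs an ``irradiance`` column, one row per light step;
    the TIFF must hold 2 + 2 * n_steps pages. Pixels violating Fm >= Fo are
    flagged in the stack's QC table, never altered.
    """
    stack_path = Path(stack_path)
    ladder = pd.read_csv(ladder_path)
    if "irradiance" not in ladder.columns:
        raise ValidationError("ladder CSV needs an 'irradiance' column")
    irr = ladder["irradiance"].to_numpy(dtype=float)
    if np.any(np.diff(irr) <= 0):
        raise ValidationError(f"ladder not strictly increasing: {irr}")
    pages = [_normalise_counts(p) for p in tifffile.imread(stack_path)]
    if len(pages) != 2 + 2 * len(irr):
        raise ValidationError(
            f"stack has {len(pages)} pages, expected {2 + 2 * len(irr)} "
            f"for {len(irr)} ladder steps"
        )
    steps = [
        RLCStep(irradiance=float(i), f_prime=pages[2 + 2 * j],
                fm_prime=pages[3 + 2 * j])
        for j, i in enumerate(irr)
    ]
    return RLCStack(fo=pages[0], fm=pages[1], steps=steps,
                    mat_id=mat_id or stack_path.stem, site_id=site_id)


def write_rlc_stack(stack: RLCStack, stack_path, ladder_path) -> None:
    """Write a stack as float32 multi-page TIFF plus a ladder CSV."""
    pages = [stack.fo, stack.fm]
    for s in stack.steps:
        pages.extend([s.f_prime, s.fm_prime])
    tifffile.imwrite(stack_path, np.stack(pages).astype(np.float32),
                     photometric="minisblack")
    pd.DataFrame({"irradiance": stack.irradiances}).to_csv(ladder_path,
                                                           index=False)


def read_design(path) -> StudyDesign:
    return StudyDesign(pd.read_csv(path))


def write_design(design: StudyDesign, path) -> None:
    design.table.to_csv(path, index=False)


def read_fragment_profiles(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    req = {"sample", "replicate", "fragment_bp", "intensity"}
    if not req.issubset(df.columns):
        raise ValidationError(f"fragment CSV needs columns {sorted(req)}")
    return df


def write_fragment_profiles(profiles: pd.DataFrame, path) -> None:
    profiles.to_csv(path, index=False)


def write_parameter_maps(maps: ParameterMaps, path) -> None:
    """Parameter maps as a 5-page float32 TIFF (y0, y_max, i_max, i_k, rms)."""
    pages = np.stack([np.asarray(getattr(maps, k), dtype=np.float32)
                      for k in _MAP_ORDER])
    tifffile.imwrite(path, pages, photometric="minisblack")


def read_parameter_maps(path, mat_id: str = "mat") -> ParameterMaps:
    pages = tifffile.imread(path).astype(float)
    fields = dict(zip(_MAP_ORDER, pages))
    return ParameterMaps(valid=np.isfinite(fields["i_k"]), mat_id=mat_id,
                         **fields)


def write_report(
    out_dir,
    maps_by_mat: dict[str, ParameterMaps] | None = None,
    variability: pd.DataFrame | None = None,
    site_summary: pd.DataFrame | None = None,
    ordinations: dict | None = None,
    tests: dict | None = None,
    masks: dict[str, LayerMask] | None = None,
) -> Path:
    """Write the result archive: CSV tables plus parameter-map TIFFs.

    The file set is deterministic given identical inputs: tables are
    written with fixed column order and sorted rows, maps as float32 TIFF.
    Missing sections produce header-only CSVs so the archive schema is
    stable.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if maps_by_mat:
        for mat, maps in sorted(maps_by_mat.items()):
            write_parameter_maps(maps, out / f"maps_{mat}.tif")
        means = pd.DataFrame(
            [{"mat_id": m, **maps.layer_means()}
             for m, maps in sorted(maps_by_mat.items())]
        )
    else:
        means = pd.DataFrame(columns=["mat_id", *_MAP_ORDER])
    means.to_csv(out / "layer_means.csv", index=False)

    cols = ["parameter", "scale", "unit", "sd", "vertical_sd",
            "horizontal_sd", "cv", "n", "flag"]
    if variability is None or variability.empty:
        pd.DataFrame(columns=cols).to_csv(out / "variability.csv", index=False)
    else:
        variability[cols].to_csv(out / "variability.csv", index=False)

    if site_summary is None or site_summary.empty:
        pd.DataFrame(columns=["parameter", "site", "mean", "sd", "rank",
                              "anova_p", "shapiro_p"]).to_csv(
            out / "site_summary.csv", index=False)
    else:
        site_summary.to_csv(out / "site_summary.csv", index=False)

    for name, ordn in (ordinations or {}).items():
        ordn.coordinates.to_csv(out / f"ordination_{name}.csv")
    if tests:
        flat = {}
        for k, v in tests.items():
            flat[k] = v if np.isscalar(v) else repr(v)
        pd.Series(flat, name="value").rename_axis("statistic").to_csv(
            out / "tests.csv")
    return out


def load_config(path) -> dict:
    """Load the pipeline YAML configuration as a plain dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValidationError("config must be a YAML mapping")
    return cfg
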