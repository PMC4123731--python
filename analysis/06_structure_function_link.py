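"""Link between community composition and photosynthetic function.

Ordinates the mats by their average physiology (classical MDS of
z-standardised A_chl, Y_max, I_k, I_max), superimposes that configuration
on the community NMDS by symmetric Procrustes, and tests the concordance
by Monte-Carlo permutation.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))

import json

import pandas as pd
from common import RESULTS, ensure_dirs, study_config

from photomat import community as comm
from photomat.io import read_design


def main() -> None:
    ensure_dirs()
    cfg = study_config()
    design = read_design(RESULTS / "design.csv")
    means = pd.read_csv(RESULTS / "layer_means.csv").set_index("mat_id")
    achl = pd.read_csv(RESULTS / "achl_means.csv").set_index("mat_id")
    phys = pd.DataFrame({
        "a_chl": achl["a_chl_two_band"],
        "y_max": means["y_max"],
        "i_k": means["i_k"],
        "i_max": means["i_max"],
    })
    nmds_coords = pd.read_csv(RESULTS / "nmds_community.csv", index_col=0)

    phys_mds = comm.metric_mds_physiology(phys.loc[nmds_coords.index])
    phys_mds.coordinates.to_csv(RESULTS / "mds_physiology.csv")

    proc = comm.procrustes_test(
        nmds_coords, phys_mds.coordinates,
        n_permutations=1000, seed=cfg.seed,
    )
    (RESULTS / "procrustes.json").write_text(json.dumps({
        "r": proc.r, "m12_squared": proc.m12_squared, "p": proc.p,
        "n_permutations": proc.n_permutations,
    }, indent=2))
    print(f"Procrustes concordance between community and physiology "
          f"ordinations: r = {proc.r:.3f} (m12^2 = {proc.m12_squared:.3f}), "
          f"p = {proc.p:.4g} over {proc.n_permutations} permutations")
    verdict = "significantly linked" if proc.p < 0.05 else "not linked"
    print(f"-> community composition and photosynthetic function are "
          f"{verdict} at alpha = 0.05")


if __name__ == "__main__":
    main()
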