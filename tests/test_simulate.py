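"""Generator contracts: truth structure, forward-inverse consistency,
determinism, and the community simulator."""

import numpy as np
import pandas as pd
import pytest

from photomat import SimConfig, ValidationError, generate_truth
from photomat.simulate import (
    DEFAULT_LADDER,
    _model_yield_fields,
    generate_study,
    simulate_community,
    simulate_reflectance,
    simulate_rlc_stack,
)


class TestGenerateTruth:
    def test_invariants_and_monotone_profiles(self, truth):
        m = truth.layer.mask
        assert np.all(truth.y0[m] >= 0)
        assert np.all(truth.y0[m] <= truth.y_max[m] + 1e-12)
        assert np.all(truth.i_k[m] > truth.i_max[m])
        rows = np.unique(np.nonzero(m)[0])
        ymax_prof = np.array([truth.y_max[r][m[r]].mean() for r in rows])
        ik_prof = np.array([truth.i_k[r][m[r]].mean() for r in rows])
        assert np.all(np.diff(ymax_prof) <= 1e-9)
        assert np.all(np.diff(ik_prof) <= 1e-9)

    def test_achl_bump_gives_subsurface_maximum(self, small_cfg):
        t = generate_truth(small_cfg, seed=3)
        prof = t.a_chl[: small_cfg.layer_rows].mean(axis=1)
        assert np.argmax(prof) > 0

    def test_no_bump_puts_achl_maximum_at_surface(self, small_cfg):
        from dataclasses import replace

        t = generate_truth(replace(small_cfg, achl_bump_amp=0.0), seed=3)
        prof = t.a_chl[: small_cfg.layer_rows].mean(axis=1)
        assert np.argmax(prof) == 0

    def test_zero_roughness_makes_columns_identical(self, small_cfg):
        from dataclasses import replace

        t = generate_truth(
            replace(small_cfg, roughness_amp=0.0, imax_patchiness=0.0), seed=3
        )
        for f in (t.y_max, t.i_k, t.a_chl, t.i_max):
            assert np.allclose(f, f[:, :1])

    def test_vertical_horizontal_ratio_near_two(self):
        from photomat.spatial import within_mat_variability

        t = generate_truth(SimConfig(), seed=0)
        wm = within_mat_variability(t.y_max, t.layer)
        assert 1.5 <= wm["vertical_sd"] / wm["horizontal_sd"] <= 2.5

    def test_degenerate_shape_rejected(self):
        with pytest.raises(ValidationError):
            SimConfig(shape=(3, 10))

    def test_deterministic_given_seed(self, small_cfg):
        a = generate_truth(small_cfg, seed=9)
        b = generate_truth(small_cfg, seed=9)
        np.testing.assert_array_equal(a.y_max, b.y_max)
        np.testing.assert_array_equal(a.i_max, b.i_max)


class TestSimulateStack:
    def test_noiseless_yields_reproduce_model_exactly(self, truth, small_cfg):
        stack = simulate_rlc_stack(truth, ladder=small_cfg.ladder,
                                   noise_sd=0.0, seed=0)
        m = truth.layer.mask
        for step in stack.steps:
            y = (step.fm_prime - step.f_prime) / step.fm_prime
            expected = _model_yield_fields(truth, step.irradiance)
            np.testing.assert_allclose(y[m], expected[m], rtol=0, atol=1e-12)
        y0 = (stack.fm - stack.fo) / stack.fm
        np.testing.assert_allclose(y0[m], truth.y0[m], atol=1e-12)

    def test_ladder_must_start_dark(self, truth):
        with pytest.raises(ValidationError):
            simulate_rlc_stack(truth, ladder=(1.0, 10.0, 100.0))

    def test_negative_noise_rejected(self, truth):
        with pytest.raises(ValidationError):
            simulate_rlc_stack(truth, noise_sd=-0.1)

    def test_multiplicative_noise_magnitude(self):
        """Relative yield error SD matches the configured noise SD."""
        cfg = SimConfig()  # 48x48, 40-row layer: > 2e4 masked yield samples
        t = generate_truth(cfg, seed=2)
        stack = simulate_rlc_stack(t, ladder=cfg.ladder, noise_sd=0.02, seed=3)
        m = t.layer.mask
        rel = []
        for step in stack.steps:
            y = (step.fm_prime - step.f_prime) / step.fm_prime
            expected = _model_yield_fields(t, step.irradiance)
            big = m & (expected > 0.02)
            rel.append((y[big] - expected[big]) / expected[big])
        rel = np.concatenate(rel)
        assert len(rel) > 10_000
        assert rel.std() == pytest.approx(0.02, rel=0.05)
        assert abs(rel.mean()) < 0.001


class TestSimulateReflectance:
    def test_two_band_limits(self, truth):
        refl, _ = simulate_reflectance(truth, noise_sd=0.0, with_cube=False)
        np.testing.assert_allclose(refl.r_r,
                                   refl.r_nir * (1 - truth.a_chl), atol=1e-12)

    def test_cube_round_trip_recovers_achl(self, truth):
        from photomat.absorptivity import achl_hyperspectral

        refl, reference = simulate_reflectance(truth, noise_sd=0.0)
        amap = achl_hyperspectral(refl.cube, refl.wavelengths, reference)
        np.testing.assert_allclose(amap.a_chl, truth.a_chl, atol=1e-10)

    def test_cube_has_edge_and_plateau(self, truth):
        from photomat.absorptivity import spectral_qc

        refl, reference = simulate_reflectance(truth, noise_sd=0.0)
        norm = refl.cube / (reference / 0.4)[None, None, :]
        r, c = 5, 5
        qc = spectral_qc(refl.wavelengths, norm[r, c])
        assert qc.passed, qc.diagnostics


class TestSimulateCommunity:
    def test_perfect_detection_gives_identical_replicates(self):
        cfg = SimConfig(mats_per_site=2, detection_p=1.0, jitter_p=0.0)
        profiles, _ = simulate_community(cfg, seed=4)
        for _, grp in profiles.groupby("sample"):
            reps = [
                g.sort_values("fragment_bp")[["fragment_bp", "intensity"]]
                .reset_index(drop=True)
                for _, g in grp.groupby("replicate")
            ]
            assert len(reps) == 3
            for r in reps[1:]:
                pd.testing.assert_frame_equal(reps[0][["fragment_bp"]],
                                              r[["fragment_bp"]])

    def test_realized_shared_fraction_tracks_config(self):
        cfg = SimConfig(mats_per_site=4, shared_fraction=0.21,
                        detection_p=0.95)
        fracs = []
        for seed in range(5):
            _, tr = simulate_community(cfg, seed=seed)
            sites = {}
            design = tr["design"]
            for mat, otus in tr["membership"].items():
                sites.setdefault(design.site_of(mat), set()).update(otus.tolist())
            allo = set().union(*sites.values())
            ubiq = set.intersection(*sites.values())
            fracs.append(len(ubiq) / len(allo))
        assert np.mean(fracs) == pytest.approx(0.21, abs=0.05)

    def test_shared_pool_of_one_removes_site_signal(self):
        """shared_fraction 1: between-site Bray-Curtis ~ within-site."""
        from photomat import community as comm

        diffs = []
        for seed in range(20):
            cfg = SimConfig(mats_per_site=3, shared_fraction=1.0,
                            detection_p=1.0, jitter_p=0.0)
            profiles, tr = simulate_community(cfg, seed=seed)
            cons = comm.consensus_profile(comm.bin_fragments(profiles))
            dm = comm.bray_curtis(comm.hellinger(cons)).to_numpy()
            design = tr["design"]
            labels = np.array([design.site_of(m) for m in cons.index])
            iu = np.triu_indices(len(labels), 1)
            same = labels[iu[0]] == labels[iu[1]]
            diffs.append(dm[iu][~same].mean() - dm[iu][same].mean())
        assert abs(np.mean(diffs)) < 0.02

    def test_site_structure_detected_by_anosim(self):
        from photomat import community as comm

        cfg = SimConfig(mats_per_site=4, shared_fraction=0.2)
        profiles, tr = simulate_community(cfg, seed=7)
        cons = comm.consensus_profile(comm.bin_fragments(profiles))
        dm = comm.bray_curtis(comm.hellinger(cons))
        design = tr["design"]
        res = comm.anosim(dm, [design.site_of(m) for m in dm.index],
                          n_permutations=999, seed=1)
        assert res.p < 0.05

    def test_zero_detection_probability_rejected(self):
        with pytest.raises(ValidationError):
            SimConfig(detection_p=0.0)

    def test_jittered_fragments_mostly_map_to_one_bin(self):
        from photomat.community import bin_fragments

        cfg = SimConfig(mats_per_site=2, jitter_p=0.3)
        profiles, tr = simulate_community(cfg, seed=11)
        binned = bin_fragments(profiles, window=2)
        # each truth OTU should put >= 50% of its intensity into one bin
        ok = 0
        total = 0
        edges = np.asarray(binned.columns, dtype=float)
        for mat, otus in tr["membership"].items():
            sub = profiles[profiles["sample"] == mat]
            for L in otus:
                near = sub[np.abs(sub["fragment_bp"] - L) <= 1]
                if near.empty:
                    continue
                total += 1
                bins = 100 + 2 * np.floor((near["fragment_bp"] - 100) / 2)
                share = near.groupby(bins)["intensity"].sum()
                if share.max() / share.sum() >= 0.5:
                    ok += 1
        assert total > 100
        assert ok / total >= 0.95
        assert set(np.unique(100 + 2 * np.floor(
            (profiles["fragment_bp"] - 100) / 2))) <= set(edges.tolist())


class TestGenerateStudy:
    def test_site_levels_separate_in_linked_mode(self):
        cfg = SimConfig(shape=(16, 16), layer_rows=12, mats_per_site=3)
        design, truths = generate_study(cfg, seed=5)
        m = {mat: t.y_max[t.layer.mask].mean() for mat, t in truths.items()}
        by_site = {
            s: np.mean([m[x] for x in design.mats if design.site_of(x) == s])
            for s in design.sites
        }
        assert by_site["AU"] > 1.4 * by_site["AD"]
        assert by_site["BR"] > 1.4 * by_site["SP"]

    def test_default_design_matches_survey_replicates(self):
        design = SimConfig().design()
        counts = design.table.groupby("site_id").size().to_dict()
        assert counts == {"AD": 13, "AU": 8, "BR": 2, "SP": 2}

    def test_ladder_default_is_twelve_light_steps(self):
        ladder = np.asarray(DEFAULT_LADDER)
        assert ladder[0] == 0 and len(ladder) == 13
        assert ladder[-1] == 1700
        assert np.all(np.diff(ladder) > 0)
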