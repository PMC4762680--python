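"""The generator must deliver exactly the ground truth it promises."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from drusenkit import (
    CohortParams,
    Druse,
    DrusenChanges,
    GAPatch,
    SimImageParams,
    VisitTransform,
    generate_cohort,
    generate_fundus_pair,
)


class TestFundusPair:
    def test_constant_background_identity_case(self):
        params = SimImageParams(
            shape=(64, 64),
            background_coeffs=((42.0, 0, 0, 0, 0, 0),),
            noise_sd=0.0,
        )
        baseline, final, truth = generate_fundus_pair(params, seed=0)
        np.testing.assert_allclose(baseline.data, 42.0)
        np.testing.assert_allclose(final.data, 42.0)
        assert not truth.drusen_mask_baseline.any()

    def test_disk_druse_mask_area_matches_analytic_disk(self):
        # radius 100 µm at 10 µm/px -> half-maximum support ≈ π·10² = 314 px
        params = SimImageParams(
            shape=(64, 64),
            scale_um_per_px=10.0,
            background_coeffs=((50.0, 0, 0, 0, 0, 0),),
            noise_sd=0.0,
            drusen=(Druse((32.0, 32.0), (100.0, 100.0), 80.0),),
        )
        _, _, truth = generate_fundus_pair(params, seed=0)
        area_px = truth.drusen_mask_baseline.sum()
        assert abs(area_px - np.pi * 100) <= 0.05 * np.pi * 100
        # and the mask is exactly the set of pixels at >= half the peak
        assert truth.druse_areas_baseline_um2[0] == pytest.approx(np.pi * 100**2)

    def test_seed_contract(self):
        params = SimImageParams(shape=(48, 48), noise_sd=2.0,
                                drusen=(Druse((24.0, 24.0), (150.0, 150.0), 30.0),))
        a1, f1, _ = generate_fundus_pair(params, seed=7)
        a2, f2, _ = generate_fundus_pair(params, seed=7)
        a3, _, _ = generate_fundus_pair(params, seed=8)
        np.testing.assert_array_equal(a1.data, a2.data)
        np.testing.assert_array_equal(f1.data, f2.data)
        assert not np.array_equal(a1.data, a3.data)

    def test_druse_outside_raster_rejected(self):
        params = SimImageParams(
            shape=(64, 64), scale_um_per_px=10.0,
            drusen=(Druse((2.0, 32.0), (100.0, 100.0), 30.0),),
        )
        with pytest.raises(ValueError, match="outside"):
            generate_fundus_pair(params, seed=0)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError, match="semi-axes"):
            generate_fundus_pair(
                SimImageParams(drusen=(Druse((50.0, 50.0), (0.0, 100.0), 10.0),)), 0
            )
        with pytest.raises(ValueError, match="invertible|nonzero"):
            generate_fundus_pair(
                SimImageParams(transform=VisitTransform(scale=0.0)), 0
            )

    def test_area_conservation_across_visits(self):
        drusen = tuple(
            Druse((r, c), (150.0, 120.0), 30.0)
            for r, c in [(30.0, 30.0), (30.0, 96.0), (96.0, 30.0), (96.0, 96.0)]
        )
        changes = DrusenChanges(
            removed=(0,),
            grown={1: 1.2},
            added=(Druse((64.0, 64.0), (140.0, 140.0), 30.0),),
        )
        params = SimImageParams(shape=(128, 128), drusen=drusen, changes=changes, noise_sd=0.0)
        _, _, truth = generate_fundus_pair(params, seed=0)
        base_total = sum(truth.druse_areas_baseline_um2)
        removed = truth.druse_areas_baseline_um2[0]
        growth_gain = truth.druse_areas_baseline_um2[1] * (1.2**2 - 1.0)
        added = changes.added[0].area_um2
        assert sum(truth.druse_areas_final_um2) == pytest.approx(
            base_total - removed + added + growth_gain
        )

    def test_final_visit_geometry_follows_transform(self):
        params = SimImageParams(
            shape=(128, 128),
            noise_sd=0.0,
            drusen=(Druse((50.0, 70.0), (200.0, 200.0), 50.0),),
            transform=VisitTransform(rotation_deg=0.0, translation_px=(6.0, -4.0)),
        )
        _, final, truth = generate_fundus_pair(params, seed=0)
        # truth mask in the final frame is the baseline mask shifted by (6, -4)
        shifted = np.roll(truth.drusen_mask_baseline, (6, -4), axis=(0, 1))
        assert (shifted ^ truth.drusen_mask_final).sum() <= 8  # boundary pixels only
        assert final.fovea_px == (63.5 + 6.0, 63.5 - 4.0)

    def test_ga_patch_marks_final_mask(self):
        params = SimImageParams(
            shape=(96, 96), scale_um_per_px=10.0, noise_sd=0.0,
            ga_patch=GAPatch((48.0, 48.0), radius_um=200.0, contrast=40.0),
        )
        _, final, truth = generate_fundus_pair(params, seed=0)
        area = truth.ga_mask_final.sum()
        assert abs(area - np.pi * 20**2) < 0.05 * np.pi * 20**2
        assert final.data[48, 48] > 100  # patch contrast present


class TestCohort:
    def test_zero_effects_zero_residual_gives_zero_deltas(self):
        params = CohortParams(
            n=50, age_diameter_corr=0.0, gender_shift=0.0, cfh_tt_shift=0.0,
            treatment_shift=0.0, residual_scale=0.0, seed=3,
        )
        df = generate_cohort(params)
        delta_cols = [c for c in df.columns if c.startswith("delta_")]
        assert (df[delta_cols] == 0).all().all()
        pd.testing.assert_frame_equal(df, generate_cohort(params))

    def test_age_correlation_recovered_at_large_n(self):
        params = CohortParams(
            n=10_000, age_diameter_corr=-0.17, gender_shift=0.0,
            cfh_tt_shift=0.0, seed=1,
        )
        df = generate_cohort(params)
        r = np.corrcoef(df["age"], df["delta_diameter_inner"])[0, 1]
        assert abs(r - (-0.17)) < 0.03

    def test_allocation_conservation(self):
        df = generate_cohort(CohortParams(n=167, seed=0))
        assert len(df) == 167
        assert df["arm"].isin(["treated", "placebo"]).all()
        assert df["arm"].value_counts().sum() == 167

    def test_marginals_converge(self):
        n = 10_000
        df = generate_cohort(CohortParams(n=n, seed=2))
        p = CohortParams()
        assert abs((df["gender"] == "female").mean() - p.prop_female) < 3 * np.sqrt(
            p.prop_female * (1 - p.prop_female) / n
        )
        assert abs(df["age"].mean() - p.age_mean) < 3 * p.age_sd / np.sqrt(n)
        tt = (df["cfh"] == "TT").mean()
        assert abs(tt - p.cfh_freqs[2]) < 3 * np.sqrt(p.cfh_freqs[2] * (1 - p.cfh_freqs[2]) / n)

    def test_field_additivity_by_construction(self):
        df = generate_cohort(CohortParams(n=200, seed=4))
        for m in ("number", "diameter", "area"):
            np.testing.assert_allclose(
                df[f"delta_{m}_all"],
                df[f"delta_{m}_inner"] + df[f"delta_{m}_middle"] + df[f"delta_{m}_outer"],
            )

    @pytest.mark.parametrize(
        "bad",
        [
            dict(n=1),
            dict(allocation=1.5),
            dict(cfh_freqs=(0.5, 0.5, 0.5)),
            dict(age_diameter_corr=1.0),
        ],
    )
    def test_invalid_cohort_params(self, bad):
        with pytest.raises(ValueError):
            generate_cohort(dataclasses.replace(CohortParams(), **bad))
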