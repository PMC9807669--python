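"""Integrated power, per-animal normalization, Naka-Rushton fitting."""

import numpy as np
import pandas as pd
import pytest

from conftest import grid_search_naka_rushton
from vepscope import (
    CONTROL,
    DKO,
    AveragedWaveform,
    fit_naka_rushton,
    fit_response_table,
    naka_rushton,
    normalize_by_animal,
    vep_power,
)

FS = 50_000.0
ONSET = 0.2


def make_avg(trace):
    return AveragedWaveform(
        trace=np.asarray(trace, dtype=float), sample_rate_hz=FS, onset_s=ONSET,
        n_included=1, n_excluded=0, baseline_uv=0.0,
    )


class TestVepPower:
    def test_constant_one_microvolt(self):
        power = vep_power(make_avg(np.full(40_000, 1.0)))
        assert power == pytest.approx(4e-13, rel=1e-6)

    def test_zero_trace(self):
        assert vep_power(make_avg(np.zeros(40_000))) == 0.0

    def test_sinusoid_closed_form(self):
        # 100 uV sine with an integer number of periods in the 0.4 s
        # window -> mean square A^2/2, power = (1e-4)^2/2 * 0.4
        t = np.arange(40_000) / FS - ONSET
        trace = 100.0 * np.sin(2 * np.pi * 50.0 * t)  # 20 periods in 0.4 s
        assert vep_power(make_avg(trace)) == pytest.approx(2e-9, rel=1e-3)

    def test_record_too_short_rejected(self):
        with pytest.raises(ValueError):
            vep_power(make_avg(np.zeros(25_000)))  # only 0.3 s past onset

    def test_power_non_negative(self):
        rng = np.random.default_rng(0)
        assert vep_power(make_avg(rng.normal(0, 30, 40_000))) >= 0.0


class TestNormalizeByAnimal:
    def test_simple_ratios(self):
        df = pd.DataFrame(
            {"animal_id": ["m1"] * 3, "dose_photons_um2": [1.0, 2.0, 3.0],
             "power_v2s": [1.0, 2.0, 4.0]}
        )
        out = normalize_by_animal(df)
        np.testing.assert_allclose(out["normalized_power"], [0.25, 0.5, 1.0])

    def test_single_point_normalizes_to_one(self):
        df = pd.DataFrame({"animal_id": ["m1"], "power_v2s": [0.37]})
        assert normalize_by_animal(df)["normalized_power"].iloc[0] == 1.0

    def test_animals_normalized_independently(self):
        rng = np.random.default_rng(12)
        df = pd.DataFrame(
            {
                "animal_id": np.repeat(["m1", "m2", "m3"], 5),
                "power_v2s": rng.uniform(0.1, 10.0, 15),
            }
        )
        out = normalize_by_animal(df)
        # brute-force per-group maxima
        for animal, grp in out.groupby("animal_id"):
            expected = grp["power_v2s"] / grp["power_v2s"].max()
            np.testing.assert_allclose(grp["normalized_power"], expected)
            assert grp["normalized_power"].max() == 1.0

    def test_all_zero_animal_flagged(self):
        df = pd.DataFrame(
            {"animal_id": ["m1", "m1", "m2"], "power_v2s": [0.0, 0.0, 1.0]}
        )
        with pytest.warns(UserWarning, match="m1"):
            out = normalize_by_animal(df)
        assert out.loc[out.animal_id == "m1", "normalized_power"].isna().all()
        assert out.loc[out.animal_id == "m2", "normalized_power"].notna().all()


class TestNakaRushtonFit:
    @pytest.mark.parametrize("preset", [CONTROL, DKO], ids=["control", "dko"])
    def test_noiseless_recovery_within_one_permille(self, preset):
        doses = np.logspace(3, 7, 12)
        r = naka_rushton(doses, preset.i50_photons_um2, preset.slope)
        fit = fit_naka_rushton(doses, r)
        assert fit.converged and fit.reliable
        assert fit.i50 == pytest.approx(preset.i50_photons_um2, rel=1e-3)
        assert fit.slope == pytest.approx(preset.slope, rel=1e-3)

    def test_half_maximal_response_at_i50(self):
        for slope in (0.1, 0.5, 1.0, 2.7):
            assert naka_rushton(1e4, 1e4, slope) == pytest.approx(0.5)

    def test_agrees_with_grid_search_oracle(self):
        doses = np.logspace(3.2, 6.8, 8)
        r = naka_rushton(doses, 5e4, 0.6) + np.array(
            [0.02, -0.03, 0.01, 0.0, -0.02, 0.03, -0.01, 0.02]
        )
        fit = fit_naka_rushton(doses, r)
        i50_g, slope_g, rss_g = grid_search_naka_rushton(doses, r)
        assert np.log10(fit.i50) == pytest.approx(np.log10(i50_g), abs=2e-3)
        assert fit.slope == pytest.approx(slope_g, abs=2e-3)
        assert fit.rss <= rss_g + 1e-12

    def test_scale_equivariance_in_intensity(self):
        doses = np.logspace(3, 7, 10)
        r = naka_rushton(doses, 2e4, 0.8)
        c = 10.0
        fit1 = fit_naka_rushton(doses, r)
        fit2 = fit_naka_rushton(c * doses, r)
        assert fit2.i50 == pytest.approx(c * fit1.i50, rel=1e-6)
        assert fit2.slope == pytest.approx(fit1.slope, rel=1e-6)

    def test_fitted_curve_strictly_increasing(self):
        doses = np.logspace(3, 7, 12)
        fit = fit_naka_rushton(doses, naka_rushton(doses, 1e5, 0.7))
        grid = np.logspace(2, 8, 200)
        assert np.all(np.diff(fit.predict(grid)) > 0)

    def test_degenerate_equal_responses_flagged_not_raised(self):
        doses = np.logspace(3, 7, 6)
        fit = fit_naka_rushton(doses, np.full(6, 0.4))
        assert not fit.converged
        assert fit.i50 > 0 and fit.slope > 0

    def test_sparse_data_flagged_unreliable(self):
        fit = fit_naka_rushton(np.array([1e4, 2e4]), np.array([0.3, 0.6]))
        assert not fit.reliable

    def test_noisy_recovery_median_within_ten_percent(self):
        """Gaussian noise (sd 0.05) on R: median recovered parameters
        over 200 seeded replicates stay within 10% of truth."""
        doses = np.logspace(3, 7, 12)
        true = naka_rushton(doses, 7.87e5, 0.817)
        rng = np.random.default_rng(2024)
        i50s, slopes = [], []
        for _ in range(200):
            fit = fit_naka_rushton(doses, true + rng.normal(0, 0.05, doses.size))
            i50s.append(fit.i50)
            slopes.append(fit.slope)
        assert np.median(i50s) == pytest.approx(7.87e5, rel=0.10)
        assert np.median(slopes) == pytest.approx(0.817, rel=0.10)

    def test_pooled_fit_of_mixed_genotypes_lies_between_presets(self):
        """A pooled fit over combined control + DKO data lands between
        the two generating parameter sets."""
        doses = np.logspace(3, 7, 12)
        i = np.concatenate([doses, doses])
        r = np.concatenate(
            [
                naka_rushton(doses, CONTROL.i50_photons_um2, CONTROL.slope),
                naka_rushton(doses, DKO.i50_photons_um2, DKO.slope),
            ]
        )
        fit = fit_naka_rushton(i, r)
        assert CONTROL.i50_photons_um2 < fit.i50 < DKO.i50_photons_um2
        assert CONTROL.slope < fit.slope < DKO.slope


class TestFitResponseTable:
    def test_pooled_and_per_animal_modes(self):
        doses = np.logspace(3, 7, 9)
        rows = []
        for animal in ("m1", "m2"):
            for d in doses:
                rows.append(
                    {"animal_id": animal, "dose_photons_um2": d,
                     "normalized_power": naka_rushton(d, 1e4, 0.5)}
                )
        df = pd.DataFrame(rows)
        pooled = fit_response_table(df, mode="pooled")
        assert len(pooled) == 1 and pooled.loc[0, "scope"] == "pooled"
        per = fit_response_table(df, mode="per_animal")
        assert set(per["animal_id"]) == {"m1", "m2"}
        assert per["reliable"].all()

    def test_sparse_animal_reported_but_unreliable(self):
        df = pd.DataFrame(
            {
                "animal_id": ["m1"] * 3,
                "dose_photons_um2": [1e3, 1e5, 1e7],
                "normalized_power": [0.2, 0.5, 1.0],
            }
        )
        per = fit_response_table(df, mode="per_animal", min_intensities_per_animal=4)
        assert len(per) == 1
        assert not per.loc[0, "reliable"]

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            fit_response_table(pd.DataFrame(), mode="bogus")
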