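"""Line-intensity measurement, confidence-band threshold and classification."""

import numpy as np
import pandas as pd
import pytest

from striacal import immuno, synth
from striacal.errors import FitError, InputError
from striacal.immuno import (
    BandModel,
    classify,
    fit_band,
    fit_band_xy,
    population_summary,
    responder_fraction,
    somatic_intensity,
)


class TestSomaticIntensity:
    def test_constant_image(self):
        image = np.full((20, 20), 7.5)
        line = np.stack([np.full(10, 10), np.arange(10)], axis=1)
        assert somatic_intensity(image, line) == pytest.approx(7.5)

    def test_hot_pixel_diluted_by_running_average(self):
        image = np.zeros((20, 20))
        image[10, 10] = 70.0
        line = np.stack([np.full(15, 10), np.arange(3, 18)], axis=1)
        assert somatic_intensity(image, line) == pytest.approx(10.0)

    def test_matches_hand_computed_profile(self, rng):
        image = rng.uniform(0, 100, size=(30, 30))
        line = np.stack([np.full(20, 15), np.arange(5, 25)], axis=1)
        profile = [image[15, c] for c in range(5, 25)]
        best = max(
            sum(profile[i : i + 7]) / 7 for i in range(len(profile) - 6)
        )
        assert somatic_intensity(image, line) == pytest.approx(best)

    def test_short_line_errors(self):
        with pytest.raises(InputError):
            somatic_intensity(np.zeros((5, 5)), np.array([[1, 1], [1, 2]]))


class TestFitBand:
    def test_exact_line_gives_degenerate_band(self):
        x = np.linspace(2.0, 3.0, 30)
        y = 10.0 + 5.0 * x
        band = fit_band_xy(x, y)
        assert band.residual_sd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(band.upper_limit(x), y, atol=1e-6)

    def test_halfwidth_minimal_at_mean_area(self, rng):
        x = rng.uniform(2.0, 3.0, 100)
        y = 100 + 50 * x + rng.normal(0, 10, 100)
        band = fit_band_xy(x, y)
        grid = np.linspace(x.min(), x.max(), 50)
        hw = band.band_halfwidth(grid)
        assert np.argmin(hw) == np.argmin(np.abs(grid - x.mean()))
        assert hw[0] > hw.min() and hw[-1] > hw.min()

    def test_coverage_near_nominal(self, rng):
        """Monte-Carlo: the simultaneous band contains the entire true line
        in ~95% of replicates (10^4-replicate check lives in acceptance)."""
        inside = 0
        reps = 600
        for _ in range(reps):
            x = rng.uniform(2.0, 2.93, 100)
            y = -150 + 180 * x + rng.normal(0, 40, 100)
            inside += fit_band_xy(x, y).contains_line(-150.0, 180.0)
        assert inside / reps == pytest.approx(0.95, abs=0.03)

    def test_too_few_controls_errors(self):
        with pytest.raises(FitError):
            fit_band_xy(np.arange(5.0), np.arange(5.0))

    def test_zero_area_variance_errors(self):
        with pytest.raises(FitError):
            fit_band_xy(np.full(20, 2.5), np.arange(20.0))

    def test_fit_band_uses_only_antibody_absent_rows(self):
        pop = synth.simulate_immuno(synth.ImmunoPopulationParams(seed=8))
        band = fit_band(pop, "GAD65")
        assert band.n_control == (~pop.primary_antibody_present).sum()


@pytest.fixture(scope="module")
def classified():
    pop = synth.simulate_immuno(
        synth.ImmunoPopulationParams(n_cells=1000, seed=3)
    )
    controls = pop[~pop.primary_antibody_present]
    bands = {m: fit_band(controls, m) for m in synth.MARKERS}
    stained = pop[pop.primary_antibody_present]
    return classify(stained, bands), bands


def classify_mixture(seed, n_cells=120):
    pop = synth.simulate_immuno(
        synth.ImmunoPopulationParams(n_cells=n_cells, seed=seed)
    )
    controls = pop[~pop.primary_antibody_present]
    bands = {m: fit_band(controls, m) for m in synth.MARKERS}
    calls = classify(pop[pop.primary_antibody_present], bands)
    return population_summary(calls, area_gate=None).set_index("cell_type")


class TestClassify:

    def test_intensity_at_threshold_is_negative(self):
        band = BandModel(slope=0.0, intercept=100.0, residual_sd=10.0,
                         n_control=50, x_mean=2.5, sxx=10.0)
        records = pd.DataFrame(
            {"area_um2": [10**2.5], "GAD65": band.upper_limit(2.5)}
        )
        calls = classify(records, {"GAD65": band})
        assert not calls["GAD65_positive"].iloc[0]

    def test_ground_truth_agreement(self, classified):
        calls, _ = classified
        agreement = (calls.cell_type == calls.true_class).mean()
        assert agreement >= 0.97

    def test_table_fractions_within_binomial_ci(self):
        """Recovered class proportions of mixtures at the reference sample
        size (n = 120) sit within the binomial 95% CI of the true 95/4/1
        fractions; the median over replicate mixtures isolates the systematic
        part from single-draw multinomial noise."""
        summaries = [classify_mixture(seed) for seed in range(5)]
        n = 120
        for label, frac in zip(synth.CLASS_LABELS, (0.95, 0.04, 0.01)):
            recovered = np.median([s.loc[label, "percent"] for s in summaries])
            half = 1.96 * np.sqrt(frac * (1 - frac) / n) * 100
            assert abs(recovered - 100 * frac) <= half + 1e-9

    def test_monotonic_in_intensity(self, classified):
        _, bands = classified
        band = bands["GAD65"]
        areas = np.full(50, 250.0)
        grid = np.linspace(0, 2000, 50)
        records = pd.DataFrame({"area_um2": areas, "GAD65": grid})
        calls = classify(records, {"GAD65": band})["GAD65_positive"].to_numpy()
        # once positive, always positive as intensity grows
        assert np.all(np.diff(calls.astype(int)) >= 0)

    def test_missing_marker_flagged_unclassified(self, classified):
        _, bands = classified
        records = pd.DataFrame({"area_um2": [250.0], "GAD65": [5000.0]})
        calls = classify(records, bands)
        assert calls["cell_type"].iloc[0] == "unclassified"
        assert pd.isna(calls["DARPP32_positive"].iloc[0])


class TestPopulationSummary:
    def test_printed_count_percentages(self):
        calls = pd.DataFrame(
            {
                "area_um2": np.full(120, 300.0),
                "cell_type": ["MSN"] * 114 + ["GABA_interneuron"] * 3
                + ["unclassified"] * 3,
            }
        )
        summary = population_summary(calls).set_index("cell_type")
        assert summary.loc["MSN", "percent"] == pytest.approx(95.0)
        assert summary.loc["GABA_interneuron", "percent"] == pytest.approx(2.5)

    def test_heterozygous_style_counts(self):
        calls = pd.DataFrame(
            {
                "area_um2": np.full(96, 300.0),
                "cell_type": ["MSN"] * 89 + ["GABA_interneuron"] * 5
                + ["unclassified"] * 2,
            }
        )
        summary = population_summary(calls).set_index("cell_type")
        assert summary.loc["MSN", "percent"] == pytest.approx(92.7, abs=0.05)
        assert summary.loc["GABA_interneuron", "percent"] == pytest.approx(
            5.2, abs=0.05
        )

    def test_single_class_is_hundred_percent(self):
        calls = pd.DataFrame(
            {"area_um2": [200.0, 300.0], "cell_type": ["MSN", "MSN"]}
        )
        summary = population_summary(calls).set_index("cell_type")
        assert summary.loc["MSN", "percent"] == 100.0
        assert summary.loc["cholinergic", "count"] == 0

    def test_area_gate_filters(self):
        calls = pd.DataFrame(
            {"area_um2": [100.0, 300.0, 900.0], "cell_type": ["MSN"] * 3}
        )
        summary = population_summary(calls, area_gate=(158.0, 537.0))
        assert summary["total"].iloc[0] == 1

    def test_empty_gate_warns(self):
        calls = pd.DataFrame({"area_um2": [50.0], "cell_type": ["MSN"]})
        with pytest.warns(UserWarning):
            out = population_summary(calls, area_gate=(158.0, 537.0))
        assert out.empty


class TestResponderFraction:
    def test_reference_counts(self):
        # 37 responders out of 43 gated -> 86%; 37 of 46 -> 80.4%
        areas = np.concatenate([np.linspace(158, 537, 37), [200] * 6, [100] * 4])
        responded = np.array([True] * 37 + [False] * 10)
        res = responder_fraction(areas, responded)
        assert res.gate == pytest.approx(158.0)
        assert res.n_gated == 43
        assert res.percent == pytest.approx(86.0, abs=0.1)

        areas2 = np.concatenate([np.linspace(158, 537, 37), [200] * 9])
        responded2 = np.array([True] * 37 + [False] * 9)
        res2 = responder_fraction(areas2, responded2)
        assert res2.n_gated == 46
        assert res2.percent == pytest.approx(80.4, abs=0.1)

    def test_all_respond(self):
        res = responder_fraction(np.array([200.0, 300.0]), np.array([True, True]))
        assert res.percent == 100.0

    def test_gate_invariance_to_small_non_responders(self, rng):
        areas = np.linspace(160, 500, 30)
        responded = rng.random(30) < 0.8
        responded[0] = True  # anchor the gate
        base = responder_fraction(areas, responded)
        extra_areas = np.concatenate([areas, [50.0, 80.0, 120.0]])
        extra_resp = np.concatenate([responded, [False, False, False]])
        augmented = responder_fraction(extra_areas, extra_resp)
        assert augmented.fraction == base.fraction
        assert augmented.n_gated == base.n_gated

    def test_no_responders_errors(self):
        with pytest.raises(InputError):
            responder_fraction(np.array([200.0]), np.array([False]))
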