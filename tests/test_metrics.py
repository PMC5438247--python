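import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import odorcode as oc
from odorcode.metrics import (PSTHConfig, auroc, classify_polarity,
                              compute_kdf, peak_and_duration,
                              polarity_matrix, response_index, sparseness,
                              synchrony_ratio, total_spiking_output,
                              tuning_shuffle_null)


def _pair_count_auroc(x, y):
    """Exhaustive pair-counting oracle: wins + half-ties over all pairs."""
    score = 0.0
    for a, b in itertools.product(x, y):
        score += 1.0 if a > b else (0.5 if a == b else 0.0)
    return score / (len(x) * len(y))


class TestKDF:
    def test_no_spikes_gives_zero_function(self):
        grid, rate = compute_kdf([np.empty(0), np.empty(0)])
        assert np.all(rate == 0)
        assert np.isnan(peak_and_duration(grid, rate)["peak_latency"])

    def test_single_spike_peaks_at_spike_time(self):
        grid, rate = compute_kdf([np.array([0.100])])
        assert grid[np.argmax(rate)] == pytest.approx(0.100, abs=1e-9)

    def test_two_close_spikes_peak_at_midpoint(self):
        """Analytic oracle: the sum of two equal Gaussians 4 ms apart
        peaks at the midpoint."""
        grid, rate = compute_kdf([np.array([0.100, 0.104])])
        assert grid[np.argmax(rate)] == pytest.approx(0.102, abs=1e-3)

    def test_mass_conservation_for_interior_spikes(self, rng):
        spikes = [rng.uniform(0.1, 0.4, 12) for _ in range(5)]
        grid, rate = compute_kdf(spikes)
        integral = np.trapezoid(rate, grid)
        mean_count = np.mean([len(s) for s in spikes])
        assert abs(integral - mean_count) / mean_count < 0.02

    def test_bad_config_rejected(self):
        with pytest.raises(ValueError):
            PSTHConfig(kernel_sd=0)
        with pytest.raises(ValueError):
            PSTHConfig(window=(0.5, 0.1))


class TestPeakAndDuration:
    def test_gaussian_bump_duration_closed_form(self):
        """Width at half height of a Gaussian bump is 2*sqrt(2 ln 2)*sd."""
        cfg = PSTHConfig()
        grid = cfg.grid
        rate = np.exp(-0.5 * ((grid - 0.25) / 0.010) ** 2)
        out = peak_and_duration(grid, rate)
        assert out["peak_latency"] == pytest.approx(0.25, abs=1e-3)
        assert out["duration50"] == pytest.approx(
            2 * np.sqrt(2 * np.log(2)) * 0.010, rel=0.02)
        assert out["duration25"] == pytest.approx(
            2 * np.sqrt(2 * np.log(4)) * 0.010, rel=0.02)

    def test_monotone_rise_has_undefined_latency(self):
        cfg = PSTHConfig()
        grid = cfg.grid
        out = peak_and_duration(grid, np.linspace(0, 5, len(grid)))
        assert np.isnan(out["peak_latency"])
        assert np.isnan(out["duration50"])

    def test_taller_second_bump_wins(self):
        """Direct grid-search oracle: latency/duration belong to the
        maximal peak."""
        cfg = PSTHConfig()
        grid = cfg.grid
        rate = (np.exp(-0.5 * ((grid - 0.1) / 0.01) ** 2)
                + 2 * np.exp(-0.5 * ((grid - 0.3) / 0.02) ** 2))
        out = peak_and_duration(grid, rate)
        assert out["peak_latency"] == pytest.approx(grid[np.argmax(rate)])
        assert abs(out["peak_latency"] - 0.3) < 0.005
        assert out["duration50"] == pytest.approx(
            2 * np.sqrt(2 * np.log(2)) * 0.02, rel=0.05)

    def test_flat_function_undefined(self):
        cfg = PSTHConfig()
        out = peak_and_duration(cfg.grid, np.full(len(cfg.grid), 2.0))
        assert np.isnan(out["peak_latency"])


class TestResponseIndex:
    def test_identical_distributions_give_zero(self):
        idx, p = response_index([1, 2, 3, 4], [1, 2, 3, 4])
        assert idx == pytest.approx(0.0)
        assert p > 0.9

    def test_perfect_separation_gives_one(self):
        idx, p = response_index([5, 6, 7], [0, 1, 2])
        assert idx == pytest.approx(1.0)

    def test_worked_example_with_ties(self):
        """odor=[0,1,2] vs blank=[0,0,1]: auROC = 6.5/9."""
        assert auroc([0, 1, 2], [0, 0, 1]) == pytest.approx(6.5 / 9)
        idx, _ = response_index([0, 1, 2], [0, 0, 1])
        assert idx == pytest.approx(2 * 6.5 / 9 - 1)

    @given(st.lists(st.integers(0, 8), min_size=3, max_size=10),
           st.lists(st.integers(0, 8), min_size=3, max_size=10))
    @settings(deadline=None, max_examples=80)
    def test_auroc_matches_pair_counting_oracle(self, x, y):
        assert auroc(x, y) == pytest.approx(_pair_count_auroc(x, y))

    @given(st.lists(st.integers(0, 8), min_size=3, max_size=10),
           st.lists(st.integers(0, 8), min_size=3, max_size=10))
    @settings(deadline=None, max_examples=40)
    def test_antisymmetry(self, x, y):
        a, _ = response_index(x, y)
        b, _ = response_index(y, x)
        assert a == pytest.approx(-b)

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            response_index([], [1, 2])


class TestSparseness:
    @pytest.mark.parametrize("r,expected", [
        ([5, 0, 0, 0, 0, 0], 1.0),
        ([3, 3, 3, 3, 3, 3], 0.0),
        ([4, 2, 0, 0, 0, 0], (1 - 0.3) / (5 / 6)),  # direct formula: 0.84
    ])
    def test_closed_form_cases(self, r, expected):
        assert sparseness(r) == pytest.approx(expected)

    def test_all_zero_is_undefined(self):
        assert np.isnan(sparseness([0, 0, 0]))

    def test_negative_responses_rectified(self):
        assert sparseness([4, 2, -1, -3, 0, 0]) == \
            pytest.approx(sparseness([4, 2, 0, 0, 0, 0]))

    @given(st.lists(st.floats(0, 50).map(lambda v: 0.0 if v < 1e-6 else v),
                    min_size=2, max_size=12),
           st.floats(0.1, 10))
    @settings(deadline=None, max_examples=60)
    def test_invariant_to_positive_scaling(self, r, scale):
        if np.all(np.asarray(r) == 0):
            return
        assert sparseness(np.asarray(r) * scale) == \
            pytest.approx(sparseness(r), abs=1e-9)

    def test_single_response_rejected(self):
        with pytest.raises(ValueError):
            sparseness([1.0])


class TestSynchrony:
    def test_flat_trace_ratio_one(self):
        assert synchrony_ratio(np.full(100, 3.0)) == pytest.approx(1.0)

    def test_direct_arithmetic(self):
        assert synchrony_ratio([0, 0, 10, 0, 0]) == pytest.approx(5.0)

    def test_zero_trace_undefined(self):
        assert np.isnan(synchrony_ratio(np.zeros(10)))

    def test_synchrony_rises_with_concentration(self, medium_dataset):
        """The latency compression built into the generator makes the
        population response more synchronous at the highest
        concentration."""
        ratios = {}
        for c in (0.0003, 0.01):
            _, trace = oc.population_psth(medium_dataset, "ethyl_butyrate",
                                          c, region="PCx")
            ratios[c] = synchrony_ratio(trace)
        assert ratios[0.01] > ratios[0.0003]


class TestPolarityClassification:
    def test_definitions(self, small_stats):
        classes = classify_polarity(small_stats, concentration=0.003)
        merged = classes.merge(
            polarity_matrix(small_stats, 0.003).reset_index(), on="unit_id")
        for _, row in merged.iterrows():
            n_pos, n_neg = row["n_activated"], row["n_suppressed"]
            expected = ("mixed" if n_pos and n_neg else
                        "activated" if n_pos else
                        "suppressed" if n_neg else "unresponsive")
            assert row["cell_class"] == expected

    def test_ground_truth_recovery(self, medium_dataset, medium_stats):
        """Polarity recovery on synthetic data: >= 80% sensitivity for
        pairs that actually carry a response at the nominal
        concentration."""
        nominal = 0.003
        gt = medium_dataset.ground_truth
        gtl = medium_dataset.gt_latencies
        df = medium_stats[np.isclose(medium_stats["concentration"],
                                     nominal)]
        m = df.merge(gt, on=["unit_id", "odorant"])
        active = gtl[np.isclose(gtl["concentration"], nominal)
                     & gtl["active"]][["unit_id", "odorant"]]
        act = m.merge(active, on=["unit_id", "odorant"])
        assert (act["polarity"] == "activated").mean() >= 0.80
        sup = m[(m["label"] == "suppressed")
                & (m["suppressed_from"] <= nominal + 1e-9)]
        assert (sup["polarity"] == "suppressed").mean() >= 0.80
        null = m[m["label"] == "unresponsive"]
        assert (null["polarity"] != "none").mean() < 0.08


class TestTuningShuffle:
    def test_per_odor_counts_conserved(self, rng):
        M = (rng.random((50, 6)) < 0.2).astype(int) \
            - (rng.random((50, 6)) < 0.1).astype(int)
        import pandas as pd
        pol = pd.DataFrame(M)
        col_sums_pos = (M > 0).sum(axis=0)
        out = tuning_shuffle_null(pol, n_shuffles=20, seed=0)
        # per-odor response counts are invariant under the shuffle, so the
        # expected number of activated cell-odor pairs is conserved
        total_expected = col_sums_pos.sum() / len(M)
        total_shuffled = (out["activated_mean"] * out["k"]).sum()
        assert total_shuffled == pytest.approx(total_expected, rel=1e-9)

    def test_disjoint_classes_give_fewer_mixed_than_null(self,
                                                         medium_stats):
        """With built-in disjoint activated/suppressed cell classes, the
        observed mixed-polarity count falls below the 5th percentile of
        the identity-shuffle null."""
        pol = polarity_matrix(medium_stats, 0.003)
        M = pol.to_numpy()
        observed_mixed = int(((M > 0).any(axis=1)
                              & (M < 0).any(axis=1)).sum())
        out = tuning_shuffle_null(pol, n_shuffles=100, seed=1)
        assert observed_mixed < np.percentile(out["mixed_counts"], 5)


class TestTotalSpikingOutput:
    def test_conc_invariant_when_no_suppression_gradient(self):
        cfg = oc.SyntheticConfig(
            n_cells_pcx=80, n_cells_ob=0, n_trials_per_stimulus=8,
            n_blank_trials=8, seed=21,
            suppression_recruitment=(1.0, 1.0, 1.0, 1.0),
            suppression_gain_per_logconc=0.0,
            frac_active_per_conc=1.0)
        ds = oc.generate_dataset(cfg)
        out = total_spiking_output(ds, region="PCx")
        assert np.all(np.abs(out["normalized"] - 1) < 0.1)

    def test_output_decreases_with_concentration_by_default(self):
        """Suppression recruitment deepens with concentration, so total
        first-sniff output trends down."""
        ds = oc.generate_dataset(oc.SyntheticConfig(
            n_cells_pcx=150, n_cells_ob=0, seed=22))
        out = total_spiking_output(ds, region="PCx")
        by_conc = out.groupby("concentration")["normalized"].mean()
        assert by_conc.loc[0.0003] > by_conc.loc[0.01]
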