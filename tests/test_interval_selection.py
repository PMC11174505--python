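import itertools
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ficss.interval_selection import (
    ELMScreener,
    IntervalCombination,
    PLSScreener,
    SelectionResult,
    combine_intervals,
    estimate_unit_spectra,
    fic_ss_select,
    global_thresholds,
    partition_spectrum,
    screen_intervals,
    sensitivity_factors,
    sensitivity_segment,
)
from ficss.spectra import SpectralDataset, split_calibration_prediction
from ficss.synthetic import generate


class CountingScreener:
    """Deterministic stub: scores a subset by a function of its channels."""

    def __init__(self, score_fn=None):
        self.calls = 0
        self.score_fn = score_fn or (lambda X: 1.0)

    def crossval(self, X, Y):
        self.calls += 1
        s = float(self.score_fn(X))
        m = Y.shape[1]
        return np.full(m, s), np.full(m, 1.0 - s)


class TestPartition:
    def test_1500_channels_into_20_intervals_of_75(self):
        part = partition_spectrum(1500, 20)
        widths = [e - s for s, e in part.boundaries]
        assert widths == [75] * 20

    def test_single_interval_covers_axis(self):
        part = partition_spectrum(10, 1)
        assert part.boundaries == ((0, 10),)

    def test_remainder_goes_to_leading_intervals(self):
        part = partition_spectrum(10, 3)
        assert [e - s for s, e in part.boundaries] == [4, 3, 3]

    @pytest.mark.parametrize("p", [0, 11])
    def test_p_out_of_range(self, p):
        with pytest.raises(ValueError):
            partition_spectrum(10, p)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(1, 400), st.data())
    def test_disjoint_cover_with_near_equal_widths(self, n, data):
        p = data.draw(st.integers(1, n))
        part = partition_spectrum(n, p)
        chans = np.concatenate([part.channels(i) for i in range(p)])
        assert np.array_equal(np.sort(chans), np.arange(n))
        widths = [e - s for s, e in part.boundaries]
        assert max(widths) - min(widths) <= 1


class TestThresholdsAndScreening:
    def test_noiseless_global_fit_is_nearly_perfect(self, small_scenario):
        ds, _ = generate(small_scenario.noiseless(), seed=3)
        ds = split_calibration_prediction(ds, seed=3)
        _, r2 = global_thresholds(ds, PLSScreener())
        assert np.all(r2 > 0.99)

    def test_thresholds_deterministic(self, small_split_dataset):
        ds, _ = small_split_dataset
        a = global_thresholds(ds, PLSScreener(seed=1))
        b = global_thresholds(ds, PLSScreener(seed=1))
        np.testing.assert_array_equal(a[0], b[0])

    def test_missing_split_rejected(self, small_scenario):
        ds, _ = generate(small_scenario, seed=0)
        with pytest.raises(ValueError, match="split"):
            global_thresholds(ds)

    def test_planted_bands_survive_noise_intervals_do_not(self, small_split_dataset):
        """Intervals holding analyte bands pass the screen; baseline-only
        intervals are eliminated."""
        ds, truth = small_split_dataset
        part = partition_spectrum(ds.n_channels, 8)
        screener = ELMScreener(seed=0)
        scores = screen_intervals(ds, part, global_thresholds(ds, screener), screener)
        informative_per_interval = [
            truth.informative_mask[part.channels(i)].sum() for i in range(8)
        ]
        for s, n_inf in zip(scores, informative_per_interval):
            if n_inf == 0:
                assert not s.survived
        assert any(
            s.survived for s, n in zip(scores, informative_per_interval) if n > 0
        )

    def test_interval_exactly_at_threshold_survives(self, small_split_dataset):
        ds, _ = small_split_dataset
        part = partition_spectrum(ds.n_channels, 4)
        stub = CountingScreener()  # every subset scores rmse=1, r2=0
        thresholds = (np.full(3, 1.0), np.full(3, 0.0))
        scores = screen_intervals(ds, part, thresholds, stub)
        assert all(s.survived for s in scores)


class TestCombination:
    def test_enumerates_all_nonempty_subsets(self, small_split_dataset):
        ds, _ = small_split_dataset
        for q in (3, 10):
            part = partition_spectrum(ds.n_channels, q)
            stub = CountingScreener(lambda X: 0.5)
            combine_intervals(ds, part, range(q), stub, q_cap=10)
            assert stub.calls == 2**q - 1

    def test_returned_subset_attains_exhaustive_minimum(self, small_split_dataset):
        ds, _ = small_split_dataset
        part = partition_spectrum(ds.n_channels, 6)
        screener = ELMScreener(seed=2)
        best = combine_intervals(ds, part, range(6), screener, q_cap=6)
        cal = ds.calibration()
        sd = cal.targets.std(axis=0)
        aggs = {}
        for t in range(1, 7):
            for members in itertools.combinations(range(6), t):
                ch = part.union(members)
                r, _ = screener.crossval(cal.absorbance[:, ch], cal.targets)
                aggs[members] = float(np.mean(r / sd))
        assert best.rmse == pytest.approx(min(aggs.values()))

    def test_tie_breaks_to_fewer_channels_then_lower_ids(self, small_split_dataset):
        ds, _ = small_split_dataset
        part = partition_spectrum(ds.n_channels, 4)
        best = combine_intervals(ds, part, range(4), CountingScreener(), q_cap=4)
        assert best.members == (0,)

    def test_single_survivor_returned(self, small_split_dataset):
        ds, _ = small_split_dataset
        part = partition_spectrum(ds.n_channels, 5)
        best = combine_intervals(ds, part, [2], ELMScreener(), q_cap=5)
        assert best.members == (2,)

    def test_cap_requires_ranking(self, small_split_dataset):
        ds, _ = small_split_dataset
        part = partition_spectrum(ds.n_channels, 8)
        with pytest.raises(ValueError, match="q_cap"):
            combine_intervals(ds, part, range(8), CountingScreener(), q_cap=3)


class TestUnitSpectra:
    def test_exact_recovery_in_noiseless_mixture(self, small_scenario):
        ds, truth = generate(small_scenario.noiseless(), seed=5)
        S = estimate_unit_spectra(ds)
        np.testing.assert_allclose(S, truth.unit_spectra, atol=1e-8)

    def test_non_absorbing_analyte_gets_zero_row(self):
        rng = np.random.default_rng(4)
        conc = rng.uniform(0.5, 2.0, size=(30, 2))
        s1 = np.exp(-0.5 * ((np.arange(40) - 20) / 5.0) ** 2)
        A = np.outer(conc[:, 0], s1)
        ds = SpectralDataset(
            wavenumbers=np.arange(40.0),
            absorbance=A,
            targets=conc,
            analyte_names=["a", "b"],
            sample_ids=[f"s{i}" for i in range(30)],
        )
        S = estimate_unit_spectra(ds, include_offset=False)
        np.testing.assert_allclose(S[0], s1, atol=1e-8)
        np.testing.assert_allclose(S[1], 0, atol=1e-8)

    def test_baseline_biases_estimates_unless_offset_included(self, small_scenario):
        sc = replace(
            small_scenario.noiseless(), baseline_coeffs=(0.15, 0.0, 0.0)
        )
        ds, truth = generate(sc, seed=6)
        biased = estimate_unit_spectra(ds, include_offset=False)
        corrected = estimate_unit_spectra(ds, include_offset=True)
        assert np.abs(biased - truth.unit_spectra).max() > 0.01
        np.testing.assert_allclose(corrected, truth.unit_spectra, atol=1e-6)

    def test_collinear_concentrations_rejected(self):
        conc = np.outer(np.linspace(1, 2, 10), [1.0, 2.0])
        ds = SpectralDataset(
            wavenumbers=np.arange(5.0),
            absorbance=np.ones((10, 5)),
            targets=conc,
            analyte_names=["a", "b"],
            sample_ids=[f"s{i}" for i in range(10)],
        )
        with pytest.raises(ValueError, match="collinear"):
            estimate_unit_spectra(ds)


class TestSensitivityFactors:
    def test_single_absorber_gets_factor_one(self):
        S = np.array([[1.0, 0.0], [0.0, 0.0]])
        prof = sensitivity_factors(S)
        assert prof.alpha[0, 0] == 1.0 and prof.alpha[1, 0] == 0.0
        assert prof.zero_channels[1]

    def test_equal_absorbers_share_equally(self):
        S = np.ones((4, 3))
        prof = sensitivity_factors(S)
        np.testing.assert_allclose(prof.alpha, 0.25)

    def test_negative_unit_spectra_rejected(self):
        with pytest.raises(ValueError):
            sensitivity_factors(np.array([[-0.1, 1.0]]))

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(1, 5), st.integers(1, 30), st.integers(0, 10_000))
    def test_normalization_sums_to_one_at_absorbing_channels(self, m, k, seed):
        rng = np.random.default_rng(seed)
        S = rng.uniform(0, 1, size=(m, k)) * (rng.uniform(size=(m, k)) > 0.3)
        prof = sensitivity_factors(S)
        sums = prof.alpha.sum(axis=0)
        absorbing = ~prof.zero_channels
        np.testing.assert_allclose(sums[absorbing], 1.0, atol=1e-12)
        np.testing.assert_allclose(sums[~absorbing], 0.0)
        assert prof.alpha.min() >= 0 and prof.alpha.max() <= 1


class TestSensitivitySegment:
    def _partition(self):
        return partition_spectrum(8, 2)  # two intervals of 4 channels

    def _combo(self, members=(0, 1)):
        return IntervalCombination(
            members=members,
            rmse=0.0,
            per_analyte_rmse=np.zeros(2),
            per_analyte_r2=np.ones(2),
        )

    def test_uniform_alpha_keeps_every_channel(self):
        prof = sensitivity_factors(np.ones((2, 8)))
        res = sensitivity_segment(self._partition(), self._combo(), prof)
        assert np.array_equal(res.selected, np.arange(8))

    def test_interferent_dominated_channel_removed(self):
        # three components; the third is a non-target interferent that owns
        # channel 2 entirely, pushing the target factors below their means
        S = np.ones((3, 8)) * np.array([[0.5], [0.5], [0.05]])
        S[0, 2], S[1, 2], S[2, 2] = 0.02, 0.02, 2.0
        prof = sensitivity_factors(S)
        res = sensitivity_segment(
            self._partition(), self._combo(), prof, analytes=[0, 1]
        )
        assert 2 not in res.selected
        assert len(res.selected) == 7

    def test_output_subset_of_combination(self, small_split_dataset):
        ds, _ = small_split_dataset
        part = partition_spectrum(ds.n_channels, 8)
        S = estimate_unit_spectra(ds)
        prof = sensitivity_factors(S)
        combo = self._combo(members=(1, 2))
        combo.per_analyte_rmse = np.zeros(3)
        res = sensitivity_segment(part, combo, prof)
        assert set(res.selected) <= set(part.union((1, 2)))

    def test_empty_combination_rejected(self):
        prof = sensitivity_factors(np.ones((2, 8)))
        with pytest.raises(ValueError):
            sensitivity_segment(self._partition(), self._combo(members=()), prof)


class TestFullPipeline:
    def test_provenance_is_monotone_chain(self, small_split_dataset):
        ds, _ = small_split_dataset
        res = fic_ss_select(ds, p=8, screener=ELMScreener(seed=1), q_cap=8)
        prov = res.provenance
        part = partition_spectrum(ds.n_channels, 8)
        survivors = set(np.concatenate([part.channels(i) for i in prov["survivor_ids"]]))
        combo = set(prov["combination_channels"])
        assert set(res.selected) <= combo <= survivors <= set(range(ds.n_channels))
        assert set(prov["combination_members"]) <= set(prov["survivor_ids"])

    def test_deterministic_given_screener_seed(self, small_split_dataset):
        ds, _ = small_split_dataset
        a = fic_ss_select(ds, p=8, screener=ELMScreener(seed=3), q_cap=8)
        b = fic_ss_select(ds, p=8, screener=ELMScreener(seed=3), q_cap=8)
        assert np.array_equal(a.selected, b.selected)
        assert a.stats == b.stats

    def test_per_channel_degeneracy_warns_but_runs(self, small_split_dataset):
        ds, _ = small_split_dataset
        tiny = ds.select_channels(np.arange(40, 60))  # keep it desk-sized
        # stub screener: single-channel subsets score better than the
        # 20-channel global model, so per-channel screening has survivors
        stub = CountingScreener(lambda X: 0.5 if X.shape[1] <= 2 else 0.9)
        with pytest.warns(UserWarning, match="per-channel"):
            res = fic_ss_select(tiny, p=20, screener=stub, q_cap=3)
        assert len(res.selected) >= 1

    def test_json_roundtrip(self, small_split_dataset):
        ds, _ = small_split_dataset
        res = fic_ss_select(ds, p=8, screener=ELMScreener(seed=1), q_cap=8)
        back = SelectionResult.from_json(res.to_json(wavenumbers=ds.wavenumbers))
        assert np.array_equal(back.selected, res.selected)
        assert back.stats == res.stats
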