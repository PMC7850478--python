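"""Growth/death estimators and correlation statistics."""

import numpy as np
import pytest

from mmlineage.io import EventRecord, extract_cycles, filter_lineages
from mmlineage.stats import (
    DivisionCurve,
    UndefinedCorrelationError,
    autocorrelation,
    correlation,
    cumulative_division_probability,
    death_rate,
    division_count_distribution,
    fit_division_rate,
    intra_lineage_correlations,
    one_pair_per_lineage_correlation,
)

DT = 1.0


def _ev(cid, t, event="division"):
    return EventRecord(cid, t, event)


class TestDivisionCurve:
    def test_two_channels_hand_case(self):
        # two channels alive, one division in frame 1, one in frame 2
        events = [
            _ev("a", 0.5), _ev("a", 50.0, "end_of_observation"),
            _ev("b", 1.5), _ev("b", 50.0, "end_of_observation"),
        ]
        curve = cumulative_division_probability(events, DT)
        assert curve.cumulative[0] == pytest.approx(0.5)
        assert curve.cumulative[1] == pytest.approx(1.0)

    def test_no_divisions_all_zero(self):
        events = [
            _ev("a", 10.0, "end_of_observation"),
            _ev("b", 10.0, "end_of_observation"),
        ]
        curve = cumulative_division_probability(events, DT)
        assert np.all(curve.cumulative == 0.0)

    def test_death_changes_denominator(self):
        # channel b dies in frame 1 (alive at its start), division in frame 2
        # happens among the single remaining lineage
        events = [
            _ev("a", 1.5), _ev("a", 50.0, "end_of_observation"),
            _ev("b", 0.7, "death"),
        ]
        curve = cumulative_division_probability(events, DT)
        assert curve.cumulative[0] == pytest.approx(0.0)
        assert curve.cumulative[1] == pytest.approx(1.0)

    def test_curve_non_decreasing_invariant(self):
        with pytest.raises(ValueError):
            DivisionCurve(
                bin_times=np.array([1.0, 2.0]),
                cumulative=np.array([1.0, 0.5]),
            )

    def test_fit_exact_line(self):
        t = np.arange(1, 100) * 0.5
        curve = DivisionCurve(bin_times=t, cumulative=0.09 * t)
        slope, se = fit_division_rate(curve)
        assert slope == pytest.approx(0.09, abs=1e-12)
        assert se == pytest.approx(0.0, abs=1e-10)

    def test_fit_invariant_to_time_shift(self):
        t = np.arange(1, 50, dtype=float)
        y = 0.07 * t + 0.3
        s1, _ = fit_division_rate(DivisionCurve(bin_times=t, cumulative=y))
        s2, _ = fit_division_rate(DivisionCurve(bin_times=t + 13.0, cumulative=y))
        assert s1 == pytest.approx(s2, abs=1e-12)


class TestDeathRate:
    def test_no_deaths(self):
        events = [
            _ev("a", 10.0, "end_of_observation"),
            _ev("b", 10.0, "end_of_observation"),
        ]
        with pytest.warns(UserWarning, match="no deaths"):
            rate, se, curve = death_rate(events, DT)
        assert rate == 0.0
        assert np.isinf(se)
        assert curve.surviving_fraction[0] == 1.0

    def test_survival_curve_shape(self):
        events = [
            _ev("a", 4.5, "death"),
            _ev("b", 8.5, "death"),
            _ev("c", 10.0, "end_of_observation"),
        ]
        rate, se, curve = death_rate(events, DT)
        f = curve.surviving_fraction
        assert f[0] == 1.0
        assert np.all(np.diff(f) <= 1e-12)
        assert f[-1] == pytest.approx(1 / 3)
        assert rate > 0

    def test_per_generation_death_probability_reference(self):
        """At the reference death rate and mean generation time the chance
        of death per generation, 1 - exp(-rate * mean tau), is about 2%."""
        p = 1.0 - np.exp(-2.239e-3 * 10.40)
        assert round(p * 100) == 2


class TestCorrelation:
    def test_perfect_positive_and_negative(self):
        assert correlation([(1, 1), (2, 2), (3, 3)], "pearson")[0] == \
            pytest.approx(1.0)
        assert correlation([(1, 1), (2, 2), (3, 3)], "spearman")[0] == \
            pytest.approx(1.0)
        assert correlation([(1, 3), (2, 2), (3, 1)], "pearson")[0] == \
            pytest.approx(-1.0)

    def test_constant_input_undefined(self):
        with pytest.raises(UndefinedCorrelationError):
            correlation([(1, 1), (1, 2), (1, 3)], "pearson")

    def test_matches_direct_formula_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = rng.integers(4, 30)
            x, y = rng.normal(size=n), rng.normal(size=n)
            r, _ = correlation(list(zip(x, y)), "pearson")
            cov = ((x - x.mean()) * (y - y.mean())).mean()
            oracle = cov / (x.std() * y.std())
            assert r == pytest.approx(oracle, abs=1e-12)
            rho, _ = correlation(list(zip(x, y)), "spearman")
            rx = np.argsort(np.argsort(x)).astype(float)
            ry = np.argsort(np.argsort(y)).astype(float)
            cov_r = ((rx - rx.mean()) * (ry - ry.mean())).mean()
            assert rho == pytest.approx(cov_r / (rx.std() * ry.std()), abs=1e-12)


def _lineage_events(taus_per_channel):
    events = []
    for i, taus in enumerate(taus_per_channel):
        t = 1.0
        events.append(_ev(f"c{i}", t))
        for tau in taus:
            t += tau
            events.append(_ev(f"c{i}", t))
        events.append(_ev(f"c{i}", t + 1.0, "end_of_observation"))
    return events


class TestOnePairPerLineage:
    def test_single_pair_lineages_have_zero_sd(self):
        # each lineage holds exactly one mother-daughter pair (2 cycles)
        events = _lineage_events([[8, 9], [10, 11], [12, 16], [9, 14]])
        cycles = extract_cycles(events)
        mean, sd = one_pair_per_lineage_correlation(
            cycles, n_resamples=50, seed=1, min_divisions=3
        )
        assert sd == pytest.approx(0.0, abs=1e-12)

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(5)
        taus = [list(rng.uniform(8, 20, rng.integers(4, 10))) for _ in range(30)]
        cycles = extract_cycles(_lineage_events(taus))
        a = one_pair_per_lineage_correlation(cycles, 200, seed=42)
        b = one_pair_per_lineage_correlation(cycles, 200, seed=42)
        assert a == b

    def test_close_to_pooled_on_calibrated_data(self):
        from mmlineage.io import ancestor_descendant_pairs
        from mmlineage.simulate import GeneratorConfig, simulate_lineages
        cfg = GeneratorConfig(n_channels=800, seed=31, baseline_hazard_per_h=0.0)
        cycles = extract_cycles(simulate_lineages(cfg))
        pooled, _ = correlation(
            ancestor_descendant_pairs(cycles, 1), "spearman"
        )
        mean, sd = one_pair_per_lineage_correlation(
            cycles, n_resamples=300, seed=7
        )
        assert mean == pytest.approx(pooled, abs=0.05)


class TestAutocorrelation:
    def test_single_lineage_matches_pooled_pairs_oracle(self):
        taus = list(np.random.default_rng(2).uniform(8, 25, 40))
        cycles = extract_cycles(_lineage_events([taus]))
        acf = autocorrelation(cycles, max_lag=3)
        for lag in (1, 2, 3):
            x = np.array(taus[:-lag])
            y = np.array(taus[lag:])
            oracle = np.corrcoef(x, y)[0, 1]
            assert acf[lag][0] == pytest.approx(oracle, abs=1e-12)

    def test_iid_taus_within_noise_of_zero(self):
        rng = np.random.default_rng(3)
        taus = [list(rng.uniform(8, 25, 15)) for _ in range(200)]
        cycles = extract_cycles(_lineage_events(taus))
        acf = autocorrelation(cycles, max_lag=5)
        for lag, (r, se) in acf.items():
            n = 200 * (15 - 1 - lag + 1)
            assert abs(r) < 3.0 / np.sqrt(n)


class TestIntraLineage:
    def test_strictly_increasing_lineage_gives_one(self):
        events = _lineage_events([[8, 9, 10, 11, 12, 13]])
        lineages = filter_lineages(extract_cycles(events), 0, events=events)
        coefs, mean, sd, n_exc = intra_lineage_correlations(lineages)
        assert coefs.tolist() == pytest.approx([1.0])
        assert n_exc == 0

    def test_per_lineage_matches_pooled_oracle(self):
        rng = np.random.default_rng(8)
        taus = [list(rng.uniform(8, 25, 8)) for _ in range(20)]
        events = _lineage_events(taus)
        lineages = filter_lineages(extract_cycles(events), 4, events=events)
        coefs, _, _, _ = intra_lineage_correlations(lineages, method="spearman")
        for s, coef in zip(lineages, coefs):
            pairs = list(zip(s.taus[:-1], s.taus[1:]))
            assert coef == pytest.approx(correlation(pairs, "spearman")[0])

    def test_mean_below_pooled_on_heritable_data(self):
        """Between-lineage differences in mean generation time inflate the
        pooled coefficient relative to the per-lineage mean."""
        from mmlineage.io import ancestor_descendant_pairs
        from mmlineage.simulate import GeneratorConfig, simulate_lineages
        cfg = GeneratorConfig(n_channels=600, seed=41, baseline_hazard_per_h=0.0)
        events = simulate_lineages(cfg)
        cycles = extract_cycles(events)
        pooled, _ = correlation(ancestor_descendant_pairs(cycles, 1), "spearman")
        lineages = filter_lineages(cycles, 4, events=events)
        _, mean, _, _ = intra_lineage_correlations(lineages)
        assert 0.0 < mean < pooled


class TestDivisionCounts:
    def test_enumeration_within_window(self):
        events = [
            _ev("a", 10.0), _ev("a", 20.0), _ev("a", 31.0),
            _ev("a", 100.0, "end_of_observation"),
        ]
        assert division_count_distribution(events, 100.0) == {"a": 3}
        assert division_count_distribution(events, 25.0) == {"a": 2}

    def test_only_survivors_excludes_deaths(self):
        events = [
            _ev("a", 10.0), _ev("a", 50.0, "end_of_observation"),
            _ev("b", 12.0), _ev("b", 20.0, "death"),
        ]
        counts = division_count_distribution(events, 50.0, only_survivors=True)
        assert counts == {"a": 1}
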