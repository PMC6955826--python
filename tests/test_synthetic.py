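"""Synthetic coupling graphs, time-courses, cohorts, components, artifacts."""

import numpy as np
import pytest
from scipy import signal, stats

from fnconn.exceptions import InvalidArgumentError
from fnconn.lagged import lagged_distance_correlation
from fnconn.network import SurrogateEdgeRule, build_fnc, compute_metrics, network_summary
from fnconn.rsn import default_templates
from fnconn.synthetic import (
    CohortSpec,
    GroupDegradation,
    bandlimited_noise,
    generate_artifact_timecourse,
    generate_cohort,
    generate_coupling_graph,
    generate_spatial_components,
    simulate_timecourses,
)


class TestCouplingGraph:
    def test_full_density_degenerate_range_forces_complete_graph(self):
        g = generate_coupling_graph(10, 1.0, (0.5, 0.5), 0, seed=3)
        off = ~np.eye(10, dtype=bool)
        assert np.all(g.weights[off] == 0.5)
        assert np.all(np.diagonal(g.weights) == 0)
        assert np.all(g.lags == 0)

    def test_seed_determinism(self):
        a = generate_coupling_graph(10, 0.4, (0.3, 0.8), 3, seed=7)
        b = generate_coupling_graph(10, 0.4, (0.3, 0.8), 3, seed=7)
        assert np.array_equal(a.weights, b.weights)
        assert np.array_equal(a.lags, b.lags)
        assert a.nonlinearity == b.nonlinearity

    def test_edge_count_within_binomial_band(self):
        # 99% interval of Binomial(45, 0.4) is [10, 27]
        counts = [
            sum(1 for _ in generate_coupling_graph(10, 0.4, (0.3, 0.8), 3, s).edges())
            for s in range(10)
        ]
        assert all(10 <= c <= 27 for c in counts)

    def test_lags_antisymmetric_and_bounded(self):
        g = generate_coupling_graph(10, 0.8, (0.2, 0.9), 3, seed=5)
        assert np.array_equal(g.lags, -g.lags.T)
        assert np.abs(g.lags).max() <= 3

    def test_invalid_arguments_rejected(self):
        with pytest.raises(InvalidArgumentError):
            generate_coupling_graph(1, 0.5, (0.3, 0.8), 3, 0)
        with pytest.raises(InvalidArgumentError):
            generate_coupling_graph(10, 0.0, (0.3, 0.8), 3, 0)
        with pytest.raises(InvalidArgumentError):
            generate_coupling_graph(10, 0.5, (0.0, 0.8), 3, 0)


class TestSimulateTimecourses:
    def single_edge_graph(self, w=0.9, lag=2):
        g = generate_coupling_graph(4, 0.0001, (w, w), 0, seed=0)
        g.weights[0, 1] = g.weights[1, 0] = w
        g.lags[0, 1], g.lags[1, 0] = lag, -lag
        return g

    def test_bitwise_seed_determinism(self):
        g = self.single_edge_graph()
        a = simulate_timecourses(g, 64, seed=9).data
        b = simulate_timecourses(g, 64, seed=9).data
        assert np.array_equal(a, b)

    def test_columns_standardized(self):
        tcs = simulate_timecourses(self.single_edge_graph(), 128, seed=2)
        assert tcs.data.mean(axis=0) == pytest.approx(np.zeros(4), abs=1e-12)
        assert tcs.data.std(axis=0) == pytest.approx(np.ones(4), abs=1e-12)

    def test_coupled_pair_dominates_null_pairs(self):
        """Coupled edge beats every uncoupled pair's lagged dCor (Monte Carlo)."""
        wins = 0
        for seed in range(20):
            tcs = simulate_timecourses(self.single_edge_graph(), 297, seed=seed)
            coupled = lagged_distance_correlation(
                tcs.data[:, 0], tcs.data[:, 1], 3
            ).dcor
            nulls = [
                lagged_distance_correlation(tcs.data[:, i], tcs.data[:, j], 3).dcor
                for i, j in [(0, 2), (1, 3), (2, 3), (0, 3), (1, 2)]
            ]
            wins += coupled > max(nulls)
        assert wins >= 19

    def test_lag_recovered_at_matching_window(self):
        tcs = simulate_timecourses(self.single_edge_graph(lag=2), 297, seed=4)
        res = lagged_distance_correlation(tcs.data[:, 0], tcs.data[:, 1], 3)
        assert res.best_lag == 2

    def test_nonlinear_edges_detectable(self):
        for tag in ("quadratic", "monotone"):
            g = self.single_edge_graph(w=0.9, lag=0)
            g.nonlinearity[(0, 1)] = tag
            tcs = simulate_timecourses(g, 297, noise_sd=0.3, seed=11)
            coupled = lagged_distance_correlation(tcs.data[:, 0], tcs.data[:, 1], 3)
            null = lagged_distance_correlation(tcs.data[:, 2], tcs.data[:, 3], 3)
            assert coupled.dcor > null.dcor

    def test_negative_noise_rejected(self):
        with pytest.raises(InvalidArgumentError):
            simulate_timecourses(self.single_edge_graph(), 64, noise_sd=-1, seed=0)

    def test_band_limited_spectrum(self):
        x = bandlimited_noise(512, 2.0, np.random.default_rng(0))
        f, p = signal.welch(x, fs=0.5, nperseg=256)
        inband = p[(f >= 0.01) & (f <= 0.1)].sum()
        assert inband / p.sum() > 0.95


class TestCohort:
    def spec(self, **kw):
        defaults = dict(
            n_subjects={"HC": 3, "UWS": 3},
            degradation={
                "HC": GroupDegradation(),
                "UWS": GroupDegradation(0.5, 0.5, 1.5),
            },
            n_timepoints=128,
            seed=5,
        )
        defaults.update(kw)
        return CohortSpec(**defaults)

    def test_identity_degradation_preserves_base_graph(self):
        from fnconn.synthetic import _degrade_graph, default_base_graph

        base = default_base_graph()
        out = _degrade_graph(base, GroupDegradation(), np.random.default_rng(0))
        assert np.array_equal(out.weights, base.weights)
        assert np.array_equal(out.lags, base.lags)

    def test_same_spec_gives_identical_cohorts(self):
        a, b = generate_cohort(self.spec()), generate_cohort(self.spec())
        for group in a:
            for ta, tb in zip(a[group], b[group]):
                assert np.array_equal(ta.data, tb.data)

    def test_groups_and_sizes_respected(self):
        cohort = generate_cohort(self.spec())
        assert sorted(cohort) == ["HC", "UWS"]
        assert all(len(v) == 3 for v in cohort.values())
        assert cohort["HC"][0].meta["group"] == "HC"

    def test_degraded_group_has_lower_mean_fnc_strength(self):
        """UWS degradation reduces mean network strength vs HC (Monte Carlo)."""
        spec = self.spec(
            n_subjects={"HC": 8, "UWS": 8}, n_timepoints=297, seed=21
        )
        cohort = generate_cohort(spec)
        means = {}
        for group, subjects in cohort.items():
            vals = [
                network_summary(
                    compute_metrics(build_fnc(t, edge_rule=SurrogateEdgeRule(seed=3)))
                )["strength"]
                for t in subjects
            ]
            means[group] = np.mean(vals)
        assert means["UWS"] < means["HC"]

    def test_strength_non_increasing_in_attenuation(self):
        """Mean average strength decreases as coupling attenuation grows."""
        levels = (0.0, 0.4, 0.8)
        means = []
        for att in levels:
            spec = CohortSpec(
                n_subjects={"G": 6},
                degradation={"G": GroupDegradation(0.0, att, 1.0)},
                n_timepoints=297,
                seed=31,
            )
            cohort = generate_cohort(spec)
            vals = [
                network_summary(
                    compute_metrics(build_fnc(t, edge_rule=SurrogateEdgeRule(seed=5)))
                )["strength"]
                for t in cohort["G"]
            ]
            means.append(np.mean(vals))
        assert means[0] >= means[1] >= means[2]

    def test_missing_degradation_rejected(self):
        with pytest.raises(InvalidArgumentError):
            CohortSpec(n_subjects={"HC": 2}, degradation={})


class TestSpatialComponents:
    def test_identity_settings_reproduce_templates(self):
        templates = default_templates((16, 16, 8))
        comps = generate_spatial_components(templates, 0, 0.0, 0, seed=0)
        assert comps.n_components == 10
        by_source = {s: m for s, m in zip(comps.source, comps.maps)}
        for name, mask in zip(templates.names, templates.masks):
            assert np.array_equal(by_source[name], mask.astype(float))

    def test_component_count_includes_extras(self):
        templates = default_templates((16, 16, 8))
        comps = generate_spatial_components(templates, 1, 0.1, 20, seed=1)
        assert comps.n_components == 30  # the 30-component decomposition regime

    def test_excessive_jitter_rejected(self):
        templates = default_templates((16, 16, 8))
        with pytest.raises(InvalidArgumentError):
            generate_spatial_components(templates, jitter=8, seed=0)

    def test_seed_determinism(self):
        templates = default_templates((16, 16, 8))
        a = generate_spatial_components(templates, 1, 0.1, 5, seed=4)
        b = generate_spatial_components(templates, 1, 0.1, 5, seed=4)
        assert np.array_equal(a.maps, b.maps)
        assert a.source == b.source


class TestArtifacts:
    def test_highfreq_power_concentrated_above_point_one_hz(self):
        x = generate_artifact_timecourse("highfreq", 297, 2.0, seed=0)
        f, p = signal.welch(x, fs=0.5, nperseg=128)
        assert p[f > 0.1].sum() / p[f > 0].sum() > 0.5

    def test_spike_has_heavy_tails_and_large_excursion(self):
        x = generate_artifact_timecourse("spike", 297, 2.0, seed=1)
        assert stats.kurtosis(x) > 3
        assert np.abs(x).max() > 5 * np.median(np.abs(x)) / 0.6745  # robust SD

    def test_sawtooth_is_strongly_autocorrelated(self):
        x = generate_artifact_timecourse("sawtooth", 297, 2.0, seed=2)
        assert np.corrcoef(x[:-1], x[1:])[0, 1] > 0.5

    def test_unknown_kind_rejected(self):
        with pytest.raises(InvalidArgumentError):
            generate_artifact_timecourse("drift", 297, 2.0, seed=0)
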