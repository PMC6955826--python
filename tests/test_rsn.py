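"""Template matching, component fingerprints, neuronal classification."""

import numpy as np
import pytest
from scipy import ndimage

from fnconn.exceptions import (
    DegenerateSeriesError,
    InfeasibleMatchError,
    InvalidArgumentError,
)
from fnconn.rsn import (
    SpatialComponentSet,
    TemplateSet,
    classify_neuronal,
    compute_fingerprint,
    default_templates,
    goodness_of_fit,
    match_templates,
    train_neuronal_classifier,
)
from fnconn.synthetic import (
    generate_artifact_timecourse,
    generate_neuronal_timecourse,
    generate_spatial_components,
)

from oracles import exhaustive_assignment

GRID = (16, 16, 8)


class TestGoodnessOfFit:
    def test_map_equal_to_mask_scores_one(self):
        mask = default_templates(GRID).masks[0]
        assert goodness_of_fit(mask.astype(float), mask) == pytest.approx(1.0)

    def test_constant_map_scores_zero(self):
        mask = default_templates(GRID).masks[0]
        assert goodness_of_fit(np.full(GRID, 0.7), mask) == pytest.approx(0.0)

    def test_displaced_blob_matches_two_mean_evaluation(self):
        mask = default_templates(GRID).masks[0]
        blob = ndimage.gaussian_filter(
            np.roll(mask.astype(float), (2, 0, 0), axis=(0, 1, 2)), sigma=1.0
        )
        expected = np.abs(blob)[mask].mean() - np.abs(blob)[~mask].mean()
        assert goodness_of_fit(blob, mask) == pytest.approx(expected, abs=1e-12)

    def test_sign_flip_invariance(self, rng):
        mask = default_templates(GRID).masks[1]
        m = rng.normal(size=GRID)
        assert goodness_of_fit(m, mask) == pytest.approx(
            goodness_of_fit(-m, mask), abs=1e-12
        )

    def test_empty_mask_rejected(self, rng):
        with pytest.raises(InvalidArgumentError):
            goodness_of_fit(rng.normal(size=GRID), np.zeros(GRID, dtype=bool))


class TestMatchTemplates:
    def test_components_equal_templates_gives_identity(self):
        templates = default_templates(GRID)
        comps = SpatialComponentSet(
            maps=templates.masks.astype(float),
            ids=[f"IC{k:02d}" for k in range(10)],
        )
        result = match_templates(comps, templates)
        for name, cid in result.mapping.items():
            k = templates.names.index(name)
            assert cid == f"IC{k:02d}"
        assert result.unmatched == []

    @pytest.mark.parametrize("seed", range(8))
    def test_equals_exhaustive_search_on_toys(self, seed):
        """Optimal assignment matches enumeration on 3-template x 4-component
        toys, including greedy-conflict instances."""
        r = np.random.default_rng(seed)
        grid2 = (8, 8, 4)
        masks = np.zeros((3, *grid2), dtype=bool)
        masks[0, :3], masks[1, 3:6, :4], masks[2, 5:, 4:] = True, True, True
        templates = TemplateSet(names=["a", "b", "c"], masks=masks)
        comps = SpatialComponentSet(
            maps=r.normal(size=(4, *grid2)), ids=["c0", "c1", "c2", "c3"]
        )
        gof = np.array(
            [
                [goodness_of_fit(comps.maps[c], masks[t]) for c in range(4)]
                for t in range(3)
            ]
        )
        best_total, _ = exhaustive_assignment(gof)
        result = match_templates(comps, templates)
        got_total = sum(result.goodness.values())
        assert got_total == pytest.approx(best_total, abs=1e-12)

    def test_ground_truth_recovery_among_thirty_components(self):
        templates = default_templates(GRID)
        comps = generate_spatial_components(templates, 1, 0.1, 20, seed=6)
        result = match_templates(comps, templates)
        truth = dict(zip(comps.ids, comps.source))
        for name, cid in result.mapping.items():
            assert truth[cid] == name

    def test_too_few_components_rejected(self):
        templates = default_templates(GRID)
        comps = SpatialComponentSet(
            maps=templates.masks[:5].astype(float), ids=[f"IC{k}" for k in range(5)]
        )
        with pytest.raises(InfeasibleMatchError):
            match_templates(comps, templates)

    def test_grid_mismatch_rejected(self, rng):
        templates = default_templates(GRID)
        comps = SpatialComponentSet(
            maps=rng.normal(size=(10, 8, 8, 4)), ids=[f"IC{k}" for k in range(10)]
        )
        with pytest.raises(InvalidArgumentError):
            match_templates(comps, templates)


class TestFingerprint:
    def test_sinusoid_concentrates_in_its_band(self, rng):
        t = np.arange(297) * 2.0
        tc = np.sin(2 * np.pi * 0.03 * t)
        fp = compute_fingerprint(tc, rng.normal(size=GRID), 2.0)
        assert np.argmax(fp.band_power) == 2  # 0.02-0.05 Hz band

    def test_band_powers_are_a_distribution(self, rng):
        fp = compute_fingerprint(rng.normal(size=297), rng.normal(size=GRID), 2.0)
        assert np.all(fp.band_power >= 0)
        assert fp.band_power.sum() == pytest.approx(1.0, abs=1e-9)

    def test_band_powers_invariant_to_positive_scaling(self, rng):
        tc, m = rng.normal(size=297), rng.normal(size=GRID)
        a = compute_fingerprint(tc, m, 2.0)
        b = compute_fingerprint(7.3 * tc, m, 2.0)
        assert a.band_power == pytest.approx(b.band_power, abs=1e-12)

    def test_gaussian_map_skewness_small(self, rng):
        """Skewness of an i.i.d. normal map stays within 3 standard errors."""
        fp = compute_fingerprint(rng.normal(size=297), rng.normal(size=GRID), 2.0)
        se = np.sqrt(6.0 / np.prod(GRID))
        assert abs(fp.skewness) < 3 * se

    def test_sawtooth_autocorrelation_high(self, rng):
        tc = generate_artifact_timecourse("sawtooth", 297, 2.0, seed=0)
        fp = compute_fingerprint(tc, rng.normal(size=GRID), 2.0)
        assert fp.one_lag_autocorrelation > 0.5

    def test_single_blob_map_fully_clustered(self):
        m = np.zeros(GRID)
        m[4:8, 4:8, 2:5] = 5.0
        fp = compute_fingerprint(
            generate_neuronal_timecourse(seed=1), m, 2.0
        )
        assert fp.degree_of_clustering == pytest.approx(1.0)

    def test_constant_timecourse_rejected(self, rng):
        with pytest.raises(DegenerateSeriesError):
            compute_fingerprint(np.ones(64), rng.normal(size=GRID), 2.0)

    def test_short_timecourse_rejected(self, rng):
        with pytest.raises(InvalidArgumentError):
            compute_fingerprint(rng.normal(size=16), rng.normal(size=GRID), 2.0)


def _fingerprints(kind, n, seed0, rng):
    fps = []
    for k in range(n):
        if kind == "neuronal":
            tc = generate_neuronal_timecourse(297, 2.0, seed=seed0 + k)
        else:
            tc = generate_artifact_timecourse(kind, 297, 2.0, seed=seed0 + k)
        fps.append(compute_fingerprint(tc, rng.normal(size=GRID), 2.0))
    return fps


class TestNeuronalClassifier:
    def test_holdout_accuracy_on_synthetic_benchmark(self, rng):
        """Band-limited vs high-frequency components separate at >= 0.9."""
        neu = _fingerprints("neuronal", 100, 0, rng)
        art = _fingerprints("highfreq", 100, 5000, rng)
        train = neu[:70] + art[:70]
        labels = ["neuronal"] * 70 + ["artifactual"] * 70
        model = train_neuronal_classifier(train, labels)
        test = neu[70:] + art[70:]
        truth = ["neuronal"] * 30 + ["artifactual"] * 30
        correct = sum(
            classify_neuronal(fp, model)[0] == lab for fp, lab in zip(test, truth)
        )
        assert correct / 60 >= 0.9

    def test_training_exemplar_far_from_margin_keeps_label(self, rng):
        neu = _fingerprints("neuronal", 30, 0, rng)
        art = _fingerprints("highfreq", 30, 9000, rng)
        model = train_neuronal_classifier(
            neu + art, ["neuronal"] * 30 + ["artifactual"] * 30
        )
        margins = [classify_neuronal(fp, model) for fp in neu]
        label, _ = max(margins, key=lambda lm: lm[1])
        assert label == "neuronal"

    def test_spike_fixture_classified_artifactual(self, rng):
        neu = _fingerprints("neuronal", 40, 0, rng)
        art = _fingerprints("spike", 20, 100, rng) + _fingerprints(
            "sawtooth", 20, 200, rng
        )
        model = train_neuronal_classifier(
            neu + art, ["neuronal"] * 40 + ["artifactual"] * 40
        )
        probe = compute_fingerprint(
            generate_artifact_timecourse("spike", 297, 2.0, seed=999),
            rng.normal(size=GRID),
            2.0,
        )
        assert classify_neuronal(probe, model)[0] == "artifactual"

    def test_single_class_training_rejected(self, rng):
        neu = _fingerprints("neuronal", 5, 0, rng)
        with pytest.raises(InvalidArgumentError):
            train_neuronal_classifier(neu, ["neuronal"] * 5)
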