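"""SOM training, Ward clustering of the codebook, and pattern labeling."""

import numpy as np
import pandas as pd
import pytest

from voc_ethogram import (
    SOMModel,
    classify_segments,
    cluster_codebook,
    find_bmu,
    label_patterns,
    normalize_features,
    quantization_error,
    train_som,
    update_weights,
)
from voc_ethogram.ethogram import (
    ClassificationError,
    DegenerateScaleError,
    LabelingError,
    N_CLUSTERS,
    PATTERNS,
    PATTERN_SIZES,
)
from voc_ethogram.kinematics import FEATURE_COLUMNS

P = len(FEATURE_COLUMNS)


def _unit_bounds():
    return pd.DataFrame({"min": np.zeros(P), "max": np.ones(P)}, index=list(FEATURE_COLUMNS))


def _model_from_weights(w):
    return SOMModel(weights=np.asarray(w, dtype=float), bounds=_unit_bounds())


def _feature_frame(X):
    return pd.DataFrame(np.asarray(X, dtype=float), columns=list(FEATURE_COLUMNS))


def _random_model(rng):
    return _model_from_weights(rng.uniform(0, 1, size=(140, P)))


class TestNormalize:
    def test_min_max_scaling_worked_example(self):
        table = _feature_frame(np.tile([[2.0], [4.0], [6.0]], (1, P)))
        norm, bounds, _ = normalize_features(table)
        np.testing.assert_allclose(norm.iloc[:, 0], [0.0, 0.5, 1.0])
        assert bounds.loc["speed", "min"] == 2.0 and bounds.loc["speed", "max"] == 6.0

    def test_reapplying_stored_bounds_is_idempotent(self, rng):
        table = _feature_frame(rng.uniform(0, 5, size=(40, P)))
        norm1, bounds, _ = normalize_features(table)
        norm2, _, _ = normalize_features(table, bounds=bounds)
        np.testing.assert_allclose(norm1.to_numpy(), norm2.to_numpy())

    def test_out_of_range_data_clipped_and_counted(self, rng):
        train = _feature_frame(rng.uniform(1, 2, size=(30, P)))
        _, bounds, _ = normalize_features(train)
        later = _feature_frame(np.vstack([
            np.full((4, P), 0.0),   # below every minimum: P clips per row
            np.full((6, P), 1.5),   # inside
        ]))
        norm, _, n_clipped = normalize_features(later, bounds=bounds)
        assert n_clipped == 4 * P
        assert norm.to_numpy().min() >= 0.0 and norm.to_numpy().max() <= 1.0

    def test_undefined_entries_imputed_to_zero_after_flagging(self, rng):
        table = _feature_frame(rng.uniform(1, 2, size=(5, P)))
        table.loc[2, "meander"] = np.nan
        norm, _, _ = normalize_features(table)
        assert norm.loc[2, "meander"] == 0.0
        assert norm.attrs["n_imputed"] == 1

    def test_constant_column_is_degenerate(self):
        table = _feature_frame(np.full((10, P), 3.0))
        with pytest.raises(DegenerateScaleError):
            normalize_features(table)


class TestBMU:
    def test_exact_node_match_has_zero_distance(self, rng):
        model = _random_model(rng)
        x = model.weights[57].copy()
        assert find_bmu(x, model) == 57

    def test_two_node_toy_model(self):
        w = np.zeros((140, P))
        w[1] = 0.9
        model = _model_from_weights(w)
        assert find_bmu(np.full(P, 0.8), model) == 1

    def test_ties_break_to_lowest_index(self):
        model = _model_from_weights(np.zeros((140, P)))
        assert find_bmu(np.full(P, 0.3), model) == 0

    def test_dimension_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            find_bmu(np.zeros(P + 1), _random_model(rng))

    def test_matches_exhaustive_scan(self, rng):
        model = _random_model(rng)
        for _ in range(200):
            x = rng.uniform(0, 1, P)
            expected = min(
                range(140), key=lambda j: float(((model.weights[j] - x) ** 2).sum())
            )
            assert find_bmu(x, model) == expected


class TestUpdate:
    def test_full_rate_zero_radius_snaps_bmu_to_input(self, rng):
        model = _random_model(rng)
        x = rng.uniform(0, 1, P)
        bmu = find_bmu(x, model)
        update_weights(model, x, bmu, alpha=1.0, radius=0.0)
        np.testing.assert_allclose(model.weights[bmu], x)

    def test_zero_rate_changes_nothing(self, rng):
        model = _random_model(rng)
        before = model.weights.copy()
        update_weights(model, rng.uniform(0, 1, P), 10, alpha=0.0, radius=2.0)
        np.testing.assert_allclose(model.weights, before)

    def test_update_decreases_bmu_distance(self, rng):
        model = _random_model(rng)
        x = rng.uniform(0, 1, P)
        bmu = find_bmu(x, model)
        d0 = float(((model.weights[bmu] - x) ** 2).sum())
        update_weights(model, x, bmu, alpha=0.3, radius=1.5)
        d1 = float(((model.weights[bmu] - x) ** 2).sum())
        assert d1 < d0


class TestTraining:
    def test_same_seed_same_model(self, rng):
        X = _feature_frame(rng.uniform(0, 1, size=(300, P)))
        a = train_som(X, seed=4)
        b = train_som(X, seed=4)
        np.testing.assert_array_equal(a.weights, b.weights)

    def test_training_reduces_quantization_error(self, rng):
        X = _feature_frame(rng.uniform(0, 1, size=(400, P)))
        trained = train_som(X, seed=2)
        init = SOMModel(
            weights=np.random.default_rng(2).uniform(0, 1, (140, P)),
            bounds=_unit_bounds(),
        )
        assert quantization_error(X, trained) < quantization_error(X, init)

    def test_separated_blobs_map_to_disjoint_regions(self, rng):
        a = np.clip(rng.normal(0.15, 0.03, size=(200, P)), 0, 1)
        b = np.clip(rng.normal(0.85, 0.03, size=(200, P)), 0, 1)
        model = train_som(_feature_frame(np.vstack([a, b])), seed=0)
        bmus_a = {find_bmu(x, model) for x in a}
        bmus_b = {find_bmu(x, model) for x in b}
        assert not bmus_a & bmus_b

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            train_som(_feature_frame(np.empty((0, P))))

    def test_json_round_trip(self, tmp_path, rng):
        X = _feature_frame(rng.uniform(0, 1, size=(150, P)))
        model = train_som(X, seed=9)
        path = model.to_json(tmp_path / "som.json")
        back = SOMModel.from_json(path)
        np.testing.assert_allclose(back.weights, model.weights)
        assert back.feature_names == model.feature_names
        assert back.seed == model.seed


class TestQuantizationError:
    def test_rows_equal_to_nodes_give_zero(self, rng):
        model = _random_model(rng)
        table = _feature_frame(model.weights[[3, 50, 120]])
        assert quantization_error(table, model) == pytest.approx(0.0, abs=1e-12)

    def test_single_row_equals_its_bmu_distance(self, rng):
        model = _random_model(rng)
        x = rng.uniform(0, 1, P)
        bmu = find_bmu(x, model)
        expected = float(np.sqrt(((model.weights[bmu] - x) ** 2).sum()))
        assert quantization_error(_feature_frame(x[None, :]), model) == pytest.approx(expected)

    def test_matches_brute_force_mean(self, rng):
        model = _random_model(rng)
        X = rng.uniform(0, 1, size=(37, P))
        expected = np.mean(
            [np.sqrt(((model.weights - x) ** 2).sum(axis=1)).min() for x in X]
        )
        assert quantization_error(_feature_frame(X), model) == pytest.approx(expected)


def _archetypes():
    """Nine codebook archetypes embodying the four pattern semantics.

    Columns: speed, acceleration, locomotory_rate, meander, stop, slipping.
    """
    return np.array(
        [
            [0.90, 0.70, 0.90, 0.10, 0.05, 0.05],  # active
            [0.85, 0.65, 0.85, 0.15, 0.08, 0.05],  # active
            [0.80, 0.60, 0.80, 0.20, 0.10, 0.05],  # active
            [0.50, 0.40, 0.55, 0.55, 0.20, 0.10],  # circling: turns per mm at mid speed
            [0.55, 0.45, 0.60, 0.95, 0.25, 0.60],  # zigzag
            [0.50, 0.40, 0.55, 0.90, 0.25, 0.55],  # zigzag
            [0.45, 0.35, 0.50, 0.85, 0.30, 0.50],  # zigzag
            [0.02, 0.05, 0.00, 0.00, 0.95, 0.00],  # stop
            [0.05, 0.08, 0.05, 0.02, 0.90, 0.02],  # stop
        ]
    )


def _planted_model(rng, noise=0.02):
    arch = _archetypes()
    assign = np.repeat(np.arange(9), 16)[:140]
    w = np.clip(arch[assign] + rng.normal(0, noise, size=(140, 6)), 0, 1)
    return _model_from_weights(w), assign


class TestClustering:
    def test_k1_collapses_to_one_cluster(self, rng):
        model = _random_model(rng)
        cm = cluster_codebook(model, k=1)
        assert set(cm.node_cluster) == {1}

    def test_k140_gives_singletons(self, rng):
        model = _random_model(rng)
        cm = cluster_codebook(model, k=140)
        assert len(set(cm.node_cluster)) == 140

    def test_k_out_of_range_rejected(self, rng):
        with pytest.raises(ValueError):
            cluster_codebook(_random_model(rng), k=0)
        with pytest.raises(ValueError):
            cluster_codebook(_random_model(rng), k=141)

    def test_heights_rescaled_to_percent(self, rng):
        cm = cluster_codebook(_random_model(rng), k=9)
        assert cm.heights_pct.max() == pytest.approx(100.0)
        assert cm.heights_pct.min() >= 0.0

    def test_planted_archetypes_recovered(self, rng):
        from sklearn.metrics import adjusted_rand_score

        model, truth = _planted_model(rng)
        cm = cluster_codebook(model, k=9)
        assert adjusted_rand_score(truth, cm.node_cluster) >= 0.9


class TestPatternLabeling:
    def test_constructed_fixture_labeled_correctly(self, rng):
        model, truth = _planted_model(rng)
        cm = label_patterns(model, cluster_codebook(model, k=9))
        node_patterns = cm.patterns_of_nodes()
        arch_pattern = ["active"] * 3 + ["circling"] + ["zigzag"] * 3 + ["stop"] * 2
        expected = np.array([arch_pattern[a] for a in truth])
        assert (node_patterns == expected).mean() > 0.95
        sizes = {p: 0 for p in PATTERNS}
        for c, p in cm.pattern_map.items():
            sizes[p] += 1
        assert sizes == PATTERN_SIZES

    def test_flat_codebook_has_no_activity_gradient(self):
        model = _model_from_weights(np.zeros((140, 6)))
        with pytest.raises(LabelingError):
            label_patterns(model, cluster_codebook(model, k=9))

    def test_requires_nine_clusters(self, rng):
        model = _random_model(rng)
        with pytest.raises(LabelingError):
            label_patterns(model, cluster_codebook(model, k=5))

    def test_labels_partition_all_clusters(self, rng):
        model = _random_model(rng)
        cm = label_patterns(model, cluster_codebook(model, k=N_CLUSTERS))
        assert sorted(cm.pattern_map) == list(range(1, 10))
        assert set(cm.pattern_map.values()) == set(PATTERNS)


class TestClassify:
    def _labeled_table(self, rng, n=40):
        table = _feature_frame(rng.uniform(0, 1, size=(n, P)))
        table.insert(0, "individual_id", [f"f{i % 4}" for i in range(n)])
        table.insert(1, "strain", "wild_type")
        table.insert(2, "treatment", "control")
        table.insert(3, "session", "pre")
        return table

    def test_fraction_arithmetic(self, rng):
        model, _ = _planted_model(rng)
        cm = label_patterns(model, cluster_codebook(model, k=9))
        arch = _archetypes()
        rows = np.vstack([arch[[0, 1, 2, 0]], arch[[7, 8]], arch[[4, 4, 3, 5]]])
        table = self._labeled_table(rng, n=10)
        table[list(FEATURE_COLUMNS)] = rows
        res = classify_segments(table, model, cm)
        frac = res.pattern_fractions.iloc[0]
        assert frac["active"] == pytest.approx(40.0)
        assert frac["stop"] == pytest.approx(20.0)

    def test_fractions_sum_to_hundred(self, rng):
        model, _ = _planted_model(rng)
        cm = label_patterns(model, cluster_codebook(model, k=9))
        res = classify_segments(self._labeled_table(rng, 200), model, cm)
        sums = res.pattern_fractions[list(PATTERNS)].sum(axis=1)
        np.testing.assert_allclose(sums, 100.0, atol=0.01)
        assert len(res.assignments) == 200

    def test_unlabeled_clusters_rejected(self, rng):
        model, _ = _planted_model(rng)
        cm = cluster_codebook(model, k=9)
        with pytest.raises(LabelingError):
            classify_segments(self._labeled_table(rng), model, cm)

    def test_missing_feature_column_rejected(self, rng):
        model, _ = _planted_model(rng)
        cm = label_patterns(model, cluster_codebook(model, k=9))
        bad = self._labeled_table(rng).drop(columns=["meander"])
        with pytest.raises(ClassificationError):
            classify_segments(bad, model, cm)

    def test_stop_dominated_cohort_is_mostly_stop_pattern(self, rng):
        from voc_ethogram import (
            BehaviorPreset,
            SimulationConfig,
            extract_features,
            generate_cohort,
        )

        sluggish = BehaviorPreset(
            name="sluggish", move_speed_mean=1.0, move_speed_sd=0.05,
            p_stop_entry=0.6, p_stop_exit=0.05, turn_sd=0.5,
            geotaxis_drift=0.05, slip_rate=0.1,
        )
        lively = BehaviorPreset(
            name="lively", move_speed_mean=4.0, move_speed_sd=0.1,
            p_stop_entry=0.02, p_stop_exit=0.5, turn_sd=0.4,
            geotaxis_drift=0.1, slip_rate=0.8, speed_jitter_frac=0.8,
        )
        cfg = SimulationConfig(duration=300.0, n_individuals=5, seed=13)
        feats = extract_features(
            generate_cohort(
                {("p53", "formaldehyde"): sluggish, ("wild_type", "control"): lively}, cfg
            )
        )
        norm, bounds, _ = normalize_features(feats)
        model = train_som(norm, seed=13, bounds=bounds)
        cm = label_patterns(model, cluster_codebook(model))
        res = classify_segments(feats, model, cm)
        slug = res.pattern_fractions.query("strain == 'p53'").iloc[0]
        assert slug["stop"] == max(slug[p] for p in PATTERNS)
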