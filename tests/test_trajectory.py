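"""Trajectory stage: z-scoring, clustering, consensus k, pattern labels."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from woundmetab.datamodel import ValidationError
from woundmetab.simulate import ARCHETYPES, SimConfig, generate_study, trajectory_archetype
from woundmetab.trajectory import (
    assign_timing_labels,
    classify_pattern,
    cluster_features,
    consensus_from_metrics,
    day_profile,
    infer_trajectories,
    select_k_consensus,
    zscore_features,
)

from conftest import make_table


class TestZscore:
    def test_hand_computed_row(self):
        t = make_table(np.array([[2.0 ** 10, 2.0 ** 20, 2.0 ** 30, 2.0 ** 20, 2.0 ** 20]]),
                       study_orders=[1, 2, 3, 4, 5], days=[7, 14, 21, 28, 60])
        z = zscore_features(t, "DPT").to_numpy()[0]
        np.testing.assert_allclose(z, [-1.5811, 0, 1.5811, 0, 0], atol=1e-4)

    def test_constant_row_maps_to_zero(self):
        t = make_table(np.full((1, 4), 32.0), study_orders=[1, 2, 3, 4],
                       days=[7, 14, 21, 28])
        np.testing.assert_allclose(zscore_features(t, "DPT").to_numpy(), 0.0)

    def test_rows_standardized(self):
        table, _ = generate_study(SimConfig(n_features=20, missing_rate=0.0, seed=0))
        z = zscore_features(table, "DPT").to_numpy()
        np.testing.assert_allclose(z.mean(axis=1), 0, atol=1e-9)
        np.testing.assert_allclose(z.std(axis=1), 1, atol=1e-9)

    def test_too_few_values_is_error(self):
        t = make_table(np.array([[np.nan, np.nan, 5.0]]), study_orders=[1, 2, 3],
                       days=[7, 14, 21])
        with pytest.raises(ValidationError, match="< 2"):
            zscore_features(t, "DPT")


class TestDayProfile:
    def test_single_sample_per_day_is_identity(self):
        t = make_table(np.array([[4.0, 8.0, 16.0]]), study_orders=[1, 2, 3],
                       days=[7, 14, 21])
        z = zscore_features(t, "DPT")
        prof = day_profile(z, t.sample_frame())
        np.testing.assert_allclose(prof.to_numpy()[0], z.to_numpy()[0])

    def test_profile_is_linear_in_features(self):
        rng = np.random.default_rng(3)
        t = make_table(rng.uniform(10, 100, (4, 6)), study_orders=list(range(1, 7)),
                       days=[7, 7, 14, 14, 21, 21])
        z = zscore_features(t, "DPT")
        prof = day_profile(z, t.sample_frame())
        np.testing.assert_allclose(prof.mean(axis=0), day_profile(
            pd.DataFrame(z.mean(axis=0)).T.set_axis(z.columns, axis=1), t.sample_frame()
        ).to_numpy()[0])


class TestClustering:
    def test_antipodal_groups_separate(self):
        z = np.array([[1, 1, 1, 1, 1], [1, 1, 1, 1, 1],
                      [-1, -1, -1, -1, -1], [-1, -1, -1, -1, -1]], dtype=float)
        labels = cluster_features(z, 2)
        assert labels[0] == labels[1] and labels[2] == labels[3]
        assert labels[0] != labels[2]

    def test_scaling_leaves_assignment_invariant(self):
        rng = np.random.default_rng(7)
        z = rng.normal(size=(12, 5))
        base = cluster_features(z, 3)
        scaled = z.copy()
        scaled[4] *= 10.0
        assert adjusted_rand_score(base, cluster_features(scaled, 3)) == 1.0

    def test_feature_reordering_up_to_relabeling(self):
        rng = np.random.default_rng(8)
        z = np.vstack([trajectory_archetype(a) + rng.normal(0, 0.05, (6, 5))
                       for a in ("U1", "D1", "P2")])
        base = cluster_features(z, 3)
        perm = rng.permutation(len(z))
        permuted = cluster_features(z[perm], 3)
        assert adjusted_rand_score(base[perm], permuted) == 1.0


class TestConsensusSelection:
    def test_unanimous_metrics(self):
        mt = pd.DataFrame(
            {"silhouette": [0.70, 0.55, 0.30],
             "calinski_harabasz": [150, 120, 90],
             "davies_bouldin": [0.40, 0.70, 1.10]},
            index=pd.Index([2, 3, 4], name="k"),
        )
        assert consensus_from_metrics(mt) == 2

    def test_rank_mean_tie_break(self):
        # k=2 ranks (1,2,2)=1.67; k=3 ranks (2,1,1)=1.33 -> k=3
        mt = pd.DataFrame(
            {"silhouette": [0.80, 0.60], "calinski_harabasz": [100, 140],
             "davies_bouldin": [0.90, 0.50]},
            index=pd.Index([2, 3], name="k"),
        )
        assert consensus_from_metrics(mt) == 3

    def test_planted_three_archetypes_recovered(self):
        ok = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            z = np.vstack([
                np.tile(trajectory_archetype(a), (20, 1)) + rng.normal(0, 0.2, (20, 5))
                for a in ("U1", "D1", "P2")
            ])
            k, _ = select_k_consensus(z, range(2, 8))
            ok += k == 3
        assert ok >= 9

    def test_too_few_features_is_error(self):
        with pytest.raises(ValidationError):
            select_k_consensus(np.ones((3, 5)), range(2, 5))


class TestPatternRules:
    @pytest.mark.parametrize(
        "centroid,letter",
        [
            ([-1.5, -0.5, 0.5, 1.0, 1.2], "U"),
            ([1.2, 0.4, -0.3, -0.6, -0.7], "D"),
            ([-0.5, 1.5, 0.3, -0.6, -0.7], "P"),
        ],
    )
    def test_letter_rules(self, centroid, letter):
        assert classify_pattern(centroid) == letter

    def test_all_archetypes_recover_their_letter(self):
        for label in ARCHETYPES:
            assert classify_pattern(trajectory_archetype(label)) == label[0]

    def test_u_timing_by_zero_crossing(self):
        u_early = np.array([-1.3, -0.5, 0.2, 0.7, 0.9])   # crosses day 21
        u_late = np.array([-0.9, -0.7, -0.2, 0.5, 1.3])   # crosses day 28
        labels = assign_timing_labels([(u_late, "U"), (u_early, "U")])
        assert labels == ["U2", "U1"]

    def test_p_timing_by_day7_value(self):
        mk = lambda v0: np.array([v0, 1.0, 1.5, 0.2, -1.0])
        labels = assign_timing_labels(
            [(mk(0.0), "P"), (mk(-0.9), "P"), (mk(0.8), "P")]
        )
        assert labels == ["P2", "P3", "P1"]

    def test_single_cluster_gets_numeral_one(self):
        assert assign_timing_labels([(np.array([1.0, 0.2, -0.5, -0.8, -1.0]), "D")]) == ["D1"]

    def test_more_than_three_same_letter_warns_and_continues(self):
        mk = lambda c: np.array([-1.0, -0.5, c, 0.8, 1.0])
        clusters = [(mk(0.1 * i), "U") for i in range(4)]
        with pytest.warns(UserWarning, match="more than 3"):
            labels = assign_timing_labels(clusters)
        assert sorted(labels) == ["U1", "U2", "U3", "U4"]


class TestEndToEnd:
    def test_six_planted_trajectories_recovered(self):
        mix = {a: 1.0 / 6 for a in ("U1", "U2", "D1", "P1", "P2", "P3")}
        ok = 0
        for seed in range(5):
            cfg = SimConfig(n_features=150, frac_time_responsive=1.0,
                            trajectory_mix=mix, noise_cv=0.1, seed=seed)
            table, truth = generate_study(cfg)
            res = infer_trajectories(table, "DPT")
            ari = adjusted_rand_score(truth["trajectory"].tolist(), res.labels)
            ok += res.k == 6 and ari >= 0.9
        assert ok >= 4
        # pattern labels cover the planted archetypes on the last run
        assert set(res.pattern_labels.values()) == set(mix)
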