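"""Generators: clustered spaces, retrieval sequences, cohorts, rosters, volumes."""

import numpy as np
import pandas as pd
import pytest

from semfluency.cohort_stats import fit_model
from semfluency.synthetic import (
    ClusterSpaceSpec,
    CohortSpec,
    RetrievalPolicy,
    VolumeSpec,
    make_clustered_space,
    make_roster,
    simulate_cohort,
    simulate_sequence,
    simulate_volumes,
)
from semfluency.vbm_glm import GLMDesign, voxelwise_glm
from semfluency.vft_scoring import Status, code_sequence, mean_adjacent_cosine


def _mean_cosine_split(space):
    """(within-cluster mean cosine, between-cluster mean cosine)."""
    unit = space.vectors / np.linalg.norm(space.vectors, axis=1, keepdims=True)
    labels = np.array([tok.split("_")[0] for tok in space.vocabulary])
    g = unit @ unit.T
    same = labels[:, None] == labels[None, :]
    iu = np.triu_indices(len(space), k=1)
    return g[iu][same[iu]].mean(), g[iu][~same[iu]].mean()


class TestClusteredSpace:
    def test_vocabulary_size_and_token_labels(self):
        space = make_clustered_space(
            ClusterSpaceSpec(n_clusters=3, words_per_cluster=4, seed=0)
        )
        assert len(space) == 12
        assert space.vocabulary[0] == "c00_w00"
        assert space.vocabulary[-1] == "c02_w03"

    def test_separated_clusters_have_higher_within_cosine(self):
        hits = 0
        for seed in range(20):
            space = make_clustered_space(
                ClusterSpaceSpec(
                    n_clusters=5, words_per_cluster=20, separation=4.0, seed=seed
                )
            )
            within, between = _mean_cosine_split(space)
            hits += within > between
        assert hits == 20

    def test_zero_separation_removes_cluster_structure(self):
        diffs = []
        for seed in range(20):
            space = make_clustered_space(
                ClusterSpaceSpec(
                    n_clusters=5, words_per_cluster=20, separation=0.0, seed=seed
                )
            )
            within, between = _mean_cosine_split(space)
            diffs.append(within - between)
        assert abs(np.mean(diffs)) < 0.01

    def test_low_dimension_with_many_clusters_rejected(self):
        with pytest.raises(ValueError, match="dimensionality"):
            ClusterSpaceSpec(n_clusters=3, dimensionality=1)

    def test_deterministic_given_seed(self):
        a = make_clustered_space(ClusterSpaceSpec(seed=5))
        b = make_clustered_space(ClusterSpaceSpec(seed=5))
        assert np.array_equal(a.vectors, b.vectors)


class TestRetrieval:
    def test_sequence_exceeding_vocabulary_rejected(self, clustered_space):
        with pytest.raises(ValueError, match="exceeds vocabulary"):
            simulate_sequence(
                clustered_space,
                RetrievalPolicy(0.5, sequence_length=len(clustered_space) + 1),
                seed=0,
            )

    def test_clean_policy_yields_all_valid_positions(self, clustered_space):
        t = simulate_sequence(clustered_space, RetrievalPolicy(0.5, 30), seed=1)
        coded = code_sequence(t, clustered_space)
        assert all(s is Status.VALID for _, s in coded.entries)
        assert len(t.tokens) == 30

    def test_injections_trigger_each_na_reason(self, clustered_space):
        policy = RetrievalPolicy(
            0.5, 40, p_oov=0.15, p_duplicate=0.15, p_disallowed=0.15
        )
        counts = {Status.NA_OOV: 0, Status.NA_DUPLICATE: 0, Status.NA_DISALLOWED: 0}
        for seed in range(10):
            t = simulate_sequence(clustered_space, policy, seed)
            coded = code_sequence(
                t, clustered_space, {"säugetiere", "vögel", "fische",
                                     "insekten", "reptilien"}
            )
            for st in counts:
                counts[st] += coded.count(st)
        assert all(v > 0 for v in counts.values())

    def test_organized_retrieval_raises_mean_cosine(self, clustered_space):
        means = {}
        for lam in (0.0, 1.0):
            vals = []
            for seed in range(60):
                t = simulate_sequence(
                    clustered_space, RetrievalPolicy(lam, 26), seed
                )
                m, _ = mean_adjacent_cosine(
                    code_sequence(t, clustered_space), clustered_space
                )
                vals.append(m)
            means[lam] = np.mean(vals)
        assert means[1.0] > means[0.0] + 0.1

    def test_random_retrieval_matches_mean_pairwise_cosine(self):
        # lambda = 0 on an unclustered space: expected adjacent cosine equals
        # the brute-force average over all ordered pairs
        space = make_clustered_space(
            ClusterSpaceSpec(n_clusters=1, words_per_cluster=60, separation=0.0,
                             seed=3)
        )
        unit = space.vectors / np.linalg.norm(space.vectors, axis=1, keepdims=True)
        g = unit @ unit.T
        iu = np.triu_indices(len(space), k=1)
        expected = g[iu].mean()
        vals = []
        for seed in range(200):
            t = simulate_sequence(space, RetrievalPolicy(0.0, 30), seed)
            m, _ = mean_adjacent_cosine(code_sequence(t, space), space)
            vals.append(m)
        se = np.std(vals) / np.sqrt(len(vals))
        assert np.mean(vals) == pytest.approx(expected, abs=4 * se)


class TestCohortGenerator:
    def test_row_count_and_columns(self):
        table, transcripts = simulate_cohort(CohortSpec(n_participants=25, seed=0))
        assert len(table) == 25 and transcripts is None
        assert {"samq", "age", "gender", "n_correct",
                "mean_cosine_similarity"} <= set(table.columns)
        assert table["samq"].between(-3, 3).all()
        assert table["age"].between(16, 40).all()

    def test_marginals_match_study_defaults(self):
        table, _ = simulate_cohort(CohortSpec(n_participants=5000, seed=1))
        assert table["n_correct"].mean() == pytest.approx(25.8, abs=0.3)
        assert table["age"].mean() == pytest.approx(24.8, abs=0.5)
        assert table["gender"].mean() == pytest.approx(23 / 101, abs=0.03)
        # modal SAMQ rating is +2, as in the study histogram
        assert table["samq"].mode()[0] == 2

    def test_planted_positive_samq_effect_recovered(self):
        hits = 0
        for rep in range(200):
            table, _ = simulate_cohort(CohortSpec(seed=rep))
            res = fit_model(
                table, "mean_cosine_similarity", ["samq", "n_correct", "age", "gender"]
            )
            hits += res["samq"]["beta"] > 0
        assert hits >= 190  # >= 95% of replicates

    def test_null_effect_rejection_rate_near_alpha(self):
        spec = CohortSpec(
            effects_cosine={
                "intercept": 0.364, "samq": 0.0, "n_correct": 0.0,
                "age": 0.0, "gender": 0.0,
            }
        )
        rejections = 0
        n_rep = 1000
        for rep in range(n_rep):
            table, _ = simulate_cohort(
                CohortSpec(
                    effects_cosine=spec.effects_cosine, seed=10_000 + rep
                )
            )
            res = fit_model(
                table, "mean_cosine_similarity", ["samq", "n_correct", "age", "gender"]
            )
            rejections += res["samq"]["p"] < 0.05
        rate = rejections / n_rep
        mc_se = np.sqrt(0.05 * 0.95 / n_rep)
        assert rate == pytest.approx(0.05, abs=2 * mc_se)

    def test_lambda_mode_produces_consistent_transcripts(self, clustered_space):
        table, transcripts = simulate_cohort(
            CohortSpec(n_participants=12, seed=4), clustered_space, mode="lambda"
        )
        assert transcripts is not None and len(transcripts) == 12
        from semfluency.vft_scoring import score_transcript

        for i, t in enumerate(transcripts):
            sc = score_transcript(t, clustered_space,
                                  {"säugetiere", "vögel", "fische",
                                   "insekten", "reptilien"})
            assert sc.mean_cosine_similarity == pytest.approx(
                table.loc[i, "mean_cosine_similarity"]
            )
            assert sc.n_correct == table.loc[i, "n_correct"]

    def test_infeasible_target_names_participant(self, clustered_space):
        spec = CohortSpec(
            n_participants=8,
            seed=0,
            effects_cosine={
                "intercept": 2.0, "samq": 0.0, "n_correct": 0.0,
                "age": 0.0, "gender": 0.0,
            },
        )
        with pytest.raises(ValueError, match="P00"):
            simulate_cohort(spec, clustered_space, mode="lambda")

    def test_tiny_cohort_rejected(self):
        with pytest.raises(ValueError, match="n_participants"):
            CohortSpec(n_participants=5)


class TestRoster:
    def test_study_counts(self):
        roster = make_roster(124, 23, seed=0)
        flagged = (
            roster["missing_vft"] | roster["missing_mri"] | (roster["age"] > 40)
        )
        assert flagged.sum() == 23

    def test_no_flags(self):
        roster = make_roster(10, 0, seed=1)
        assert not roster["missing_vft"].any()
        assert not roster["missing_mri"].any()
        assert (roster["age"] <= 40).all()

    def test_reproducible_under_seed(self):
        a = make_roster(50, 10, seed=9)
        b = make_roster(50, 10, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            make_roster(10, -1)
        with pytest.raises(ValueError):
            make_roster(5, 6)


class TestVolumes:
    def test_stack_shape_and_affine(self):
        spec = VolumeSpec(shape=(10, 10, 10), seed=0)
        stack = simulate_volumes(np.linspace(0.3, 0.4, 8), spec)
        assert stack.data.shape == (8, 10, 10, 10)
        assert np.allclose(stack.affine, np.diag([1.5, 1.5, 1.5, 1.0]))

    def test_region_outside_grid_rejected(self):
        with pytest.raises(ValueError, match="outside grid"):
            VolumeSpec(shape=(8, 8, 8), region_center=(8, 4, 4))

    def test_planted_effect_localizes_peak_t(self):
        rng = np.random.default_rng(0)
        spec = VolumeSpec(
            shape=(10, 10, 10), region_center=(5, 5, 5), region_radius=2.0,
            effect_size=3.0, noise_sd=0.05, seed=1,
        )
        hits = 0
        n_rep = 20
        region = spec.region_mask()
        for rep in range(n_rep):
            scores = rng.normal(0.36, 0.03, size=24)
            stack = simulate_volumes(
                scores, VolumeSpec(**{**spec.__dict__, "seed": rep})
            )
            design = GLMDesign(
                np.column_stack([np.ones(24), scores]),
                ("intercept", "score"),
                np.array([0.0, 1.0]),
            )
            statmap = voxelwise_glm(stack, design, mask=np.ones((10, 10, 10), bool))
            peak = np.unravel_index(np.argmax(statmap.t), statmap.t.shape)
            hits += bool(region[peak])
        assert hits >= 18  # >= 90%

    def test_zero_effect_gives_flat_t_field(self):
        spec = VolumeSpec(shape=(8, 8, 8), effect_size=0.0, seed=2,
                          region_center=(4, 4, 4))
        scores = np.linspace(0.3, 0.4, 20)
        stack = simulate_volumes(scores, spec)
        design = GLMDesign(
            np.column_stack([np.ones(20), scores]),
            ("intercept", "score"),
            np.array([0.0, 1.0]),
        )
        statmap = voxelwise_glm(stack, design, mask=np.ones((8, 8, 8), bool))
        assert np.abs(statmap.t).max() < 6.0  # no planted signal anywhere
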