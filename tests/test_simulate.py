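import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from mdsinfer import (
    LatentWorld,
    StudyDesign,
    build_schedule,
    filter_rt,
    ground_truth,
    sample_participant_space,
    sensitivity_matrices,
    simulate_study,
)
from mdsinfer.experiments import (
    REPLICATE_DESIGN,
    _simulate_dprime_matrices,
    congruent_groups_configuration,
    dprime_recovery,
)
from mdsinfer.simulate import _rng


class TestSchedule:
    def test_default_design_counts(self):
        design = StudyDesign()
        assert design.trials_per_participant == 300
        assert design.total_trials == 7500
        sched = build_schedule(design, "p01", seed=0)
        assert len(sched) == 300
        same = (sched["stim_first"] == sched["stim_second"]).sum()
        assert same == 150  # balanced same/different responses
        assert len(sched) - same == 150

    def test_full_study_row_count(self):
        table = simulate_study(StudyDesign(), LatentWorld(seed=0))
        assert len(table) == 7500
        assert table.n_participants == 25

    def test_minimal_two_object_design_by_enumeration(self):
        design = StudyDesign(
            objects=("a", "b"),
            base_same_trials=2,
            base_different_trials=1,
            extra_same_per_object=1,
            n_participants=1,
        )
        sched = build_schedule(design, "p01", seed=0)
        assert len(sched) == design.trials_per_participant == 5
        pairs = list(zip(sched["stim_first"], sched["stim_second"]))
        assert sum(a == b for a, b in pairs) == 4  # 2 base + 1 extra per object
        assert sum(a != b for a, b in pairs) == 1

    def test_round_robin_remainder_distribution(self):
        # 7 different trials over 3 pairs -> 3/2/2
        design = StudyDesign(
            objects=("a", "b", "c"),
            base_same_trials=3,
            base_different_trials=7,
            extra_same_per_object=0,
            n_participants=1,
        )
        sched = build_schedule(design, "p01", seed=0)
        diff = sched[sched["stim_first"] != sched["stim_second"]]
        key = [tuple(sorted(p)) for p in zip(diff["stim_first"], diff["stim_second"])]
        counts = sorted(
            (key.count(p) for p in {("a", "b"), ("a", "c"), ("b", "c")}), reverse=True
        )
        assert counts == [3, 2, 2]

    def test_schedule_deterministic_by_seed(self):
        d = StudyDesign()
        a = build_schedule(d, "p03", seed=9)
        b = build_schedule(d, "p03", seed=9)
        assert a.equals(b)
        c = build_schedule(d, "p03", seed=10)
        assert not a.equals(c)


class TestParticipantSpaces:
    def test_no_noise_reproduces_latent_configuration(self):
        world = LatentWorld(
            participant_jitter_sd=0.0, participant_transform="none", seed=5
        )
        for i in range(5):
            np.testing.assert_array_equal(
                sample_participant_space(world, i), world.true_configuration
            )

    def test_rigid_transform_preserves_distances(self):
        world = LatentWorld(
            participant_jitter_sd=0.0, participant_transform="rigid", seed=5
        )
        latent = pdist(world.true_configuration)
        for i in range(10):
            space = sample_participant_space(world, i)
            np.testing.assert_allclose(pdist(space), latent, atol=1e-10)
            assert not np.allclose(space, world.true_configuration)

    def test_same_seed_identical(self):
        world = LatentWorld(seed=11)
        np.testing.assert_array_equal(
            sample_participant_space(world, 3), sample_participant_space(world, 3)
        )


class TestResponses:
    def test_study_deterministic_by_seed(self, small_design):
        t1 = simulate_study(small_design, LatentWorld(seed=3))
        t2 = simulate_study(small_design, LatentWorld(seed=3))
        assert t1.data.to_csv() == t2.data.to_csv()  # byte-identical
        t3 = simulate_study(small_design, LatentWorld(seed=4))
        assert t1.data.to_csv() != t3.data.to_csv()

    def test_null_world_recovers_zero_dprime(self):
        design = StudyDesign(
            objects=("a", "b"),
            base_same_trials=4000,
            base_different_trials=4000,
            extra_same_per_object=0,
            n_participants=1,
        )
        world = LatentWorld(
            true_configuration=np.array([[0.0, 0.0], [2.0, 0.0]]),
            participant_jitter_sd=0.0,
            participant_transform="none",
            dprime_scale=0.0,
            criterion=0.5,
            seed=6,
        )
        mats = sensitivity_matrices(simulate_study(design, world))
        assert abs(mats["p01"].values[0, 1]) < 0.08

    def test_dprime_estimator_consistency(self):
        est, true = dprime_recovery(true_dprime=1.5, n_trials_per_kind=10_000, seed=2)
        assert est == pytest.approx(true, abs=0.05)

    def test_rt_contamination_exercises_filter(self, small_design):
        world = LatentWorld(seed=8, rt_contamination=0.2)
        table = simulate_study(small_design, world)
        out_of_window = (
            (table.data["rt_ms"] < 300) | (table.data["rt_ms"] > 2300)
        ).mean()
        assert 0.15 < out_of_window < 0.25
        kept = filter_rt(table)
        assert ((kept.data["rt_ms"] >= 300) & (kept.data["rt_ms"] <= 2300)).all()

    def test_default_rts_inside_window(self, small_study):
        rt = small_study.data["rt_ms"]
        assert rt.between(400, 1500).all()


class TestCountPathAgreesWithTrialPath:
    """The binomial count simulator and the trial-level simulator implement
    the same response model; their d' estimates must agree in distribution."""

    def test_mean_dprime_matrices_agree(self):
        design = StudyDesign(
            objects=REPLICATE_DESIGN.objects,
            base_same_trials=REPLICATE_DESIGN.base_same_trials,
            base_different_trials=REPLICATE_DESIGN.base_different_trials,
            extra_same_per_object=REPLICATE_DESIGN.extra_same_per_object,
            n_participants=40,
        )
        cfg = congruent_groups_configuration(1.0)
        world = LatentWorld(
            true_configuration=cfg,
            participant_jitter_sd=0.0,
            participant_transform="none",
            seed=13,
        )
        # trial-level path
        mats = sensitivity_matrices(simulate_study(design, world))
        trial_mean = np.mean([m.values for m in mats.values()], axis=0)
        # count-level path
        count_mats = _simulate_dprime_matrices(
            design, world, _rng(13, 4, 0), cfg
        )
        count_mean = count_mats.mean(axis=0)
        # the two paths must agree with each other everywhere
        assert np.abs(trial_mean - count_mean).max() < 0.45
        # ... and with scale * latent distance where d' is estimable at these
        # trial counts (within-group pairs, true d' ~1.5; the rate clamp
        # biases estimates of the much larger cross-group d' values)
        latent = squareform(pdist(cfg))
        within = np.zeros((6, 6), dtype=bool)
        within[:3, :3] = within[3:, 3:] = True
        np.fill_diagonal(within, False)
        assert np.abs((trial_mean - latent)[within]).max() < 0.35
        assert np.abs((count_mean - latent)[within]).max() < 0.35


def test_parameter_recovery_under_rigid_motion():
    """With moderate sensitivities, many trials and per-participant rigid
    transforms, mean per-participant distance estimates are nearly unbiased
    for the latent distances (the d' cap never binds in this regime)."""
    from mdsinfer import per_participant_solutions
    from mdsinfer.geometry import distance as geo_distance
    from mdsinfer.pcoa import embed_batch

    design = StudyDesign(
        objects=REPLICATE_DESIGN.objects,
        base_same_trials=12_000,
        base_different_trials=30_000,  # 2,000 per pair
        extra_same_per_object=0,
        n_participants=100,
    )
    cfg = congruent_groups_configuration(1.0)
    world = LatentWorld(
        true_configuration=cfg,
        participant_jitter_sd=0.05,
        participant_transform="rigid",
        dprime_scale=0.6,
        seed=19,
    )
    mats = _simulate_dprime_matrices(design, world, _rng(19, 4, 0), cfg)
    coords, _, _, _ = embed_batch(mats, k=2)
    latent = squareform(pdist(cfg))
    for i, j in ((0, 1), (1, 2), (3, 5)):
        est = np.mean(geo_distance(coords[:, i], coords[:, j])) / world.dprime_scale
        assert abs(est - latent[i, j]) / latent[i, j] < 0.05

    # at a few hundred trials per pair, estimation noise in the matrix
    # spreads the embedded points and inflates the shortest distances
    sparse = StudyDesign(
        objects=design.objects,
        base_same_trials=2400,
        base_different_trials=6000,  # 400 per pair
        extra_same_per_object=0,
        n_participants=100,
    )
    mats = _simulate_dprime_matrices(sparse, world, _rng(19, 4, 1), cfg)
    coords, _, _, _ = embed_batch(mats, k=2)
    est = np.mean(geo_distance(coords[:, 0], coords[:, 1])) / world.dprime_scale
    assert (est - latent[0, 1]) / latent[0, 1] > 0.05  # upward, not random


def test_ground_truth_contains_latent_quantities():
    design, world = StudyDesign(), LatentWorld(seed=0)
    truth = ground_truth(design, world)
    assert truth["objects"] == list(design.objects)
    assert len(truth["true_distances"]) == 15
    assert truth["true_area_rhotics"] > 0
    assert truth["true_area_fricatives"] > 0
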