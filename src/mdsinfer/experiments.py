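"""Replicate-study simulations: type-I calibration, power, and d' recovery.

These experiments run the full analysis chain — binomial response counts →
per-pair d' → per-participant classical MDS → geometry statistics →
two-sample comparison — over thousands of independently seeded synthetic
studies.  Response counts per (participant, pair, trial kind) are drawn
directly from the binomial response model rather than materialising
individual trial rows; trials are exchangeable and carry no sequential
structure, so the two routes are distributionally identical (the trial-level
simulator is cross-checked against this path in the test suite).

The calibration null uses two *congruent, disjoint* object groups (equal
latent areas; equal latent distances between disjoint pairs).  Two statistics
computed from the same participants are nevertheless not independent samples:
sharing an object correlates them positively (shared same-trials), and even
disjoint groups are coupled negatively through the joint 2-D embedding, so an
unpaired t-test on within-participant statistics is mis-calibrated (anti-
conservative here).  Hence two calibrated modes:

* ``mode="within"`` — both statistics from the same participants, compared
  with the *paired* t-test (the design-appropriate test);
* ``mode="between"`` — the same statistic from two independently simulated
  cohorts, compared with Welch's unpaired test.

``mode="within"`` with an unpaired test is still available, precisely to
demonstrate the miscalibration.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Literal, Sequence

import numpy as np
from scipy.special import ndtr

from . import geometry, pcoa, sensitivity
from .inference import compare
from .simulate import DEFAULT_OBJECTS, LatentWorld, StudyDesign, _rng

#: Base triangle of the congruent-groups null configuration (area ~1.015 p.u.^2,
#: side lengths ~1.4-1.6 p.u., i.e. true d' ~1.5 at unit scale).
NULL_TRIANGLE = np.array([[-0.7, -0.5], [0.8, -0.4], [0.0, 0.9]])

#: Horizontal separation of the two groups (keeps them distinct in the embedding).
GROUP_OFFSET = 1.6

#: Reduced per-participant trial counts used by the replicate studies:
#: 8 different trials per pair (15 pairs) and 20 same trials per object.
REPLICATE_DESIGN = StudyDesign(
    objects=DEFAULT_OBJECTS,
    base_same_trials=60,
    base_different_trials=120,
    extra_same_per_object=10,
    n_participants=25,
)


def congruent_groups_configuration(effect_scale: float = 1.0) -> np.ndarray:
    """Two congruent triangles, the second dilated about its centroid.

    ``effect_scale = 1`` is the exact null (equal latent areas and congruent
    pairwise distances); ``effect_scale = s`` multiplies the second group's
    distances by s and its area by s**2.
    """
    left = NULL_TRIANGLE + np.array([-GROUP_OFFSET, 0.0])
    right = NULL_TRIANGLE * effect_scale + np.array([GROUP_OFFSET, 0.0])
    return np.vstack([left, right])


def _simulate_dprime_matrices(
    design: StudyDesign,
    world: LatentWorld,
    rng: np.random.Generator,
    configuration: np.ndarray,
) -> np.ndarray:
    """(P, n, n) d' matrices for one study under the binomial response model."""
    P, n = design.n_participants, design.n_objects
    iu, ju = np.triu_indices(n, k=1)
    n_pairs = len(iu)

    # participant spaces: rigid motion (rotation + reflection) + jitter
    coords = np.broadcast_to(configuration, (P, n, 2)).copy()
    if world.participant_transform == "rigid":
        theta = rng.uniform(0.0, 2.0 * np.pi, size=P)
        ct, st = np.cos(theta), np.sin(theta)
        R = np.stack([np.stack([ct, -st], -1), np.stack([st, ct], -1)], -2)
        coords = np.einsum("pij,pnj->pni", R, coords)
        reflect = rng.random(P) < 0.5
        coords[reflect, :, 0] *= -1.0
    if world.participant_jitter_sd > 0:
        coords = coords + rng.normal(0.0, world.participant_jitter_sd, size=coords.shape)

    dist = np.sqrt(((coords[:, iu] - coords[:, ju]) ** 2).sum(axis=-1))  # (P, pairs)
    c = world.effective_criterion
    true_d = world.dprime_scale * dist

    same_counts = np.array(
        [
            base + design.extra_same_per_object
            for base in _same_base_counts(design)
        ]
    )
    diff_counts = np.asarray(_diff_counts(design))

    hits = rng.binomial(diff_counts[None, :], ndtr(true_d - c), size=(P, n_pairs))
    same_diff_resp = rng.binomial(same_counts[None, :], ndtr(-c), size=(P, n))

    hit_rate = hits / diff_counts
    n_fa = same_counts[iu] + same_counts[ju]
    fa_rate = (same_diff_resp[:, iu] + same_diff_resp[:, ju]) / n_fa
    d = sensitivity.dprime(hit_rate, fa_rate, diff_counts[None, :], n_fa[None, :])
    d = np.maximum(d, 0.0)  # floor negative d', as in the trial-level pipeline

    mats = np.zeros((P, n, n))
    mats[:, iu, ju] = d
    mats[:, ju, iu] = d
    return mats


def _same_base_counts(design: StudyDesign) -> list[int]:
    base, rem = divmod(design.base_same_trials, design.n_objects)
    return [base + (1 if i < rem else 0) for i in range(design.n_objects)]


def _diff_counts(design: StudyDesign) -> list[int]:
    n_pairs = design.n_objects * (design.n_objects - 1) // 2
    base, rem = divmod(design.base_different_trials, n_pairs)
    return [base + (1 if i < rem else 0) for i in range(n_pairs)]


def _group_statistics(coords: np.ndarray, statistic: str):
    """The two group statistics (per participant) from a (P, 6, 2) embedding."""
    if statistic == "area":
        a = geometry.triangle_area(coords[:, 0], coords[:, 1], coords[:, 2])
        b = geometry.triangle_area(coords[:, 3], coords[:, 4], coords[:, 5])
    elif statistic == "distance":
        a = geometry.distance(coords[:, 0], coords[:, 1])
        b = geometry.distance(coords[:, 3], coords[:, 4])
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    return a, b


def replicate_pvalues(
    n_studies: int,
    seed: int,
    statistic: Literal["area", "distance"] = "area",
    effect_scale: float = 1.0,
    design: StudyDesign = REPLICATE_DESIGN,
    world: LatentWorld | None = None,
    test: str = "paired_t",
    mode: Literal["within", "between"] = "within",
) -> np.ndarray:
    """p-values of the group comparison across independent replicate studies.

    ``mode="within"``: each study simulates one cohort perceiving the
    congruent-groups configuration (second group dilated by ``effect_scale``),
    runs the per-participant d' → MDS pipeline and compares the two group
    statistics across the same participants — paired by design, so the
    default test is ``paired_t``.

    ``mode="between"``: each study simulates two independent cohorts (the
    second cohort's configuration dilated by ``effect_scale``) and compares
    the *first* group's statistic between cohorts with an unpaired test
    (pass ``test="welch_t"``).
    """
    if world is None:
        world = LatentWorld(participant_transform="rigid", participant_jitter_sd=0.15)
    pvals = np.empty(n_studies)
    if mode == "within":
        configuration = congruent_groups_configuration(effect_scale)
        for s in range(n_studies):
            rng = _rng(seed, 4, s)
            mats = _simulate_dprime_matrices(design, world, rng, configuration)
            coords, _, _, _ = pcoa.embed_batch(mats, k=2)
            stat_a, stat_b = _group_statistics(coords, statistic)
            pvals[s] = compare(stat_a, stat_b, test=test).p_value
    elif mode == "between":
        configs = (
            congruent_groups_configuration(1.0),
            _scaled_configuration(effect_scale),
        )
        for s in range(n_studies):
            samples = []
            for cohort, cfg in enumerate(configs):
                rng = _rng(seed, 5, s, cohort)
                mats = _simulate_dprime_matrices(design, world, rng, cfg)
                coords, _, _, _ = pcoa.embed_batch(mats, k=2)
                samples.append(_group_statistics(coords, statistic)[0])
            pvals[s] = compare(samples[0], samples[1], test=test).p_value
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return pvals


def _scaled_configuration(effect_scale: float) -> np.ndarray:
    """Congruent-groups configuration with *group A* dilated (between-cohort effect)."""
    left = NULL_TRIANGLE * effect_scale + np.array([-GROUP_OFFSET, 0.0])
    right = NULL_TRIANGLE + np.array([GROUP_OFFSET, 0.0])
    return np.vstack([left, right])


def rejection_rate(
    n_studies: int,
    seed: int,
    statistic: Literal["area", "distance"] = "area",
    effect_scale: float = 1.0,
    alpha: float = 0.05,
    **kwargs,
) -> float:
    """Fraction of replicate studies rejecting H0 at level alpha.

    With ``effect_scale = 1`` this is the empirical type-I error rate; with
    ``effect_scale > 1`` it is power."""
    pvals = replicate_pvalues(
        n_studies, seed, statistic=statistic, effect_scale=effect_scale, **kwargs
    )
    return float((pvals < alpha).mean())


def power_curve(
    effect_scales: Sequence[float],
    n_studies: int,
    seed: int,
    statistic: Literal["area", "distance"] = "area",
    alpha: float = 0.05,
    **kwargs,
) -> dict[float, float]:
    """Rejection rate at each effect scale (1.0 = null), same study machinery."""
    return {
        float(s): rejection_rate(
            n_studies, seed + i + 1, statistic=statistic, effect_scale=s,
            alpha=alpha, **kwargs,
        )
        for i, s in enumerate(effect_scales)
    }


def dprime_recovery(
    true_dprime: float = 1.5,
    n_trials_per_kind: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Estimate d' from a simulated single-pair study via the trial pipeline.

    Simulates a 2-object world whose latent distance maps to ``true_dprime``,
    with ``n_trials_per_kind`` different trials and the same number of same
    trials, then runs the standard trial-level estimator.  Returns
    ``(estimate, true value)``.
    """
    from .simulate import simulate_study
    from .trials import filter_rt

    design = StudyDesign(
        objects=("A", "B"),
        base_different_trials=n_trials_per_kind,
        base_same_trials=n_trials_per_kind,
        extra_same_per_object=0,
        n_participants=1,
    )
    world = LatentWorld(
        true_configuration=np.array([[0.0, 0.0], [true_dprime, 0.0]]),
        participant_jitter_sd=0.0,
        participant_transform="none",
        dprime_scale=1.0,
        seed=seed,
    )
    table = filter_rt(simulate_study(design, world))
    matrix = sensitivity.sensitivity_matrix(table, design.participant_ids[0])
    return float(matrix.values[0, 1]), true_dprime
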