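"""Synthetic same-different studies with known perceptual ground truth.

The generator mirrors the design of a 6-object AX discrimination study with
25 participants: 60 same + 150 different base trials per participant, plus
90 extra same trials (15 per object) to balance same and different responses
at 150 each, i.e. 300 trials per participant and 7,500 in total.

The response process inverts the d' front end of the analysis pipeline.
Each participant has their own perceptual configuration: the latent
configuration, optionally moved by a random rigid motion (rotation,
reflection, translation — the invariance the per-participant method is
designed to survive) plus Gaussian jitter on each object.  A pair at
perceptual distance ``d`` has true sensitivity ``d' = scale * d``; with
response criterion ``c`` the probability of answering "different" is
``Phi(d' - c)`` on different trials and ``Phi(-c)`` on same trials, so the
yes/no estimator recovers the true d' without bias.  Reaction times are
uniform inside the plausible window, with an optional contamination fraction
outside the 300-2300 ms filter bounds to exercise the filter.

Randomness is organised as named streams per (seed, participant, stage), so
results are reproducible regardless of evaluation order.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from itertools import combinations
from typing import Literal

import numpy as np
import pandas as pd
from scipy.special import ndtr
from scipy.spatial.distance import pdist, squareform

from .trials import RESPONSE_DIFFERENT, RESPONSE_SAME, TRIAL_COLUMNS, DissimilarityMatrix, TrialTable

#: The 6 perceptual objects of the reference design: three rhotics and three
#: dental/retroflex/alveolo-palatal fricatives.
DEFAULT_OBJECTS = ("r", "ɻ", "ʀ", "z̪", "ʐ", "ʑ")

#: Latent 2-D configuration (p.u.): a rhotic cluster on the left and a
#: fricative cluster on the right, within-cluster distances ~1.2-1.9 and
#: between-cluster distances ~2.5-4.5 — d' values in the usual range for a
#: discriminable but imperfect contrast when scale = 1.
DEFAULT_CONFIGURATION = np.array(
    [
        [-2.2, 0.6],   # r
        [-1.0, 0.8],   # ɻ
        [-1.6, -0.9],  # ʀ
        [1.0, 0.9],    # z̪
        [2.2, 0.5],    # ʐ
        [1.5, -0.9],   # ʑ
    ]
)


@dataclass(frozen=True)
class StudyDesign:
    """Trial-schedule arithmetic of one study.

    Defaults reproduce the reference design: 6 objects, 60 + 150 base trials,
    15 extra same trials per object, 25 participants, 300 trials each.
    """

    objects: tuple[str, ...] = DEFAULT_OBJECTS
    base_same_trials: int = 60
    base_different_trials: int = 150
    extra_same_per_object: int = 15
    n_participants: int = 25
    rt_range_ms: tuple[float, float] = (400.0, 1500.0)

    def __post_init__(self):
        if len(self.objects) < 2:
            raise ValueError("need at least 2 objects")
        if min(self.base_same_trials, self.base_different_trials) <= 0:
            raise ValueError("trial counts must be positive")
        if self.extra_same_per_object < 0 or self.n_participants <= 0:
            raise ValueError("counts must be positive")

    @property
    def n_objects(self) -> int:
        return len(self.objects)

    @property
    def n_same(self) -> int:
        return self.base_same_trials + self.extra_same_per_object * self.n_objects

    @property
    def n_different(self) -> int:
        return self.base_different_trials

    @property
    def trials_per_participant(self) -> int:
        return self.n_same + self.n_different

    @property
    def total_trials(self) -> int:
        return self.trials_per_participant * self.n_participants

    @property
    def participant_ids(self) -> tuple[str, ...]:
        return tuple(f"p{i + 1:02d}" for i in range(self.n_participants))


@dataclass(frozen=True)
class LatentWorld:
    """Ground-truth generative parameters of a synthetic study.

    Attributes
    ----------
    true_configuration
        n x 2 latent object coordinates (p.u.), row-aligned with the design's
        object inventory.
    participant_jitter_sd
        SD of the iid Gaussian perturbation applied to every object of every
        participant's personal configuration (p.u.).
    participant_transform
        ``"rigid"`` applies a random rotation + reflection + translation per
        participant before jittering (distances and areas are preserved);
        ``"none"`` keeps the latent orientation.
    dprime_scale
        Linear map from perceptual distance to true d'.
    criterion
        Response criterion c; ``None`` means ``dprime_scale / 2``.
    rt_contamination
        Fraction of trials whose reaction time falls outside the 300-2300 ms
        window (half too fast, half too slow), to exercise the RT filter.
    seed
        Base seed; identical seeds give byte-identical studies.
    """

    true_configuration: np.ndarray = field(
        default_factory=lambda: DEFAULT_CONFIGURATION.copy()
    )
    participant_jitter_sd: float = 0.15
    participant_transform: Literal["none", "rigid"] = "rigid"
    dprime_scale: float = 1.0
    criterion: float | None = None
    rt_contamination: float = 0.0
    seed: int = 0

    def __post_init__(self):
        cfg = np.asarray(self.true_configuration, dtype=float)
        object.__setattr__(self, "true_configuration", cfg)
        if cfg.ndim != 2 or cfg.shape[1] != 2:
            raise ValueError("true_configuration must be an (n, 2) array")
        if self.participant_jitter_sd < 0:
            raise ValueError("jitter SD must be >= 0")
        if not 0 <= self.rt_contamination < 1:
            raise ValueError("rt_contamination must be in [0, 1)")

    @property
    def effective_criterion(self) -> float:
        return self.dprime_scale / 2.0 if self.criterion is None else self.criterion

    def with_seed(self, seed: int) -> "LatentWorld":
        return replace(self, seed=seed)


def _rng(seed: int, *stream: int) -> np.random.Generator:
    """Named random stream: independent generator per (seed, *stream) key."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(stream)))


def _round_robin(total: int, n_bins: int) -> list[int]:
    """Spread `total` over `n_bins` as evenly as possible (first bins get +1)."""
    base, rem = divmod(total, n_bins)
    return [base + (1 if i < rem else 0) for i in range(n_bins)]


def build_schedule(
    design: StudyDesign, participant_id: str, seed: int = 0
) -> pd.DataFrame:
    """One participant's randomised trial schedule.

    Same trials are spread round-robin over objects (base count, plus the
    extra same trials per object); different trials are spread round-robin
    over unordered pairs, splitting each pair's count as evenly as possible
    between the two presentation orders.  Trial order is shuffled by a
    stream derived from ``(seed, participant)``.

    Returns a frame with columns ``participant, stim_first, stim_second``.
    """
    objects = list(design.objects)
    pairs = list(combinations(objects, 2))

    first, second = [], []
    same_counts = _round_robin(design.base_same_trials, len(objects))
    for obj, n_base in zip(objects, same_counts):
        n = n_base + design.extra_same_per_object
        first += [obj] * n
        second += [obj] * n
    for (a, b), n in zip(pairs, _round_robin(design.base_different_trials, len(pairs))):
        n_ab = n // 2
        first += [a] * n_ab + [b] * (n - n_ab)
        second += [b] * n_ab + [a] * (n - n_ab)

    df = pd.DataFrame(
        {"participant": participant_id, "stim_first": first, "stim_second": second}
    )
    if participant_id in design.participant_ids:
        p_index = design.participant_ids.index(participant_id)
    else:
        p_index = zlib.crc32(participant_id.encode("utf-8")) % 2**31
    rng = _rng(seed, p_index, 0)
    return df.iloc[rng.permutation(len(df))].reset_index(drop=True)


def _rigid_motion(rng: np.random.Generator, coords: np.ndarray) -> np.ndarray:
    theta = rng.uniform(0.0, 2.0 * np.pi)
    R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    out = coords @ R.T
    if rng.random() < 0.5:
        out = out * np.array([-1.0, 1.0])  # reflect across the y-axis
    return out + rng.uniform(-1.0, 1.0, size=2)


def sample_participant_space(world: LatentWorld, participant_index: int) -> np.ndarray:
    """One participant's personal configuration: rigid motion + Gaussian jitter."""
    coords = world.true_configuration
    if world.participant_transform == "rigid":
        coords = _rigid_motion(_rng(world.seed, participant_index, 1), coords)
    if world.participant_jitter_sd > 0:
        jitter = _rng(world.seed, participant_index, 2).normal(
            0.0, world.participant_jitter_sd, size=coords.shape
        )
        coords = coords + jitter
    return coords


def simulate_responses(
    space: np.ndarray,
    schedule: pd.DataFrame,
    world: LatentWorld,
    design: StudyDesign,
    participant_index: int,
) -> pd.DataFrame:
    """Fill a schedule with SDT responses and reaction times.

    Different trials of a pair at perceptual distance d: P("different") =
    Phi(scale * d - c); same trials: P("different") = Phi(-c).
    """
    index = {lab: i for i, lab in enumerate(design.objects)}
    i1 = schedule["stim_first"].map(index).to_numpy()
    i2 = schedule["stim_second"].map(index).to_numpy()
    d = np.sqrt(((space[i1] - space[i2]) ** 2).sum(axis=1))
    c = world.effective_criterion
    p_diff = ndtr(world.dprime_scale * d - c)
    p_diff[i1 == i2] = ndtr(-c)

    rng = _rng(world.seed, participant_index, 3)
    responses = np.where(
        rng.random(len(schedule)) < p_diff, RESPONSE_DIFFERENT, RESPONSE_SAME
    )
    lo, hi = design.rt_range_ms
    rt = rng.uniform(lo, hi, size=len(schedule))
    if world.rt_contamination > 0:
        contaminate = rng.random(len(schedule)) < world.rt_contamination
        fast = rng.random(len(schedule)) < 0.5
        rt = np.where(contaminate & fast, rng.uniform(50.0, 299.0, len(schedule)), rt)
        rt = np.where(
            contaminate & ~fast, rng.uniform(2301.0, 3200.0, len(schedule)), rt
        )
    out = schedule.copy()
    out["response"] = responses
    out["rt_ms"] = rt
    return out


def simulate_study(design: StudyDesign, world: LatentWorld) -> TrialTable:
    """A complete synthetic study: every participant's schedule and responses."""
    frames = []
    for i, pid in enumerate(design.participant_ids):
        schedule = build_schedule(design, pid, seed=world.seed)
        space = sample_participant_space(world, i)
        frames.append(simulate_responses(space, schedule, world, design, i))
    data = pd.concat(frames, ignore_index=True)[list(TRIAL_COLUMNS)]
    return TrialTable(data, design.objects)


def participant_spaces(design: StudyDesign, world: LatentWorld) -> list[np.ndarray]:
    """Each participant's personal configuration, in participant order."""
    return [
        sample_participant_space(world, i) for i in range(design.n_participants)
    ]


def exact_sensitivity_matrices(
    design: StudyDesign, world: LatentWorld
) -> dict[str, DissimilarityMatrix]:
    """Infinite-trial d' matrices: scale x pairwise distance of each space.

    This is the noise-free limit of the response simulation — useful for
    checking that the per-participant pipeline recovers latent distances and
    areas exactly under rigid motion.
    """
    out = {}
    for pid, space in zip(design.participant_ids, participant_spaces(design, world)):
        D = world.dprime_scale * squareform(pdist(space))
        out[pid] = DissimilarityMatrix(design.objects, D)
    return out


def ground_truth(design: StudyDesign, world: LatentWorld) -> dict:
    """Latent quantities for recovery scoring: coordinates, distances, areas."""
    from .geometry import group_area

    cfg = world.true_configuration
    labels = design.objects
    dist = squareform(pdist(cfg))
    truth = {
        "objects": list(labels),
        "true_configuration": cfg.tolist(),
        "true_distances": {
            f"{a}-{b}": float(dist[i, j])
            for (i, a), (j, b) in combinations(enumerate(labels), 2)
        },
    }
    if len(labels) >= 6:
        rhotics, fricatives = labels[:3], labels[3:6]
        for name, grp in (("rhotics", rhotics), ("fricatives", fricatives)):
            pts = cfg[[labels.index(g) for g in grp]]
            area, _ = group_area(pts, grp)
            truth[f"true_area_{name}"] = float(area)
    return truth
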