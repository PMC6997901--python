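"""Statsmodels-style front end: a PerceptualMDS model and its fitted results.

``PerceptualMDS`` bundles the whole per-participant pipeline — reaction-time
filtering, per-pair d' sensitivity, classical MDS per participant — behind a
single ``fit()`` call; the returned :class:`PerceptualMDSResults` exposes the
per-participant solutions, geometry statistics (distances in p.u., dispersion
areas in p.u.^2), their cross-participant comparisons, a text summary, and
the plots.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.iolib.table import SimpleTable

from . import geometry, pcoa, sensitivity
from .exceptions import ValidationError
from .inference import ComparisonResult, TestName, compare
from .trials import (
    RT_MAX_MS,
    RT_MIN_MS,
    DissimilarityMatrix,
    TrialTable,
    filter_rt,
    read_trials,
)


class PerceptualMDS:
    """Per-participant multidimensional scaling of discrimination data.

    Parameters
    ----------
    trials
        Trial-level discrimination data, or ``None`` when constructing from
        pre-computed dissimilarity matrices.
    dissimilarities
        Mapping participant id -> :class:`DissimilarityMatrix`, bypassing the
        d' front end.
    rt_bounds
        Reaction-time window in ms; trials outside it are discarded before
        computing sensitivities (inclusive bounds).  ``None`` disables the
        filter.
    correction
        Extreme-rate correction for d' (``"clamp"`` or ``"loglinear"``).
    floor_negative
        Floor negative d' at 0 when building dissimilarity matrices.
    k
        Embedding dimensionality (2 for the standard planar solution).
    align
        ``"none"`` averages raw coordinates for the mean plot (the literal
        procedure); ``"procrustes"`` rigidly aligns solutions first.
    """

    def __init__(
        self,
        trials: TrialTable | None = None,
        dissimilarities: Mapping[str, DissimilarityMatrix] | None = None,
        *,
        rt_bounds: tuple[float, float] | None = (RT_MIN_MS, RT_MAX_MS),
        correction: sensitivity.Correction = "clamp",
        floor_negative: bool = True,
        k: int = 2,
        align: pcoa.Align = "none",
    ):
        if (trials is None) == (dissimilarities is None):
            raise ValidationError(
                "supply exactly one of trials= or dissimilarities="
            )
        self.trials = trials
        self.dissimilarities = dict(dissimilarities) if dissimilarities else None
        self.rt_bounds = rt_bounds
        self.correction = correction
        self.floor_negative = floor_negative
        self.k = k
        self.align = align

    @classmethod
    def from_csv(cls, path: str | Path, objects: Sequence[str] | None = None, **kwargs):
        """Build the model from a trial CSV (see :func:`mdsinfer.read_trials`)."""
        return cls(trials=read_trials(path, objects), **kwargs)

    @classmethod
    def from_dissimilarities(
        cls, matrices: Mapping[str, DissimilarityMatrix], **kwargs
    ):
        """Build the model from per-participant dissimilarity matrices."""
        return cls(dissimilarities=matrices, **kwargs)

    def fit(self) -> "PerceptualMDSResults":
        """Run filtering, d' estimation and per-participant classical MDS."""
        if self.dissimilarities is not None:
            matrices = dict(self.dissimilarities)
            n_filtered = 0
        else:
            table = self.trials
            n_before = len(table)
            if self.rt_bounds is not None:
                table = filter_rt(table, *self.rt_bounds)
            n_filtered = n_before - len(table)
            matrices = sensitivity.sensitivity_matrices(
                table,
                correction=self.correction,
                floor_negative=self.floor_negative,
            )
        if not matrices:
            raise ValidationError("no participant yielded a complete d' matrix")
        solutions = pcoa.per_participant_solutions(matrices, k=self.k)
        aggregate = pcoa.average_coordinates(solutions, align=self.align)
        grand_mean = pcoa.grand_mean_solution(matrices, k=self.k)
        return PerceptualMDSResults(
            model=self,
            matrices=matrices,
            solutions=solutions,
            aggregate=aggregate,
            grand_mean=grand_mean,
            n_trials_filtered=n_filtered,
        )


class PerceptualMDSResults:
    """Fitted per-participant MDS: solutions, geometry statistics, comparisons."""

    def __init__(
        self,
        model: PerceptualMDS,
        matrices: Mapping[str, DissimilarityMatrix],
        solutions: list[pcoa.MDSSolution],
        aggregate: pcoa.AggregateConfiguration,
        grand_mean: pcoa.MDSSolution,
        n_trials_filtered: int,
    ):
        self.model = model
        self.matrices = dict(matrices)
        self.solutions = solutions
        self.aggregate = aggregate
        self.grand_mean = grand_mean
        self.n_trials_filtered = n_trials_filtered

    @property
    def participants(self) -> list[str]:
        return [s.participant_id for s in self.solutions]

    @property
    def labels(self) -> tuple[str, ...]:
        return self.solutions[0].labels

    @property
    def n_participants(self) -> int:
        return len(self.solutions)

    # ---- geometry statistics -------------------------------------------------

    def distances(self, a: str, b: str) -> list[geometry.GeometryStat]:
        """Per-participant Euclidean distance between objects a and b (p.u.)."""
        return geometry.per_participant_stats(self.solutions, (a, b), "distance")

    def areas(self, members: Sequence[str]) -> list[geometry.GeometryStat]:
        """Per-participant dispersion area of an object group (p.u.^2)."""
        return geometry.per_participant_stats(self.solutions, members, "area")

    def compare_distances(
        self,
        pair_a: tuple[str, str],
        pair_b: tuple[str, str],
        test: TestName = "welch_t",
        alpha: float = 0.05,
    ) -> ComparisonResult:
        """Compare two object-pair distances across participants."""
        return compare(
            self.distances(*pair_a), self.distances(*pair_b), test=test, alpha=alpha
        )

    def compare_areas(
        self,
        group_a: Sequence[str],
        group_b: Sequence[str],
        test: TestName = "welch_t",
        alpha: float = 0.05,
    ) -> ComparisonResult:
        """Compare the dispersion areas of two object groups across participants."""
        return compare(self.areas(group_a), self.areas(group_b), test=test, alpha=alpha)

    # ---- tables and summary --------------------------------------------------

    def coordinates_frame(self) -> pd.DataFrame:
        """Tidy per-participant coordinates (participant, label, dim1, dim2, ...)."""
        return pd.concat([s.to_frame() for s in self.solutions], ignore_index=True)

    def mean_coordinates(self) -> pd.DataFrame:
        return self.aggregate.to_frame()

    def eigenvalue_diagnostics(self) -> pd.DataFrame:
        """Per-participant eigenvalue diagnostics for non-Euclidean inputs."""
        return pd.DataFrame(
            {
                "participant": [s.participant_id for s in self.solutions],
                "top_eigenvalue": [s.eigenvalues[0] for s in self.solutions],
                "n_negative_eigenvalues": [
                    s.n_negative_eigenvalues for s in self.solutions
                ],
                "negative_share": [s.negative_share for s in self.solutions],
            }
        )

    def summary(self) -> str:
        """Human-readable fit summary (participants, diagnostics, mean layout)."""
        diag = self.eigenvalue_diagnostics()
        header = SimpleTable(
            [
                ["participants", str(self.n_participants)],
                ["objects", " ".join(self.labels)],
                ["dimensions (k)", str(self.model.k)],
                ["alignment", self.aggregate.align],
                ["trials removed by RT filter", str(self.n_trials_filtered)],
                ["mean negative-eigenvalue share", f"{diag['negative_share'].mean():.3f}"],
            ],
            title="Per-participant MDS fit",
        )
        mean = self.mean_coordinates()
        coords = SimpleTable(
            [
                [row["label"]] + [f"{row[c]:+.3f}" for c in mean.columns[1:]]
                for _, row in mean.iterrows()
            ],
            headers=["object"] + list(mean.columns[1:]),
            title="Mean coordinates (p.u.)",
        )
        return f"{header.as_text()}\n\n{coords.as_text()}"

    # ---- plotting ------------------------------------------------------------

    def plot(self, groups=None, comparisons=None, ax=None):
        """Mean-configuration scatter (see :func:`mdsinfer.plotting.plot_mds`)."""
        from .plotting import plot_mds

        return plot_mds(self.aggregate, groups=groups, comparisons=comparisons, ax=ax)

    def plot_violin(self, stats_a, stats_b, labels=None, ax=None):
        from .plotting import plot_violin

        return plot_violin(stats_a, stats_b, labels=labels, ax=ax)
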