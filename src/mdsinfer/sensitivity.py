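"""Per-participant, per-pair d' sensitivity and the d' dissimilarity matrix.

For an unordered stimulus pair {A, B}, the hit rate is the proportion of
"different" responses on trials that actually presented A and B (either
order), and the false-alarm rate pools the "different" responses on the
same-trials AA and BB.  Sensitivity is the yes/no-style index

    d' = z(hit rate) - z(false-alarm rate),

with z the standard-normal quantile.  Extreme rates (0 or 1) are corrected so
d' stays finite; each participant's pairwise d' values form their personal
dissimilarity matrix, the input to multidimensional scaling.
"""

from __future__ import annotations

import logging
import warnings
from itertools import combinations
from typing import Iterable, Literal

import numpy as np
import pandas as pd
from scipy.special import ndtri

from .exceptions import MissingCellError, NegativeDPrimeWarning
from .trials import RESPONSE_DIFFERENT, DissimilarityMatrix, TrialTable

logger = logging.getLogger(__name__)

Correction = Literal["clamp", "loglinear"]

RATE_COLUMNS = (
    "participant",
    "stim_a",
    "stim_b",
    "hit_rate",
    "fa_rate",
    "n_hit_trials",
    "n_fa_trials",
)


def response_rates(table: TrialTable, participant: str | None = None) -> pd.DataFrame:
    """Tabulate hit and false-alarm rates per participant and unordered pair.

    Returns a tidy frame with columns ``participant, stim_a, stim_b, hit_rate,
    fa_rate, n_hit_trials, n_fa_trials``; pairs for which either trial kind is
    absent get NaN rates and a zero count (the missing-cell signal consumed by
    :func:`sensitivity_matrix`).  ``(A,B)`` and ``(B,A)`` presentations are
    pooled.
    """
    df = table.data
    if participant is not None:
        df = df[df["participant"] == participant]
    objects = list(table.objects)

    is_diff_resp = df["response"] == RESPONSE_DIFFERENT
    is_same_trial = df["stim_first"] == df["stim_second"]

    # per participant x object: same-trial counts ("different" responses = FAs)
    same = df[is_same_trial]
    fa_counts = (
        pd.DataFrame(
            {
                "participant": same["participant"],
                "obj": same["stim_first"],
                "fa": is_diff_resp[is_same_trial].astype(int),
            }
        )
        .groupby(["participant", "obj"], sort=False)["fa"]
        .agg(["sum", "count"])
    )

    # per participant x unordered pair: different-trial counts (hits)
    diff = df[~is_same_trial]
    first_low = diff["stim_first"] <= diff["stim_second"]
    lo = diff["stim_first"].where(first_low, diff["stim_second"])
    hi = diff["stim_second"].where(first_low, diff["stim_first"])
    hit_counts = (
        pd.DataFrame(
            {
                "participant": diff["participant"],
                "a": lo,
                "b": hi,
                "hit": is_diff_resp[~is_same_trial].astype(int),
            }
        )
        .groupby(["participant", "a", "b"], sort=False)["hit"]
        .agg(["sum", "count"])
    )

    participants = [participant] if participant is not None else list(
        dict.fromkeys(df["participant"])
    )
    rows = []
    for pid in participants:
        for a, b in combinations(objects, 2):
            key = (pid, *sorted((a, b)))
            if key in hit_counts.index:
                h_sum, h_n = hit_counts.loc[key]
            else:
                h_sum, h_n = 0, 0
            f_sum = f_n = 0
            for obj in (a, b):
                if (pid, obj) in fa_counts.index:
                    s, c = fa_counts.loc[(pid, obj)]
                    f_sum += s
                    f_n += c
            rows.append(
                {
                    "participant": pid,
                    "stim_a": a,
                    "stim_b": b,
                    "hit_rate": h_sum / h_n if h_n else np.nan,
                    "fa_rate": f_sum / f_n if f_n else np.nan,
                    "n_hit_trials": int(h_n),
                    "n_fa_trials": int(f_n),
                }
            )
    return pd.DataFrame(rows, columns=list(RATE_COLUMNS))


def _correct_rate(rate, n, correction: Correction):
    rate = np.asarray(rate, dtype=float)
    n = np.asarray(n, dtype=float)
    if correction == "clamp":
        lo = 1.0 / (2.0 * n)
        return np.clip(rate, lo, 1.0 - lo)
    if correction == "loglinear":
        return (rate * n + 0.5) / (n + 1.0)
    raise ValueError(f"unknown correction {correction!r}")


def dprime(
    hit_rate,
    fa_rate,
    n_hit_trials,
    n_fa_trials,
    correction: Correction = "clamp",
):
    """Sensitivity d' = z(hit) - z(fa) with an extreme-rate correction.

    ``correction="clamp"`` clips each rate into ``[1/(2N), 1 - 1/(2N)]``
    (N = number of trials behind that rate); ``"loglinear"`` uses the
    (count + 0.5)/(N + 1) smoothing.  Accepts scalars or arrays (broadcasting).
    """
    h = _correct_rate(hit_rate, n_hit_trials, correction)
    f = _correct_rate(fa_rate, n_fa_trials, correction)
    return ndtri(h) - ndtri(f)


def sensitivity_matrix(
    table: TrialTable,
    participant: str,
    correction: Correction = "clamp",
    floor_negative: bool = True,
) -> DissimilarityMatrix:
    """One participant's symmetric d' dissimilarity matrix (zero diagonal).

    Raises :class:`MissingCellError` when any pair lacks hit or false-alarm
    trials.  Negative d' values are floored at 0 by default (with a warning),
    since PCoA expects non-negative dissimilarities; pass
    ``floor_negative=False`` to keep them (the matrix constructor will then
    reject the negative entries).
    """
    if participant not in table.participants:
        raise MissingCellError(f"participant {participant!r} not present in table")
    rates = response_rates(table, participant)
    missing = rates[(rates["n_hit_trials"] == 0) | (rates["n_fa_trials"] == 0)]
    if len(missing):
        pairs = [f"({r.stim_a},{r.stim_b})" for r in missing.itertuples()]
        raise MissingCellError(
            f"participant {participant!r} has no usable trials for pair(s) "
            f"{', '.join(pairs)}"
        )
    d = dprime(
        rates["hit_rate"],
        rates["fa_rate"],
        rates["n_hit_trials"],
        rates["n_fa_trials"],
        correction=correction,
    )
    d = np.asarray(d, dtype=float)
    if floor_negative and (d < 0).any():
        warnings.warn(
            f"participant {participant!r}: floored {(d < 0).sum()} negative d' "
            "value(s) at 0",
            NegativeDPrimeWarning,
        )
        d = np.maximum(d, 0.0)

    labels = tuple(table.objects)
    index = {lab: i for i, lab in enumerate(labels)}
    values = np.zeros((len(labels), len(labels)))
    for (_, a, b), val in zip(
        rates[["participant", "stim_a", "stim_b"]].itertuples(index=False), d
    ):
        i, j = index[a], index[b]
        values[i, j] = values[j, i] = val
    return DissimilarityMatrix(labels, values)


def sensitivity_matrices(
    table: TrialTable,
    correction: Correction = "clamp",
    floor_negative: bool = True,
    on_missing: Literal["skip", "raise"] = "skip",
) -> dict[str, DissimilarityMatrix]:
    """d' matrices for every participant, keyed by participant id.

    Participants with any missing pair are excluded with a logged warning
    (``on_missing="skip"``, the default) so that every retained participant
    contributes a complete matrix to the downstream statistics.
    """
    out: dict[str, DissimilarityMatrix] = {}
    for pid in table.participants:
        try:
            out[pid] = sensitivity_matrix(
                table, pid, correction=correction, floor_negative=floor_negative
            )
        except MissingCellError:
            if on_missing == "raise":
                raise
            warnings.warn(
                f"excluding participant {pid!r}: incomplete d' matrix after filtering",
                UserWarning,
            )
            logger.warning("excluding participant %s: incomplete d' matrix", pid)
    return out


def grand_mean_matrix(
    matrices: Iterable[DissimilarityMatrix],
) -> DissimilarityMatrix:
    """Element-wise mean of per-participant matrices (the 'average d-prime' input)."""
    matrices = list(matrices)
    if not matrices:
        raise ValueError("no matrices to average")
    labels = matrices[0].labels
    for m in matrices[1:]:
        if m.labels != labels:
            raise ValueError("matrices have mismatched labels")
    return DissimilarityMatrix(labels, np.mean([m.values for m in matrices], axis=0))
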