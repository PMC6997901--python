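"""Trial-level discrimination data and dissimilarity matrices.

The raw input of the pipeline is a long-format table of AX (same-different)
discrimination trials: one row per trial with the participant, the two stimulus
labels, the binary response and the reaction time in milliseconds.  The unit
handed to multidimensional scaling is a labelled, symmetric, zero-diagonal
dissimilarity matrix per participant ("perceptual units", p.u.).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import FormatError, ValidationError

logger = logging.getLogger(__name__)

RESPONSE_SAME = "same"
RESPONSE_DIFFERENT = "different"
RESPONSES = (RESPONSE_SAME, RESPONSE_DIFFERENT)

#: Required columns of a trial CSV, in canonical order.
TRIAL_COLUMNS = ("participant", "stim_first", "stim_second", "response", "rt_ms")

#: Reaction-time window outside which responses are discarded (ms).
RT_MIN_MS = 300.0
RT_MAX_MS = 2300.0


@dataclass(frozen=True)
class TrialTable:
    """An ordered collection of discrimination trials plus the object inventory.

    Parameters
    ----------
    data
        DataFrame with columns ``participant, stim_first, stim_second,
        response, rt_ms``.  Responses are normalised to ``"same"`` /
        ``"different"``; reaction times are positive floats in milliseconds.
    objects
        The declared stimulus inventory.  Every label appearing in the data
        must be a member.
    """

    data: pd.DataFrame
    objects: tuple[str, ...]

    def __post_init__(self):
        missing = [c for c in TRIAL_COLUMNS if c not in self.data.columns]
        if missing:
            raise FormatError(f"trial table missing column(s): {', '.join(missing)}")
        if len(self.objects) < 2:
            raise ValidationError("object inventory must contain at least 2 labels")
        inventory = set(self.objects)
        seen = set(self.data["stim_first"]) | set(self.data["stim_second"])
        unknown = seen - inventory
        if unknown:
            raise ValidationError(
                f"trial labels not in object inventory: {sorted(unknown)}"
            )
        bad_resp = set(self.data["response"]) - set(RESPONSES)
        if bad_resp:
            raise ValidationError(f"invalid response values: {sorted(bad_resp)}")
        if len(self.data) and not (self.data["rt_ms"] > 0).all():
            raise ValidationError("reaction times must be positive")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def participants(self) -> list[str]:
        """Participant identifiers in order of first appearance."""
        return list(dict.fromkeys(self.data["participant"]))

    @property
    def n_participants(self) -> int:
        return len(self.participants)

    def for_participant(self, participant_id: str) -> pd.DataFrame:
        return self.data[self.data["participant"] == participant_id]

    def is_same_trial(self) -> pd.Series:
        """Boolean mask: True where the two presented stimuli are identical."""
        return self.data["stim_first"] == self.data["stim_second"]


def read_trials(
    path: str | Path, object_inventory: Sequence[str] | None = None
) -> TrialTable:
    """Read a trial CSV (``participant,stim_first,stim_second,response,rt_ms``).

    Responses are case-insensitive.  When *object_inventory* is omitted the
    inventory is inferred from the labels present (sorted for determinism);
    when given, unknown labels raise :class:`ValidationError`.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={c: str for c in TRIAL_COLUMNS[:4]}, encoding="utf-8")
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path.name}: missing column(s): {', '.join(missing)}")

    rt = pd.to_numeric(df["rt_ms"], errors="coerce")
    bad = rt.isna() | (rt <= 0)
    if bad.any():
        # +2: one for the header row, one for 0- vs 1-based indexing
        lines = [str(i + 2) for i in df.index[bad][:5]]
        raise FormatError(
            f"{path.name}: non-numeric or non-positive rt_ms on line(s) {', '.join(lines)}"
        )
    df = df.assign(rt_ms=rt.astype(float))

    resp = df["response"].str.strip().str.lower()
    bad = ~resp.isin(RESPONSES)
    if bad.any():
        lines = [str(i + 2) for i in df.index[bad][:5]]
        raise FormatError(
            f"{path.name}: response must be same/different; bad value(s) on line(s) "
            f"{', '.join(lines)}"
        )
    df = df.assign(response=resp)

    for col in ("participant", "stim_first", "stim_second"):
        df[col] = df[col].str.strip()

    if object_inventory is None:
        objects = tuple(sorted(set(df["stim_first"]) | set(df["stim_second"])))
    else:
        objects = tuple(object_inventory)
    return TrialTable(df[list(TRIAL_COLUMNS)].reset_index(drop=True), objects)


def filter_rt(
    table: TrialTable, min_ms: float = RT_MIN_MS, max_ms: float = RT_MAX_MS
) -> TrialTable:
    """Discard trials with reaction times outside ``[min_ms, max_ms]``.

    Boundary values are kept (only responses strictly faster than *min_ms* or
    strictly slower than *max_ms* are discarded).  Record order is preserved
    and the per-participant removal counts are logged.
    """
    if not min_ms < max_ms:
        raise ValueError(f"min_ms ({min_ms}) must be < max_ms ({max_ms})")
    keep = (table.data["rt_ms"] >= min_ms) & (table.data["rt_ms"] <= max_ms)
    removed = table.data.loc[~keep, "participant"].value_counts()
    for pid, n in removed.items():
        logger.info("filter_rt: participant %s: removed %d trial(s)", pid, n)
    out = TrialTable(table.data[keep].reset_index(drop=True), table.objects)
    if len(table) and not len(out):
        warnings.warn(
            f"filter_rt removed every trial (bounds {min_ms}-{max_ms} ms)", UserWarning
        )
    return out


@dataclass(frozen=True)
class DissimilarityMatrix:
    """A labelled symmetric dissimilarity matrix with zero diagonal.

    Entries are non-negative dissimilarities in the input's own unit — here
    d' values, i.e. perceptual units (p.u.).
    """

    labels: tuple[str, ...]
    values: np.ndarray
    #: numeric tolerance for the symmetry / zero-diagonal checks
    tol: float = field(default=1e-9, repr=False, compare=False)

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "labels", tuple(self.labels))
        n = len(self.labels)
        if values.shape != (n, n):
            raise ValidationError(
                f"matrix shape {values.shape} does not match {n} labels"
            )
        if n < 2:
            raise ValidationError("dissimilarity matrix needs at least 2 objects")
        if not np.all(np.isfinite(values)):
            raise ValidationError("dissimilarity matrix contains non-finite entries")
        asym = np.abs(values - values.T).max() if n else 0.0
        if asym > self.tol:
            raise ValidationError(f"matrix asymmetric (max |D - D'| = {asym:.3g})")
        diag = np.abs(np.diag(values)).max()
        if diag > self.tol:
            raise ValidationError(f"matrix diagonal not zero (max |d_ii| = {diag:.3g})")
        if (values < -self.tol).any():
            raise ValidationError("dissimilarity matrix has negative entries")

    @property
    def n(self) -> int:
        return len(self.labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def read_dissimilarity(path: str | Path) -> DissimilarityMatrix:
    """Read a labelled square dissimilarity CSV (labels in header and first column)."""
    path = Path(path)
    df = pd.read_csv(path, index_col=0, encoding="utf-8")
    labels = tuple(str(c) for c in df.columns)
    row_labels = tuple(str(i) for i in df.index)
    if labels != row_labels:
        raise FormatError(
            f"{path.name}: row labels {row_labels} do not match column labels {labels}"
        )
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise FormatError(f"{path.name}: non-numeric matrix entry ({exc})") from None
    return DissimilarityMatrix(labels, values)


def write_dissimilarity(matrix: DissimilarityMatrix, path: str | Path) -> None:
    """Write a labelled square dissimilarity CSV; round-trips through read."""
    matrix.to_frame().to_csv(Path(path), encoding="utf-8")
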