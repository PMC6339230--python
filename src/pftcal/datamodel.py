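"""Core data types, fixation extraction, and training-set assembly.

An eye tracker emits a stream of timestamped feature vectors ``(e1..en)`` in
device units (eye-camera pixel coordinates, glint vectors, EOG voltages, ...).
Implicit calibration aggregates this stream into *fixations*, attaches to each
fixation the list of probable fixation targets (PFTs) visible on screen at the
time, and searches for the assignment of one target per fixation that best
explains the uncalibrated signal.  The types here carry that pipeline:

``Fixation``      one aggregated eye event with a representative feature vector
``TargetSet``     the candidate targets attached to one fixation
``TrainingSet``   the M (fixation, target set) pairs a mapping is scored on
``Mapping``       one chosen target index per fixation (0-based internally)
``ReferenceSet``  (features, known position) pairs for explicit calibration
                  (calPoints) or error measurement (refPoints)

All target/gaze coordinates are scene-percent: 0-100% of scene width/height.
Eye features stay in device units throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import prod
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Fixation",
    "TargetSet",
    "TrainingSet",
    "Mapping",
    "ScoredMapping",
    "ReferenceSet",
    "SceneEntry",
    "SceneSchedule",
    "extract_fixations",
    "build_training_set",
    "mapping_space_size",
]


@dataclass(frozen=True)
class Fixation:
    """One aggregated eye event.

    Attributes
    ----------
    id : int
        Ordinal within the session (0-based).
    E : ndarray of shape (n,)
        Representative eye-feature vector: the centroid of the samples that
        form the fixation, in device units.
    t_start, t_end : float
        Timestamps (ms) of the first and last sample in the run.
    n_samples : int
        Number of raw samples aggregated.
    """

    id: int
    E: np.ndarray
    t_start: float
    t_end: float
    n_samples: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "E", np.asarray(self.E, dtype=float))
        if self.t_end < self.t_start:
            raise ValueError("fixation must end after it starts")
        if self.n_samples < 1:
            raise ValueError("fixation needs at least one sample")

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.t_start + self.t_end)


@dataclass(frozen=True)
class TargetSet:
    """Ordered candidate targets for one fixation (indices are meaningful)."""

    fixation_id: int
    targets: np.ndarray  # (m_i, 2) scene-percent

    def __post_init__(self) -> None:
        t = np.atleast_2d(np.asarray(self.targets, dtype=float))
        if t.shape[0] < 1 or t.shape[1] != 2:
            raise ValueError("a target set needs at least one (x, y) target")
        if not np.all(np.isfinite(t)):
            raise ValueError("targets must be finite")
        object.__setattr__(self, "targets", t)

    def __len__(self) -> int:
        return self.targets.shape[0]


class TrainingSet:
    """The M fixations with their candidate-target lists.

    Parameters
    ----------
    features : array-like of shape (M, n)
        Representative eye-feature vector per fixation, device units.
    target_sets : sequence of array-like, each of shape (m_i, 2)
        Candidate targets per fixation, scene-percent.
    fixations : optional sequence of :class:`Fixation`
        Timing metadata; not required for scoring.
    """

    def __init__(
        self,
        features,
        target_sets: Sequence,
        fixations: Sequence[Fixation] | None = None,
    ):
        self.features = np.atleast_2d(np.asarray(features, dtype=float))
        self.target_sets = [
            np.atleast_2d(np.asarray(t, dtype=float)) for t in target_sets
        ]
        if self.features.shape[0] != len(self.target_sets):
            raise ValueError("one target set per fixation is required")
        for t in self.target_sets:
            if t.shape[0] < 1 or t.shape[1] != 2:
                raise ValueError("every fixation needs at least one (x, y) target")
        self.fixations = list(fixations) if fixations is not None else None

    @property
    def M(self) -> int:
        return self.features.shape[0]

    @property
    def n(self) -> int:
        return self.features.shape[1]

    @property
    def m(self) -> np.ndarray:
        """Number of candidate targets per fixation, shape (M,)."""
        return np.array([t.shape[0] for t in self.target_sets])

    def prefix(self, k: int) -> "TrainingSet":
        """The training set restricted to the first ``k`` fixations."""
        return TrainingSet(
            self.features[:k],
            self.target_sets[:k],
            self.fixations[:k] if self.fixations is not None else None,
        )

    def chosen(self, mapping) -> np.ndarray:
        """Target coordinates selected by a mapping, shape (M, 2)."""
        idx = np.asarray(getattr(mapping, "indices", mapping), dtype=int)
        return np.array(
            [self.target_sets[i][idx[i]] for i in range(self.M)]
        )

    def chosen_batch(self, mappings: np.ndarray) -> np.ndarray:
        """Targets for a batch of mappings, shape (B, M, 2).

        Vectorized by padding the per-fixation target lists to a common
        length; indices must already be valid so padding is never selected.
        """
        mappings = np.atleast_2d(np.asarray(mappings, dtype=int))
        k = mappings.shape[1]  # may be a prefix during incremental search
        pad = self._padded_targets()
        return pad[np.arange(k)[None, :], mappings]

    def _padded_targets(self) -> np.ndarray:
        cached = getattr(self, "_pad_cache", None)
        if cached is None:
            m_max = int(self.m.max())
            cached = np.zeros((self.M, m_max, 2))
            for i, t in enumerate(self.target_sets):
                cached[i, : t.shape[0]] = t
            self._pad_cache = cached
        return cached

    def validate_mapping(self, indices: np.ndarray) -> None:
        indices = np.asarray(indices, dtype=int)
        if indices.shape != (self.M,):
            raise ValueError(f"mapping length {indices.shape} != M={self.M}")
        if np.any(indices < 0) or np.any(indices >= self.m):
            raise ValueError("mapping index outside its fixation's target count")

    def __len__(self) -> int:
        return self.M


@dataclass(frozen=True)
class Mapping:
    """One chosen target index per fixation (0-based)."""

    indices: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "indices", np.asarray(self.indices, dtype=int).ravel()
        )

    def __len__(self) -> int:
        return self.indices.shape[0]

    def __eq__(self, other) -> bool:
        if isinstance(other, Mapping):
            other = other.indices
        return np.array_equal(self.indices, np.asarray(other))


@dataclass(frozen=True)
class ScoredMapping:
    """A mapping together with its score under one comparison function."""

    mapping: Mapping
    score: float
    mcf_id: str

    def __post_init__(self) -> None:
        if not np.isfinite(self.score):
            raise ValueError("mapping score must be finite")


@dataclass(frozen=True)
class ReferenceSet:
    """Eye features paired with known on-screen positions.

    ``role='calibration'`` marks calPoints (input to explicit calibration);
    ``role='reference'`` marks refPoints (ground truth for error reports).
    """

    features: np.ndarray  # (K, n)
    points: np.ndarray  # (K, 2) scene-percent
    role: str = "reference"

    def __post_init__(self) -> None:
        f = np.atleast_2d(np.asarray(self.features, dtype=float))
        p = np.atleast_2d(np.asarray(self.points, dtype=float))
        if f.shape[0] != p.shape[0] or f.shape[0] == 0:
            raise ValueError("features and points must pair up, non-empty")
        if self.role not in ("calibration", "reference"):
            raise ValueError("role must be 'calibration' or 'reference'")
        object.__setattr__(self, "features", f)
        object.__setattr__(self, "points", p)

    def __len__(self) -> int:
        return self.features.shape[0]


@dataclass(frozen=True)
class SceneEntry:
    """One schedule entry: a scene shown during [t_start, t_end)."""

    scene_id: str
    t_start: float
    t_end: float
    targets: np.ndarray  # (m, 2) scene-percent; template copied to fixations
    stimulus: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "targets", np.atleast_2d(np.asarray(self.targets, dtype=float))
        )
        if self.t_end <= self.t_start:
            raise ValueError("scene interval must have positive length")

    def contains(self, t: float) -> bool:
        return self.t_start <= t < self.t_end


class SceneSchedule:
    """Time-sorted, non-overlapping list of :class:`SceneEntry`."""

    def __init__(self, entries: Iterable[SceneEntry]):
        self.entries = sorted(entries, key=lambda e: e.t_start)
        for a, b in zip(self.entries, self.entries[1:]):
            if b.t_start < a.t_end:
                raise ValueError(
                    f"scene intervals overlap: {a.scene_id} and {b.scene_id}"
                )

    def entry_at(self, t: float) -> SceneEntry | None:
        for e in self.entries:
            if e.contains(t):
                return e
        return None

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)


# ---------------------------------------------------------------------------
# Fixation extraction (dispersion-threshold aggregation)
# ---------------------------------------------------------------------------

def _as_samples(samples) -> tuple[np.ndarray, np.ndarray]:
    """Accept a DataFrame (column 't' + feature columns) or an (t, E) pair."""
    if isinstance(samples, pd.DataFrame):
        if "t" not in samples.columns:
            raise ValueError("samples DataFrame needs a 't' column")
        t = samples["t"].to_numpy(dtype=float)
        E = samples.drop(columns="t").to_numpy(dtype=float)
    else:
        t, E = samples
        t = np.asarray(t, dtype=float)
        E = np.atleast_2d(np.asarray(E, dtype=float))
        if E.shape[0] != t.shape[0]:
            E = E.T
    return t, E


def extract_fixations(samples, min_run: int = 5, dispersion: float = 5.0):
    """Aggregate a raw sample stream into fixations.

    A maximal run of at least ``min_run`` consecutive samples whose features
    all stay strictly within ``dispersion`` (Euclidean, device units) of the
    run's running centroid becomes one :class:`Fixation` whose representative
    feature is the centroid of its samples.  Samples not in any such run are
    discarded.  The defaults mirror the common headset protocol: five
    consecutive eye images with eye centers closer than five eye-camera
    points.

    Parameters
    ----------
    samples : DataFrame with columns ``t, e1..en`` or (t, E) arrays
    min_run : int
        Minimum number of consecutive samples, >= 2.
    dispersion : float
        Strict distance bound from the running centroid, > 0.

    Returns
    -------
    list of Fixation
    """
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    t, E = _as_samples(samples)
    N = t.shape[0]
    if N == 0:
        return []
    if np.any(np.diff(t) <= 0):
        bad = int(np.argmax(np.diff(t) <= 0))
        raise ValueError(
            f"timestamps must be strictly increasing (violation after index {bad})"
        )

    fixations: list[Fixation] = []
    i = 0
    while i < N:
        # grow a run greedily: each new sample must stay within `dispersion`
        # of the centroid of the samples accepted so far
        centroid = E[i].copy()
        j = i + 1
        while j < N:
            if np.linalg.norm(E[j] - centroid) < dispersion:
                centroid += (E[j] - centroid) / (j - i + 1)
                j += 1
            else:
                break
        if j - i >= min_run:
            fixations.append(
                Fixation(
                    id=len(fixations),
                    E=E[i:j].mean(axis=0),
                    t_start=float(t[i]),
                    t_end=float(t[j - 1]),
                    n_samples=j - i,
                )
            )
            i = j
        else:
            i += 1  # slide: the run was too short, retry from the next sample
    return fixations


def build_training_set(
    fixations: Sequence[Fixation], schedule: SceneSchedule
) -> TrainingSet:
    """Join fixations to the scene on screen at their temporal midpoint.

    Fixations whose midpoint falls in a gap between entries, in an entry
    flagged non-stimulus, or that span two schedule entries are dropped
    (with a log message for the spanning case).
    """
    kept: list[Fixation] = []
    target_sets: list[np.ndarray] = []
    for f in fixations:
        entry = schedule.entry_at(f.midpoint)
        if entry is None or not entry.stimulus:
            continue
        start_entry = schedule.entry_at(f.t_start)
        end_entry = schedule.entry_at(f.t_end)
        if (start_entry is not None and start_entry is not entry) or (
            end_entry is not None and end_entry is not entry
        ):
            logger.info(
                "dropping fixation %d: spans scene boundary at t=%.1f ms",
                f.id,
                entry.t_end,
            )
            continue
        kept.append(f)
        target_sets.append(entry.targets.copy())
    features = (
        np.array([f.E for f in kept]) if kept else np.empty((0, 0))
    )
    return TrainingSet(features, target_sets, fixations=kept)


def mapping_space_size(ts: TrainingSet) -> int:
    """Size of the mapping search space: the product of all m_i."""
    return prod(int(x) for x in ts.m) if ts.M else 1
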