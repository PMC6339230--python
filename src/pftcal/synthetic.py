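"""Synthetic gaze sessions with planted ground truth.

The generator emulates everything the real pipeline consumes so every stage
is testable end to end: a hidden, well-conditioned gaze->eye-feature
transform (the quantity the calibration must recover, optionally mirrored
horizontally the way an eye camera mirrors the scene), scenes with planted
targets, fixations that land on a target with probability ``attention_prob``
(and otherwise anywhere on the scene — distractor fixations), Gaussian
fixation jitter in gaze space and Gaussian sensor noise in feature space,
and 9-point calibration/reference grids recorded through the same noise
model.

What it deliberately does not model: saccade dynamics, blinks, head
movement, pupil-size effects, or temporally correlated drift.  Distractors
are uniform over the scene.

Everything derives from explicit integer seeds; identical configuration
yields bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datamodel import (
    Fixation,
    ReferenceSet,
    SceneEntry,
    SceneSchedule,
    TrainingSet,
)

__all__ = [
    "GroundTruth",
    "SyntheticConfig",
    "SimulatedSession",
    "make_ground_truth",
    "generate_scene_targets",
    "simulate_session",
    "reference_grid",
]

_MIN_TARGET_SEPARATION = 8.0  # percent; keeps candidate targets distinguishable
_MIN_CONSECUTIVE_GAZE_SEP = 4.0  # percent; keeps consecutive fixations separable
_SAMPLE_DT_MS = 33.0
_FIXATION_GAP_MS = 100.0
_SCENE_GAP_MS = 250.0


@dataclass(frozen=True)
class GroundTruth:
    """Hidden gaze -> eye-feature transform.

    ``e = A @ g + b (+ quadratic perturbation)`` with ``g`` in scene-percent
    and ``e`` in device units.  ``mirrored`` records whether the x-axis
    relation is flipped (negative x-column of A), which is what makes the
    horizontal-flip variant of the direction score appropriate.
    """

    A: np.ndarray  # (2, 2)
    b: np.ndarray  # (2,)
    quad: np.ndarray | None  # (2, 3) coefficients on (g_x², g_y², g_x·g_y)
    mirrored: bool
    family: str

    def inverse(self, gaze) -> np.ndarray:
        """Map gaze points (scene-percent) to eye features (device units)."""
        g = np.atleast_2d(np.asarray(gaze, dtype=float))
        e = g @ self.A.T + self.b
        if self.quad is not None:
            mono = np.column_stack([g[:, 0] ** 2, g[:, 1] ** 2, g[:, 0] * g[:, 1]])
            e = e + mono @ self.quad.T
        return e if np.asarray(gaze).ndim == 2 else e[0]

    @property
    def feature_scale(self) -> float:
        """Approximate device units per gaze percent (singular value scale)."""
        return float(np.linalg.svd(self.A, compute_uv=False).mean())


def make_ground_truth(
    seed: int, family: str = "affine", mirrored: bool = False
) -> GroundTruth:
    """Draw a random, well-conditioned transform.

    The affine part is a rotation within +/-15 degrees composed with mild
    anisotropic scaling (condition number <= ~1.4) and a translation, so
    feature-space geometry stays a faithful (optionally mirrored) image of
    gaze-space geometry.  The ``quadratic`` family adds a small curvature
    term of a few percent of the feature range, emulating lens/cornea
    nonlinearity.
    """
    if family not in ("affine", "quadratic"):
        raise ValueError("family must be 'affine' or 'quadratic'")
    rng = np.random.default_rng(seed)
    s = rng.uniform(2.4, 4.0)  # device units per percent
    if family == "affine":
        # axis-aligned uniform scaling (+ optional mirror): exactly the
        # direction-preserving geometry the direction score assumes, under
        # which the planted mapping is provably its optimum on noise-free
        # sessions (feature displacements stay (mirror-)parallel to gaze
        # displacements, so every planted pair has cosine 1)
        A = np.diag([s, s])
    else:
        # realistic sensor geometry: small rotation, mild anisotropy and
        # curvature; recovery is then approximate, with no exactness claim
        theta = rng.uniform(-np.pi / 12, np.pi / 12)
        aniso = rng.uniform(0.85, 1.18)
        R = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        A = R @ np.diag([s, s * aniso])
    b = rng.uniform(60.0, 160.0, size=2)
    if mirrored:
        A = np.diag([-1.0, 1.0]) @ A
        b[0] += rng.uniform(420.0, 520.0)
    quad = None
    if family == "quadratic":
        quad = rng.uniform(-0.002, 0.002, size=(2, 3))
    return GroundTruth(A=A, b=b, quad=quad, mirrored=mirrored, family=family)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one simulated session.

    Defaults encode a natural-viewing session: a handful of image scenes,
    3-5 salient targets each, the viewer attending a planted target 80% of
    the time, fixation jitter of 1% of the scene and sensor noise of one
    device unit (the feature scale is a few units per scene percent).
    """

    n_scenes: int = 4
    fixations_per_scene: int = 15
    targets_per_scene: tuple[int, int] = (3, 5)
    attention_prob: float = 0.8
    fixation_jitter_sigma: float = 1.0  # scene-percent
    sensor_noise_sigma: float = 1.0  # device units
    min_run: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.attention_prob <= 1.0:
            raise ValueError("attention_prob must lie in [0, 1]")
        lo, hi = self._target_range()
        if lo < 1 or hi > 16:
            raise ValueError("targets_per_scene must stay within 1-16")

    def _target_range(self) -> tuple[int, int]:
        t = self.targets_per_scene
        return (t, t) if isinstance(t, int) else (int(t[0]), int(t[1]))

    @property
    def distractor_fraction(self) -> float:
        """Expected fraction of fixations not aimed at any planted target."""
        return 1.0 - self.attention_prob


@dataclass
class SimulatedSession:
    """Everything one synthetic session produces."""

    samples: pd.DataFrame  # columns t, e1, e2
    schedule: SceneSchedule
    planted: np.ndarray  # (M,) planted target index; -1 marks distractors
    gaze: np.ndarray  # (M, 2) true gaze point per fixation (percent)
    training_set: TrainingSet  # ideal aggregation (per-fixation sample means)
    cal: ReferenceSet  # 9-point calibration grid (calPoints)
    ref: ReferenceSet  # 9-point reference grid (refPoints)
    ground_truth: GroundTruth
    config: SyntheticConfig


def generate_scene_targets(config: SyntheticConfig, seed: int | None = None):
    """Planted target layouts: per scene, points in [5, 95]² percent with
    pairwise separation >= 8 percent."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    lo, hi = config._target_range()
    scenes = []
    for _ in range(config.n_scenes):
        m = int(rng.integers(lo, hi + 1))
        pts: list[np.ndarray] = []
        tries = 0
        while len(pts) < m:
            p = rng.uniform(5.0, 95.0, size=2)
            if all(
                np.linalg.norm(p - q) >= _MIN_TARGET_SEPARATION for q in pts
            ):
                pts.append(p)
            tries += 1
            if tries > 2000:
                raise ValueError(
                    f"cannot place {m} targets with "
                    f"{_MIN_TARGET_SEPARATION}% separation"
                )
        scenes.append(np.array(pts))
    return scenes


def reference_grid() -> np.ndarray:
    """The nine equally distributed screen points: {16.7, 50, 83.3}² percent."""
    line = 100.0 * np.array([1.0, 3.0, 5.0]) / 6.0
    gx, gy = np.meshgrid(line, line)
    return np.column_stack([gx.ravel(), gy.ravel()])


def _noisy_grid_pairs(
    gt: GroundTruth, config: SyntheticConfig, rng, role: str, reps: int = 2
) -> ReferenceSet:
    pts = np.repeat(reference_grid(), reps, axis=0)
    gaze = pts + rng.normal(0.0, config.fixation_jitter_sigma, size=pts.shape)
    feats = gt.inverse(gaze) + rng.normal(
        0.0, config.sensor_noise_sigma, size=pts.shape
    )
    return ReferenceSet(features=feats, points=pts, role=role)


def simulate_session(
    gt: GroundTruth,
    scenes: list[np.ndarray] | None = None,
    config: SyntheticConfig | None = None,
) -> SimulatedSession:
    """Generate a full session.

    Per fixation: with probability ``attention_prob`` a planted target is
    chosen (its index recorded in ``planted``); otherwise the fixation is a
    distractor at a uniform scene point (recorded as −1).  The fixation's
    gaze point is the chosen location plus Gaussian jitter; the fixation
    emits 6-12 samples whose features are ``gt.inverse(gaze)`` plus Gaussian
    sensor noise.  Consecutive fixations are redrawn (bounded retries) until
    their gaze points are separated enough for dispersion-based extraction
    to distinguish them.  calPoints and refPoints 3x3 grids pass through the
    same noise model.
    """
    config = config or SyntheticConfig()
    rng = np.random.default_rng(config.seed)
    if scenes is None:
        scenes = generate_scene_targets(config, seed=int(rng.integers(2**31)))

    rows = []
    entries = []
    planted: list[int] = []
    gaze_points: list[np.ndarray] = []
    feat_means: list[np.ndarray] = []
    target_sets: list[np.ndarray] = []
    fixations: list[Fixation] = []

    t = 0.0
    prev_gaze: np.ndarray | None = None
    for s_idx, targets in enumerate(scenes):
        scene_start = t
        for _ in range(config.fixations_per_scene):
            # the attended/distractor decision is drawn once so the realized
            # distractor fraction stays Binomial(M, 1 - attention_prob);
            # only the location is retried for separability
            attended = rng.random() < config.attention_prob
            for _attempt in range(60):
                if attended:
                    idx = int(rng.integers(targets.shape[0]))
                    point = targets[idx]
                else:
                    idx = -1
                    point = rng.uniform(0.0, 100.0, size=2)
                gaze = point + rng.normal(
                    0.0, config.fixation_jitter_sigma, size=2
                )
                if (
                    prev_gaze is None
                    or np.linalg.norm(gaze - prev_gaze)
                    >= _MIN_CONSECUTIVE_GAZE_SEP
                ):
                    break
            n_samp = int(rng.integers(max(6, config.min_run + 1), 13))
            feats = gt.inverse(gaze)[None, :] + rng.normal(
                0.0, config.sensor_noise_sigma, size=(n_samp, 2)
            )
            times = t + _SAMPLE_DT_MS * np.arange(n_samp)
            for ti, (e1, e2) in zip(times, feats):
                rows.append((ti, e1, e2))
            fixations.append(
                Fixation(
                    id=len(fixations),
                    E=feats.mean(axis=0),
                    t_start=float(times[0]),
                    t_end=float(times[-1]),
                    n_samples=n_samp,
                )
            )
            planted.append(idx)
            gaze_points.append(gaze)
            feat_means.append(feats.mean(axis=0))
            target_sets.append(targets)
            prev_gaze = gaze
            t = times[-1] + _FIXATION_GAP_MS
        entries.append(
            SceneEntry(
                scene_id=f"scene_{s_idx}",
                t_start=scene_start - 1.0,
                t_end=t + 1.0,
                targets=targets,
            )
        )
        t += _SCENE_GAP_MS

    samples = pd.DataFrame(rows, columns=["t", "e1", "e2"])
    cal = _noisy_grid_pairs(gt, config, rng, role="calibration")
    ref = _noisy_grid_pairs(gt, config, rng, role="reference")
    ts = TrainingSet(np.array(feat_means), target_sets, fixations=fixations)
    return SimulatedSession(
        samples=samples,
        schedule=SceneSchedule(entries),
        planted=np.array(planted, dtype=int),
        gaze=np.array(gaze_points),
        training_set=ts,
        cal=cal,
        ref=ref,
        ground_truth=gt,
        config=config,
    )
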