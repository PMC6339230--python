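"""Mapping-comparison functions (MCFs).

A *mapping* assigns one candidate target to every fixation.  Without ground
truth, the only evidence for or against a mapping is internal consistency
between the raw (uncalibrated) eye-feature trajectory and the target
trajectory the mapping implies.  Four scores formalize this:

``reg``   fit a linear model eye-features -> target per axis and combine the
          coefficients of determination: score = (R²_x · R²_y)².
``dist``  for every fixation triple (i, j, k) compare the distance ratio
          ||E_i,E_j|| / ||E_i,E_k|| against the same ratio of the chosen
          targets via P_ijk = (ratio_E − 1) / (ratio_T − 1); the score counts
          triples with P_ijk > 0 (both ratios on the same side of 1).
``distc`` Pearson correlation between the series of consecutive-fixation
          feature distances and consecutive chosen-target distances.
``dir``   sum over fixation pairs of the cosine between the feature
          displacement vector and the target displacement vector; with
          ``flip_horizontal`` the feature vector's x-component is negated
          first (eye-camera images mirror the scene horizontally).

Higher is better for all four.  A fused score is a weighted sum of
components, optionally normalized so each component is O(1): ``dir`` is
divided by the number of pairs M(M−1)/2 and ``dist`` by the number of
triples C(M,3).

Conventions for degenerate geometry (all documented, all finite): zero-length
displacement vectors, zero distance-ratio denominators, and zero-variance
distance series contribute 0; a rank-deficient regression design scores 0
with a warning; zero target variance on an axis yields R² = 1 when the
residuals vanish too, else 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np

from .datamodel import TrainingSet

__all__ = [
    "MappingComparisonFunction",
    "RegressionMCF",
    "DistanceRatioMCF",
    "DistanceCorrelationMCF",
    "DirectionMCF",
    "FusedMCF",
    "FusionSpec",
    "mcf_from_spec",
    "mcf_reg",
    "mcf_dist",
    "mcf_distc",
    "mcf_dir",
    "mcf_fused",
]

_RES_TOL = 1e-10  # residual tolerance for the zero-target-variance branch
_NORM_EPS = 1e-9  # below this a displacement/distance counts as zero-length
_RATIO_EPS = 1e-12  # below this a distance ratio counts as exactly 1


def _as_batch(ts: TrainingSet, mappings) -> np.ndarray:
    b = np.atleast_2d(np.asarray(mappings, dtype=int))
    if b.shape[1] != ts.M:
        raise ValueError(f"mapping length {b.shape[1]} != M={ts.M}")
    return b


class MappingComparisonFunction:
    """Base class: scalar score for a mapping, higher is better."""

    id: str = "base"

    def score(self, ts: TrainingSet, mapping) -> float:
        idx = np.asarray(getattr(mapping, "indices", mapping), dtype=int)
        return float(self.score_batch(ts, idx[None, :])[0])

    def score_batch(self, ts: TrainingSet, mappings: np.ndarray) -> np.ndarray:
        """Scores for a (B, M) batch of mappings; shape (B,)."""
        raise NotImplementedError

    def normalizer(self, M: int) -> float:
        """Divisor that makes the score O(1) for fusion purposes."""
        return 1.0

    # -- incremental extension (beam search fast path) ---------------------
    supports_incremental = False

    def init_extension_state(self, ts: TrainingSet, beam: np.ndarray):
        """Auxiliary per-beam state for O(M)-per-step rescoring, or None."""
        return None

    def extend_scores(self, ts, beam, state, k):
        """Scores and state for every beam mapping extended by every target
        of fixation ``k``; generic implementation rescores from scratch.

        Returns
        -------
        scores : ndarray of shape (B, m_k)
        new_state : per-extended-mapping state, indexable as [B*m_k] after
            the caller flattens row-major, or None
        """
        m_k = ts.target_sets[k].shape[0]
        B = beam.shape[0]
        ext = np.concatenate(
            [
                np.repeat(beam, m_k, axis=0),
                np.tile(np.arange(m_k), B)[:, None],
            ],
            axis=1,
        )
        scores = self.score_batch(ts.prefix(k + 1), ext)
        return scores.reshape(B, m_k), None

    def select_state(self, state, order):
        """Reorder/truncate extension state after beam sorting."""
        return None

    def __repr__(self) -> str:  # pragma: no cover
        return f"{type(self).__name__}(id={self.id!r})"


class RegressionMCF(MappingComparisonFunction):
    """Linear-regression fit quality: ``(R²_x · R²_y)²``.

    Per axis, an ordinary least-squares fit of the degree-1 polynomial in the
    eye features predicts the chosen target coordinate; R² compares the
    predictions with the targets.  The two axes are combined multiplicatively
    and squared, so the score lies in [0, 1] with 1 for an exactly linear
    eye-to-target relation.
    """

    id = "reg"

    def score_batch(self, ts: TrainingSet, mappings: np.ndarray) -> np.ndarray:
        mappings = _as_batch(ts, mappings)
        B, M = mappings.shape
        n = ts.n
        if M < n + 2:
            # under-determined prefix: no meaningful fit quality
            return np.zeros(B)
        X = np.column_stack([np.ones(M), ts.features])
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            warnings.warn(
                "degenerate regression design (constant or collinear eye "
                "features); MCF_REG scored 0",
                stacklevel=2,
            )
            return np.zeros(B)
        T = ts.chosen_batch(mappings)  # (B, M, 2)
        Xp = np.linalg.pinv(X)  # (n+1, M)
        beta = np.einsum("km,bmd->bkd", Xp, T)
        pred = np.einsum("mk,bkd->bmd", X, beta)
        ss_res = np.sum((pred - T) ** 2, axis=1)  # (B, 2)
        ss_tot = np.sum((T - T.mean(axis=1, keepdims=True)) ** 2, axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            r2 = 1.0 - ss_res / ss_tot
        # zero target variance: perfect if residuals vanish, else worthless
        degenerate = ss_tot <= 0
        r2 = np.where(degenerate, np.where(ss_res < _RES_TOL, 1.0, 0.0), r2)
        r2 = np.clip(r2, 0.0, 1.0)
        return (r2[:, 0] * r2[:, 1]) ** 2


class DistanceRatioMCF(MappingComparisonFunction):
    """Count of fixation triples whose distance-ratio proportion is positive.

    For each triple i<j<k,
    ``P_ijk = (||E_i,E_j||/||E_i,E_k|| − 1) / (||T_i,T_j||/||T_i,T_k|| − 1)``
    and the score is the number of triples with ``P_ijk > 0``.  Triples with a
    zero denominator distance or a target ratio of exactly 1 contribute 0.
    """

    id = "dist"

    def normalizer(self, M: int) -> float:
        return max(1.0, M * (M - 1) * (M - 2) / 6.0)

    @staticmethod
    def _triples(M: int) -> np.ndarray:
        return (
            np.array(list(combinations(range(M), 3)), dtype=int)
            if M >= 3
            else np.empty((0, 3), dtype=int)
        )

    def score_batch(self, ts: TrainingSet, mappings: np.ndarray) -> np.ndarray:
        mappings = _as_batch(ts, mappings)
        B, M = mappings.shape
        tri = self._triples(M)
        if tri.shape[0] == 0:
            return np.zeros(B)
        i, j, k = tri.T
        E = ts.features
        e_num = np.linalg.norm(E[j] - E[i], axis=1)
        e_den = np.linalg.norm(E[k] - E[i], axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            a = e_num / e_den - 1.0
        T = ts.chosen_batch(mappings)  # (B, M, 2)
        t_num = np.linalg.norm(T[:, j] - T[:, i], axis=2)  # (B, Q)
        t_den = np.linalg.norm(T[:, k] - T[:, i], axis=2)
        with np.errstate(divide="ignore", invalid="ignore"):
            b = t_num / t_den - 1.0
        # P = a / b > 0 iff a and b are nonzero with the same sign;
        # invalid denominators fall to the zero-contribution branch
        valid = (e_den > _NORM_EPS)[None, :] & (t_den > _NORM_EPS) & (np.abs(b) > _RATIO_EPS)
        positive = valid & (np.sign(a)[None, :] * np.sign(b) > 0)
        return positive.sum(axis=1).astype(float)


class DistanceCorrelationMCF(MappingComparisonFunction):
    """Pearson correlation between consecutive-pair distance series.

    ``||E|| = (||E_i, E_{i+1}||)`` and ``||T||`` likewise for the chosen
    targets; the score is ρ(||E||, ||T||) in [−1, 1], with 0 when either
    series has zero variance.  Unlike the pair/triple scores this one depends
    on fixation order.
    """

    id = "distc"

    def score_batch(self, ts: TrainingSet, mappings: np.ndarray) -> np.ndarray:
        mappings = _as_batch(ts, mappings)
        B, M = mappings.shape
        if M < 3:
            return np.zeros(B)
        E = ts.features
        dE = np.linalg.norm(E[1:] - E[:-1], axis=1)  # (M-1,)
        T = ts.chosen_batch(mappings)
        dT = np.linalg.norm(T[:, 1:] - T[:, :-1], axis=2)  # (B, M-1)
        return _pearson_rows(dE, dT)

    # -- incremental: Pearson from running sums ---------------------------
    supports_incremental = True

    def init_extension_state(self, ts: TrainingSet, beam: np.ndarray):
        k = beam.shape[1]
        E = ts.features
        dE = np.linalg.norm(E[1:k] - E[: k - 1], axis=1)
        T = ts.chosen_batch(beam)
        dT = np.linalg.norm(T[:, 1:] - T[:, :-1], axis=2) if k >= 2 else np.zeros(
            (beam.shape[0], 0)
        )
        return {
            "count": dT.shape[1],
            "sx": np.full(beam.shape[0], dE.sum()),
            "sxx": np.full(beam.shape[0], (dE**2).sum()),
            "sy": dT.sum(axis=1),
            "syy": (dT**2).sum(axis=1),
            "sxy": dT @ dE,
        }

    def extend_scores(self, ts, beam, state, k):
        B = beam.shape[0]
        targets_k = ts.target_sets[k]  # (m_k, 2)
        m_k = targets_k.shape[0]
        E = ts.features
        x_new = np.linalg.norm(E[k] - E[k - 1])  # new feature-space distance
        last = ts.chosen_batch(beam)[:, -1]  # (B, 2) last chosen targets
        # new target-space distance for every (mapping, new index)
        y_new = np.linalg.norm(
            targets_k[None, :, :] - last[:, None, :], axis=2
        )  # (B, m_k)
        cnt = state["count"] + 1
        sx = state["sx"][:, None] + x_new
        sxx = state["sxx"][:, None] + x_new**2
        sy = state["sy"][:, None] + y_new
        syy = state["syy"][:, None] + y_new**2
        sxy = state["sxy"][:, None] + x_new * y_new
        with np.errstate(divide="ignore", invalid="ignore"):
            cov = sxy - sx * sy / cnt
            vx = sxx - sx**2 / cnt
            vy = syy - sy**2 / cnt
            rho = cov / np.sqrt(vx * vy)
        ok = (vx > _RES_TOL) & (vy > _RES_TOL) & (cnt >= 2)
        scores = np.where(ok, np.nan_to_num(rho), 0.0)
        flat = lambda a: np.broadcast_to(a, (B, m_k)).reshape(-1)
        new_state = {
            "count": cnt,
            "sx": flat(sx),
            "sxx": flat(sxx),
            "sy": sy.reshape(-1),
            "syy": syy.reshape(-1),
            "sxy": sxy.reshape(-1),
        }
        return scores, new_state

    def select_state(self, state, order):
        return {
            "count": state["count"],
            **{key: state[key][order] for key in ("sx", "sxx", "sy", "syy", "sxy")},
        }


class DirectionMCF(MappingComparisonFunction):
    """Sum of cosines between feature and target displacement vectors.

    For every fixation pair i<j the displacement in feature space,
    ``E_ij = (e_x(j)−e_x(i), e_y(j)−e_y(i))`` — or, with the horizontal flip
    for mirrored eye-camera geometries, ``(e_x(i)−e_x(j), e_y(j)−e_y(i))`` —
    is compared by cosine with the chosen-target displacement
    ``T_ij = (t_x(j)−t_x(i), t_y(j)−t_y(i))``.  Requires 2-D eye features.
    Zero-length displacements contribute 0.
    """

    id = "dir"

    def __init__(self, flip_horizontal: bool = False):
        self.flip_horizontal = flip_horizontal

    def normalizer(self, M: int) -> float:
        return max(1.0, M * (M - 1) / 2.0)

    def _unit_feature_vectors(self, ts: TrainingSet, upto: int | None = None):
        M = ts.M if upto is None else upto
        if ts.n != 2:
            raise ValueError("the direction score requires 2-D eye features")
        i, j = np.triu_indices(M, 1)
        dE = ts.features[j] - ts.features[i]
        if self.flip_horizontal:
            dE = dE.copy()
            dE[:, 0] = -dE[:, 0]
        nE = np.linalg.norm(dE, axis=1, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            uE = np.where(nE > _NORM_EPS, dE / nE, 0.0)
        return i, j, uE

    def score_batch(self, ts: TrainingSet, mappings: np.ndarray) -> np.ndarray:
        mappings = _as_batch(ts, mappings)
        B, M = mappings.shape
        if M < 2:
            return np.zeros(B)
        i, j, uE = self._unit_feature_vectors(ts, M)
        T = ts.chosen_batch(mappings)
        dT = T[:, j] - T[:, i]  # (B, P, 2)
        nT = np.linalg.norm(dT, axis=2)
        dot = np.einsum("bpk,pk->bp", dT, uE)
        cos = np.divide(dot, nT, out=np.zeros_like(dot), where=nT > _NORM_EPS)
        return cos.sum(axis=1)

    # -- incremental: add the k-1 new pairs' cosines -----------------------
    supports_incremental = True

    def init_extension_state(self, ts, beam):
        return None  # the score itself is the running pair-cosine sum

    def extend_scores(self, ts, beam, state, k):
        B = beam.shape[0]
        targets_k = ts.target_sets[k]
        m_k = targets_k.shape[0]
        dE = ts.features[k] - ts.features[:k]  # (k, 2) vectors i -> k
        dE = -dE * np.array([1.0, -1.0]) if self.flip_horizontal else dE
        nE = np.linalg.norm(dE, axis=1, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            uE = np.where(nE > _NORM_EPS, dE / nE, 0.0)  # (k, 2)
        chosen = ts.chosen_batch(beam)  # (B, k, 2)
        # dT[b, t, i] = targets_k[t] − chosen[b, i]
        dT = targets_k[None, :, None, :] - chosen[:, None, :, :]  # (B, m_k, k, 2)
        nT = np.linalg.norm(dT, axis=3)
        dot = np.einsum("btik,ik->bti", dT, uE)
        cos = np.divide(dot, nT, out=np.zeros_like(dot), where=nT > _NORM_EPS)
        return cos.sum(axis=2), None  # (B, m_k) increments... see note

    def select_state(self, state, order):
        return None


# For DIR the extension increment must be added to the old score; the beam
# driver handles this via `extends_additively`.
DirectionMCF.extends_additively = True
DistanceCorrelationMCF.extends_additively = False
MappingComparisonFunction.extends_additively = False


@dataclass(frozen=True)
class FusionSpec:
    """Weighted combination of component scores: list of (mcf_id, weight)."""

    components: tuple

    def __post_init__(self) -> None:
        comps = tuple((str(m), float(w)) for m, w in self.components)
        if not comps:
            raise ValueError("a fusion needs at least one component")
        for mcf_id, w in comps:
            if not np.isfinite(w) or w < 0:
                raise ValueError(f"weight for {mcf_id!r} must be finite and >= 0")
        object.__setattr__(self, "components", comps)


class FusedMCF(MappingComparisonFunction):
    """Weighted sum of component MCFs.

    With ``normalize=True`` (default) the pair/triple-sum components are
    divided by their combinatorial count (``dir`` by M(M−1)/2, ``dist`` by
    C(M,3)) before weighting, so all components are O(1) and the weights are
    comparable across training-set sizes.  ``normalize=False`` sums the raw
    scores.
    """

    def __init__(self, components: Sequence, normalize: bool = True,
                 flip_horizontal: bool = False):
        self.components = [
            (_make_single(mcf_id, flip_horizontal), float(w))
            for mcf_id, w in components
        ]
        self.normalize = normalize
        self.id = "+".join(
            f"{w:g}x{m.id}" if w != 1 else m.id for m, w in self.components
        )

    def score_batch(self, ts: TrainingSet, mappings: np.ndarray) -> np.ndarray:
        mappings = _as_batch(ts, mappings)
        total = np.zeros(mappings.shape[0])
        for mcf, w in self.components:
            s = mcf.score_batch(ts, mappings)
            if self.normalize:
                s = s / mcf.normalizer(ts.M)
            total += w * s
        return total


_REGISTRY = {
    "reg": RegressionMCF,
    "dist": DistanceRatioMCF,
    "distc": DistanceCorrelationMCF,
    "dir": DirectionMCF,
}


def _make_single(mcf_id: str, flip_horizontal: bool) -> MappingComparisonFunction:
    try:
        cls = _REGISTRY[mcf_id]
    except KeyError:
        raise ValueError(
            f"unknown MCF id {mcf_id!r}; expected one of {sorted(_REGISTRY)}"
        ) from None
    if cls is DirectionMCF:
        return cls(flip_horizontal=flip_horizontal)
    return cls()


def mcf_from_spec(spec, flip_horizontal: bool = False,
                  normalize: bool = True) -> MappingComparisonFunction:
    """Build an MCF from an id string, a FusionSpec, or a list of
    ``{"mcf": id, "weight": w}`` / ``(id, w)`` entries."""
    if isinstance(spec, MappingComparisonFunction):
        return spec
    if isinstance(spec, str):
        return _make_single(spec, flip_horizontal)
    if isinstance(spec, FusionSpec):
        comps = spec.components
    else:
        comps = [
            (e["mcf"], e["weight"]) if isinstance(e, dict) else tuple(e)
            for e in spec
        ]
    if len(comps) == 1 and comps[0][1] == 1.0:
        return _make_single(comps[0][0], flip_horizontal)
    return FusedMCF(comps, normalize=normalize, flip_horizontal=flip_horizontal)


# --------------------------------------------------------------------------
# Thin functional wrappers
# --------------------------------------------------------------------------

def mcf_reg(ts: TrainingSet, mapping) -> float:
    return RegressionMCF().score(ts, mapping)


def mcf_dist(ts: TrainingSet, mapping) -> float:
    return DistanceRatioMCF().score(ts, mapping)


def mcf_distc(ts: TrainingSet, mapping) -> float:
    return DistanceCorrelationMCF().score(ts, mapping)


def mcf_dir(ts: TrainingSet, mapping, flip_horizontal: bool = False) -> float:
    return DirectionMCF(flip_horizontal=flip_horizontal).score(ts, mapping)


def mcf_fused(ts: TrainingSet, mapping, spec, normalize: bool = True,
              flip_horizontal: bool = False) -> float:
    return mcf_from_spec(
        spec, flip_horizontal=flip_horizontal, normalize=normalize
    ).score(ts, mapping)


def _pearson_rows(x: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Pearson correlation of vector ``x`` against each row of ``Y``;
    zero-variance rows (or x) give 0."""
    xc = x - x.mean()
    Yc = Y - Y.mean(axis=1, keepdims=True)
    vx = (xc**2).sum()
    vy = (Yc**2).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = (Yc @ xc) / np.sqrt(vx * vy)
    ok = (vx > _RES_TOL) & (vy > _RES_TOL)
    return np.where(ok, np.nan_to_num(rho), 0.0)
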