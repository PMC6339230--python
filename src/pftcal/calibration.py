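"""Calibration models, outlier removal, error reports, and the full
implicit-calibration pipeline.

The calibration function maps an eye-feature vector ``e = (e1..en)`` to a
gaze point ``(g_x, g_y)`` in scene-percent coordinates.  A degree-2
polynomial per axis is the workhorse; for 2-D features this is the classic
quadratic form

    g_x = A_x e_x² + B_x e_y² + C_x e_x e_y + D_x e_x + E_x e_y + F_x
    g_y = A_y e_x² + B_y e_y² + C_y e_x e_y + D_y e_x + E_y e_y + F_y

For general n the design contains every monomial of total degree <= degree.
Fits are linear in the parameters, so the damped-least-squares optimum is
obtained in closed form whenever the design has full rank.

``ImplicitCalibrator`` is the end-to-end estimator: mapping search over the
candidate targets, single-pass outlier removal against a degree-1 fit,
polynomial fit on the surviving pairs, gaze prediction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.preprocessing import PolynomialFeatures
from sklearn.utils.validation import check_array, check_is_fitted

from .datamodel import ReferenceSet, ScoredMapping, TrainingSet
from .mcf import mcf_from_spec
from .search import (
    GeneticParams,
    exhaustive_search,
    genetic_search,
    incremental_search,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PolynomialGazeRegressor",
    "ImplicitCalibrator",
    "ErrorReport",
    "remove_outliers",
    "fit_calibration",
    "predict_gaze",
    "evaluate_error",
    "explicit_calibration",
    "run_implicit_pipeline",
]


@dataclass(frozen=True)
class ErrorReport:
    """Per-axis mean absolute gaze error as a percentage of scene size.

    ``error_x = mean(100 · |rp_x − g_x| / scene_w)`` and likewise for y;
    ``avg_error`` is the mean of the two axis errors.  ``residuals`` keeps
    the per-point absolute differences (already in percent).
    """

    error_x: float
    error_y: float
    avg_error: float
    n_refpoints: int
    residuals: np.ndarray

    def as_dict(self) -> dict:
        return {
            "error_x": self.error_x,
            "error_y": self.error_y,
            "avg_error": self.avg_error,
            "n_refpoints": self.n_refpoints,
        }


class PolynomialGazeRegressor(RegressorMixin, BaseEstimator):
    """Polynomial eye-feature -> gaze model (degree 1 or 2).

    Parameters
    ----------
    degree : int, default 2
        Polynomial degree; the design holds all monomials of total degree
        <= ``degree`` including the constant term.

    Attributes
    ----------
    coef_ : ndarray of shape (n_terms, 2)
        Per-axis coefficients, one column per gaze axis, rows in the order
        of ``powers_``.
    powers_ : ndarray of shape (n_terms, n_features)
        Exponents of each monomial.
    residuals_ : ndarray of shape (n_samples, 2)
        Training residuals (prediction − target).
    """

    def __init__(self, degree: int = 2):
        self.degree = degree

    def fit(self, X, y):
        if self.degree not in (1, 2):
            raise ValueError("degree must be 1 or 2")
        X = check_array(X, ensure_2d=True, dtype=float)
        y = check_array(y, ensure_2d=True, dtype=float)
        if y.shape != (X.shape[0], 2):
            raise ValueError("y must be (n_samples, 2) gaze coordinates")
        poly = PolynomialFeatures(degree=self.degree, include_bias=True)
        D = poly.fit_transform(X)
        if X.shape[0] < D.shape[1]:
            raise ValueError(
                f"{X.shape[0]} pairs cannot determine {D.shape[1]} "
                f"coefficients per axis"
            )
        coef, _, rank, _ = np.linalg.lstsq(D, y, rcond=None)
        if rank < D.shape[1]:
            raise ValueError(
                "rank-deficient polynomial design (degenerate eye features); "
                "cannot fit a calibration model"
            )
        self._poly = poly
        self.n_features_in_ = X.shape[1]
        self.powers_ = poly.powers_
        self.coef_ = coef
        self.residuals_ = D @ coef - y
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = check_array(X, ensure_2d=True, dtype=float)
        return self._poly.transform(X) @ self.coef_

    # -- serialization -----------------------------------------------------
    # For n=2, degree=2 the JSON order is the classic (A, B, C, D, E, F):
    # ex², ey², ex·ey, ex, ey, 1.
    _QUAD_ORDER_2D = [(2, 0), (0, 2), (1, 1), (1, 0), (0, 1), (0, 0)]

    def to_dict(self) -> dict:
        check_is_fitted(self, "coef_")
        powers = [tuple(p) for p in self.powers_]
        if self.n_features_in_ == 2 and self.degree == 2:
            order = [powers.index(p) for p in self._QUAD_ORDER_2D]
        else:
            order = list(range(len(powers)))
        return {
            "degree": self.degree,
            "n": int(self.n_features_in_),
            "powers": [[int(p) for p in powers[i]] for i in order],
            "coeffs_x": self.coef_[order, 0].tolist(),
            "coeffs_y": self.coef_[order, 1].tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PolynomialGazeRegressor":
        model = cls(degree=int(d["degree"]))
        n = int(d["n"])
        poly = PolynomialFeatures(degree=model.degree, include_bias=True)
        poly.fit(np.zeros((1, n)))
        powers = [tuple(p) for p in poly.powers_]
        coef = np.zeros((len(powers), 2))
        for p, cx, cy in zip(d["powers"], d["coeffs_x"], d["coeffs_y"]):
            coef[powers.index(tuple(p))] = (cx, cy)
        model._poly = poly
        model.n_features_in_ = n
        model.powers_ = poly.powers_
        model.coef_ = coef
        model.residuals_ = np.zeros((0, 2))
        return model


def remove_outliers(features, targets, removal_percent: float = 0.2):
    """Single-pass removal of the worst-fitting pairs.

    A degree-1 polynomial (linear) calibration is fitted to all pairs; the
    ``floor(removal_percent · M)`` pairs with the largest Euclidean distance
    between the linear prediction and their target are removed.  Even a
    correct mapping contains fixations that landed off-target; they surface
    as the largest linear-fit residuals.

    Returns
    -------
    (features_kept, targets_kept, keep_mask)
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    y = np.atleast_2d(np.asarray(targets, dtype=float))
    if not 0.0 <= removal_percent < 1.0:
        raise ValueError("removal_percent must lie in [0, 1)")
    M, n = X.shape
    k = int(np.floor(removal_percent * M))
    if M - k < n + 2:
        raise ValueError(
            f"removing {k} of {M} pairs leaves fewer than {n + 2} for a fit"
        )
    if k == 0:
        return X, y, np.ones(M, dtype=bool)
    linear = PolynomialGazeRegressor(degree=1).fit(X, y)
    dist = np.linalg.norm(linear.predict(X) - y, axis=1)
    worst = np.argsort(dist, kind="stable")[M - k:]
    keep = np.ones(M, dtype=bool)
    keep[worst] = False
    return X[keep], y[keep], keep


def fit_calibration(features, targets, degree: int = 2) -> PolynomialGazeRegressor:
    """Least-squares polynomial calibration fit (thin wrapper)."""
    return PolynomialGazeRegressor(degree=degree).fit(features, targets)


def predict_gaze(model: PolynomialGazeRegressor, E) -> np.ndarray:
    """Evaluate the calibration polynomial; accepts a single vector or a
    batch."""
    E = np.asarray(E, dtype=float)
    single = E.ndim == 1
    out = model.predict(E[None, :] if single else E)
    return out[0] if single else out


def evaluate_error(
    model: PolynomialGazeRegressor,
    refs: ReferenceSet,
    scene_w: float = 100.0,
    scene_h: float = 100.0,
) -> ErrorReport:
    """Mean absolute error against reference points, in percent of scene size.

    Each axis error is ``100 · |rp − g| / scene_dim`` averaged over the
    reference pairs.  When positions are already in scene-percent the scene
    dimensions are 100 x 100 (the default).
    """
    g = model.predict(refs.features)
    res = np.abs(refs.points - g) * (100.0 / np.array([scene_w, scene_h]))
    ex, ey = res.mean(axis=0)
    return ErrorReport(
        error_x=float(ex),
        error_y=float(ey),
        avg_error=float(0.5 * (ex + ey)),
        n_refpoints=len(refs),
        residuals=res,
    )


def explicit_calibration(cal: ReferenceSet, degree: int = 2) -> PolynomialGazeRegressor:
    """Classic calibration: fit directly on calPoints pairs."""
    return fit_calibration(cal.features, cal.points, degree=degree)


class ImplicitCalibrator(RegressorMixin, BaseEstimator):
    """End-to-end implicit calibration: search, clean, fit, predict.

    Parameters
    ----------
    mcf : str or spec, default "dir"
        Mapping-comparison function: ``reg | dist | distc | dir`` or a
        fusion spec (list of ``(id, weight)`` pairs).
    flip_horizontal : bool, default False
        Mirror correction for the direction score (eye-camera geometries).
    search : {"genetic", "incremental", "exhaustive"}, default "genetic"
    search_params : GeneticParams or dict, optional
        Genetic-search knobs (ignored by the other algorithms).
    cutoff : int, default 100
        Beam width for incremental search.
    seed_depth : int, default 3
        Fixations enumerated exhaustively to seed the beam.
    removal_percent : float, default 0.2
        Fraction of worst-fitting pairs dropped before the final fit.
    degree : {1, 2}, default 2
        Calibration polynomial degree.
    normalize_fusion : bool, default True
        Normalize fused components to O(1) before weighting.
    random_state : int, optional
        Seed for the genetic search.

    Attributes
    ----------
    mapping_ : ndarray of shape (M,)
        Best mapping found (0-based target index per fixation).
    mapping_score_ : float
    model_ : PolynomialGazeRegressor
    inlier_mask_ : ndarray of bool, shape (M,)
        Pairs that survived outlier removal.
    training_set_ : TrainingSet
    """

    def __init__(
        self,
        mcf="dir",
        flip_horizontal: bool = False,
        search: str = "genetic",
        search_params=None,
        cutoff: int = 100,
        seed_depth: int = 3,
        removal_percent: float = 0.2,
        degree: int = 2,
        normalize_fusion: bool = True,
        random_state: int | None = None,
    ):
        self.mcf = mcf
        self.flip_horizontal = flip_horizontal
        self.search = search
        self.search_params = search_params
        self.cutoff = cutoff
        self.seed_depth = seed_depth
        self.removal_percent = removal_percent
        self.degree = degree
        self.normalize_fusion = normalize_fusion
        self.random_state = random_state

    def _build_mcf(self):
        return mcf_from_spec(
            self.mcf,
            flip_horizontal=self.flip_horizontal,
            normalize=self.normalize_fusion,
        )

    def fit(self, X, y):
        """Fit from eye features and per-fixation candidate targets.

        Parameters
        ----------
        X : array-like of shape (M, n) or TrainingSet
            Eye features per fixation (ignored as features when a
            TrainingSet is passed directly, in which case ``y`` is unused).
        y : sequence of M arrays of shape (m_i, 2)
            Candidate targets per fixation, scene-percent.
        """
        if isinstance(X, TrainingSet):
            ts = X
        else:
            ts = TrainingSet(X, list(y))
        if ts.M < ts.n + 2:
            raise ValueError("too few fixations to calibrate")
        n_terms = PolynomialFeatures(
            degree=self.degree, include_bias=True
        ).fit(np.zeros((1, ts.n))).n_output_features_
        if ts.M - int(np.floor(self.removal_percent * ts.M)) < n_terms:
            raise ValueError(
                f"M={ts.M} with removal_percent={self.removal_percent} "
                f"leaves fewer than the {n_terms} pairs a degree-"
                f"{self.degree} fit needs"
            )
        mcf = self._build_mcf()
        if self.search == "genetic":
            params = self.search_params
            if isinstance(params, dict):
                params = GeneticParams(**params)
            best = genetic_search(ts, mcf, params=params, seed=self.random_state)
        elif self.search == "incremental":
            best = incremental_search(
                ts, mcf, cutoff=self.cutoff, seed_depth=self.seed_depth
            )
        elif self.search == "exhaustive":
            best = exhaustive_search(ts, mcf)
        else:
            raise ValueError(f"unknown search algorithm {self.search!r}")
        chosen = ts.chosen(best.mapping)
        Xk, yk, keep = remove_outliers(
            ts.features, chosen, removal_percent=self.removal_percent
        )
        self.model_ = fit_calibration(Xk, yk, degree=self.degree)
        self.training_set_ = ts
        self.mapping_ = best.mapping.indices
        self.mapping_score_ = best.score
        self.inlier_mask_ = keep
        self.n_features_in_ = ts.n
        logger.info(
            "implicit calibration: mcf=%s score=%.4f inliers=%d/%d",
            mcf.id,
            best.score,
            int(keep.sum()),
            ts.M,
        )
        return self

    def predict(self, X):
        check_is_fitted(self, "model_")
        return self.model_.predict(X)

    def evaluate(self, refs: ReferenceSet, scene_w: float = 100.0,
                 scene_h: float = 100.0) -> ErrorReport:
        check_is_fitted(self, "model_")
        return evaluate_error(self.model_, refs, scene_w, scene_h)


def run_implicit_pipeline(
    ts: TrainingSet,
    mcf_spec="dir",
    search_spec: str = "genetic",
    removal_percent: float = 0.2,
    degree: int = 2,
    refs: ReferenceSet | None = None,
    flip_horizontal: bool = False,
    seed: int | None = None,
    **search_kwargs,
):
    """Search -> outlier removal -> polynomial fit (-> optional evaluation).

    Returns ``(model, scored_mapping, report_or_None)``.
    """
    cal = ImplicitCalibrator(
        mcf=mcf_spec,
        flip_horizontal=flip_horizontal,
        search=search_spec,
        removal_percent=removal_percent,
        degree=degree,
        random_state=seed,
        **search_kwargs,
    ).fit(ts, None)
    from .datamodel import Mapping  # local to avoid cycle at import time

    scored = ScoredMapping(Mapping(cal.mapping_), cal.mapping_score_, str(mcf_spec))
    report = cal.evaluate(refs) if refs is not None else None
    return cal.model_, scored, report
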