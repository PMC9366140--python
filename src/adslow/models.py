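"""Polynomial latency-prediction models, cross-validation and grid search.

The predictive model is ordinary least-squares regression of normalized
latency on the polynomial expansion (degree ``d``, interactions included by
default) of the spike-count history vector.  Out-of-range predictions are
clipped to the range of the training targets, mirroring the practice of
rejecting predictions outside the observed latency range while keeping one
prediction per test row so that R² stays comparable across configurations.

Model selection runs an exhaustive grid over ``T_min``, ``N`` and ``d``,
scored by the R² averaged over the three protocol-aware folds.  Inter-fiber
transfer refits the chosen configuration on one fiber's complete data and
scores it on another fiber, each normalized with its own baseline.

An autoregressive variant with exogenous input (ARX) is also provided: the
next normalized latency is predicted from its last ``n_lags`` values plus
the spike count in a recent exogenous window (default 8.1 s).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.preprocessing import PolynomialFeatures

from .errors import EmptyInputError, ParameterError, ValidationError
from .features import FeatureMatrix, WindowScheme, count_history, featurize
from .folds import FoldAssignment, fold_rotations, three_fold_split
from .records import FiberRecord

__all__ = [
    "PolyModel",
    "PredictionResult",
    "FitResult",
    "ARXModel",
    "GridSearchResult",
    "fit_poly",
    "predict",
    "r2_score",
    "cross_validate",
    "grid_search",
    "transfer_evaluate",
    "fit_arx",
    "predict_arx",
    "DEFAULT_T_MIN_GRID",
    "DEFAULT_N_GRID",
    "DEFAULT_D_GRID",
]

logger = logging.getLogger(__name__)

DEFAULT_T_MIN_GRID = (0.125, 0.25, 0.5, 1.0)
DEFAULT_N_GRID = tuple(range(5, 11))
DEFAULT_D_GRID = (1, 2, 3)


def _expansion_powers(n_features: int, degree: int, expansion: str) -> np.ndarray:
    """Exponent matrix (n_terms, n_features) of the expansion, bias excluded."""
    if degree < 1:
        raise ParameterError(f"polynomial degree must be >= 1, got {degree}")
    if expansion == "full":
        pf = PolynomialFeatures(degree=degree, include_bias=False)
        pf.fit(np.zeros((1, n_features)))
        return pf.powers_.astype(np.int64)
    if expansion == "pure":
        powers = np.zeros((n_features * degree, n_features), dtype=np.int64)
        for p in range(1, degree + 1):
            for j in range(n_features):
                powers[(p - 1) * n_features + j, j] = p
        return powers
    raise ParameterError(f"expansion must be 'full' or 'pure', got {expansion!r}")


def _design(counts: np.ndarray, powers: np.ndarray) -> np.ndarray:
    x = counts.astype(float)
    return np.prod(x[:, None, :] ** powers[None, :, :], axis=2)


def term_names(scheme: WindowScheme, powers: np.ndarray) -> list[str]:
    """Readable name per expansion term, e.g. ``s_1``, ``s_2^2``, ``s_1*s_3``."""
    names = []
    for row in powers:
        parts = [
            f"s_{j + 1}" + (f"^{p}" if p > 1 else "")
            for j, p in enumerate(row)
            if p > 0
        ]
        names.append("*".join(parts))
    return names


@dataclass
class PolyModel:
    """Fitted polynomial regression with an output clip range."""

    degree: int
    scheme: WindowScheme
    powers: np.ndarray
    coefficients: np.ndarray
    intercept: float
    clip_range: tuple[float, float]
    expansion: str = "full"

    def __post_init__(self) -> None:
        if self.clip_range[0] > self.clip_range[1]:
            raise ValidationError(f"invalid clip range {self.clip_range}")
        if len(self.coefficients) != len(self.powers):
            raise ValidationError("coefficient vector does not match expansion size")


@dataclass
class PredictionResult:
    """Clipped predictions with the raw values and per-row clip flags."""

    values: np.ndarray
    raw: np.ndarray
    clipped: np.ndarray
    excluded: np.ndarray | None = None


@dataclass
class FitResult:
    """Cross-validation outcome: per-rotation models and R² scores."""

    scheme: WindowScheme
    degree: int
    per_fold_r2: np.ndarray
    models: list[PolyModel]

    @property
    def mean_r2(self) -> float:
        return float(np.mean(self.per_fold_r2))


@dataclass
class GridSearchResult:
    """Best (scheme, degree) plus the full score table of the grid."""

    best_scheme: WindowScheme
    best_degree: int
    best_result: FitResult
    table: pd.DataFrame


@dataclass
class ARXModel:
    """Autoregressive latency model with a spike-count exogenous input."""

    n_lags: int
    exo_window: float
    lag_coefficients: np.ndarray
    exo_coefficient: float
    intercept: float

    def __post_init__(self) -> None:
        if self.n_lags < 1:
            raise ParameterError(f"n_lags must be >= 1, got {self.n_lags}")
        if self.exo_window <= 0:
            raise ParameterError(f"exo_window must be > 0 s, got {self.exo_window}")


def fit_poly(
    features: FeatureMatrix,
    degree: int,
    *,
    expansion: str = "full",
    clip_targets: np.ndarray | None = None,
) -> PolyModel:
    """Least-squares fit of the degree-``d`` polynomial model.

    The solve is minimum-norm (``numpy.linalg.lstsq``): a rank-deficient
    design — e.g. an always-zero count column — fits fine with a logged
    warning, and zero columns receive exactly zero weight.  The clip range
    is the min/max of the training targets (or of ``clip_targets`` when the
    all-data clipping variant is requested by the caller).
    """
    counts, y = features.counts, features.targets
    powers = _expansion_powers(counts.shape[1], degree, expansion)
    n_terms = len(powers)
    if len(y) < n_terms + 1:
        raise EmptyInputError(
            f"need at least {n_terms + 1} rows to fit {n_terms} expansion terms "
            f"+ intercept, got {len(y)}"
        )
    if not (np.isfinite(counts).all() and np.isfinite(y).all()):
        raise ValidationError("features and targets must be finite")
    X = np.column_stack([np.ones(len(y)), _design(counts, powers)])
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        logger.warning(
            "rank-deficient design (rank %d of %d columns); using the "
            "minimum-norm solution",
            rank,
            X.shape[1],
        )
    clip_src = y if clip_targets is None else np.asarray(clip_targets, dtype=float)
    return PolyModel(
        degree=degree,
        scheme=features.scheme,
        powers=powers,
        coefficients=beta[1:],
        intercept=float(beta[0]),
        clip_range=(float(clip_src.min()), float(clip_src.max())),
        expansion=expansion,
    )


def predict(
    model: PolyModel, features: FeatureMatrix, *, mode: str = "clip"
) -> PredictionResult:
    """Predict normalized latencies, restricted to the model's clip range.

    ``mode="clip"`` (default) clamps out-of-range predictions to the range
    bounds and flags them, keeping one prediction per row; ``mode="exclude"``
    additionally marks them for exclusion from scoring.
    """
    if features.scheme != model.scheme:
        raise ValidationError(
            f"feature scheme {features.scheme} does not match model scheme {model.scheme}"
        )
    if mode not in ("clip", "exclude"):
        raise ParameterError(f"mode must be 'clip' or 'exclude', got {mode!r}")
    raw = model.intercept + _design(features.counts, model.powers) @ model.coefficients
    lo, hi = model.clip_range
    values = np.clip(raw, lo, hi)
    clipped = (raw < lo) | (raw > hi)
    excluded = clipped.copy() if mode == "exclude" else None
    return PredictionResult(values=values, raw=raw, clipped=clipped, excluded=excluded)


def r2_score(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Coefficient of determination, ``1 - SS_res / SS_tot``.

    Negative when predictions are worse than the observed mean.  Constant
    observations make the score undefined; by convention it is 0 here, with
    a warning.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1:
        raise ValidationError("observed and predicted must be equal-length 1-D")
    if obs.size < 2:
        raise EmptyInputError("R² needs at least 2 observations")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        warnings.warn("R² undefined for constant observations; returning 0", stacklevel=2)
        return 0.0
    ss_res = float(np.sum((obs - pred) ** 2))
    return 1.0 - ss_res / ss_tot


def cross_validate(
    record: FiberRecord,
    scheme: WindowScheme,
    degree: int,
    *,
    expansion: str = "full",
    clip_source: str = "train",
    assignment: FoldAssignment | None = None,
    drop_truncated: bool = False,
) -> FitResult:
    """Protocol-aware 3-fold cross-validation of one model configuration.

    For each rotation the model is fitted on two folds and scored (with
    clipping) on the third; the headline figure is the mean R² over the
    three rotations.  ``clip_source="all"`` reproduces the literal
    all-latencies clip-range reading instead of the leak-free train-only
    default.
    """
    if clip_source not in ("train", "all"):
        raise ParameterError(f"clip_source must be 'train' or 'all', got {clip_source!r}")
    fm = featurize(record, scheme, drop_truncated=drop_truncated)
    if assignment is None:
        assignment = three_fold_split(record)
    if len(assignment) != len(fm):
        raise ValidationError("fold assignment does not match the feature matrix")
    scores, models = [], []
    for r, (train, test) in enumerate(fold_rotations(assignment), start=1):
        try:
            clip_targets = fm.targets if clip_source == "all" else None
            model = fit_poly(
                fm.subset(train), degree, expansion=expansion, clip_targets=clip_targets
            )
            pred = predict(model, fm.subset(test))
            scores.append(r2_score(fm.targets[test], pred.values))
            models.append(model)
        except Exception as exc:
            raise type(exc)(f"rotation {r}: {exc}") from exc
    return FitResult(scheme, degree, np.asarray(scores), models)


def grid_search(
    record: FiberRecord,
    t_min_grid: tuple[float, ...] = DEFAULT_T_MIN_GRID,
    n_grid: tuple[int, ...] = DEFAULT_N_GRID,
    d_grid: tuple[int, ...] = DEFAULT_D_GRID,
    **cv_kwargs,
) -> GridSearchResult:
    """Exhaustive search over ``(T_min, N, d)`` scored by mean 3-fold R².

    Every combination is evaluated (72 with the default grids); failures
    score ``-inf`` and are logged, not fatal.  Ties on mean R² break toward
    the simpler model: smaller ``d``, then smaller ``N``, then larger
    ``T_min`` (a coarser, shorter-vector scheme).
    """
    if not (t_min_grid and n_grid and d_grid):
        raise ParameterError("all three grids must be non-empty")
    assignment = three_fold_split(record)
    rows = []
    results: dict[tuple[float, int, int], FitResult] = {}
    for t_min in t_min_grid:
        for n in n_grid:
            scheme = WindowScheme(t_min, n)
            for d in d_grid:
                try:
                    res = cross_validate(
                        record, scheme, d, assignment=assignment, **cv_kwargs
                    )
                    fold_r2 = list(res.per_fold_r2)
                    mean = res.mean_r2
                    results[(t_min, n, d)] = res
                except Exception:
                    logger.exception(
                        "grid combination T_min=%g N=%d d=%d failed", t_min, n, d
                    )
                    fold_r2, mean = [np.nan] * 3, -np.inf
                rows.append([t_min, n, d, *fold_r2, mean])
    table = pd.DataFrame(
        rows, columns=["T_min", "N", "d", "r2_fold1", "r2_fold2", "r2_fold3", "r2_mean"]
    )
    best = select_best(table)
    t_min, n, d = float(best["T_min"]), int(best["N"]), int(best["d"])
    if (t_min, n, d) not in results:
        raise ValidationError("every grid combination failed to fit")
    return GridSearchResult(WindowScheme(t_min, n), d, results[(t_min, n, d)], table)


def select_best(table: pd.DataFrame) -> pd.Series:
    """Argmax row of a grid-search score table with the deterministic tie-break."""
    finite = table[np.isfinite(table["r2_mean"])]
    if finite.empty:
        raise ValidationError("score table holds no finite r2_mean")
    top = finite[finite["r2_mean"] == finite["r2_mean"].max()]
    top = top.sort_values(["d", "N", "T_min"], ascending=[True, True, False])
    return top.iloc[0]


def transfer_evaluate(
    train_record: FiberRecord,
    test_record: FiberRecord,
    scheme: WindowScheme,
    degree: int,
    *,
    expansion: str = "full",
) -> float:
    """R² of a model fitted on all of one fiber and scored on another fiber.

    Both records must be normalized with their own baselines.  The clip
    range comes from the training fiber, so a scale mismatch between fibers
    (different per-spike slowing magnitudes) yields strongly negative R².
    """
    train_fm = featurize(train_record, scheme)
    test_fm = featurize(test_record, scheme)
    model = fit_poly(train_fm, degree, expansion=expansion)
    pred = predict(model, test_fm)
    return r2_score(test_fm.targets, pred.values)


def _arx_design(record: FiberRecord, n_lags: int, exo_window: float):
    lat = record.latencies
    if lat.norm is None:
        raise ValidationError("ARX models operate on normalized latencies")
    if len(lat) < n_lags + 2:
        raise EmptyInputError(
            f"ARX({n_lags}) needs at least {n_lags + 2} latency points, got {len(lat)}"
        )
    y = lat.norm[n_lags:]
    lags = np.column_stack(
        [lat.norm[n_lags - i : len(lat) - i] for i in range(1, n_lags + 1)]
    )
    exo = np.array(
        [
            count_history(record.spikes, t, exo_window)
            for t in lat.stimulus_times[n_lags:]
        ],
        dtype=float,
    )
    X = np.column_stack([np.ones(len(y)), lags, exo])
    return X, y


def fit_arx(
    record: FiberRecord, n_lags: int = 3, exo_window: float = 8.1
) -> ARXModel:
    """Least-squares ARX fit: ``l_t = c + sum_i a_i l_{t-i} + b * count(t, exo_window)``.

    The exogenous input is the spike count in the ``exo_window`` seconds
    before each background stimulus; the default window is 8.1 s.
    """
    X, y = _arx_design(record, n_lags, exo_window)
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        logger.warning("rank-deficient ARX design; minimum-norm solution used")
    return ARXModel(
        n_lags=n_lags,
        exo_window=exo_window,
        lag_coefficients=beta[1 : 1 + n_lags],
        exo_coefficient=float(beta[1 + n_lags]),
        intercept=float(beta[0]),
    )


def predict_arx(model: ARXModel, record: FiberRecord) -> np.ndarray:
    """One-step-ahead ARX predictions using observed lags.

    Returns predictions aligned with ``record.latencies[n_lags:]``; the
    first ``n_lags`` points carry no prediction and are excluded from
    scoring.
    """
    X, _ = _arx_design(record, model.n_lags, model.exo_window)
    beta = np.concatenate(
        [[model.intercept], model.lag_coefficients, [model.exo_coefficient]]
    )
    return X @ beta
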