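"""Ensemble habitat-suitability modelling.

Implements the ensemble-forecasting protocol used for the distribution
model: presences deduplicated to one valid occurrence per grid cell; five
scenarios of random pseudo-absences; a stratified 70/30
calibration/testing split with 15 repetitions per run; learners evaluated
by the True Skill Statistic (TSS = sensitivity + specificity - 1) at their
own best threshold; members with TSS above 0.8 combined into a
TSS-weighted mean; ensemble suitability reported on a 0-1000 integer
scale with a minimum-suitable-habitat threshold on that scale.

The core learner is a natively implemented logistic regression (binomial
likelihood fitted by iteratively reweighted least squares).  Other
algorithms attach through the same ``fit(X, y) -> predict(X) in [0, 1]``
contract; a random-forest adapter over scikit-learn is provided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .rasters import ClimateStack, GridGeometry, Raster

SUITABILITY_SCALE = 1000

# ---------------------------------------------------------------------------
# occurrences and pseudo-absences
# ---------------------------------------------------------------------------


@dataclass
class OccurrenceSet:
    """Rasterized presences plus (optionally) pseudo-absence draws."""

    geometry: GridGeometry
    presence_cells: np.ndarray                    # (n, 2) unique (row, col)
    presence_points: np.ndarray                   # (m, 2) original x, y
    pa_cells: dict[int, np.ndarray] = field(default_factory=dict)  # scenario -> (k, 2)

    @property
    def n_valid(self) -> int:
        """Number of valid occurrences (one per occupied cell)."""
        return len(self.presence_cells)


def rasterize_occurrences(points: np.ndarray, geometry: GridGeometry) -> OccurrenceSet:
    """Deduplicate point records to one valid occurrence per grid cell.

    Cell membership follows the half-open convention of
    :meth:`GridGeometry.cell_of`.  Raises on points outside the grid or on
    an empty point set.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.size == 0:
        raise ValueError("no points to rasterize")
    cells = geometry.cells_of(points)
    unique = np.unique(cells, axis=0)
    return OccurrenceSet(geometry=geometry, presence_cells=unique, presence_points=points)


def sample_pseudo_absences(
    occ: OccurrenceSet,
    domain: Raster | np.ndarray | None = None,
    n_pa: int | None = None,
    n_scenarios: int = 5,
    seed: int = 0,
) -> OccurrenceSet:
    """Draw ``n_scenarios`` independent pseudo-absence sets.

    Each scenario is a uniform draw without replacement of ``n_pa`` cells
    from the domain cells not occupied by a presence.  ``domain`` may be a
    boolean mask or a raster (cells with data are eligible); default is
    the whole grid.  ``n_pa`` defaults to max(100, 10 x presences), capped
    at the number of available cells.  Deterministic per seed.
    """
    geo = occ.geometry
    if domain is None:
        mask = np.ones((geo.n_rows, geo.n_cols), dtype=bool)
    elif isinstance(domain, Raster):
        mask = domain.mask
    else:
        mask = np.asarray(domain, dtype=bool)
    mask = mask.copy()
    mask[occ.presence_cells[:, 0], occ.presence_cells[:, 1]] = False
    avail = np.flatnonzero(mask.ravel())
    if n_pa is None:
        n_pa = min(max(100, 10 * occ.n_valid), len(avail))
    if len(avail) < n_pa:
        raise ValueError(
            f"domain has only {len(avail)} non-presence cells, need {n_pa}"
        )
    rng = np.random.default_rng(seed)
    pa = {}
    for s in range(n_scenarios):
        chosen = rng.choice(avail, size=n_pa, replace=False)
        pa[s] = np.column_stack(np.unravel_index(chosen, mask.shape))
    return OccurrenceSet(
        geometry=geo,
        presence_cells=occ.presence_cells,
        presence_points=occ.presence_points,
        pa_cells=pa,
    )


def split_calibration(
    labels: np.ndarray, ratio: float = 0.7, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified calibration/test split of record indices.

    Per class, round(ratio * n_class) records go to calibration; the split
    is disjoint and exhaustive.  Both classes must have >= 2 records and
    the test set must be non-empty.
    """
    labels = np.asarray(labels)
    if not 0 < ratio < 1:
        raise ValueError("split ratio must lie strictly between 0 and 1")
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError("both classes must be present")
    rng = np.random.default_rng(seed)
    cal_idx, test_idx = [], []
    for c in classes:
        idx = np.flatnonzero(labels == c)
        if len(idx) < 2:
            raise ValueError(f"class {c} has fewer than 2 records")
        rng.shuffle(idx)
        n_cal = int(round(ratio * len(idx)))
        n_cal = min(max(n_cal, 1), len(idx) - 1)  # keep both sides non-empty
        cal_idx.append(idx[:n_cal])
        test_idx.append(idx[n_cal:])
    return np.sort(np.concatenate(cal_idx)), np.sort(np.concatenate(test_idx))


# ---------------------------------------------------------------------------
# learners
# ---------------------------------------------------------------------------


class LogisticLearner:
    """Binomial GLM with logit link, fitted by IRLS.

    Converges on the deviance to ``tol`` (default 1e-8) within ``max_iter``
    iterations.  Perfect separation is detected (diverging linear
    predictor), flagged on ``separation_``, and predictions are clipped to
    [1e-6, 1 - 1e-6]; the learner is still returned.
    """

    algorithm = "glm"

    def __init__(self, tol: float = 1e-8, max_iter: int = 100) -> None:
        self.tol = tol
        self.max_iter = max_iter
        self.coef_: np.ndarray | None = None   # [intercept, slopes...]
        self.converged_: bool = False
        self.separation_: bool = False

    def fit(self, X: np.ndarray, y: np.ndarray) -> "LogisticLearner":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if set(np.unique(y)) - {0.0, 1.0}:
            raise ValueError("labels must be binary 0/1")
        if len(np.unique(y)) < 2:
            raise ValueError("both classes required to fit")
        A = np.column_stack([np.ones(len(X)), X])
        beta = np.zeros(A.shape[1])
        dev_old = np.inf
        for _ in range(self.max_iter):
            eta = np.clip(A @ beta, -35, 35)
            mu = 1.0 / (1.0 + np.exp(-eta))
            w = np.maximum(mu * (1.0 - mu), 1e-12)
            z = eta + (y - mu) / w
            WA = A * w[:, None]
            try:
                beta = np.linalg.solve(A.T @ WA, WA.T @ z)
            except np.linalg.LinAlgError:
                beta, *_ = np.linalg.lstsq(A * np.sqrt(w)[:, None], z * np.sqrt(w), rcond=None)
            eta = np.clip(A @ beta, -35, 35)
            mu = np.clip(1.0 / (1.0 + np.exp(-eta)), 1e-12, 1 - 1e-12)
            dev = -2.0 * np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu))
            if abs(dev_old - dev) < self.tol * (abs(dev) + 0.1):
                self.converged_ = True
                break
            dev_old = dev
        self.coef_ = beta
        if np.max(np.abs(A @ beta)) > 30 or not self.converged_:
            if np.max(np.abs(A @ beta)) > 30:
                self.separation_ = True
                warnings.warn("possible perfect separation; predictions clipped")
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self.coef_ is None:
            raise RuntimeError("learner is not fitted")
        X = np.asarray(X, dtype=float)
        eta = self.coef_[0] + X @ self.coef_[1:]
        p = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
        return np.clip(p, 1e-6, 1 - 1e-6)


class RandomForestLearner:
    """Random-forest adapter satisfying the learner contract."""

    algorithm = "rf"

    def __init__(self, n_estimators: int = 200, seed: int = 0) -> None:
        from sklearn.ensemble import RandomForestClassifier

        self._model = RandomForestClassifier(
            n_estimators=n_estimators, random_state=seed
        )

    def fit(self, X: np.ndarray, y: np.ndarray) -> "RandomForestLearner":
        self._model.fit(np.asarray(X), np.asarray(y).astype(int))
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        proba = self._model.predict_proba(np.asarray(X))
        col = list(self._model.classes_).index(1)
        return proba[:, col]


LEARNER_FACTORIES: dict[str, Callable[..., object]] = {
    "glm": lambda seed=0: LogisticLearner(),
    "rf": lambda seed=0: RandomForestLearner(seed=seed),
}


@dataclass
class FittedLearner:
    """One fitted member of the ensemble protocol."""

    algorithm: str
    learner: object
    pa_scenario: int
    repetition: int
    tss_test: float
    threshold: float  # this member's best threshold on its test split

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.learner.predict(X)


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------


def tss(scores: np.ndarray, labels: np.ndarray, threshold: float) -> float:
    """True Skill Statistic at a threshold: sensitivity + specificity - 1.

    A score >= threshold predicts presence.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present")
    pred = scores >= threshold
    sens = np.mean(pred[labels])
    spec = np.mean(~pred[~labels])
    return float(sens + spec - 1.0)


def best_threshold(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Threshold maximizing TSS, scanned over midpoints of unique scores.

    Returns ``(threshold, tss)``.  Ties resolve to the lowest threshold; a
    single unique score is its own (only) candidate.
    """
    scores = np.asarray(scores, dtype=float)
    uniq = np.unique(scores)
    if len(uniq) == 1:
        candidates = uniq
    else:
        candidates = (uniq[:-1] + uniq[1:]) / 2.0
    best_t, best_s = candidates[0], -np.inf
    for t in candidates:
        s = tss(scores, labels, t)
        if s > best_s + 1e-15:
            best_t, best_s = t, s
    return float(best_t), float(best_s)


# ---------------------------------------------------------------------------
# ensemble
# ---------------------------------------------------------------------------


@dataclass
class SuitabilityMap:
    """Ensemble suitability on the 0-1000 integer scale."""

    raster: Raster
    scenario: str

    @property
    def values(self) -> np.ndarray:
        return self.raster.values


@dataclass
class EnsembleModel:
    """TSS-weighted mean of the learners passing the inclusion rule."""

    members: list[FittedLearner]
    weights: np.ndarray
    predictors: list[str]
    tss_min: float
    threshold: float | None = None      # minimum-suitable-habitat, 0-1000 scale
    ensemble_tss: float | None = None   # TSS of the ensemble on pooled test data

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Weighted-mean suitability in [0, 1] for a predictor matrix."""
        preds = np.stack([m.predict(X) for m in self.members])
        return self.weights @ preds


def build_ensemble(
    members: Sequence[FittedLearner],
    predictors: Sequence[str],
    tss_min: float = 0.8,
) -> EnsembleModel:
    """Keep members with TSS strictly above ``tss_min``; weight by TSS."""
    included = [m for m in members if m.tss_test > tss_min]
    if not included:
        best = max((m.tss_test for m in members), default=float("nan"))
        raise ValueError(
            f"no member exceeds TSS {tss_min}; best achieved TSS was {best:.3f}"
        )
    w = np.array([m.tss_test for m in included], dtype=float)
    return EnsembleModel(
        members=included,
        weights=w / w.sum(),
        predictors=list(predictors),
        tss_min=tss_min,
    )


def project(model: EnsembleModel, stack: ClimateStack, scenario: str = "present") -> SuitabilityMap:
    """Project the ensemble over a stack; 0-1000 integers, NaN propagates."""
    X = stack.as_matrix(model.predictors)
    ok = np.isfinite(X).all(axis=1)
    out = np.full(X.shape[0], np.nan)
    if ok.any():
        out[ok] = np.round(model.predict(X[ok]) * SUITABILITY_SCALE)
    geo = stack.geometry
    return SuitabilityMap(
        raster=Raster(out.reshape(geo.n_rows, geo.n_cols), geo), scenario=scenario
    )


def binarize(suitability: SuitabilityMap, threshold: float) -> Raster:
    """1 where suitability >= threshold, 0 below, NaN where missing."""
    if not 0 <= threshold <= SUITABILITY_SCALE:
        raise ValueError("threshold must be on the 0-1000 suitability scale")
    v = suitability.values
    out = np.where(np.isfinite(v), (v >= threshold).astype(float), np.nan)
    return Raster(out, suitability.raster.geometry)


# ---------------------------------------------------------------------------
# full protocol
# ---------------------------------------------------------------------------


def fit_sdm_protocol(
    stack: ClimateStack,
    occ: OccurrenceSet,
    predictors: Sequence[str] | None = None,
    algorithms: Sequence[str] = ("glm",),
    n_pa_scenarios: int = 5,
    n_repetitions: int = 15,
    split_ratio: float = 0.7,
    tss_min: float = 0.8,
    n_pa: int | None = None,
    seed: int = 0,
) -> EnsembleModel:
    """Run the full ensemble protocol and return the fitted ensemble.

    algorithms x pseudo-absence scenarios x repetitions combinations are
    fitted (default 1 x 5 x 15 = 75; with three algorithms, 225).  Each
    combination is calibrated on a stratified ``split_ratio`` share, its
    best threshold and TSS computed on its own test split, and members
    with TSS > ``tss_min`` enter the TSS-weighted ensemble.  The ensemble's
    own minimum-suitable-habitat threshold is the best-TSS threshold of
    the ensemble's pooled test-set predictions, expressed on the 0-1000
    scale, and its pooled test TSS is stored as ``ensemble_tss``.
    """
    predictors = list(predictors) if predictors is not None else stack.layer_names
    ss = np.random.SeedSequence(seed)
    s_pa, s_split = (int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(2))
    occ = sample_pseudo_absences(
        occ, domain=stack.valid_mask(), n_pa=n_pa, n_scenarios=n_pa_scenarios, seed=s_pa
    )

    X_pres = stack.as_matrix(predictors, occ.presence_cells)
    members: list[FittedLearner] = []
    pooled_scores: list[np.ndarray] = []
    pooled_labels: list[np.ndarray] = []
    test_sets: list[tuple[np.ndarray, np.ndarray]] = []
    split_rng = np.random.default_rng(s_split)

    for pa_id in range(n_pa_scenarios):
        X_abs = stack.as_matrix(predictors, occ.pa_cells[pa_id])
        X = np.vstack([X_pres, X_abs])
        y = np.concatenate([np.ones(len(X_pres)), np.zeros(len(X_abs))])
        for rep in range(n_repetitions):
            cal, test = split_calibration(y, split_ratio, seed=int(split_rng.integers(2**31 - 1)))
            for alg in algorithms:
                learner = LEARNER_FACTORIES[alg](seed=int(split_rng.integers(2**31 - 1)))
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    learner.fit(X[cal], y[cal])
                scores = learner.predict(X[test])
                thr, score = best_threshold(scores, y[test])
                members.append(
                    FittedLearner(
                        algorithm=alg,
                        learner=learner,
                        pa_scenario=pa_id,
                        repetition=rep,
                        tss_test=score,
                        threshold=thr,
                    )
                )
                test_sets.append((X[test], y[test]))

    model = build_ensemble(members, predictors, tss_min)
    # pool test predictions of the *ensemble* over each included member's split
    for m, (Xt, yt) in zip(members, test_sets):
        if m in model.members:
            pooled_scores.append(model.predict(Xt))
            pooled_labels.append(yt)
    scores = np.concatenate(pooled_scores)
    labels = np.concatenate(pooled_labels)
    thr, ens_tss = best_threshold(scores, labels)
    model.threshold = float(np.round(thr * SUITABILITY_SCALE))
    model.ensemble_tss = ens_tss
    return model
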