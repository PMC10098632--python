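"""Calibration-free BP regression from normalized pulse-waveform windows.

A supervised regressor maps a fixed-length, min-max-normalized sensor
window plus two demographic covariates (age in days, weight in kg) to
the (SBP, DBP, MAP) triplet. Because the window is normalized upstream,
predictions are exactly invariant to the unknown affine gain/offset of
the unscaled sensor — no per-patient calibration is needed.

Evaluation uses individual-grouped k-fold cross-validation: folds
partition *patients*, never windows, so no patient contributes to both
the training and the test side of any fold (subject-wise leakage
control). Model ranking follows the clinical selection rule: minimize
the worst-component bias, then the worst-component SD, then slope
distance from identity, then correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from sklearn.neural_network import MLPRegressor

from .beats import BPTriplet
from .sync import PairedWindow

__all__ = ["CVPlan", "ModelReport", "ComponentStats", "BPRegressor",
           "GradientBoostedBPRegressor",
           "make_folds", "featurize", "train_bp_model", "infer_bp",
           "rank_models", "MODEL_INPUT_LEN"]

BEAT_TEMPLATE_LEN = 128
MODEL_INPUT_LEN = BEAT_TEMPLATE_LEN + 1  # + mean beat period feature
COMPONENTS = ("sbp", "dbp", "map")
_DEFAULT_FS = 125.0


@dataclass(frozen=True)
class CVPlan:
    """Patient-level fold assignment for grouped cross-validation."""

    k: int
    assignment: dict[str, int]  # patient_id -> fold index

    def __post_init__(self) -> None:
        counts = np.bincount(list(self.assignment.values()), minlength=self.k)
        if counts.max() - counts.min() > 1:
            raise ValueError("fold patient-counts must differ by at most 1")

    def fold_of(self, patient_id: str) -> int:
        return self.assignment[patient_id]


@dataclass(frozen=True)
class ComponentStats:
    """Agreement statistics for one BP component (held-out predictions)."""

    mae: float    # signed mean difference (bias), mmHg
    sd: float     # SD of differences, mmHg
    slope: float  # OLS slope of predicted on true
    corr: float   # Pearson correlation


@dataclass
class ModelReport:
    """Held-out performance of one fitted model across all CV folds."""

    name: str
    pooled: dict[str, ComponentStats]
    per_fold: list[dict[str, ComponentStats]] = field(default_factory=list)

    def worst_abs_mae(self) -> float:
        return max(abs(s.mae) for s in self.pooled.values())

    def worst_sd(self) -> float:
        return max(s.sd for s in self.pooled.values())

    def worst_slope_dist(self) -> float:
        return max(abs(s.slope - 1.0) for s in self.pooled.values())

    def min_corr(self) -> float:
        return min(s.corr for s in self.pooled.values())


def make_folds(patient_ids: Sequence[str], k: int = 10, seed: int = 0) -> CVPlan:
    """Seeded uniform partition of patients into k folds of near-equal size."""
    ids = list(dict.fromkeys(patient_ids))
    if len(ids) < k:
        raise ValueError(f"need >= {k} patients for {k}-fold CV, got {len(ids)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    assignment = {ids[j]: int(i % k) for i, j in enumerate(order)}
    return CVPlan(k=k, assignment=assignment)


def featurize(sensor_samples: np.ndarray, age_days: float,
              weight_kg: float, fs: float = _DEFAULT_FS) -> np.ndarray:
    """One model input row from a normalized window.

    The window is canonicalized to its time-normalized ensemble-average
    beat: each detected beat is resampled to a common 128-sample phase
    axis and the beats are averaged, putting the pressure-informative
    landmarks (systolic upstroke, dicrotic bump, end-diastolic shelf)
    at stable positions regardless of heart rate. The mean beat period
    (seconds) is appended so rate information is not lost, followed by
    the two demographic covariates. Covariates are appended raw here;
    per-fold min-max scaling with training-fold statistics happens
    inside the regressor.

    Because the input window is min-max normalized upstream and the
    ensemble beat is re-normalized, the features — hence every
    prediction — are exactly invariant to affine rescaling of the raw
    sensor stream.
    """
    from .beats import segment_beats  # local import to avoid cycle at import time

    x = np.asarray(sensor_samples, dtype=float)
    dst = np.linspace(0.0, 1.0, BEAT_TEMPLATE_LEN)
    beats = segment_beats(x - x.mean(), fs)
    if len(beats) >= 2:
        mats = []
        for b in beats:
            seg = x[b.start:b.end]
            src = np.linspace(0.0, 1.0, len(seg))
            mats.append(np.interp(dst, src, seg))
        template = np.mean(mats, axis=0)
        period = float(np.mean([b.end - b.start for b in beats])) / fs
    else:  # degenerate window: fall back to the resampled window itself
        src = np.linspace(0.0, 1.0, len(x))
        template = np.interp(dst, src, x)
        period = len(x) / fs
    span = np.ptp(template)
    if span > 0:
        template = (template - template.min()) / span
    return np.concatenate([template, [period, age_days, weight_kg]])


def _design(windows: Sequence[PairedWindow]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    X = np.stack([featurize(w.sensor_samples, w.age_days, w.weight_kg)
                  for w in windows])
    y = np.stack([w.bp_truth.as_array() for w in windows])  # (sbp, dbp, map)
    pids = np.array([w.patient_id for w in windows])
    return X, y, pids


class BPRegressor:
    """Small fully-connected network behind a fit/predict interface.

    Covariate columns (the last two) are min-max scaled with statistics
    frozen from the training fold. Predicted triplets are projected onto
    the physiological ordering dbp <= map <= sbp by sorting.
    """

    def __init__(self, hidden: tuple[int, ...] = (64, 32), max_iter: int = 150,
                 seed: int = 0):
        self.hidden = hidden
        self.max_iter = max_iter
        self.seed = seed
        self._net: Optional[MLPRegressor] = None
        self._cov_lo: Optional[np.ndarray] = None
        self._cov_span: Optional[np.ndarray] = None

    def _scale(self, X: np.ndarray) -> np.ndarray:
        X = X.copy()
        X[:, -2:] = (X[:, -2:] - self._cov_lo) / self._cov_span
        return X

    def fit(self, X: np.ndarray, y: np.ndarray) -> "BPRegressor":
        cov = X[:, -2:]
        self._cov_lo = cov.min(axis=0)
        self._cov_span = np.where(np.ptp(cov, axis=0) > 0, np.ptp(cov, axis=0), 1.0)
        self._net = MLPRegressor(hidden_layer_sizes=self.hidden,
                                 activation="relu", solver="adam",
                                 max_iter=self.max_iter, random_state=self.seed,
                                 early_stopping=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # convergence warnings at capped iters
            self._net.fit(self._scale(X), y)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self._net is None:
            raise RuntimeError("regressor is not fitted")
        raw = self._net.predict(self._scale(np.atleast_2d(X)))
        # enforce dbp <= map <= sbp: sort (dbp, map, sbp) ascending
        srt = np.sort(raw[:, [1, 2, 0]], axis=1)
        return np.column_stack([srt[:, 2], srt[:, 0], srt[:, 1]])

    def predict_triplet(self, x: np.ndarray) -> BPTriplet:
        p = self.predict(x)[0]
        return BPTriplet(sbp=float(p[0]), dbp=float(p[1]), map=float(p[2]))


class GradientBoostedBPRegressor:
    """Gradient-boosted-tree baseline behind the same fit/predict surface.

    One LightGBM model per BP component; useful for ablating the neural
    regressor (trees need no covariate scaling and are insensitive to
    feature monotonicity). Requires the optional ``lightgbm`` extra.
    """

    def __init__(self, n_estimators: int = 200, seed: int = 0):
        self.n_estimators = n_estimators
        self.seed = seed
        self._models: Optional[list] = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "GradientBoostedBPRegressor":
        import lightgbm as lgb

        self._models = []
        for j in range(y.shape[1]):
            m = lgb.LGBMRegressor(n_estimators=self.n_estimators,
                                  random_state=self.seed, verbose=-1)
            m.fit(X, y[:, j])
            self._models.append(m)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self._models is None:
            raise RuntimeError("regressor is not fitted")
        X = np.atleast_2d(X)
        raw = np.column_stack([m.predict(X) for m in self._models])
        srt = np.sort(raw[:, [1, 2, 0]], axis=1)
        return np.column_stack([srt[:, 2], srt[:, 0], srt[:, 1]])

    def predict_triplet(self, x: np.ndarray) -> BPTriplet:
        p = self.predict(x)[0]
        return BPTriplet(sbp=float(p[0]), dbp=float(p[1]), map=float(p[2]))


def _component_stats(pred: np.ndarray, true: np.ndarray) -> dict[str, ComponentStats]:
    out = {}
    for j, name in enumerate(COMPONENTS):
        d = pred[:, j] - true[:, j]
        if np.std(true[:, j]) > 0 and len(d) > 2:
            slope = float(np.polyfit(true[:, j], pred[:, j], 1)[0])
            corr = float(stats.pearsonr(true[:, j], pred[:, j])[0])
        else:
            slope, corr = float("nan"), float("nan")
        out[name] = ComponentStats(mae=float(np.mean(d)),
                                   sd=float(np.std(d, ddof=1)) if len(d) > 1 else 0.0,
                                   slope=slope, corr=corr)
    return out


def train_bp_model(db: Sequence[PairedWindow], plan: CVPlan, seed: int = 0,
                   hidden: tuple[int, ...] = (64, 32), max_iter: int = 150,
                   name: str = "mlp",
                   ) -> tuple[dict[int, BPRegressor], ModelReport, "HeldOutPredictions"]:
    """Individual-grouped k-fold CV training.

    For each fold, a fresh regressor is fit on the other k-1 folds and
    evaluated on the held-out fold; the report pools held-out
    predictions only, so every number reflects patients the model never
    saw. Returns the per-fold fitted models, the report, and the pooled
    held-out predictions (with patient labels, for agreement analysis).
    """
    if len(db) == 0:
        raise ValueError("empty paired database")
    X, y, pids = _design(db)
    folds = np.array([plan.fold_of(p) for p in pids])
    pred = np.full_like(y, np.nan)
    models: dict[int, BPRegressor] = {}
    per_fold = []
    for f in range(plan.k):
        test = folds == f
        train = ~test
        if not np.any(test):
            warnings.warn(f"fold {f} has zero windows; skipped")
            continue
        # leakage guard: no test patient may appear in the training side
        assert not (set(pids[test]) & set(pids[train]))
        reg = BPRegressor(hidden=hidden, max_iter=max_iter, seed=seed).fit(
            X[train], y[train])
        models[f] = reg
        pred[test] = reg.predict(X[test])
        per_fold.append(_component_stats(pred[test], y[test]))
    ok = ~np.isnan(pred[:, 0])
    report = ModelReport(name=name, pooled=_component_stats(pred[ok], y[ok]),
                         per_fold=per_fold)
    held_out = HeldOutPredictions(pred=pred[ok], true=y[ok], patient_ids=pids[ok])
    return models, report, held_out


@dataclass
class HeldOutPredictions:
    """Pooled held-out predictions from a grouped-CV run."""

    pred: np.ndarray        # (n, 3): sbp, dbp, map
    true: np.ndarray        # (n, 3)
    patient_ids: np.ndarray


def infer_bp(model: BPRegressor, stream_windows, fs: float,
             ) -> list[tuple[float, Optional[BPTriplet]]]:
    """Apply a fitted model to a stream of analysis windows.

    ``stream_windows`` yields ``(time_s, normalized_window_or_None,
    age_days, weight_kg)``; gated-out windows (``None``) produce gaps,
    never interpolated values. One estimate is emitted per hop.
    """
    out = []
    for t, win, age, weight in stream_windows:
        if win is None:
            out.append((t, None))
            continue
        x = featurize(win, age, weight)
        out.append((t, model.predict_triplet(x)))
    return out


def rank_models(reports: Sequence[ModelReport],
                tol: float = 0.05) -> list[ModelReport]:
    """Order candidate models by the clinical selection rule.

    Lexicographic with tolerance: worst-component |bias|, then
    worst-component SD, then worst slope distance from 1, then minimum
    correlation (descending). Keys within ``tol`` of each other are
    treated as tied and fall through to the next criterion.
    """
    if not reports:
        raise ValueError("no reports to rank")

    def keys(r: ModelReport) -> tuple[float, float, float, float]:
        return (r.worst_abs_mae(), r.worst_sd(), r.worst_slope_dist(),
                -r.min_corr())

    quantized = [tuple(round(v / tol) for v in keys(r)) for r in reports]
    order = sorted(range(len(reports)), key=lambda i: (quantized[i], i))
    return [reports[i] for i in order]
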