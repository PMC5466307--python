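"""Cardiac models of end-systole duration as a linear function of heart rate.

The patient-adapted cardiac model (PACM) is a robust linear regression of
the measured end-systole duration (s) on instantaneous heart rate (bpm),
fitted per subject on the chronologically first 80% of accepted cycles.
Its quality gate is the standard deviation of the regression residuals:
above 10 ms the subject's model is flagged as bad and the subject excluded.
The same regression pooled over a whole (single-sex) population gives the
"PACM averaged" model; Weissler's historical phonocardiographic regression
provides the fixed global reference constants.

:class:`SystoleRegressor` is a scikit-learn compatible estimator; the
module-level ``fit_pacm`` / ``fit_population_model`` functions are thin
wrappers returning :class:`CardiacModel` records.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import statsmodels.api as sm
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .systole import SystoleSample

#: Global model constants: (slope s/bpm, intercept s, residual SD s, r_squared).
#: Weissler's rows are historical population regressions of systolic time on
#: heart rate; the PACM-averaged and echocardiography rows are pooled fits
#: usable as generator presets.
GLOBAL_MODEL_TABLE = {
    ("weissler", "M"): (-0.0018, 0.456, 0.014, None),
    ("weissler", "F"): (-0.0016, 0.461, 0.014, None),
    ("pacm_averaged", "M"): (-0.0016, 0.441, 0.023, 0.96),
    ("pacm_averaged", "F"): (-0.0018, 0.464, 0.016, 0.96),
    ("echo", None): (-0.0020, 0.488, 0.017, 0.54),
}

MODEL_KINDS = ("pacm", "pacm_averaged", "weissler", "echo")


@dataclass
class CardiacModel:
    """A fitted (or fixed) linear end-systole model.

    ``quality_ok`` applies the residual-SD gate; for fixed global models it
    is always True.
    """

    slope: float          # s/bpm
    intercept: float      # s
    residual_sd: float    # s
    r_squared: Optional[float]
    n_train: int
    quality_ok: bool
    kind: str
    sex: Optional[str] = None
    subject_id: str = ""
    slope_se: float = np.nan
    intercept_se: float = np.nan
    r_squared_subject_means: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {self.kind!r}")
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be >= 0")

    def predict(self, hr_bpm) -> np.ndarray:
        return predict_end_systole(self, hr_bpm)


class SystoleRegressor(RegressorMixin, BaseEstimator):
    """Linear regression of end-systole duration on heart rate.

    Parameters
    ----------
    method : {'huber', 'ols'}
        'huber' (default) fits an M-estimator by iteratively reweighted
        least squares with Huber weights; 'ols' is ordinary least squares
        (useful as an oracle on outlier-free data).
    huber_t : float
        Huber tuning constant in units of scale (1.345 gives 95% Gaussian
        efficiency).
    quality_threshold_s : float
        Residual-SD gate; ``quality_ok_`` is True when the residual SD does
        not exceed it.

    Attributes
    ----------
    slope_, intercept_ : float
        Coefficients of ``systole = intercept_ + slope_ * hr``.
    residual_sd_ : float
        SD of the residuals around the fitted line (n-2 denominator).
    r_squared_ : float or nan
        Per-cycle determination coefficient (nan when the outcome or the
        regressor has zero variance).
    quality_ok_ : bool
    """

    def __init__(
        self,
        method: str = "huber",
        huber_t: float = 1.345,
        quality_threshold_s: float = 0.010,
    ):
        self.method = method
        self.huber_t = huber_t
        self.quality_threshold_s = quality_threshold_s

    def fit(self, X, y):
        X, y = check_X_y(X, y, ensure_min_samples=2)
        if X.shape[1] != 1:
            raise ValueError("expected a single regressor (heart rate, bpm)")
        if self.method not in ("huber", "ols"):
            raise ValueError(f"method must be 'huber' or 'ols', got {self.method!r}")
        hr = X[:, 0]
        n = len(hr)
        if np.ptp(hr) == 0.0:
            # Degenerate design: constant heart rate.  The model collapses to
            # a robust location; still usable for prediction.
            self.slope_ = 0.0
            self.intercept_ = float(np.median(y)) if self.method == "huber" else float(np.mean(y))
            resid = y - self.intercept_
            dof = max(n - 2, 1)
            self.residual_sd_ = float(np.sqrt(np.sum(resid**2) / dof))
            self.r_squared_ = math.nan
            self.slope_se_ = math.nan
            self.intercept_se_ = math.nan
        else:
            design = sm.add_constant(hr)
            if self.method == "ols":
                res = sm.OLS(y, design).fit()
            else:
                res = sm.RLM(y, design, M=sm.robust.norms.HuberT(t=self.huber_t)).fit()
            self.intercept_ = float(res.params[0])
            self.slope_ = float(res.params[1])
            resid = y - (self.intercept_ + self.slope_ * hr)
            dof = max(n - 2, 1)
            self.residual_sd_ = float(np.sqrt(np.sum(resid**2) / dof))
            ss_tot = float(np.sum((y - y.mean()) ** 2))
            self.r_squared_ = (
                1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else math.nan
            )
            self.intercept_se_ = float(res.bse[0])
            self.slope_se_ = float(res.bse[1])
        self.coef_ = np.array([self.slope_])
        self.n_features_in_ = 1
        self.quality_ok_ = bool(self.residual_sd_ <= self.quality_threshold_s)
        return self

    def predict(self, X):
        check_is_fitted(self, "slope_")
        X = check_array(X)
        return self.intercept_ + self.slope_ * X[:, 0]


def _samples_to_xy(samples: Sequence[SystoleSample]) -> Tuple[np.ndarray, np.ndarray]:
    use = [s for s in samples if s.valid]
    hr = np.array([s.hr for s in use], dtype=float)
    y = np.array([s.systole_s for s in use], dtype=float)
    return hr, y


def fit_pacm(
    samples: Sequence[SystoleSample],
    method: str = "huber",
    quality_threshold_s: float = 0.010,
    kind: str = "pacm",
    sex: Optional[str] = None,
    subject_id: str = "",
) -> CardiacModel:
    """Fit a patient-adapted cardiac model on one subject's training cycles.

    Only valid samples enter the regression; at least 2 are required.
    """
    hr, y = _samples_to_xy(samples)
    if len(hr) < 2:
        raise ValueError("need at least 2 valid samples to fit a model")
    est = SystoleRegressor(method=method, quality_threshold_s=quality_threshold_s)
    est.fit(hr[:, None], y)
    return CardiacModel(
        slope=est.slope_,
        intercept=est.intercept_,
        residual_sd=est.residual_sd_,
        r_squared=None if math.isnan(est.r_squared_) else est.r_squared_,
        n_train=len(hr),
        quality_ok=est.quality_ok_,
        kind=kind,
        sex=sex,
        subject_id=subject_id,
        slope_se=est.slope_se_,
        intercept_se=est.intercept_se_,
    )


def fit_population_model(
    samples: Sequence[SystoleSample],
    sex: Optional[str] = None,
    method: str = "huber",
    subject_means: bool = True,
) -> CardiacModel:
    """Pooled ("PACM averaged") regression over the valid samples of one sex.

    Besides the per-cycle determination coefficient, an R^2 computed on
    subject-mean points (mean heart rate vs mean systole per subject) is
    reported when subject identifiers are available, since the two variants
    can differ strongly for pooled data.
    """
    model = fit_pacm(samples, method=method, kind="pacm_averaged", sex=sex)
    if subject_means:
        ids = {s.subject_id for s in samples if s.valid}
        if len(ids) > 2 and any(ids):
            hr_m, y_m = [], []
            for sid in sorted(ids):
                sub = [s for s in samples if s.valid and s.subject_id == sid]
                hr_m.append(np.mean([s.hr for s in sub]))
                y_m.append(np.mean([s.systole_s for s in sub]))
            pred = model.intercept + model.slope * np.asarray(hr_m)
            resid = np.asarray(y_m) - pred
            ss_tot = float(np.sum((np.asarray(y_m) - np.mean(y_m)) ** 2))
            if ss_tot > 0:
                model.r_squared_subject_means = 1.0 - float(np.sum(resid**2)) / ss_tot
    return model


def weissler_model(sex: str) -> CardiacModel:
    """Weissler's fixed global constants for the given sex."""
    if sex not in ("M", "F"):
        raise ValueError(f"sex must be 'M' or 'F', got {sex!r}")
    slope, intercept, sd, r2 = GLOBAL_MODEL_TABLE[("weissler", sex)]
    return CardiacModel(
        slope=slope,
        intercept=intercept,
        residual_sd=sd,
        r_squared=r2,
        n_train=0,
        quality_ok=True,
        kind="weissler",
        sex=sex,
    )


def global_model(kind: str, sex: Optional[str] = None) -> CardiacModel:
    """Any fixed global-model row (weissler, pacm_averaged, echo)."""
    key = (kind, sex if kind != "echo" else None)
    if key not in GLOBAL_MODEL_TABLE:
        raise ValueError(f"no global model for kind={kind!r}, sex={sex!r}")
    slope, intercept, sd, r2 = GLOBAL_MODEL_TABLE[key]
    return CardiacModel(
        slope=slope,
        intercept=intercept,
        residual_sd=sd,
        r_squared=r2,
        n_train=0,
        quality_ok=True,
        kind=kind,
        sex=sex,
    )


def predict_end_systole(model: CardiacModel, hr_bpm) -> np.ndarray:
    """End-systole duration (s) predicted at the given heart rates (bpm)."""
    hr = np.asarray(hr_bpm, dtype=float)
    if np.any(hr <= 0):
        raise ValueError("heart rate must be positive")
    return model.intercept + model.slope * hr


@dataclass
class TrainHoldoutSplit:
    """Chronological per-subject split of valid samples."""

    train: List[SystoleSample]
    holdout: List[SystoleSample]
    flagged_subjects: List[str] = field(default_factory=list)


def split_train_holdout(
    samples: Sequence[SystoleSample],
    frac: float = 0.8,
    min_per_subject: int = 5,
) -> TrainHoldoutSplit:
    """Per subject: first ``floor(frac * n)`` valid cycles train, rest holdout.

    Samples must be chronologically ordered within each subject.  Subjects
    with fewer than ``min_per_subject`` valid cycles are flagged and excluded
    entirely.
    """
    if not 0.0 < frac <= 1.0:
        raise ValueError("frac must be in (0, 1]")
    by_subject: dict = {}
    order: List[str] = []
    for s in samples:
        if not s.valid:
            continue
        if s.subject_id not in by_subject:
            by_subject[s.subject_id] = []
            order.append(s.subject_id)
        by_subject[s.subject_id].append(s)
    train: List[SystoleSample] = []
    holdout: List[SystoleSample] = []
    flagged: List[str] = []
    for sid in order:
        sub = by_subject[sid]
        if len(sub) < min_per_subject:
            flagged.append(sid)
            continue
        k = int(math.floor(frac * len(sub)))
        train.extend(sub[:k])
        holdout.extend(sub[k:])
    return TrainHoldoutSplit(train=train, holdout=holdout, flagged_subjects=flagged)
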