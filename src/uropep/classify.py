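"""Class-weighted RBF support-vector classification of peptide-marker panels.

The classifier is a soft-margin C-SVC with Gaussian kernel
K(u, v) = exp(-gamma * ||u - v||^2) trained on the panel's amplitudes,
transformed as ln(1 + a) and standardized with training-set mean/SD.  Class
imbalance is compensated by per-class penalties C_k = C * n_total / (2 n_k),
so the minority class pays proportionally more per misclassification.  A
sample's *membership score* is the signed decision value (positive =
case-like); a fixed decision threshold (default -0.25, recomputable via the
Youden index) turns scores into test results.

Evaluation utilities: leave-one-out cross-validation, ROC analysis with
Mann–Whitney AUC, DeLong AUC confidence intervals, Clopper–Pearson exact
binomial CIs for sensitivity/specificity, Youden-optimal thresholding, and
logistic-regression adjustment of scores for age and sex.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.svm import SVC

from .types import PeakMatrix, SampleRecord, case_mask


@dataclass(frozen=True)
class SVMConfig:
    C: float = 2.2691
    gamma: float = 0.0764
    eps: float = 0.001
    class_weighting: bool = True
    feature_transform: str = "ln1p_standardized"  # or "raw"
    decision_threshold: float = -0.25

    def __post_init__(self) -> None:
        if self.C <= 0 or self.gamma <= 0 or self.eps <= 0:
            raise ValueError("C, gamma and eps must be positive")
        if self.feature_transform not in ("ln1p_standardized", "raw"):
            raise ValueError(f"unknown feature_transform {self.feature_transform!r}")


def class_weights(labels: np.ndarray) -> dict[int, float]:
    """Penalty multipliers n_total / (2 n_k) per class (effective per-class
    cost C_k = C * n_total / (2 n_k))."""
    n_total = len(labels)
    out = {}
    for k in np.unique(labels):
        n_k = int((labels == k).sum())
        out[int(k)] = n_total / (2.0 * n_k)
    return out


@dataclass
class ClassifierModel:
    """A trained panel classifier.

    Holds the panel peptide ids, the feature-transform constants, the fitted
    SVC and the fixed decision threshold.  ``artifact`` is a plain-JSON
    description (support vectors, dual coefficients, kernel parameters,
    standardization constants) sufficient to recompute decision values
    without sklearn state.
    """

    panel: list
    config: SVMConfig
    svc: SVC | None
    feature_mean: np.ndarray
    feature_sd: np.ndarray
    threshold: float

    # -- feature pipeline ----------------------------------------------------
    def _features(self, peaks: PeakMatrix) -> np.ndarray:
        missing = [p for p in self.panel if p not in peaks.amplitudes.columns]
        if missing:
            raise KeyError(f"panel peptides missing from matrix: {missing}")
        X = peaks.amplitudes[self.panel].to_numpy(dtype=float)
        if self.config.feature_transform == "ln1p_standardized":
            X = np.log1p(X)
            X = (X - self.feature_mean) / self.feature_sd
        return X

    def decision_values(self, peaks: PeakMatrix) -> pd.Series:
        X = self._features(peaks)
        if self.svc is not None:
            scores = self.svc.decision_function(X)
        else:
            scores = _kernel_decision(self.artifact(), X)
        return pd.Series(scores, index=peaks.amplitudes.index, name="score")

    def classify(self, peaks: PeakMatrix) -> pd.Series:
        """Positive test iff score >= threshold."""
        return self.decision_values(peaks) >= self.threshold

    # -- serialization -------------------------------------------------------
    def artifact(self) -> dict:
        if self.svc is None:
            return self._artifact
        svc = self.svc
        return {
            "panel": [str(p) for p in self.panel],
            "kernel": "rbf",
            "C": self.config.C,
            "gamma": self.config.gamma,
            "eps": self.config.eps,
            "feature_transform": self.config.feature_transform,
            "class_weighting": self.config.class_weighting,
            "threshold": self.threshold,
            "feature_mean": self.feature_mean.tolist(),
            "feature_sd": self.feature_sd.tolist(),
            "support_vectors": svc.support_vectors_.tolist(),
            "dual_coef": svc.dual_coef_[0].tolist(),
            "intercept": float(svc.intercept_[0]),
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.artifact(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "ClassifierModel":
        with open(path) as fh:
            art = json.load(fh)
        config = SVMConfig(
            C=art["C"], gamma=art["gamma"], eps=art["eps"],
            class_weighting=art["class_weighting"],
            feature_transform=art["feature_transform"],
            decision_threshold=art["threshold"],
        )
        model = cls(
            panel=list(art["panel"]),
            config=config,
            svc=None,
            feature_mean=np.asarray(art["feature_mean"], dtype=float),
            feature_sd=np.asarray(art["feature_sd"], dtype=float),
            threshold=float(art["threshold"]),
        )
        model._artifact = art
        return model


def _kernel_decision(art: dict, X: np.ndarray) -> np.ndarray:
    """Decision values from the serialized dual form:
    f(x) = sum_i alpha_i K(sv_i, x) + b."""
    sv = np.asarray(art["support_vectors"], dtype=float)
    alpha = np.asarray(art["dual_coef"], dtype=float)
    gamma = float(art["gamma"])
    d2 = ((X[:, None, :] - sv[None, :, :]) ** 2).sum(axis=2)
    K = np.exp(-gamma * d2)
    return K @ alpha + float(art["intercept"])


def train_svm(
    peaks: PeakMatrix,
    records: Sequence[SampleRecord],
    panel: Sequence,
    config: SVMConfig = SVMConfig(),
) -> ClassifierModel:
    """Train the class-weighted RBF C-SVC on the panel amplitudes.

    Labels come from the records (case = HCC); scores are oriented so that
    positive decision values point toward the case class.
    """
    if [r.sample_id for r in records] != peaks.sample_ids:
        raise ValueError("records must align with the peak-matrix samples")
    y = case_mask(records).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("training requires both classes")
    sub = peaks.subset_peptides(list(panel))
    X = sub.amplitudes.to_numpy(dtype=float)
    if config.feature_transform == "ln1p_standardized":
        X = np.log1p(X)
        mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        sd = np.where(sd > 0, sd, 1.0)
        X = (X - mean) / sd
    else:
        mean = np.zeros(X.shape[1])
        sd = np.ones(X.shape[1])
    weight = class_weights(y) if config.class_weighting else None
    svc = SVC(
        kernel="rbf", C=config.C, gamma=config.gamma, tol=config.eps,
        class_weight=weight,
    )
    svc.fit(X, y)
    return ClassifierModel(
        panel=list(panel),
        config=config,
        svc=svc,
        feature_mean=mean,
        feature_sd=sd,
        threshold=config.decision_threshold,
    )


def membership_scores(model: ClassifierModel, peaks: PeakMatrix) -> pd.Series:
    """Signed decision value per sample (positive = case-like)."""
    return model.decision_values(peaks)


def loo_cross_validate(
    peaks: PeakMatrix,
    records: Sequence[SampleRecord],
    panel: Sequence,
    config: SVMConfig = SVMConfig(),
) -> pd.Series:
    """Leave-one-out cross-validated membership scores.

    Each sample is scored by a model trained on all remaining samples, with
    the feature standardization refit per fold.
    """
    y = case_mask(records)
    if int(y.sum()) < 3 or int((~y).sum()) < 3:
        raise ValueError("leave-one-out needs at least 3 samples per class")
    scores = pd.Series(np.nan, index=peaks.amplitudes.index, name="loo_score")
    sample_ids = peaks.sample_ids
    for i, sid in enumerate(sample_ids):
        rest = [s for s in sample_ids if s != sid]
        model = train_svm(
            peaks.subset_samples(rest),
            [r for r in records if r.sample_id != sid],
            panel,
            config,
        )
        scores.loc[sid] = model.decision_values(peaks.subset_samples([sid])).iloc[0]
    return scores


# ---------------------------------------------------------------------------
# ROC machinery


def auc_mann_whitney(scores: Sequence[float], labels: Sequence[bool]) -> float:
    """AUC as the Mann–Whitney concordance probability with tie correction."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if y.all() or not y.any():
        raise ValueError("need both positive and negative labels")
    ranks = stats.rankdata(s)
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    return float((ranks[y].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def delong_variance(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """DeLong AUC and its variance for one classifier."""
    auc, (v10, v01) = _delong_components(scores, labels)
    n_pos, n_neg = len(v10), len(v01)
    var = v10.var(ddof=1) / n_pos + v01.var(ddof=1) / n_neg
    return auc, var


def _delong_components(scores: np.ndarray, labels: np.ndarray):
    pos = scores[labels]
    neg = scores[~labels]
    m, n = len(pos), len(neg)
    all_ranks = _midrank(np.concatenate([pos, neg]))
    pos_ranks = _midrank(pos)
    neg_ranks = _midrank(neg)
    auc = (all_ranks[:m].sum() - m * (m + 1) / 2) / (m * n)
    v10 = (all_ranks[:m] - pos_ranks) / n          # structural components, positives
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m    # structural components, negatives
    return float(auc), (v10, v01)


def delong_ci(scores: Sequence[float], labels: Sequence[bool], level: float = 0.95) -> tuple[float, float, float]:
    """(AUC, lower, upper) by DeLong's asymptotic normal interval, clipped to [0, 1]."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    auc, var = delong_variance(s, y)
    z = stats.norm.ppf(0.5 + level / 2)
    half = z * np.sqrt(max(var, 0.0))
    return auc, float(max(0.0, auc - half)), float(min(1.0, auc + half))


def delong_paired_test(
    scores_a: Sequence[float], scores_b: Sequence[float], labels: Sequence[bool]
) -> tuple[float, float, float]:
    """Paired DeLong test for AUC difference on the same samples.

    Returns (auc_a, auc_b, two-sided p).
    """
    y = np.asarray(labels, dtype=bool)
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    auc_a, (v10a, v01a) = _delong_components(a, y)
    auc_b, (v10b, v01b) = _delong_components(b, y)
    n_pos, n_neg = len(v10a), len(v01a)
    s10 = np.cov(np.stack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.stack([v01a, v01b]), ddof=1)
    var = (
        s10[0, 0] / n_pos + s10[1, 1] / n_pos - 2 * s10[0, 1] / n_pos
        + s01[0, 0] / n_neg + s01[1, 1] / n_neg - 2 * s01[0, 1] / n_neg
    )
    if var <= 0:
        return auc_a, auc_b, 1.0
    z = (auc_a - auc_b) / np.sqrt(var)
    return auc_a, auc_b, float(2 * stats.norm.sf(abs(z)))


def clopper_pearson(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact binomial (Clopper–Pearson) CI for a proportion k/n."""
    alpha = 1 - level
    lo = stats.beta.ppf(alpha / 2, k, n - k + 1) if k > 0 else 0.0
    hi = stats.beta.ppf(1 - alpha / 2, k + 1, n - k) if k < n else 1.0
    return float(lo), float(hi)


@dataclass
class ROCResult:
    auc: float
    auc_ci_95: tuple[float, float]
    threshold: float
    sensitivity: float
    sensitivity_ci_95: tuple[float, float]
    specificity: float
    specificity_ci_95: tuple[float, float]
    operating_points: pd.DataFrame  # columns: threshold, sensitivity, specificity


def roc_analysis(
    scores: Sequence[float], labels: Sequence[bool], threshold: float
) -> ROCResult:
    """ROC summary at a fixed decision threshold (positive iff score >= it).

    AUC is the Mann–Whitney concordance with DeLong 95% CI; sensitivity and
    specificity carry exact binomial (Clopper–Pearson) 95% CIs.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if y.all() or not y.any():
        raise ValueError("need both positive and negative labels")
    auc, lo, hi = delong_ci(s, y)
    pos = s >= threshold
    tp = int((pos & y).sum())
    tn = int((~pos & ~y).sum())
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    sens = tp / n_pos
    spec = tn / n_neg
    cand = np.concatenate([[-np.inf], _midpoints(np.unique(s)), [np.inf]])
    ops = pd.DataFrame(
        {
            "threshold": cand,
            "sensitivity": [float((s[y] >= t).mean()) for t in cand],
            "specificity": [float((s[~y] < t).mean()) for t in cand],
        }
    )
    return ROCResult(
        auc=auc,
        auc_ci_95=(lo, hi),
        threshold=float(threshold),
        sensitivity=sens,
        sensitivity_ci_95=clopper_pearson(tp, n_pos),
        specificity=spec,
        specificity_ci_95=clopper_pearson(tn, n_neg),
        operating_points=ops,
    )


def _midpoints(sorted_unique: np.ndarray) -> np.ndarray:
    return (sorted_unique[:-1] + sorted_unique[1:]) / 2.0


def youden_threshold(scores: Sequence[float], labels: Sequence[bool]) -> tuple[float, float]:
    """Threshold maximizing Youden's J = sensitivity + specificity - 1.

    Candidates are the midpoints between adjacent sorted unique scores
    (positive iff score >= threshold); ties in J are broken toward the
    lower threshold, i.e. higher sensitivity.  Returns (threshold, J).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if y.all() or not y.any():
        raise ValueError("need both positive and negative labels")
    uniq = np.unique(s)
    if len(uniq) == 1:
        return float(uniq[0]), 0.0
    best_t, best_j = None, -np.inf
    for t in _midpoints(uniq):
        j = float((s[y] >= t).mean()) + float((s[~y] < t).mean()) - 1.0
        if j > best_j + 1e-12:
            best_t, best_j = float(t), j
    return best_t, best_j


@dataclass
class CovariateAdjustment:
    probabilities: pd.Series
    auc_unadjusted: float
    auc_adjusted: float
    delong_p: float
    coefficients: dict
    separation_fallback: bool


def adjust_covariates(
    scores: Sequence[float], records: Sequence[SampleRecord]
) -> CovariateAdjustment:
    """Logistic regression of case status on (score, age, sex).

    Returns fitted case probabilities as the adjusted classifier output and
    a paired DeLong comparison of adjusted vs unadjusted AUC.  If the fit
    separates perfectly (or otherwise fails), falls back to a
    ridge-stabilized fit and flags it.
    """
    import statsmodels.api as sm

    s = np.asarray(scores, dtype=float)
    y = case_mask(records).astype(float)
    age = np.array([r.age for r in records], dtype=float)
    sex = np.array([1.0 if r.sex == "F" else 0.0 for r in records])
    if np.isnan(age).any():
        raise ValueError("age missing for some samples")
    X = sm.add_constant(np.column_stack([s, age, sex]), has_constant="add")
    fallback = False
    params = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
            params = fit.params
            if not np.all(np.isfinite(params)) or np.abs(params).max() > 1e3:
                raise RuntimeError("separation suspected")
        except Exception:
            fallback = True
            fit = sm.Logit(y, X).fit_regularized(
                disp=0, alpha=1.0, L1_wt=0.0, maxiter=500
            )
            params = np.asarray(fit.params)
    eta = X @ np.asarray(params)
    prob = 1.0 / (1.0 + np.exp(-eta))
    auc_a, auc_b, p = delong_paired_test(prob, s, y.astype(bool))
    names = ["const", "score", "age", "sex_female"]
    return CovariateAdjustment(
        probabilities=pd.Series(prob, index=[r.sample_id for r in records]),
        auc_unadjusted=auc_b,
        auc_adjusted=auc_a,
        delong_p=p,
        coefficients=dict(zip(names, np.asarray(params, dtype=float))),
        separation_fallback=fallback,
    )
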