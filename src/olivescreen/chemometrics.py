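"""Multivariate machinery for fingerprint classification.

Implements the chemometric core of the screening tool: unit-variance scaling
with mean centring, PCA with Hotelling's T² / Q-residual outlier screening,
PLS1 discriminant analysis fitted by NIPALS on a 0/1 dummy response,
stratified leave-10%-out cross-validation with Q²/RMSEcv latent-variable
selection, label-permutation testing, and ANOVA on the cross-validation
residuals (CV-ANOVA).

Conventions: column SDs use the n-1 denominator; zero-variance columns get
scale 1 so they centre to exactly zero and stay inert (keeping the column
index aligned with the scan axis); Q² uses the global total sum of squares
about the mean of the training dummy.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# autoscaling

@dataclass
class Preprocessor:
    """Column means/SDs learned on training data; apply-only on new data."""

    column_means: np.ndarray
    column_scales: np.ndarray
    fitted_on: int

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, float) - self.column_means) / self.column_scales

    def inverse_transform(self, Xs: np.ndarray) -> np.ndarray:
        return np.asarray(Xs, float) * self.column_scales + self.column_means


def autoscale_fit(X: np.ndarray) -> Preprocessor:
    X = np.asarray(X, float)
    if X.shape[0] < 2:
        raise ValueError("autoscaling needs at least 2 rows")
    means = X.mean(axis=0)
    scales = X.std(axis=0, ddof=1)
    scales = np.where(scales > 0, scales, 1.0)
    return Preprocessor(column_means=means, column_scales=scales,
                        fitted_on=X.shape[0])


def autoscale_apply(pre: Preprocessor, X: np.ndarray) -> np.ndarray:
    return pre.transform(X)


# ---------------------------------------------------------------------------
# PCA and outlier screening

@dataclass
class PCAModel:
    loadings: np.ndarray                 # p x A, orthonormal columns
    scores: np.ndarray                   # n x A
    explained_variance_ratio: np.ndarray
    singular_values: np.ndarray
    A: int
    residual_eigenvalues: np.ndarray     # variances of unused components
    preprocessor: Preprocessor | None = None


def pca_fit(X: np.ndarray, A: int, preprocessed: bool = False) -> PCAModel:
    """PCA by SVD of the autoscaled matrix (or of X as-is if preprocessed)."""
    X = np.asarray(X, float)
    n, p = X.shape
    if A > min(n - 1, p):
        raise ValueError(f"A={A} exceeds min(n-1, p)={min(n - 1, p)}")
    pre = None
    if not preprocessed:
        pre = autoscale_fit(X)
        X = pre.transform(X)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    total_var = (s**2).sum()
    evr = s[:A] ** 2 / total_var if total_var > 0 else np.zeros(A)
    resid_eig = s[A:] ** 2 / (n - 1)
    return PCAModel(
        loadings=Vt[:A].T,
        scores=U[:, :A] * s[:A],
        explained_variance_ratio=evr,
        singular_values=s[:A],
        A=A,
        residual_eigenvalues=resid_eig,
        preprocessor=pre,
    )


@dataclass
class OutlierReport:
    t2: np.ndarray
    t2_limit: float
    q: np.ndarray
    q_limit: float
    outlier_flags: np.ndarray


def hotelling_t2(scores: np.ndarray) -> np.ndarray:
    """T²_i = sum_a t_ia² / var(t_a), variances with the n-1 denominator."""
    var = scores.var(axis=0, ddof=1)
    var = np.where(var > 0, var, np.inf)
    return (scores**2 / var).sum(axis=1)


def t2_limit(n: int, A: int, confidence: float = 0.95) -> float:
    """F-based Hotelling limit: A(n-1)(n+1) / (n(n-A)) * F(A, n-A)."""
    if n <= A:
        raise ValueError("need n > A for a T² limit")
    f = stats.f.ppf(confidence, A, n - A)
    return A * (n - 1) * (n + 1) / (n * (n - A)) * f


def q_limit_jm(residual_eigenvalues: np.ndarray, confidence: float = 0.95) -> float:
    """Jackson-Mudholkar upper control limit for the Q residual statistic."""
    lam = np.asarray(residual_eigenvalues, float)
    th1 = lam.sum()
    if th1 <= 0:
        return 0.0
    th2 = (lam**2).sum()
    th3 = (lam**3).sum()
    h0 = 1.0 - 2.0 * th1 * th3 / (3.0 * th2**2) if th2 > 0 else 1.0
    if h0 <= 0:
        h0 = 1e-4
    c = stats.norm.ppf(confidence)
    term = (c * np.sqrt(2 * th2 * h0**2) / th1
            + 1.0 + th2 * h0 * (h0 - 1.0) / th1**2)
    return float(th1 * np.sign(term) * np.abs(term) ** (1.0 / h0))


def outlier_screen(model: PCAModel, X: np.ndarray,
                   confidence: float = 0.95) -> OutlierReport:
    """Flag samples with T² or Q above their control limits.

    ``X`` must be the matrix the model was fitted on (or new data on the same
    columns); it is passed through the model's preprocessor when present.
    """
    X = np.asarray(X, float)
    Xs = model.preprocessor.transform(X) if model.preprocessor is not None else X
    scores = Xs @ model.loadings
    resid = Xs - scores @ model.loadings.T
    q = (resid**2).sum(axis=1)
    var = model.scores.var(axis=0, ddof=1)
    var = np.where(var > 0, var, np.inf)
    t2 = (scores**2 / var).sum(axis=1)
    n = model.scores.shape[0]
    t2_lim = t2_limit(n, model.A, confidence)
    q_lim = q_limit_jm(model.residual_eigenvalues, confidence)
    flags = (t2 > t2_lim) | (q > q_lim)
    return OutlierReport(t2=t2, t2_limit=t2_lim, q=q, q_limit=q_lim,
                         outlier_flags=flags)


# ---------------------------------------------------------------------------
# PLS1-DA (NIPALS)

@dataclass
class PLSDAModel:
    """Binary PLS1 discriminant model on autoscaled fingerprints.

    The dummy response is 1 for the positive class and 0 otherwise; the
    predicted value (PV) of a new sample is an unbounded real around [0, 1].
    """

    dummy_coding: dict[str, int]
    n_lv: int
    weights: np.ndarray      # p x A
    x_loadings: np.ndarray   # p x A
    scores: np.ndarray       # n x A
    y_loadings: np.ndarray   # A
    coefficients: np.ndarray  # p, on the autoscaled scale
    intercept: float          # mean of the training dummy
    preprocessor: Preprocessor
    training_ids: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "dummy_coding": self.dummy_coding,
            "n_lv": self.n_lv,
            "weights": self.weights.tolist(),
            "x_loadings": self.x_loadings.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "coefficients": self.coefficients.tolist(),
            "intercept": self.intercept,
            "column_means": self.preprocessor.column_means.tolist(),
            "column_scales": self.preprocessor.column_scales.tolist(),
            "fitted_on": self.preprocessor.fitted_on,
            "training_ids": self.training_ids,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PLSDAModel":
        pre = Preprocessor(
            column_means=np.asarray(d["column_means"], float),
            column_scales=np.asarray(d["column_scales"], float),
            fitted_on=int(d["fitted_on"]),
        )
        W = np.asarray(d["weights"], float)
        return cls(
            dummy_coding={k: int(v) for k, v in d["dummy_coding"].items()},
            n_lv=int(d["n_lv"]),
            weights=W,
            x_loadings=np.asarray(d["x_loadings"], float),
            scores=np.zeros((0, W.shape[1])),
            y_loadings=np.asarray(d["y_loadings"], float),
            coefficients=np.asarray(d["coefficients"], float),
            intercept=float(d["intercept"]),
            preprocessor=pre,
            training_ids=list(d.get("training_ids", [])),
        )


def _nipals_pls1(Xs: np.ndarray, yc: np.ndarray, n_lv: int):
    """NIPALS PLS1 on centred/scaled X and centred y.

    Returns (W, P, T, q, n_used); stops early if y is fully deflated.
    """
    n, p = Xs.shape
    X = Xs.copy()
    y = yc.copy()
    W = np.zeros((p, n_lv))
    P = np.zeros((p, n_lv))
    T = np.zeros((n, n_lv))
    q = np.zeros(n_lv)
    used = 0
    for a in range(n_lv):
        w = X.T @ y
        norm = np.linalg.norm(w)
        if norm < 1e-12:
            break
        w /= norm
        t = X @ w
        tt = float(t @ t)
        if tt < 1e-12:
            break
        pa = X.T @ t / tt
        qa = float(y @ t) / tt
        X -= np.outer(t, pa)
        y = y - t * qa
        W[:, a], P[:, a], T[:, a], q[a] = w, pa, t, qa
        used += 1
    return W[:, :used], P[:, :used], T[:, :used], q[:used], used


def _coefficients(W: np.ndarray, P: np.ndarray, q: np.ndarray, k: int) -> np.ndarray:
    """Regression vector using the first k latent variables: b = W(PᵀW)⁻¹q."""
    Wk, Pk, qk = W[:, :k], P[:, :k], q[:k]
    return Wk @ np.linalg.solve(Pk.T @ Wk, qk)


def pls1_fit(
    X: np.ndarray,
    y_dummy: np.ndarray,
    n_lv: int,
    dummy_coding: dict[str, int] | None = None,
    training_ids: list[str] | None = None,
) -> PLSDAModel:
    """Fit a PLS1-DA model: autoscale X, centre the dummy, run NIPALS."""
    X = np.asarray(X, float)
    y = np.asarray(y_dummy, float)
    if n_lv < 1:
        raise ValueError("n_lv must be >= 1")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("degenerate dummy: y contains a single class")
    pre = autoscale_fit(X)
    Xs = pre.transform(X)
    ybar = float(y.mean())
    W, P, T, q, used = _nipals_pls1(Xs, y - ybar, n_lv)
    if used < n_lv:
        log.info("NIPALS stopped after %d of %d latent variables", used, n_lv)
    b = _coefficients(W, P, q, used)
    return PLSDAModel(
        dummy_coding=dict(dummy_coding or {"positive": 1, "negative": 0}),
        n_lv=used,
        weights=W, x_loadings=P, scores=T, y_loadings=q,
        coefficients=b, intercept=ybar, preprocessor=pre,
        training_ids=list(training_ids or []),
    )


def pls1_predict(model: PLSDAModel, X_new: np.ndarray) -> np.ndarray:
    """Predicted values (PV) of the dummy for new rows."""
    X_new = np.atleast_2d(np.asarray(X_new, float))
    Xs = model.preprocessor.transform(X_new)
    return Xs @ model.coefficients + model.intercept


# ---------------------------------------------------------------------------
# cross-validation

@dataclass
class CVResult:
    fold_assignment: np.ndarray   # per-sample fold id
    oof_pv: np.ndarray            # n x max_lv out-of-fold predicted values
    press: np.ndarray             # per LV count
    rmsecv: np.ndarray
    q2: np.ndarray
    chosen_lv: int
    seed: int

    @property
    def oof_at_chosen(self) -> np.ndarray:
        return self.oof_pv[:, self.chosen_lv - 1]


def _stratified_folds(y: np.ndarray, n_folds: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Seeded stratified fold ids: within each class, shuffle and deal round-robin."""
    folds = np.empty(y.size, dtype=int)
    start = int(rng.integers(n_folds))
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        for k, i in enumerate(idx):
            folds[i] = (start + k) % n_folds
    return folds


def cross_validate(
    X: np.ndarray,
    y_dummy: np.ndarray,
    max_lv: int = 10,
    n_folds: int = 10,
    stratified: bool = True,
    seed: int = 0,
) -> CVResult:
    """Leave-10%-out cross-validation of PLS1-DA over 1..max_lv LVs.

    The preprocessor and the PLS model are refit inside every fold on the
    remaining 90% of samples only, so held-out rows never leak into the
    column statistics. The LV count minimizing RMSEcv is chosen (ties go to
    fewer LVs).
    """
    X = np.asarray(X, float)
    y = np.asarray(y_dummy, float)
    n = y.size
    if n < n_folds:
        raise ValueError(f"need at least n_folds={n_folds} samples, got {n}")
    if np.unique(y).size < 2:
        raise ValueError("degenerate dummy: y contains a single class")
    counts = np.array([(y == c).sum() for c in np.unique(y)])
    if stratified and counts.min() < n_folds:
        warnings.warn(
            "a class has fewer members than folds; stratification is partial",
            stacklevel=2)
    rng = np.random.default_rng(seed % (2**31))
    if stratified:
        folds = _stratified_folds(y, n_folds, rng)
    else:
        folds = np.arange(n) % n_folds
        rng.shuffle(folds)
    max_lv = min(max_lv, X.shape[1])
    oof = np.full((n, max_lv), np.nan)
    for f in range(n_folds):
        test = folds == f
        train = ~test
        if not test.any():
            continue
        if np.unique(y[train]).size < 2:
            raise ValueError(f"fold {f}: training split lost a class")
        k_max = min(max_lv, int(train.sum()) - 1)
        pre = autoscale_fit(X[train])
        Xs_tr = pre.transform(X[train])
        Xs_te = pre.transform(X[test])
        ybar = float(y[train].mean())
        W, P, T, q, used = _nipals_pls1(Xs_tr, y[train] - ybar, k_max)
        for k in range(1, max_lv + 1):
            kk = min(k, used)
            b = _coefficients(W, P, q, kk)
            oof[test, k - 1] = Xs_te @ b + ybar
    press = ((oof - y[:, None]) ** 2).sum(axis=0)
    rmsecv = np.sqrt(press / n)
    tss = float(((y - y.mean()) ** 2).sum())
    q2 = 1.0 - press / tss
    chosen = int(np.argmin(rmsecv)) + 1  # argmin takes the first (fewest LVs) on ties
    return CVResult(fold_assignment=folds, oof_pv=oof, press=press,
                    rmsecv=rmsecv, q2=q2, chosen_lv=chosen, seed=seed)


# ---------------------------------------------------------------------------
# permutation test and CV-ANOVA

@dataclass
class PermutationResult:
    n_perm: int
    permuted_q2: np.ndarray
    permuted_r2: np.ndarray
    original_q2: float
    original_r2: float
    empirical_p: float
    original_exceeds_all: bool


def _r2_fit(X: np.ndarray, y: np.ndarray, n_lv: int) -> float:
    model = pls1_fit(X, y, n_lv)
    fitted = pls1_predict(model, X)
    tss = ((y - y.mean()) ** 2).sum()
    return float(1.0 - ((y - fitted) ** 2).sum() / tss)


def permutation_test(
    X: np.ndarray,
    y_dummy: np.ndarray,
    n_lv: int,
    n_perm: int = 20,
    seed: int = 0,
    n_folds: int = 10,
) -> PermutationResult:
    """Label-permutation check for overfitting / chance correlation.

    The dummy is permuted ``n_perm`` times; model fitting and
    cross-validation are rerun each time at the same LV count. Reported are
    the empirical p-value (1 + #{permuted Q² >= original}) / (n_perm + 1)
    and the strict flag that the original Q² exceeds every permuted one.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    X = np.asarray(X, float)
    y = np.asarray(y_dummy, float)
    cv0 = cross_validate(X, y, max_lv=n_lv, n_folds=n_folds, seed=seed)
    orig_q2 = float(cv0.q2[min(n_lv, cv0.q2.size) - 1])
    orig_r2 = _r2_fit(X, y, n_lv)
    rng = np.random.default_rng([seed % (2**31), 59359])
    pq2 = np.empty(n_perm)
    pr2 = np.empty(n_perm)
    for i in range(n_perm):
        yp = rng.permutation(y)
        while np.unique(yp).size < 2:  # cannot happen for a two-class dummy
            yp = rng.permutation(y)
        cv = cross_validate(X, yp, max_lv=n_lv, n_folds=n_folds,
                            seed=int(rng.integers(2**31)))
        pq2[i] = cv.q2[min(n_lv, cv.q2.size) - 1]
        pr2[i] = _r2_fit(X, yp, n_lv)
    emp_p = (1 + int((pq2 >= orig_q2).sum())) / (n_perm + 1)
    return PermutationResult(
        n_perm=n_perm, permuted_q2=pq2, permuted_r2=pr2,
        original_q2=orig_q2, original_r2=orig_r2,
        empirical_p=emp_p, original_exceeds_all=bool(orig_q2 > pq2.max()),
    )


@dataclass
class CVANOVAResult:
    ss_null: float
    ss_model: float
    f_stat: float
    df1: int
    df2: int
    p_value: float


def cv_anova(cv: CVResult, y_dummy: np.ndarray) -> CVANOVAResult:
    """ANOVA on the cross-validation residuals at the chosen LV count.

    F = ((SS_null - PRESS)/df1) / (PRESS/df2) with df1 = number of LVs and
    df2 = n - LVs - 1; a model no better than the mean clamps F to 0, p = 1.
    """
    y = np.asarray(y_dummy, float)
    n = y.size
    lv = cv.chosen_lv
    df1 = lv
    df2 = n - lv - 1
    if df2 <= 0:
        raise ValueError("non-positive residual degrees of freedom")
    ss_null = float(((y - y.mean()) ** 2).sum())
    ss_model = float(cv.press[lv - 1])
    num = ss_null - ss_model
    if num <= 0 or ss_model <= 0:
        f_stat = 0.0
        p = 1.0
    else:
        f_stat = (num / df1) / (ss_model / df2)
        p = float(stats.f.sf(f_stat, df1, df2))
    return CVANOVAResult(ss_null=ss_null, ss_model=ss_model, f_stat=f_stat,
                         df1=df1, df2=df2, p_value=p)
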