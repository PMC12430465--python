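"""OPLS-DA implemented from scratch with the NIPALS orthogonal-filtering scheme.

The model regresses a centered +/-1 class coding on X after removing latent
components that are orthogonal to the response (Trygg-Wold style orthogonal
signal correction), leaving a single predictive component for binary
discrimination. Validation follows chemometrics practice: Q2 from stratified
cross-validation with pooled PRESS, and a label-permutation test on Q2 with
the add-one p-value rule.

With ``n_ortho=0`` the fit reduces exactly to single-component PLS1, which the
test suite exploits as an independent oracle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted

from .preprocess import pareto_scale_matrix

_EPS = 1e-12


@dataclass
class ValidationReport:
    """Cross-validated Q2 with permutation significance for one fitted model."""

    q2: float
    r2y: float
    p_perm: float
    n_perm: int
    n_folds: int

    def to_dict(self) -> dict:
        return {"q2": self.q2, "r2y": self.r2y, "p_perm": self.p_perm,
                "n_perm": self.n_perm, "n_folds": self.n_folds}


@dataclass
class MarkerRecord:
    """Per-feature marker evidence: VIP, adjusted p, S-plot coords, effect size.

    ``significant`` is the conjunction VIP > 1 and adjusted p < 0.05.
    """

    feature_id: str
    vip: float
    p_adj: float
    s_cov: float
    s_corr: float
    cohens_d: float
    d_category: str
    significant: bool

    def to_dict(self) -> dict:
        return {
            "feature_id": self.feature_id, "vip": self.vip, "p_adj": self.p_adj,
            "s_cov": self.s_cov, "s_corr": self.s_corr,
            "cohens_d": self.cohens_d, "d_category": self.d_category,
            "significant": self.significant,
        }


def _code_y(y) -> tuple[np.ndarray, np.ndarray]:
    """Map two class labels onto -1/+1 (sorted label order)."""
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(f"OPLS-DA needs exactly 2 classes, got {len(classes)}")
    coded = np.where(y == classes[1], 1.0, -1.0)
    return coded, classes


def _scale_matrix(X: np.ndarray, scale: str | None):
    if scale == "pareto":
        return pareto_scale_matrix(X)
    if scale == "center":
        means = X.mean(axis=0)
        return X - means, means, np.ones(X.shape[1])
    if scale is None or scale == "none":
        return X, np.zeros(X.shape[1]), np.ones(X.shape[1])
    raise ValueError(f"unknown scale {scale!r}")


class OPLSDA(BaseEstimator, ClassifierMixin):
    """Binary OPLS-DA classifier with one predictive component.

    Parameters
    ----------
    n_ortho : int or "auto", default="auto"
        Number of y-orthogonal components removed before the predictive fit.
        "auto" adds components while the cross-validated Q2 improves by more
        than `auto_tol`, up to `max_ortho`.
    scale : {"pareto", "center", "none"}, default="pareto"
        Column preprocessing estimated at fit time and stored on the model
        (applied again to new data in `predict`). Cross-validation re-estimates
        it on each training fold so held-out samples never leak into scaling.
    n_folds : int, default=10
        Upper bound on stratified CV folds; lowered to the smaller class size,
        refusing to validate below 3.
    max_ortho : int, default=5
    auto_tol : float, default=0.01
    random_state : int or None
        Seeds the CV fold shuffling used by "auto" selection.

    Attributes
    ----------
    w_ : ndarray (n_features,)  unit-norm predictive weights
    t_ : ndarray (n_samples,)   predictive scores (after orthogonal deflation)
    p_ : ndarray (n_features,)  predictive loadings
    c_ : float                  y-loading
    W_o_, T_o_, P_o_ : ndarrays orthogonal weights / scores / loadings
    n_ortho_ : int              orthogonal components actually extracted
    r2y_ : float                fraction of coded-y variance explained
    classes_ : ndarray          the two labels, mapped to (-1, +1) in order
    x_mean_, x_scale_ : stored preprocessing state
    """

    def __init__(self, n_ortho="auto", scale="pareto", n_folds=10,
                 max_ortho=5, auto_tol=0.01, random_state=None):
        self.n_ortho = n_ortho
        self.scale = scale
        self.n_folds = n_folds
        self.max_ortho = max_ortho
        self.auto_tol = auto_tol
        self.random_state = random_state

    # -- core NIPALS ---------------------------------------------------

    @staticmethod
    def _decompose(Xc: np.ndarray, yc: np.ndarray, n_ortho: int):
        """Extract n_ortho orthogonal components, then one predictive component.

        Returns (w, t, p, c, W_o, T_o, P_o, n_extracted). Xc and yc must be
        centered. Truncates (with a warning) when the residual rank runs out.
        """
        X = Xc.copy()
        n, d = X.shape
        W_o, T_o, P_o = [], [], []
        for _ in range(n_ortho):
            w = X.T @ yc
            nw = np.linalg.norm(w)
            if nw < _EPS:
                warnings.warn("orthogonal extraction stopped early: residual X "
                              "is uncorrelated with y", stacklevel=2)
                break
            w /= nw
            t = X @ w
            tt = t @ t
            if tt < _EPS:
                break
            p = X.T @ t / tt
            w_o = p - (w @ p) * w
            n_wo = np.linalg.norm(w_o)
            if n_wo < _EPS:
                warnings.warn("requested orthogonal components exceed the "
                              "structured rank of X; truncating", stacklevel=2)
                break
            w_o /= n_wo
            t_o = X @ w_o
            tt_o = t_o @ t_o
            if tt_o < _EPS:
                break
            p_o = X.T @ t_o / tt_o
            X = X - np.outer(t_o, p_o)
            W_o.append(w_o)
            T_o.append(t_o)
            P_o.append(p_o)

        w = X.T @ yc
        nw = np.linalg.norm(w)
        if nw < _EPS:
            # X carries no y-covariance (e.g. constant X): degenerate model
            w = np.zeros(d)
            t = np.zeros(n)
            p = np.zeros(d)
            c = 0.0
        else:
            w /= nw
            t = X @ w
            tt = t @ t
            p = X.T @ t / tt if tt > _EPS else np.zeros(d)
            c = (yc @ t / tt) if tt > _EPS else 0.0
        return (w, t, p, float(c),
                np.column_stack(W_o) if W_o else np.zeros((d, 0)),
                np.column_stack(T_o) if T_o else np.zeros((n, 0)),
                np.column_stack(P_o) if P_o else np.zeros((d, 0)),
                len(W_o))

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        coded, classes = _code_y(y)
        counts = [(coded == v).sum() for v in (-1, 1)]
        if min(counts) < 2:
            raise ValueError("each class needs at least 2 samples")

        Xs, means, scales = _scale_matrix(X, self.scale)
        y_mean = coded.mean()
        yc = coded - y_mean

        if self.n_ortho == "auto":
            n_ortho = self._select_n_ortho(X, y, coded)
        else:
            n_ortho = int(self.n_ortho)
            if n_ortho < 0:
                raise ValueError("n_ortho must be >= 0")

        (self.w_, self.t_, self.p_, self.c_,
         self.W_o_, self.T_o_, self.P_o_, self.n_ortho_) = self._decompose(Xs, yc, n_ortho)

        fitted = self.t_ * self.c_
        tss = yc @ yc
        self.r2y_ = float(1.0 - ((yc - fitted) @ (yc - fitted)) / tss) if tss > 0 else 0.0
        self.classes_ = classes
        self.x_mean_ = means
        self.x_scale_ = scales
        self.y_mean_ = float(y_mean)
        self.n_features_in_ = X.shape[1]
        return self

    def _select_n_ortho(self, X, y, coded) -> int:
        smaller = min((coded == -1).sum(), (coded == 1).sum())
        folds = min(self.n_folds, smaller)
        if folds < 3:
            return 1  # too few samples to tune; canonical single filter
        best_q2 = cross_validate(X, y, n_folds=folds, n_ortho=0, scale=self.scale,
                                 random_state=self.random_state)
        best = 0
        for k in range(1, self.max_ortho + 1):
            q2 = cross_validate(X, y, n_folds=folds, n_ortho=k, scale=self.scale,
                                random_state=self.random_state)
            if q2 > best_q2 + self.auto_tol:
                best_q2, best = q2, k
            else:
                break
        return best

    # -- prediction ----------------------------------------------------

    def _project(self, X):
        """Scale new data, strip orthogonal variation, return predictive scores."""
        check_is_fitted(self, "w_")
        X = np.asarray(X, dtype=float)
        Xs = (X - self.x_mean_) / self.x_scale_
        for a in range(self.n_ortho_):
            t_o = Xs @ self.W_o_[:, a]
            Xs = Xs - np.outer(t_o, self.P_o_[:, a])
        return Xs @ self.w_

    def decision_function(self, X):
        return self._project(X) * self.c_ + self.y_mean_

    def predict(self, X):
        yhat = self.decision_function(X)
        return np.where(yhat >= 0, self.classes_[1], self.classes_[0])

    def score_transform(self, X):
        """Predictive score t for new samples (the OPLS-DA score-plot axis)."""
        return self._project(X)


# ---------------------------------------------------------------------------
# functional surface


def fit_oplsda(X, y, n_ortho="auto", scale="pareto", random_state=None) -> OPLSDA:
    """Fit an :class:`OPLSDA` model and return it."""
    return OPLSDA(n_ortho=n_ortho, scale=scale, random_state=random_state).fit(X, y)


def cross_validate(X, y, n_folds: int = 10, n_ortho=1, scale="pareto",
                   random_state=None) -> float:
    """Stratified K-fold Q2 for an OPLS-DA fit.

    Q2 = 1 - PRESS/TSS with PRESS pooled over the concatenated held-out
    predictions of the coded response and TSS from the centered coded y.
    Scaling parameters are re-estimated on every training fold.
    """
    X = np.asarray(X, dtype=float)
    coded, _ = _code_y(y)
    smaller = min((coded == -1).sum(), (coded == 1).sum())
    if n_folds > smaller:
        n_folds = int(smaller)
    if n_folds < 3:
        raise ValueError("stratified CV needs the smaller class to allow >= 3 folds")

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=random_state)
    press = 0.0
    for train, test in skf.split(X, coded):
        Xtr, Xte = X[train], X[test]
        ytr = coded[train]
        Xs, means, scales = _scale_matrix(Xtr, scale)
        y_mean = ytr.mean()
        w, t, p, c, W_o, T_o, P_o, k = OPLSDA._decompose(Xs, ytr - y_mean,
                                                         0 if n_ortho is None else int(n_ortho))
        Xte_s = (Xte - means) / scales
        for a in range(k):
            t_o = Xte_s @ W_o[:, a]
            Xte_s = Xte_s - np.outer(t_o, P_o[:, a])
        yhat = Xte_s @ w * c + y_mean
        press += float(((coded[test] - yhat) ** 2).sum())
    yc = coded - coded.mean()
    tss = float(yc @ yc)
    return 1.0 - press / tss


def permutation_test(X, y, n_perm: int = 999, seed=None, n_folds: int = 10,
                     n_ortho=1, scale="pareto") -> ValidationReport:
    """Label-permutation significance of the cross-validated Q2.

    The class labels are shuffled uniformly ``n_perm`` times; Q2 is recomputed
    for each shuffle with the same fold scheme, and the add-one rule gives
    p = (b + 1) / (n_perm + 1) where b counts permuted Q2 >= the observed Q2,
    so p can never reach 0.
    """
    if n_perm < 19:
        raise ValueError("n_perm must be >= 19 for a meaningful test")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    cv_seed = int(rng.integers(2**31 - 1))

    coded, _ = _code_y(y)
    smaller = min((coded == -1).sum(), (coded == 1).sum())
    folds = min(n_folds, int(smaller))
    q2_obs = cross_validate(X, y, n_folds=folds, n_ortho=n_ortho, scale=scale,
                            random_state=cv_seed)
    b = 0
    for _ in range(n_perm):
        y_perm = rng.permutation(y)
        if len(np.unique(y_perm)) < 2:  # cannot happen with 2 real classes
            continue
        try:
            q2p = cross_validate(X, y_perm, n_folds=folds, n_ortho=n_ortho,
                                 scale=scale, random_state=cv_seed)
        except ValueError:
            q2p = -np.inf
        if q2p >= q2_obs:
            b += 1
    p = (b + 1) / (n_perm + 1)

    model = OPLSDA(n_ortho=n_ortho, scale=scale).fit(X, y)
    return ValidationReport(q2=float(q2_obs), r2y=model.r2y_, p_perm=float(p),
                            n_perm=int(n_perm), n_folds=int(folds))


def vip_scores(model: OPLSDA) -> np.ndarray:
    """VIP over the predictive component (discriminatory VIP).

    VIP_j = sqrt(d * SS_Y * (w_j/||w||)^2 / SS_Y) = sqrt(d) * |w_j| for the
    single predictive component with unit-norm w, so mean(VIP^2) = 1 exactly.
    """
    check_is_fitted(model, "w_")
    w = model.w_
    d = w.size
    nw = np.linalg.norm(w)
    if nw < _EPS:
        return np.zeros(d)
    return np.sqrt(d) * np.abs(w) / nw


def s_plot(model: OPLSDA, X) -> tuple[np.ndarray, np.ndarray]:
    """S-plot coordinates: per-feature covariance and correlation with t.

    ``X`` is given in the model's input space; the stored scaling is applied
    so the coordinates refer to the (scaled) training matrix. Features with
    zero variance get correlation 0 by convention.
    """
    check_is_fitted(model, "t_")
    X = np.asarray(X, dtype=float)
    Xs = (X - model.x_mean_) / model.x_scale_
    t = model.t_
    n = len(t)
    tc = t - t.mean()
    Xc = Xs - Xs.mean(axis=0)
    cov = Xc.T @ tc / (n - 1)
    sd_t = tc.std(ddof=1)
    sd_x = Xc.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = cov / (sd_t * sd_x)
    corr = np.where((sd_x < _EPS) | (sd_t < _EPS), 0.0, corr)
    return cov, np.clip(corr, -1.0, 1.0)


def select_markers(feature_ids, vips, adj_pvalues, s_coords, d_stats,
                   vip_threshold: float = 1.0, alpha: float = 0.05) -> list[MarkerRecord]:
    """Assemble per-feature marker records, sorted by descending VIP.

    A feature is significant iff VIP strictly exceeds ``vip_threshold`` and
    its adjusted p is strictly below ``alpha``.
    """
    vips = np.asarray(vips, dtype=float)
    adj_pvalues = np.asarray(adj_pvalues, dtype=float)
    s_cov, s_corr = s_coords
    d_vals, d_cats = d_stats
    lengths = {len(feature_ids), len(vips), len(adj_pvalues),
               len(s_cov), len(s_corr), len(d_vals), len(d_cats)}
    if len(lengths) != 1:
        raise ValueError(f"marker inputs have mismatched lengths: {sorted(lengths)}")
    records = [
        MarkerRecord(
            feature_id=fid, vip=float(v), p_adj=float(p),
            s_cov=float(sc), s_corr=float(sr),
            cohens_d=float(dv), d_category=dc,
            significant=bool(v > vip_threshold and p < alpha),
        )
        for fid, v, p, sc, sr, dv, dc
        in zip(feature_ids, vips, adj_pvalues, s_cov, s_corr, d_vals, d_cats)
    ]
    records.sort(key=lambda r: -r.vip)
    return records
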