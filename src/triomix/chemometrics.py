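"""Multivariate metabolomics core, implemented from first principles.

Everything here operates on an ``X`` of shape (samples, features) — the
chemometrics convention — while :class:`~triomix.io.OmicsMatrix` stores
features as rows; :func:`preprocess` bridges the two.

The discriminant machinery is the classic two-class OPLS-DA: the class
vector y is coded -1/+1 and centered, X-variation orthogonal to y is
stripped off component by component (Trygg-Wold orthogonal signal
correction), and a single predictive PLS component is fitted on the
filtered matrix. Variable influence is summarized by VIP scores computed
from the predictive component(s) only, normalized so that the mean squared
VIP equals one.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .io import OmicsMatrix, TriomixError

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PreprocessSpec:
    """Metabolite-table preprocessing recipe.

    imputation: ``halfmin`` (half the feature's observed minimum) or ``none``.
    normalization: ``sum`` (equal sample totals on the linear scale) or ``none``.
    scaling: ``uv`` (unit variance), ``pareto`` (divide by sqrt(sd)) or ``none``.
    centering: subtract the feature mean (default on).
    """

    imputation: str = "halfmin"
    normalization: str = "none"
    scaling: str = "pareto"
    centering: bool = True

    def __post_init__(self) -> None:
        if self.imputation not in ("halfmin", "none"):
            raise TriomixError(f"unknown imputation {self.imputation!r}")
        if self.normalization not in ("sum", "none"):
            raise TriomixError(f"unknown normalization {self.normalization!r}")
        if self.scaling not in ("uv", "pareto", "none"):
            raise TriomixError(f"unknown scaling {self.scaling!r}")


def preprocess(matrix: OmicsMatrix, spec: PreprocessSpec | None = None) -> OmicsMatrix:
    """Impute, normalize, scale and center a (metabolite) matrix feature-wise."""
    spec = spec or PreprocessSpec()
    X = matrix.values.copy()
    if spec.imputation == "halfmin":
        all_missing = np.all(np.isnan(X), axis=1)
        if all_missing.any():
            fid = matrix.feature_ids[int(np.argmax(all_missing))]
            raise TriomixError(f"feature {fid!r} is entirely missing; cannot impute")
        mins = np.nanmin(X, axis=1)
        rows, cols = np.where(np.isnan(X))
        X[rows, cols] = mins[rows] / 2.0
    elif np.isnan(X).any():
        raise TriomixError("missing values present and imputation='none'")
    if spec.normalization == "sum":
        linear = np.power(2.0, X)
        totals = linear.sum(axis=0)
        if np.any(totals <= 0):
            raise TriomixError("non-positive sample total during sum normalization")
        linear = linear * (totals.mean() / totals)[None, :]
        X = np.log2(linear)
    if spec.scaling != "none":
        sd = np.std(X, axis=1, ddof=1)
        if np.any(sd == 0):
            fid = matrix.feature_ids[int(np.argmax(sd == 0))]
            raise TriomixError(f"feature {fid!r} has zero variance; cannot scale")
        denom = sd if spec.scaling == "uv" else np.sqrt(sd)
        X = X / denom[:, None]
    if spec.centering:
        X = X - X.mean(axis=1)[:, None]
    return dataclasses.replace(matrix, values=X, allow_missing=False)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PcaModel:
    scores: np.ndarray        # (n, A)
    loadings: np.ndarray      # (J, A), orthonormal columns
    explained: np.ndarray     # fraction of total variance per component
    mean: np.ndarray          # (J,) training mean


def pca(X: np.ndarray, n_comp: int) -> PcaModel:
    """PCA via SVD with a deterministic sign convention.

    Each loading's largest-magnitude element is made positive (scores flip
    along). ``X`` is (samples, features); centering is applied internally.
    """
    X = np.asarray(X, float)
    n, J = X.shape
    if n_comp > min(n, J):
        raise TriomixError(f"n_comp={n_comp} exceeds min(shape)={min(n, J)}")
    mean = X.mean(axis=0)
    Xc = X - mean
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    scores = U[:, :n_comp] * S[:n_comp]
    loadings = Vt[:n_comp].T
    total = float(np.sum(S**2))
    explained = (S[:n_comp] ** 2) / total if total > 0 else np.zeros(n_comp)
    for a in range(n_comp):
        j = int(np.argmax(np.abs(loadings[:, a])))
        if loadings[j, a] < 0:
            loadings[:, a] *= -1
            scores[:, a] *= -1
    return PcaModel(scores=scores, loadings=loadings, explained=explained, mean=mean)


# ---------------------------------------------------------------------------
# PLS1 (NIPALS) and O-PLS
# ---------------------------------------------------------------------------

def _center_scale(X, y, scale):
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    x_mean = X.mean(axis=0)
    if scale == "uv":
        x_scale = X.std(axis=0, ddof=1)
    elif scale == "pareto":
        x_scale = np.sqrt(X.std(axis=0, ddof=1))
    elif scale is None or scale == "none":
        x_scale = np.ones(X.shape[1])
    else:
        raise TriomixError(f"unknown scale {scale!r}")
    if np.any(x_scale == 0):
        raise TriomixError("zero-variance column; cannot scale")
    y_mean = y.mean()
    return (X - x_mean) / x_scale, y - y_mean, x_mean, x_scale, y_mean


def _fix_sign(w):
    """Return +1/-1 so that w's largest-magnitude element is positive."""
    j = int(np.argmax(np.abs(w)))
    return 1.0 if w[j] >= 0 else -1.0


@dataclass
class PlsModel:
    """Single-y NIPALS PLS with A components on centered/scaled data."""

    W: np.ndarray            # (J, A) x-weights, unit norm columns
    T: np.ndarray            # (n, A) x-scores
    P: np.ndarray            # (J, A) x-loadings
    q: np.ndarray            # (A,) y-loadings
    ssy: np.ndarray          # (A,) sum of squared y explained per component
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    fitted: np.ndarray       # (n,) on the original y scale
    r2y: float
    r2x: float

    @property
    def n_components(self) -> int:
        return self.W.shape[1]

    def predict(self, Xnew: np.ndarray) -> np.ndarray:
        Xc = (np.asarray(Xnew, float) - self.x_mean) / self.x_scale
        yhat = np.zeros(Xc.shape[0])
        for a in range(self.n_components):
            t = Xc @ self.W[:, a]
            yhat += t * self.q[a]
            Xc = Xc - np.outer(t, self.P[:, a])
        return yhat + self.y_mean


def pls1(X: np.ndarray, y: np.ndarray, n_comp: int, scale: str | None = None) -> PlsModel:
    """NIPALS PLS regression with a single response.

    Per component: w = X'y/||X'y||, t = Xw, p = X't/(t't), q = y't/(t't),
    then X and y are deflated. Centering (and optional scaling) happens
    internally and is stored for projection of new samples.
    """
    Xc, yc, x_mean, x_scale, y_mean = _center_scale(X, y, scale)
    n, J = Xc.shape
    if n_comp < 1 or n_comp > min(n - 1, J):
        raise TriomixError(f"n_comp={n_comp} out of range for shape {Xc.shape}")
    ssy_total = float(yc @ yc)
    ssx_total = float(np.sum(Xc**2))
    W = np.zeros((J, n_comp))
    T = np.zeros((n, n_comp))
    P = np.zeros((J, n_comp))
    q = np.zeros(n_comp)
    ssy = np.zeros(n_comp)
    Xd, yd = Xc.copy(), yc.copy()
    for a in range(n_comp):
        w = Xd.T @ yd
        nw = np.linalg.norm(w)
        if nw < 1e-14:
            raise TriomixError("X carries no covariance with y; cannot extract component")
        w /= nw
        s = _fix_sign(w)
        w *= s
        t = Xd @ w
        tt = float(t @ t)
        p = Xd.T @ t / tt
        qa = float(yd @ t) / tt
        Xd = Xd - np.outer(t, p)
        yd = yd - qa * t
        W[:, a], T[:, a], P[:, a], q[a] = w, t, p, qa
        ssy[a] = qa**2 * tt
    fitted = T @ q + y_mean
    resid = yc - T @ q
    r2y = 1.0 - float(resid @ resid) / ssy_total if ssy_total > 0 else 0.0
    r2x = 1.0 - float(np.sum(Xd**2)) / ssx_total if ssx_total > 0 else 0.0
    return PlsModel(W, T, P, q, ssy, x_mean, x_scale, y_mean, fitted, r2y, r2x)


@dataclass
class OplsModel:
    """Two-class OPLS(-DA): orthogonal filter plus one predictive component."""

    w_pred: np.ndarray       # (J,) unit-norm predictive weight
    t_pred: np.ndarray       # (n,)
    p_pred: np.ndarray       # (J,)
    q: float
    W_o: np.ndarray          # (J, k) orthogonal weights (unit norm, ⟂ w_pred)
    T_o: np.ndarray          # (n, k) orthogonal scores
    P_o: np.ndarray          # (J, k)
    n_ortho: int             # orthogonal components actually kept
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    fitted: np.ndarray
    ssy: np.ndarray          # (1,) SSY explained by the predictive component
    r2y: float
    r2x: float

    def predict(self, Xnew: np.ndarray) -> np.ndarray:
        Xc = (np.asarray(Xnew, float) - self.x_mean) / self.x_scale
        for k in range(self.n_ortho):
            t_o = Xc @ self.W_o[:, k]
            Xc = Xc - np.outer(t_o, self.P_o[:, k])
        t = Xc @ self.w_pred
        return t * self.q + self.y_mean


def opls(X: np.ndarray, y: np.ndarray, n_ortho: int, scale: str | None = None) -> OplsModel:
    """Trygg-Wold O-PLS with a single predictive component.

    The predictive weight w ∝ X'y is computed, then up to ``n_ortho``
    orthogonal components (p minus its projection on w, normalized) are
    stripped from X before the final one-component PLS fit. With
    ``n_ortho=0`` the result reproduces ``pls1(X, y, 1)`` exactly. If no
    orthogonal variation remains (||w_o|| < 1e-12) extraction stops early
    and the model records fewer orthogonal components.
    """
    if n_ortho < 0:
        raise TriomixError("n_ortho must be >= 0")
    Xc, yc, x_mean, x_scale, y_mean = _center_scale(X, y, scale)
    n, J = Xc.shape
    ssx_total = float(np.sum(Xc**2))
    ssy_total = float(yc @ yc)
    W_o, T_o, P_o = [], [], []
    Xd = Xc.copy()
    for _ in range(n_ortho):
        w = Xd.T @ yc
        nw = np.linalg.norm(w)
        if nw < 1e-14:
            raise TriomixError("X carries no covariance with y")
        w /= nw
        t = Xd @ w
        tt = float(t @ t)
        p = Xd.T @ t / tt
        w_o = p - float(w @ p) * w
        n_wo = np.linalg.norm(w_o)
        if n_wo < 1e-12:
            log.info("no orthogonal variation left; stopping at %d orthogonal components", len(W_o))
            break
        w_o /= n_wo
        w_o *= _fix_sign(w_o)
        t_o = Xd @ w_o
        p_o = Xd.T @ t_o / float(t_o @ t_o)
        Xd = Xd - np.outer(t_o, p_o)
        W_o.append(w_o)
        T_o.append(t_o)
        P_o.append(p_o)
    k = len(W_o)
    W_o = np.column_stack(W_o) if k else np.zeros((J, 0))
    T_o = np.column_stack(T_o) if k else np.zeros((n, 0))
    P_o = np.column_stack(P_o) if k else np.zeros((J, 0))
    # predictive component on the filtered matrix
    w = Xd.T @ yc
    w /= np.linalg.norm(w)
    w *= _fix_sign(w)
    t = Xd @ w
    tt = float(t @ t)
    p = Xd.T @ t / tt
    q = float(yc @ t) / tt
    fitted = t * q + y_mean
    resid = yc - t * q
    r2y = 1.0 - float(resid @ resid) / ssy_total if ssy_total > 0 else 0.0
    Xresid = Xd - np.outer(t, p)
    r2x = 1.0 - float(np.sum(Xresid**2)) / ssx_total if ssx_total > 0 else 0.0
    return OplsModel(
        w_pred=w, t_pred=t, p_pred=p, q=q, W_o=W_o, T_o=T_o, P_o=P_o, n_ortho=k,
        x_mean=x_mean, x_scale=x_scale, y_mean=y_mean, fitted=fitted,
        ssy=np.array([q**2 * tt]), r2y=r2y, r2x=r2x,
    )


# ---------------------------------------------------------------------------
# VIP, cross-validated Q2, selection
# ---------------------------------------------------------------------------

def vip(model: PlsModel | OplsModel) -> np.ndarray:
    """Variable importance in the projection, predictive components only.

    VIP_j = sqrt( J * Σ_a SSY_a (w_ja/||w_a||)^2 / Σ_a SSY_a ); the
    normalization guarantees Σ_j VIP_j^2 = J.
    """
    if isinstance(model, OplsModel):
        W = model.w_pred[:, None]
        ssy = model.ssy
    else:
        W = model.W
        ssy = model.ssy
    J = W.shape[0]
    wn = W / np.linalg.norm(W, axis=0, keepdims=True)
    total = float(ssy.sum())
    if total <= 0:
        raise TriomixError("model explains no y variance; VIP undefined")
    return np.sqrt(J * (wn**2 @ ssy) / total)


def q2_cv(
    X: np.ndarray,
    y: np.ndarray,
    n_ortho: int = 1,
    folds: int = 7,
    seed: int = 0,
    scale: str | None = None,
) -> float:
    """Cross-validated Q2 = 1 - PRESS/SSY for the OPLS model.

    Fold assignment is stratified by class and seeded; the fold count is
    capped at the smallest class size (each training split must contain
    both classes).
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    if folds < 2:
        raise TriomixError("folds must be >= 2")
    labels = (y > np.mean(y)).astype(int)
    smallest = int(min(np.bincount(labels)))
    if folds > smallest:
        log.info("capping cv folds at smallest class size %d (requested %d)", smallest, folds)
        folds = smallest
    splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    press = 0.0
    for train, test in splitter.split(X, labels):
        model = opls(X[train], y[train], n_ortho=n_ortho, scale=scale)
        yhat = model.predict(X[test])
        press += float(np.sum((y[test] - yhat) ** 2))
    ssy_total = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - press / ssy_total


def select_by_vip(
    vip_scores: np.ndarray, feature_ids: list[str], threshold: float
) -> list[str]:
    """Feature ids with VIP strictly above ``threshold``, ranked by VIP
    descending (ties by id)."""
    if threshold <= 0:
        raise TriomixError("threshold must be > 0")
    pairs = [
        (float(v), str(f)) for v, f in zip(vip_scores, feature_ids) if v > threshold
    ]
    pairs.sort(key=lambda vf: (-vf[0], vf[1]))
    return [f for _, f in pairs]


def class_vector(
    sample_ids: list[str], group_of: dict[str, str], group_a: str, group_b: str
) -> np.ndarray:
    """Code a two-group design as -1 (group_a) / +1 (group_b)."""
    y = np.empty(len(sample_ids))
    for i, s in enumerate(sample_ids):
        g = group_of[s]
        if g == group_a:
            y[i] = -1.0
        elif g == group_b:
            y[i] = 1.0
        else:
            raise TriomixError(f"sample {s!r} belongs to neither contrast group")
    return y
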