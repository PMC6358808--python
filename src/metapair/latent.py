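"""Multilevel (within-pair) latent-variable models: PCA and PLS-DA.

For matched designs the between-pair variation is nuisance; the multilevel
decomposition replaces each sample by its deviation from its pair mean so
latent-variable models act on within-pair differences only.  Both PCA and
the PLS-DA classifier are computed with NIPALS (power-iteration deflation),
after unit-variance scaling whose statistics are fit on the training
partition and re-applied, never refit, to test samples.

PLS-DA is PLS1 regression on a centered 0/1 class label.  Variable
importance in projection (VIP) scores summarize each variable's
contribution across components; their mean square is identically 1, so
VIP > 1 marks above-average contribution to the discrimination.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

NIPALS_TOL = 1e-12
# power iteration converges linearly at the eigenvalue ratio; close leading
# eigenvalues need far more than a few hundred sweeps at this tolerance
NIPALS_MAX_ITER = 20000


class ModelError(ValueError):
    """Latent model cannot be fitted or applied."""


# ---------------------------------------------------------------------------
# within-pair (multilevel) decomposition
# ---------------------------------------------------------------------------

def within_pair_transform(values: np.ndarray, pair_ids) -> np.ndarray:
    """Deviation of each sample from its pair mean.

    For two-member pairs with values (a, b) this yields
    ((a - b) / 2, (b - a) / 2).  Every pair must be complete (at least two
    members); per-pair column means of the output are exactly zero.
    """
    X = np.asarray(values, float)
    pair_ids = np.asarray(pair_ids)
    if len(pair_ids) != X.shape[0]:
        raise ModelError("one pair id per row is required")
    out = np.empty_like(X)
    for pid in np.unique(pair_ids):
        idx = np.flatnonzero(pair_ids == pid)
        if len(idx) < 2:
            raise ModelError(f"incomplete pair {pid!r}")
        if len(idx) == 2:
            # antisymmetric form keeps the pair sum exactly zero
            half = (X[idx[0]] - X[idx[1]]) / 2.0
            out[idx[0]], out[idx[1]] = half, -half
        else:
            out[idx] = X[idx] - X[idx].mean(axis=0)
    return out


# ---------------------------------------------------------------------------
# unit-variance scaling
# ---------------------------------------------------------------------------

@dataclass
class ScaledMatrix:
    """Autoscaled training block plus the statistics to transform new data."""

    values: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    kept: np.ndarray  # boolean mask over original columns (sd > 0)

    def apply(self, new: np.ndarray) -> np.ndarray:
        """Transform new samples with the *training* statistics."""
        new = np.asarray(new, float)
        if new.shape[1] != self.kept.size:
            raise ModelError(
                f"expected {self.kept.size} columns, got {new.shape[1]}")
        return (new[:, self.kept] - self.mean) / self.sd


def autoscale(
    train: np.ndarray, test: np.ndarray | None = None
) -> tuple[ScaledMatrix, np.ndarray | None]:
    """Center and scale columns to unit variance (n-1 denominator).

    Statistics come from ``train`` only; ``test`` is transformed with them.
    Zero-variance training columns are dropped with a warning.
    """
    X = np.asarray(train, float)
    if X.shape[0] < 2:
        raise ModelError("need at least 2 training rows to estimate variance")
    sd = X.std(axis=0, ddof=1)
    kept = sd > 0
    if not kept.all():
        warnings.warn(f"dropping {int((~kept).sum())} zero-variance columns",
                      stacklevel=2)
    if not kept.any():
        raise ModelError("all columns have zero variance")
    mean = X[:, kept].mean(axis=0)
    scaled = ScaledMatrix(
        values=(X[:, kept] - mean) / sd[kept], mean=mean, sd=sd[kept], kept=kept)
    return scaled, (scaled.apply(test) if test is not None else None)


# ---------------------------------------------------------------------------
# NIPALS PCA + Hotelling T2 screening
# ---------------------------------------------------------------------------

@dataclass
class PCAModel:
    scores: np.ndarray        # samples x components
    loadings: np.ndarray      # variables x components, orthonormal columns
    explained: np.ndarray     # fraction of total variance per component


def pca_nipals(X: np.ndarray, n_components: int) -> PCAModel:
    """Principal components by NIPALS on a centered matrix.

    Components are extracted one at a time by power iteration with
    deflation; sign convention fixes the largest-magnitude loading element
    positive.  Raises on non-convergence.
    """
    X = np.asarray(X, float).copy()
    n, p = X.shape
    if n_components > min(n - 1, p):
        raise ModelError("n_components exceeds min(rows - 1, columns)")
    total_ss = float((X ** 2).sum())
    if total_ss == 0:
        raise ModelError("zero matrix has no principal components")
    T = np.zeros((n, n_components))
    P = np.zeros((p, n_components))
    explained = np.zeros(n_components)
    for a in range(n_components):
        t = X[:, int(np.argmax((X ** 2).sum(axis=0)))].copy()
        for _ in range(NIPALS_MAX_ITER):
            pvec = X.T @ t / (t @ t)
            pvec /= np.linalg.norm(pvec)
            t_new = X @ pvec
            if np.linalg.norm(t_new - t) <= NIPALS_TOL * np.linalg.norm(t_new):
                t = t_new
                break
            t = t_new
        else:
            raise ModelError(f"NIPALS did not converge for component {a + 1}")
        j = int(np.argmax(np.abs(pvec)))
        if pvec[j] < 0:
            pvec, t = -pvec, -t
        T[:, a], P[:, a] = t, pvec
        explained[a] = float(t @ t) / total_ss
        X -= np.outer(t, pvec)
    return PCAModel(scores=T, loadings=P, explained=explained)


def hotelling_t2(
    model: PCAModel, alpha: float = 0.95
) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample Hotelling T2 in score space with F-based outlier limit.

    T2_i = sum_a t_ia^2 / var(t_a); the control limit is
    ``A (n-1) / (n - A) * F_{1-alpha... }`` evaluated at probability
    ``alpha`` of the F(A, n - A) distribution.  Returns (t2, flags).
    """
    T = model.scores
    n, A = T.shape
    if A < 2 or n < 3:
        raise ModelError("need >= 2 components and >= 3 samples")
    var = T.var(axis=0, ddof=1)
    if np.any(var <= 0):
        raise ModelError("degenerate (zero-variance) score column")
    t2 = ((T ** 2) / var).sum(axis=1)
    limit = A * (n - 1) / (n - A) * stats.f.ppf(alpha, A, n - A)
    return t2, t2 > limit


# ---------------------------------------------------------------------------
# NIPALS PLS1 discriminant model
# ---------------------------------------------------------------------------

@dataclass
class PLSModel:
    """NIPALS PLS1 discriminant model on a centered 0/1 response.

    ``weights`` (W) have unit-norm columns; ``scores`` (T) columns are
    orthogonal; ``ssy`` holds the response sum of squares explained per
    component, used for VIP weighting.  ``coef`` maps (scaled) X directly
    to the predicted response: y_hat = X @ coef + intercept.
    """

    weights: np.ndarray      # variables x components (W)
    x_loadings: np.ndarray   # variables x components (P)
    scores: np.ndarray       # samples x components (T)
    y_loadings: np.ndarray   # components (q)
    coef: np.ndarray         # variables
    intercept: float
    ssy: np.ndarray          # explained y sum of squares per component
    vip: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.vip is None:
            self.vip = vip(self)

    @property
    def n_components(self) -> int:
        return self.weights.shape[1]

    def to_json(self, path: str | Path, scaler: ScaledMatrix | None = None) -> None:
        obj = {
            "weights": self.weights.tolist(),
            "x_loadings": self.x_loadings.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "coef": self.coef.tolist(),
            "intercept": self.intercept,
            "ssy": self.ssy.tolist(),
            "vip": self.vip.tolist(),
        }
        if scaler is not None:
            obj["scaling"] = {"mean": scaler.mean.tolist(),
                              "sd": scaler.sd.tolist(),
                              "kept": scaler.kept.tolist()}
        Path(path).write_text(json.dumps(obj))


def plsda_fit(X: np.ndarray, y: np.ndarray, n_components: int = 2) -> PLSModel:
    """Fit PLS1 on dummy-coded class labels.

    ``X`` must already be scaled (columns centered); ``y`` is a binary 0/1
    vector containing both classes and is centered internally.  For a
    single response NIPALS components are closed-form: w_a = X'y / |X'y|.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    if X.shape[0] != y.size:
        raise ModelError("X rows and y length differ")
    if len(np.unique(y)) < 2:
        raise ModelError("both classes must be present in y")
    if n_components < 1:
        raise ModelError("n_components must be >= 1")
    y_mean = float(y.mean())
    Xa = X.copy()
    ya = y - y_mean
    n, p = X.shape
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    T = np.zeros((n, n_components))
    q = np.zeros(n_components)
    ssy = np.zeros(n_components)
    for a in range(n_components):
        w = Xa.T @ ya
        nw = np.linalg.norm(w)
        if nw <= NIPALS_TOL:
            raise ModelError(
                f"no covariance left for component {a + 1}; reduce n_components")
        w /= nw
        t = Xa @ w
        tt = float(t @ t)
        if tt <= NIPALS_TOL:
            raise ModelError(f"degenerate score for component {a + 1}")
        pvec = Xa.T @ t / tt
        qa = float(ya @ t) / tt
        Xa = Xa - np.outer(t, pvec)
        ya = ya - qa * t
        W[:, a], P[:, a], T[:, a], q[a] = w, pvec, t, qa
        ssy[a] = qa ** 2 * tt
    # regression vector in terms of the original (scaled) X
    R = W @ np.linalg.pinv(P.T @ W)
    coef = R @ q
    return PLSModel(weights=W, x_loadings=P, scores=T, y_loadings=q,
                    coef=coef, intercept=y_mean, ssy=ssy)


def plsda_predict(model: PLSModel, X_new: np.ndarray) -> np.ndarray:
    """Continuous predicted response for new (already scaled) samples."""
    X_new = np.asarray(X_new, float)
    if X_new.ndim != 2 or X_new.shape[1] != model.coef.size:
        raise ModelError(
            f"expected {model.coef.size} columns, got {X_new.shape}")
    return X_new @ model.coef + model.intercept


def vip(model: PLSModel) -> np.ndarray:
    """Variable importance in projection.

    VIP_j = sqrt( p * sum_a SSY_a w_aj^2 / sum_a SSY_a ) with p variables
    and unit-norm weight columns, so mean(VIP^2) = 1 identically.
    """
    total = float(model.ssy.sum())
    if total <= 0:
        raise ModelError("zero explained response variance; VIP undefined")
    p = model.weights.shape[0]
    contrib = (model.weights ** 2) @ model.ssy
    return np.sqrt(p * contrib / total)


def scores_table(model: PLSModel, index=None) -> pd.DataFrame:
    cols = [f"t{a + 1}" for a in range(model.n_components)]
    return pd.DataFrame(model.scores, columns=cols, index=index)
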