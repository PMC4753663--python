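"""Single-response partial least squares regression (NIPALS) with VIP.

Fits one latent-variable model per response on autoscaled data
(mean-centered, unit variance with ddof=1), reports R2X / R2Y /
cross-validated Q2, autoscaled regression coefficients, and Wold's
variable importance in projection:

    VIP_j = sqrt( p * sum_a SS_a (w_aj / ||w_a||)^2 / sum_a SS_a )

where SS_a is the response sum of squares explained by component a.
The sign of each weight vector is fixed so its largest-magnitude element
is positive (NIPALS sign ambiguity); predictions are sign-invariant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["PLSModel", "fit_pls", "cross_validate", "vip", "coefficients"]

_RANK_TOL = 1e-12


@dataclass
class PLSModel:
    """A fitted single-response PLS model on autoscaled data."""

    n_components: int
    weights: np.ndarray      # W, p x A
    x_loadings: np.ndarray   # P, p x A
    x_scores: np.ndarray     # T, n x A
    y_loadings: np.ndarray   # q, A
    ss_y: np.ndarray         # per-component explained Y sum of squares (scaled metric)
    r2x: float
    r2y: float
    x_mean: np.ndarray
    x_std: np.ndarray
    y_mean: float
    y_std: float
    columns: list[str] = field(default_factory=list)
    q2: float | None = None

    @property
    def coef_(self) -> np.ndarray:
        """Regression coefficients for autoscaled X and y."""
        return coefficients(self)

    def transform_x(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return (X - self.x_mean) / self.x_std

    def predict(self, X) -> np.ndarray:
        """Predict the response on the original (unscaled) metric."""
        y_scaled = self.transform_x(X) @ self.coef_
        return y_scaled * self.y_std + self.y_mean

    def summary(self) -> dict:
        out = {
            "n_components": int(self.n_components),
            "r2x": float(self.r2x),
            "r2y": float(self.r2y),
        }
        if self.q2 is not None:
            out["q2"] = float(self.q2)
        return out


def _autoscale(X: np.ndarray, y: np.ndarray):
    x_mean = X.mean(axis=0)
    x_std = X.std(axis=0, ddof=1)
    if np.any(x_std <= 0):
        dead = np.where(x_std <= 0)[0]
        raise ValueError(
            f"constant X columns at indices {dead.tolist()}; filter them before fitting"
        )
    y_mean = float(y.mean())
    y_std = float(y.std(ddof=1))
    if y_std <= 0:
        raise ValueError("constant response: nothing to model")
    return (X - x_mean) / x_std, (y - y_mean) / y_std, x_mean, x_std, y_mean, y_std


def fit_pls(X, y, n_components: int = 2, columns: list[str] | None = None) -> PLSModel:
    """Fit a NIPALS PLS1 model of autoscaled ``y`` on autoscaled ``X``.

    With a single response the per-component weight has the closed form
    w = X'y / ||X'y|| on the deflated X. If the requested number of
    components exceeds the effective rank of X, the model is truncated
    with a warning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n < 3:
        raise ValueError("need at least 3 samples to fit PLS")
    if len(y) != n:
        raise ValueError("X and y sample counts differ")
    if np.any(~np.isfinite(X)) or np.any(~np.isfinite(y)):
        raise ValueError("X/y contain missing or non-finite values")

    Xs, ys, x_mean, x_std, y_mean, y_std = _autoscale(X, y)
    ssx_total = float(np.sum(Xs**2))
    ssy_total = float(np.sum(ys**2))

    Xd = Xs.copy()
    yd = ys.copy()
    W, P, T, Q, SS = [], [], [], [], []
    for _ in range(int(n_components)):
        cov = Xd.T @ yd
        norm = np.linalg.norm(cov)
        if norm <= _RANK_TOL * max(1.0, np.linalg.norm(Xd)):
            warnings.warn(
                f"X exhausted after {len(W)} components; truncating from {n_components}",
                RuntimeWarning,
                stacklevel=2,
            )
            break
        w = cov / norm
        # fix NIPALS sign ambiguity deterministically
        if w[np.argmax(np.abs(w))] < 0:
            w = -w
        t = Xd @ w
        tt = float(t @ t)
        if tt <= _RANK_TOL:
            warnings.warn(
                f"degenerate score at component {len(W) + 1}; truncating",
                RuntimeWarning,
                stacklevel=2,
            )
            break
        p_load = Xd.T @ t / tt
        q_load = float(yd @ t / tt)
        Xd = Xd - np.outer(t, p_load)
        yd = yd - q_load * t
        W.append(w)
        P.append(p_load)
        T.append(t)
        Q.append(q_load)
        SS.append(q_load**2 * tt)

    if not W:
        raise ValueError("X carries no covariance with y; no components fitted")

    W = np.column_stack(W)
    P = np.column_stack(P)
    T = np.column_stack(T)
    Q = np.asarray(Q)
    SS = np.asarray(SS)

    ss_res = float(np.sum(yd**2))
    r2y = 1.0 - ss_res / ssy_total
    r2x = float(np.sum((T**2).sum(axis=0) * (P**2).sum(axis=0)) / ssx_total)

    return PLSModel(
        n_components=W.shape[1],
        weights=W,
        x_loadings=P,
        x_scores=T,
        y_loadings=Q,
        ss_y=SS,
        r2x=r2x,
        r2y=r2y,
        x_mean=x_mean,
        x_std=x_std,
        y_mean=y_mean,
        y_std=y_std,
        columns=list(columns) if columns is not None else [f"x{j}" for j in range(p)],
    )


def coefficients(model: PLSModel) -> np.ndarray:
    """Autoscaled regression coefficient vector B = W (P'W)^-1 q."""
    PtW = model.x_loadings.T @ model.weights
    try:
        inv = np.linalg.inv(PtW)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise ValueError("singular P'W: collinear components") from exc
    cond = np.linalg.cond(PtW)
    if not np.isfinite(cond) or cond > 1e12:
        raise ValueError(f"ill-conditioned P'W (cond={cond:.3g}): collinearity diagnostic")
    return model.weights @ inv @ model.y_loadings


def vip(model: PLSModel) -> np.ndarray:
    """Wold's VIP score per predictor; satisfies sum_j VIP_j^2 = p."""
    ss = model.ss_y
    total = float(ss.sum())
    if total <= 0:
        raise ValueError("no explained response variance; VIP undefined")
    W = model.weights
    p = W.shape[0]
    wnorm2 = (W**2) / np.sum(W**2, axis=0, keepdims=True)
    return np.sqrt(p * (wnorm2 @ ss) / total)


def _fold_assignment(n: int, folds: int, seed: int) -> np.ndarray:
    """Deterministic interleaved fold labels on a seed-shuffled sample order."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    labels = np.empty(n, dtype=int)
    labels[order] = np.arange(n) % folds
    return labels


def cross_validate(
    X,
    y,
    max_components: int | None = None,
    folds: int = 7,
    seed: int = 0,
    min_increment: float = 0.01,
):
    """K-fold cross-validation: Q2 per component count and a chosen A.

    Q2(A) = 1 - PRESS(A) / SS_tot with PRESS summed over held-out folds on
    the original response metric; fold scaling is re-estimated on each
    training split. The component count is chosen as the last component
    whose Q2 increment is at least ``min_increment`` (at least one
    component is always kept).

    Returns
    -------
    (q2_per_components, chosen_A) where ``q2_per_components`` is a list
    indexed by A-1.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if folds < 2:
        raise ValueError("need at least 2 folds")
    if n < folds:
        raise ValueError(f"cannot split {n} samples into {folds} folds")
    if max_components is None:
        max_components = min(p, n - max(2, n // folds) - 1, 10)
        max_components = max(max_components, 1)

    labels = _fold_assignment(n, folds, seed)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot <= 0:
        raise ValueError("constant response: Q2 undefined")

    press = np.zeros(max_components)
    for f in range(folds):
        test = labels == f
        train = ~test
        if train.sum() < 3:
            raise ValueError("fold leaves fewer than 3 training samples")
        keep = np.std(X[train], axis=0, ddof=1) > 0
        if not keep.any():
            raise ValueError("all X columns constant within a training fold")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            model = fit_pls(X[train][:, keep], y[train], n_components=max_components)
        # rebuild predictions per truncated component count
        Xs_test = model.transform_x(X[test][:, keep])
        for a in range(model.n_components):
            sub = PLSModel(
                n_components=a + 1,
                weights=model.weights[:, : a + 1],
                x_loadings=model.x_loadings[:, : a + 1],
                x_scores=model.x_scores[:, : a + 1],
                y_loadings=model.y_loadings[: a + 1],
                ss_y=model.ss_y[: a + 1],
                r2x=np.nan,
                r2y=np.nan,
                x_mean=model.x_mean,
                x_std=model.x_std,
                y_mean=model.y_mean,
                y_std=model.y_std,
            )
            y_hat = (Xs_test @ sub.coef_) * model.y_std + model.y_mean
            press[a] += float(np.sum((y[test] - y_hat) ** 2))
        # folds whose model truncated early reuse their deepest fit
        for a in range(model.n_components, max_components):
            y_hat = (Xs_test @ model.coef_) * model.y_std + model.y_mean
            press[a] += float(np.sum((y[test] - y_hat) ** 2))

    q2 = [1.0 - press[a] / ss_tot for a in range(max_components)]
    chosen = 1
    prev = 0.0
    for a, q in enumerate(q2, start=1):
        if q - prev >= min_increment or a == 1:
            chosen = a
            prev = q
        else:
            break
    return q2, chosen
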