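"""Sparse partial least squares (sPLS) in regression mode.

PLS finds pairs of latent variates t_h = X u_h, s_h = Y v_h maximising
cov(t_h, s_h); the sparse variant restricts the number of non-zero
entries of the weight vectors through soft-thresholding, expressed here
as a per-component cardinality budget (keepX / keepY): at each inner
iteration the weight vector is soft-thresholded with the threshold set
to the magnitude of its (keep+1)-th largest entry, so exactly ``keep``
entries survive, then renormalised to unit length.

Regression mode is asymmetric: it predicts Y from X, and both blocks are
deflated with respect to the X-variate t_h:

    X_{h+1} = X_h - t_h (t_h' X_h) / (t_h' t_h)
    Y_{h+1} = Y_h - t_h (t_h' Y_h) / (t_h' t_h)

which makes successive X-variates mutually orthogonal.  Columns of both
blocks are mean-centered and unit-variance scaled before fitting.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class SplsModel:
    """Fitted sPLS model: weights, variates and preprocessing vectors."""

    n_components: int
    x_names: list[str]
    y_names: list[str]
    x_weights: np.ndarray  # genes x H, unit columns
    y_weights: np.ndarray  # phenotypes x H, unit columns
    x_variates: np.ndarray  # samples x H
    y_variates: np.ndarray  # samples x H
    x_center: np.ndarray
    x_scale: np.ndarray
    y_center: np.ndarray
    y_scale: np.ndarray
    keep_x: list[int]
    keep_y: list[int]
    n_iter: list[int] = field(default_factory=list)
    converged: list[bool] = field(default_factory=list)
    # deflation-consistent projection: t_new = X_scaled @ rotation
    x_rotation: np.ndarray | None = None

    def save(self, path) -> None:
        payload = {
            "n_components": self.n_components,
            "x_names": self.x_names,
            "y_names": self.y_names,
            "keep_x": self.keep_x,
            "keep_y": self.keep_y,
            "n_iter": self.n_iter,
            "converged": self.converged,
        }
        for name in (
            "x_weights",
            "y_weights",
            "x_variates",
            "y_variates",
            "x_center",
            "x_scale",
            "y_center",
            "y_scale",
            "x_rotation",
        ):
            payload[name] = getattr(self, name).tolist()
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "SplsModel":
        with open(path) as fh:
            payload = json.load(fh)
        for name in (
            "x_weights",
            "y_weights",
            "x_variates",
            "y_variates",
            "x_center",
            "x_scale",
            "y_center",
            "y_scale",
            "x_rotation",
        ):
            payload[name] = np.asarray(payload[name], dtype=float)
        return cls(**payload)


def _center_scale(arr: np.ndarray, names: list[str]):
    center = arr.mean(axis=0)
    scale = arr.std(axis=0, ddof=1)
    keep = scale > 0
    if not keep.all():
        dropped = [names[i] for i in np.nonzero(~keep)[0]]
        logger.info("dropping zero-variance column(s): %s", dropped)
    return center, scale, keep


def soft_threshold_keep(a: np.ndarray, keep: int) -> np.ndarray:
    """Soft-threshold so that exactly ``keep`` entries survive (keep largest).

    The threshold is the (keep+1)-th largest |a|; survivors shrink by it.
    ``keep`` >= len(a) leaves the vector untouched (dense limit).
    """
    p = len(a)
    if keep >= p:
        return a.copy()
    if keep < 1:
        raise ValueError("keep must be >= 1")
    magnitudes = np.abs(a)
    lam = np.partition(magnitudes, p - keep - 1)[p - keep - 1]
    out = np.sign(a) * np.maximum(magnitudes - lam, 0.0)
    return out


def fit_spls(
    X,
    Y,
    n_components: int = 3,
    keep_x: int | list[int] | None = None,
    keep_y: int | list[int] | None = None,
    tol: float = 1e-9,
    max_iter: int = 500,
) -> SplsModel:
    """Fit sPLS in regression mode (predict Y from X).

    ``X`` is samples x genes, ``Y`` samples x phenotypes (DataFrames or
    arrays, row-aligned).  ``keep_x`` / ``keep_y`` give the per-component
    number of retained variables (int applies to all components; None
    keeps all).  Initialisation is the leading singular pair of X_h' Y_h;
    the weight sign is fixed so each component's largest-|u| entry is
    positive.
    """
    x_names = list(X.columns) if isinstance(X, pd.DataFrame) else [f"x{i}" for i in range(np.shape(X)[1])]
    y_names = list(Y.columns) if isinstance(Y, pd.DataFrame) else [f"y{i}" for i in range(np.shape(Y)[1])]
    Xa = np.asarray(X, dtype=float)
    Ya = np.asarray(Y, dtype=float)
    if Xa.shape[0] != Ya.shape[0]:
        raise ValueError("X and Y must have the same number of rows (samples)")
    n = Xa.shape[0]
    if np.isnan(Xa).any() or np.isnan(Ya).any():
        raise ValueError("missing values are not supported")
    if n_components > min(n - 1, Ya.shape[1]):
        raise ValueError(
            f"n_components={n_components} exceeds min(samples-1, phenotypes)"
        )

    xc, xs, xkeep = _center_scale(Xa, x_names)
    yc, ys, ykeep = _center_scale(Ya, y_names)
    x_names = [x_names[i] for i in np.nonzero(xkeep)[0]]
    y_names = [y_names[i] for i in np.nonzero(ykeep)[0]]
    Xh = (Xa[:, xkeep] - xc[xkeep]) / xs[xkeep]
    Yh = (Ya[:, ykeep] - yc[ykeep]) / ys[ykeep]
    p, q = Xh.shape[1], Yh.shape[1]

    def _budget(keep, dim) -> list[int]:
        if keep is None:
            return [dim] * n_components
        if np.isscalar(keep):
            return [min(int(keep), dim)] * n_components
        if len(keep) != n_components:
            raise ValueError("per-component keep list length must equal n_components")
        return [min(int(k), dim) for k in keep]

    keep_x_list = _budget(keep_x, p)
    keep_y_list = _budget(keep_y, q)

    U = np.zeros((p, n_components))
    V = np.zeros((q, n_components))
    T = np.zeros((n, n_components))
    S = np.zeros((n, n_components))
    loadings_c = np.zeros((p, n_components))  # X deflation loadings
    n_iters, convs = [], []

    for h in range(n_components):
        M = Xh.T @ Yh
        # leading singular pair as initialisation
        left, sing, right = np.linalg.svd(M, full_matrices=False)
        u, v = left[:, 0], right[0, :]
        delta = np.inf
        for it in range(1, max_iter + 1):
            u_new = soft_threshold_keep(M @ v, keep_x_list[h])
            norm = np.linalg.norm(u_new)
            if norm == 0:
                u_new = u
                break
            u_new /= norm
            v_new = soft_threshold_keep(M.T @ u_new, keep_y_list[h])
            vnorm = np.linalg.norm(v_new)
            if vnorm == 0:
                v_new = v
                break
            v_new /= vnorm
            delta = np.max(np.abs(u_new - u))
            u, v = u_new, v_new
            if delta < tol:
                break
        converged = delta < tol or it < max_iter
        if not converged:
            logger.warning("component %d did not converge in %d iterations", h + 1, max_iter)
        # deterministic orientation
        flip = np.sign(u[np.argmax(np.abs(u))])
        if flip < 0:
            u, v = -u, -v
        t = Xh @ u
        s = Yh @ v
        tt = float(t @ t)
        c = Xh.T @ t / tt
        Xh = Xh - np.outer(t, c)
        Yh = Yh - np.outer(t, Yh.T @ t / tt)
        U[:, h], V[:, h], T[:, h], S[:, h] = u, v, t, s
        loadings_c[:, h] = c
        n_iters.append(it)
        convs.append(bool(converged))

    # rotation giving variates directly from scaled X: R = U (C'U)^-1
    rotation = U @ np.linalg.pinv(loadings_c.T @ U)

    return SplsModel(
        n_components=n_components,
        x_names=x_names,
        y_names=y_names,
        x_weights=U,
        y_weights=V,
        x_variates=T,
        y_variates=S,
        x_center=xc[xkeep],
        x_scale=xs[xkeep],
        y_center=yc[ykeep],
        y_scale=ys[ykeep],
        keep_x=keep_x_list,
        keep_y=keep_y_list,
        n_iter=n_iters,
        converged=convs,
        x_rotation=rotation,
    )


def transform(model: SplsModel, X_new) -> np.ndarray:
    """Project new samples onto the X-variate space (deflation-consistent).

    Columns must match the training genes (order-independent when a
    DataFrame with matching column names is given).
    """
    if isinstance(X_new, pd.DataFrame):
        missing = set(model.x_names) - set(X_new.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)[:5]} ...")
        arr = X_new[model.x_names].to_numpy(dtype=float)
    else:
        arr = np.atleast_2d(np.asarray(X_new, dtype=float))
        if arr.shape[1] != len(model.x_names):
            raise ValueError(
                f"expected {len(model.x_names)} columns, got {arr.shape[1]}"
            )
    scaled = (arr - model.x_center) / model.x_scale
    return scaled @ model.x_rotation


def export_coordinates(model: SplsModel, X, Y, n_components: int | None = None):
    """Correlation-circle variable coordinates and sample scores.

    Variable coordinates are cor(column, t_h) for every X and Y column,
    per component (bounded in [-1, 1]); sample coordinates are the
    X-variate scores.
    """
    H = n_components or min(model.n_components, 3)
    Xa = np.asarray(X[model.x_names] if isinstance(X, pd.DataFrame) else X, dtype=float)
    Ya = np.asarray(Y[model.y_names] if isinstance(Y, pd.DataFrame) else Y, dtype=float)
    var_rows = []
    for names, arr in ((model.x_names, Xa), (model.y_names, Ya)):
        cors = _columns_variate_correlations(arr, model.x_variates[:, :H])
        for i, name in enumerate(names):
            var_rows.append({"variable": name, **{f"comp{h+1}": cors[i, h] for h in range(H)}})
    variables = pd.DataFrame(var_rows).set_index("variable")
    samples = pd.DataFrame(
        model.x_variates[:, :H], columns=[f"comp{h+1}" for h in range(H)]
    )
    return variables, samples


def _columns_variate_correlations(arr: np.ndarray, variates: np.ndarray) -> np.ndarray:
    """cor of each column of ``arr`` with each variate; 0 for constant columns."""
    a = arr - arr.mean(axis=0)
    t = variates - variates.mean(axis=0)
    sa = np.sqrt((a**2).sum(axis=0))
    st = np.sqrt((t**2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        cors = (a.T @ t) / np.outer(sa, st)
    return np.nan_to_num(cors, nan=0.0)
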