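"""Within-animal decomposition and multilevel latent-variable models.

A repeated-measures matrix ``X`` (N = n animals x T times rows, p features)
splits exactly into

    X = offset + between + within

where ``offset`` repeats the grand column means, ``between`` the per-animal
mean deviations (constant within animal) and ``within`` the deviations of
each observation from its own animal's mean.  PCA, PLS and sparse PLS run on
the within-animal part isolate condition (time) effects from stable
inter-individual differences — the "multilevel" versions of those methods.

Model classes follow the fit-then-results pattern: construct with data,
call :meth:`fit`, read estimates off the returned :class:`LatentResults`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import DesignError, LongitudinalMatrix, MultilevelDecomposition

__all__ = [
    "decompose",
    "PCA",
    "PLS",
    "SPLS",
    "LatentResults",
    "multilevel_pca",
    "multilevel_pls",
]


# --------------------------------------------------------------------------- #
# Decomposition
# --------------------------------------------------------------------------- #
def decompose(matrix: LongitudinalMatrix) -> MultilevelDecomposition:
    """Split ``X`` into offset + between-animal + within-animal parts.

    Requires a balanced design (every animal observed once per time point);
    the per-animal means the decomposition divides by assume an equal number
    of observations per animal.
    """
    matrix.require_balanced()
    X = matrix.values
    grand = X.mean(axis=0)
    animal_means = X.groupby(matrix.animal.values).transform("mean")

    offset = pd.DataFrame(
        np.tile(grand.values, (len(X), 1)), index=X.index, columns=X.columns
    )
    between = animal_means - offset.values
    within = X - animal_means.values
    return MultilevelDecomposition(
        offset=offset, between=between, within=within, source=matrix
    )


# --------------------------------------------------------------------------- #
# Latent models
# --------------------------------------------------------------------------- #
@dataclass
class LatentResults:
    """Scores/loadings of a fitted PCA / PLS / sPLS model."""

    method: str
    n_components: int
    x_scores: pd.DataFrame
    x_loadings: pd.DataFrame
    y_scores: pd.DataFrame | None = None
    y_loadings: pd.DataFrame | None = None
    explained_variance_ratio: np.ndarray | None = None
    score_covariances: np.ndarray | None = None
    kept_x: list[list[str]] | None = None
    kept_y: list[list[str]] | None = None
    x_center: pd.Series | None = None
    x_scale: pd.Series | None = None
    y_center: pd.Series | None = None
    y_scale: pd.Series | None = None

    def summary(self) -> str:
        lines = [f"{self.method} with {self.n_components} component(s)"]
        if self.explained_variance_ratio is not None:
            for j, ev in enumerate(self.explained_variance_ratio, start=1):
                lines.append(f"  comp {j}: explained variance {ev:.4f}")
        if self.score_covariances is not None:
            for j, cv in enumerate(self.score_covariances, start=1):
                lines.append(f"  comp {j}: score covariance {cv:.6g}")
        if self.kept_x is not None:
            for j, kept in enumerate(self.kept_x, start=1):
                lines.append(f"  comp {j}: keeps {len(kept)} X variable(s): {kept}")
        return "\n".join(lines)

    def write_dir(self, path: str | Path) -> None:
        """Serialize as a directory of TSVs plus a metadata file."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.x_scores.to_csv(path / "x_scores.tsv", sep="\t")
        self.x_loadings.to_csv(path / "x_loadings.tsv", sep="\t")
        if self.y_scores is not None:
            self.y_scores.to_csv(path / "y_scores.tsv", sep="\t")
            self.y_loadings.to_csv(path / "y_loadings.tsv", sep="\t")
        meta = {
            "method": self.method,
            "n_components": self.n_components,
        }
        if self.explained_variance_ratio is not None:
            meta["explained_variance_ratio"] = [
                float(v) for v in self.explained_variance_ratio
            ]
        if self.kept_x is not None:
            meta["kept_x"] = self.kept_x
        if self.kept_y is not None:
            meta["kept_y"] = self.kept_y
        import json

        (path / "metadata.json").write_text(json.dumps(meta, indent=2))


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, LongitudinalMatrix):
        return X.values
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X, dtype=float)
    return pd.DataFrame(X)


def _center_scale(X: pd.DataFrame, center: bool, scale: bool):
    mean = X.mean(axis=0) if center else pd.Series(0.0, index=X.columns)
    if scale:
        sd = X.std(axis=0, ddof=1)
        zero = sd[sd == 0]
        if len(zero):
            raise ValueError(
                f"cannot unit-scale zero-variance column {zero.index[0]!r}"
            )
    else:
        sd = pd.Series(1.0, index=X.columns)
    return (X - mean) / sd, mean, sd


def _fix_sign(loading: np.ndarray) -> float:
    """Sign making the largest-magnitude loading entry positive (first on ties)."""
    j = int(np.argmax(np.abs(loading)))
    s = np.sign(loading[j])
    return 1.0 if s == 0 else float(s)


class PCA:
    """Principal components analysis with a deterministic sign convention.

    Components are ordered by decreasing explained variance; within each
    component the largest-magnitude loading entry is made positive so results
    are reproducible across linear-algebra backends.
    """

    def __init__(self, X, n_components: int = 2, center: bool = True, scale: bool = False):
        self.X = _as_frame(X)
        self.n_components = n_components
        self.center = center
        self.scale = scale

    def fit(self) -> LatentResults:
        Xc, mean, sd = _center_scale(self.X, self.center, self.scale)
        rank = min(Xc.shape)
        if self.n_components > rank:
            raise ValueError(
                f"n_components={self.n_components} exceeds the maximum rank {rank}"
            )
        U, S, Vt = np.linalg.svd(Xc.values, full_matrices=False)
        k = self.n_components
        loadings = Vt[:k].T.copy()
        scores = U[:, :k] * S[:k]
        for j in range(k):
            s = _fix_sign(loadings[:, j])
            loadings[:, j] *= s
            scores[:, j] *= s
        total_var = (S**2).sum()
        evr = (S[:k] ** 2) / total_var if total_var > 0 else np.zeros(k)
        comp = [f"PC{j + 1}" for j in range(k)]
        return LatentResults(
            method="PCA",
            n_components=k,
            x_scores=pd.DataFrame(scores, index=Xc.index, columns=comp),
            x_loadings=pd.DataFrame(loadings, index=Xc.columns, columns=comp),
            explained_variance_ratio=evr,
            x_center=mean,
            x_scale=sd,
        )


def _soft_threshold_keep(u: np.ndarray, keep: int) -> np.ndarray:
    """Soft-threshold ``u`` so exactly ``keep`` entries remain nonzero.

    The threshold is the largest magnitude among the dropped entries; ties
    are broken by column order (earlier columns kept).
    """
    p = u.shape[0]
    if keep >= p:
        return u.copy()
    mag = np.abs(u)
    # stable sort on (-magnitude, index): earlier columns win ties
    order = np.argsort(-mag, kind="stable")
    kept_idx = order[:keep]
    lam = mag[order[keep]]
    out = np.sign(u) * np.maximum(mag - lam, 0.0)
    mask = np.zeros(p, dtype=bool)
    mask[kept_idx] = True
    out[~mask] = 0.0
    # a kept entry tied with lam would shrink to zero; nudge it to stay kept
    zeroed = mask & (out == 0.0)
    if zeroed.any():
        out[zeroed] = np.sign(u[zeroed]) * 1e-12
    return out


class PLS:
    """Partial least squares by NIPALS with SVD initialization.

    Per component, the loading pair maximizes the covariance between the X
    and Y scores; matrices are then deflated by regression on their own
    scores (``mode='canonical'``, default) or both on the X score
    (``mode='regression'``).
    """

    method_name = "PLS"

    def __init__(
        self,
        X,
        Y,
        n_components: int = 2,
        mode: str = "canonical",
        center: bool = True,
        scale_x: bool = False,
        scale_y: bool = False,
        tol: float = 1e-9,
        max_iter: int = 500,
    ):
        self.X = _as_frame(X)
        self.Y = _as_frame(Y)
        if len(self.X) != len(self.Y):
            raise ValueError(
                f"X and Y must be row-aligned: {len(self.X)} vs {len(self.Y)} rows"
            )
        if mode not in ("canonical", "regression"):
            raise ValueError(f"unknown mode {mode!r}")
        self.n_components = n_components
        self.mode = mode
        self.center = center
        self.scale_x = scale_x
        self.scale_y = scale_y
        self.tol = tol
        self.max_iter = max_iter

    # per-component sparsity; dense PLS keeps everything
    def _keep(self, comp: int) -> tuple[int, int]:
        return self.X.shape[1], self.Y.shape[1]

    def fit(self) -> LatentResults:
        Xc, x_mean, x_sd = _center_scale(self.X, self.center, self.scale_x)
        Yc, y_mean, y_sd = _center_scale(self.Y, self.center, self.scale_y)
        Xr = Xc.values.copy()
        Yr = Yc.values.copy()
        n, px = Xr.shape
        py = Yr.shape[1]
        k = self.n_components

        U = np.zeros((px, k))
        V = np.zeros((py, k))
        Tx = np.zeros((n, k))
        Ty = np.zeros((n, k))
        covs = np.zeros(k)
        kept_x: list[list[str]] = []
        kept_y: list[list[str]] = []

        for h in range(k):
            keep_x, keep_y = self._keep(h)
            M = Xr.T @ Yr
            # SVD initialization with the dominant singular pair
            u_svd, s, v_svd = np.linalg.svd(M, full_matrices=False)
            u, v = u_svd[:, 0], v_svd[0]
            for _ in range(self.max_iter):
                u_new = M @ v
                if keep_x < px:
                    u_new = _soft_threshold_keep(u_new, keep_x)
                nu = np.linalg.norm(u_new)
                u_new = u_new / nu if nu > 0 else u_new
                v_new = M.T @ u_new
                if keep_y < py:
                    v_new = _soft_threshold_keep(v_new, keep_y)
                nv = np.linalg.norm(v_new)
                v_new = v_new / nv if nv > 0 else v_new
                if np.linalg.norm(u_new - u) < self.tol and np.linalg.norm(v_new - v) < self.tol:
                    u, v = u_new, v_new
                    break
                u, v = u_new, v_new

            sign = _fix_sign(u)
            u, v = u * sign, v * sign
            xi = Xr @ u
            omega = Yr @ v
            U[:, h], V[:, h] = u, v
            Tx[:, h], Ty[:, h] = xi, omega
            covs[h] = float(xi @ omega) / max(n - 1, 1)
            kept_x.append([c for c, w in zip(Xc.columns, u) if w != 0.0])
            kept_y.append([c for c, w in zip(Yc.columns, v) if w != 0.0])

            # deflation
            xi_norm2 = xi @ xi
            if xi_norm2 > 0:
                Xr = Xr - np.outer(xi, xi @ Xr) / xi_norm2
            if self.mode == "canonical":
                om_norm2 = omega @ omega
                if om_norm2 > 0:
                    Yr = Yr - np.outer(omega, omega @ Yr) / om_norm2
            else:
                if xi_norm2 > 0:
                    Yr = Yr - np.outer(xi, xi @ Yr) / xi_norm2

        comp = [f"C{j + 1}" for j in range(k)]
        sparse = self.method_name == "sPLS"
        return LatentResults(
            method=self.method_name,
            n_components=k,
            x_scores=pd.DataFrame(Tx, index=Xc.index, columns=comp),
            x_loadings=pd.DataFrame(U, index=Xc.columns, columns=comp),
            y_scores=pd.DataFrame(Ty, index=Yc.index, columns=comp),
            y_loadings=pd.DataFrame(V, index=Yc.columns, columns=comp),
            score_covariances=covs,
            kept_x=kept_x if sparse else None,
            kept_y=kept_y if sparse else None,
            x_center=x_mean,
            x_scale=x_sd,
            y_center=y_mean,
            y_scale=y_sd,
        )


class SPLS(PLS):
    """Sparse PLS: per-component cardinality constraints on the loadings.

    The X loading of each component is soft-thresholded so exactly ``keep_x``
    entries are nonzero (likewise ``keep_y``), the operational form of the L1
    penalty; with ``keep_x = p_X`` and ``keep_y = p_Y`` the fit coincides
    with dense PLS.
    """

    method_name = "sPLS"

    def __init__(self, X, Y, n_components: int = 2, keep_x=None, keep_y=None, **kwargs):
        super().__init__(X, Y, n_components=n_components, **kwargs)
        px, py = self.X.shape[1], self.Y.shape[1]
        self.keep_x = self._expand(keep_x, px, n_components, "keep_x")
        self.keep_y = self._expand(keep_y, py, n_components, "keep_y")

    @staticmethod
    def _expand(keep, p: int, k: int, name: str) -> list[int]:
        if keep is None:
            keep = p
        if np.isscalar(keep):
            keep = [int(keep)] * k
        keep = [int(x) for x in keep]
        if len(keep) != k:
            raise ValueError(f"{name} must have one entry per component")
        for x in keep:
            if not 1 <= x <= p:
                raise ValueError(f"{name} entries must lie in [1, {p}], got {x}")
        return keep

    def _keep(self, comp: int) -> tuple[int, int]:
        return self.keep_x[comp], self.keep_y[comp]


# --------------------------------------------------------------------------- #
# Multilevel conveniences
# --------------------------------------------------------------------------- #
def multilevel_pca(matrix: LongitudinalMatrix, n_components: int = 2, **kwargs) -> LatentResults:
    """PCA on the within-animal component of ``matrix``."""
    return PCA(decompose(matrix).within, n_components=n_components, **kwargs).fit()


def multilevel_pls(
    X: LongitudinalMatrix,
    Y: LongitudinalMatrix,
    n_components: int = 2,
    keep_x=None,
    keep_y=None,
    **kwargs,
) -> LatentResults:
    """PLS (sparse if ``keep_x``/``keep_y`` given) on within-animal components."""
    Xw = decompose(X).within
    Yw = decompose(Y).within
    if keep_x is None and keep_y is None:
        return PLS(Xw, Yw, n_components=n_components, **kwargs).fit()
    return SPLS(Xw, Yw, n_components=n_components, keep_x=keep_x, keep_y=keep_y, **kwargs).fit()
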