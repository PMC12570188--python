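"""Generative Topographic Mapping: model, EM training, results.

The GTM is a constrained Gaussian mixture: K nodes ``u_k`` on a regular 2-D
latent grid are mapped into data space through a radial-basis-function
expansion,

    y_k = W' Phi(u_k),

and each mixture component is an isotropic Gaussian N(y_k, 1/beta) with a
uniform prior 1/K. Training maximises the data log-likelihood by EM with a
ridge penalty alpha on W. The API follows the statsmodels model/results
split: ``GTM(X, ...)`` holds data and hyperparameters, ``GTM.fit()`` returns
a :class:`GTMResults` carrying the fitted parameters, the log-likelihood
trace, responsibilities and everything downstream (magnification factors,
macroclusters, plots) hangs off the results object.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy.spatial.distance import cdist
from scipy.special import logsumexp

__all__ = [
    "LatentGrid",
    "RBFBasis",
    "GTM",
    "GTMResults",
    "build_basis_matrix",
    "init_gtm",
    "e_step",
    "m_step",
    "reference_vectors",
    "mode_project",
]


def _grid_coords(shape: tuple[int, int]) -> np.ndarray:
    """Row-major lattice of points over [-1, 1]^2; (x across columns, y down rows)."""
    rows, cols = shape
    xs = np.linspace(-1.0, 1.0, cols) if cols > 1 else np.array([0.0])
    ys = np.linspace(-1.0, 1.0, rows) if rows > 1 else np.array([0.0])
    gx, gy = np.meshgrid(xs, ys)
    return np.column_stack([gx.ravel(), gy.ravel()])


@dataclass(frozen=True)
class LatentGrid:
    """Uniform grid of K = rows * cols latent nodes over [-1, 1]^2."""

    shape: tuple[int, int] = (8, 8)

    @property
    def K(self) -> int:
        return self.shape[0] * self.shape[1]

    @property
    def nodes(self) -> np.ndarray:
        return _grid_coords(self.shape)

    def node_rowcol(self, k: int) -> tuple[int, int]:
        return divmod(k, self.shape[1])


@dataclass(frozen=True)
class RBFBasis:
    """Gaussian RBF centers on a uniform grid over the latent square.

    ``width_factor`` scales the common width: sigma = width_factor times the
    distance between adjacent centers (the dominant convention in reference
    GTM implementations; set ``absolute_width`` to use sigma directly).
    """

    shape: tuple[int, int] = (3, 3)
    width_factor: float = 0.8
    absolute_width: float | None = None

    @property
    def S(self) -> int:
        return self.shape[0] * self.shape[1]

    @property
    def centers(self) -> np.ndarray:
        return _grid_coords(self.shape)

    @property
    def sigma(self) -> float:
        if self.absolute_width is not None:
            sig = float(self.absolute_width)
        else:
            cols = max(self.shape)
            spacing = 2.0 / (cols - 1) if cols > 1 else 2.0
            sig = self.width_factor * spacing
        if sig <= 0:
            raise ValueError(f"RBF width must be > 0, got {sig}")
        return sig


def build_basis_matrix(grid: LatentGrid, basis: RBFBasis) -> np.ndarray:
    """K x (S+1) design matrix: Gaussian responses plus a constant bias column."""
    sigma = basis.sigma
    d2 = cdist(grid.nodes, basis.centers, metric="sqeuclidean")
    phi = np.exp(-d2 / (2.0 * sigma**2))
    return np.column_stack([phi, np.ones(grid.K)])


# ---------------------------------------------------------------------------
# EM pieces (module-level so they can be tested and reused directly)


def init_gtm(
    X: np.ndarray, grid: LatentGrid, basis: RBFBasis, alpha: float = 1.0
) -> tuple[np.ndarray, float]:
    """Deterministic PCA initialization of (W, beta).

    W is the least-squares solution of Phi W ~ mean + U diag(sqrt(l1), sqrt(l2)) V'
    with (l_i, v_i) the leading data eigenpairs and U the latent node grid;
    eigenvector signs are fixed so the largest-magnitude loading is positive.
    beta^-1 starts at max(l3, (half the minimum distance between distinct
    initial reference vectors)^2), falling back to l2/2 when fewer than three
    positive eigenvalues exist.
    """
    X = np.asarray(X, dtype=float)
    N, D = X.shape
    mean = X.mean(axis=0)
    Xc = X - mean
    cov = (Xc.T @ Xc) / max(N - 1, 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    for j in range(min(2, D)):
        i = np.argmax(np.abs(evecs[:, j]))
        if evecs[i, j] < 0:
            evecs[:, j] = -evecs[:, j]

    U = grid.nodes  # K x 2
    target = mean + (U * np.sqrt(np.maximum(evals[:2], 0.0))) @ evecs[:, :2].T
    phi = build_basis_matrix(grid, basis)
    W, *_ = np.linalg.lstsq(phi, target, rcond=None)

    Y0 = phi @ W
    dists = cdist(Y0, Y0)
    np.fill_diagonal(dists, np.inf)
    dmin = dists.min()
    n_pos = int(np.sum(evals > 1e-12))
    if n_pos >= 3:
        beta_inv = max(float(evals[2]), (0.5 * dmin) ** 2 if np.isfinite(dmin) else 0.0)
    else:
        beta_inv = float(evals[1]) / 2.0
    if beta_inv <= 0:
        beta_inv = max(float(np.var(Xc)), 1e-6)
    return W, 1.0 / beta_inv


def e_step(
    X: np.ndarray, phi: np.ndarray, W: np.ndarray, beta: float
) -> tuple[np.ndarray, float]:
    """Responsibilities and log-likelihood under uniform node priors.

    R[n, k] is proportional to exp(-(beta/2) ||x_n - y_k||^2), normalised over k
    with log-sum-exp stabilisation; the log-likelihood includes the Gaussian
    normalising constant (beta/2 pi)^(D/2) and the 1/K prior.
    """
    X = np.asarray(X, dtype=float)
    N, D = X.shape
    Y = phi @ W
    K = Y.shape[0]
    log_w = -0.5 * beta * cdist(X, Y, metric="sqeuclidean")  # N x K
    lse = logsumexp(log_w, axis=1)
    R = np.exp(log_w - lse[:, None])
    ll = float(np.sum(lse) + N * (0.5 * D * np.log(beta / (2.0 * np.pi)) - np.log(K)))
    return R, ll


def m_step(
    X: np.ndarray, phi: np.ndarray, R: np.ndarray, alpha: float, beta: float
) -> tuple[np.ndarray, float]:
    """Regularised GTM M-step: update W, then beta with the new W."""
    X = np.asarray(X, dtype=float)
    N, D = X.shape
    G = R.sum(axis=0)  # K, column sums
    A = phi.T @ (phi * G[:, None]) + (alpha / beta) * np.eye(phi.shape[1])
    B = phi.T @ (R.T @ X)
    try:
        W = sla.solve(A, B, assume_a="pos")
    except (sla.LinAlgError, np.linalg.LinAlgError):
        warnings.warn("singular M-step system; falling back to least squares", stacklevel=2)
        W, *_ = np.linalg.lstsq(A, B, rcond=None)
    Y = phi @ W
    d2 = cdist(X, Y, metric="sqeuclidean")
    beta_inv = float(np.sum(R * d2)) / (N * D)
    if beta_inv <= 0:
        beta_inv = np.finfo(float).tiny
    return W, 1.0 / beta_inv


def reference_vectors(phi: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Data-space node images Y = Phi W (K x D)."""
    return phi @ W


def mode_project(R: np.ndarray) -> np.ndarray:
    """Per-row argmax node index; ties go to the lowest node index."""
    return np.argmax(R, axis=1)


# ---------------------------------------------------------------------------
# model / results objects


class GTM:
    """Generative Topographic Mapping of a standardized feature table.

    Parameters
    ----------
    X : array-like or DataFrame, shape (N, D)
        Standardized training data (rows = snippets, columns = features).
    grid_shape, rbf_shape : tuple
        Latent node grid and RBF center grid; the study configuration is an
        8 x 8 grid with a 3 x 3 RBF arrangement.
    width : float
        RBF width factor (sigma = width x center spacing).
    alpha : float
        Ridge regularization constant on W.
    feature_names : optional list of column names.
    standardizer : optional fitted preprocessing.Standardizer, kept as model
        metadata so new snippets can be projected consistently.
    """

    def __init__(
        self,
        X,
        grid_shape: tuple[int, int] = (8, 8),
        rbf_shape: tuple[int, int] = (3, 3),
        width: float = 0.8,
        alpha: float = 1.0,
        feature_names: list[str] | None = None,
        standardizer=None,
        absolute_width: float | None = None,
    ):
        if isinstance(X, pd.DataFrame):
            feature_names = feature_names or list(X.columns)
            X = X.to_numpy(dtype=float)
        self.X = np.asarray(X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[1] < 2:
            raise ValueError("X must be 2-D with at least 2 feature columns")
        self.grid = LatentGrid(tuple(grid_shape))
        self.basis = RBFBasis(tuple(rbf_shape), width_factor=width, absolute_width=absolute_width)
        self.alpha = float(alpha)
        self.feature_names = feature_names or [f"x{j}" for j in range(self.X.shape[1])]
        self.standardizer = standardizer
        self.phi = build_basis_matrix(self.grid, self.basis)

    @classmethod
    def from_dataframe(cls, table: pd.DataFrame, standardizer=None, **kwargs) -> "GTM":
        """Build from a (standardized) feature table; bookkeeping columns
        (ecg_id, snippet_index, quality, diagnosis) are set aside."""
        from rhythmmap.preprocessing import META_COLUMNS

        feats = [c for c in table.columns if c not in META_COLUMNS]
        return cls(table[feats], feature_names=feats, standardizer=standardizer, **kwargs)

    def fit(
        self,
        max_iter: int = 200,
        tol: float = 1e-5,
        init: str = "pca",
        seed: int | None = None,
    ) -> "GTMResults":
        """Train by EM until the relative log-likelihood change drops below
        ``tol`` or ``max_iter`` iterations have run."""
        if init == "pca":
            W, beta = init_gtm(self.X, self.grid, self.basis, self.alpha)
        elif init == "random":
            rng = np.random.default_rng(seed)
            W = rng.normal(scale=0.1, size=(self.phi.shape[1], self.X.shape[1]))
            beta = 1.0 / max(float(np.var(self.X)), 1e-6)
        else:
            raise ValueError(f"unknown init {init!r}")

        # With alpha > 0 EM performs MAP estimation: the ascended objective is
        # the *penalized* log-likelihood ll - (alpha/2)||W||^2 (it reduces to
        # the plain log-likelihood at alpha = 0), so that is what the trace
        # stores and the stopping rule watches.
        def objective(ll, W):
            return ll - 0.5 * self.alpha * float(np.sum(W**2))

        R, ll = e_step(self.X, self.phi, W, beta)
        obj = objective(ll, W)
        trace = [obj]
        if not np.isfinite(obj):
            raise RuntimeError("non-finite log-likelihood at initialization")
        for _ in range(max_iter):
            W, beta = m_step(self.X, self.phi, R, self.alpha, beta)
            R, ll = e_step(self.X, self.phi, W, beta)
            obj_new = objective(ll, W)
            if not np.isfinite(obj_new):
                raise RuntimeError("non-finite log-likelihood during EM")
            trace.append(obj_new)
            if abs(obj_new - obj) < tol * abs(obj):
                break
            obj = obj_new
        return GTMResults(self, W, beta, np.asarray(trace), R)


class GTMResults:
    """Fitted GTM: parameters, responsibilities and downstream analyses."""

    def __init__(self, model: GTM, W: np.ndarray, beta: float, loglik_trace, R: np.ndarray):
        self.model = model
        self.W = W
        self.beta = float(beta)
        self.loglik_trace = np.asarray(loglik_trace, dtype=float)
        self.responsibilities_ = R
        self.magnification_ = None  # attached by attach_magnification()

    # -- core quantities ---------------------------------------------------

    @property
    def reference_vectors_(self) -> np.ndarray:
        return reference_vectors(self.model.phi, self.W)

    @property
    def loglik(self) -> float:
        return float(self.loglik_trace[-1])

    def responsibilities(self, X=None) -> np.ndarray:
        """Responsibility matrix for X (training data when X is None)."""
        if X is None:
            X = self.model.X
        if isinstance(X, pd.DataFrame):
            X = X.to_numpy(dtype=float)
        R, _ = e_step(np.atleast_2d(X), self.model.phi, self.W, self.beta)
        return R

    def project(self, X=None) -> np.ndarray:
        """Mode projection: the most responsible node per row."""
        return mode_project(self.responsibilities(X))

    def transform_new(self, table: pd.DataFrame) -> np.ndarray:
        """Standardize a raw feature table with the stored parameters and
        return responsibilities."""
        if self.model.standardizer is None:
            raise ValueError("model carries no standardizer")
        Z = self.model.standardizer.transform(table)
        return self.responsibilities(Z.to_numpy(dtype=float))

    # -- magnification ------------------------------------------------------

    def magnification_factors(self):
        from rhythmmap.magnification import magnification_factors

        return magnification_factors(self)

    def attach_magnification(self):
        """Compute the magnification field and persist it with the model."""
        self.magnification_ = self.magnification_factors()
        return self.magnification_

    # -- reporting ----------------------------------------------------------

    def summary(self) -> str:
        rows, cols = self.model.grid.shape
        srows, scols = self.model.basis.shape
        occ = np.bincount(self.project(), minlength=self.model.grid.K)
        lines = [
            "Generative Topographic Mapping results",
            "=" * 46,
            f"observations          {self.model.X.shape[0]}",
            f"features              {self.model.X.shape[1]}",
            f"latent grid           {rows} x {cols} ({self.model.grid.K} nodes)",
            f"RBF centers           {srows} x {scols} (+ bias), sigma = {self.model.basis.sigma:.4f}",
            f"regularization alpha  {self.model.alpha:g}",
            f"beta (1/noise var)    {self.beta:.6g}",
            f"EM iterations         {len(self.loglik_trace) - 1}",
            f"final log-likelihood  {self.loglik:.4f}",
            f"occupied nodes        {int(np.sum(occ > 0))} / {self.model.grid.K}",
        ]
        return "\n".join(lines)

    # -- serialization -------------------------------------------------------

    def save(self, directory) -> Path:
        """Two-file archive: JSON manifest + full-precision CSV for W."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        manifest = {
            "grid_shape": list(self.model.grid.shape),
            "rbf_shape": list(self.model.basis.shape),
            "width_factor": self.model.basis.width_factor,
            "absolute_width": self.model.basis.absolute_width,
            "alpha": self.model.alpha,
            "beta": self.beta,
            "loglik_trace": self.loglik_trace.tolist(),
            "feature_names": list(self.model.feature_names),
            "standardizer": (
                self.model.standardizer.to_dict() if self.model.standardizer else None
            ),
            "magnification": (
                self.magnification_.values.tolist() if self.magnification_ is not None else None
            ),
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))
        np.savetxt(directory / "W.csv", self.W, delimiter=",", fmt="%.17g")
        return directory

    @classmethod
    def load(cls, directory) -> "GTMResults":
        from rhythmmap.magnification import MagnificationField
        from rhythmmap.preprocessing import Standardizer

        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        W = np.loadtxt(directory / "W.csv", delimiter=",", ndmin=2)
        scaler = (
            Standardizer.from_dict(manifest["standardizer"])
            if manifest.get("standardizer")
            else None
        )
        model = GTM(
            np.zeros((2, W.shape[1])),  # placeholder; training data not archived
            grid_shape=tuple(manifest["grid_shape"]),
            rbf_shape=tuple(manifest["rbf_shape"]),
            width=manifest["width_factor"],
            absolute_width=manifest.get("absolute_width"),
            alpha=manifest["alpha"],
            feature_names=manifest["feature_names"],
            standardizer=scaler,
        )
        res = cls(model, W, manifest["beta"], manifest["loglik_trace"], R=None)
        if manifest.get("magnification") is not None:
            res.magnification_ = MagnificationField(
                values=np.asarray(manifest["magnification"], dtype=float), grid=model.grid
            )
        return res
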