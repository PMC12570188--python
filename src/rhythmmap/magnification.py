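"""Magnification factors of the trained GTM manifold.

The latent-to-data map y(u) = W' Phi(u) is smooth, so an infinitesimal
rectangle at a latent node u_k maps to a parallelogram in data space whose
area is inflated by

    MF_k = sqrt(det(J_k' J_k)),      J_k = W' (dPhi/du at u_k)  (D x 2).

High MF marks regions where the manifold stretches to cover sparse data;
the field is evaluated exactly at the latent nodes because the macrocluster
KNN constraint operates on nodes (a finer mesh is a plotting option only).
All quantities live in the standardized data space the model was trained in.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from rhythmmap.gtm import GTMResults, LatentGrid, RBFBasis

__all__ = ["MagnificationField", "basis_jacobian", "magnification_factors"]


@dataclass
class MagnificationField:
    """Per-node areal expansion factors of the latent-to-data mapping."""

    values: np.ndarray  # length K, dimensionless, >= 0
    grid: LatentGrid

    def __len__(self) -> int:
        return self.values.size

    def to_frame(self) -> pd.DataFrame:
        rows, cols = self.grid.shape
        nodes = self.grid.nodes
        idx = np.arange(self.grid.K)
        return pd.DataFrame(
            {
                "node_row": idx // cols,
                "node_col": idx % cols,
                "u1": nodes[:, 0],
                "u2": nodes[:, 1],
                "MF": self.values,
            }
        )


def basis_jacobian(grid: LatentGrid, basis: RBFBasis) -> np.ndarray:
    """Derivatives of the basis outputs w.r.t. the latent coordinates.

    Returns a (K, S+1, 2) array: for the Gaussian components
    dPhi_s/du = -((u - mu_s)/sigma^2) Phi_s(u); the bias row is zero.
    """
    sigma = basis.sigma
    nodes = grid.nodes  # K x 2
    centers = basis.centers  # S x 2
    diff = nodes[:, None, :] - centers[None, :, :]  # K x S x 2
    phi = np.exp(-np.sum(diff**2, axis=2) / (2.0 * sigma**2))  # K x S
    dphi = -(diff / sigma**2) * phi[:, :, None]  # K x S x 2
    K = grid.K
    out = np.zeros((K, basis.S + 1, 2))
    out[:, : basis.S, :] = dphi
    return out


def magnification_factors(results: GTMResults) -> MagnificationField:
    """Areal magnification sqrt(det(J'J)) at every latent node."""
    model = results.model
    dphi = basis_jacobian(model.grid, model.basis)  # K x (S+1) x 2
    W = results.W  # (S+1) x D
    field = np.empty(model.grid.K)
    for k in range(model.grid.K):
        J = W.T @ dphi[k]  # D x 2
        g = J.T @ J  # 2 x 2 metric tensor
        det = g[0, 0] * g[1, 1] - g[0, 1] * g[1, 0]
        if det < -1e-12:
            raise FloatingPointError(f"negative metric determinant {det} at node {k}")
        field[k] = np.sqrt(max(det, 0.0))
    return MagnificationField(values=field, grid=model.grid)
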