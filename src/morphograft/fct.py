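"""Flux-corrected transport limiting and Patankar source splitting.

The transport update blends a provably non-negative low-order solution
(lumped mass + algebraic artificial diffusion, implicit losses) with a
high-order Galerkin candidate through Zalesak's limiter: antidiffusive edge
fluxes are accepted only as far as they cannot create new extrema below the
low-order local bounds. The corrected field is conservative because the
edge fluxes are antisymmetric.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse

__all__ = ["artificial_diffusion", "extract_edges", "apply_fct", "split_sources"]


def artificial_diffusion(K: sparse.spmatrix) -> sparse.csr_matrix:
    """Symmetric artificial diffusion D rendering K + D local-extremum-diminishing.

    D_ij = max(0, -K_ij, -K_ji) for i != j and D_ii = -sum_j D_ij, so D has
    zero row sums and K + D has non-negative off-diagonal entries.
    """
    K = K.tocsr()
    A = K.minimum(K.T)  # symmetric lower envelope
    A = A.tocoo()
    mask = (A.row != A.col) & (A.data < 0)
    rows, cols, vals = A.row[mask], A.col[mask], -A.data[mask]
    n = K.shape[0]
    D = sparse.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    diag = -np.asarray(D.sum(axis=1)).ravel()
    return (D + sparse.diags(diag)).tocsr()


def extract_edges(*mats: sparse.spmatrix) -> np.ndarray:
    """Unique undirected off-diagonal edges (i < j) of the union sparsity pattern."""
    rows, cols = [], []
    for m in mats:
        coo = m.tocoo()
        rows.append(coo.row)
        cols.append(coo.col)
    r = np.concatenate(rows)
    c = np.concatenate(cols)
    mask = r < c
    edges = np.unique(np.stack([r[mask], c[mask]], axis=1), axis=0)
    return edges


def apply_fct(
    z_low: np.ndarray,
    z_high: np.ndarray,
    lumped_mass: np.ndarray,
    edges: np.ndarray,
    fluxes: np.ndarray,
    *,
    prelimit: bool = False,
    locked: np.ndarray | None = None,
) -> np.ndarray:
    """Zalesak-limited correction of the low-order solution.

    ``edges`` is (k, 2) with node pairs (i, j) and ``fluxes`` the signed
    antidiffusive flux from j into i (f_ji = -f_ij implicitly). When the
    fluxes decompose lumped_mass * (z_high - z_low) exactly and no bound is
    active, the corrected field equals the high-order candidate; with all
    fluxes zero it is the low-order solution. ``locked`` nodes (e.g.
    Dirichlet) take no correction. The result never drops below the
    low-order local minima, hence stays non-negative.
    """
    z_low = np.asarray(z_low, dtype=float)
    n = z_low.size
    if len(edges) == 0:
        return z_low.copy()
    i, j = edges[:, 0], edges[:, 1]
    f = np.asarray(fluxes, dtype=float).copy()

    if locked is not None and locked.any():
        f[locked[i] | locked[j]] = 0.0
    if prelimit:
        # cancel fluxes that would steepen the low-order gradient
        f[f * (z_low[j] - z_low[i]) > 0.0] = 0.0

    # local bounds from the low-order solution over each node's edge star
    z_max = z_low.copy()
    z_min = z_low.copy()
    np.maximum.at(z_max, i, z_low[j])
    np.maximum.at(z_max, j, z_low[i])
    np.minimum.at(z_min, i, z_low[j])
    np.minimum.at(z_min, j, z_low[i])

    Pp = np.zeros(n)
    Pm = np.zeros(n)
    np.add.at(Pp, i, np.maximum(f, 0.0))
    np.add.at(Pp, j, np.maximum(-f, 0.0))
    np.add.at(Pm, i, np.minimum(f, 0.0))
    np.add.at(Pm, j, np.minimum(-f, 0.0))

    Qp = lumped_mass * (z_max - z_low)
    Qm = lumped_mass * (z_min - z_low)
    with np.errstate(divide="ignore", invalid="ignore"):
        Rp = np.where(Pp > 0.0, np.minimum(1.0, Qp / np.where(Pp > 0, Pp, 1.0)), 1.0)
        Rm = np.where(Pm < 0.0, np.minimum(1.0, Qm / np.where(Pm < 0, Pm, -1.0)), 1.0)

    alpha = np.where(f >= 0.0, np.minimum(Rp[i], Rm[j]), np.minimum(Rm[i], Rp[j]))
    corr = np.zeros(n)
    np.add.at(corr, i, alpha * f)
    np.add.at(corr, j, -alpha * f)
    return z_low + corr / lumped_mass


def split_sources(reaction_value, state_value):
    """Patankar sign split of a reaction term into (production, loss_rate).

    reaction = production - loss_rate * state with production >= 0 and
    loss_rate >= 0: non-negative reactions are pure production; negative
    reactions are recast as a linear implicit loss, which guarantees
    positivity of the reaction update. At state_value = 0 the loss is zero
    (structural positivity makes the reaction non-negative there).
    """
    r = np.asarray(reaction_value, dtype=float)
    z = np.asarray(state_value, dtype=float)
    production = np.maximum(r, 0.0)
    loss = np.zeros(np.broadcast(r, z).shape)
    neg = np.broadcast_to(r, loss.shape) < 0.0
    zb = np.broadcast_to(z, loss.shape)
    np.divide(
        -np.broadcast_to(r, loss.shape), zb, out=loss, where=neg & (zb > 0)
    )
    if loss.ndim == 0:
        return float(production), float(loss)
    return production, loss
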