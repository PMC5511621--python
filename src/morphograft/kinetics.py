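"""Pointwise reaction terms and flux vectors for the four constituents.

The dermal slice carries four constituents: fibroblasts N, myofibroblasts M,
a generic signaling molecule c (e.g. TGF-beta), and collagen rho. MMP
activity is a derived quantity g(N, M, c, rho), not a state variable. All
functions broadcast over numpy arrays and are pure; the FEM engine and the
homogeneous ODE oracle both consume them.

Conventions: saturating fractions c/(a + c) extend continuously with
0/0 -> 0; powers N^(1+q) are evaluated on max(N, 0) so floating-point noise
below zero cannot produce complex values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ConstituentPoint",
    "mmp_level",
    "reaction_fibroblasts",
    "reaction_myofibroblasts",
    "reaction_signal",
    "reaction_collagen",
    "reaction_terms_split",
    "flux_cells",
    "flux_signal",
]


@dataclass
class ConstituentPoint:
    """State (and optionally gradients) of the constituents at a point.

    Gradients are 2-vectors in the (Y, Z) slice plane and are only needed
    for flux evaluation.
    """

    N: float | np.ndarray = 0.0
    M: float | np.ndarray = 0.0
    c: float | np.ndarray = 0.0
    rho: float | np.ndarray = 0.0
    grad_N: np.ndarray = field(default_factory=lambda: np.zeros(2))
    grad_M: np.ndarray = field(default_factory=lambda: np.zeros(2))
    grad_c: np.ndarray = field(default_factory=lambda: np.zeros(2))


def hill(c, a):
    """Saturating fraction c / (a + c), with the continuous extension 0/0 -> 0."""
    c = np.asarray(c, dtype=float)
    denom = a + c
    out = np.zeros(np.broadcast(c, denom).shape)
    np.divide(c, denom, out=out, where=denom > 0)
    return out if out.ndim else float(out)


def _pow1q(z, q):
    """z**(1+q) on the clipped non-negative part (1+q > 0 by parameter invariant)."""
    return np.maximum(np.asarray(z, dtype=float), 0.0) ** (1.0 + q)


def _powq(z, q):
    """z**q for z > 0, else 0 (q may be negative)."""
    z = np.asarray(z, dtype=float)
    out = np.zeros(z.shape)
    np.power(z, q, out=out, where=z > 0)
    return out if out.ndim else float(out)


def mmp_level(p: ConstituentPoint, params):
    """MMP activity g = (N + eta_II M) rho / (1 + a_c_III c), cells g / cm^6.

    Secretion by (myo)fibroblasts scaled by collagen availability and
    inhibited by the signaling molecule.
    """
    return (p.N + params.eta_II * p.M) * p.rho / (1.0 + params.a_c_III * p.c)


def reaction_fibroblasts(p: ConstituentPoint, params):
    """dN/dt: enhanced logistic-type division - differentiation - apoptosis."""
    enh = params.r_F * (1.0 + params.r_F_max * hill(p.c, params.a_c_I))
    crowd = 1.0 - params.kappa_F * (p.N + p.M)
    return (
        enh * crowd * _pow1q(p.N, params.q)
        - params.k_F * p.c * p.N
        - params.delta_N * p.N
    )


def reaction_myofibroblasts(p: ConstituentPoint, params):
    """dM/dt: signal-gated division + differentiation from N - apoptosis."""
    enh = params.r_F * (1.0 + params.r_F_max) * hill(p.c, params.a_c_I)
    crowd = 1.0 - params.kappa_F * (p.N + p.M)
    return (
        enh * crowd * _pow1q(p.M, params.q)
        + params.k_F * p.c * p.N
        - params.delta_M * p.M
    )


def reaction_signal(p: ConstituentPoint, params):
    """dc/dt: autocrine secretion - MMP-mediated proteolytic breakdown."""
    return (
        params.k_c * hill(p.c, params.a_c_II) * (p.N + params.eta_I * p.M)
        - params.delta_c * mmp_level(p, params) * p.c
    )


def reaction_collagen(p: ConstituentPoint, params):
    """drho/dt: signal-enhanced secretion - MMP-mediated breakdown."""
    return (
        params.k_rho
        * (1.0 + params.k_rho_max * hill(p.c, params.a_c_IV))
        * (p.N + params.eta_I * p.M)
        - params.delta_rho * mmp_level(p, params) * p.rho
    )


def reaction_terms_split(p: ConstituentPoint, params):
    """Term-wise split of each reaction into (production, loss_rate).

    Returns a dict keyed by constituent with pairs (P, lam) satisfying
    R = P - lam * z, P >= 0, lam >= 0. The crowding factor may turn negative
    in transiently over-crowded tissue; its negative part is moved into the
    loss rate so the split stays sign-correct.
    """
    enh_N = params.r_F * (1.0 + params.r_F_max * hill(p.c, params.a_c_I))
    enh_M = params.r_F * (1.0 + params.r_F_max) * hill(p.c, params.a_c_I)
    crowd = 1.0 - params.kappa_F * (p.N + p.M)
    crowd_pos = np.maximum(crowd, 0.0)
    crowd_neg = np.maximum(-crowd, 0.0)
    g = mmp_level(p, params)

    P_N = enh_N * crowd_pos * _pow1q(p.N, params.q)
    lam_N = params.k_F * p.c + params.delta_N + enh_N * crowd_neg * _powq(p.N, params.q)

    P_M = enh_M * crowd_pos * _pow1q(p.M, params.q) + params.k_F * p.c * p.N
    lam_M = params.delta_M + enh_M * crowd_neg * _powq(p.M, params.q)

    P_c = params.k_c * hill(p.c, params.a_c_II) * (p.N + params.eta_I * p.M)
    lam_c = params.delta_c * g

    P_rho = (
        params.k_rho
        * (1.0 + params.k_rho_max * hill(p.c, params.a_c_IV))
        * (p.N + params.eta_I * p.M)
    )
    lam_rho = params.delta_rho * g

    return {
        "N": (P_N, lam_N),
        "M": (P_M, lam_M),
        "c": (P_c, lam_c),
        "rho": (P_rho, lam_rho),
    }


def flux_cells(p: ConstituentPoint, params):
    """Cell fluxes J_N, J_M: density-dependent motility plus chemotaxis up grad c."""
    F = p.N + p.M
    J_N = -params.D_F * F * np.asarray(p.grad_N) + params.chi_F * p.N * np.asarray(p.grad_c)
    J_M = -params.D_F * F * np.asarray(p.grad_M) + params.chi_F * p.M * np.asarray(p.grad_c)
    return J_N, J_M


def flux_signal(p: ConstituentPoint, params):
    """Fickian signal flux J_c = -D_c grad c. Collagen has no flux (J_rho = 0)."""
    return -params.D_c * np.asarray(p.grad_c)
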