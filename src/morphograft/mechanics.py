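"""Constitutive law, traction body force, growth tensor, and strain evolution.

The computation lives on an infinitely thin dermal slice in the (Y, Z)
plane: out-of-plane strain components vanish identically, so symmetric
tensors are stored by their three in-plane components (t22, t23, t33) and
all traces are taken over the stored components, tr = t22 + t33. The full
in-plane velocity gradient L = grad v is kept unsymmetrized because the
strain evolution needs its spin (skew) part for the Jaumann correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PlaneTensor",
    "VelocityGradient",
    "youngs_modulus",
    "cauchy_stress",
    "traction_stress",
    "growth_tensor",
    "strain_rate",
]


@dataclass
class PlaneTensor:
    """Symmetric in-plane 2x2 tensor field with components (t22, t23, t33)."""

    t22: float | np.ndarray = 0.0
    t23: float | np.ndarray = 0.0
    t33: float | np.ndarray = 0.0

    @property
    def trace(self):
        return self.t22 + self.t33

    def frobenius(self):
        """Frobenius norm of the full symmetric 2x2 tensor."""
        return np.sqrt(self.t22**2 + 2.0 * self.t23**2 + self.t33**2)

    def __add__(self, other: "PlaneTensor") -> "PlaneTensor":
        return PlaneTensor(self.t22 + other.t22, self.t23 + other.t23, self.t33 + other.t33)

    def __sub__(self, other: "PlaneTensor") -> "PlaneTensor":
        return PlaneTensor(self.t22 - other.t22, self.t23 - other.t23, self.t33 - other.t33)

    def scaled(self, a) -> "PlaneTensor":
        return PlaneTensor(a * self.t22, a * self.t23, a * self.t33)

    def as_matrix(self) -> np.ndarray:
        return np.array([[self.t22, self.t23], [self.t23, self.t33]])


@dataclass
class VelocityGradient:
    """Full in-plane velocity gradient L = grad v, components l_ab = dv_a/dx_b."""

    l22: float | np.ndarray = 0.0
    l23: float | np.ndarray = 0.0
    l32: float | np.ndarray = 0.0
    l33: float | np.ndarray = 0.0

    def sym(self) -> PlaneTensor:
        return PlaneTensor(self.l22, 0.5 * (self.l23 + self.l32), self.l33)

    def spin(self):
        """Scalar spin omega: skw(L) = [[0, omega], [-omega, 0]]."""
        return 0.5 * (self.l23 - self.l32)


def youngs_modulus(rho, params):
    """Collagen-dependent stiffness E(rho) = E_I sqrt(rho), N/cm^2."""
    return params.E_I * np.sqrt(np.maximum(np.asarray(rho, dtype=float), 0.0))


def cauchy_stress(eps: PlaneTensor, L: VelocityGradient, rho, params) -> PlaneTensor:
    """Visco-elastic stress: viscous response to sym(L) plus linear elasticity in eps.

    sigma = mu_1 sym(L) + mu_2 tr(sym L) I + [E(rho)/(1+nu)] {eps + tr(eps) nu/(1-2nu) I}
    with the trace over the in-plane components (the out-of-plane strain is zero
    by the slice assumptions). The incompressible limit nu = 1/2 is rejected.
    """
    if params.nu >= 0.5:
        raise ValueError("nu must be < 1/2 (incompressible limit is not supported)")
    symL = L.sym()
    visc = symL.scaled(params.mu_1)
    dil = params.mu_2 * symL.trace
    k_el = youngs_modulus(rho, params) / (1.0 + params.nu)
    lam = params.nu / (1.0 - 2.0 * params.nu)
    el_dil = k_el * eps.trace * lam
    return PlaneTensor(
        visc.t22 + dil + k_el * eps.t22 + el_dil,
        visc.t23 + k_el * eps.t23,
        visc.t33 + dil + k_el * eps.t33 + el_dil,
    )


def traction_stress(M, rho, params) -> PlaneTensor:
    """Isotropic myofibroblast pulling stress psi = xi M rho/(R^2 + rho^2) I.

    The body force in the momentum balance is f = div psi; the saturating
    collagen dependence peaks at rho = R_const.
    """
    psi = params.xi * np.asarray(M, dtype=float) * rho / (params.R_const**2 + np.asarray(rho, dtype=float) ** 2)
    return PlaneTensor(psi, np.zeros_like(psi) if np.ndim(psi) else 0.0, psi)


def growth_tensor(eps: PlaneTensor, point, params) -> PlaneTensor:
    """Rate of active (plastic-like) strain change.

    G = zeta (N + eta_II M) c / (1 + a_c_III c) * eps: remodeling is driven
    by MMP activity and the signaling molecule, and acts along the current
    effective strain (the collagen concentration cancels against the MMP
    level).
    """
    factor = (
        params.zeta
        * (point.N + params.eta_II * point.M)
        * point.c
        / (1.0 + params.a_c_III * point.c)
    )
    return eps.scaled(factor)


def morphoelastic_rate_coefficient(point, params):
    """The scalar k with de/dt = -zeta k e in the homogeneous reduction."""
    return (point.N + params.eta_II * point.M) * point.c / (1.0 + params.a_c_III * point.c)


def strain_rate(eps: PlaneTensor, L: VelocityGradient, G: PlaneTensor) -> PlaneTensor:
    """Material rate of the effective strain.

    D eps/Dt = -[tr(eps) - 1] sym(L) - G - eps skw(L) + skw(L) eps; the
    Jaumann spin correction is moved to the right-hand side, and the result
    is symmetric whenever eps is.
    """
    symL = L.sym()
    w = L.spin()
    coef = -(eps.trace - 1.0)
    return PlaneTensor(
        coef * symL.t22 - G.t22 + 2.0 * w * eps.t23,
        coef * symL.t23 - G.t23 + w * (eps.t33 - eps.t22),
        coef * symL.t33 - G.t33 - 2.0 * w * eps.t23,
    )
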