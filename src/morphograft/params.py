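"""Dimensional model parameters: loading, validation, and equilibrium completion.

All quantities use the cm / day / g / cells unit convention. The unwounded
dermis is characterized by the equilibrium state (N_bar, M_bar, c_bar,
rho_bar); a subset of the rate constants is a necessary consequence of the
values chosen for the others, because the equilibrium must be a fixed point
of the reaction kinetics. :func:`derive_equilibrium_parameters` completes a
partial parameter set accordingly.
"""

from __future__ import annotations

import dataclasses
import json
import math
import tomllib
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
from scipy import optimize

__all__ = [
    "ModelParameters",
    "ParameterError",
    "load_parameters",
    "default_parameters",
    "derive_equilibrium_parameters",
    "equilibrium_residuals",
]


class ParameterError(ValueError):
    """Raised for parse failures, unknown keys, or invariant violations."""


@dataclass(frozen=True)
class ModelParameters:
    """Complete dimensional parameter set of the contraction model.

    Units: rates 1/day (or per the docstrings in the default parameter
    file), densities cells/cm^3, concentrations g/cm^3, moduli N/cm^2,
    lengths cm, times day.
    """

    # (myo)fibroblast kinetics
    r_F: float
    r_F_max: float
    a_c_I: float
    kappa_F: float
    q: float
    k_F: float
    delta_N: float
    delta_M: float
    # cell transport
    D_F: float
    chi_F: float
    # signaling molecule
    k_c: float
    eta_I: float
    eta_II: float
    a_c_II: float
    a_c_III: float
    a_c_IV: float
    delta_c: float
    D_c: float
    # collagen
    k_rho: float
    k_rho_max: float
    delta_rho: float
    # mechanics
    mu_1: float
    mu_2: float
    nu: float
    E_I: float
    xi: float
    R_const: float
    zeta: float
    rho_t: float
    # equilibria / initial conditions
    N_bar: float
    M_bar: float
    c_bar: float
    rho_bar: float
    c_w: float
    I_w: float
    # graft geometry
    s1: float
    s2: float
    theta_r: float

    def __post_init__(self) -> None:
        self.validate()

    # fields that must be non-negative (rates, densities, concentrations, moduli)
    _NONNEGATIVE = (
        "r_F", "r_F_max", "a_c_I", "kappa_F", "k_F", "delta_N", "delta_M",
        "D_F", "chi_F", "k_c", "eta_I", "eta_II", "a_c_II", "a_c_III",
        "a_c_IV", "delta_c", "D_c", "k_rho", "k_rho_max", "delta_rho",
        "mu_1", "mu_2", "E_I", "xi", "R_const", "zeta", "rho_t",
        "N_bar", "M_bar", "c_bar", "rho_bar", "c_w",
    )

    def validate(self) -> None:
        for name in self._NONNEGATIVE:
            value = getattr(self, name)
            if not np.isfinite(value) or value < 0:
                raise ParameterError(f"{name} must be >= 0 and finite, got {value!r}")
        if not 0.0 < self.nu < 0.5:
            raise ParameterError(f"nu out of (0, 0.5): got {self.nu!r}")
        if not 0.0 <= self.I_w <= 1.0:
            raise ParameterError(f"I_w out of [0, 1]: got {self.I_w!r}")
        if not self.s2 > 0:
            raise ParameterError(f"s2 must be > 0, got {self.s2!r}")
        if not self.s1 >= 0:
            raise ParameterError(f"s1 must be >= 0, got {self.s1!r}")
        if not self.kappa_F * self.N_bar < 1.0:
            raise ParameterError(
                f"kappa_F*N_bar must be < 1, got {self.kappa_F * self.N_bar!r}"
            )
        if not self.q > -1.0:
            raise ParameterError(f"q must be > -1 (so 1+q > 0), got {self.q!r}")

    def replace(self, **changes: float) -> "ModelParameters":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)

    def to_json(self, path: str | Path | None = None) -> str:
        """JSON export of the (completed) parameter set for provenance."""
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


_FIELD_NAMES = tuple(f.name for f in dataclasses.fields(ModelParameters))


def _default_dict() -> dict[str, float]:
    source = resources.files("morphograft").joinpath("data/default_parameters.toml")
    return tomllib.loads(source.read_text())


def load_parameters(source: str | Path | dict | None = None) -> ModelParameters:
    """Load a parameter set from TOML text, a TOML file path, or a mapping.

    Keys absent from ``source`` fall back to the packaged defaults; unknown
    keys are rejected by name. ``None`` returns the defaults (without
    equilibrium completion; see :func:`default_parameters`).
    """
    if source is None:
        data: dict[str, float] = {}
    elif isinstance(source, dict):
        data = dict(source)
    else:
        text = None
        if isinstance(source, Path) or (
            isinstance(source, str) and "\n" not in source and source.endswith(".toml")
        ):
            text = Path(source).read_text()
        else:
            text = str(source)
        try:
            data = tomllib.loads(text)
        except tomllib.TOMLDecodeError as exc:
            raise ParameterError(f"could not parse parameter source: {exc}") from exc

    unknown = sorted(set(data) - set(_FIELD_NAMES))
    if unknown:
        raise ParameterError(f"unknown parameter keys: {', '.join(unknown)}")
    merged = _default_dict()
    merged.update(data)
    try:
        values = {k: float(merged[k]) for k in _FIELD_NAMES}
    except KeyError as exc:
        raise ParameterError(f"missing required parameter: {exc.args[0]}") from exc
    return ModelParameters(**values)


def equilibrium_residuals(params: ModelParameters) -> dict[str, float]:
    """Reaction residuals R_N, R_M, R_c, R_rho at the unwounded equilibrium."""
    from . import kinetics  # local import to avoid a cycle at module load

    p = kinetics.ConstituentPoint(
        N=params.N_bar, M=params.M_bar, c=params.c_bar, rho=params.rho_bar
    )
    return {
        "R_N": float(kinetics.reaction_fibroblasts(p, params)),
        "R_M": float(kinetics.reaction_myofibroblasts(p, params)),
        "R_c": float(kinetics.reaction_signal(p, params)),
        "R_rho": float(kinetics.reaction_collagen(p, params)),
    }


_RESIDUAL_TOL = 1e-10


def derive_equilibrium_parameters(
    partial: ModelParameters,
    unknowns: tuple[str, ...] | list[str] = ("delta_N", "k_rho"),
) -> ModelParameters:
    """Complete ``partial`` so the unwounded state is an exact reaction fixed point.

    Solves R_N = R_M = R_c = R_rho = 0 at (N_bar, M_bar, c_bar, rho_bar) for
    the named ``unknowns`` (at most 3). Constraints that vanish identically
    (e.g. R_M and R_c when M_bar = c_bar = 0, since every term carries a
    factor M or c) are dropped automatically. Closed forms are used for the
    default unknowns; other combinations fall back to a damped Newton solve.
    """
    unknowns = tuple(unknowns)
    if len(unknowns) > 3:
        raise ParameterError("at most 3 unknowns can be derived")
    for name in unknowns:
        if name not in _FIELD_NAMES:
            raise ParameterError(f"unknown parameter name: {name}")

    # Closed forms for the canonical case M_bar = c_bar = 0.
    if (
        partial.M_bar == 0.0
        and partial.c_bar == 0.0
        and set(unknowns) <= {"delta_N", "k_rho"}
    ):
        changes: dict[str, float] = {}
        if "delta_N" in unknowns:
            changes["delta_N"] = (
                partial.r_F
                * (1.0 - partial.kappa_F * partial.N_bar)
                * partial.N_bar**partial.q
            )
        if "k_rho" in unknowns:
            changes["k_rho"] = partial.delta_rho * partial.rho_bar**2
        completed = partial.replace(**changes)
        _check_completed(completed)
        return completed

    return _derive_numeric(partial, unknowns)


def _residual_vector(params: ModelParameters) -> np.ndarray:
    res = equilibrium_residuals(params)
    return np.array([res["R_N"], res["R_M"], res["R_c"], res["R_rho"]])


def _derive_numeric(
    partial: ModelParameters, unknowns: tuple[str, ...]
) -> ModelParameters:
    x0 = np.array([max(getattr(partial, u), 1e-30) for u in unknowns])

    def apply(x: np.ndarray) -> ModelParameters:
        return partial.replace(**{u: float(v) for u, v in zip(unknowns, x)})

    # Identify active (non-structurally-zero) constraints by probing.
    base = _residual_vector(partial)
    scale = np.maximum(np.abs(base), 1e-30)
    probes = [_residual_vector(apply(x0 * (1 + 0.5 * (i + 1)))) for i in range(2)]
    active = np.abs(base) > 0
    for pr in probes:
        active |= np.abs(pr - base) > 0
    idx = np.flatnonzero(active)
    if len(idx) == 0:
        _check_completed(partial)
        return partial
    if len(idx) != len(unknowns):
        raise ParameterError(
            f"{len(idx)} active equilibrium constraints but {len(unknowns)} unknowns; "
            "system is over- or under-determined"
        )

    def fun(x: np.ndarray) -> np.ndarray:
        return _residual_vector(apply(x))[idx]

    sol = optimize.least_squares(fun, x0, xtol=1e-15, ftol=1e-15, gtol=1e-15)
    completed = apply(sol.x)
    for u in unknowns:
        if u in ModelParameters._NONNEGATIVE and getattr(completed, u) < 0:
            raise ParameterError(f"derived value for {u} is negative")
    _check_completed(completed)
    return completed


def _check_completed(params: ModelParameters) -> None:
    res = _residual_vector(params)
    worst = float(np.max(np.abs(res)))
    if worst > _RESIDUAL_TOL:
        raise ParameterError(
            f"equilibrium constraints not satisfied: max |residual| = {worst:.3e} "
            "in the equations' natural units"
        )


def default_parameters(**overrides: float) -> ModelParameters:
    """The packaged defaults, equilibrium-completed, with optional overrides."""
    params = load_parameters(overrides or None)
    return derive_equilibrium_parameters(params)
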