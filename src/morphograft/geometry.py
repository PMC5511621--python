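"""Computational slice, graft indicator, initial fields, and tracer polygon.

The domain is a square box [-hw, hw]^2 in the Lagrangian (Y, Z) plane of an
infinitely thin dermal slice. The skin graft is a rotated square described
by a smooth indicator w in [0, 1]: w = 0 on grafted dermis, w = 1 on
unwounded dermis, with a sinusoidal blend of half-width s2 across the graft
boundary (the square of half-side s1, rotated by theta_r). Material tracer
points on the w = 1/2 level set form the polygon whose displaced shoelace
area measures graft contraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import ModelParameters

__all__ = [
    "Mesh",
    "StateFields",
    "TracerSet",
    "ramp",
    "graft_indicator",
    "build_mesh",
    "initial_state",
    "place_tracers",
    "shoelace_area",
]


@dataclass
class Mesh:
    """Conforming P1 triangulation with Lagrangian reference and moved coordinates.

    ``ref_coords`` are fixed material coordinates; ``cur_coords`` = reference +
    displacement follow the tissue (pure Lagrangian moving grid).
    ``vertex_parents[i]`` is (-1, -1) for original nodes, else the two edge
    endpoints whose midpoint node i is (refinement genealogy).
    """

    ref_coords: np.ndarray          # (n, 2)
    cur_coords: np.ndarray          # (n, 2)
    triangles: np.ndarray           # (m, 3) int
    boundary_mask: np.ndarray       # (n,) bool
    level: np.ndarray               # (m,) int refinement level
    parent: np.ndarray              # (m,) int parent record id, -1 for roots
    vertex_parents: np.ndarray = None  # (n, 2) int
    half_width: float = 10.0
    # archived parent-element records for recoarsement: list of dicts
    genealogy: list = field(default_factory=list)

    def __post_init__(self):
        if self.vertex_parents is None:
            self.vertex_parents = np.full((len(self.ref_coords), 2), -1, dtype=int)

    @property
    def n_nodes(self) -> int:
        return len(self.ref_coords)

    @property
    def n_elements(self) -> int:
        return len(self.triangles)

    def element_areas(self, current: bool = True) -> np.ndarray:
        """Signed triangle areas (positive for the stored CCW orientation)."""
        xy = self.cur_coords if current else self.ref_coords
        a, b, c = (xy[self.triangles[:, k]] for k in range(3))
        return 0.5 * ((b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1])
                      - (c[:, 0] - a[:, 0]) * (b[:, 1] - a[:, 1]))

    def copy(self) -> "Mesh":
        return Mesh(
            self.ref_coords.copy(), self.cur_coords.copy(), self.triangles.copy(),
            self.boundary_mask.copy(), self.level.copy(), self.parent.copy(),
            self.vertex_parents.copy(), self.half_width, list(self.genealogy),
        )


@dataclass
class StateFields:
    """Nodal fields: constituents, displacement, velocity, effective strain.

    The strain storage realizes the slice reduction: only eps22, eps23
    (= eps32) and eps33 can be nonzero; the trace used by the mechanics is
    eps22 + eps33. ``graft_marker`` is the material graft indicator w,
    carried along for refinement indicators and plotting.
    """

    N: np.ndarray
    M: np.ndarray
    c: np.ndarray
    rho: np.ndarray
    u: np.ndarray        # (n, 2) displacement (v-, w-components), cm
    v: np.ndarray        # (n, 2) velocity (v2, v3), cm/day
    eps22: np.ndarray
    eps23: np.ndarray
    eps33: np.ndarray
    graft_marker: np.ndarray = None

    CONSTITUENTS = ("N", "M", "c", "rho")

    def __post_init__(self):
        if self.graft_marker is None:
            self.graft_marker = np.ones_like(self.N)

    def copy(self) -> "StateFields":
        return StateFields(
            self.N.copy(), self.M.copy(), self.c.copy(), self.rho.copy(),
            self.u.copy(), self.v.copy(),
            self.eps22.copy(), self.eps23.copy(), self.eps33.copy(),
            self.graft_marker.copy(),
        )

    def strain_frobenius(self) -> np.ndarray:
        return np.sqrt(self.eps22**2 + 2.0 * self.eps23**2 + self.eps33**2)


@dataclass
class TracerSet:
    """Material points on the graft boundary, ordered counterclockwise."""

    ref_points: np.ndarray  # (k, 2)

    @property
    def reference_area(self) -> float:
        return shoelace_area(self.ref_points)


def shoelace_area(points: np.ndarray) -> float:
    """Signed polygon area by the shoelace formula (positive for CCW order)."""
    p = np.asarray(points, dtype=float)
    x, y = p[:, 0], p[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def ramp(r, s1: float, s2: float):
    """One-sided sinusoidal ramp: 0 below s1 - s2, 1 above s1 + s2.

    Continuous and non-decreasing in r, with the blend
    (1 + sin((r - s1) pi / (2 s2))) / 2 on |r - s1| <= s2.
    """
    if s2 <= 0:
        raise ValueError(f"s2 must be > 0, got {s2!r}")
    r = np.asarray(r, dtype=float)
    out = 0.5 * (1.0 + np.sin((r - s1) * np.pi / (2.0 * s2)))
    out = np.where(r < s1 - s2, 0.0, out)
    out = np.where(r > s1 + s2, 1.0, out)
    return out if out.ndim else float(out)


def _bump(r, s1: float, s2: float):
    """1 on |r| < s1 - s2, 0 for |r| > s1 + s2, smooth blend between."""
    return (1.0 - ramp(r, s1, s2)) * ramp(r, -s1, s2)


def graft_indicator(Y, Z, params: ModelParameters):
    """Graft shape indicator w(Y, Z) in [0, 1].

    The point is rotated by theta_r about the out-of-plane axis and tested
    against a square of half-side s1: w = 1 - B(Y_r) B(Z_r) where B is a
    smooth bump of half-width s1 and blend width 2 s2. w = 0 on the grafted
    core, w = 1 in the far-field unwounded dermis, and w is invariant under
    (Y, Z) -> (-Y, -Z).
    """
    ct, st = np.cos(params.theta_r), np.sin(params.theta_r)
    Y = np.asarray(Y, dtype=float)
    Z = np.asarray(Z, dtype=float)
    Yr = ct * Y - st * Z
    Zr = st * Y + ct * Z
    w = 1.0 - _bump(Yr, params.s1, params.s2) * _bump(Zr, params.s1, params.s2)
    return w if np.ndim(w) else float(w)


def build_mesh(
    half_width: float = 10.0,
    target_edge: float = 1.0,
    symmetric: bool = True,
) -> Mesh:
    """Uniform right-triangle mesh of [-half_width, half_width]^2.

    Each grid cell is split along the same diagonal; that pattern is
    invariant under the point reflection (Y, Z) -> (-Y, -Z) when the cell
    count is even, which ``symmetric=True`` enforces.
    """
    if half_width <= 0 or target_edge <= 0:
        raise ValueError("half_width and target_edge must be > 0")
    n_cells = max(2, int(np.ceil(2.0 * half_width / target_edge)))
    if symmetric and n_cells % 2:
        n_cells += 1
    ticks = np.linspace(-half_width, half_width, n_cells + 1)
    YY, ZZ = np.meshgrid(ticks, ticks, indexing="xy")
    coords = np.column_stack([YY.ravel(), ZZ.ravel()])

    def nid(i, j):  # column i (Y), row j (Z)
        return j * (n_cells + 1) + i

    tris = []
    for j in range(n_cells):
        for i in range(n_cells):
            n00, n10 = nid(i, j), nid(i + 1, j)
            n01, n11 = nid(i, j + 1), nid(i + 1, j + 1)
            tris.append((n00, n10, n11))  # lower triangle, CCW
            tris.append((n00, n11, n01))  # upper triangle, CCW
    triangles = np.array(tris, dtype=int)
    boundary = (
        (np.abs(coords[:, 0]) >= half_width - 1e-12)
        | (np.abs(coords[:, 1]) >= half_width - 1e-12)
    )
    m = len(triangles)
    return Mesh(
        ref_coords=coords,
        cur_coords=coords.copy(),
        triangles=triangles,
        boundary_mask=boundary,
        level=np.zeros(m, dtype=int),
        parent=np.full(m, -1, dtype=int),
        half_width=half_width,
    )


def initial_state(mesh: Mesh, params: ModelParameters) -> StateFields:
    """Post-grafting initial fields.

    N = {I_w + (1 - I_w) w} N_bar (a reduced fibroblast population inside
    the graft), M = M_bar, c = (1 - w) c_w + w c_bar (signal present in the
    grafted area), rho = rho_bar, and a mechanically virgin state
    u = v = 0, eps = 0.
    """
    Y, Z = mesh.ref_coords[:, 0], mesh.ref_coords[:, 1]
    w = graft_indicator(Y, Z, params)
    n = mesh.n_nodes
    return StateFields(
        N=(params.I_w + (1.0 - params.I_w) * w) * params.N_bar,
        M=np.full(n, params.M_bar),
        c=(1.0 - w) * params.c_w + w * params.c_bar,
        rho=np.full(n, params.rho_bar),
        u=np.zeros((n, 2)),
        v=np.zeros((n, 2)),
        eps22=np.zeros(n),
        eps23=np.zeros(n),
        eps33=np.zeros(n),
        graft_marker=np.asarray(w, dtype=float),
    )


def place_tracers(params: ModelParameters, n_per_side: int = 2) -> TracerSet:
    """Material tracer points on the w = 1/2 graft boundary, CCW order.

    The boundary is the square of half-side s1 in the rotated frame; each
    side carries ``n_per_side`` evenly spaced points starting at its corner
    (n_per_side = 1 gives the 4 corners, 2 adds the edge midpoints).
    """
    if n_per_side < 1:
        raise ValueError("n_per_side must be >= 1")
    s1 = params.s1
    corners = np.array([(-s1, -s1), (s1, -s1), (s1, s1), (-s1, s1)])
    pts = []
    for k in range(4):
        a, b = corners[k], corners[(k + 1) % 4]
        for frac in np.arange(n_per_side) / n_per_side:
            pts.append(a + frac * (b - a))
    pts = np.array(pts)
    # inverse rotation back to the lab frame (w uses X_r = R(theta_r) X)
    ct, st = np.cos(params.theta_r), np.sin(params.theta_r)
    lab = np.column_stack([ct * pts[:, 0] + st * pts[:, 1],
                           -st * pts[:, 0] + ct * pts[:, 1]])
    return TracerSet(ref_points=lab)
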