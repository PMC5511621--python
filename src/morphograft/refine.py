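"""Conforming mesh refinement and recoarsement by longest-edge bisection.

Flagged triangles are bisected at the midpoint of their longest reference
edge (Rivara's algorithm): if the neighbor across that edge does not share
it as its own longest edge, the neighbor is refined first, recursively, so
the mesh never contains hanging nodes. Every bisection archives the parent
triangle in the mesh genealogy, which recoarsement consults to merge
sibling pairs back and delete their midpoint node. Nodal state is
transferred by linear interpolation; a lumped redistribution step restores
the per-constituent mass lost where a removed midpoint was no longer the
linear interpolant of its edge endpoints.
"""

from __future__ import annotations

import warnings
from collections import defaultdict, deque

import numpy as np

from .geometry import Mesh, StateFields

__all__ = ["refine_elements", "recoarsen", "refine_recoarsen", "element_indicator"]

_SCALAR_FIELDS = ("N", "M", "c", "rho", "eps22", "eps23", "eps33", "graft_marker")
_VECTOR_FIELDS = ("u", "v")


def _edge_len2(coords, a, b):
    d = coords[a] - coords[b]
    return float(d @ d)


def _reorder_longest(tri, coords):
    """Cyclic rotation of (v0, v1, v2) so the longest edge is (v0, v1)."""
    i0, i1, i2 = tri
    lengths = (
        _edge_len2(coords, i0, i1),
        _edge_len2(coords, i1, i2),
        _edge_len2(coords, i2, i0),
    )
    k = int(np.argmax(lengths))  # first maximum: deterministic tie-break
    if k == 0:
        return i0, i1, i2
    if k == 1:
        return i1, i2, i0
    return i2, i0, i1


class _Worker:
    """Mutable mesh/state view used during refinement passes."""

    def __init__(self, mesh: Mesh, state: StateFields):
        self.mesh = mesh.copy()
        self.state = state.copy()
        self.tris = [tuple(t) for t in self.mesh.triangles]
        self.level = list(self.mesh.level)
        self.parent = list(self.mesh.parent)
        self.alive = [True] * len(self.tris)
        self.ref = [tuple(p) for p in self.mesh.ref_coords]
        self.cur = [tuple(p) for p in self.mesh.cur_coords]
        self.boundary = list(self.mesh.boundary_mask)
        self.vparents = [tuple(p) for p in self.mesh.vertex_parents]
        self.fields = {k: list(getattr(self.state, k)) for k in _SCALAR_FIELDS}
        self.vfields = {k: [tuple(r) for r in getattr(self.state, k)] for k in _VECTOR_FIELDS}
        self.genealogy = list(self.mesh.genealogy)
        self.edge_map: dict[tuple, set] = defaultdict(set)
        for e, tri in enumerate(self.tris):
            for key in self._edge_keys(tri):
                self.edge_map[key].add(e)

    @staticmethod
    def _edge_keys(tri):
        a, b, c = tri
        return (
            (min(a, b), max(a, b)),
            (min(b, c), max(b, c)),
            (min(c, a), max(c, a)),
        )

    def neighbor(self, e, a, b):
        key = (min(a, b), max(a, b))
        for t in self.edge_map[key]:
            if t != e and self.alive[t]:
                return t
        return None

    def _new_midnode(self, a, b):
        ref = tuple((np.array(self.ref[a]) + np.array(self.ref[b])) / 2.0)
        cur = tuple((np.array(self.cur[a]) + np.array(self.cur[b])) / 2.0)
        hw = self.mesh.half_width
        on_bd = bool(
            self.boundary[a]
            and self.boundary[b]
            and (abs(abs(ref[0]) - hw) < 1e-12 or abs(abs(ref[1]) - hw) < 1e-12)
            and (
                abs(self.ref[a][0] - self.ref[b][0]) < 1e-12
                or abs(self.ref[a][1] - self.ref[b][1]) < 1e-12
            )
        )
        self.ref.append(ref)
        self.cur.append(cur)
        self.boundary.append(on_bd)
        self.vparents.append((a, b))
        for k in _SCALAR_FIELDS:
            vals = self.fields[k]
            vals.append(0.5 * (vals[a] + vals[b]))
        for k in _VECTOR_FIELDS:
            vals = self.vfields[k]
            vals.append(tuple((np.array(vals[a]) + np.array(vals[b])) / 2.0))
        return len(self.ref) - 1

    def _add_element(self, tri, level, parent):
        self.tris.append(tuple(tri))
        self.level.append(level)
        self.parent.append(parent)
        self.alive.append(True)
        e = len(self.tris) - 1
        for key in self._edge_keys(tri):
            self.edge_map[key].add(e)
        return e

    def _remove_element(self, e):
        self.alive[e] = False
        for key in self._edge_keys(self.tris[e]):
            self.edge_map[key].discard(e)

    def _bisect(self, e, m, a, b):
        """Split element e across edge (a, b) at existing midnode m."""
        tri = _reorder_longest(self.tris[e], np.array(self.ref))
        v0, v1, v2 = tri
        assert {v0, v1} == {a, b}
        rec_id = len(self.genealogy)
        self.genealogy.append(
            {"nodes": (v0, v1, v2), "level": self.level[e], "parent": self.parent[e], "mid": m}
        )
        lv = self.level[e] + 1
        self._remove_element(e)
        self._add_element((v2, v0, m), lv, rec_id)
        self._add_element((v1, v2, m), lv, rec_id)

    def refine(self, flagged):
        stack = list(sorted(flagged, reverse=True))
        guard = 0
        while stack:
            guard += 1
            if guard > 100 * (len(self.tris) + 10):
                raise RuntimeError("refinement propagation did not terminate")
            t = stack[-1]
            if not self.alive[t]:
                stack.pop()
                continue
            coords = np.array(self.ref)
            a, b, _ = _reorder_longest(self.tris[t], coords)
            nb = self.neighbor(t, a, b)
            if nb is not None:
                na, nbb, _ = _reorder_longest(self.tris[nb], coords)
                if {na, nbb} != {a, b}:
                    stack.append(nb)
                    continue
            m = self._new_midnode(a, b)
            self._bisect(t, m, a, b)
            if nb is not None:
                self._bisect(nb, m, a, b)
            stack.pop()

    def recoarsen(self, coarsen_flags):
        """Merge sibling pairs whose midpoint star is fully coarsenable."""
        # group alive children by parent record
        children = defaultdict(list)
        for e, al in enumerate(self.alive):
            if al and self.parent[e] >= 0:
                children[self.parent[e]].append(e)
        # elements touching each node
        touching = defaultdict(set)
        for e, al in enumerate(self.alive):
            if al:
                for v in self.tris[e]:
                    touching[v].add(e)
        # candidate mid nodes, deepest level first
        recs_by_mid = defaultdict(list)
        for rec_id, elems in children.items():
            rec = self.genealogy[rec_id]
            if rec is None or len(elems) != 2:
                continue
            recs_by_mid[rec["mid"]].append(rec_id)
        removed_nodes = []
        order = sorted(
            recs_by_mid,
            key=lambda m: -max(self.level[e] for r in recs_by_mid[m] for e in children[r]),
        )
        for m in order:
            rec_ids = recs_by_mid[m]
            star = set()
            for r in rec_ids:
                star.update(children[r])
            if star != touching[m]:
                continue  # other elements still use the midnode
            if not all(coarsen_flags(e) for e in star):
                continue
            for r in rec_ids:
                rec = self.genealogy[r]
                for e in children[r]:
                    self._remove_element(e)
                restored = self._add_element(rec["nodes"], rec["level"], rec["parent"])
                for v in rec["nodes"]:
                    touching[v].add(restored)
                    touching[v] -= {e for e in children[r]}
                self.genealogy[r] = None
            for e in star:
                for v in self.tris[e]:
                    touching[v].discard(e)
            del touching[m]
            removed_nodes.append(m)
        return removed_nodes

    def finish(self, removed_nodes=()):
        """Compact node/element arrays into a fresh Mesh + StateFields."""
        keep = np.ones(len(self.ref), dtype=bool)
        keep[list(removed_nodes)] = False
        node_map = -np.ones(len(self.ref), dtype=int)
        node_map[keep] = np.arange(int(keep.sum()))

        alive_ids = [e for e, al in enumerate(self.alive) if al]
        tris = np.array([[node_map[v] for v in self.tris[e]] for e in alive_ids], dtype=int)
        if (tris < 0).any():
            raise RuntimeError("an active element references a removed node")
        genealogy = []
        for rec in self.genealogy:
            if rec is None:
                genealogy.append(None)
                continue
            nodes = tuple(int(node_map[v]) for v in rec["nodes"])
            mid = int(node_map[rec["mid"]]) if keep[rec["mid"]] else -1
            if min(nodes) < 0:
                genealogy.append(None)  # stale record below removed nodes
                continue
            genealogy.append({**rec, "nodes": nodes, "mid": mid})

        ref = np.array(self.ref)[keep]
        cur = np.array(self.cur)[keep]
        vparents = []
        for i in np.flatnonzero(keep):
            a, b = self.vparents[i]
            if a < 0:
                vparents.append((-1, -1))
            else:
                vparents.append((int(node_map[a]), int(node_map[b])))
        mesh = Mesh(
            ref_coords=ref,
            cur_coords=cur,
            triangles=tris,
            boundary_mask=np.array(self.boundary)[keep],
            level=np.array([self.level[e] for e in alive_ids], dtype=int),
            parent=np.array([self.parent[e] for e in alive_ids], dtype=int),
            vertex_parents=np.array(vparents, dtype=int),
            half_width=self.mesh.half_width,
            genealogy=genealogy,
        )
        kw = {}
        for k in _SCALAR_FIELDS:
            kw[k] = np.array(self.fields[k])[keep]
        for k in _VECTOR_FIELDS:
            kw[k] = np.array(self.vfields[k])[keep]
        state = StateFields(
            N=kw["N"], M=kw["M"], c=kw["c"], rho=kw["rho"], u=kw["u"], v=kw["v"],
            eps22=kw["eps22"], eps23=kw["eps23"], eps33=kw["eps33"],
            graft_marker=kw["graft_marker"],
        )
        return mesh, state


def _consistent_integrals(mesh: Mesh, state: StateFields) -> dict:
    areas = mesh.element_areas(current=True)
    out = {}
    for k in ("N", "M", "c", "rho"):
        z = getattr(state, k)
        out[k] = float(np.sum(areas * z[mesh.triangles].sum(axis=1) / 3.0))
    return out


def refine_elements(
    mesh: Mesh, state: StateFields, flags, max_level: int | None = None
) -> tuple[Mesh, StateFields]:
    """Bisect the flagged elements (plus conformity closure); interpolate state."""
    flags = np.asarray(flags)
    if flags.dtype == bool:
        flagged = np.flatnonzero(flags)
    else:
        flagged = flags.astype(int)
    if max_level is not None:
        over = [e for e in flagged if mesh.level[e] >= max_level]
        if over:
            warnings.warn(
                f"refinement level cap {max_level} reached for {len(over)} element(s); skipped",
                stacklevel=2,
            )
        flagged = [e for e in flagged if mesh.level[e] < max_level]
    if len(flagged) == 0:
        return mesh, state
    w = _Worker(mesh, state)
    w.refine(flagged)
    return w.finish()


def recoarsen(
    mesh: Mesh, state: StateFields, flags=None, conserve_mass: bool = True
) -> tuple[Mesh, StateFields]:
    """Merge coarsenable sibling pairs back to their parents.

    ``flags`` marks elements allowed to coarsen (None = all). Surviving
    nodes keep their values (linear restriction); the constituent mass
    removed with each midpoint node is redistributed over the restored
    parent nodes so the domain integral is preserved.
    """
    if flags is None:
        allowed = lambda e: True  # noqa: E731
    else:
        arr = np.asarray(flags, dtype=bool)
        allowed = lambda e: bool(arr[e]) if e < len(arr) else True  # noqa: E731
    before = _consistent_integrals(mesh, state)
    w = _Worker(mesh, state)
    removed = w.recoarsen(allowed)
    if not removed:
        return mesh, state
    new_mesh, new_state = w.finish(removed)
    if conserve_mass:
        _restore_mass(new_mesh, new_state, before)
    return new_mesh, new_state


def _restore_mass(mesh: Mesh, state: StateFields, before: dict) -> None:
    from .fem_engine import lumped_mass, precompute_geometry

    after = _consistent_integrals(mesh, state)
    geo = precompute_geometry(mesh.cur_coords, mesh.triangles)
    ml = lumped_mass(geo)
    total = float(ml.sum())
    for k in ("N", "M", "c", "rho"):
        deficit = before[k] - after[k]
        if deficit == 0.0:
            continue
        z = getattr(state, k)
        znew = np.maximum(z + deficit / total, 0.0)
        setattr(state, k, znew)


def element_indicator(mesh: Mesh, state: StateFields, c_floor: float = 1e-12) -> np.ndarray:
    """Default refinement indicator: scaled signal gradient + graft-edge marker."""
    from .fem_engine import element_gradient, precompute_geometry

    geo = precompute_geometry(mesh.cur_coords, mesh.triangles)
    h = np.sqrt(2.0 * geo.area)
    gc = element_gradient(geo, state.c)
    gw = element_gradient(geo, state.graft_marker)
    c_scale = max(float(np.max(np.abs(state.c))), c_floor)
    return h * (np.linalg.norm(gc, axis=1) / c_scale + np.linalg.norm(gw, axis=1))


def refine_recoarsen(
    mesh: Mesh,
    state: StateFields,
    indicator_threshold: float,
    max_level: int = 2,
    coarsen_ratio: float = 0.1,
) -> tuple[Mesh, StateFields]:
    """One adapt cycle: bisect high-indicator elements, merge low-indicator ones."""
    ind = element_indicator(mesh, state)
    refine_flags = ind > indicator_threshold
    if refine_flags.any():
        mesh, state = refine_elements(mesh, state, refine_flags, max_level=max_level)
        ind = element_indicator(mesh, state)
    coarse_flags = ind < coarsen_ratio * indicator_threshold
    if coarse_flags.any():
        mesh, state = recoarsen(mesh, state, coarse_flags)
    return mesh, state
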