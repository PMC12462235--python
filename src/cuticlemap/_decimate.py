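"""Quadric edge-collapse mesh decimation.

Garland–Heckbert style simplification targeting an exact vertex budget:
each collapse removes one vertex, so the requested vertex count is hit
exactly whenever enough valid collapses exist.  Candidate placements per
edge are the two endpoints and the midpoint (no 4x4 solve); collapses that
would flip a face normal, create a degenerate face, or violate the edge
link condition (non-manifold result) are rejected.  Deterministic: heap
ties break on insertion order.
"""

from __future__ import annotations

import heapq

import numpy as np

__all__ = ["quadric_decimate"]


def _tri_normal(a, b, c):
    ux, uy, uz = b[0] - a[0], b[1] - a[1], b[2] - a[2]
    vx, vy, vz = c[0] - a[0], c[1] - a[1], c[2] - a[2]
    return (uy * vz - uz * vy, uz * vx - ux * vz, ux * vy - uy * vx)


def _dot3(a, b):
    return a[0] * b[0] + a[1] * b[1] + a[2] * b[2]


def _vertex_quadrics(V: np.ndarray, F: np.ndarray) -> np.ndarray:
    e1 = V[F[:, 1]] - V[F[:, 0]]
    e2 = V[F[:, 2]] - V[F[:, 0]]
    n = np.cross(e1, e2)
    norm = np.linalg.norm(n, axis=1)
    ok = norm > 1e-12
    n[ok] /= norm[ok, None]
    d = -np.einsum("ij,ij->i", n, V[F[:, 0]])
    p = np.concatenate([n, d[:, None]], axis=1)  # plane (a, b, c, d)
    K = np.einsum("ij,ik->ijk", p, p)
    Q = np.zeros((len(V), 4, 4))
    for col in range(3):
        np.add.at(Q, F[:, col], K)
    return Q


def quadric_decimate(
    vertices: np.ndarray, faces: np.ndarray, target_vertices: int
) -> tuple[np.ndarray, np.ndarray]:
    """Collapse edges until ``target_vertices`` remain.

    Returns (vertices, faces) of the simplified mesh.  Face winding (hence
    orientation) of surviving faces is preserved.
    """
    V = np.asarray(vertices, dtype=np.float64).copy()
    F = np.asarray(faces, dtype=np.int64).copy()
    nv = len(V)
    target = int(target_vertices)
    if target < 4:
        raise ValueError("target vertex count must be at least 4")
    if target >= nv:
        return V.copy(), F.copy()

    Q = _vertex_quadrics(V, F)
    vert_faces: list[set[int]] = [set() for _ in range(nv)]
    for fi, (a, b, c) in enumerate(F):
        vert_faces[a].add(fi)
        vert_faces[b].add(fi)
        vert_faces[c].add(fi)
    nbrs: list[set[int]] = [set() for _ in range(nv)]
    for a, b, c in F:
        nbrs[a].update((b, c))
        nbrs[b].update((a, c))
        nbrs[c].update((a, b))

    alive_v = np.ones(nv, dtype=bool)
    alive_f = np.ones(len(F), dtype=bool)
    stamps = np.zeros(nv, dtype=np.int64)

    def edge_cost(u: int, v: int):
        """Quadric cost plus a tiny edge-length term that breaks the flat-
        region ties (otherwise collapses pile onto single vertices and the
        mesh degenerates).  Returns candidate placements cheapest-first:
        midpoint, then the two endpoints."""
        Qe = Q[u] + Q[v]
        d = V[u] - V[v]
        mid = 0.5 * (V[u] + V[v])
        H = np.empty((3, 4))
        H[0, :3], H[1, :3], H[2, :3] = mid, V[u], V[v]
        H[:, 3] = 1.0
        costs = (H @ Qe * H).sum(axis=1)
        order = np.argsort(np.round(costs, 9), kind="stable")
        cost = float(costs[order[0]]) + 1e-6 * float(d @ d)
        return cost, [H[i, :3].copy() for i in order]

    heap: list = []
    tie = 0
    for u in range(nv):
        for v in nbrs[u]:
            if u < v:
                cost, cands = edge_cost(u, v)
                heap.append((cost, tie, u, v, cands, 0, 0))
                tie += 1
    heapq.heapify(heap)

    n_current = nv
    while n_current > target and heap:
        cost, _, u, v, cands, su, sv = heapq.heappop(heap)
        if not (alive_v[u] and alive_v[v]):
            continue
        if su != stamps[u] or sv != stamps[v]:
            continue
        if v not in nbrs[u]:
            continue
        shared = vert_faces[u] & vert_faces[v]
        if len(shared) != 2:
            continue  # boundary or non-manifold edge
        wings = set()
        for fi in shared:
            for w in F[fi]:
                if w != u and w != v:
                    wings.add(int(w))
        if nbrs[u] & nbrs[v] != wings:
            continue  # link condition: collapse would pinch the surface

        # normal-flip / degeneracy check on every surviving incident face,
        # trying candidate placements cheapest-first
        moved = (vert_faces[u] | vert_faces[v]) - shared
        pos = None
        for cand in cands:
            p_new = (cand[0], cand[1], cand[2])
            ok = True
            for fi in moved:
                a, b, c = F[fi]
                pa = tuple(V[a]) if a != u and a != v else p_new
                pb = tuple(V[b]) if b != u and b != v else p_new
                pc = tuple(V[c]) if c != u and c != v else p_new
                n_new = _tri_normal(pa, pb, pc)
                n_old = _tri_normal(tuple(V[a]), tuple(V[b]), tuple(V[c]))
                if _dot3(n_new, n_new) < 1e-18 or _dot3(n_new, n_old) <= 0.0:
                    ok = False
                    break
            if ok:
                pos = cand
                break
        if pos is None:
            continue

        # collapse v into u at pos
        V[u] = pos
        Q[u] = Q[u] + Q[v]
        alive_v[v] = False
        n_current -= 1
        for fi in shared:
            alive_f[fi] = False
            for w in F[fi]:
                vert_faces[int(w)].discard(fi)
        for fi in list(vert_faces[v]):
            tri = F[fi]
            F[fi] = [u if int(w) == v else int(w) for w in tri]
            vert_faces[u].add(fi)
        vert_faces[v].clear()
        for w in list(nbrs[v]):
            nbrs[w].discard(v)
            if w != u:
                nbrs[w].add(u)
                nbrs[u].add(w)
        nbrs[u].discard(u)
        nbrs[u].discard(v)
        nbrs[v].clear()
        stamps[u] += 1
        for w in sorted(nbrs[u]):
            c2, cands2 = edge_cost(u, w)
            heapq.heappush(heap, (c2, tie, min(u, w), max(u, w), cands2,
                                  int(stamps[min(u, w)]), int(stamps[max(u, w)])))
            tie += 1

    new_index = -np.ones(nv, dtype=np.int64)
    keep = np.flatnonzero(alive_v)
    new_index[keep] = np.arange(len(keep))
    out_faces = new_index[F[alive_f]]
    return V[keep], out_faces
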