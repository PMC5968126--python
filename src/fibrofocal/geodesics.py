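"""First-arrival computation on triangulated surfaces.

Fast marching over vertices with a two-point triangle update: for a vertex C
whose opposite edge AB carries known times, the update minimizes
``T(P) + f |C - P|`` over points ``P = A + lam (B - A)`` of the edge with
linearly interpolated time ``T(P)`` (closed-form minimizer).  For acute
triangles this equals the classical planar-wavefront (Kimmel-Sethian)
update; in degenerate cases it gracefully reduces to the Dijkstra edge
relaxation, which is also used for explicit extra edges such as
inter-atrial connections.  With unit slowness the result is the geodesic
distance; with a per-vertex slowness field it is the eikonal first-arrival
time.  Infinite slowness marks a barrier vertex (never reached).
"""

from __future__ import annotations

import heapq
import math

import numpy as np


class SurfaceGeodesics:
    """Precomputed connectivity for repeated fast-marching solves."""

    def __init__(self, vertices: np.ndarray, faces: np.ndarray,
                 extra_edges: list[tuple[int, int]] | None = None):
        self.vertices = np.asarray(vertices, dtype=float)
        self.faces = np.asarray(faces, dtype=np.int64)
        n = len(self.vertices)

        # vertex -> list of (neighbour, edge length); includes extra edges
        nbrs: list[dict[int, float]] = [dict() for _ in range(n)]
        # vertex C -> list of (A, B, p=e.w, q=|e|^2, r=|w|^2) with
        # e = B - A, w = C - A for each incident triangle
        fans: list[list[tuple[int, int, float, float, float]]] = [[] for _ in range(n)]
        V = self.vertices
        for tri in self.faces:
            for k in range(3):
                c, ai, bi = int(tri[k]), int(tri[(k + 1) % 3]), int(tri[(k + 2) % 3])
                e = V[bi] - V[ai]
                w = V[c] - V[ai]
                nbrs[c][ai] = float(np.linalg.norm(w))
                nbrs[c][bi] = float(np.linalg.norm(V[c] - V[bi]))
                fans[c].append((ai, bi, float(e @ w), float(e @ e), float(w @ w)))
        if extra_edges:
            for u, v in extra_edges:
                d = float(np.linalg.norm(V[u] - V[v]))
                nbrs[u][v] = d
                nbrs[v][u] = d
        self._nbrs = [sorted(d.items()) for d in nbrs]
        self._fans = fans
        # area-weighted vertex normals, used for the curvature-corrected
        # exact initialization around sources
        fn = np.cross(V[self.faces[:, 1]] - V[self.faces[:, 0]],
                      V[self.faces[:, 2]] - V[self.faces[:, 0]])
        vn = np.zeros_like(V)
        for k in range(3):
            np.add.at(vn, self.faces[:, k], fn)
        norm = np.linalg.norm(vn, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        self._vertex_normal = vn / norm

    # ---------------------------------------------------------------- solve
    def travel_times(self, sources, slowness=None,
                     exact_init_rings: int = 12) -> np.ndarray:
        """First-arrival time from ``sources`` (vertex ids) to every vertex."""
        n = len(self.vertices)
        if slowness is None:
            s = np.ones(n)
        elif np.isscalar(slowness):
            s = np.full(n, float(slowness))
        else:
            s = np.asarray(slowness, dtype=float)
        if np.any(s[np.isfinite(s)] <= 0):
            raise ValueError("slowness must be positive (inf = barrier)")
        T = np.full(n, np.inf)
        state = np.zeros(n, dtype=np.int8)  # 0 far, 1 trial, 2 accepted
        heap: list[tuple[float, int]] = []
        nbrs = self._nbrs
        fans = self._fans
        for src in np.atleast_1d(sources):
            src = int(src)
            if not math.isfinite(s[src]):
                continue
            T[src] = 0.0
            heapq.heappush(heap, (0.0, src))
            state[src] = 1
            # Exact (straight-line) initialization around the source removes
            # the front-curvature error of the planar update where it is
            # worst.  Expansion stops at the first slowness heterogeneity so
            # regional speed changes and fibrotic patches are never
            # short-circuited, and after ``exact_init_rings`` rings so the
            # chordal approximation stays local.
            V = self.vertices
            covered = {src}
            ring = {src}
            for _ in range(exact_init_rings):
                nxt = {v for u in ring for (v, _) in nbrs[u]} - covered
                if any(not math.isclose(s[v], s[src], rel_tol=1e-9)
                       for v in nxt):
                    break
                covered |= nxt
                ring = nxt
            n_src = self._vertex_normal[src]
            for v in covered:
                if v == src:
                    continue
                chord = float(np.linalg.norm(V[v] - V[src]))
                # curvature correction: arc = chord * (theta/2)/sin(theta/2)
                # with theta the normal rotation (exact on spheres)
                c_t = float(np.clip(self._vertex_normal[v] @ n_src, -1.0, 1.0))
                theta = math.acos(c_t)
                if theta > 1e-8:
                    chord *= (theta / 2.0) / math.sin(theta / 2.0)
                cand = chord * s[src]
                if cand < T[v]:
                    T[v] = cand
                    heapq.heappush(heap, (cand, v))
                    state[v] = 1
        while heap:
            t, c = heapq.heappop(heap)
            if state[c] == 2 or t > T[c]:
                continue
            state[c] = 2
            for (v, d) in nbrs[c]:
                if state[v] == 2 or not math.isfinite(s[v]):
                    continue
                f = s[v]
                cand = t + d * f  # Dijkstra relaxation along the edge
                for (ai, bi, p, q, r) in fans[v]:
                    if ai != c and bi != c:
                        continue
                    upd = _edge_source_update(T[ai], T[bi], p, q, r, f)
                    if upd < cand:
                        cand = upd
                if cand < T[v]:
                    T[v] = cand
                    heapq.heappush(heap, (cand, v))
                    state[v] = 1
        # corrective Gauss-Seidel sweeps: the single heap pass can freeze a
        # vertex slightly early; iterate the update to its fixed point
        order = np.argsort(T, kind="stable")
        for _ in range(20):
            changed = 0.0
            for v in order:
                tv = T[v]
                if tv == 0.0 or not math.isfinite(s[v]):
                    continue
                f = s[v]
                best = tv
                for (u, d) in nbrs[v]:
                    c2 = T[u] + d * f
                    if c2 < best:
                        best = c2
                for (ai, bi, p, q, r) in fans[v]:
                    upd = _edge_source_update(T[ai], T[bi], p, q, r, f)
                    if upd < best:
                        best = upd
                if best < tv:
                    T[v] = best
                    changed = max(changed, tv - best)
            if changed < 1e-12:
                break
        return T

    def distances(self, sources) -> np.ndarray:
        return self.travel_times(sources, slowness=1.0)


def _edge_source_update(ta: float, tb: float, p: float, q: float, r: float,
                        f: float) -> float:
    """min over lam in [0,1] of ta + lam (tb - ta) + f |C - A - lam (B - A)|.

    ``p = (B-A).(C-A)``, ``q = |B-A|^2``, ``r = |C-A|^2``.
    """
    if not (math.isfinite(ta) and math.isfinite(tb)):
        return math.inf
    u = tb - ta
    best = math.inf
    # interior stationary points: f^2 (p - lam q)^2 = u^2 (r - 2 lam p + lam^2 q)
    alpha = q * (f * f * q - u * u)
    beta = 2.0 * p * (u * u - f * f * q)
    gamma = f * f * p * p - u * u * r
    if alpha != 0.0:
        hi = ta if ta > tb else tb
        disc = beta * beta - 4.0 * alpha * gamma
        if disc >= 0.0:
            sq = math.sqrt(disc)
            for lam in ((-beta - sq) / (2.0 * alpha), (-beta + sq) / (2.0 * alpha)):
                if 0.0 < lam < 1.0:
                    d2 = r - 2.0 * lam * p + lam * lam * q
                    if d2 > 0.0:
                        val = ta + lam * u + f * math.sqrt(d2)
                        # causality: the update must not undercut its own
                        # inputs, or the fixed point stops being unique
                        if hi <= val < best:
                            best = val
    # edge endpoints
    e0 = ta + f * math.sqrt(max(r, 0.0))
    e1 = tb + f * math.sqrt(max(r - 2.0 * p + q, 0.0))
    return min(best, e0, e1)
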