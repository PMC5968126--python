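"""Synthetic atrial/torso geometry and organ-scale activation surrogate.

The anatomical stand-in is deliberately simple: two ellipsoidal shells
(left and right atrium) built from subdivided icospheres, carrying the
region labels the rest of the pipeline needs (posterior LA wall, four PV
ostia, appendages, valve rings, fossa ovalis, coronary sinus, crista
terminalis / Bachmann's bundle), joined by three explicit inter-atrial
connection edges (BB, FO rim, CS).  The torso is a scaled ellipsoid point
cloud ("electrode vest").

Organ-scale activation is computed with an anisotropy-free eikonal
(fast-marching) surrogate: per-vertex conduction speeds follow the regional
longitudinal CVs of the tissue model, fibrotic vertices are slowed by a
calibrated factor, and vertices deep inside fibrotic patches (two or more
rings from healthy tissue, the surface equivalent of a >=3-element
transmural wall) block conduction entirely -- the slowing/block rules are
anchored to the voxel-slab barrier experiments.  All lengths are mm, times
ms, speeds mm/ms (= m/s).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import trimesh
from scipy import sparse
from scipy.spatial import ConvexHull

from . import fibrosis as fib_mod
from .constants import REGION_TABLE
from .geodesics import SurfaceGeodesics

#: conduction speed (mm/ms) per atlas region, from the regional CV table
REGION_SPEED = {
    "LA": 0.633, "LA_posterior": 0.633, "PV": 0.75, "LAA": 0.633,
    "MVR": 0.629, "CS": 0.972, "FO_ring": 0.633, "FO": 0.0,
    "RA": 0.633, "PM": 1.154, "CT_BB": 1.0, "TVR": 0.633, "RAA": 0.633,
}
FIB_SLOW_FACTOR = 0.5   # fibrotic speed multiplier (0.85 -> ~0.5 m/s class)
FIB_BLOCK_DEPTH = 2     # rings from healthy tissue at which fibrosis blocks
FIB_ATTENUATION = 0.58  # AP amplitude factor on conducting fibrotic tissue


class NoCaptureError(RuntimeError):
    """The focus lies in a blocked fibrotic zone; the run is excluded."""


@dataclass(frozen=True)
class EctopicFocus:
    id: str
    vertex: int
    region: str


@dataclass
class TorsoSurface:
    """Closed torso-like electrode surface (node coordinates in mm)."""

    vertices: np.ndarray
    faces: np.ndarray

    @property
    def n_nodes(self) -> int:
        return len(self.vertices)


@dataclass
class AtrialSurface:
    vertices: np.ndarray          # (n, 3) mm
    faces: np.ndarray             # (m, 3)
    region: np.ndarray            # (n,) str
    atrium: np.ndarray            # (n,) 0 = LA, 1 = RA
    speed: np.ndarray             # (n,) mm/ms
    connection_edges: list = field(default_factory=list)  # (u, v, name)

    _geod: SurfaceGeodesics | None = None
    _vertex_area: np.ndarray | None = None

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def geodesics(self) -> SurfaceGeodesics:
        if self._geod is None:
            self._geod = SurfaceGeodesics(
                self.vertices, self.faces,
                extra_edges=[(u, v) for (u, v, _) in self.connection_edges])
        return self._geod

    @property
    def vertex_areas(self) -> np.ndarray:
        """Barycentric vertex areas (mm^2): one third of incident faces."""
        if self._vertex_area is None:
            v = self.vertices
            f = self.faces
            cross = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
            fa = 0.5 * np.linalg.norm(cross, axis=1)
            va = np.zeros(self.n_vertices)
            for k in range(3):
                np.add.at(va, f[:, k], fa / 3.0)
            self._vertex_area = va
        return self._vertex_area

    @property
    def la_mask(self) -> np.ndarray:
        return self.atrium == 0

    def vertex_adjacency(self) -> sparse.csr_matrix:
        n = self.n_vertices
        f = self.faces
        rows = np.concatenate([f[:, 0], f[:, 1], f[:, 2], f[:, 1], f[:, 2], f[:, 0]])
        cols = np.concatenate([f[:, 1], f[:, 2], f[:, 0], f[:, 0], f[:, 1], f[:, 2]])
        a = sparse.csr_matrix((np.ones(rows.size, dtype=np.uint8), (rows, cols)),
                              shape=(n, n))
        a.data[:] = 1
        return a


@dataclass
class Atlas:
    atria: AtrialSurface
    torso: TorsoSurface
    foci: list[EctopicFocus]           # all 57
    primary_ids: list[str]             # the 19-focus subset
    config: dict = field(default_factory=dict)

    def focus(self, focus_id: str) -> EctopicFocus:
        for f in self.foci:
            if f.id == focus_id:
                return f
        raise KeyError(focus_id)

    @property
    def primary_foci(self) -> list[EctopicFocus]:
        return [f for f in self.foci if f.id in set(self.primary_ids)]


# ------------------------------------------------------------ construction
def _unit_dirs(vertices: np.ndarray, center, axes) -> np.ndarray:
    u = (vertices - np.asarray(center)) / np.asarray(axes)
    return u / np.linalg.norm(u, axis=1, keepdims=True)


def _label_la(u: np.ndarray) -> np.ndarray:
    n = len(u)
    region = np.full(n, "LA", dtype=object)
    cos20 = np.cos(np.radians(20))
    pv_dirs = [np.array([sx * 0.45, -0.75, sz * 0.45])
               for sx in (-1, 1) for sz in (-1, 1)]
    # precedence: later assignments do not overwrite earlier special labels
    region[u[:, 1] < -0.45] = "LA_posterior"
    region[(u[:, 2] < -0.55) & (u[:, 1] < 0)] = "CS"
    region[(u[:, 2] < -0.75) & (region == "LA")] = "MVR"
    laa = np.array([-0.75, 0.55, 0.35])
    region[u @ (laa / np.linalg.norm(laa)) > np.cos(np.radians(18))] = "LAA"
    fo = np.array([0.95, 0.1, -0.2])
    cfo = u @ (fo / np.linalg.norm(fo))
    region[(cfo > np.cos(np.radians(16))) & (cfo <= np.cos(np.radians(8)))] = "FO_ring"
    region[cfo > np.cos(np.radians(8))] = "FO"
    for d in pv_dirs:
        region[u @ (d / np.linalg.norm(d)) > cos20] = "PV"
    return region.astype(str)


def _label_ra(u: np.ndarray) -> np.ndarray:
    n = len(u)
    region = np.full(n, "RA", dtype=object)
    region[(u[:, 1] > 0.5) & (np.abs(u[:, 2]) < 0.5)] = "PM"
    region[u[:, 2] < -0.75] = "TVR"
    raa = np.array([-0.3, 0.8, 0.4])
    region[u @ (raa / np.linalg.norm(raa)) > np.cos(np.radians(20))] = "RAA"
    region[u[:, 2] > 0.7] = "CT_BB"
    return region.astype(str)


def _farthest_point_subset(points: np.ndarray, candidates: np.ndarray,
                           k: int, rng: np.random.Generator) -> np.ndarray:
    """Greedy spread-maximizing subset of candidate vertex ids."""
    if k >= candidates.size:
        return candidates.copy()
    chosen = [int(rng.choice(candidates))]
    d = np.linalg.norm(points[candidates] - points[chosen[0]], axis=1)
    for _ in range(k - 1):
        nxt = int(candidates[np.argmax(d)])
        chosen.append(nxt)
        d = np.minimum(d, np.linalg.norm(points[candidates] - points[nxt], axis=1))
    return np.array(sorted(chosen))


#: (region, count) layout of the 19 clinically motivated foci
PRIMARY_FOCUS_PLAN = [
    ("LA_posterior", 3), ("PV", 4), ("LAA", 1), ("MVR", 1), ("CS", 1),
    ("FO_ring", 1), ("LA", 1),                       # 12 left-atrial
    ("CT_BB", 1), ("RAA", 1), ("TVR", 1), ("PM", 1), ("RA", 3),  # 7 right-atrial
]
#: (region, count) layout of the 38 extra foci of the no-fibrosis set
EXTRA_FOCUS_PLAN = [
    ("LA_posterior", 4), ("PV", 4), ("LAA", 2), ("MVR", 3), ("CS", 2),
    ("LA", 5),                                        # 20 left-atrial
    ("CT_BB", 2), ("RAA", 2), ("TVR", 3), ("PM", 3), ("RA", 8),  # 18 right-atrial
]


def build_atlas(subdivisions: int = 4, torso_nodes: int = 14157,
                rng_seed: int = 0) -> Atlas:
    """Deterministic synthetic atlas: atria + torso + 57/19 focus sets."""
    if subdivisions < 2:
        raise ValueError("need subdivisions >= 2 for usable region caps")
    la_axes, la_center = (28.0, 25.0, 22.0), (-22.0, 0.0, 0.0)
    ra_axes, ra_center = (25.0, 23.0, 21.0), (28.0, 0.0, 0.0)

    la = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    ra = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    la_v = la.vertices * la_axes + la_center
    ra_v = ra.vertices * ra_axes + ra_center
    vertices = np.vstack([la_v, ra_v])
    faces = np.vstack([la.faces, ra.faces + len(la_v)])
    atrium = np.concatenate([np.zeros(len(la_v), dtype=int),
                             np.ones(len(ra_v), dtype=int)])
    u_la = _unit_dirs(la_v, la_center, la_axes)
    u_ra = _unit_dirs(ra_v, ra_center, ra_axes)
    region = np.concatenate([_label_la(u_la), _label_ra(u_ra)])
    speed = np.array([REGION_SPEED[r] for r in region])

    # inter-atrial connections: nearest vertices to anatomical directions
    def la_near(d):
        d = np.asarray(d) / np.linalg.norm(d)
        return int(np.argmax(u_la @ d))

    def ra_near(d):
        d = np.asarray(d) / np.linalg.norm(d)
        return int(np.argmax(u_ra @ d)) + len(la_v)

    connections = [
        (la_near((0.8, 0.5, 0.55)), ra_near((-0.8, 0.5, 0.55)), "BB"),
        (la_near((0.95, 0.25, -0.2)), ra_near((-0.95, 0.25, -0.2)), "FO"),
        (la_near((0.5, -0.5, -0.7)), ra_near((-0.5, -0.5, -0.7)), "CS"),
    ]
    surface = AtrialSurface(vertices=vertices, faces=faces, region=region,
                            atrium=atrium, speed=speed,
                            connection_edges=connections)

    # ---- foci ----
    rng = np.random.default_rng(rng_seed)
    conducting = speed > 0
    foci: list[EctopicFocus] = []
    primary_ids: list[str] = []
    used = np.zeros(len(vertices), dtype=bool)
    counters = {0: 0, 1: 0}

    def place_side(plan, side, primary):
        for reg, k in plan:
            cand = np.nonzero((region == reg) & (atrium == side)
                              & conducting & ~used)[0]
            if cand.size < k:
                raise ValueError(f"region {reg} too small for {k} foci")
            sel = _farthest_point_subset(vertices, cand, k, rng)
            for v in sel:
                counters[side] += 1
                fid = ("LA" if side == 0 else "RA") + str(counters[side])
                foci.append(EctopicFocus(fid, int(v), reg))
                used[v] = True
                if primary:
                    primary_ids.append(fid)

    la_plan = [(r, k) for r, k in PRIMARY_FOCUS_PLAN[:7]]
    ra_plan = [(r, k) for r, k in PRIMARY_FOCUS_PLAN[7:]]
    place_side(la_plan, 0, True)
    place_side(ra_plan, 1, True)
    la_extra = [(r, k) for r, k in EXTRA_FOCUS_PLAN[:6]]
    ra_extra = [(r, k) for r, k in EXTRA_FOCUS_PLAN[6:]]
    place_side(la_extra, 0, False)
    place_side(ra_extra, 1, False)
    assert len(foci) == 57 and len(primary_ids) == 19

    # ---- torso ----
    torso = build_torso(torso_nodes)
    return Atlas(atria=surface, torso=torso, foci=foci,
                 primary_ids=primary_ids,
                 config=dict(subdivisions=subdivisions,
                             torso_nodes=torso_nodes, rng_seed=rng_seed))


def build_torso(n_nodes: int = 14157,
                axes=(180.0, 130.0, 280.0)) -> TorsoSurface:
    """Ellipsoidal electrode vest sampled with a Fibonacci lattice (mm)."""
    if n_nodes < 256:
        raise ValueError("torso needs at least 256 nodes")
    i = np.arange(n_nodes)
    golden = (1 + 5 ** 0.5) / 2
    z = 1.0 - 2.0 * (i + 0.5) / n_nodes
    theta = 2 * np.pi * i / golden
    r = np.sqrt(np.maximum(1 - z * z, 0.0))
    pts = np.column_stack([r * np.cos(theta), r * np.sin(theta), z]) * axes
    hull = ConvexHull(pts)
    return TorsoSurface(vertices=pts, faces=hull.simplices.copy())


# ------------------------------------------------------------- activation
def fibrosis_depth(surface: AtrialSurface, fibrotic: np.ndarray) -> np.ndarray:
    """Ring distance of each fibrotic vertex from the nearest healthy vertex.

    Depth 1 = fibrotic with a healthy neighbour, 2 = one ring further in,
    etc.; 0 for healthy vertices.
    """
    adj = surface.vertex_adjacency()
    depth = np.zeros(surface.n_vertices, dtype=int)
    frontier = np.asarray(fibrotic & (adj @ (~fibrotic).astype(np.int8) > 0))
    level = 1
    remaining = fibrotic.copy()
    while frontier.any():
        depth[frontier] = level
        remaining = remaining & ~frontier
        if not remaining.any():
            break
        reach = (adj @ frontier.astype(np.int8) > 0)
        frontier = remaining & reach
        level += 1
    depth[remaining & fibrotic] = level  # enclosed cores
    return depth


def fibrosis_slowness(surface: AtrialSurface,
                      fibrotic: np.ndarray | None,
                      slow_factor: float = FIB_SLOW_FACTOR,
                      block_depth: int = FIB_BLOCK_DEPTH) -> np.ndarray:
    """Per-vertex slowness (ms/mm) including fibrotic slowing and block."""
    with np.errstate(divide="ignore"):
        slowness = np.where(surface.speed > 0, 1.0 / surface.speed, np.inf)
    if fibrotic is not None and fibrotic.any():
        depth = fibrosis_depth(surface, fibrotic)
        slowed = fibrotic & (depth < block_depth)
        blocked = fibrotic & (depth >= block_depth)
        slowness[slowed] = slowness[slowed] / slow_factor
        slowness[blocked] = np.inf
    return slowness


def eikonal_activation(surface: AtrialSurface, focus: EctopicFocus,
                       fibrotic: np.ndarray | None = None,
                       slow_factor: float = FIB_SLOW_FACTOR,
                       block_depth: int = FIB_BLOCK_DEPTH) -> np.ndarray:
    """LAT map (ms) of one ectopic activation; NaN where never activated."""
    if not (0 <= focus.vertex < surface.n_vertices):
        raise ValueError("focus vertex not on surface")
    slowness = fibrosis_slowness(surface, fibrotic, slow_factor, block_depth)
    if not np.isfinite(slowness[focus.vertex]):
        raise NoCaptureError(
            f"focus {focus.id} lies in a blocked fibrotic zone")
    lat = surface.geodesics.travel_times(focus.vertex, slowness)
    lat[~np.isfinite(lat)] = np.nan
    return lat


def synthesize_transmembrane(lat: np.ndarray, template_t: np.ndarray,
                             template_v: np.ndarray,
                             attenuation: np.ndarray | None = None,
                             fs_khz: float = 1.0,
                             duration_ms: float | None = None) -> np.ndarray:
    """Per-vertex V(t): the AP template shifted by the local activation time.

    Unreached vertices (NaN LAT) stay at the template resting value; an
    optional per-vertex ``attenuation`` scales the AP excursion (fibrotic
    amplitude reduction).  Sampled at ``fs_khz`` kHz.
    """
    rmp = float(template_v[0])
    max_lat = np.nanmax(lat)
    if duration_ms is None:
        duration_ms = float(max_lat + template_t[-1])
    if template_t[-1] > duration_ms:
        pass  # template longer than window is fine; it is cropped
    n_t = int(np.ceil(duration_ms * fs_khz)) + 1
    t_axis = np.arange(n_t) / fs_khz
    n_v = lat.size
    V = np.full((n_v, n_t), rmp)
    reached = np.isfinite(lat)
    local_t = t_axis[None, :] - lat[reached, None]
    ap = np.interp(local_t, template_t, template_v, left=rmp, right=template_v[-1])
    if attenuation is not None:
        ap = rmp + (ap - rmp) * attenuation[reached, None]
    V[reached] = ap
    return V


# ---------------------------------------------------------------- datasets
@dataclass
class ActivationRun:
    run_id: str
    focus: EctopicFocus
    case: int          # 0 = no fibrosis
    stage: int         # 0 = no fibrosis
    excluded: bool
    lat: np.ndarray | None


@dataclass
class ActivationDataset:
    runs: list[ActivationRun]
    atlas: Atlas
    fibrosis_library: dict

    def manifest(self) -> pd.DataFrame:
        return pd.DataFrame(
            [dict(run_id=r.run_id, focus=r.focus.id, region=r.focus.region,
                  case=r.case, stage=r.stage, excluded=r.excluded)
             for r in self.runs])

    def included(self) -> list[ActivationRun]:
        return [r for r in self.runs if not r.excluded]


def la_element_mesh(surface: AtrialSurface) -> fib_mod.ElementMesh:
    """LA vertex submesh as a fibrosis-generator element set.

    Elements are LA vertices (barycentric areas as volumes); indices into
    the submesh are positions within ``la_index``.
    """
    la_idx = np.nonzero(surface.la_mask)[0]
    pos = -np.ones(surface.n_vertices, dtype=int)
    pos[la_idx] = np.arange(la_idx.size)
    adj = surface.vertex_adjacency()[la_idx][:, la_idx]
    mesh = fib_mod.ElementMesh(
        adjacency=adj, volumes=surface.vertex_areas[la_idx],
        regions=surface.region[la_idx])
    mesh.la_index = la_idx
    return mesh


def fibrotic_vertex_mask(surface: AtrialSurface, mesh,
                         model: fib_mod.FibrosisModel) -> np.ndarray:
    mask = np.zeros(surface.n_vertices, dtype=bool)
    mask[mesh.la_index[model.element_labels.astype(bool)]] = True
    return mask


def save_surface_vtk(surface: AtrialSurface, path,
                     vertex_arrays: dict | None = None) -> None:
    """Write the atrial surface as legacy ASCII VTK polydata with named
    per-vertex arrays (region code, conduction speed, plus extras)."""
    region_codes = {r: i for i, r in enumerate(sorted(set(surface.region)))}
    arrays = {"region_code": np.array([region_codes[r] for r in surface.region],
                                      dtype=float),
              "speed_mm_ms": surface.speed.astype(float)}
    arrays.update(vertex_arrays or {})
    v = surface.vertices
    f = surface.faces
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nfibrofocal atrial surface\n"
                 "ASCII\nDATASET POLYDATA\n")
        fh.write(f"POINTS {len(v)} float\n")
        fh.writelines(f"{p[0]:.6g} {p[1]:.6g} {p[2]:.6g}\n" for p in v)
        fh.write(f"POLYGONS {len(f)} {4 * len(f)}\n")
        fh.writelines(f"3 {a} {b} {c}\n" for a, b, c in f)
        fh.write(f"POINT_DATA {len(v)}\n")
        for name, arr in arrays.items():
            fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
            fh.write("\n".join(f"{x:.6g}" for x in
                               np.nan_to_num(arr, nan=-1.0)))
            fh.write("\n")


MODEL_STAGES = {"M0": (), "M1": (1,), "M2": (1, 2), "M3": (1, 2, 3),
                "M4": (1, 2, 3, 4), "M5": (1, 2, 3, 4, 5)}


def build_dataset(atlas: Atlas, model_spec: str = "M5", rng_seed: int = 0,
                  n_cases: int = 5,
                  fibrosis_library: dict | None = None) -> ActivationDataset:
    """Labelled activation-map set for one dataset model (M0..M5).

    M0: all 57 foci on the fibrosis-free atlas.  M1..M5: the 19 primary
    foci on every fibrosis case at the included stages, with non-capturing
    focus/fibrosis combinations excluded.
    """
    if model_spec not in MODEL_STAGES:
        raise ValueError(f"unknown model spec {model_spec!r}")
    surface = atlas.atria
    runs: list[ActivationRun] = []
    library = {}
    if model_spec == "M0":
        for f in atlas.foci:
            lat = eikonal_activation(surface, f, None)
            runs.append(ActivationRun(f"nofib_{f.id}", f, 0, 0, False, lat))
    else:
        mesh = la_element_mesh(surface)
        if fibrosis_library is None:
            fibrosis_library = fib_mod.build_case_library(
                mesh, n_cases=n_cases, rng_base=rng_seed)
        library = fibrosis_library
        stages = MODEL_STAGES[model_spec]
        for (case, stage), model in sorted(library.items()):
            if stage not in stages:
                continue
            fibmask = fibrotic_vertex_mask(surface, mesh, model)
            for f in atlas.primary_foci:
                rid = f"c{case}s{stage}_{f.id}"
                try:
                    lat = eikonal_activation(surface, f, fibmask)
                    runs.append(ActivationRun(rid, f, case, stage, False, lat))
                except NoCaptureError:
                    runs.append(ActivationRun(rid, f, case, stage, True, None))
    return ActivationDataset(runs=runs, atlas=atlas,
                             fibrosis_library=library)


def subset_dataset(dataset: ActivationDataset,
                   model_spec: str) -> ActivationDataset:
    """Model M_k as the stage-filtered view of a larger fibrotic dataset."""
    stages = set(MODEL_STAGES[model_spec])
    runs = [r for r in dataset.runs if r.stage in stages and r.stage > 0]
    return ActivationDataset(runs=runs, atlas=dataset.atlas,
                             fibrosis_library=dataset.fibrosis_library)
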