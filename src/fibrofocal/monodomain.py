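"""Voxel-grid monodomain reaction-diffusion solver for mixed atrial tissue.

The transmembrane voltage obeys C_m dV/dt = div(D grad V) - I_ion with
no-flux boundaries; the reaction term is the regional CRN myocyte model or
the MacCannell fibroblast model per voxel.  Time stepping is Godunov
operator splitting: one Rush-Larsen/Euler reaction step followed by one
explicit 7-point finite-difference diffusion step with harmonic-mean face
conductivities (equivalent to the low-order FEM at this resolution).

Includes builders for the 50 x 50 x 0.3 mm slab experiments: a homogeneous
left-atrial control, transverse fibroblast barriers of 1-3 voxels,
fibroblast slabs with a healthy conduction channel, and patchy-fibrosis
slabs staged by the Utah classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels, ionic
from .constants import (LABEL_FIBROBLAST, LABEL_NONCONDUCTING, N_STATE,
                        REGION_INDEX, REGION_NAMES, REGION_TABLE, TISSUE,
                        crn_initial_state)

VOXEL_MM = 0.3          # slab lattice resolution (300 um voxels)
SLAB_MM = 50.0
LAT_THRESHOLD = -40.0   # mV, upstroke crossing
DEFAULT_DT = 0.02       # ms
SLAB_STIM_AMP = 40.0    # pA/pF, rectangular 2 ms planar stimulus


class NumericalBlowupError(RuntimeError):
    pass


@dataclass
class Stimulus:
    """Space-time rectangular current injection (density in pA/pF)."""

    mask: np.ndarray            # boolean, one entry per voxel (flat)
    amplitude: float = SLAB_STIM_AMP
    start: float = 0.0          # ms
    duration: float = 2.0      # ms
    period: float = 0.0         # ms; > 0 repeats the pulse (pacing train)


@dataclass
class VoxelGrid:
    """Labelled 3D tissue lattice.

    ``label`` holds -1 (non-conducting), -2 (fibroblast) or a myocyte region
    index into :data:`fibrofocal.constants.REGION_NAMES`; ``sigma_l`` is the
    per-voxel longitudinal conductivity (S/cm), ``anisotropy`` the
    sigma_t/sigma_l ratio, ``fiber_axis`` the longitudinal lattice axis
    (0=x, 1=y, 2=z) per voxel.
    """

    dims: tuple[int, int, int]
    spacing: float = VOXEL_MM
    label: np.ndarray = None
    sigma_l: np.ndarray = None
    anisotropy: np.ndarray = None
    fiber_axis: np.ndarray = None
    probes: dict[str, int] = field(default_factory=dict)  # name -> flat index

    def __post_init__(self):
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        n = int(np.prod(self.dims))
        if self.label is None:
            self.label = np.full(n, REGION_INDEX["LA"], dtype=np.int64)
        if self.sigma_l is None:
            self.sigma_l = np.full(n, REGION_TABLE["LA"]["sigma_l"])
        if self.anisotropy is None:
            self.anisotropy = np.full(n, REGION_TABLE["LA"]["anisotropy"])
        if self.fiber_axis is None:
            self.fiber_axis = np.full(n, 1, dtype=np.int64)  # along y
        if np.any(self.sigma_l < 0):
            raise ValueError("conductivities must be >= 0")

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.dims))

    def flat_index(self, ix: int, iy: int, iz: int) -> int:
        nx, ny, nz = self.dims
        return (ix * ny + iy) * nz + iz

    def diffusion_coefficients(self) -> np.ndarray:
        """Per-voxel, per-axis diffusion coefficients (mm^2/ms).

        D_l = diffusion_scale * sigma_l along the fiber axis, D_t =
        anisotropy * D_l transversely.  Fibroblast voxels use
        fib_conductivity_factor times the healthy LA value, isotropic.
        """
        scale = TISSUE["diffusion_scale"]
        d_l = scale * self.sigma_l
        fib = self.label == LABEL_FIBROBLAST
        d_l = np.where(
            fib,
            TISSUE["fib_conductivity_factor"] * scale * REGION_TABLE["LA"]["sigma_l"],
            d_l)
        # fibrotic tissue keeps the host fiber frame but with its own
        # (stronger) anisotropy: interstitial fibrosis disrupts side-to-side
        # coupling much more than longitudinal coupling
        anis = np.where(fib, TISSUE["fib_anisotropy"], self.anisotropy)
        D = np.empty((self.n_voxels, 3))
        for ax in range(3):
            D[:, ax] = np.where(self.fiber_axis == ax, d_l, anis * d_l)
        D[self.label == LABEL_NONCONDUCTING] = 0.0
        return D


@dataclass
class SimulationResult:
    """Activation map plus optional probe traces / voltage movie."""

    lat: np.ndarray                       # ms, NaN where never activated
    dims: tuple[int, int, int]
    meta: dict
    probe_traces: dict[str, np.ndarray] = field(default_factory=dict)
    probe_dt: float = 0.0
    movie: np.ndarray | None = None       # (frames, n_voxels)
    movie_dt: float = 0.0
    final_state: np.ndarray | None = None

    @property
    def total_activation_time(self) -> float:
        """Latest defined LAT (ms since simulation start)."""
        return float(np.nanmax(self.lat))

    def lat_3d(self) -> np.ndarray:
        return self.lat.reshape(self.dims)


def _face_weights(grid: VoxelGrid):
    nx, ny, nz = grid.dims
    h2 = grid.spacing ** 2
    D = grid.diffusion_coefficients()
    out = []
    for ax, shape_ax in ((0, nx), (1, ny), (2, nz)):
        Dax = D[:, ax].reshape(nx, ny, nz)
        wm = np.zeros((nx, ny, nz))
        wp = np.zeros((nx, ny, nz))
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[ax] = slice(None, -1)
        sl_hi[ax] = slice(1, None)
        a = Dax[tuple(sl_lo)]
        b = Dax[tuple(sl_hi)]
        with np.errstate(divide="ignore", invalid="ignore"):
            face = np.where(a + b > 0, 2.0 * a * b / (a + b), 0.0) / h2
        wp[tuple(sl_lo)] = face
        wm[tuple(sl_hi)] = face
        out.extend([wm, wp])
    # order: xm, xp, ym, yp, zm, zp
    return out[0], out[1], out[2], out[3], out[4], out[5]


def initial_tissue_state(grid: VoxelGrid,
                         myocyte_state: np.ndarray | None = None) -> np.ndarray:
    """(N_STATE, n_voxels) state array: myocyte rest / fibroblast rest."""
    n = grid.n_voxels
    S = np.zeros((N_STATE, n))
    myo = (myocyte_state if myocyte_state is not None else crn_initial_state())
    S[:] = np.asarray(myo).reshape(N_STATE, 1)
    fib = grid.label == LABEL_FIBROBLAST
    if np.any(fib):
        S[:, fib] = ionic.fibroblast_initial_state().reshape(N_STATE, 1)
    return np.ascontiguousarray(S)


def solve_monodomain(grid: VoxelGrid, stimulus: Stimulus, duration: float,
                     dt: float = DEFAULT_DT,
                     initial_state: np.ndarray | None = None,
                     probe_every_ms: float = 0.1,
                     movie_every_ms: float = 0.0) -> SimulationResult:
    """Run the operator-splitting monodomain solver.

    ``initial_state`` may be a full (N_STATE, n) array or a single myocyte
    state column (e.g., a pre-paced diastolic state) applied to every
    myocyte voxel.
    """
    if dt > 0.05:
        raise ValueError("dt must be <= 0.05 ms for gate stability")
    if stimulus.mask.shape[0] != grid.n_voxels:
        raise ValueError("stimulus mask does not match grid")
    if not np.any(grid.label != LABEL_NONCONDUCTING):
        raise ValueError("grid has no conducting voxel")
    if not np.any(stimulus.mask):
        raise ValueError("stimulus outside grid (empty mask)")

    n = grid.n_voxels
    if initial_state is not None and initial_state.ndim == 2 and initial_state.shape[1] == n:
        S = np.ascontiguousarray(initial_state.copy())
    else:
        S = initial_tissue_state(grid, initial_state)

    fto = np.ones(n)
    fcal = np.ones(n)
    fkr = np.ones(n)
    for name, idx in REGION_INDEX.items():
        m = grid.label == idx
        if np.any(m):
            row = REGION_TABLE[name]
            fto[m] = row["f_gto"]
            fcal[m] = row["f_gCaL"]
            fkr[m] = row["f_gKr"]

    wxm, wxp, wym, wyp, wzm, wzp = _face_weights(grid)
    # explicit-diffusion stability check
    wmax = (wxm + wxp + wym + wyp + wzm + wzp).max()
    if wmax > 0 and dt > 2.0 / wmax:
        raise ValueError(f"dt {dt} ms unstable for diffusion (max {2.0 / wmax:.3f})")

    n_steps = int(round(duration / dt))
    lat = np.full(n, -1.0)  # sentinel, converted to NaN after the run
    probe_idx = np.asarray(sorted(grid.probes.values()), dtype=np.int64)
    probe_every = max(int(round(probe_every_ms / dt)), 1)
    n_rec = (n_steps - 1) // probe_every + 1
    probe_out = np.empty((probe_idx.size, n_rec)) if probe_idx.size else np.empty((0, 0))
    if movie_every_ms > 0:
        movie_every = max(int(round(movie_every_ms / dt)), 1)
        movie = np.empty(((n_steps - 1) // movie_every + 1, n))
    else:
        movie_every = 0
        movie = np.empty((0, 0))

    status = _kernels.tissue_run(
        S, grid.label, fto, fcal, fkr,
        wxm, wxp, wym, wyp, wzm, wzp,
        stimulus.mask.astype(np.bool_), float(stimulus.amplitude),
        float(stimulus.start), float(stimulus.duration), float(stimulus.period),
        float(dt), n_steps, float(TISSUE["fib_current_scale"]),
        lat, LAT_THRESHOLD,
        probe_idx, probe_out, probe_every,
        movie, movie_every)
    if status != 0:
        raise NumericalBlowupError(
            "monodomain solve diverged (|V| > 200 mV); reduce dt or check grid")
    lat[lat < 0] = np.nan

    names = [k for k, _ in sorted(grid.probes.items(), key=lambda kv: kv[1])]
    traces = {nm: probe_out[i] for i, nm in enumerate(names)}
    return SimulationResult(
        lat=lat, dims=grid.dims,
        meta=dict(dt=dt, duration=duration, stim_start=stimulus.start,
                  stim_amplitude=stimulus.amplitude,
                  stim_duration=stimulus.duration),
        probe_traces=traces, probe_dt=probe_every * dt,
        movie=(movie if movie_every else None),
        movie_dt=(movie_every * dt if movie_every else 0.0),
        final_state=S)


# ------------------------------------------------------------ slab builders
def _slab_dims(width_mm: float = SLAB_MM, height_mm: float = SLAB_MM,
               spacing: float = VOXEL_MM) -> tuple[int, int, int]:
    return (int(round(width_mm / spacing)), int(round(height_mm / spacing)), 1)


def build_control_slab(region: str = "LA", spacing: float = VOXEL_MM,
                       width_mm: float = SLAB_MM,
                       height_mm: float = SLAB_MM) -> VoxelGrid:
    """Homogeneous 50 x 50 x 0.3 mm slab, fibers along the propagation (y) axis."""
    dims = _slab_dims(width_mm, height_mm, spacing)
    n = int(np.prod(dims))
    row = REGION_TABLE[region]
    grid = VoxelGrid(
        dims=dims, spacing=spacing,
        label=np.full(n, REGION_INDEX[region], dtype=np.int64),
        sigma_l=np.full(n, row["sigma_l"]),
        anisotropy=np.full(n, row["anisotropy"]),
    )
    nx, ny, nz = dims
    grid.probes = {
        "bottom": grid.flat_index(nx // 2, 0, 0),
        "mid": grid.flat_index(nx // 2, ny // 2, 0),
        "top": grid.flat_index(nx // 2, ny - 1, 0),
    }
    return grid


def build_barrier_slab(width_voxels: int, region: str = "LA") -> VoxelGrid:
    """LA slab with a full-width transverse fibroblast band at mid-height."""
    if width_voxels < 0:
        raise ValueError("width_voxels must be >= 0")
    grid = build_control_slab(region)
    nx, ny, nz = grid.dims
    if width_voxels > ny:
        raise ValueError("barrier exceeds slab height")
    lab3 = grid.label.reshape(nx, ny, nz)
    y0 = ny // 2 - width_voxels // 2
    lab3[:, y0:y0 + width_voxels, :] = LABEL_FIBROBLAST
    grid.probes["pre_barrier"] = grid.flat_index(nx // 2, max(y0 - 4, 0), 0)
    grid.probes["post_barrier"] = grid.flat_index(
        nx // 2, min(y0 + width_voxels + 3, ny - 1), 0)
    return grid


def build_channel_slab(channel_width_mm: float, region: str = "LA") -> VoxelGrid:
    """Fibroblast slab with a centered healthy channel along the y axis.

    Four probe sites are placed evenly along the channel mid-line
    (entrance = probe 1 ... exit = probe 4).
    """
    grid = build_control_slab(region)
    nx, ny, nz = grid.dims
    w_vox = int(round(channel_width_mm / grid.spacing))
    if w_vox > nx:
        raise ValueError("channel wider than slab")
    lab3 = grid.label.reshape(nx, ny, nz)
    x0 = nx // 2 - w_vox // 2
    keep = np.zeros(nx, dtype=bool)
    keep[x0:x0 + w_vox] = True
    lab3[~keep, :, :] = LABEL_FIBROBLAST
    xc = x0 + w_vox // 2
    ys = np.linspace(3, ny - 4, 4).round().astype(int)
    grid.probes = {f"ch{i+1}": grid.flat_index(xc, y, 0)
                   for i, y in enumerate(ys)}
    return grid


def build_patchy_slab(stage: int, case_seed: int, region: str = "LA",
                      drop_prob: float | None = None) -> VoxelGrid:
    """Slab with patchy fibrosis grown to the Utah band of ``stage`` (1-5)."""
    from . import fibrosis as fib_mod

    if stage not in (1, 2, 3, 4, 5):
        raise ValueError("stage must be in 1..5")
    grid = build_control_slab(region)
    nx, ny, nz = grid.dims
    adjacency = fib_mod.grid_adjacency(nx, ny)
    volumes = np.ones(nx * ny)
    seeds = fib_mod.place_seeds_uniform(nx * ny, 50, 977 * (case_seed + 1))
    dp = fib_mod.DEFAULT_DROP_PROB if drop_prob is None else drop_prob
    model = None
    for s in range(1, stage + 1):  # nested growth: stages are supersets
        model = fib_mod.grow_fibrosis(
            adjacency, volumes, seeds, fib_mod.DEFAULT_STAGE_TARGETS[s - 1],
            drop_prob=dp, rng_seed=977 * (case_seed + 1) + s,
            case_id=case_seed, stage=s,
            start_labels=None if model is None else model.element_labels)
    lab3 = grid.label.reshape(nx, ny, nz)
    fibmask = model.element_labels.astype(bool).reshape(nx, ny)
    lab3[fibmask, :] = LABEL_FIBROBLAST
    # six probes along the mid-height row (Figure-4-like arrangement)
    ys = np.linspace(0.2, 0.8, 3) * ny
    xs = np.linspace(0.2, 0.8, 2) * nx
    grid.probes = {f"p{k+1}": grid.flat_index(int(x), int(y), 0)
                   for k, (x, y) in enumerate((x, y) for y in ys for x in xs)}
    grid.fibrosis = model
    return grid


def bottom_edge_stimulus(grid: VoxelGrid, amplitude: float = SLAB_STIM_AMP,
                         rows: int = 2) -> Stimulus:
    """Cross-wise flat impulse: simultaneous stimulus of the bottom voxel rows."""
    nx, ny, nz = grid.dims
    mask3 = np.zeros(grid.dims, dtype=bool)
    mask3[:, :rows, :] = True
    return Stimulus(mask=mask3.reshape(-1), amplitude=amplitude)


def run_slab(grid: VoxelGrid, duration: float = 120.0,
             dt: float = DEFAULT_DT, prepaced_state: np.ndarray | None = None,
             **kw) -> SimulationResult:
    """Stimulate the bottom edge and solve; convenience for the slab suite."""
    return solve_monodomain(grid, bottom_edge_stimulus(grid), duration,
                            dt=dt, initial_state=prepaced_state, **kw)


# ------------------------------------------------------------ equilibration
def equilibrate(grid: VoxelGrid, duration: float = 200.0,
                dt: float = DEFAULT_DT,
                initial_state: np.ndarray | None = None) -> np.ndarray:
    """Relax the coupled tissue to its resting equilibrium (no stimulus).

    Myocytes adjacent to fibroblasts settle to an elevated resting potential
    through electrotonic coupling; simulating from the uncoupled single-cell
    rest states without this step injects a large artificial transient.
    Returns the relaxed (N_STATE, n) state array.
    """
    stim = Stimulus(mask=np.ones(grid.n_voxels, dtype=bool), amplitude=0.0,
                    start=0.0, duration=0.0)
    res = solve_monodomain(grid, stim, duration, dt=dt,
                           initial_state=initial_state, probe_every_ms=duration)
    return res.final_state


def _profile_grid(grid: VoxelGrid, invariant_axis: int) -> VoxelGrid:
    """1-voxel-thick slice of the grid along its structurally invariant axis."""
    nx, ny, nz = grid.dims
    sl = [slice(None)] * 3
    sl[invariant_axis] = slice(0, 1)
    sl = tuple(sl)

    def cut(arr):
        return np.ascontiguousarray(arr.reshape(nx, ny, nz)[sl]).reshape(-1)

    dims = list(grid.dims)
    dims[invariant_axis] = 1
    return VoxelGrid(dims=tuple(dims), spacing=grid.spacing,
                     label=cut(grid.label), sigma_l=cut(grid.sigma_l),
                     anisotropy=cut(grid.anisotropy),
                     fiber_axis=cut(grid.fiber_axis))


def equilibrated_state(grid: VoxelGrid, invariant_axis: int | None = None,
                       duration: float = 200.0, dt: float = DEFAULT_DT,
                       myocyte_state: np.ndarray | None = None) -> np.ndarray:
    """Coupled resting state of the grid, tiled from a 1D cross-section.

    When the tissue layout is invariant along ``invariant_axis`` (barrier
    bands: x; channels: y) the coupled equilibrium varies only across the
    profile, so it is relaxed on a 1-voxel-thick slice and tiled back --
    orders of magnitude cheaper than relaxing the full slab.  With
    ``invariant_axis=None`` the full grid is relaxed.
    """
    if invariant_axis is None:
        init = initial_tissue_state(grid, myocyte_state)
        return equilibrate(grid, duration, dt, init)
    pg = _profile_grid(grid, invariant_axis)
    S1 = equilibrate(pg, duration, dt, initial_tissue_state(pg, myocyte_state))
    nx, ny, nz = grid.dims
    pshape = list(grid.dims)
    pshape[invariant_axis] = 1
    S4 = np.broadcast_to(S1.reshape(N_STATE, *pshape),
                         (N_STATE, nx, ny, nz))
    return np.ascontiguousarray(S4.reshape(N_STATE, -1))


def paced_control_ap(region: str = "LA", bcl: float = 500.0,
                     n_beats: int = 20, dt: float = DEFAULT_DT,
                     probe_every_ms: float = 0.1):
    """Control tissue AP: plane-wave pacing of a healthy strip.

    Paces a 1-voxel-wide strip of homogeneous tissue from the bottom edge
    for ``n_beats`` at the given cycle length and returns (t, V) of the
    final beat at the mid-strip probe -- the propagated-wave counterpart of
    single-cell pacing, including the electrotonic load of the tissue.
    """
    grid = build_control_slab(region, width_mm=VOXEL_MM)
    stim = bottom_edge_stimulus(grid)
    stim.period = bcl
    duration = n_beats * bcl
    res = solve_monodomain(grid, stim, duration, dt=dt,
                           probe_every_ms=probe_every_ms)
    v = res.probe_traces["mid"]
    per_beat = int(round(bcl / res.probe_dt))
    last = v[(n_beats - 1) * per_beat:]
    t = np.arange(last.size) * res.probe_dt
    return t, last


# ------------------------------------------------------------- measurements
def measure_cv_delay(result: SimulationResult, probes: list[int],
                     path_length_mm: float):
    """Conduction velocity (m/s) over a probe path plus pairwise delays (ms).

    Returns (cv, delays) where ``cv`` is NaN if any endpoint never activated
    (conduction block) and inf if the endpoints activated simultaneously.
    ``delays[i]`` is LAT(probe[i+1]) - LAT(probe[i]), NaN across a block.
    """
    if len(probes) < 2:
        raise ValueError("need at least two probes")
    lats = np.array([result.lat[p] for p in probes])
    delays = np.diff(lats)
    if np.isnan(lats[0]) or np.isnan(lats[-1]):
        return float("nan"), delays
    dt_total = lats[-1] - lats[0]
    if dt_total == 0:
        return float("inf"), delays
    return (path_length_mm / dt_total), delays  # mm/ms == m/s


def total_activation_time(result: SimulationResult) -> float:
    return result.total_activation_time


def top_edge_activated(result: SimulationResult) -> bool:
    nx, ny, nz = result.dims
    lat3 = result.lat_3d()
    return bool(np.any(np.isfinite(lat3[:, ny - 1, :])))


# ---------------------------------------------------------------------- io
def save_grid_vtk(grid: VoxelGrid, path, lat: np.ndarray | None = None) -> None:
    """Write the labelled lattice (and optionally a LAT map) as legacy
    ASCII VTK structured points, viewable in ParaView."""
    nx, ny, nz = grid.dims
    n = grid.n_voxels
    arrays = [("tissue_label", grid.label.astype(float)),
              ("sigma_l", grid.sigma_l)]
    if lat is not None:
        arrays.append(("lat_ms", np.nan_to_num(lat, nan=-1.0)))
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nfibrofocal voxel grid\n"
                 "ASCII\nDATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {nx} {ny} {nz}\n")
        fh.write(f"SPACING {grid.spacing} {grid.spacing} {grid.spacing}\n")
        fh.write("ORIGIN 0 0 0\n")
        fh.write(f"POINT_DATA {n}\n")
        for name, arr in arrays:
            fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
            # VTK structured points expect x fastest; our flat order is
            # C-order (z fastest), so transpose
            vals = arr.reshape(nx, ny, nz).transpose(2, 1, 0).reshape(-1)
            fh.write("\n".join(f"{v:.6g}" for v in vals))
            fh.write("\n")


# --------------------------------------------------------------- calibration
def plane_wave_cv(diffusion_scale: float | None = None, region: str = "LA",
                  dt: float = DEFAULT_DT, length_mm: float = SLAB_MM) -> float:
    """Plane-wave CV (m/s) on a narrow strip; used to calibrate
    ``diffusion_scale`` against the 59 ms slab-crossing anchor."""
    grid = build_control_slab(region, width_mm=3 * VOXEL_MM, height_mm=length_mm)
    ny = grid.dims[1]
    p1 = grid.flat_index(1, int(0.3 * ny), 0)
    p2 = grid.flat_index(1, int(0.7 * ny), 0)
    dist = (int(0.7 * ny) - int(0.3 * ny)) * grid.spacing
    saved = TISSUE["diffusion_scale"]
    if diffusion_scale is not None:
        TISSUE["diffusion_scale"] = diffusion_scale
    try:
        res = run_slab(grid, duration=1.4 * length_mm / 0.5, dt=dt)
    finally:
        TISSUE["diffusion_scale"] = saved
    cv, _ = measure_cv_delay(res, [p1, p2], dist)
    return cv
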