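"""Stochastic patchy-fibrosis generation with Utah staging.

Fibrosis is seeded in named left-atrial regions (pulmonary veins, coronary
sinus, fossa-ovalis ring, posterior LA wall) and grown by iterative frontier
expansion; each newly added contour element is randomly reverted to healthy
with probability ``drop_prob``, producing irregular patch shapes that can
enclose surviving healthy islands.  Growth is staged by the Utah
classification of left-atrial fibrotic burden (quartiles of the
fibrotic-to-atrial volume ratio): stage I < 8.1 %, II < 16 %, III < 21 %,
IV > 21 %, with two growth targets inside the top quartile (stages IV and V).

The generator is mesh-agnostic: it works on any element set given as a CSR
adjacency plus per-element volumes (voxel lattices and triangulated surfaces
alike).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

DEFAULT_DROP_PROB = 0.3
#: growth targets (volume fractions) for stages I..V, spanning 2-40 %
DEFAULT_STAGE_TARGETS = (0.02, 0.12, 0.18, 0.28, 0.40)
#: Utah band edges: stage I < 0.081 <= II < 0.16 <= III < 0.21 <= IV
UTAH_EDGES = (0.081, 0.16, 0.21)
#: default seed regions, equal weights (stated proportions are unspecified)
DEFAULT_SEED_REGIONS = ("PV", "CS", "FO_ring", "LA_posterior")
STAGE_NAMES = ("I", "II", "III", "IV", "V")


class UnreachableTargetError(RuntimeError):
    def __init__(self, achieved: float, target: float):
        super().__init__(
            f"growth exhausted the connected domain at fraction "
            f"{achieved:.4f} < target {target:.4f}")
        self.achieved = achieved


@dataclass(frozen=True)
class StageSpec:
    """Utah band for one stage: fraction in (lower, upper]."""

    stage: int
    lower: float
    upper: float

    @property
    def name(self) -> str:
        return STAGE_NAMES[self.stage - 1]


def stage_specs() -> tuple[StageSpec, ...]:
    e1, e2, e3 = UTAH_EDGES
    return (StageSpec(1, 0.0, e1), StageSpec(2, e1, e2), StageSpec(3, e2, e3),
            StageSpec(4, e3, 1.0), StageSpec(5, e3, 1.0))


@dataclass
class FibrosisModel:
    """Per-element fibrotic/healthy labelling of one generated distribution."""

    element_labels: np.ndarray        # uint8, 1 = fibrotic
    case_id: int
    stage: int
    fraction: float                   # fibrotic / reference volume
    seed_regions: dict = field(default_factory=dict)
    rng_seed: int = 0

    @property
    def fibrotic_index(self) -> np.ndarray:
        return np.nonzero(self.element_labels)[0]

    def metadata(self) -> dict:
        return dict(case_id=self.case_id, stage=self.stage,
                    fraction=self.fraction, rng_seed=self.rng_seed,
                    seed_regions=self.seed_regions,
                    n_fibrotic=int(self.element_labels.sum()))

    def save(self, path_prefix) -> None:
        """Write the per-element labels (text) plus a JSON metadata sidecar."""
        import json
        from pathlib import Path

        prefix = Path(path_prefix)
        np.savetxt(prefix.with_suffix(".labels.txt"), self.element_labels,
                   fmt="%d")
        prefix.with_suffix(".json").write_text(json.dumps(self.metadata(),
                                                          indent=2))

    @classmethod
    def load(cls, path_prefix) -> "FibrosisModel":
        import json
        from pathlib import Path

        prefix = Path(path_prefix)
        labels = np.loadtxt(prefix.with_suffix(".labels.txt"),
                            dtype=np.uint8, ndmin=1)
        meta = json.loads(prefix.with_suffix(".json").read_text())
        return cls(element_labels=labels, case_id=meta["case_id"],
                   stage=meta["stage"], fraction=meta["fraction"],
                   seed_regions=meta.get("seed_regions", {}),
                   rng_seed=meta.get("rng_seed", 0))


@dataclass
class ElementMesh:
    """Minimal element-set view used by the generator.

    ``adjacency`` is a (n x n) boolean/binary CSR matrix of shared-border
    neighbourhood; ``volumes`` per-element volume (or area) and ``regions``
    per-element region names.  ``reference_volume`` is the denominator of
    the fibrotic fraction (the LA volume in the staging definition); it
    defaults to the total volume of the mesh.
    """

    adjacency: sparse.csr_matrix
    volumes: np.ndarray
    regions: np.ndarray | None = None
    reference_volume: float | None = None

    def __post_init__(self):
        self.adjacency = sparse.csr_matrix(self.adjacency)
        self.volumes = np.asarray(self.volumes, dtype=float)
        if self.reference_volume is None:
            self.reference_volume = float(self.volumes.sum())

    @property
    def n_elements(self) -> int:
        return self.volumes.size


def grid_adjacency(nx: int, ny: int) -> sparse.csr_matrix:
    """4-neighbour adjacency of an nx-by-ny voxel sheet (C-order flat)."""
    g = sparse.lil_matrix((nx * ny, nx * ny), dtype=np.uint8)
    idx = np.arange(nx * ny).reshape(nx, ny)
    for a, b in ((idx[:-1, :], idx[1:, :]), (idx[:, :-1], idx[:, 1:])):
        g[a.ravel(), b.ravel()] = 1
        g[b.ravel(), a.ravel()] = 1
    return g.tocsr()


# -------------------------------------------------------------------- seeds
def place_seeds(mesh: ElementMesh, n_seeds: int,
                region_weights: dict[str, float] | None = None,
                rng_seed: int = 0) -> np.ndarray:
    """Draw ``n_seeds`` distinct elements across weighted regions.

    Seeds are allocated to regions proportionally to the weights (largest
    remainder rounding) and drawn uniformly within each region.
    """
    if n_seeds == 0:
        return np.empty(0, dtype=np.int64)
    if n_seeds < 0:
        raise ValueError("n_seeds must be >= 0")
    rng = np.random.default_rng(rng_seed)
    if region_weights is None:
        if mesh.regions is None:
            return rng.choice(mesh.n_elements, size=n_seeds, replace=False)
        region_weights = {r: 1.0 for r in DEFAULT_SEED_REGIONS}
    total_w = sum(region_weights.values())
    names = sorted(region_weights)
    quotas = {}
    exact = {r: n_seeds * region_weights[r] / total_w for r in names}
    base = {r: int(np.floor(exact[r])) for r in names}
    rem = n_seeds - sum(base.values())
    order = sorted(names, key=lambda r: exact[r] - base[r], reverse=True)
    for r in names:
        quotas[r] = base[r]
    for r in order[:rem]:
        quotas[r] += 1
    members = {r: np.nonzero(mesh.regions == r)[0] for r in names}
    for r in names:
        if region_weights[r] > 0 and members[r].size == 0:
            raise ValueError(f"seed region {r!r} has no elements on the mesh")
    # cap quotas at the region size and redistribute the overflow to
    # regions with spare capacity (coarse meshes can have tiny regions)
    overflow = 0
    for r in names:
        if quotas[r] > members[r].size:
            overflow += quotas[r] - members[r].size
            quotas[r] = members[r].size
    while overflow:
        spare = [r for r in names if quotas[r] < members[r].size]
        if not spare:
            raise ValueError("fewer candidate elements than requested seeds")
        for r in sorted(spare, key=lambda r: region_weights[r], reverse=True):
            if overflow == 0:
                break
            quotas[r] += 1
            overflow -= 1
    seeds = []
    for r in names:
        if quotas[r]:
            seeds.append(rng.choice(members[r], size=quotas[r], replace=False))
    return np.sort(np.concatenate(seeds))


def place_seeds_uniform(n_elements: int, n_seeds: int, rng_seed: int) -> np.ndarray:
    """Region-free variant for homogeneous slabs."""
    rng = np.random.default_rng(rng_seed)
    return np.sort(rng.choice(n_elements, size=n_seeds, replace=False))


# ------------------------------------------------------------------- growth
def grow_fibrosis(adjacency: sparse.csr_matrix, volumes: np.ndarray,
                  seeds: np.ndarray, target_fraction: float,
                  drop_prob: float = DEFAULT_DROP_PROB, rng_seed: int = 0,
                  case_id: int = 0, stage: int = 0,
                  reference_volume: float | None = None,
                  start_labels: np.ndarray | None = None,
                  seed_regions: dict | None = None) -> FibrosisModel:
    """Grow patches from ``seeds`` until the fibrotic fraction reaches target.

    Each iteration adds the frontier of the most recently added elements and
    reverts every newly added element independently with ``drop_prob``;
    reverted contour sites adjacent to older fibrosis are not retried, which
    yields ragged contours and enclosed healthy islands.  If the running
    frontier dies out, growth resumes from the full fibrotic boundary.
    Passing ``start_labels`` continues growth from a previous stage, making
    consecutive stages nested supersets.
    """
    if not (0.0 < target_fraction < 1.0) and start_labels is None:
        if target_fraction == 0.0 or seeds.size == 0:
            lab = np.zeros(volumes.size, dtype=np.uint8)
            return FibrosisModel(lab, case_id, stage, 0.0, seed_regions or {}, rng_seed)
        raise ValueError("target_fraction must be in (0, 1)")
    if not (0.0 <= drop_prob < 1.0):
        raise ValueError("drop_prob must be in [0, 1)")
    adjacency = sparse.csr_matrix(adjacency)
    volumes = np.asarray(volumes, dtype=float)
    ref = float(volumes.sum()) if reference_volume is None else float(reference_volume)
    rng = np.random.default_rng(rng_seed)

    fib = (np.zeros(volumes.size, dtype=bool) if start_labels is None
           else start_labels.astype(bool).copy())
    if start_labels is None:
        fib[seeds] = True
        recent = np.asarray(seeds, dtype=np.int64)
    else:
        recent = np.nonzero(fib)[0]

    indptr, indices = adjacency.indptr, adjacency.indices

    def neighbours(of: np.ndarray) -> np.ndarray:
        if of.size == 0:
            return np.empty(0, dtype=np.int64)
        parts = [indices[indptr[i]:indptr[i + 1]] for i in of]
        return np.unique(np.concatenate(parts))

    frac = float(volumes[fib].sum() / ref)
    while frac < target_fraction:
        cand = neighbours(recent)
        cand = cand[~fib[cand]]
        if cand.size == 0:
            # running frontier extinguished: resume from the full boundary
            cand = neighbours(np.nonzero(fib)[0])
            cand = cand[~fib[cand]]
            if cand.size == 0:
                raise UnreachableTargetError(frac, target_fraction)
        keep = rng.random(cand.size) >= drop_prob
        added = cand[keep]
        if added.size == 0:
            # do not let pure chance stall an iteration
            added = cand[rng.integers(cand.size):][:1]
        # trim the final batch so the achieved fraction lands at the target
        # (at most one element of overshoot) instead of a full frontier layer
        needed = target_fraction * ref - float(volumes[fib].sum())
        batch_vol = np.cumsum(volumes[added])
        if batch_vol[-1] > needed:
            stop = int(np.searchsorted(batch_vol, needed)) + 1
            added = added[:stop]
        fib[added] = True
        recent = added
        frac = float(volumes[fib].sum() / ref)

    return FibrosisModel(fib.astype(np.uint8), case_id, stage, frac,
                         seed_regions or {}, rng_seed)


def classify_utah_stage(fraction: float, generator_stage: int | None = None) -> int:
    """Utah stage (1..5) of a fibrotic fraction.

    Band edges go up: a fraction exactly at an edge belongs to the higher
    stage.  Stages 4 and 5 share the top quartile; they are disambiguated by
    the generator's growth target (``generator_stage``), defaulting to 4.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    e1, e2, e3 = UTAH_EDGES
    if fraction < e1:
        return 1
    if fraction < e2:
        return 2
    if fraction < e3:
        return 3
    return 5 if generator_stage == 5 else 4


def build_case_library(mesh: ElementMesh, n_cases: int = 5,
                       stage_targets: tuple = DEFAULT_STAGE_TARGETS,
                       rng_base: int = 0, n_seeds: int = 50,
                       region_weights: dict[str, float] | None = None,
                       drop_prob: float = DEFAULT_DROP_PROB
                       ) -> dict[tuple[int, int], FibrosisModel]:
    """5 cases x 5 nested stages of patchy fibrosis on one mesh."""
    if list(stage_targets) != sorted(stage_targets):
        raise ValueError("stage_targets must be increasing")
    library: dict[tuple[int, int], FibrosisModel] = {}
    for case in range(1, n_cases + 1):
        case_seed = int(rng_base) * 1000 + case * 37
        seeds = place_seeds(mesh, n_seeds, region_weights, rng_seed=case_seed)
        w = region_weights or (
            {r: 1.0 for r in DEFAULT_SEED_REGIONS} if mesh.regions is not None else {})
        prev = None
        for stage, target in enumerate(stage_targets, start=1):
            model = grow_fibrosis(
                mesh.adjacency, mesh.volumes, seeds, target,
                drop_prob=drop_prob, rng_seed=case_seed + stage,
                case_id=case, stage=stage,
                reference_volume=mesh.reference_volume,
                start_labels=(None if prev is None else prev.element_labels),
                seed_regions=w)
            library[(case, stage)] = model
            prev = model
    return library


# ------------------------------------------------------------------ queries
def healthy_islands(adjacency: sparse.csr_matrix, labels: np.ndarray) -> int:
    """Number of healthy connected components fully bordered by fibrosis.

    A component touching any element with no fibrotic neighbour on its
    border... more simply: healthy components none of whose members border
    the outer healthy bulk; computed as healthy components other than the
    largest one that are entirely surrounded (all outside-neighbours
    fibrotic).
    """
    healthy = ~labels.astype(bool)
    sub = adjacency[healthy][:, healthy]
    n_comp, comp = sparse.csgraph.connected_components(sub, directed=False)
    if n_comp <= 1:
        return 0
    sizes = np.bincount(comp)
    return int(n_comp - 1) if sizes.size > 1 else 0
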