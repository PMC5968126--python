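"""Clustering, validation and classification of body-surface integral maps.

Pipeline stages over a runs-by-electrodes BSPiM feature table:

* electrode reduction -- the dense torso sampling is partitioned into P
  spatially contiguous, size-balanced patches and one random representative
  node per patch becomes an electrode;
* unsupervised Ward agglomerative clustering of the maps, cut at K = 2..10;
* association of clusters to atrial regions through the ectopic graph
  (foci connected when their geodesic-Voronoi patches share a border), with
  persistence, overlapped-regions (OR), connection-ratio (CR) and region
  area metrics;
* chi-squared feature (electrode) selection for N = 2, 4, ..., 256;
* RBF-kernel SVM classification with stratified 4-fold cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.cluster import KMeans
from sklearn.feature_selection import chi2 as sk_chi2
from sklearn.model_selection import GridSearchCV, StratifiedKFold, cross_val_score
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

DEFAULT_K_RANGE = tuple(range(2, 11))
DEFAULT_N_LIST = (2, 4, 8, 16, 32, 64, 128, 256)
SVM_C_GRID = (0.1, 1.0, 10.0, 100.0)
SVM_GAMMA_GRID = ("scale", 0.001, 0.01, 0.1)


# ------------------------------------------------------ electrode reduction
@dataclass
class ElectrodeLayout:
    """Partition of torso nodes into patches with one representative each."""

    patch_of_node: np.ndarray      # (n_nodes,) patch id
    representatives: np.ndarray    # (P,) node ids
    rng_seed: int

    @property
    def n_patches(self) -> int:
        return len(self.representatives)

    def patch_sizes(self) -> np.ndarray:
        return np.bincount(self.patch_of_node, minlength=self.n_patches)


def reduce_electrodes(torso, P: int = 256, rng_seed: int = 0) -> ElectrodeLayout:
    """Partition the torso into P contiguous patches; sample one node each.

    The balanced geometric partition is a k-means tessellation of the node
    coordinates (deterministic initialisation), giving mean patch size
    n_nodes / P; representative sampling is separately seeded so the same
    patches can host different electrode draws.
    """
    n = torso.n_nodes
    if P > n:
        raise ValueError("more patches than torso nodes")
    km = KMeans(n_clusters=P, n_init=1, random_state=0)
    patch = km.fit_predict(np.asarray(torso.vertices))
    rng = np.random.default_rng(rng_seed)
    reps = np.empty(P, dtype=np.int64)
    for p in range(P):
        members = np.nonzero(patch == p)[0]
        reps[p] = int(rng.choice(members))
    return ElectrodeLayout(patch_of_node=patch, representatives=reps,
                           rng_seed=rng_seed)


# ---------------------------------------------------------------- clustering
@dataclass
class ClusteringResult:
    linkage: np.ndarray                    # scipy linkage matrix
    labels: dict[int, np.ndarray]          # K -> per-sample labels (0..K-1)

    def cut(self, K: int) -> np.ndarray:
        return self.labels[K]


def ward_cluster(features: np.ndarray,
                 k_range=DEFAULT_K_RANGE) -> ClusteringResult:
    """Ward variance-minimizing agglomerative clustering, cut at each K."""
    X = np.asarray(features, dtype=float)
    if X.ndim != 2:
        raise ValueError("features must be 2-D (runs x electrodes)")
    if np.isnan(X).any():
        raise ValueError("features contain missing values")
    if X.shape[0] < max(k_range):
        raise ValueError("fewer samples than the largest requested K")
    Z = hierarchy.linkage(X, method="ward")
    labels = {}
    for K in k_range:
        lab = hierarchy.fcluster(Z, t=K, criterion="maxclust") - 1
        labels[K] = lab
    return ClusteringResult(linkage=Z, labels=labels)


# ------------------------------------------------------------- ectopic graph
@dataclass
class EctopicGraph:
    graph: nx.Graph                 # nodes = focus ids
    patch_of_vertex: np.ndarray     # (n_vertices,) focus index, -1 unassigned
    patch_area: dict[str, float]    # cm^2 per focus
    focus_ids: list[str]


def build_ectopic_graph(atlas, foci=None) -> EctopicGraph:
    """Geodesic-Voronoi tessellation of the atria around the foci.

    Every surface vertex is assigned to its geodesically closest focus;
    foci are connected when their patches share a mesh edge (or an
    inter-atrial connection edge).
    """
    surface = atlas.atria
    foci = list(atlas.primary_foci if foci is None else foci)
    ids = [f.id for f in foci]
    D = np.vstack([surface.geodesics.distances(f.vertex) for f in foci])
    owner = np.argmin(D, axis=0)
    owner[~np.isfinite(D.min(axis=0))] = -1
    areas_mm2 = np.zeros(len(foci))
    np.add.at(areas_mm2, owner[owner >= 0],
              surface.vertex_areas[owner >= 0])
    g = nx.Graph()
    g.add_nodes_from(ids)
    edges = set()
    f = surface.faces
    for (a, b) in [(0, 1), (1, 2), (2, 0)]:
        pa, pb = owner[f[:, a]], owner[f[:, b]]
        m = (pa != pb) & (pa >= 0) & (pb >= 0)
        edges.update(map(tuple, np.sort(np.stack([pa[m], pb[m]], 1), axis=1)))
    for (u, v, _name) in surface.connection_edges:
        if owner[u] >= 0 and owner[v] >= 0 and owner[u] != owner[v]:
            edges.add(tuple(sorted((owner[u], owner[v]))))
    g.add_edges_from((ids[i], ids[j]) for i, j in edges)
    patch_area = {ids[i]: areas_mm2[i] / 100.0 for i in range(len(ids))}  # cm^2
    return EctopicGraph(graph=g, patch_of_vertex=owner,
                        patch_area=patch_area, focus_ids=ids)


# ------------------------------------------------------- cluster association
def induce_atrial_clusters(labels: np.ndarray, run_foci: list[str],
                           K: int) -> dict[str, frozenset[int]]:
    """Label set accumulated by each focus from its runs' cluster labels."""
    if len(labels) != len(run_foci):
        raise ValueError("one focus id per run required")
    sets: dict[str, set[int]] = {}
    for lab, fid in zip(labels, run_foci):
        sets.setdefault(fid, set()).add(int(lab))
    return {fid: frozenset(s) for fid, s in sets.items()}


@dataclass
class ClusterMetrics:
    K: int
    mean_area: float          # cm^2, double-counting multiply-labelled foci
    sd_area: float
    OR: float                 # % foci with > 1 label
    CR: float                 # % foci in the largest component of their class
    CR_clusters: float        # % clusters whose subgraph is connected
    persistence: dict[str, float]


def compute_metrics(labelsets: dict[str, frozenset[int]],
                    graph: EctopicGraph, K: int) -> ClusterMetrics:
    """Persistence / OR / CR / region-area metrics of one induced clustering.

    CR uses the node-based reading (fraction of foci belonging to the
    largest connected component of their class subgraph); the
    cluster-based variant (connected classes over all classes) is reported
    as a secondary value.
    """
    if not labelsets:
        raise ValueError("empty label sets")
    foci = sorted(labelsets)
    n = len(foci)
    n_multi = sum(1 for f in foci if len(labelsets[f]) > 1)
    OR = 100.0 * n_multi / n
    persistence = {f: len(labelsets[f]) / K for f in foci}

    # class subgraphs over the ectopic graph
    members: dict[int, list[str]] = {}
    for f in foci:
        for lab in labelsets[f]:
            members.setdefault(lab, []).append(f)
    n_connected_classes = 0
    not_isolated: set[str] = set()
    for lab, mem in members.items():
        sub = graph.graph.subgraph(mem)
        if nx.is_connected(sub) if len(mem) > 0 else True:
            n_connected_classes += 1
        if len(mem) == 1:
            # a singleton class is a trivially well-formed region
            not_isolated.add(mem[0])
        else:
            for f in mem:
                if sub.degree(f) > 0:
                    not_isolated.add(f)
    # node-based connection ratio: foci that are linked to their class
    # (isolated ectopics are the ones subtracted in the worked example)
    CR = 100.0 * len(not_isolated) / n
    CR_clusters = 100.0 * n_connected_classes / max(len(members), 1)

    areas = []
    for lab, mem in members.items():
        areas.append(sum(graph.patch_area.get(f, 0.0) for f in mem))
    areas = np.asarray(areas)
    return ClusterMetrics(K=K, mean_area=float(areas.mean()),
                          sd_area=float(areas.std()),
                          OR=OR, CR=CR, CR_clusters=CR_clusters,
                          persistence=persistence)


# --------------------------------------------------------- feature selection
def chi2_select(features: np.ndarray, labels: np.ndarray, N: int) -> np.ndarray:
    """Top-N electrode indices by chi-squared dependence on the class label.

    BSPiM values in [-1, 1] are min-max rescaled to [0, 1] per feature
    before scoring (the statistic requires non-negative inputs); ties break
    toward the lower index.  A single global ranking guarantees nested
    feature sets across N.
    """
    if N > np.asarray(features).shape[1]:
        raise ValueError("N exceeds the number of features")
    return np.sort(chi2_ranking(features, labels)[:N])


def chi2_ranking(features: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Global electrode ranking (descending score, ties toward lower index)."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if np.unique(y).size < 2:
        raise ValueError("chi-squared scoring needs at least two classes")
    lo = X.min(axis=0)
    span = X.max(axis=0) - lo
    span[span == 0] = 1.0
    scores, _ = sk_chi2((X - lo) / span, y)
    scores = np.nan_to_num(scores, nan=0.0)
    return np.lexsort((np.arange(scores.size), -scores))


# ------------------------------------------------------------ classification
def classify_cv(features: np.ndarray, labels: np.ndarray, folds: int = 4,
                rng_seed: int = 0, fast: bool = False) -> float:
    """Mean stratified k-fold accuracy of an RBF-SVM on the given features.

    Hyperparameters (C and kernel width) are tuned by an inner 3-fold grid
    search on each training split; features are standardized inside the
    pipeline.  Classes smaller than the fold count are merged into the
    nearest (by centroid distance) larger class with a warning.
    """
    import warnings

    X = np.asarray(features, dtype=float)
    y = np.asarray(labels).copy()
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("single-class labels")
    small = classes[counts < folds]
    if small.size:
        warnings.warn(f"merging {small.size} classes smaller than {folds} "
                      "into their nearest larger class")
        big = classes[counts >= folds]
        if big.size == 0:
            raise ValueError("all classes smaller than the fold count")
        cents = {c: X[y == c].mean(axis=0) for c in classes}
        for c in small:
            tgt = min(big, key=lambda b: np.linalg.norm(cents[c] - cents[b]))
            y[y == c] = tgt
    if fast:
        clf = Pipeline([("scale", StandardScaler()),
                        ("svm", SVC(kernel="rbf", C=10.0, gamma="scale"))])
    else:
        grid = {"svm__C": list(SVM_C_GRID), "svm__gamma": list(SVM_GAMMA_GRID)}
        clf = GridSearchCV(
            Pipeline([("scale", StandardScaler()), ("svm", SVC(kernel="rbf"))]),
            grid, cv=3, n_jobs=1)
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=rng_seed)
    scores = cross_val_score(clf, X, y, cv=cv, n_jobs=1)
    return float(scores.mean())


# ------------------------------------------------------------- full pipeline
@dataclass
class PipelineReport:
    model: str
    metrics: pd.DataFrame          # per K: mean_area, sd_area, OR, CR, CA
    labelsets: dict[int, dict]
    accuracy: pd.DataFrame         # per (K, N): CA
    selected: dict[tuple[int, int], np.ndarray] = field(default_factory=dict)
    linkage: np.ndarray | None = None  # Ward tree (for dendrograms)


def run_full_pipeline(features: np.ndarray, run_foci: list[str],
                      graph: EctopicGraph, model: str = "M?",
                      k_range=DEFAULT_K_RANGE, n_list=(256,),
                      rng_seed: int = 0, fast: bool = False) -> PipelineReport:
    """Clustering -> induction -> metrics -> chi2 selection -> SVM accuracy."""
    clus = ward_cluster(features, k_range)
    rows, acc_rows, labelsets_by_k, selected = [], [], {}, {}
    for K in k_range:
        labels = clus.cut(K)
        sets = induce_atrial_clusters(labels, run_foci, K)
        met = compute_metrics(sets, graph, K)
        labelsets_by_k[K] = sets
        ca256 = None
        for N in n_list:
            sel = chi2_select(features, labels, N)
            selected[(K, N)] = sel
            ca = classify_cv(features[:, sel], labels, rng_seed=rng_seed,
                             fast=fast)
            acc_rows.append(dict(model=model, K=K, N=N, CA=ca))
            if N == max(n_list):
                ca256 = ca
        rows.append(dict(model=model, K=K, mean_area=met.mean_area,
                         sd_area=met.sd_area, OR=met.OR, CR=met.CR,
                         CA=ca256))
    return PipelineReport(model=model, metrics=pd.DataFrame(rows),
                          labelsets=labelsets_by_k,
                          accuracy=pd.DataFrame(acc_rows), selected=selected,
                          linkage=clus.linkage)
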