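"""Electrode reduction, Ward clustering, metrics, selection, classification."""

import networkx as nx
import numpy as np
import pytest

from fibrofocal import mlpipe as ml


# ----------------------------------------------------- electrode reduction
def test_patches_partition_nodes_with_expected_mean(small_atlas):
    layout = ml.reduce_electrodes(small_atlas.torso, 256, rng_seed=0)
    sizes = layout.patch_sizes()
    assert sizes.sum() == small_atlas.torso.n_nodes
    assert sizes.mean() == pytest.approx(small_atlas.torso.n_nodes / 256)
    assert np.all(sizes > 0)
    # one representative per patch, inside its patch
    assert len(layout.representatives) == 256
    assert all(layout.patch_of_node[r] == p
               for p, r in enumerate(layout.representatives))


def test_identity_layout_when_p_equals_nodes():
    from fibrofocal.atlas import build_torso

    torso = build_torso(256)
    layout = ml.reduce_electrodes(torso, 256, rng_seed=1)
    assert np.array_equal(np.sort(layout.representatives), np.arange(256))


def test_same_patches_different_representatives(small_atlas):
    a = ml.reduce_electrodes(small_atlas.torso, 64, rng_seed=0)
    b = ml.reduce_electrodes(small_atlas.torso, 64, rng_seed=1)
    assert np.array_equal(a.patch_of_node, b.patch_of_node)
    assert not np.array_equal(a.representatives, b.representatives)


def test_too_many_patches_rejected(small_atlas):
    with pytest.raises(ValueError):
        ml.reduce_electrodes(small_atlas.torso, small_atlas.torso.n_nodes + 1)


# -------------------------------------------------------------- clustering
def test_ward_separates_two_blobs(rng):
    a = rng.normal(0.0, 0.1, size=(20, 8))
    b = rng.normal(5.0, 0.1, size=(30, 8)) * [1, -1, 1, -1, 1, -1, 1, -1]
    X = np.vstack([a, b])
    res = ml.ward_cluster(X, (2,))
    lab = res.cut(2)
    assert len(set(lab[:20])) == 1 and len(set(lab[20:])) == 1
    assert lab[0] != lab[20]
    # first split conserves the sample count
    assert np.bincount(lab).sum() == 50


def test_ward_merge_heights_nondecreasing(rng):
    X = rng.normal(size=(40, 6))
    res = ml.ward_cluster(X, (2, 3))
    heights = res.linkage[:, 2]
    assert np.all(np.diff(heights) >= -1e-12)


def test_tree_cut_consistency(rng):
    """Cutting at K then K+1 splits exactly one cluster."""
    X = rng.normal(size=(60, 5))
    res = ml.ward_cluster(X, tuple(range(2, 11)))
    for K in range(2, 10):
        a, b = res.cut(K), res.cut(K + 1)
        # map each K+1 cluster to the K cluster containing it
        parents = {}
        for i in range(len(a)):
            parents.setdefault(b[i], set()).add(a[i])
        assert all(len(p) == 1 for p in parents.values())
        split = [pa for pa, kids in _children(a, b).items() if len(kids) > 1]
        assert len(split) == 1


def _children(a, b):
    out = {}
    for i in range(len(a)):
        out.setdefault(a[i], set()).add(b[i])
    return out


def test_ward_input_validation(rng):
    with pytest.raises(ValueError):
        ml.ward_cluster(rng.normal(size=(4, 3)), (10,))
    bad = rng.normal(size=(20, 3))
    bad[0, 0] = np.nan
    with pytest.raises(ValueError):
        ml.ward_cluster(bad, (2,))


# ----------------------------------------------------- induction + metrics
def _line_graph(ids):
    g = nx.Graph()
    g.add_nodes_from(ids)
    g.add_edges_from(zip(ids[:-1], ids[1:]))
    return g


def _graph_for(ids, edges=None):
    g = _line_graph(ids) if edges is None else nx.Graph(edges)
    if edges is not None:
        g.add_nodes_from(ids)
    return ml.EctopicGraph(graph=g, patch_of_vertex=np.empty(0),
                           patch_area={i: 1.0 for i in ids}, focus_ids=ids)


def test_persistence_definition_and_bounds():
    ids = [f"F{i}" for i in range(19)]
    labels = np.zeros(19, dtype=int)
    sets = ml.induce_atrial_clusters(labels, ids, K=5)
    met = ml.compute_metrics(sets, _graph_for(ids), K=5)
    assert all(v == pytest.approx(1 / 5) for v in met.persistence.values())
    # a focus in two clusters of K=10 has persistence 2/10
    labels2 = np.array([0] * 19 + [1])
    sets2 = ml.induce_atrial_clusters(labels2, ids + [ids[-1]], K=10)
    met2 = ml.compute_metrics(sets2, _graph_for(ids), K=10)
    assert met2.persistence[ids[-1]] == pytest.approx(2 / 10)
    for v in met2.persistence.values():
        assert 1 / 10 <= v <= 1.0


def test_or_worked_example_one_of_nineteen():
    """1 of 19 foci spread over two clusters -> OR = 5.26 %."""
    ids = [f"F{i}" for i in range(19)]
    runs = ids + [ids[4]]
    labels = np.array([0] * 10 + [1] * 9 + [1])  # F4 appears in 0 and 1
    sets = ml.induce_atrial_clusters(labels, runs, K=10)
    met = ml.compute_metrics(sets, _graph_for(ids), K=10)
    assert met.OR == pytest.approx(100 * 1 / 19, abs=0.005)
    assert met.OR == pytest.approx(5.26, abs=0.01)


def test_cr_worked_example_two_isolated_of_nineteen():
    """Two foci isolated from their class subgraph -> CR = 89.4 %."""
    ids = [f"F{i}" for i in range(19)]
    g = _line_graph(ids)
    # class 1 = {F0, F10}: not adjacent in the line graph -> both isolated
    labels = np.array([1] + [0] * 9 + [1] + [0] * 8)
    eg = ml.EctopicGraph(graph=g, patch_of_vertex=np.empty(0),
                         patch_area={i: 1.0 for i in ids}, focus_ids=ids)
    sets = ml.induce_atrial_clusters(labels, ids, K=6)
    met = ml.compute_metrics(sets, eg, K=6)
    assert met.CR == pytest.approx(100 * 17 / 19, abs=0.01)
    assert met.CR == pytest.approx(89.4, abs=0.1)


def test_fully_connected_classes_give_cr_100_and_or_0():
    ids = [f"F{i}" for i in range(12)]
    labels = np.array([0] * 6 + [1] * 6)  # two contiguous line segments
    sets = ml.induce_atrial_clusters(labels, ids, K=2)
    met = ml.compute_metrics(sets, _graph_for(ids), K=2)
    assert met.OR == 0.0
    assert met.CR == 100.0
    assert met.CR_clusters == 100.0


def test_region_area_double_counts_multilabel_foci():
    ids = ["A", "B", "C"]
    runs = ["A", "B", "C", "C"]
    labels = np.array([0, 1, 0, 1])  # C belongs to both clusters
    sets = ml.induce_atrial_clusters(labels, runs, K=2)
    met = ml.compute_metrics(sets, _graph_for(ids), K=2)
    # areas: cluster0 = {A, C} -> 2, cluster1 = {B, C} -> 2 (C counted twice)
    assert met.mean_area == pytest.approx(2.0)


# --------------------------------------------------------- chi2 selection
def test_chi2_recovers_planted_informative_electrodes(rng):
    y = np.repeat([0, 1, 2], 30)
    X = rng.uniform(-1, 1, size=(90, 64))
    for k in range(4):  # electrodes 0-3 encode the class
        X[:, k] = y * 0.6 - 0.6 + rng.uniform(-0.05, 0.05, size=90)
    top4 = ml.chi2_select(X, y, 4)
    assert set(top4) == {0, 1, 2, 3}


def test_chi2_constant_feature_ranked_last(rng):
    y = np.repeat([0, 1], 20)
    X = rng.uniform(0, 1, size=(40, 10))
    X[:, 7] = 0.42
    ranking = ml.chi2_ranking(X, y)
    assert ranking[-1] == 7 or ml.chi2_select(X, y, 9).tolist().count(7) == 0


def test_chi2_identity_when_n_equals_features(rng):
    y = np.repeat([0, 1], 10)
    X = rng.uniform(size=(20, 6))
    assert np.array_equal(ml.chi2_select(X, y, 6), np.arange(6))


def test_chi2_single_class_rejected(rng):
    with pytest.raises(ValueError):
        ml.chi2_select(rng.uniform(size=(10, 4)), np.zeros(10), 2)


def test_chi2_feature_sets_nest(rng):
    y = np.repeat([0, 1, 2], 20)
    X = rng.uniform(-1, 1, size=(60, 32))
    X[:, :6] += y[:, None] * 0.4
    prev = set()
    for N in (2, 4, 8, 16, 32):
        cur = set(ml.chi2_select(X, y, N).tolist())
        assert prev <= cur
        prev = cur


def test_chi2_invariant_to_feature_permutation(rng):
    y = np.repeat([0, 1], 25)
    X = rng.uniform(-1, 1, size=(50, 12))
    X[:, 3] += y
    perm = rng.permutation(12)
    sel = ml.chi2_select(X, y, 3)
    sel_p = ml.chi2_select(X[:, perm], y, 3)
    assert set(perm[sel_p]) == set(sel)


def test_zero_fibrosis_perturbation_recovers_baseline_labels(
        all_datasets, electrode_layout, ap_template, small_config):
    """If the fibrosis perturbation vanishes, every focus's 25 runs carry
    the same map (up to noise) and persistence collapses to 1/K."""
    from fibrofocal import atlas as at
    from fibrofocal import experiments as ex

    _, _, datasets = all_datasets
    m0 = datasets["M0"]
    base = {r.focus.id: r for r in m0.runs}
    runs = []
    for case in range(1, 6):
        for stage in range(1, 6):
            for fid in m0.atlas.primary_ids:
                b = base[fid]
                runs.append(at.ActivationRun(f"c{case}s{stage}_{fid}",
                                             b.focus, case, stage, False,
                                             b.lat))
    flat = at.ActivationDataset(runs=runs, atlas=m0.atlas,
                                fibrosis_library={})
    X, foci, _ = ex.bspim_features(flat, electrode_layout, ap_template,
                                   small_config)
    for K in (4, 6):
        y = ml.ward_cluster(X, (K,)).cut(K)
        sets = ml.induce_atrial_clusters(y, foci, K)
        assert all(len(s) == 1 for s in sets.values())  # persistence 1/K


# ------------------------------------------------------------ classifier
def test_separable_blobs_classify_perfectly(rng):
    X = np.vstack([rng.normal(0, 0.05, (20, 6)), rng.normal(3, 0.05, (20, 6))])
    y = np.repeat([0, 1], 20)
    assert ml.classify_cv(X, y, rng_seed=0, fast=True) == 1.0


def test_shuffled_labels_score_at_chance(rng):
    """Random balanced labels: CA ~ 1/K within 3 binomial sigmas."""
    K, n = 4, 160
    X = rng.normal(size=(n, 10))
    y = np.tile(np.arange(K), n // K)
    ca = ml.classify_cv(X, y, rng_seed=1, fast=True)
    p = 1 / K
    sigma = np.sqrt(p * (1 - p) / n)
    assert abs(ca - p) < 3 * sigma + 0.02


def test_single_class_rejected(rng):
    with pytest.raises(ValueError):
        ml.classify_cv(rng.normal(size=(12, 3)), np.zeros(12), fast=True)


def test_small_classes_merged_with_warning(rng):
    X = np.vstack([rng.normal(0, 0.1, (20, 4)), rng.normal(4, 0.1, (20, 4)),
                   rng.normal(4.2, 0.1, (2, 4))])
    y = np.array([0] * 20 + [1] * 20 + [2] * 2)
    with pytest.warns(UserWarning):
        ca = ml.classify_cv(X, y, fast=True)
    assert ca > 0.9
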