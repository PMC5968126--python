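"""Monodomain solver unit tests on small grids (fast); the full-size slab
experiments live in the acceptance suite."""

import numpy as np
import pytest

from fibrofocal import ionic
from fibrofocal import monodomain as md
from fibrofocal.constants import LABEL_NONCONDUCTING, REGION_INDEX


def small_slab(mm=12.0, region="LA"):
    return md.build_control_slab(region, width_mm=mm, height_mm=mm)


def test_uniform_rest_is_preserved_without_stimulus():
    """No-flux boundaries: a uniform resting slab stays at rest for 100 ms."""
    g = small_slab(6.0)
    stim = md.Stimulus(mask=np.ones(g.n_voxels, bool), amplitude=0.0,
                       duration=0.0)
    res = md.solve_monodomain(g, stim, duration=100.0)
    v = res.final_state[0]
    assert np.ptp(v) < 1e-6            # spatially uniform to solver precision
    assert abs(v[0] - (-81.18)) < 0.05  # still at rest


def test_nonconducting_isolation():
    """With everything non-conducting except the stimulus site, only the
    stimulated voxels activate."""
    g = small_slab(6.0)
    g.label[:] = LABEL_NONCONDUCTING
    nx, ny, _ = g.dims
    stim_vox = [g.flat_index(nx // 2, ny // 2, 0),
                g.flat_index(nx // 2 + 1, ny // 2, 0)]
    g.label[stim_vox] = REGION_INDEX["LA"]
    mask = np.zeros(g.n_voxels, bool)
    mask[stim_vox] = True
    res = md.solve_monodomain(g, md.Stimulus(mask=mask, amplitude=40.0),
                              duration=50.0)
    activated = np.nonzero(np.isfinite(res.lat))[0]
    assert set(activated) == set(stim_vox)


def test_point_stimulus_activation_is_mirror_symmetric():
    """Isotropic slab, centred point stimulus: the LAT map is symmetric
    about both in-plane axes."""
    g = small_slab(9.0)
    g.anisotropy[:] = 1.0
    nx, ny, _ = g.dims
    mask3 = np.zeros(g.dims, bool)
    mask3[nx // 2 - 2: nx // 2 + 2, ny // 2 - 2: ny // 2 + 2, :] = True
    res = md.solve_monodomain(g, md.Stimulus(mask=mask3.reshape(-1),
                                             amplitude=80.0, duration=4.0),
                              duration=60.0)
    lat = res.lat_3d()[:, :, 0]
    assert np.isfinite(lat).all()
    assert np.nanmax(np.abs(lat - lat[::-1, :])) <= res.meta["dt"] + 1e-9
    assert np.nanmax(np.abs(lat - lat[:, ::-1])) <= res.meta["dt"] + 1e-9


def test_plane_wave_cv_converges_under_refinement():
    """Halving the voxel size changes the plane-wave CV by < 5 %."""
    cv_coarse = _strip_cv(spacing=0.3)
    cv_fine = _strip_cv(spacing=0.15)
    assert cv_coarse == pytest.approx(cv_fine, rel=0.05)


def _strip_cv(spacing):
    g = md.build_control_slab("LA", spacing=spacing, width_mm=3 * spacing,
                              height_mm=20.0)
    ny = g.dims[1]
    p1 = g.flat_index(1, int(0.3 * ny), 0)
    p2 = g.flat_index(1, int(0.7 * ny), 0)
    # keep the stimulated depth ~0.6 mm regardless of the voxel size
    stim = md.bottom_edge_stimulus(g, rows=max(2, round(0.6 / spacing)))
    res = md.solve_monodomain(g, stim, duration=45.0)
    cv, _ = md.measure_cv_delay(res, [p1, p2],
                                (int(0.7 * ny) - int(0.3 * ny)) * spacing)
    return cv


def test_cv_delay_arithmetic():
    """50 mm in 59 ms is 0.847 m/s; 99 ms gives 0.505; equal LATs flag inf."""
    res = md.SimulationResult(lat=np.array([1.0, 60.0]), dims=(2, 1, 1),
                              meta={})
    cv, d = md.measure_cv_delay(res, [0, 1], 50.0)
    assert cv == pytest.approx(50.0 / 59.0, abs=1e-9)
    assert d[0] == pytest.approx(59.0)
    res.lat = np.array([1.0, 100.0])
    cv, _ = md.measure_cv_delay(res, [0, 1], 50.0)
    assert cv == pytest.approx(0.505, abs=0.001)
    res.lat = np.array([5.0, 5.0])
    cv, _ = md.measure_cv_delay(res, [0, 1], 50.0)
    assert np.isinf(cv)
    res.lat = np.array([5.0, np.nan])
    cv, d = md.measure_cv_delay(res, [0, 1], 50.0)
    assert np.isnan(cv) and np.isnan(d[0])  # block reported per segment


def test_builder_validation():
    with pytest.raises(ValueError):
        md.build_barrier_slab(500)          # band exceeds slab height
    with pytest.raises(ValueError):
        md.build_channel_slab(100.0)        # channel wider than slab
    g = small_slab(6.0)
    with pytest.raises(ValueError):
        md.solve_monodomain(g, md.Stimulus(mask=np.zeros(g.n_voxels, bool)),
                            duration=10.0)  # stimulus outside grid
    with pytest.raises(ValueError):
        md.solve_monodomain(g, md.bottom_edge_stimulus(g), duration=10.0,
                            dt=0.1)         # dt too large for the gates


def test_patchy_slab_fraction_tracks_stage():
    fracs = []
    for stage in (1, 3, 5):
        g = md.build_patchy_slab(stage, case_seed=1)
        fracs.append((g.label == md.LABEL_FIBROBLAST).mean())
    assert fracs[0] < 0.081          # stage I below the first Utah edge
    assert fracs[0] < fracs[1] < fracs[2]


def test_patchy_growth_monotone_across_stages():
    masks = []
    for stage in (1, 2, 3):
        g = md.build_patchy_slab(stage, case_seed=2)
        masks.append(g.label == md.LABEL_FIBROBLAST)
    assert np.all(masks[1] >= masks[0]) and np.all(masks[2] >= masks[1])


def test_profile_equilibration_matches_full_grid():
    """Tiled 1D-profile equilibrium equals the full-grid equilibrium for an
    x-invariant barrier layout."""
    g = md.build_control_slab(width_mm=1.5, height_mm=6.0)
    nx, ny, nz = g.dims
    lab3 = g.label.reshape(nx, ny, nz)
    lab3[:, ny // 2: ny // 2 + 1, :] = md.LABEL_FIBROBLAST
    tiled = md.equilibrated_state(g, invariant_axis=0, duration=50.0)
    full = md.equilibrated_state(g, invariant_axis=None, duration=50.0)
    assert np.allclose(tiled[0], full[0], atol=1e-8)


def test_blowup_detection():
    g = small_slab(3.0)
    init = md.initial_tissue_state(g)
    init[0, :] = 150.0  # absurd start far outside the model's range
    stim = md.Stimulus(mask=np.ones(g.n_voxels, bool), amplitude=500.0,
                       duration=50.0)
    with pytest.raises(md.NumericalBlowupError):
        md.solve_monodomain(g, stim, duration=50.0, initial_state=init)


def test_lat_is_after_stimulus_onset_where_defined():
    g = small_slab(6.0)
    res = md.run_slab(g, duration=40.0)
    lat = res.lat
    assert np.nanmin(lat) >= 0.0
    assert np.isfinite(lat).all()


def test_grid_vtk_export(tmp_path):
    g = small_slab(3.0)
    res = md.run_slab(g, duration=15.0)
    path = tmp_path / "slab.vtk"
    md.save_grid_vtk(g, path, lat=res.lat)
    text = path.read_text()
    assert "STRUCTURED_POINTS" in text
    assert f"POINT_DATA {g.n_voxels}" in text
    for name in ("tissue_label", "sigma_l", "lat_ms"):
        assert name in text


def test_movie_recording_shape():
    g = small_slab(4.5)
    res = md.run_slab(g, duration=20.0, movie_every_ms=1.0)
    assert res.movie is not None
    assert res.movie.shape[1] == g.n_voxels
    assert res.movie_dt == pytest.approx(1.0)
    # the movie must show propagation: later frames activated
    assert res.movie[0].max() < 0 < res.movie[-1].max() + 80
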