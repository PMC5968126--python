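"""End-to-end experiment drivers tying the scientific modules together.

Three suites mirror the study's structure:

* ``slab`` -- coupled myocyte/fibroblast slab experiments (control,
  transverse barriers, conduction channels, patchy stages);
* ``dataset`` -- synthetic-atlas activation datasets M0..M5 with the
  forward BSPM/BSPiM chain;
* ``pipeline`` -- clustering/validation/classification over the datasets.

Every function is deterministic for a fixed :class:`ExperimentConfig`.
"""

from __future__ import annotations

import json
import logging
import time
import zlib
from pathlib import Path

import numpy as np
import pandas as pd

from . import atlas as at
from . import fibrosis as fib_mod
from . import forward_bspm as fw
from . import ionic
from . import mlpipe as ml
from . import monodomain as md
from .config import ExperimentConfig

log = logging.getLogger("fibrofocal")

CHANNEL_WIDTHS_MM = (1.2, 1.5, 1.8, 2.4, 2.7, 4.8)  # 4.8 = ">3 mm" control
PWAVE_MARGIN_MS = 30.0  # depolarization margin after the last activation


# ------------------------------------------------------------- slab suite
def run_barrier_experiment(width_voxels: int, config: ExperimentConfig
                           = ExperimentConfig(), full_width: bool = True):
    """Activation time of the slab with a transverse fibroblast barrier.

    Returns dict with the total activation time (NaN = conduction block)
    and the simulation result.  ``full_width=False`` runs the equivalent
    1-voxel-wide strip (the geometry is x-invariant), which is much faster.
    """
    if full_width:
        grid = md.build_barrier_slab(width_voxels)
    else:
        grid = md.build_control_slab(width_mm=md.VOXEL_MM)
        if width_voxels:
            nx, ny, nz = grid.dims
            lab3 = grid.label.reshape(nx, ny, nz)
            y0 = ny // 2 - width_voxels // 2
            lab3[:, y0:y0 + width_voxels, :] = md.LABEL_FIBROBLAST
    S0 = md.equilibrated_state(grid, invariant_axis=0,
                               duration=config.equilibration_ms,
                               dt=config.dt_ms)
    res = md.run_slab(grid, duration=(120.0 if width_voxels < 3 else 170.0),
                      dt=config.dt_ms, prepaced_state=S0)
    blocked = not md.top_edge_activated(res)
    return dict(width_voxels=width_voxels,
                activation_time_ms=(np.nan if blocked
                                    else res.total_activation_time),
                blocked=blocked, result=res)


def run_channel_experiment(width_mm: float, config: ExperimentConfig
                           = ExperimentConfig(), duration: float = 300.0):
    """AP properties at the entrance/exit probes of a conduction channel."""
    grid = md.build_channel_slab(width_mm)
    S0 = md.equilibrated_state(grid, invariant_axis=1,
                               duration=config.equilibration_ms,
                               dt=config.dt_ms)
    res = md.run_slab(grid, duration=duration, dt=config.dt_ms,
                      prepaced_state=S0)
    lat = {k: res.lat[i] for k, i in grid.probes.items()}
    out = dict(width_mm=width_mm, result=res)
    for name in ("ch1", "ch4"):
        tr = res.probe_traces[name]
        out[f"RMP_{name}"] = float(tr[0])
        out[f"peak_{name}"] = float(tr.max())
        out[f"amp_{name}"] = float(tr.max() - tr[0])
        out[f"LAT_{name}"] = float(lat[name])
    out["delay_4_1_ms"] = float(lat["ch4"] - lat["ch1"])
    out["blocked"] = bool(np.isnan(lat["ch4"]))
    return out


def slab_suite_tables(config: ExperimentConfig = ExperimentConfig(),
                      channel_widths=CHANNEL_WIDTHS_MM):
    """Barrier and channel summary tables (the slab-experiment analogues)."""
    rows = []
    for w in (0, 1, 2, 3):
        r = run_barrier_experiment(w, config)
        rows.append({k: r[k] for k in ("width_voxels", "activation_time_ms",
                                       "blocked")})
    barrier = pd.DataFrame(rows)
    rows = []
    for wmm in channel_widths:
        r = run_channel_experiment(wmm, config)
        rows.append({k: v for k, v in r.items() if k != "result"})
    channel = pd.DataFrame(rows)
    return barrier, channel


def control_cell_metrics(config: ExperimentConfig = ExperimentConfig(),
                         tissue: bool = True) -> ionic.APMetrics:
    """Control AP metrics under the pacing-stabilization protocol.

    ``tissue=True`` measures the propagated AP on a paced healthy strip
    (the measurement context of the printed control values);
    ``tissue=False`` paces an isolated myocyte.
    """
    if tissue:
        t, v = md.paced_control_ap(bcl=config.bcl_ms, n_beats=config.n_beats,
                                   dt=config.dt_ms)
        return ionic.compute_ap_metrics(t, v)
    p = ionic.MyocyteParams.from_region("LA")
    t, v, _ = ionic.pace_single_cell(p, bcl=config.bcl_ms,
                                     n_beats=config.n_beats, dt=config.dt_ms)
    return ionic.compute_ap_metrics(t, v)


# --------------------------------------------------------------- datasets
def ap_template(config: ExperimentConfig = ExperimentConfig(),
                fs_khz: float = 1.0):
    """1 kHz action-potential template from the paced control myocyte."""
    p = ionic.MyocyteParams.from_region("LA")
    t, v, _ = ionic.pace_single_cell(p, bcl=config.bcl_ms,
                                     n_beats=config.n_beats, dt=config.dt_ms)
    # start the template at the upstroke so template(t - LAT) activates at LAT
    i_up = int(np.argmax(np.gradient(v)))
    t2, v2 = t[i_up:] - t[i_up], v[i_up:].copy()
    v2[0] = v[0]  # pre-upstroke resting value
    tt = np.arange(0.0, t2[-1], 1.0 / fs_khz)
    return tt, np.interp(tt, t2, v2)


def build_all_datasets(config: ExperimentConfig = ExperimentConfig(),
                       models=("M0", "M1", "M2", "M3", "M4", "M5")):
    """Atlas + fibrosis library + activation datasets for the model specs."""
    atlas = at.build_atlas(subdivisions=config.atlas_subdivisions,
                           torso_nodes=config.torso_nodes,
                           rng_seed=config.seed)
    mesh = at.la_element_mesh(atlas.atria)
    library = fib_mod.build_case_library(
        mesh, n_cases=config.n_cases, stage_targets=config.stage_targets,
        rng_base=config.seed, n_seeds=config.n_seeds,
        drop_prob=config.drop_prob)
    datasets = {}
    fibrotic = [m for m in models if m != "M0"]
    if fibrotic:
        top = max(fibrotic)  # activation maps are shared across M1..Mk views
        full = at.build_dataset(atlas, top, rng_seed=config.seed,
                                n_cases=config.n_cases,
                                fibrosis_library=library)
        for m in fibrotic:
            datasets[m] = (full if m == top else at.subset_dataset(full, m))
    if "M0" in models:
        datasets["M0"] = at.build_dataset(atlas, "M0", rng_seed=config.seed,
                                          n_cases=config.n_cases,
                                          fibrosis_library=library)
    return atlas, library, datasets


def bspim_features(dataset: at.ActivationDataset,
                   layout: ml.ElectrodeLayout,
                   template=None,
                   config: ExperimentConfig = ExperimentConfig(),
                   noise: bool = True):
    """BSPiM feature matrix (runs x electrodes) for one dataset.

    Chain per run: template-shifted transmembrane movie -> dipole lead-field
    projection at the representative electrodes -> calibrated white noise ->
    Savitzky-Golay smoothing -> trapezoidal P-wave integral -> [-1, 1]
    normalization.
    """
    atlas = dataset.atlas
    surface = atlas.atria
    if template is None:
        template = ap_template(config)
    tt, tv = template
    electrodes = np.asarray(atlas.torso.vertices)[layout.representatives]
    lead = fw.build_lead_field(surface, electrodes,
                               electrode_index=layout.representatives)
    mesh = at.la_element_mesh(surface) if dataset.fibrosis_library else None
    feats, run_foci, kept_ids = [], [], []
    for k, run in enumerate(dataset.included()):
        atten = None
        if run.stage > 0 and mesh is not None:
            model = dataset.fibrosis_library[(run.case, run.stage)]
            fibmask = at.fibrotic_vertex_mask(surface, mesh, model)
            atten = np.where(fibmask, at.FIB_ATTENUATION, 1.0)
        # P-wave window: depolarization only (activation + upstroke margin);
        # including repolarization would largely cancel the time integral
        p_end = float(np.nanmax(run.lat)) + PWAVE_MARGIN_MS
        V = at.synthesize_transmembrane(run.lat, tt, tv, attenuation=atten,
                                        duration_ms=p_end)
        bspm = fw.project(lead, V)
        if noise:
            # seed from the run id so dataset views share realizations
            rid_seed = zlib.crc32(run.run_id.encode()) % (1 << 20)
            bspm = fw.add_noise(bspm,
                                rng_seed=config.noise_seed * 1048576 + rid_seed,
                                power_ratio=config.noise_power_ratio)
            bspm = fw.smooth(bspm, config.sg_window, config.sg_order)
        feats.append(fw.integrate_pwave(bspm))
        run_foci.append(run.focus.id)
        kept_ids.append(run.run_id)
    return np.vstack(feats), run_foci, kept_ids


def run_pipeline_suite(config: ExperimentConfig = ExperimentConfig(),
                       models=("M0", "M1", "M2", "M3", "M4", "M5"),
                       n_list=None):
    """Full Table-5-analogue metric/accuracy grid over the dataset models."""
    t0 = time.time()
    atlas, library, datasets = build_all_datasets(config, models)
    log.info("datasets built in %.1f s", time.time() - t0)
    layout = ml.reduce_electrodes(atlas.torso, config.n_electrodes,
                                  rng_seed=config.electrode_seed)
    template = ap_template(config)
    graph_all = ml.build_ectopic_graph(atlas, atlas.foci)
    graph_19 = ml.build_ectopic_graph(atlas, atlas.primary_foci)
    reports = {}
    for m in models:
        feats, run_foci, _ = bspim_features(datasets[m], layout, template,
                                            config)
        graph = graph_all if m == "M0" else graph_19
        reports[m] = ml.run_full_pipeline(
            feats, run_foci, graph, model=m, k_range=config.k_range,
            n_list=(n_list or (max(config.n_list),)),
            rng_seed=config.seed, fast=config.fast_svm)
        log.info("pipeline %s done (%.1f s)", m, time.time() - t0)
    metrics = pd.concat([r.metrics for r in reports.values()],
                        ignore_index=True)
    accuracy = pd.concat([r.accuracy for r in reports.values()],
                         ignore_index=True)
    return dict(atlas=atlas, library=library, datasets=datasets,
                layout=layout, reports=reports, metrics=metrics,
                accuracy=accuracy)


# ------------------------------------------------------------ orchestration
def run_experiment(config: ExperimentConfig, which: str = "all",
                   out_dir="results") -> Path:
    """Run a named suite and write its tables under ``out_dir``.

    ``which`` is one of ``slab-suite``, ``dataset``, ``pipeline``, ``all``.
    A manifest with the config hash accompanies every output.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    produced = []
    t0 = time.time()
    if which not in ("slab-suite", "dataset", "pipeline", "all"):
        raise ValueError(f"unknown suite {which!r}")
    if which in ("slab-suite", "all"):
        barrier, channel = slab_suite_tables(config)
        barrier.to_csv(out / "barrier_suite.csv", index=False)
        channel.to_csv(out / "channel_suite.csv", index=False)
        produced += ["barrier_suite.csv", "channel_suite.csv"]
    if which in ("dataset", "pipeline", "all"):
        result = run_pipeline_suite(config)
        man = pd.concat([d.manifest() for d in result["datasets"].values()],
                        ignore_index=True)
        man.to_csv(out / "dataset_manifest.csv", index=False)
        produced.append("dataset_manifest.csv")
        if which in ("pipeline", "all"):
            result["metrics"].to_csv(out / "cluster_metrics.csv", index=False)
            result["accuracy"].to_csv(out / "classification_accuracy.csv",
                                      index=False)
            produced += ["cluster_metrics.csv", "classification_accuracy.csv"]
    manifest = dict(config_hash=config.config_hash, which=which,
                    files=produced, elapsed_s=round(time.time() - t0, 1),
                    config=config.to_dict())
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
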