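"""Single-cell electrophysiology baseline.

Paces the regional atrial myocyte variants and the fibroblast model,
prints the action-potential metrics of the stabilized control (20 beats at
BCL 500 ms) for both the isolated cell and the propagated tissue AP, and
writes the summary under results/.
"""

import pathlib
import sys

import pandas as pd

from fibrofocal import ionic
from fibrofocal import monodomain as md
from fibrofocal.config import ExperimentConfig

OUT = pathlib.Path(__file__).resolve().parents[1] / "results"


def main():
    cfg = ExperimentConfig()
    rows = []
    for region in ("RA", "LA", "PV", "MVR", "LAA"):
        p = ionic.MyocyteParams.from_region(region)
        t, v, _ = ionic.pace_single_cell(p, bcl=cfg.bcl_ms,
                                         n_beats=cfg.n_beats, dt=cfg.dt_ms,
                                         stim_amp=22.0)
        m = ionic.compute_ap_metrics(t, v)
        rows.append(dict(region=region, protocol="cell", RMP=m.RMP,
                         peak=m.peak, amplitude=m.amplitude,
                         APD90=m.APD90, APD50=m.APD50))
        print(f"{region:4s} cell  RMP {m.RMP:7.2f}  APD90 {m.APD90:6.1f}  "
              f"amp {m.amplitude:6.2f}")

    t, v = md.paced_control_ap(bcl=cfg.bcl_ms, n_beats=cfg.n_beats,
                               dt=cfg.dt_ms)
    m = ionic.compute_ap_metrics(t, v)
    rows.append(dict(region="LA", protocol="tissue_strip", RMP=m.RMP,
                     peak=m.peak, amplitude=m.amplitude, APD90=m.APD90,
                     APD50=m.APD50))
    print(f"LA   strip RMP {m.RMP:7.2f}  APD90 {m.APD90:6.1f}  "
          f"amp {m.amplitude:6.2f}  (propagated control)")
    print(f"fibroblast resting potential: "
          f"{ionic.fibroblast_resting_potential():.2f} mV")

    OUT.mkdir(exist_ok=True)
    pd.DataFrame(rows).to_csv(OUT / "single_cell_metrics.csv", index=False)
    print(f"wrote {OUT / 'single_cell_metrics.csv'}")


if __name__ == "__main__":
    sys.exit(main())
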