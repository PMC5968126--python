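"""Load the versioned ionic/tissue constants shipped with the package.

The YAML file is the single source of truth; this module materializes it
into plain dictionaries and numpy-friendly structures used by the numba
kernels (which capture scalar constants at compile time).
"""

from __future__ import annotations

import functools
from importlib import resources

import numpy as np
import yaml

#: order of the myocyte state variables in every state array
CRN_STATE_NAMES = (
    "V", "m", "h", "j", "oa", "oi", "ua", "ui", "xr", "xs",
    "d", "f", "fCa", "u", "v", "w", "Na_i", "K_i", "Ca_i", "Ca_up", "Ca_rel",
)
N_STATE = len(CRN_STATE_NAMES)

#: fibroblast gating variables live in the myocyte gate slots (r -> m, s -> h)
FIB_R_SLOT = 1
FIB_S_SLOT = 2

# voxel / vertex tissue labels
LABEL_NONCONDUCTING = -1
LABEL_FIBROBLAST = -2  # any label >= 0 is a myocyte region index


@functools.lru_cache(maxsize=1)
def load_constants() -> dict:
    with resources.files("fibrofocal.data").joinpath("ionic_constants.yaml").open() as fh:
        return yaml.safe_load(fh)


CONSTANTS = load_constants()
CRN = CONSTANTS["crn"]
CRN_INITIAL = CONSTANTS["crn_initial_state"]
MACCANNELL = CONSTANTS["maccannell"]
REGION_TABLE = CONSTANTS["regions"]
TISSUE = CONSTANTS["tissue"]

REGION_NAMES = tuple(REGION_TABLE)  # 11 labelled atrial regions
REGION_INDEX = {name: i for i, name in enumerate(REGION_NAMES)}


def crn_initial_state() -> np.ndarray:
    """Resting-state vector of the base myocyte model (column layout)."""
    return np.array([CRN_INITIAL[k] for k in CRN_STATE_NAMES], dtype=np.float64)


def region_factors(region: str) -> tuple[float, float, float]:
    """(f_gto, f_gCaL, f_gKr) conductance factors for an atrial region."""
    row = REGION_TABLE[region]
    return row["f_gto"], row["f_gCaL"], row["f_gKr"]
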