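"""Study configurations: the full simulation protocol and a desk-scale one.

``full_*`` functions mirror the reference acquisition protocol: 128^3
volumes at 1 mm isotropic resolution, 24 cardiac phases, 7 mm (human) or
4 mm (porcine) tag distance, SNR 5-35, 260 cases split 80/10/10, 64^3
patches on a 16-voxel lattice, and N = 64 UNets trained for 25 epochs.

``scaled_*`` functions define the down-scaled configuration used by the
self-contained verification experiments, chosen so a complete
simulate-train-evaluate cycle runs on a single CPU core in minutes: a
48^3 grid at 2 mm spacing (96 mm field of view), 4 cardiac phases,
proportionally smaller ventricles, N = 8 depth-2 networks on 12^3
patches, and a 20/3/5 case split. Tag distance, SNR range, epoch count,
the masked loss, and the LR-halving schedule are unchanged from the
full protocol; batch size 16 and initial learning rate 1e-3 are the
scaled-preset training choices (the smaller network trains stably at a
higher rate, and 16 patches fill a batch from far fewer cases).
"""

from __future__ import annotations

import numpy as np

from .grids import GridSpec
from .network import NetworkSpec, TrainConfig
from .tagging import AcqConfig

__all__ = [
    "full_grid",
    "full_acq_human",
    "full_acq_porcine",
    "full_network_spec",
    "full_train_config",
    "scaled_grid",
    "scaled_acq",
    "scaled_geometry_ranges",
    "scaled_network_spec",
    "scaled_train_config",
    "SCALED_PATCH_SIZE",
    "SCALED_PATCH_STRIDE",
    "SCALED_N_PHASES",
    "SCALED_SPLIT",
]

# -- full protocol -------------------------------------------------------


def full_grid() -> GridSpec:
    return GridSpec((128, 128, 128), (1.0, 1.0, 1.0))


def full_acq_human(snr: float = np.inf) -> AcqConfig:
    return AcqConfig.human(snr)


def full_acq_porcine(snr: float = np.inf) -> AcqConfig:
    return AcqConfig.porcine(snr)


def full_network_spec(out_channels: int) -> NetworkSpec:
    return NetworkSpec(base_channels=64, depth=4, out_channels=out_channels)


def full_train_config(seed: int = 0) -> TrainConfig:
    return TrainConfig(epochs=25, batch_size=32, initial_lr=1e-4, seed=seed)


# -- scaled protocol -----------------------------------------------------

SCALED_PATCH_SIZE = 12
SCALED_PATCH_STRIDE = 12
SCALED_N_PHASES = 4
#: train / validation / test case counts
SCALED_SPLIT = (20, 3, 5)


def scaled_grid() -> GridSpec:
    return GridSpec((48, 48, 48), (2.0, 2.0, 2.0))


def scaled_acq(snr: float = np.inf) -> AcqConfig:
    return AcqConfig(
        tag_distance=7.0,
        acq_spacing=(2.0, 2.0, 2.0),
        out_spacing=(2.0, 2.0, 2.0),
        snr=snr,
    )


def scaled_geometry_ranges(grid: GridSpec | None = None) -> dict:
    """LV parameter ranges that fit the scaled field of view with margin."""
    return {
        "endo_radius_eq": (10.0, 16.0),
        "wall_thickness": (5.0, 8.0),
        "long_axis_length": (50.0, 66.0),
        "base_truncation_fraction": (0.5, 0.7),
    }


def scaled_network_spec(out_channels: int) -> NetworkSpec:
    return NetworkSpec(base_channels=8, depth=2, out_channels=out_channels)


def scaled_train_config(seed: int = 0) -> TrainConfig:
    return TrainConfig(epochs=25, batch_size=16, initial_lr=1e-3, seed=seed)
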