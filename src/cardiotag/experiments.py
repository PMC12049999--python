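"""End-to-end verification experiments at the desk-scale configuration.

``run_scaled_learning`` executes the whole pipeline — simulate a cohort
of randomized cases, train the SAX and LAX displacement networks, infer
full-volume fields on held-out cases — and reports displacement-error
summaries and pooled Pearson correlations against the analytic ground
truth. It is the package's own reduced-scale counterpart of a
full-protocol training campaign and is deliberately deterministic for a
fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .anatomy import LABEL_MYOCARDIUM, sample_lv_geometry
from .evaluation import error_summary, pearson_r
from .grids import GridSpec
from .motion import sample_motion_params
from .network import extract_patches, infer_field, train
from .presets import (
    SCALED_N_PHASES,
    SCALED_PATCH_SIZE,
    SCALED_PATCH_STRIDE,
    SCALED_SPLIT,
    scaled_acq,
    scaled_geometry_ranges,
    scaled_grid,
    scaled_network_spec,
    scaled_train_config,
)
from .tagging import AcqConfig, simulate_case

__all__ = ["ScaledLearningResult", "simulate_scaled_cohort", "run_scaled_learning"]


@dataclass
class ScaledLearningResult:
    """Outcome of one simulate-train-evaluate cycle."""

    median_abs_error_mm: dict  # per component 'x','y','z'
    signed_error_summaries: dict  # per component ErrorSummary
    pearson: dict  # per component pooled predicted-vs-truth r
    sax_net: object
    lax_net: object
    sax_history: object
    lax_history: object
    test_cases: list
    train_patch_count: int
    config: dict = field(default_factory=dict)


def simulate_scaled_cohort(n_cases: int, seed: int, n_phases: int = SCALED_N_PHASES,
                           grid: GridSpec | None = None, acq: AcqConfig | None = None):
    """Simulate ``n_cases`` randomized scaled cases, deterministically."""
    grid = grid or scaled_grid()
    ranges = scaled_geometry_ranges(grid)
    rng = np.random.default_rng(seed)
    cases = []
    for _ in range(n_cases):
        geo_seed, mot_seed, snr_seed, sim_seed = rng.integers(0, 2**31 - 1, 4)
        geo = sample_lv_geometry(int(geo_seed), ranges)
        mot = sample_motion_params(int(mot_seed), n_phases=n_phases)
        snr = float(np.random.default_rng(int(snr_seed)).uniform(5.0, 35.0))
        acq_c = acq if acq is not None else scaled_acq(snr)
        cases.append(simulate_case(geo, mot, acq_c, seed=int(sim_seed), grid=grid))
    return cases


def _patches(case, case_id):
    myo = case.ed_labels.labels == LABEL_MYOCARDIUM
    ed = case.images[0].intensities
    out = []
    for ph in range(1, case.motion.n_phases):
        out += extract_patches(
            ed,
            case.images[ph].intensities,
            case.fields[ph].vectors,
            myo,
            size=SCALED_PATCH_SIZE,
            stride=SCALED_PATCH_STRIDE,
            case_id=case_id,
            phase=ph,
        )
    return out


def run_scaled_learning(
    seed: int = 0,
    split=SCALED_SPLIT,
    epochs: int | None = None,
    infer_stride: int = SCALED_PATCH_SIZE // 2,
) -> ScaledLearningResult:
    """Simulate, train both networks, and evaluate on held-out cases.

    Held-out displacement errors are pooled over myocardial voxels of
    every non-reference phase of every test case; the per-component
    median absolute error (mm) and the Pearson correlation between
    predicted and ground-truth values are reported.
    """
    n_train, n_val, n_test = split
    cases = simulate_scaled_cohort(n_train + n_val + n_test, seed)
    train_s, val_s = [], []
    for i in range(n_train):
        train_s += _patches(cases[i], i)
    for i in range(n_train, n_train + n_val):
        val_s += _patches(cases[i], i)
    test_cases = cases[n_train + n_val :]

    from dataclasses import replace

    cfg = scaled_train_config(seed=seed)
    if epochs is not None:
        cfg = replace(cfg, epochs=epochs)
    sax_net, sax_hist = train(train_s, val_s, scaled_network_spec(2), cfg)
    lax_net, lax_hist = train(train_s, val_s, scaled_network_spec(1), cfg)

    grid = scaled_grid()
    errs = {c: [] for c in "xyz"}
    truth = {c: [] for c in "xyz"}
    pred = {c: [] for c in "xyz"}
    for case in test_cases:
        myo = case.ed_labels.labels == LABEL_MYOCARDIUM
        for ph in range(1, case.motion.n_phases):
            f = infer_field(
                case.images[0],
                case.images[ph],
                sax_net,
                lax_net,
                grid=grid,
                patch_size=SCALED_PATCH_SIZE,
                stride=infer_stride,
                phase_index=ph,
            )
            gt = case.fields[ph].vectors
            for ci, c in enumerate("xyz"):
                errs[c].append((f.vectors[..., ci] - gt[..., ci])[myo])
                truth[c].append(gt[..., ci][myo])
                pred[c].append(f.vectors[..., ci][myo])
    med = {}
    summaries = {}
    pearson = {}
    for c in "xyz":
        e = np.concatenate(errs[c])
        med[c] = float(np.median(np.abs(e)))
        summaries[c] = error_summary(np.concatenate(pred[c]), np.concatenate(truth[c]), "mm")
        pearson[c] = pearson_r(np.concatenate(truth[c]), np.concatenate(pred[c]))
    return ScaledLearningResult(
        median_abs_error_mm=med,
        signed_error_summaries=summaries,
        pearson=pearson,
        sax_net=sax_net,
        lax_net=lax_net,
        sax_history=sax_hist,
        lax_history=lax_hist,
        test_cases=test_cases,
        train_patch_count=len(train_s),
        config={
            "seed": seed,
            "split": tuple(split),
            "epochs": cfg.epochs,
            "patch_size": SCALED_PATCH_SIZE,
            "patch_stride": SCALED_PATCH_STRIDE,
            "n_phases": SCALED_N_PHASES,
        },
    )
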