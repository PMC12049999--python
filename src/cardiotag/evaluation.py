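"""Descriptive statistics for displacement and strain agreement.

Error distributions are summarized as M(Q1/Q3) — median with lower and
upper quartiles of the *signed* error — alongside Pearson correlation
of pooled predicted-vs-reference values and Bland-Altman agreement
(bias and 1.96 SD limits). The SNR sensitivity sweep re-synthesizes the
same simulated motion at several noise levels and runs the full
inference + strain pipeline per level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .anatomy import LABEL_MYOCARDIUM, local_directions
from .errors import DomainError
from .motion import ground_truth_strains
from .tagging import AcqConfig, simulate_case

__all__ = [
    "ErrorSummary",
    "BlandAltmanReport",
    "error_summary",
    "pearson_r",
    "bland_altman",
    "snr_sweep",
]

#: quartile convention used throughout (numpy's default)
QUARTILE_METHOD = "linear"


@dataclass(frozen=True)
class ErrorSummary:
    """M(Q1/Q3) of signed errors (pred - ref)."""

    median: float
    q1: float
    q3: float
    n: int
    units: str = ""
    quartile_method: str = QUARTILE_METHOD

    def __str__(self):
        u = f" {self.units}" if self.units else ""
        return f"{self.median:.2f}({self.q1:.2f}/{self.q3:.2f}){u}"


@dataclass(frozen=True)
class BlandAltmanReport:
    bias: float
    sd: float
    loa_low: float
    loa_high: float
    n: int


def error_summary(pred, ref, units: str = "") -> ErrorSummary:
    """Signed-difference summary; quartiles by linear interpolation."""
    pred = np.asarray(pred, dtype=float).ravel()
    ref = np.asarray(ref, dtype=float).ravel()
    if pred.size == 0 or pred.size != ref.size:
        raise DomainError("error_summary needs equal-length non-empty samples")
    d = pred - ref
    q1, med, q3 = np.percentile(d, [25, 50, 75], method=QUARTILE_METHOD)
    return ErrorSummary(float(med), float(q1), float(q3), int(d.size), units)


def pearson_r(a, b) -> float:
    """Product-moment correlation; NaN (with warning) for constant input."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size != b.size or a.size < 2:
        raise DomainError("pearson_r needs two samples of equal length >= 2")
    if np.std(a) == 0 or np.std(b) == 0:
        warnings.warn("pearson_r undefined for constant input", stacklevel=2)
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def bland_altman(a, b) -> BlandAltmanReport:
    """Agreement of paired measurements: bias and 1.96 SD limits."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size != b.size or a.size < 2:
        raise DomainError("bland_altman needs paired samples, n >= 2")
    d = a - b
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return BlandAltmanReport(bias, sd, bias - 1.96 * sd, bias + 1.96 * sd, int(d.size))


def snr_sweep(
    case_specs: list,
    snr_values,
    sax_net,
    lax_net,
    grid,
    acq: AcqConfig,
    seed: int = 0,
    patch_size: int = 64,
    stride: int = 32,
    sax_fraction: float = 0.5,
) -> pd.DataFrame:
    """Noise-sensitivity table: same motion, re-noised per SNR level.

    ``case_specs`` is a list of (geometry, motion) pairs; for each SNR
    the identical cases are re-synthesized with fresh noise seeds only,
    displacement fields are inferred with the trained networks, and
    displacement errors (myocardial voxels pooled over phases) plus
    peak-strain errors are summarized as M(Q1/Q3) per component.
    """
    from .network.inference import infer_field
    from .strain import strain_curves

    rng = np.random.default_rng(seed)
    # fresh noise seeds per SNR row; identical geometry/motion/background
    # across rows
    bg_seeds = rng.integers(0, 2**31 - 1, size=len(case_specs))
    case_seeds = rng.integers(0, 2**31 - 1, size=(len(snr_values), len(case_specs)))
    rows = []
    manifests = {}
    for ri, snr in enumerate(snr_values):
        acq_s = replace(acq, snr=float(snr))
        disp_err = {0: [], 1: [], 2: []}
        strain_err = {"e_r": [], "e_c": [], "e_l": []}
        ids = []
        for ci, (geo, mot) in enumerate(case_specs):
            case = simulate_case(
                geo,
                mot,
                acq_s,
                seed=int(case_seeds[ri, ci]),
                grid=grid,
                background_seed=int(bg_seeds[ci]),
            )
            ids.append(dict(case.manifest["geometry"], **case.manifest["motion"]))
            myo = case.ed_labels.mask(LABEL_MYOCARDIUM)
            fields = []
            for ph in range(mot.n_phases):
                f = infer_field(
                    case.images[0],
                    case.images[ph],
                    sax_net,
                    lax_net,
                    grid=case.images[0].grid,
                    patch_size=patch_size,
                    stride=stride,
                    phase_index=ph,
                )
                fields.append(f)
                if ph > 0:
                    for c in range(3):
                        disp_err[c].append(
                            (f.vectors[..., c] - case.fields[ph].vectors[..., c])[myo]
                        )
            dirs = local_directions(geo, case.ed_labels)
            # the ED anatomy is carried to each phase by the *inferred*
            # fields, exactly as an in-vivo analysis must do
            from .anatomy import LabelVolume
            from .strain import strain_curves, warp_mask_forward

            ed_myo = case.ed_labels.mask(LABEL_MYOCARDIUM)
            warped = [
                LabelVolume(
                    f.grid,
                    (warp_mask_forward(ed_myo, f) if f.phase_index else ed_myo).astype(
                        np.int16
                    ),
                )
                for f in fields
            ]
            gt = np.array([ground_truth_strains(geo, mot, p) for p in range(mot.n_phases)])
            try:
                curves = strain_curves(fields, warped, dirs, sax_fraction=sax_fraction)
                ps = curves.peak_systolic
                strain_err["e_r"].append(ps["e_r_ps"] - gt[:, 0].max())
                strain_err["e_c"].append(ps["e_c_ps"] - gt[:, 1].min())
                strain_err["e_l"].append(ps["e_l_ps"] - gt[:, 2].min())
            except DomainError as exc:  # degenerate predicted anatomy
                warnings.warn(f"strain skipped for one case: {exc}", stacklevel=2)
                for k in strain_err:
                    strain_err[k].append(np.nan)
        manifests[float(snr)] = ids
        row = {"snr": float(snr)}
        for c, name in zip(range(3), ("dx", "dy", "dz")):
            s = error_summary(np.concatenate(disp_err[c]), 0.0 * np.concatenate(disp_err[c]), "mm")
            row[f"{name}_median"], row[f"{name}_q1"], row[f"{name}_q3"] = s.median, s.q1, s.q3
        for name in ("e_r", "e_c", "e_l"):
            vals = np.asarray(strain_err[name], dtype=float)
            vals = vals[np.isfinite(vals)]
            if vals.size:
                s = error_summary(vals, np.zeros_like(vals))
                triple = (s.median, s.q1, s.q3)
            else:
                triple = (np.nan, np.nan, np.nan)
            row[f"d{name}_median"], row[f"d{name}_q1"], row[f"d{name}_q3"] = triple
        rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["case_manifests"] = manifests
    return df
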