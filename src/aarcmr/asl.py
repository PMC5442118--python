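"""Blood-pool-input FAIR perfusion quantification (bpMBF).

Myocardial blood flow follows from paired slice-selective ("control") and
global ("tagged") Look-Locker T1 maps:

    MBF = 60 * (lambda / T1_blood) * (T1_global / T1_selective - 1)   [ml/g/min]

with lambda the blood-tissue water partition coefficient and T1_blood either
configured or estimated as the median global-inversion T1 over the blood
pool.  The formula is kept in one place so an alternative quantification can
be swapped in.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .containers import ASLConstants, ParameterMap

log = logging.getLogger(__name__)


@dataclass
class PerfusionInputs:
    """Paired T1 maps plus constants; joint validity is the mask intersection."""

    t1_selective: ParameterMap
    t1_global: ParameterMap
    constants: ASLConstants = field(default_factory=ASLConstants)
    blood_mask: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.t1_selective.values.shape != self.t1_global.values.shape:
            raise ValueError("selective and global maps must share geometry")


def estimate_blood_t1(t1_global: ParameterMap, blood_mask: Optional[np.ndarray] = None,
                      default_s: Optional[float] = None) -> float:
    """Median global-inversion T1 over the blood pool, or the configured default."""
    if blood_mask is None:
        if default_s is None:
            raise ValueError("no blood mask and no default blood T1 configured")
        log.warning("estimate_blood_t1: no blood ROI supplied, using default %.3f s", default_s)
        return float(default_s)
    blood_mask = np.asarray(blood_mask, dtype=bool)
    sel = blood_mask & t1_global.valid
    if not sel.any():
        if default_s is None:
            raise ValueError("blood ROI has no valid pixels and no default is configured")
        log.warning("estimate_blood_t1: empty valid blood ROI, using default %.3f s", default_s)
        return float(default_s)
    return float(np.median(t1_global.values[sel]))


def compute_perfusion_map(inputs: PerfusionInputs,
                          t1_blood_s: Optional[float] = None) -> ParameterMap:
    """Pixel-wise bpMBF perfusion map in ml/g/min.

    Pixels where T1_selective exceeds T1_global come out negative; they are
    retained (so downstream SD-threshold statistics stay unbiased) but
    counted in the ``n_negative`` diagnostic.  Pixels invalid in either input
    map, or with non-positive selective T1, are invalid here.
    """
    sel, glo = inputs.t1_selective, inputs.t1_global
    lam = inputs.constants.lambda_ml_per_g
    if t1_blood_s is None:
        t1_blood_s = estimate_blood_t1(glo, inputs.blood_mask,
                                       default_s=inputs.constants.t1_blood_s)
    if t1_blood_s <= 0 or lam <= 0:
        raise ValueError("t1_blood and lambda must be positive")
    valid = sel.valid & glo.valid & (np.nan_to_num(sel.values) > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        mbf = 60.0 * (lam / t1_blood_s) * (glo.values / sel.values - 1.0)
    mbf = np.where(valid, mbf, np.nan)
    n_negative = int(np.sum(valid & (mbf < 0)))
    diag = {
        "t1_blood_s": float(t1_blood_s),
        "t1_blood_source": "estimated" if inputs.blood_mask is not None else "default",
        "lambda_ml_per_g": float(lam),
        "n_negative": n_negative,
        "n_invalid": int(np.sum((sel.valid | glo.valid) & ~valid)),
    }
    return ParameterMap(mbf, valid, "ml/g/min", diag)


@dataclass
class QCReport:
    n_valid: int
    n_invalid: int
    n_negative: int
    per_slice_median: list

    def as_dict(self) -> dict:
        return {"n_valid": self.n_valid, "n_invalid": self.n_invalid,
                "n_negative": self.n_negative, "per_slice_median": self.per_slice_median}


def perfusion_qc(pmap: ParameterMap) -> QCReport:
    """Counts of negative/invalid pixels and per-slice medians, for the run log."""
    n_valid = pmap.n_valid
    n_invalid = int(pmap.valid.size - n_valid) if "n_invalid" not in pmap.diagnostics \
        else int(pmap.diagnostics["n_invalid"])
    n_negative = int(np.sum(pmap.valid & (np.nan_to_num(pmap.values, nan=0.0) < 0)))
    medians = []
    for s in range(pmap.n_slices):
        v = pmap.values[s][pmap.valid[s]]
        medians.append(float(np.median(v)) if v.size else float("nan"))
    report = QCReport(n_valid, n_invalid, n_negative, medians)
    log.info("perfusion QC: %d valid, %d invalid, %d negative", n_valid, n_invalid, n_negative)
    return report
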