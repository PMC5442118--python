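"""Shared in-memory containers for image stacks, labels and fitted maps.

Array layout convention used throughout the package:

* image series   -- ``(n_slices, n_points, ny, nx)`` float arrays,
* label images   -- ``(n_slices, ny, nx)`` small-int arrays,
* parameter maps -- ``(n_slices, ny, nx)`` float arrays with a boolean
  validity mask of the same shape.

Slices are always ordered apex -> base, so the "second from most basal"
slice used for the normal ROI is index ``n_slices - 2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

# Region label codes (one class per pixel).
BACKGROUND = 0
BLOOD = 1
REMOTE = 2
AAR_SALVAGED = 3
INFARCT = 4

LABEL_NAMES = {
    BACKGROUND: "background",
    BLOOD: "blood",
    REMOTE: "remote",
    AAR_SALVAGED: "aar_salvaged",
    INFARCT: "infarct",
}


@dataclass
class AcquisitionMeta:
    """Acquisition metadata carried beside every simulated series.

    Defaults mirror the 9.4 T mouse protocol: nine spin-echo echo times for
    T2 mapping and a 50-point Look-Locker inversion-recovery readout
    (flip angle 5 deg, 3 ms excitation spacing, 13.5 s inversion repetition)
    for T1/ASL mapping.
    """

    modality: str  # "multi_echo_se" | "look_locker_ir" | "lge"
    te_list_ms: Optional[tuple] = None
    ti_list_s: Optional[tuple] = None
    n_points: int = 50
    flip_angle_deg: float = 5.0
    tr_rf_ms: float = 3.0
    tr_inv_s: float = 13.5
    te_ms: float = 1.18
    inversion_scope: Optional[str] = None  # "selective" | "global"
    slice_thickness_mm: float = 1.0
    magnitude: bool = True

    def __post_init__(self):
        if self.modality not in ("multi_echo_se", "look_locker_ir", "lge"):
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.te_list_ms is not None:
            te = np.asarray(self.te_list_ms, dtype=float)
            if te.ndim != 1 or len(te) == 0 or np.any(te <= 0) or np.any(np.diff(te) <= 0):
                raise ValueError("te_list_ms must be strictly increasing and positive")
            self.te_list_ms = tuple(float(v) for v in te)
        if self.ti_list_s is not None:
            ti = np.asarray(self.ti_list_s, dtype=float)
            if ti.ndim != 1 or len(ti) == 0 or ti[0] <= 0 or np.any(np.diff(ti) <= 0):
                raise ValueError("ti_list_s must be strictly increasing, starting > 0")
            self.ti_list_s = tuple(float(v) for v in ti)
            self.n_points = len(self.ti_list_s)
        if self.modality == "look_locker_ir" and self.inversion_scope not in ("selective", "global"):
            raise ValueError("look_locker_ir series need inversion_scope 'selective' or 'global'")
        if not 0.0 < self.flip_angle_deg < 90.0:
            raise ValueError("flip angle must lie in (0, 90) degrees")

    def to_dict(self) -> dict:
        d = asdict(self)
        for k in ("te_list_ms", "ti_list_s"):
            if d[k] is not None:
                d[k] = list(d[k])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionMeta":
        d = dict(d)
        for k in ("te_list_ms", "ti_list_s"):
            if d.get(k) is not None:
                d[k] = tuple(d[k])
        return cls(**d)


def default_t2_meta() -> AcquisitionMeta:
    """Nine-echo multi-echo spin-echo protocol for T2 mapping."""
    return AcquisitionMeta(
        modality="multi_echo_se",
        te_list_ms=(3.5, 7.0, 10.0, 12.0, 15.0, 17.0, 20.0, 25.0, 30.0),
    )


def default_ir_meta(scope: str, n_points: int = 50,
                    t_first_s: float = 0.05, t_last_s: float = 10.0) -> AcquisitionMeta:
    """Look-Locker IR protocol; recovery sampled uniformly on [0.05, 10] s."""
    ti = tuple(np.linspace(t_first_s, t_last_s, n_points))
    return AcquisitionMeta(modality="look_locker_ir", ti_list_s=ti, inversion_scope=scope)


def default_lge_meta() -> AcquisitionMeta:
    return AcquisitionMeta(modality="lge", magnitude=True)


@dataclass
class SliceStack:
    """A multi-slice, multi-timepoint image series plus acquisition metadata."""

    data: np.ndarray  # (n_slices, n_points, ny, nx)
    meta: AcquisitionMeta

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError("SliceStack.data must be (n_slices, n_points, ny, nx)")

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]

    @property
    def n_points(self) -> int:
        return self.data.shape[1]

    @property
    def spatial_shape(self) -> tuple:
        return self.data.shape[2:]


@dataclass
class RegionLabels:
    """Per-pixel ground-truth classes plus the edema mask used by T2/T1 simulation.

    ``labels`` holds one class per pixel (background, blood, remote,
    AAR-salvaged, infarct).  ``edema`` marks the subset of the AAR that
    actually expresses elevated T2/T1; it equals the full AAR except for
    preconditioning-like phantoms where the edema extent is reduced.
    """

    labels: np.ndarray  # (n_slices, ny, nx) int
    edema: Optional[np.ndarray] = None  # bool, same shape

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be (n_slices, ny, nx)")
        if self.edema is not None:
            self.edema = np.asarray(self.edema, dtype=bool)
            if self.edema.shape != self.labels.shape:
                raise ValueError("edema mask shape mismatch")

    @property
    def n_slices(self) -> int:
        return self.labels.shape[0]

    @property
    def blood_mask(self) -> np.ndarray:
        return self.labels == BLOOD

    @property
    def myocardium_mask(self) -> np.ndarray:
        return (self.labels == REMOTE) | (self.labels == AAR_SALVAGED) | (self.labels == INFARCT)

    @property
    def aar_mask(self) -> np.ndarray:
        return (self.labels == AAR_SALVAGED) | (self.labels == INFARCT)

    @property
    def infarct_mask(self) -> np.ndarray:
        return self.labels == INFARCT

    @property
    def remote_mask(self) -> np.ndarray:
        return self.labels == REMOTE

    def copy(self) -> "RegionLabels":
        return RegionLabels(self.labels.copy(),
                            None if self.edema is None else self.edema.copy())


@dataclass
class ASLConstants:
    """Constants of the blood-pool-input FAIR quantification.

    lambda_ml_per_g is the equilibrium blood-tissue water partition
    coefficient; t1_blood_s the blood-pool longitudinal relaxation time at
    9.4 T (overridable, and estimable from the blood ROI of the global map).
    """

    lambda_ml_per_g: float = 0.95
    t1_blood_s: float = 2.4

    def __post_init__(self):
        if self.lambda_ml_per_g <= 0 or self.t1_blood_s <= 0:
            raise ValueError("ASL constants must be strictly positive")


@dataclass
class ParameterMap:
    """A per-pixel fitted quantity with fit diagnostics and a validity mask."""

    values: np.ndarray  # (n_slices, ny, nx)
    valid: np.ndarray  # bool, same shape
    units: str
    diagnostics: dict = field(default_factory=dict)  # name -> array or scalar

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.values.shape != self.valid.shape:
            raise ValueError("values/valid shape mismatch")
        if self.values.ndim != 3:
            raise ValueError("ParameterMap arrays must be (n_slices, ny, nx)")

    @property
    def n_slices(self) -> int:
        return self.values.shape[0]

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())
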