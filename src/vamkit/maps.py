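"""Vessel size index, microvessel density, rCBV, and parameter-map assembly.

Peak relaxation-rate changes from the fitted curve pair feed two
steady-state microvascular estimators:

- vessel size index  VSI = 0.425 * (ADC / (gamma * dchi * B0))**0.5
                           * (dR2*/dR2)**1.5           [micrometres]
- microvessel density  Q = dR2 / (dR2*)**(2/3)         [s^(-1/3)]

Relative cerebral blood volume is the trapezoidal integral of the
leakage-corrected dR2* curve over the post-baseline window, normalized
by the healthy-hemisphere whole-brain mean of the same integral (so the
healthy-hemisphere mean rCBV is exactly 1 before any report scaling).

Maps are 3D arrays on the acquisition grid: NaN outside the brain mask
(and wherever a fit failed), zero everywhere in the lesioned hemisphere.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "PhysicalConstants",
    "HemisphereSpec",
    "PARAMETER_NAMES",
    "compute_q",
    "compute_vsi",
    "rcbv_integral",
    "normalize_rcbv",
    "q_to_table_units",
    "rcbv_to_table_units",
    "assemble_maps",
    "hemisphere_split",
    "save_parameter_maps",
    "load_parameter_maps",
]

#: canonical order of the nine per-voxel parameters
PARAMETER_NAMES = ("I", "VTI", "VIPS", "CGI", "CBI", "BVF", "VSI", "Q", "rCBV")


@dataclass(frozen=True)
class PhysicalConstants:
    """Constants entering the vessel size index.

    gamma : proton gyromagnetic ratio, rad/(s*T).
    delta_chi : blood/tissue susceptibility difference at peak contrast
        concentration, dimensionless (SI).
    b0 : main field strength, tesla.
    adc : apparent water diffusion coefficient, mm^2/s (scalar default;
        a per-voxel map may be passed to :func:`compute_vsi` instead).
    """

    gamma: float = 2.675e8
    delta_chi: float = 1.15e-7
    b0: float = 3.0
    adc: float = 0.8e-3

    def __post_init__(self) -> None:
        for name in ("gamma", "delta_chi", "b0", "adc"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def vsi_prefactor_um(self) -> float:
        """``0.425 * sqrt(ADC / (gamma*dchi*B0))`` converted mm -> um."""
        return 0.425 * float(
            np.sqrt(self.adc / (self.gamma * self.delta_chi * self.b0))
        ) * 1.0e3


@dataclass(frozen=True)
class HemisphereSpec:
    """Which hemisphere carries the lesion; the other one is analyzed.

    The midline is a grid-column plane: voxels with first-axis index
    below ``midline_index`` belong to the left hemisphere.
    """

    lesion_side: str
    midline_index: int

    def __post_init__(self) -> None:
        if self.lesion_side not in ("left", "right"):
            raise ValueError(f"lesion_side must be left/right, got {self.lesion_side}")

    @property
    def healthy_side(self) -> str:
        return "right" if self.lesion_side == "left" else "left"


def hemisphere_split(shape: tuple, spec: HemisphereSpec) -> tuple[np.ndarray, np.ndarray]:
    """Boolean (healthy, lesioned) masks for a grid of ``shape``."""
    x = np.arange(shape[0])[:, None, None]
    left = np.broadcast_to(x < spec.midline_index, shape)
    lesioned = left if spec.lesion_side == "left" else ~left
    return ~lesioned, lesioned


# ---------------------------------------------------------------------------
# scalar estimators (vectorized over arrays)


def compute_q(dr2_peak, dr2star_peak):
    """Microvessel density ``Q = dR2 / dR2*^(2/3)`` in s^(-1/3).

    NaN wherever ``dR2* <= 0`` or ``dR2 < 0`` (undefined regime).
    """
    dr2 = np.asarray(dr2_peak, dtype=float)
    dr2s = np.asarray(dr2star_peak, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        q = np.where((dr2s > 0) & (dr2 >= 0), dr2 / np.power(dr2s, 2.0 / 3.0), np.nan)
    return q if q.ndim else float(q)


def compute_vsi(dr2star_peak, dr2_peak, constants: PhysicalConstants | None = None,
                adc=None):
    """Vessel size index in micrometres.

    ``VSI = 0.425*sqrt(ADC/(gamma*dchi*B0)) * (dR2*/dR2)**1.5``; NaN
    wherever either peak is non-positive.  ``adc`` may be a per-voxel
    map in mm^2/s overriding the scalar constant.
    """
    constants = constants or PhysicalConstants()
    dr2s = np.asarray(dr2star_peak, dtype=float)
    dr2 = np.asarray(dr2_peak, dtype=float)
    if adc is None:
        pref = constants.vsi_prefactor_um
    else:
        pref = 0.425 * np.sqrt(
            np.asarray(adc, dtype=float)
            / (constants.gamma * constants.delta_chi * constants.b0)
        ) * 1.0e3
    with np.errstate(invalid="ignore", divide="ignore"):
        vsi = np.where(
            (dr2s > 0) & (dr2 > 0), pref * np.power(dr2s / dr2, 1.5), np.nan
        )
    return vsi if vsi.ndim else float(vsi)


def rcbv_integral(dr2star_curve: np.ndarray, times: np.ndarray,
                  n_baseline: int) -> float:
    """Trapezoidal integral of a corrected dR2* curve after the baseline.

    Negative integrals (no coherent bolus) are returned as NaN so that
    the voxel propagates as missing.
    """
    curve = np.asarray(dr2star_curve, dtype=float)
    val = float(np.trapezoid(curve[n_baseline:], np.asarray(times)[n_baseline:]))
    return val if val >= 0 else float("nan")


def normalize_rcbv(integral_map: np.ndarray, healthy_brain_mask: np.ndarray) -> np.ndarray:
    """Divide by the healthy-hemisphere brain-mean integral (mean -> 1)."""
    vals = integral_map[healthy_brain_mask]
    vals = vals[np.isfinite(vals)]
    if len(vals) == 0:
        raise ValueError("no valid voxels in the healthy brain mask")
    ref = float(np.mean(vals))
    if not ref > 0:
        raise ValueError("non-positive reference integral; cannot normalize")
    return integral_map / ref


def q_to_table_units(q_si):
    """Convert Q from s^(-1/3) to the reporting unit 10^2 * ms^(-1/3)."""
    return np.asarray(q_si, dtype=float) * 10.0


def rcbv_to_table_units(rcbv):
    """Reporting scale for rCBV tables (values quoted x 10^-2)."""
    return np.asarray(rcbv, dtype=float) * 1.0e2


# ---------------------------------------------------------------------------
# map assembly and NIfTI I/O


def assemble_maps(
    voxel_values: dict[str, np.ndarray],
    brain_mask: np.ndarray,
    hemisphere: HemisphereSpec,
) -> dict[str, np.ndarray]:
    """Final whole-volume maps: NaN outside mask, lesioned side zeroed.

    ``voxel_values`` holds one 3D array per parameter name with NaN at
    voxels whose fits were invalid (missing values propagate).
    """
    brain_mask = np.asarray(brain_mask, dtype=bool)
    _, lesioned = hemisphere_split(brain_mask.shape, hemisphere)
    out: dict[str, np.ndarray] = {}
    for name, vals in voxel_values.items():
        vals = np.asarray(vals, dtype=float)
        if vals.shape != brain_mask.shape:
            raise ValueError(f"map {name!r} shape {vals.shape} does not match "
                             f"mask shape {brain_mask.shape}")
        arr = np.where(brain_mask, vals, np.nan)
        arr[lesioned] = 0.0
        out[name] = arr
    return out


def save_parameter_maps(
    maps: dict[str, np.ndarray],
    out_dir: str | Path,
    subject_id: str,
    affine: np.ndarray | None = None,
    metadata: dict | None = None,
) -> list[Path]:
    """Write one NIfTI per parameter plus a JSON sidecar with metadata."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if affine is None:
        affine = np.eye(4)
    written = []
    for name, arr in maps.items():
        path = out_dir / f"{subject_id}_{name}.nii.gz"
        nib.save(nib.Nifti1Image(np.asarray(arr, dtype=np.float64), affine), path)
        written.append(path)
    sidecar = out_dir / f"{subject_id}_maps.json"
    payload = {"subject_id": subject_id, "parameters": sorted(maps)}
    if metadata:
        payload.update(metadata)
    sidecar.write_text(json.dumps(payload, indent=2, sort_keys=True))
    written.append(sidecar)
    return written


def load_parameter_maps(out_dir: str | Path, subject_id: str) -> dict[str, np.ndarray]:
    """Read back maps written by :func:`save_parameter_maps`."""
    out_dir = Path(out_dir)
    maps = {}
    for path in sorted(out_dir.glob(f"{subject_id}_*.nii.gz")):
        name = path.name[len(subject_id) + 1 : -len(".nii.gz")]
        maps[name] = np.asarray(nib.load(path).get_fdata())
    if not maps:
        raise FileNotFoundError(f"no maps for subject {subject_id!r} in {out_dir}")
    return maps
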