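"""Extracellular-volume (ECV) mapping from paired unenhanced / portal-venous CT.

The ECV fraction of a tissue can be estimated from a conventional dual-phase
contrast-enhanced CT study as the contrast enhancement of the tissue relative
to the enhancement of the blood pool (abdominal aorta), corrected for the
intracellular fraction of blood::

    ECV = (1 - hematocrit) * (dHU_tissue / dHU_aorta) * 100  [percent]

where ``dHU = PVP - unenhanced`` attenuation in Hounsfield units.  This module
computes per-voxel ECV maps on voxel-aligned volume pairs, extracts VOI
statistics, and quantifies inter-reader agreement on segmentations (Dice).

Registration of the two phases is treated as an external pre-processing step:
inputs are assumed voxel-aligned, and mismatched grids are rejected.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np

__all__ = [
    "PhaseVolumePair",
    "BinaryMask",
    "ECVMap",
    "compute_delta_hu",
    "blood_pool_delta",
    "compute_ecv_map",
    "mean_ecv_in_voi",
    "average_reader_values",
    "dice",
    "agreement_thresholds",
    "normalize_hematocrit",
    "load_phase_pair",
    "load_mask",
    "save_volume",
    "ecv_sidecar",
]


def _default_affine(spacing: Sequence[float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


@dataclass
class PhaseVolumePair:
    """Voxel-aligned unenhanced and portal-venous-phase attenuation volumes (HU)."""

    unenhanced: np.ndarray
    pvp: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.unenhanced = np.asarray(self.unenhanced, dtype=float)
        self.pvp = np.asarray(self.pvp, dtype=float)
        if self.unenhanced.ndim != 3 or self.pvp.ndim != 3:
            raise ValueError("phase volumes must be 3-D")
        if self.unenhanced.shape != self.pvp.shape:
            raise ValueError(
                f"phase volumes must share a grid: {self.unenhanced.shape} vs {self.pvp.shape}"
            )
        if not (np.isfinite(self.unenhanced).all() and np.isfinite(self.pvp).all()):
            raise ValueError("attenuation values must be finite")
        if self.affine is None:
            self.affine = _default_affine(self.spacing)
        else:
            self.affine = np.asarray(self.affine, dtype=float)
            if self.affine.shape != (4, 4):
                raise ValueError("affine must be 4x4")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.unenhanced.shape


@dataclass
class BinaryMask:
    """0/1 segmentation on the same grid as its volume pair."""

    data: np.ndarray
    label: str = "tumor"

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        uniq = np.unique(arr)
        if not np.isin(uniq, (0, 1)).all():
            raise ValueError("mask must contain only 0/1 values")
        self.data = arr.astype(bool)

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def require_nonempty(self) -> None:
        if self.n_voxels == 0:
            raise ValueError(f"mask '{self.label}' is empty")


@dataclass
class ECVMap:
    """Per-voxel ECV percentages plus the blood-pool scalar used to compute them.

    Values are *not* clipped; voxels outside [0, 100] % are flagged for audit.
    """

    values: np.ndarray
    delta_aorta: float
    hematocrit: float
    flags: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.flags = (self.values < 0.0) | (self.values > 100.0)

    @property
    def n_flagged(self) -> int:
        return int(self.flags.sum())


def normalize_hematocrit(hematocrit: float) -> float:
    """Return hematocrit as a fraction in [0, 1).

    Values in (1, 100] are interpreted as percent and divided by 100 (with a
    warning); anything else outside [0, 1) is rejected.
    """
    hct = float(hematocrit)
    if 1.0 < hct <= 100.0:
        warnings.warn(
            f"hematocrit {hct} looks like a percentage; interpreting as {hct / 100.0:.3f}",
            stacklevel=2,
        )
        hct = hct / 100.0
    if not (0.0 <= hct < 1.0):
        raise ValueError(f"hematocrit must be a fraction in [0, 1), got {hematocrit}")
    return hct


def compute_delta_hu(pair: PhaseVolumePair) -> np.ndarray:
    """Voxel-wise enhancement: PVP minus unenhanced attenuation (HU)."""
    return pair.pvp - pair.unenhanced


def blood_pool_delta(delta: np.ndarray, aorta: BinaryMask, stat: str = "mean") -> float:
    """Summarize enhancement over the aortic blood-pool mask.

    The summary statistic is the mean by default (median available).  A
    non-positive result is rejected: the blood pool must enhance for the ECV
    ratio to be meaningful.
    """
    aorta.require_nonempty()
    if aorta.data.shape != np.shape(delta):
        raise ValueError("aorta mask grid does not match the enhancement volume")
    vals = np.asarray(delta, dtype=float)[aorta.data]
    if stat == "mean":
        out = float(vals.mean())
    elif stat == "median":
        out = float(np.median(vals))
    else:
        raise ValueError(f"unknown blood-pool statistic {stat!r}")
    if out <= 0.0:
        raise ValueError(f"blood-pool enhancement must be positive, got {out:.3f} HU")
    return out


def compute_ecv_map(delta: np.ndarray, delta_aorta: float, hematocrit: float) -> ECVMap:
    """Per-voxel ECV (percent) from an enhancement volume and blood-pool scalar."""
    if not np.isfinite(delta_aorta) or delta_aorta <= 0.0:
        raise ValueError(f"delta_aorta must be positive and finite, got {delta_aorta}")
    hct = normalize_hematocrit(hematocrit)
    values = (1.0 - hct) * (np.asarray(delta, dtype=float) / delta_aorta) * 100.0
    return ECVMap(values=values, delta_aorta=float(delta_aorta), hematocrit=hct)


def mean_ecv_in_voi(ecv: ECVMap | np.ndarray, voi: BinaryMask) -> float:
    """Arithmetic mean ECV (percent) over the tumor VOI."""
    voi.require_nonempty()
    values = ecv.values if isinstance(ecv, ECVMap) else np.asarray(ecv, dtype=float)
    if voi.data.shape != values.shape:
        raise ValueError("VOI mask grid does not match the ECV map")
    return float(values[voi.data].mean())


def average_reader_values(values: Sequence[float]) -> float:
    """Average of measurements from multiple readers (two radiologists typically)."""
    if len(values) == 0:
        raise ValueError("need at least one reader value")
    return float(np.mean([float(v) for v in values]))


def dice(a: BinaryMask, b: BinaryMask) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A|+|B|) between two segmentations."""
    if a.data.shape != b.data.shape:
        raise ValueError("masks must share a grid")
    na, nb = a.n_voxels, b.n_voxels
    if na == 0 and nb == 0:
        raise ValueError("Dice undefined for two empty masks")
    inter = int(np.logical_and(a.data, b.data).sum())
    return 2.0 * inter / (na + nb)


def agreement_thresholds(dsc: float) -> str:
    """Categorize a Dice coefficient for reader-agreement reporting.

    > 0.80 is 'satisfactory', < 0.50 requires consensus re-segmentation,
    anything between is 'acceptable'.
    """
    if not (0.0 <= dsc <= 1.0):
        raise ValueError(f"Dice coefficient must be in [0, 1], got {dsc}")
    if dsc > 0.80:
        return "satisfactory"
    if dsc < 0.50:
        return "consensus-required"
    return "acceptable"


# ---------------------------------------------------------------------------
# NIfTI I/O


def load_phase_pair(unenhanced_path: str | Path, pvp_path: str | Path) -> PhaseVolumePair:
    n_img = nib.load(str(unenhanced_path))
    p_img = nib.load(str(pvp_path))
    if n_img.shape != p_img.shape or not np.allclose(n_img.affine, p_img.affine):
        raise ValueError("unenhanced and PVP volumes are not voxel-aligned")
    spacing = tuple(float(z) for z in n_img.header.get_zooms()[:3])
    return PhaseVolumePair(
        unenhanced=np.asanyarray(n_img.dataobj),
        pvp=np.asanyarray(p_img.dataobj),
        spacing=spacing,
        affine=n_img.affine,
    )


def load_mask(path: str | Path, label: str = "tumor") -> BinaryMask:
    img = nib.load(str(path))
    return BinaryMask(data=np.rint(np.asanyarray(img.dataobj)).astype(int), label=label)


def save_volume(data: np.ndarray, path: str | Path, affine: np.ndarray | None = None) -> None:
    if affine is None:
        affine = np.eye(4)
    arr = np.asarray(data)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
    nib.save(nib.Nifti1Image(arr, affine), str(path))


def ecv_sidecar(
    ecv: ECVMap, voi: BinaryMask, path: str | Path | None = None
) -> dict:
    """JSON-able summary of an ECV computation (blood pool, VOI mean, flags)."""
    payload = {
        "delta_hu_aorta": ecv.delta_aorta,
        "hematocrit": ecv.hematocrit,
        "voi_mean_ecv_pct": mean_ecv_in_voi(ecv, voi),
        "voi_voxels": voi.n_voxels,
        "flagged_voxels": ecv.n_flagged,
    }
    if path is not None:
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))
    return payload
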