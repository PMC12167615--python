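"""Tumour-burden metrics from lesion segmentations.

TLV (total lesion volume) is the summed volume of all segmented lesions in
cm^3.  TLU (total lesion uptake) is TLV times the SUVmean over the pooled
lesion voxels, i.e. the voxelwise integral of SUV over the lesions.  Because
SUV is activity normalized by injected activity per gram (density 1 g/cm^3),
TLU/(weight in g) is the fraction of the decay-corrected administered
activity residing in tumour; it is reported as a percentage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .suvcore import PETVolume, ScanMeta


@dataclass
class LesionSet:
    """Disjoint lesion segmentations as one labelled integer grid.

    Label 0 is background; each positive label is one lesion.  ``sites``
    optionally maps labels to anatomical sites (prostate / node / bone).
    """

    labels: np.ndarray
    sites: dict[int, str] | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("lesion label grid must be 3D")
        if np.any(self.labels < 0):
            raise ValueError("lesion labels must be non-negative")

    @classmethod
    def from_masks(cls, masks, sites=None) -> "LesionSet":
        """Build from a list of binary masks; masks must be disjoint."""
        masks = [np.asarray(m, dtype=bool) for m in masks]
        if not masks:
            raise ValueError("from_masks requires at least one mask")
        labels = np.zeros(masks[0].shape, dtype=int)
        for i, m in enumerate(masks, start=1):
            if m.shape != labels.shape:
                raise ValueError("lesion mask shapes differ")
            if np.any(labels[m] != 0):
                raise ValueError("lesion masks overlap")
            labels[m] = i
        site_map = dict(zip(range(1, len(masks) + 1), sites)) if sites else None
        return cls(labels, site_map)

    @classmethod
    def empty(cls, shape) -> "LesionSet":
        return cls(np.zeros(shape, dtype=int))

    @property
    def union_mask(self) -> np.ndarray:
        return self.labels > 0

    @property
    def lesion_labels(self) -> np.ndarray:
        labs = np.unique(self.labels)
        return labs[labs > 0]


@dataclass(frozen=True)
class BurdenMetrics:
    """Per-patient tumour burden: TLV (cm^3), TLU (SUV*cm^3), % injected."""

    tlv_cm3: float
    tlu: float
    pct_injected: float


def compute_tlv(lesions: LesionSet, spacing) -> float:
    """Total lesion volume in cm^3: voxel count times voxel volume."""
    voxvol_cm3 = float(np.prod(np.asarray(spacing, dtype=float))) / 1000.0
    return float(np.count_nonzero(lesions.labels)) * voxvol_cm3


def lesion_suv_mean(vol: PETVolume, lesions: LesionSet) -> float:
    """Mean SUV over the pooled lesion voxels (one global mean)."""
    if vol.value_kind != "suv":
        raise ValueError("lesion_suv_mean requires an SUV volume")
    if lesions.labels.shape != vol.values.shape:
        raise ValueError("lesion grid and volume geometry differ")
    m = lesions.union_mask
    if not m.any():
        raise ValueError("no lesion voxels")
    return float(vol.values[m].mean())


def compute_tlu(vol: PETVolume, lesions: LesionSet) -> float:
    """Total lesion uptake: TLV times pooled-lesion SUVmean (SUV*cm^3).

    Algebraically identical to the voxelwise sum of SUV times voxel volume
    over the lesions; zero when there are no lesions.
    """
    if not lesions.union_mask.any():
        return 0.0
    return compute_tlv(lesions, vol.spacing) * lesion_suv_mean(vol, lesions)


def pct_injected_activity(tlu: float, meta: ScanMeta) -> float:
    """Percentage of the administered activity located in tumour.

    With density 1 g/cm^3, SUV integrated over a volume (= TLU, SUV*cm^3)
    divided by body mass in grams is the activity fraction; times 100 for %.
    """
    return 100.0 * tlu / (meta.weight_kg * 1000.0)


def compute_burden(vol: PETVolume, lesions: LesionSet,
                   meta: ScanMeta) -> BurdenMetrics:
    tlv = compute_tlv(lesions, vol.spacing)
    tlu = compute_tlu(vol, lesions)
    return BurdenMetrics(tlv, tlu, pct_injected_activity(tlu, meta))
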