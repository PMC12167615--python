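"""NIfTI and sidecar I/O.

Volumes and masks travel as NIfTI-1 (affine honoured, spacing from the
header zooms); scan metadata travels as a small YAML sidecar with ISO-8601
timestamps.  All unit conversions happen here: images are activity
concentration in kBq/mL unless stated otherwise.
"""

from __future__ import annotations

from datetime import datetime
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .burden import LesionSet
from .suvcore import PETVolume, ScanMeta


def load_pet(path, value_kind: str = "activity") -> PETVolume:
    img = nib.load(str(path))
    values = np.asarray(img.get_fdata(), dtype=float)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return PETVolume(values, spacing, np.asarray(img.affine), value_kind)


def save_volume(values: np.ndarray, affine: np.ndarray, path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(values, dtype=np.float32),
                             np.asarray(affine)), str(path))


def save_mask(mask: np.ndarray, affine: np.ndarray, path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(mask, dtype=np.uint8),
                             np.asarray(affine)), str(path))


def load_labelled_masks(path, labels_yaml) -> dict[str, np.ndarray]:
    """Split a labelled NIfTI into named binary masks.

    ``labels_yaml`` maps integer label -> organ name, e.g. ``1: kidneys``.
    """
    img = nib.load(str(path))
    data = np.rint(np.asarray(img.get_fdata())).astype(int)
    with open(labels_yaml) as fh:
        mapping = yaml.safe_load(fh)
    return {str(name): data == int(label) for label, name in mapping.items()}


def load_lesions(path) -> LesionSet:
    img = nib.load(str(path))
    labels = np.rint(np.asarray(img.get_fdata())).astype(int)
    return LesionSet(labels)


def load_meta(path) -> ScanMeta:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    kwargs = {}
    if "isotope_half_life_min" in d:
        kwargs["isotope_half_life_min"] = float(d["isotope_half_life_min"])
    return ScanMeta(
        injected_activity_mbq=float(d["injected_activity_mbq"]),
        injection_time=datetime.fromisoformat(str(d["injection_time"])),
        scan_time=datetime.fromisoformat(str(d["scan_time"])),
        weight_kg=float(d["weight_kg"]),
        **kwargs)


def save_meta(meta: ScanMeta, path) -> None:
    d = {
        "injected_activity_mbq": float(meta.injected_activity_mbq),
        "injection_time": meta.injection_time.isoformat(),
        "scan_time": meta.scan_time.isoformat(),
        "weight_kg": float(meta.weight_kg),
        "isotope_half_life_min": float(meta.isotope_half_life_min),
    }
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))
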