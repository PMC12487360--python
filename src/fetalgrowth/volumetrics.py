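"""Compartment volumes from anatomical label images and summary ratios.

Label volumes are integer-valued 3-D images whose codes follow the fetal
macaque template scheme: 1 CSF, 2 cortical plate, 3 subplate, 4 ventricles,
5 germinal/fibrous matrix (GMAT), 6 thalamus, 7 cerebellum, 8 brainstem,
9 corpus callosum, 10 striatum, 101 lentiform/putamen, 102 caudate,
103 hippocampus, 104 globus pallidus, 106 amygdala, 107 hypothalamus.
Volumes are voxel counts times the voxel volume, reported in mL
(mm^3 / 1000).  The default aggregation merges the transient zones into
compartments identifiable at every fetal age: all striatal and deep-gray
codes fall into subcortical gray, and subplate + GMAT + corpus callosum
form the nascent white matter.  Labels absent at a given age (e.g. no
caudate at G85) contribute zero volume with a warning.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .exceptions import DataError, DomainError

logger = logging.getLogger(__name__)

__all__ = [
    "TISSUE_LABELS",
    "PAPER_DEFAULT_SCHEME",
    "LabelVolume",
    "compartment_volumes",
    "percent_of_adult",
    "mean_daily_growth",
    "fold_change",
    "load_label_volume",
]

TISSUE_LABELS: dict[int, str] = {
    1: "csf",
    2: "cortical_plate",
    3: "subplate",
    4: "ventricles",
    5: "gmat",
    6: "thalamus",
    7: "cerebellum",
    8: "brainstem",
    9: "corpus_callosum",
    10: "striatum",
    101: "lentiform_putamen",
    102: "caudate",
    103: "hippocampus",
    104: "globus_pallidus",
    106: "amygdala",
    107: "hypothalamus",
}

_ALL = frozenset(TISSUE_LABELS)

#: compartments identifiable at every fetal age
PAPER_DEFAULT_SCHEME: dict[str, frozenset[int]] = {
    "whole_brain": frozenset(_ALL - {1}),
    "icv": frozenset(_ALL),
    "extra_axial_csf": frozenset({1}),
    "cortical_plate": frozenset({2}),
    "nascent_white_matter": frozenset({3, 5, 9}),
    "subcortical_gray": frozenset({6, 10, 101, 102, 103, 104, 106, 107}),
    "brainstem": frozenset({8}),
    "cerebellum": frozenset({7}),
    "ventricles": frozenset({4}),
}

#: the disjoint regions entering the regional analyses (whole_brain excluded:
#: it is their union plus ventricles)
ANALYSIS_REGIONS = (
    "cortical_plate",
    "nascent_white_matter",
    "subcortical_gray",
    "brainstem",
    "cerebellum",
    "ventricles",
    "whole_brain",
)


@dataclass
class LabelVolume:
    """Integer label array with voxel dimensions (mm) and a label dictionary."""

    labels: np.ndarray
    voxel_dims: np.ndarray
    label_map: dict[int, str] = field(default_factory=lambda: dict(TISSUE_LABELS))
    affine: np.ndarray | None = None

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise DataError("label array must be 3-D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise DataError("label array must be integer valued")
        self.voxel_dims = np.asarray(self.voxel_dims, dtype=float)
        if self.voxel_dims.shape != (3,) or np.any(self.voxel_dims <= 0):
            raise DataError("voxel_dims must be three positive lengths in mm")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_dims))

    def label_counts(self) -> dict[int, int]:
        codes, counts = np.unique(self.labels, return_counts=True)
        return {int(c): int(k) for c, k in zip(codes, counts) if c != 0}


def load_label_volume(path: str | Path) -> LabelVolume:
    """Read a NIfTI label image; voxel dimensions come from the header."""
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if not np.issubdtype(data.dtype, np.integer):
        rounded = np.rint(data)
        if not np.allclose(data, rounded, atol=1e-6):
            raise DataError(f"{path} does not contain integer labels")
        data = rounded.astype(np.int32)
    zooms = np.asarray(img.header.get_zooms()[:3], dtype=float)
    if np.any(zooms <= 0):
        raise DataError(f"{path} header has non-positive voxel dimensions")
    return LabelVolume(labels=data, voxel_dims=zooms, affine=img.affine)


def compartment_volumes(
    vol: LabelVolume, scheme: dict[str, frozenset[int]] | None = None
) -> dict[str, float]:
    """Aggregate label counts into compartment volumes in mL.

    ``volume = n_voxels * voxel_volume_mm3 / 1000``.  Labels named by the
    scheme but absent from the image contribute zero with a warning (they
    may legitimately be unsegmentable at young ages).
    """
    scheme = PAPER_DEFAULT_SCHEME if scheme is None else scheme
    counts = vol.label_counts()
    missing = sorted(
        {code for codes in scheme.values() for code in codes} - set(counts)
    )
    if missing:
        warnings.warn(
            f"labels {missing} absent from the image; they contribute 0 volume"
        )
    ml_per_voxel = vol.voxel_volume_mm3 / 1000.0
    return {
        name: ml_per_voxel * sum(counts.get(code, 0) for code in codes)
        for name, codes in scheme.items()
    }


def percent_of_adult(fetal_ml: float, adult_ml: float) -> float:
    """Fetal volume as a percentage of the adult reference volume."""
    if adult_ml <= 0:
        raise DomainError("adult volume must be positive")
    return 100.0 * fetal_ml / adult_ml


def mean_daily_growth(v_start: float, t_start: float, v_end: float, t_end: float) -> float:
    """Average growth rate (mL/day) between two (volume, age) observations."""
    if t_end <= t_start:
        raise DomainError("t_end must exceed t_start")
    return (v_end - v_start) / (t_end - t_start)


def fold_change(v_start: float, v_end: float) -> float:
    """Multiplicative increase ``v_end / v_start``."""
    if v_start <= 0:
        raise DomainError("starting value must be positive")
    return v_end / v_start
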