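"""Myocardial segmentation and coronary-territory aggregation.

Segmentation mirrors the clinical analysis chain: the myocardial wall is
delineated on the perfusable-tissue-fraction (PTF) image, optionally after
censoring voxels whose anatomical tissue fraction (ATF = 1 - V_A - V_RV)
falls below a threshold; the surviving wall is split into the three
coronary territories (LAD, RCA, LCX) by circumferential angle about the LV
long axis, and MBF/MBFt are averaged per territory and globally.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd
from scipy import ndimage

if TYPE_CHECKING:  # pragma: no cover
    from .kinetics import ParametricMaps

__all__ = [
    "SegmentationError",
    "DEFAULT_ATF_THRESHOLD",
    "DEFAULT_PTF_FLOOR",
    "REGION_NAMES",
    "compute_atf",
    "segment_myocardium",
    "circumferential_territories",
    "assign_territories",
    "regional_values",
]

#: Censor voxels with anatomical tissue fraction below this before
#: segmentation (the "ATF rule").
DEFAULT_ATF_THRESHOLD = 0.25
#: Minimum PTF (g/mL) for a voxel to count as myocardium.
DEFAULT_PTF_FLOOR = 0.25

REGION_NAMES = ("LV", "LAD", "RCA", "LCX")
_CODES = {"LAD": 1, "RCA": 2, "LCX": 3}
_26_CONN = np.ones((3, 3, 3), dtype=bool)


class SegmentationError(RuntimeError):
    """Raised when no myocardial wall can be delineated.

    Mirrors the clinical failure mode where severe attenuation artifacts in
    PTF make the wall impossible to segment.
    """


def compute_atf(maps: "ParametricMaps") -> np.ndarray:
    """Anatomical tissue fraction per voxel: 1 - V_A - V_RV, clipped to [0, 1].

    The non-blood fraction of the voxel; near zero in cavities, near one in
    compact myocardium.
    """
    return np.clip(1.0 - maps.v_a - maps.v_rv, 0.0, 1.0)


def segment_myocardium(
    ptf_map: np.ndarray,
    atf_map: np.ndarray,
    atf_threshold: float = DEFAULT_ATF_THRESHOLD,
    apply_atf_rule: bool = True,
    ptf_floor: float = DEFAULT_PTF_FLOOR,
) -> tuple[np.ndarray, np.ndarray]:
    """Delineate the myocardial wall on a PTF image.

    When ``apply_atf_rule`` is on, PTF is set to zero wherever ATF falls
    below ``atf_threshold``; the wall mask is then the largest 26-connected
    component of ``PTF > ptf_floor``.  Returns ``(mask, censored_ptf)``.

    Raises :class:`SegmentationError` when nothing survives - the analysis
    for that scan must be recorded as failed, not silently skipped.
    """
    ptf_map = np.asarray(ptf_map, dtype=float)
    atf_map = np.asarray(atf_map, dtype=float)
    if ptf_map.shape != atf_map.shape:
        raise ValueError("PTF and ATF maps must be aligned")
    if not (0 <= atf_threshold <= 1):
        raise ValueError("atf_threshold must lie in [0, 1]")
    censored = ptf_map.copy()
    if apply_atf_rule:
        censored[atf_map < atf_threshold] = 0.0
    candidate = censored > ptf_floor
    if not candidate.any():
        raise SegmentationError(
            "no voxels above the PTF floor; myocardium impossible to segment"
        )
    labelled, n_comp = ndimage.label(candidate, structure=_26_CONN)
    sizes = ndimage.sum_labels(candidate, labelled, index=np.arange(1, n_comp + 1))
    mask = labelled == (1 + int(np.argmax(sizes)))
    return mask, censored


def circumferential_territories(
    mask: np.ndarray, center_mm: np.ndarray, voxel_size_mm: float
) -> np.ndarray:
    """Label a wall mask by circumferential sector about the LV long axis.

    With +X patient-left and +Y anterior, the angle phi = atan2(y, x) of each
    voxel about the long axis (Z) selects the territory:

    * LCX  : phi in [-60, 60)    - lateral wall
    * LAD  : phi in [60, 180)    - anterior and anteroseptal wall
    * RCA  : phi in [-180, -60)  - inferior and inferoseptal wall

    Returns an integer map with codes {0 background, 1 LAD, 2 RCA, 3 LCX}.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("cannot assign territories to an empty mask")
    idx = np.argwhere(mask)
    pos = (idx + 0.5) * voxel_size_mm
    dx = pos[:, 0] - center_mm[0]
    dy = pos[:, 1] - center_mm[1]
    if np.all((dx == 0) & (dy == 0)):
        raise ValueError("degenerate geometry: mask lies on the long axis")
    phi = np.degrees(np.arctan2(dy, dx))
    codes = np.where(
        (phi >= -60.0) & (phi < 60.0),
        _CODES["LCX"],
        np.where((phi >= 60.0) & (phi < 180.0), _CODES["LAD"], _CODES["RCA"]),
    )
    labels = np.zeros(mask.shape, dtype=np.int8)
    labels[mask] = codes
    return labels


def assign_territories(mask: np.ndarray, geometry) -> np.ndarray:
    """Territory labels for a segmented wall, given the heart geometry.

    ``geometry`` needs ``lv_center_mm`` and ``voxel_size_mm`` attributes
    (e.g. a :class:`~watermbf.synth.PhantomGeometry`); the LV long axis is
    taken along Z per the package axis convention.
    """
    return circumferential_territories(
        mask, np.asarray(geometry.lv_center_mm), float(geometry.voxel_size_mm)
    )


def regional_values(maps: "ParametricMaps", labels: np.ndarray) -> pd.DataFrame:
    """Mean MBF and MBFt per coronary territory and globally.

    Returns a DataFrame indexed by region (LV, LAD, RCA, LCX) with columns
    ``mbf``, ``mbft`` and ``n_voxels``; the LV row is the voxel-count-
    weighted mean of the three territories by construction.
    """
    labels = np.asarray(labels)
    if labels.shape != maps.mbf.shape:
        raise ValueError("labels must be aligned with the parameter maps")
    rows = []
    for name in ("LAD", "RCA", "LCX"):
        sel = labels == _CODES[name]
        n = int(sel.sum())
        if n == 0:
            raise ValueError(f"territory {name} is empty")
        rows.append((name, maps.mbf[sel].mean(), maps.mbft[sel].mean(), n))
    all_sel = labels > 0
    lv = ("LV", maps.mbf[all_sel].mean(), maps.mbft[all_sel].mean(), int(all_sel.sum()))
    df = pd.DataFrame(
        [lv] + rows, columns=["region", "mbf", "mbft", "n_voxels"]
    ).set_index("region")
    return df
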