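"""Clinical geometric indices measured on a 3-D spine geometry.

All measurements mirror standard radiographic practice applied to the 3-D
model:

* **Coronal Cobb angle** -- angle between the coronal-plane (YZ) projections
  of the upper end vertebra's superior endplate line and the lower end
  vertebra's inferior endplate line, where an endplate line joins the left
  and right endplate corner midpoints.
* **Sagittal angle** (kyphosis / lordosis) -- the same construction projected
  onto the sagittal plane (XZ), signed so that thoracic kyphosis and lumbar
  lordosis are positive under their respective conventions.  Default
  measurement levels: kyphosis T2-T12, lordosis L1-S1 (the pelvis sacral
  plate standing in for S1); both are configurable and recorded in the
  report metadata since radiographic conventions vary.
* **Apical vertebral rotation** -- transverse-plane angle between the apical
  vertebra's local sagittal (anterior) axis and the global sagittal plane.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import SpineGeometry
from .indices import ClinicalIndices

__all__ = ["IndexReport", "cobb_angle", "signed_cobb", "sagittal_angle",
           "apical_rotation", "index_report"]

KYPHOSIS_LEVELS = ("T2", "T12")
LORDOSIS_LEVELS = ("L1", "PELVIS")


def _endplate_dir_coronal(geometry, level, plate):
    """Coronal-plane endplate line direction (dy, dz), normalized dy >= 0."""
    v = geometry[level]
    left = 0.5 * (v.world(f"{plate}_corner_al") + v.world(f"{plate}_corner_pl"))
    right = 0.5 * (v.world(f"{plate}_corner_ar") + v.world(f"{plate}_corner_pr"))
    d = left - right
    dy, dz = d[1], d[2]
    if dy < 0 or (dy == 0 and dz < 0):
        dy, dz = -dy, -dz
    return dy, dz


def _endplate_dir_sagittal(geometry, level, plate):
    """Sagittal-plane endplate direction (dx, dz), normalized dx >= 0."""
    v = geometry[level]
    ant = 0.5 * (v.world(f"{plate}_corner_al") + v.world(f"{plate}_corner_ar"))
    post = 0.5 * (v.world(f"{plate}_corner_pl") + v.world(f"{plate}_corner_pr"))
    d = ant - post
    dx, dz = d[0], d[2]
    if dx < 0 or (dx == 0 and dz < 0):
        dx, dz = -dx, -dz
    return dx, dz


def signed_cobb(geometry: SpineGeometry, upper_end: str, lower_end: str) -> float:
    """Signed coronal Cobb (deg): upper superior-endplate tilt minus lower
    inferior-endplate tilt.  The sign encodes curve direction and is used
    internally (e.g. by the flexibility calibration); the clinical Cobb is
    its magnitude."""
    from . import levels as _lv
    if not _lv.cephalad_of(upper_end, lower_end):
        raise ValueError(f"invalid level pair: {upper_end} not cephalad of "
                         f"{lower_end}")
    au = np.arctan2(*reversed(_endplate_dir_coronal(geometry, upper_end, "sup")))
    al = np.arctan2(*reversed(_endplate_dir_coronal(geometry, lower_end, "inf")))
    return float(np.degrees(au - al))


def cobb_angle(geometry: SpineGeometry, upper_end: str, lower_end: str) -> float:
    """Coronal Cobb angle in [0, 180) degrees."""
    return abs(signed_cobb(geometry, upper_end, lower_end))


def sagittal_angle(geometry: SpineGeometry, upper_end: str, lower_end: str,
                   convention: str = "kyphosis") -> float:
    """Sagittal-plane Cobb between upper superior and lower inferior
    endplates, signed: positive = posterior-convex for ``convention=
    'kyphosis'``, positive = anterior-convex for ``'lordosis'``."""
    from . import levels as _lv
    if not _lv.cephalad_of(upper_end, lower_end):
        raise ValueError(f"invalid level pair: {upper_end} not cephalad of "
                         f"{lower_end}")
    au = np.arctan2(*reversed(_endplate_dir_sagittal(geometry, upper_end, "sup")))
    al = np.arctan2(*reversed(_endplate_dir_sagittal(geometry, lower_end, "inf")))
    ang = float(np.degrees(al - au))
    if convention == "lordosis":
        ang = -ang
    elif convention != "kyphosis":
        raise ValueError(f"unknown sagittal convention: {convention!r}")
    return ang


def apical_rotation(geometry: SpineGeometry, apex: str) -> float:
    """Transverse-plane rotation (deg, in [0, 90]) of the apical vertebra's
    local sagittal axis away from the global sagittal plane."""
    v = geometry[apex]
    ax = v.rotation @ np.array([1.0, 0.0, 0.0])   # local anterior axis
    return float(np.degrees(np.arctan2(abs(ax[1]), abs(ax[0]))))


@dataclass
class IndexReport:
    """Measured regional indices for one geometry (Table-2-shaped)."""

    pt_cobb: float
    mt_cobb: float
    tll_cobb: float
    kyphosis: float
    lordosis: float
    mt_avr: float
    tll_avr: float
    levels_used: dict = field(default_factory=dict)
    conventions: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        row = {k: round(getattr(self, k), 3)
               for k in ("pt_cobb", "mt_cobb", "tll_cobb", "kyphosis",
                         "lordosis", "mt_avr", "tll_avr")}
        row.update({f"levels_{k}": v for k, v in self.levels_used.items()})
        return row


def index_report(geometry: SpineGeometry, indices: ClinicalIndices,
                 kyphosis_levels=KYPHOSIS_LEVELS,
                 lordosis_levels=LORDOSIS_LEVELS) -> IndexReport:
    """Measure all regional indices using the end/apex levels of ``indices``."""
    spans = {r: indices.region_span(r) for r in ("PT", "MT", "TLL")}
    return IndexReport(
        pt_cobb=cobb_angle(geometry, *spans["PT"]),
        mt_cobb=cobb_angle(geometry, *spans["MT"]),
        tll_cobb=cobb_angle(geometry, *spans["TLL"]),
        kyphosis=sagittal_angle(geometry, *kyphosis_levels, "kyphosis"),
        lordosis=sagittal_angle(geometry, *lordosis_levels, "lordosis"),
        mt_avr=apical_rotation(geometry, indices.mt_apex),
        tll_avr=apical_rotation(geometry, indices.tll_apex),
        levels_used={"PT": "-".join(spans["PT"]), "MT": "-".join(spans["MT"]),
                     "TLL": "-".join(spans["TLL"]),
                     "kyphosis": "-".join(kyphosis_levels),
                     "lordosis": "-".join(lordosis_levels),
                     "mt_apex": indices.mt_apex, "tll_apex": indices.tll_apex},
        conventions={"avr": "transverse projection of the local sagittal axis",
                     "kyphosis_sign": "posterior-convex positive",
                     "lordosis_sign": "anterior-convex positive"},
    )
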