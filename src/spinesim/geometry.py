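"""Spine geometry containers: per-vertebra frames and anatomical landmarks.

Global coordinate convention (used everywhere in the package): right-handed,
Z cephalad, X anterior, Y toward the patient's left.  The coronal plane is
YZ, the sagittal plane XZ, the transverse plane XY.  All interface angles
are degrees, lengths mm.

Each vertebra carries a rigid frame (position of the body center plus a
rotation matrix) and a set of named landmarks in the local frame: endplate
centers and corners, pedicle entry points, transverse-process tips and the
spinous-process tip, mirroring what a biplanar-radiograph 3-D reconstruction
delivers.  Derived soft-tissue attachment points (ligament and facet
locations) are stored alongside with ``att_`` prefixes.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from . import levels

__all__ = ["VertebraGeometry", "SpineGeometry", "vertebra_landmarks"]

#: landmark names guaranteed present on every vertebra
CORE_LANDMARKS = [
    "sup_center", "inf_center",
    "sup_corner_al", "sup_corner_ar", "sup_corner_pl", "sup_corner_pr",
    "inf_corner_al", "inf_corner_ar", "inf_corner_pl", "inf_corner_pr",
    "pedicle_l", "pedicle_r", "transverse_l", "transverse_r", "spinous",
]


def vertebra_landmarks(width: float, depth: float, height: float) -> dict:
    """Local-frame landmark set for a vertebral body of the given dimensions.

    x anterior, y left, z cephalad; origin at the body center.  Left/right
    pairs mirror exactly across the local sagittal (xz) plane.
    """
    w2, d2, h2 = width / 2.0, depth / 2.0, height / 2.0
    spinous_len = 0.9 * depth          # posterior extent of the spinous process
    lm = {
        "sup_center": (0.0, 0.0, h2),
        "inf_center": (0.0, 0.0, -h2),
        "pedicle_l": (-d2, 0.30 * width, 0.25 * height),
        "pedicle_r": (-d2, -0.30 * width, 0.25 * height),
        "transverse_l": (-0.2 * depth, w2 + 0.55 * width, 0.0),
        "transverse_r": (-0.2 * depth, -(w2 + 0.55 * width), 0.0),
        "spinous": (-(d2 + spinous_len), 0.0, -0.2 * height),
    }
    for sgn_z, plate in ((1.0, "sup"), (-1.0, "inf")):
        for sgn_x, ap in ((1.0, "a"), (-1.0, "p")):
            for sgn_y, side in ((1.0, "l"), (-1.0, "r")):
                lm[f"{plate}_corner_{ap}{side}"] = (
                    sgn_x * d2, sgn_y * w2, sgn_z * h2)
    # soft-tissue attachment points (derived, not radiographic landmarks):
    # ligament cables attach per endplate side; the interspinous attachment
    # sits partway along the spinous process, facet points just posterior
    # and lateral of the body.
    isl_x = -(d2 + 0.35 * spinous_len)
    for sgn_z, plate in ((1.0, "sup"), (-1.0, "inf")):
        lm[f"att_all_{plate}"] = (d2, 0.0, sgn_z * h2)
        lm[f"att_pll_{plate}"] = (-d2, 0.0, sgn_z * h2)
        lm[f"att_lf_{plate}"] = (-0.65 * depth, 0.0, sgn_z * h2)
        lm[f"att_isl_{plate}"] = (isl_x, 0.0, sgn_z * 0.35 * height)
        lm[f"att_facet_l_{plate}"] = (-0.30 * depth, 0.06 * depth, sgn_z * h2)
        lm[f"att_facet_r_{plate}"] = (-0.30 * depth, -0.06 * depth, sgn_z * h2)
    return {k: np.asarray(v, dtype=float) for k, v in lm.items()}


@dataclass
class VertebraGeometry:
    """One rigid vertebra: level label, frame, local landmarks."""

    level: str
    position: np.ndarray                    # (3,) body-center, global mm
    rotation: np.ndarray                    # (3, 3) local -> global
    landmarks: dict = field(default_factory=dict)
    dims: tuple = (0.0, 0.0, 0.0)           # (width, depth, height) mm

    def world(self, name: str) -> np.ndarray:
        """Global position of a named landmark."""
        try:
            lm = self.landmarks[name]
        except KeyError:
            raise KeyError(
                f"vertebra {self.level}: missing landmark {name!r}") from None
        return self.position + self.rotation @ lm

    @property
    def orientation_deg(self) -> np.ndarray:
        return Rotation.from_matrix(self.rotation).as_rotvec(degrees=True)

    def transformed(self, du, dR) -> "VertebraGeometry":
        """Rigidly moved copy: new position = du + dR-applied displacement."""
        return VertebraGeometry(self.level, np.asarray(du, float),
                                np.asarray(dR, float) @ self.rotation,
                                self.landmarks, self.dims)


@dataclass
class SpineGeometry:
    """Ordered T1..L5 vertebrae plus the pelvis (as a sacral-plate body)."""

    vertebrae: list                          # of VertebraGeometry, T1 first
    pelvis: VertebraGeometry = None

    def __getitem__(self, level: str) -> VertebraGeometry:
        lab = level.upper()
        if self.pelvis is not None and lab == self.pelvis.level:
            return self.pelvis
        for v in self.vertebrae:
            if v.level == lab:
                return v
        raise KeyError(f"no body with level label {level!r}")

    @property
    def bodies(self) -> list:
        """All rigid bodies, vertebrae then pelvis."""
        return list(self.vertebrae) + [self.pelvis]

    def validate(self):
        """Check ordering and non-interpenetration invariants."""
        zs = [v.position[2] for v in self.bodies]
        if not all(a > b for a, b in zip(zs, zs[1:])):
            raise ValueError("vertebral centers not strictly ordered "
                             "cephalad to caudal")
        for a, b in zip(self.bodies, self.bodies[1:]):
            gap = np.linalg.norm(a.position - b.position)
            min_gap = 0.9 * (a.dims[2] / 2 + b.dims[2] / 2)
            if gap < min_gap:
                raise ValueError(
                    f"vertebral bodies {a.level} and {b.level} interpenetrate "
                    f"(spacing {gap:.2f} mm < {min_gap:.2f} mm)")
        return self

    def moved(self, configuration) -> "SpineGeometry":
        """Geometry after applying a solver configuration to the spine bodies.

        The configuration's first ``len(bodies)`` entries must correspond to
        T1..L5 then the pelvis (extra bodies, e.g. rod nodes, are ignored).
        """
        state = configuration.to_state()
        out = []
        for i, v in enumerate(self.bodies):
            dR = state.R[i]
            pos = v.position + state.u[i]
            out.append(VertebraGeometry(v.level, pos, dR @ v.rotation,
                                        v.landmarks, v.dims))
        return SpineGeometry(out[:-1], out[-1])

    def mirrored(self) -> "SpineGeometry":
        """Coronal mirror image (y -> -y), with left/right landmarks swapped."""
        M = np.diag([1.0, -1.0, 1.0])

        def flip(v):
            lms = {_swap_side(k): M @ p for k, p in v.landmarks.items()}
            return VertebraGeometry(v.level, M @ v.position,
                                    M @ v.rotation @ M, lms, v.dims)

        vs = [flip(v) for v in self.vertebrae]
        return SpineGeometry(vs, flip(self.pelvis))

    # -- serialization ----------------------------------------------------
    def to_json(self, path=None) -> str:
        doc = {"coordinate_convention":
               "right-handed; x anterior, y patient-left, z cephalad; mm",
               "bodies": []}
        for v in self.bodies:
            doc["bodies"].append({
                "level": v.level,
                "position_mm": v.position.tolist(),
                "rotation_matrix": v.rotation.tolist(),
                "dims_mm": list(v.dims),
                "landmarks_local_mm": {k: p.tolist()
                                       for k, p in v.landmarks.items()},
            })
        text = json.dumps(doc, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, text_or_path) -> "SpineGeometry":
        if "\n" not in str(text_or_path) and str(text_or_path).endswith(".json"):
            with open(text_or_path) as fh:
                doc = json.load(fh)
        else:
            doc = json.loads(text_or_path)
        bodies = []
        for b in doc["bodies"]:
            bodies.append(VertebraGeometry(
                b["level"], np.asarray(b["position_mm"]),
                np.asarray(b["rotation_matrix"]),
                {k: np.asarray(p) for k, p in b["landmarks_local_mm"].items()},
                tuple(b["dims_mm"])))
        return cls(bodies[:-1], bodies[-1])

    def to_obj(self, path):
        """Wavefront-OBJ point cloud of all world landmarks (visualization)."""
        with open(path, "w") as fh:
            for v in self.bodies:
                for name in v.landmarks:
                    p = v.world(name)
                    fh.write(f"v {p[0]:.3f} {p[1]:.3f} {p[2]:.3f}\n")


def _swap_side(name: str) -> str:
    if name.endswith("_l") or "_l_" in name:
        return name.replace("_l_", "_r_") if "_l_" in name else name[:-2] + "_r"
    if name.endswith("_r") or "_r_" in name:
        return name.replace("_r_", "_l_") if "_r_" in name else name[:-2] + "_l"
    if name.endswith("al") or name.endswith("pl"):
        return name[:-1] + "r"
    if name.endswith("ar") or name.endswith("pr"):
        return name[:-1] + "l"
    return name
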