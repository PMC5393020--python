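"""Flexible multibody model of the spine.

Each functional spinal unit (FSU — two adjacent vertebrae and their
connecting soft tissue) is modeled with:

* six tension-only cables for the ligaments: anterior and posterior
  longitudinal ligaments (ALL, PLL), ligamentum flavum (LF), left and right
  intertransverse ligaments (ITL), and the interspinous + supraspinous
  ligaments combined (ISL_SSL).  Cable stiffness in compression is exactly
  zero; traction stiffnesses at the T6-T7 reference unit are the cadaveric
  values 23.6 (ALL), 24.9 (PLL), 32.6 (LF), 12.9 (ITL each side) and
  32.1 N/mm (ISL+SSL), scaled at other levels by the vertebral-body depth
  ratio (a proxy for ligament cross-section).
* two six-dimensional general springs for the left/right facet joint
  capsules, and
* one primary six-dimensional general spring for the intervertebral disc,
  which also absorbs every effect not explicitly modeled.  In particular the
  rib cage stiffens thoracic units by 40 / 35 / 31 % in flexion-extension /
  lateral bending / axial rotation; these weighting factors enter the
  calibrated diagonal of the primary spring so the assembled FSU stiffens by
  exactly those ratios.

Pedicle-screw placement surgery removes the facet capsules and the
interspinous elements; :func:`apply_surgical_release` performs that removal,
and the calibration module apportions element stiffnesses so the removal
reduces FSU stiffness by 17 % (axial rotation), 15 % (flexion), 3.8 %
(coronal bending) and 14 % (axial compression).

Elements are assembled force-free in the input (preoperative) geometry.
"""
from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np

from . import levels, solver
from .geometry import SpineGeometry, VertebraGeometry, vertebra_landmarks
from .synthetic import (DEFAULT_DIMENSIONS_MM, DISC_HEIGHT_FRACTION,
                        REFERENCE_HEIGHT_CM, vertebral_dimensions)

__all__ = [
    "CableElement", "GeneralSpring6D", "StiffnessParams", "MultibodyModel",
    "default_stiffness_params", "cable_force", "assemble_model",
    "apply_surgical_release", "fsu_stiffness", "canonical_fsu_model",
    "CABLE_NAMES", "RELEASED_ELEMENTS", "PROBE_MODES",
]

CABLE_NAMES = ["ALL", "PLL", "LF", "ITL_left", "ITL_right", "ISL_SSL"]
SPRING_NAMES = ["facet_left", "facet_right", "primary_disc"]
#: elements removed by the pedicle-screw placement release
RELEASED_ELEMENTS = {"facet_left", "facet_right", "ISL_SSL"}

#: printed reference cable traction stiffnesses, T6-T7 unit, N/mm
REFERENCE_CABLE_K = {"ALL": 23.6, "PLL": 24.9, "LF": 32.6,
                     "ITL_left": 12.9, "ITL_right": 12.9, "ISL_SSL": 32.1}

#: rib-cage weighting of thoracic FSU stiffness per rotational mode
RIBCAGE_WEIGHTS = {"ry": 1.40, "rx": 1.35, "rz": 1.31}

#: FSU stiffness reduction targets of the surgical release
RELEASE_REDUCTIONS = {"axial_rotation": 0.17, "flexion": 0.15,
                      "lateral_bending": 0.038, "axial_compression": 0.14}

#: small-displacement probe magnitudes for secant FSU stiffness
PROBE_ROT_DEG = 0.5
PROBE_TRANS_MM = 0.5

_DIAG_KEYS = ["tx", "ty", "tz", "rx", "ry", "rz"]

#: probe direction per mode: (kind, axis)
PROBE_MODES = {
    "flexion": ("rot", np.array([0.0, 1.0, 0.0])),
    "extension": ("rot", np.array([0.0, -1.0, 0.0])),
    "lateral_bending": ("rot", np.array([1.0, 0.0, 0.0])),
    "axial_rotation": ("rot", np.array([0.0, 0.0, 1.0])),
    "axial_compression": ("trans", np.array([0.0, 0.0, -1.0])),
    "shear_ap": ("trans", np.array([1.0, 0.0, 0.0])),
    "shear_lat": ("trans", np.array([0.0, 1.0, 0.0])),
}
#: primary-spring diagonal entry controlling each calibrated mode
MODE_DIAG = {"flexion": "ry", "extension": "ry", "lateral_bending": "rx",
             "axial_rotation": "rz", "axial_compression": "tz",
             "shear_ap": "tx", "shear_lat": "ty"}


def fsu_labels() -> list:
    """FSU ids named after the upper vertebra: 'T1' = T1-T2 ... 'L5' = L5-pelvis."""
    return levels.VERTEBRAE[:]


def is_thoracic_fsu(fsu: str) -> bool:
    """FSUs between two thoracic vertebrae carry the rib-cage weighting."""
    return fsu in levels.THORACIC[:-1]


@dataclass
class CableElement:
    """Tension-only translational spring between two vertebral attachments."""

    name: str
    fsu: str
    body_a: str
    body_b: str
    attach_a: np.ndarray            # world offset from body-a reference, mm
    attach_b: np.ndarray
    stiffness: float                # N/mm, traction only
    rest_length: float              # mm


@dataclass
class GeneralSpring6D:
    """Six-dimensional diagonal spring between two attachment frames."""

    role: str                       # facet_left / facet_right / primary_disc
    fsu: str
    body_a: str
    body_b: str
    attach_a: np.ndarray
    attach_b: np.ndarray
    frame: np.ndarray               # (3,3) element axes at assembly
    diag: np.ndarray                # (6,) [tx,ty,tz] N/mm, [rx,ry,rz] N·mm/deg

    @property
    def matrix(self) -> np.ndarray:
        """Full 6x6 stiffness matrix (diagonal, hence symmetric PSD)."""
        return np.diag(self.diag)


def cable_force(element: CableElement, length: float) -> float:
    """Tension (N) at the given cable length: max(0, k * (L - L0))."""
    if length <= 0:
        raise ValueError("cable length must be positive")
    return max(0.0, element.stiffness * (length - element.rest_length))


@dataclass
class StiffnessParams:
    """Every stiffness the model uses, per FSU; round-trips through YAML."""

    cable_k: dict                   # fsu -> {name: N/mm}
    primary_diag: dict              # fsu -> (6,) array
    facet_diag: dict                # fsu -> (6,) array
    level_scale: dict               # fsu -> unitless depth-ratio scale
    ribcage_weights: dict = field(default_factory=lambda: dict(RIBCAGE_WEIGHTS))
    release_reductions: dict = field(
        default_factory=lambda: dict(RELEASE_REDUCTIONS))

    def copy(self) -> "StiffnessParams":
        return copy.deepcopy(self)

    def validate(self):
        for fsu, tab in self.cable_k.items():
            for name, k in tab.items():
                if k < 0:
                    raise ValueError(f"negative cable stiffness {fsu}/{name}")
        for d in (self.primary_diag, self.facet_diag):
            for fsu, diag in d.items():
                if np.any(np.asarray(diag) < 0):
                    raise ValueError(f"negative 6-D spring diagonal at {fsu}")
        for mode, r in self.release_reductions.items():
            if not 0.0 < r < 1.0:
                raise ValueError(f"release reduction {mode} outside (0,1)")
        return self

    # -- flat config round trip (units in key names) ----------------------
    def to_flat(self) -> dict:
        flat = {}
        for fsu in self.cable_k:
            for name, k in self.cable_k[fsu].items():
                flat[f"cable.{fsu}.{name}.N_per_mm"] = float(k)
            for i, key in enumerate(_DIAG_KEYS):
                unit = "N_per_mm" if i < 3 else "Nmm_per_deg"
                flat[f"primary.{fsu}.{key}.{unit}"] = float(
                    self.primary_diag[fsu][i])
                flat[f"facet.{fsu}.{key}.{unit}"] = float(
                    self.facet_diag[fsu][i])
            flat[f"level_scale.{fsu}"] = float(self.level_scale[fsu])
        for k, v in self.ribcage_weights.items():
            flat[f"ribcage_weight.{k}"] = float(v)
        for k, v in self.release_reductions.items():
            flat[f"release_reduction.{k}"] = float(v)
        return flat

    @classmethod
    def from_flat(cls, flat: dict) -> "StiffnessParams":
        out = default_stiffness_params()
        for key, val in flat.items():
            parts = key.split(".")
            if parts[0] == "cable":
                out.cable_k[parts[1]][parts[2]] = float(val)
            elif parts[0] in ("primary", "facet"):
                d = out.primary_diag if parts[0] == "primary" else out.facet_diag
                d[parts[1]][_DIAG_KEYS.index(parts[2])] = float(val)
            elif parts[0] == "level_scale":
                out.level_scale[parts[1]] = float(val)
            elif parts[0] == "ribcage_weight":
                out.ribcage_weights[parts[1]] = float(val)
            elif parts[0] == "release_reduction":
                out.release_reductions[parts[1]] = float(val)
            else:
                raise ValueError(f"unknown stiffness config key: {key}")
        return out


def _depth(level: str) -> float:
    return DEFAULT_DIMENSIONS_MM.get(level, DEFAULT_DIMENSIONS_MM["L5"])[1]


def default_stiffness_params() -> StiffnessParams:
    """Shipped defaults: printed T6-T7 cable values, depth-ratio level
    scaling, and pre-calibration 6-D spring diagonals (the calibration
    module replaces the latter)."""
    ref_depth = 0.5 * (_depth("T6") + _depth("T7"))
    cable_k, primary, facet, scale = {}, {}, {}, {}
    for fsu in fsu_labels():
        lower = levels.ALL_BODIES[levels.index_of(fsu) + 1]
        d = 0.5 * (_depth(fsu) + _depth(lower if lower != levels.PELVIS
                                        else "L5"))
        s = d / ref_depth
        scale[fsu] = s
        cable_k[fsu] = {name: k * s for name, k in REFERENCE_CABLE_K.items()}
        primary[fsu] = np.array([400.0, 400.0, 800.0,
                                 3000.0, 3000.0, 3000.0]) * s
        facet[fsu] = np.array([20.0, 20.0, 70.0, 20.0, 60.0, 300.0]) * s
    return StiffnessParams(cable_k, primary, facet, scale)


# ---------------------------------------------------------------------------
# model assembly


@dataclass
class MultibodyModel:
    """Rigid bodies + flexible elements + boundary conditions."""

    geometry: SpineGeometry
    params: StiffnessParams
    body_labels: list
    cables: list                     # of CableElement
    springs: list                    # of GeneralSpring6D
    fixed: np.ndarray                # (n, 6) bool
    released: set = field(default_factory=set)
    fsu_scale: dict = field(default_factory=dict)   # patient-calibration scales

    def body_index(self, label: str) -> int:
        return self.body_labels.index(label.upper())

    @property
    def n_bodies(self):
        return len(self.body_labels)

    def copy(self) -> "MultibodyModel":
        m = copy.copy(self)
        m.cables = list(self.cables)
        m.springs = list(self.springs)
        m.fixed = self.fixed.copy()
        m.released = set(self.released)
        m.fsu_scale = dict(self.fsu_scale)
        return m

    def scaled(self, factors: dict) -> "MultibodyModel":
        """Copy with per-FSU stiffness multipliers (patient calibration)."""
        m = self.copy()
        m.fsu_scale = {**self.fsu_scale}
        for fsu, s in factors.items():
            m.fsu_scale[fsu] = m.fsu_scale.get(fsu, 1.0) * float(s)
        return m

    def elements_of(self, fsu: str) -> list:
        return ([c for c in self.cables if c.fsu == fsu]
                + [s for s in self.springs if s.fsu == fsu])

    def fix_body(self, label: str, dofs=None):
        dofs = slice(None) if dofs is None else dofs
        self.fixed[self.body_index(label), dofs] = True

    def free_body(self, label: str):
        self.fixed[self.body_index(label), :] = False

    def build_system(self) -> solver.System:
        x0 = np.array([b.position for b in self.geometry.bodies
                       ])[:len(self.body_labels)]
        idx = {lab: i for i, lab in enumerate(self.body_labels)}

        m = len(self.cables)
        cb = np.zeros((m, 2), dtype=int)
        coff = np.zeros((m, 2, 3))
        ck = np.zeros(m)
        cL0 = np.zeros(m)
        for e, c in enumerate(self.cables):
            cb[e] = idx[c.body_a], idx[c.body_b]
            coff[e, 0], coff[e, 1] = c.attach_a, c.attach_b
            ck[e] = c.stiffness * self.fsu_scale.get(c.fsu, 1.0)
            cL0[e] = c.rest_length

        s = len(self.springs)
        sb = np.zeros((s, 2), dtype=int)
        soff = np.zeros((s, 2, 3))
        sE0 = np.zeros((s, 3, 3))
        sKt = np.zeros((s, 3))
        sKr = np.zeros((s, 3))
        sdt0 = np.zeros((s, 3))
        for e, sp in enumerate(self.springs):
            sb[e] = idx[sp.body_a], idx[sp.body_b]
            soff[e, 0], soff[e, 1] = sp.attach_a, sp.attach_b
            sE0[e] = sp.frame
            # patient-calibration factors represent coronal-plane bending
            # flexibility: they scale the coronal rotational stiffness and
            # the ligament cables only; sagittal/axial rotational terms and
            # all translational disc/facet stiffness stay anatomical
            sc = self.fsu_scale.get(sp.fsu, 1.0)
            sKt[e] = sp.diag[:3]
            kr = sp.diag[3:].copy()
            kr[0] *= sc
            sKr[e] = kr * (180.0 / np.pi)                  # N·mm/deg -> /rad
            pa = x0[sb[e, 0]] + sp.attach_a
            pb = x0[sb[e, 1]] + sp.attach_b
            sdt0[e] = sp.frame.T @ (pb - pa)
        return solver.System(x0=x0, fixed=self.fixed.copy(),
                             cab_bodies=cb, cab_off=coff, cab_k=ck,
                             cab_L0=cL0,
                             spr_bodies=sb, spr_off=soff, spr_E0=sE0,
                             spr_Kt=sKt, spr_Kr=sKr, spr_dt0=sdt0)

    def zero_loads(self) -> np.ndarray:
        return np.zeros((self.n_bodies, 6))

    def to_json(self, path=None) -> str:
        """Model summary: every element with attachments and stiffness."""
        import json
        elements = []
        for c in self.cables:
            elements.append({
                "kind": "cable", "name": c.name, "fsu": c.fsu,
                "bodies": [c.body_a, c.body_b],
                "attach_offsets_mm": [c.attach_a.tolist(),
                                      c.attach_b.tolist()],
                "stiffness_N_per_mm": c.stiffness,
                "rest_length_mm": c.rest_length,
            })
        for s in self.springs:
            elements.append({
                "kind": "spring6d", "role": s.role, "fsu": s.fsu,
                "bodies": [s.body_a, s.body_b],
                "attach_offsets_mm": [s.attach_a.tolist(),
                                      s.attach_b.tolist()],
                "diag_N_per_mm_and_Nmm_per_deg": s.diag.tolist(),
            })
        doc = {"bodies": self.body_labels,
               "released_fsus": sorted(self.released),
               "fsu_scale_factors": dict(self.fsu_scale),
               "elements": elements}
        text = json.dumps(doc, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _world_attach(v: VertebraGeometry, name: str) -> np.ndarray:
    """World-frame offset of a landmark from the body reference point."""
    return v.world(name) - v.position


def _fsu_elements(upper: VertebraGeometry, lower: VertebraGeometry,
                  fsu: str, params: StiffnessParams):
    """Six cables + two facet springs + one primary spring for one FSU."""

    def mk_cable(name, lm_u, lm_l):
        a = _world_attach(upper, lm_u)
        b = _world_attach(lower, lm_l)
        L0 = float(np.linalg.norm((lower.position + b) - (upper.position + a)))
        return CableElement(name, fsu, upper.level, lower.level, a, b,
                            params.cable_k[fsu][name], L0)

    cables = [
        mk_cable("ALL", "att_all_inf", "att_all_sup"),
        mk_cable("PLL", "att_pll_inf", "att_pll_sup"),
        mk_cable("LF", "att_lf_inf", "att_lf_sup"),
        mk_cable("ITL_left", "transverse_l", "transverse_l"),
        mk_cable("ITL_right", "transverse_r", "transverse_r"),
        mk_cable("ISL_SSL", "att_isl_inf", "att_isl_sup"),
    ]

    frame = upper.rotation.copy()      # element axes follow the upper vertebra

    def mk_spring(role, lm_u, lm_l, diag):
        return GeneralSpring6D(role, fsu, upper.level, lower.level,
                               _world_attach(upper, lm_u),
                               _world_attach(lower, lm_l),
                               frame, np.asarray(diag, float))

    # the primary (disc) spring acts at the disc center: both attachments
    # coincide there, so pure relative rotation about the disc center costs
    # no translational energy (clean mode separation for calibration)
    disc_c = 0.5 * (upper.world("inf_center") + lower.world("sup_center"))
    springs = [
        mk_spring("facet_left", "att_facet_l_inf", "att_facet_l_sup",
                  params.facet_diag[fsu]),
        mk_spring("facet_right", "att_facet_r_inf", "att_facet_r_sup",
                  params.facet_diag[fsu]),
        GeneralSpring6D("primary_disc", fsu, upper.level, lower.level,
                        disc_c - upper.position, disc_c - lower.position,
                        frame, np.asarray(params.primary_diag[fsu], float)),
    ]
    return cables, springs


def assemble_model(geometry: SpineGeometry,
                   params: StiffnessParams | None = None) -> MultibodyModel:
    """Assemble the intact multibody model; every element force-free in the
    input configuration; pelvis fixed."""
    params = (params or default_stiffness_params()).validate()
    bodies = geometry.bodies
    labels = [b.level for b in bodies]
    cables, springs = [], []
    for upper, lower in zip(bodies, bodies[1:]):
        fsu = upper.level
        cs, ss = _fsu_elements(upper, lower, fsu, params)
        cables.extend(cs)
        springs.extend(ss)
    fixed = np.zeros((len(labels), 6), dtype=bool)
    model = MultibodyModel(geometry, params, labels, cables, springs, fixed)
    model.fix_body(levels.PELVIS)
    return model


def apply_surgical_release(model: MultibodyModel, release_levels) -> MultibodyModel:
    """Remove facet capsules and interspinous elements at the given FSUs.

    ``release_levels``: iterable of FSU ids, either the upper vertebra label
    ('T6') or the pair form ('T6-T7').  Other elements are untouched.
    """
    norm = set()
    for lab in release_levels:
        fsu = str(lab).split("-")[0].upper()
        if fsu not in fsu_labels():
            raise ValueError(f"unknown FSU label for release: {lab!r}")
        norm.add(fsu)
    m = model.copy()
    m.cables = [c for c in m.cables
                if not (c.fsu in norm and c.name in RELEASED_ELEMENTS)]
    m.springs = [s for s in m.springs
                 if not (s.fsu in norm and s.role in RELEASED_ELEMENTS)]
    m.released = model.released | norm
    return m


# ---------------------------------------------------------------------------
# FSU stiffness probing


def _fsu_submodel(model: MultibodyModel, fsu: str) -> MultibodyModel:
    if fsu not in fsu_labels():
        raise ValueError(f"invalid FSU level: {fsu!r}")
    upper = fsu
    lower = levels.ALL_BODIES[levels.index_of(fsu) + 1]
    g = model.geometry
    sub_geom = SpineGeometry([g[upper]], g[lower])
    fixed = np.zeros((2, 6), dtype=bool)
    fixed[1, :] = True
    sub = MultibodyModel(sub_geom, model.params, [upper, lower],
                         [c for c in model.cables if c.fsu == fsu],
                         [s for s in model.springs if s.fsu == fsu],
                         fixed, model.released & {fsu},
                         {fsu: model.fsu_scale.get(fsu, 1.0)})
    return sub


def disc_center(model: MultibodyModel, fsu: str) -> np.ndarray:
    upper = model.geometry[fsu]
    lower = model.geometry[levels.ALL_BODIES[levels.index_of(fsu) + 1]]
    return 0.5 * (upper.world("inf_center") + lower.world("sup_center"))


def fsu_stiffness(model: MultibodyModel, fsu: str, mode: str,
                  rot_deg: float = PROBE_ROT_DEG,
                  trans_mm: float = PROBE_TRANS_MM) -> float:
    """Secant FSU stiffness from a small displacement-controlled probe.

    The lower vertebra is held, the upper is rigidly displaced about the
    disc center along the mode direction, and the holding generalized force
    gives the stiffness (N/mm for translation modes, N·mm/deg for rotation
    modes).
    """
    try:
        kind, axis = PROBE_MODES[mode]
    except KeyError:
        raise ValueError(f"unknown FSU probe mode: {mode!r}") from None
    sub = _fsu_submodel(model, fsu)
    system = sub.build_system()
    state = solver.State.rest(system)
    c = disc_center(model, fsu)
    x_ref = system.x0[0]
    if kind == "rot":
        from scipy.spatial.transform import Rotation
        Rd = Rotation.from_rotvec(np.radians(rot_deg) * axis).as_matrix()
        state.R[0] = Rd
        state.u[0] = (Rd - np.eye(3)) @ (x_ref - c)
        res = solver.residual(system, state)[0]
        F, M = res[:3], res[3:]
        M_c = M + np.cross(x_ref + state.u[0] - c, F)
        return float(-(M_c @ axis) / rot_deg)
    state.u[0] = trans_mm * axis
    res = solver.residual(system, state)[0]
    return float(-(res[:3] @ axis) / trans_mm)


def canonical_fsu_model(fsu: str, params: StiffnessParams | None = None,
                        height: float = REFERENCE_HEIGHT_CM) -> MultibodyModel:
    """Two-vertebra straight-spine FSU model at the default dimensions —
    the reference configuration used by FSU-level calibration."""
    params = params or default_stiffness_params()
    upper_lab = fsu
    lower_lab = levels.ALL_BODIES[levels.index_of(fsu) + 1]
    dims_u = vertebral_dimensions(upper_lab, height)
    dims_l = vertebral_dimensions(lower_lab, height)
    disc = DISC_HEIGHT_FRACTION * 0.5 * (dims_u[2] + dims_l[2])
    zl = -(0.5 * dims_u[2] + disc + 0.5 * dims_l[2])
    upper = VertebraGeometry(upper_lab, np.zeros(3), np.eye(3),
                             vertebra_landmarks(*dims_u), dims_u)
    lower = VertebraGeometry(lower_lab, np.array([0.0, 0.0, zl]), np.eye(3),
                             vertebra_landmarks(*dims_l), dims_l)
    geom = SpineGeometry([upper], lower)
    cables, springs = _fsu_elements(upper, lower, fsu, params)
    fixed = np.zeros((2, 6), dtype=bool)
    fixed[1, :] = True
    return MultibodyModel(geom, params, [upper_lab, lower_lab],
                          cables, springs, fixed)
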