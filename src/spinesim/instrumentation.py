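"""Pedicle-screw constructs and the segmental-translation correction maneuver.

**Screw patterns.**  Five patterns per case: a reference pattern with
bilateral polyaxial screws at every fused level, and four alternatives with
~23 % fewer screws.  Dropouts are unilateral — on the convex or concave side
— either at alternate levels (starting one level caudal to the upper
instrumented vertebra, every other level, possibly reaching the lower
instrumented vertebra) or at consecutive periapical levels (the same number
of dropouts as the alternate patterns, centered on the apical vertebra).
The upper instrumented vertebra always keeps both screws.

**Rods.**  5.5 mm cobalt-chrome rods, sagittally contoured: 25 deg over the
thoracic segment for the convex rod, 35 deg for the concave rod, with a
lumbar counter-bend.  Mechanically each rod is a chain of rigid nodes
joined by 6-D beam springs with slender-beam stiffnesses (EA/L, EI/L,
GJ/L); a rigid-rod toggle simply scales these up.

**Maneuver.**  Simultaneous two-rod segmental translation: every screw is
drawn toward its rod by a stiff bilateral connector whose rest length ramps
from the initial screw-rod gap down to the locked head standoff over an
incremental schedule, equilibrating at every step (polyaxial heads transmit
no moment; dorsal height adjustability is the ramped standoff).  At the end
of the ramp the construct is locked: the final equilibrium is the locked
state and the bone-screw force is the connector reaction transmitted at
each anchor.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import levels, metrics, solver
from . import model as md
from .indices import ClinicalIndices

__all__ = [
    "ScrewDef", "ScrewPattern", "RodDef", "SimulationResult",
    "make_pattern", "patterns_for_case", "reduction_stats", "contour_rod",
    "default_rods", "simulate_segmental_translation", "bone_screw_forces",
    "convex_side_of",
]

PATTERN_NAMES = {1: "reference (bilateral all levels)",
                 2: "convex alternate dropouts",
                 3: "concave alternate dropouts",
                 4: "convex periapical dropouts",
                 5: "concave periapical dropouts"}

THORACIC_SCREW_DIAMETER = 5.0       # mm, within the 4.5-5.5 range
LUMBAR_SCREW_DIAMETER = 5.5         # mm, within the 5.5-6.0 range

ROD_DIAMETER_MM = 5.5
ROD_E_MPA = 230e3                    # cobalt-chrome elastic modulus, N/mm^2
ROD_G_MPA = 88e3
ROD_NODE_SPACING_MM = 15.0
CONVEX_ROD_CONTOUR_DEG = 25.0
CONCAVE_ROD_CONTOUR_DEG = 35.0
LUMBAR_CONTOUR_DEG = 20.0

CONNECTOR_K_N_MM = 800.0             # screw-rod penalty stiffness (ramp)
CONNECTOR_K_LOCKED_N_MM = 3000.0     # after locking
#: locked ball-to-rod-axis distance (the dorsal screw-head height at lock)
HEAD_STANDOFF_MM = 15.0
#: dorsal offset of the polyaxial ball joint from the pedicle entry point
BALL_OFFSET_MM = 3.0
#: polyaxial cone half-angle: the rod may approach the head from any
#: direction within this angle of the screw shank axis without force.
#: None disables the clamp (fully free approach direction).
POLYAXIAL_CONE_DEG = 25.0
#: rotational stiffness of a locked (set-screw tightened) saddle, N·mm/rad
LOCKED_KR_NMM_RAD = 5.0e4
GAP_TOL_MM = 0.1
#: cap on beam translational stiffness entries (N/mm): rod axial/shear
#: compliance is mechanically irrelevant here and capping improves the
#: conditioning of the Newton tangent
BEAM_KT_CAP_N_MM = 2.0e4


@dataclass
class ScrewDef:
    """One polyaxial pedicle screw with dorsal height adjustability."""

    level: str
    side: str                        # 'left' / 'right'
    diameter: float
    anchor_landmark: str = ""        # pedicle entry landmark name

    def __post_init__(self):
        if not self.anchor_landmark:
            self.anchor_landmark = ("pedicle_l" if self.side == "left"
                                    else "pedicle_r")
        lo, hi = ((4.5, 5.5) if levels.is_thoracic(self.level)
                  else (5.5, 6.0))
        if not lo <= self.diameter <= hi:
            raise ValueError(
                f"screw diameter {self.diameter} mm outside [{lo}, {hi}] "
                f"for level {self.level}")


@dataclass
class ScrewPattern:
    pattern_id: int
    screws: list                      # of ScrewDef
    fused: list                       # level labels, UIV..LIV
    dropouts: list                    # of (level, side)
    convex_side: str

    @property
    def n_screws(self) -> int:
        return len(self.screws)

    @property
    def reference_count(self) -> int:
        return 2 * len(self.fused)

    @property
    def reduction_pct(self) -> float:
        return 100.0 * len(self.dropouts) / self.reference_count

    @property
    def density(self) -> float:
        """Screws per fused level (2.0 = bilateral everywhere)."""
        return self.n_screws / len(self.fused)


def make_pattern(fused, apex: str, convex_side: str, pattern_id: int,
                 allow_liv_dropout: bool = True) -> ScrewPattern:
    """Build one of the five screw patterns for a fusion segment.

    ``fused`` must be a contiguous cephalad-to-caudal level list with the
    apex strictly interior; at least 4 levels.
    """
    fused = [str(x).upper() for x in fused]
    if fused != levels.span(fused[0], fused[-1]):
        raise ValueError("fused levels must be contiguous, cephalad first")
    n = len(fused)
    if n < 4:
        raise ValueError(f"fewer than 4 fused levels ({n})")
    apex = apex.upper()
    if apex not in fused[1:-1]:
        raise ValueError(f"apex {apex} not strictly interior to the fusion "
                         f"{fused[0]}-{fused[-1]}")
    if convex_side not in ("left", "right"):
        raise ValueError(f"convex_side must be 'left'/'right': {convex_side!r}")
    if pattern_id not in PATTERN_NAMES:
        raise ValueError(f"pattern_id must be 1..5, got {pattern_id}")

    stop = n if allow_liv_dropout else n - 1
    alternate = list(range(1, stop, 2))
    d = len(alternate)
    if pattern_id in (4, 5):
        start = fused.index(apex) - (d - 1) // 2
        start = max(1, min(start, stop - d))
        drop_idx = list(range(start, start + d))
    elif pattern_id in (2, 3):
        drop_idx = alternate
    else:
        drop_idx = []
    concave = "left" if convex_side == "right" else "right"
    drop_side = (convex_side if pattern_id in (2, 4) else concave)
    dropouts = [(fused[i], drop_side) for i in drop_idx]

    screws = []
    for lab in fused:
        for side in ("left", "right"):
            if (lab, side) in dropouts:
                continue
            dia = (THORACIC_SCREW_DIAMETER if levels.is_thoracic(lab)
                   else LUMBAR_SCREW_DIAMETER)
            screws.append(ScrewDef(lab, side, dia))
    return ScrewPattern(pattern_id, screws, fused, dropouts, convex_side)


def convex_side_of(geometry, indices: ClinicalIndices) -> str:
    """Convex side of the MT curve from the apex's lateral deviation sign
    (y > 0 is the patient's left)."""
    apex = geometry[indices.mt_apex].position
    ends = 0.5 * (geometry[indices.mt_sup_end].position
                  + geometry[indices.mt_inf_end].position)
    return "left" if (apex[1] - ends[1]) > 0 else "right"


def patterns_for_case(indices: ClinicalIndices, geometry=None,
                      pattern_ids=(1, 2, 3, 4, 5), **kw) -> dict:
    convex = (convex_side_of(geometry, indices) if geometry is not None
              else indices.mt_convexity)
    fused = indices.fused_levels
    return {pid: make_pattern(fused, indices.mt_apex, convex, pid, **kw)
            for pid in pattern_ids}


def reduction_stats(patterns_by_case: dict):
    """Per-construct reductions/densities and overall summary.

    ``patterns_by_case``: {case_id: {pattern_id: ScrewPattern}}.
    Returns (pandas.DataFrame, summary dict).
    """
    import pandas as pd
    rows = []
    for case_id, pats in patterns_by_case.items():
        for pid, pat in sorted(pats.items()):
            rows.append({"case_id": case_id, "pattern": pid,
                         "n_screws": pat.n_screws,
                         "n_dropped": len(pat.dropouts),
                         "reduction_pct": pat.reduction_pct,
                         "density": pat.density})
    df = pd.DataFrame(rows)
    alt = df[df["pattern"] > 1]
    summary = {
        "mean_reduction_pct": float(alt["reduction_pct"].mean()) if len(alt) else 0.0,
        "min_reduction_pct": float(alt["reduction_pct"].min()) if len(alt) else 0.0,
        "max_reduction_pct": float(alt["reduction_pct"].max()) if len(alt) else 0.0,
        "n_alternative_constructs": int(len(alt)),
    }
    return df, summary


# ---------------------------------------------------------------------------
# rods


@dataclass
class RodDef:
    """Discretized planar-contoured rod."""

    side: str                        # 'left' / 'right' (placement side)
    role: str                        # 'convex' / 'concave'
    diameter: float
    contour_angle: float             # deg over the thoracic segment
    lumbar_angle: float
    node_spacing: float
    s: np.ndarray                    # (k,) arc length, mm
    xi: np.ndarray                   # (k,) sagittal bow (anterior +), mm
    tangent_deg: np.ndarray          # (k,) tangent angle vs chord
    thoracic_span: tuple             # (s_start, s_end) of the thoracic part
    elastic_modulus: float = ROD_E_MPA
    shear_modulus: float = ROD_G_MPA
    rigid: bool = False

    @property
    def length(self) -> float:
        return float(self.s[-1])

    @property
    def n_nodes(self) -> int:
        return len(self.s)

    def measured_contour(self) -> float:
        """Tangent subtension (deg) across the thoracic span (whose ends are
        grid nodes by construction)."""
        i0 = int(np.argmin(np.abs(self.s - self.thoracic_span[0])))
        i1 = int(np.argmin(np.abs(self.s - self.thoracic_span[1])))
        return float(abs(self.tangent_deg[i1] - self.tangent_deg[i0]))

    def bow_depth(self) -> float:
        return float(np.max(np.abs(self.xi)))

    def section_stiffness(self):
        """(EA, EI, GJ) of the rod cross-section; large if rigid."""
        r = self.diameter / 2.0
        A = math.pi * r**2
        I = math.pi * r**4 / 4.0
        J = 2.0 * I
        f = 1e3 if self.rigid else 1.0
        return (f * self.elastic_modulus * A, f * self.elastic_modulus * I,
                f * self.shear_modulus * J)


def contour_rod(side: str, geometry, contour_angle: float,
                uiv: str, liv: str, lumbar_angle: float = LUMBAR_CONTOUR_DEG,
                node_spacing: float = ROD_NODE_SPACING_MM,
                margin: float = 12.0, role: str | None = None,
                rigid: bool = False) -> RodDef:
    """Planar sagittal rod whose thoracic tangents subtend ``contour_angle``.

    The rod covers the UIV..LIV chord plus a margin at both ends; the
    kyphotic (posterior-bulge) arc spans the thoracic fraction of the
    instrumented segment and the lordotic counter-bend the lumbar fraction.
    """
    fused = levels.span(uiv, liv)
    chord = float(np.linalg.norm(geometry[liv].position
                                 - geometry[uiv].position))
    # the rod must cover the posterior arc-length of the instrumented
    # segment (longer than the chord on a curved spine)
    lm = "pedicle_l" if side == "left" else "pedicle_r"
    pts = [geometry[l].world(lm) for l in fused]
    arc = float(sum(np.linalg.norm(b - a) for a, b in zip(pts, pts[1:])))
    length = max(chord, arc) + 2 * margin
    n_thor = sum(levels.is_thoracic(l) for l in fused)
    frac_t = n_thor / len(fused)
    Lt = max(frac_t * length, node_spacing)
    Ll = length - Lt

    k = max(int(round(length / node_spacing)) + 1, 4)
    s = np.unique(np.round(np.concatenate([np.linspace(0.0, length, k),
                                           [Lt]]), 9))
    kappa_t = math.radians(contour_angle) / Lt
    kappa_l = (math.radians(lumbar_angle) / Ll) if Ll > node_spacing else 0.0
    # tangent angle (rad) vs chord; kyphotic arc then lordotic counter-bend
    tau = np.where(
        s <= Lt,
        -0.5 * math.radians(contour_angle) + kappa_t * s,
        0.5 * math.radians(contour_angle) - kappa_l * (s - Lt))
    xi = np.concatenate([[0.0], np.cumsum(
        0.5 * (np.tan(tau[1:]) + np.tan(tau[:-1])) * np.diff(s))])
    # bow measured anterior-positive: the kyphotic arc bulges posterior
    return RodDef(side=side, role=role or "convex", diameter=ROD_DIAMETER_MM,
                  contour_angle=contour_angle, lumbar_angle=lumbar_angle,
                  node_spacing=node_spacing, s=s, xi=xi,
                  tangent_deg=np.degrees(tau),
                  thoracic_span=(0.0, Lt), rigid=rigid)


def default_rods(geometry, indices: ClinicalIndices,
                 convex_contour: float = CONVEX_ROD_CONTOUR_DEG,
                 concave_contour: float = CONCAVE_ROD_CONTOUR_DEG,
                 rigid: bool = False, **kw) -> list:
    """The two contoured rods of a case: convex 25 deg, concave 35 deg."""
    convex = convex_side_of(geometry, indices)
    concave = "left" if convex == "right" else "right"
    return [
        contour_rod(convex, geometry, convex_contour, indices.uiv,
                    indices.liv, role="convex", rigid=rigid, **kw),
        contour_rod(concave, geometry, concave_contour, indices.uiv,
                    indices.liv, role="concave", rigid=rigid, **kw),
    ]


# ---------------------------------------------------------------------------
# segmental translation


@dataclass
class SimulationResult:
    """Final state of one instrumented-correction simulation."""

    pattern: ScrewPattern
    configuration: solver.Configuration       # spine + rod bodies
    corrected_geometry: object                # SpineGeometry
    screw_forces: list                        # dicts per screw
    trace: list                               # per-step maneuver record
    max_gap_mm: float
    converged: bool
    report: metrics.IndexReport | None = None
    steps_completed: int = 0

    def force_magnitudes(self) -> np.ndarray:
        return np.array([s["magnitude"] for s in self.screw_forces])

    def forces_frame(self):
        import pandas as pd
        return pd.DataFrame(self.screw_forces)


def bone_screw_forces(result: SimulationResult):
    """Per-screw magnitudes and a (mean, sd, min, max, n) summary."""
    mags = result.force_magnitudes()
    if len(mags) == 0:
        return mags, {"mean": 0.0, "sd": 0.0, "min": 0.0, "max": 0.0, "n": 0}
    return mags, {"mean": float(np.mean(mags)),
                  "sd": float(np.std(mags, ddof=1)) if len(mags) > 1 else 0.0,
                  "min": float(np.min(mags)), "max": float(np.max(mags)),
                  "n": int(len(mags))}


def _rod_world_nodes(rod: RodDef, geometry, uiv, liv, standoff):
    """Place the rod in the world: chord through the dorsal standoff points
    of the UIV/LIV pedicle entries on the rod's side, bow in the chord's
    sagittal plane (posterior bulge for the kyphotic arc)."""
    lm = "pedicle_l" if rod.side == "left" else "pedicle_r"

    def dorsal_point(lab):
        v = geometry[lab]
        post = v.rotation @ np.array([-1.0, 0.0, 0.0])
        return v.world(lm) + (BALL_OFFSET_MM + standoff) * post

    qu, ql = dorsal_point(uiv), dorsal_point(liv)
    chord = ql - qu
    c_hat = chord / np.linalg.norm(chord)
    ant = np.array([1.0, 0.0, 0.0])
    xi_hat = ant - (ant @ c_hat) * c_hat
    xi_hat /= np.linalg.norm(xi_hat)
    # map arc length to chord coordinate so margins overhang both ends
    margin = 0.5 * (rod.length - np.linalg.norm(chord))
    zeta = rod.s - margin
    return qu + zeta[:, None] * c_hat + rod.xi[:, None] * xi_hat


def _beam_frame(d):
    z = d / np.linalg.norm(d)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(z @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    x = ref - (ref @ z) * z
    x /= np.linalg.norm(x)
    y = np.cross(z, x)
    return np.column_stack([x, y, z])


def simulate_segmental_translation(
        model: md.MultibodyModel, pattern: ScrewPattern, rods: list,
        indices: ClinicalIndices | None = None, schedule_steps: int = 20,
        connector_k: float = CONNECTOR_K_N_MM,
        standoff: float = HEAD_STANDOFF_MM,
        options: solver.SolverOptions | None = None) -> SimulationResult:
    """Run the simultaneous two-rod segmental translation maneuver.

    ``model`` should already carry the surgical release at the fused levels
    and the patient-calibration scale factors.  Boundary conditions: pelvis
    fully fixed, T1 transverse-plane translations constrained.
    """
    geom = model.geometry
    uiv, liv = pattern.fused[0], pattern.fused[-1]

    spine = model.copy()
    spine.fixed = spine.fixed.copy()
    spine.fix_body("T1", slice(0, 2))
    base = spine.build_system()
    n_spine = base.n_bodies

    # --- append rod bodies and beam springs
    x0 = [base.x0]
    rod_nodes = {}
    spr_b, spr_off, spr_E0, spr_Kt, spr_Kr = [], [], [], [], []
    next_idx = n_spine
    for rod in rods:
        pts = _rod_world_nodes(rod, geom, uiv, liv, standoff)
        idx0 = next_idx
        next_idx += len(pts)
        tangents = []
        for i in range(len(pts)):
            lo, hi = max(i - 1, 0), min(i + 1, len(pts) - 1)
            tangents.append(_beam_frame(pts[hi] - pts[lo]))
        rod_nodes[rod.side] = (idx0, pts, tangents)
        x0.append(pts)
        EA, EI, GJ = rod.section_stiffness()
        for i in range(len(pts) - 1):
            d = pts[i + 1] - pts[i]
            ell = np.linalg.norm(d)
            E0 = _beam_frame(d)
            mid = 0.5 * (pts[i] + pts[i + 1])
            spr_b.append([idx0 + i, idx0 + i + 1])
            spr_off.append([mid - pts[i], mid - pts[i + 1]])
            spr_E0.append(E0)
            # transverse shear, axial, then bending/bending/torsion
            cap = BEAM_KT_CAP_N_MM * (1e3 if rod.rigid else 1.0)
            spr_Kt.append([min(12 * EI / ell**3, cap),
                           min(12 * EI / ell**3, cap), min(EA / ell, cap)])
            spr_Kr.append([EI / ell, EI / ell, GJ / ell])
        # weak rotational grounding suppresses the rod's torsional rigid mode
        for i in range(len(pts)):
            spr_b.append([idx0 + i, spine.body_index(levels.PELVIS)])
            spr_off.append([np.zeros(3), np.zeros(3)])
            spr_E0.append(np.eye(3))
            spr_Kt.append([0.0, 0.0, 0.0])
            spr_Kr.append([50.0, 50.0, 50.0])     # N·mm/rad, negligible

    # --- screw-rod connectors.  Each polyaxial screw is reduced by drawing
    # the rod toward the ball joint of its head: the constraint is the
    # ball-to-rod-line *distance* (ramped from the initial gap down to the
    # locked head standoff).  The approach direction is free — the
    # polyaxial cone and dorsal height adjustability accommodate
    # medio-lateral and dorsoventral misfit without force — and the rod
    # slides freely through the saddles; the most cephalad screw of each
    # rod pins the rod's axial seating.  Locking freezes distance, angle
    # and sliding at their achieved values.
    conn_meta = []
    axial_pinned = set()
    for screw in sorted(pattern.screws,
                        key=lambda s: levels.index_of(s.level)):
        if screw.side not in rod_nodes:
            raise ValueError(f"no rod on side {screw.side!r}")
        v = geom[screw.level]
        post = v.rotation @ np.array([-1.0, 0.0, 0.0])
        ball = v.world(screw.anchor_landmark) + BALL_OFFSET_MM * post
        idx0, pts, tangents = rod_nodes[screw.side]
        j = int(np.argmin(np.linalg.norm(pts - ball, axis=1)))
        if j in (0, len(pts) - 1):
            d_end = np.linalg.norm(pts[j] - ball)
            if d_end > 2.0 * np.linalg.norm(pts[1] - pts[0]):
                raise ValueError(
                    f"rod too short: level {screw.level} ({screw.side}) is "
                    f"{d_end:.0f} mm beyond the rod end")
        E0 = tangents[j]                      # z along the rod
        rel = E0.T @ (ball - pts[j])
        g0t = float(np.linalg.norm(rel[:2]))
        pin = screw.side not in axial_pinned
        axial_pinned.add(screw.side)
        spr_b.append([idx0 + j, spine.body_index(screw.level)])
        spr_off.append([np.zeros(3), ball - v.position])
        spr_E0.append(E0)
        spr_Kt.append([connector_k, connector_k,
                       connector_k if pin else 0.0])
        spr_Kr.append([0.0, 0.0, 0.0])
        conn_meta.append({"screw": screw, "g0t": g0t,
                          "axial0": float(rel[2]), "pinned": pin,
                          "vert": spine.body_index(screw.level),
                          "node": idx0 + j, "post0": post.copy()})

    n_total = next_idx
    fixed = np.zeros((n_total, 6), dtype=bool)
    fixed[:n_spine] = base.fixed
    n_aux = len(spr_b) - len(conn_meta)       # beams + grounding
    system = solver.System(
        x0=np.concatenate(x0, axis=0), fixed=fixed,
        cab_bodies=base.cab_bodies, cab_off=base.cab_off,
        cab_k=base.cab_k, cab_L0=base.cab_L0,
        cab_bilateral=np.zeros(len(base.cab_k), bool),
        spr_bodies=np.concatenate(
            [base.spr_bodies, np.asarray(spr_b, int).reshape(-1, 2)], axis=0),
        spr_off=np.concatenate(
            [base.spr_off, np.asarray(spr_off).reshape(-1, 2, 3)], axis=0),
        spr_E0=np.concatenate(
            [base.spr_E0, np.asarray(spr_E0).reshape(-1, 3, 3)], axis=0),
        spr_Kt=np.concatenate([base.spr_Kt,
                               np.asarray(spr_Kt).reshape(-1, 3)], axis=0),
        spr_Kr=np.concatenate([base.spr_Kr,
                               np.asarray(spr_Kr).reshape(-1, 3)], axis=0),
        spr_dt0=np.concatenate(
            [base.spr_dt0, np.zeros((len(spr_b), 3))], axis=0),
    )
    n_base_spr = len(base.spr_Kt)
    conn_slice = slice(n_base_spr + n_aux, n_base_spr + len(spr_b))

    cone_cos = (math.cos(math.radians(POLYAXIAL_CONE_DEG))
                if POLYAXIAL_CONE_DEG is not None else -1.0)

    lock_rate = max(max(m["g0t"] - standoff, 0.0) for m in conn_meta) \
        / schedule_steps

    def set_rest(frac, cur_state):
        """Advance the persuaders: each unlocked ball-to-rod distance is
        reduced at a common rate toward the locked standoff.

        The approach direction follows the current geometry freely within
        the polyaxial cone around the screw shank axis and is clamped at
        the cone boundary — polyaxial angulation accommodates misfit
        without force, but only over its physical range."""
        dt_raw = _connector_raw_offsets(system, cur_state, conn_slice)
        for i, meta in enumerate(conn_meta):
            if meta.get("locked"):
                continue
            g = max(standoff, meta["g0t"] - lock_rate * frac * schedule_steps)
            E_A = cur_state.R[meta["node"]] @ system.spr_E0[conn_slice][i]
            # the ball sits ventral of the rod: the cone axis (rest offset
            # direction, ball relative to rod) is the negative shank axis
            a = -(E_A.T @ (cur_state.R[meta["vert"]] @ meta["post0"]))
            a2 = a[:2]
            na = np.linalg.norm(a2)
            t = dt_raw[i, :2]
            nt = np.linalg.norm(t)
            t_hat = t / nt if nt > 1e-9 else np.array([1.0, 0.0])
            if na > 1e-9 and cone_cos > -1.0:
                a_hat = a2 / na
                c = float(t_hat @ a_hat)
                if c < cone_cos:
                    # approach is free within the polyaxial cone and
                    # clamped at its boundary: angulation absorbs misfit
                    # over its physical range only
                    sgn = 1.0 if (a_hat[0] * t_hat[1]
                                  - a_hat[1] * t_hat[0]) >= 0 else -1.0
                    sn = sgn * math.sqrt(max(0.0, 1.0 - cone_cos**2))
                    t_hat = np.array(
                        [cone_cos * a_hat[0] - sn * a_hat[1],
                         sn * a_hat[0] + cone_cos * a_hat[1]])
            system.spr_dt0[conn_slice][i] = [
                t_hat[0] * g, t_hat[1] * g,
                meta["axial0"] if meta["pinned"] else 0.0]

    opts = options or solver.SolverOptions()
    # intermediate steps equilibrate to a loosened tolerance; the final
    # locked state is re-solved at the strict tolerances
    ramp_opts = solver.SolverOptions(
        force_tol=5.0 * opts.force_tol, torque_tol=5.0 * opts.torque_tol,
        max_iter=opts.max_iter, max_halvings=opts.max_halvings,
        regularization=opts.regularization)
    state = solver.State.rest(system)
    trace, converged, steps_done = [], True, 0

    def advance(s0, s1, step_opts, depth=0):
        """Equilibrate at ramp fraction s1, bisecting the increment on
        Newton failure (the maneuver is displacement-driven, so the ramp
        fraction, not a load factor, is the continuation parameter)."""
        nonlocal state
        set_rest(s1, state)
        try:
            cfg = solver.solve_equilibrium(system, n_steps=1, state=state,
                                           options=step_opts)
            state = cfg.to_state()
            return cfg
        except solver.ConvergenceError:
            if depth >= 7:
                raise
            mid = 0.5 * (s0 + s1)
            advance(s0, mid, step_opts, depth + 1)
            return advance(mid, s1, step_opts, depth + 1)

    def lock_seated(force_all=False):
        """Rigidly lock every seated screw: freeze distance, arc position
        and relative rotation at their achieved values (no force jump)."""
        raw = _connector_raw_offsets(system, state, conn_slice)
        _, dr_all = solver.spring_deflections(system, state)
        gaps = _connector_gaps(system, state, conn_slice)
        n_locked = 0
        for i, meta in enumerate(conn_meta):
            if meta.get("locked"):
                continue
            seated = (np.linalg.norm(raw[i, :2]) <= standoff + 0.5
                      and gaps[i] < 0.5)
            if not (seated or force_all):
                continue
            j = conn_slice.start + i
            # freeze sliding and direction; keep existing elastic force
            system.spr_dt0[j, 2] = raw[i, 2] - (
                system.spr_Kt[j, 2] / connector_k
                * (raw[i, 2] - system.spr_dt0[j, 2]) if system.spr_Kt[j, 2]
                else 0.0)
            system.spr_Kt[j] = connector_k
            system.spr_Kr[j] = LOCKED_KR_NMM_RAD
            system.spr_dr0[j] = dr_all[j] + system.spr_dr0[j]
            meta["locked"] = True
            n_locked += 1
        return n_locked

    for step in range(1, schedule_steps + 1):
        frac = step / schedule_steps
        try:
            cfg = advance((step - 1) / schedule_steps, frac, ramp_opts)
        except solver.ConvergenceError as e:
            converged = False
            if e.state is not None:
                state = e.state.to_state()
            trace.append({"step": step, "converged": False})
            break
        steps_done = step
        gaps = _connector_gaps(system, state, conn_slice)
        n_locked = lock_seated()
        trace.append({
            "step": step, "converged": True,
            "iterations": sum(r.iterations for r in cfg.records),
            "max_force_residual": max(r.max_force_residual
                                      for r in cfg.records),
            "max_gap_mm": float(np.max(gaps)),
            "locked": sum(1 for m in conn_meta if m.get("locked")),
        })

    # --- final locking: clamp any remaining screws, stiffen all locked
    # connections (set-screw torque) keeping forces continuous, and solve
    # the locked equilibrium at the strict tolerances
    if converged:
        try:
            lock_seated(force_all=True)
            cfg = solver.solve_equilibrium(system, n_steps=1, state=state,
                                           options=opts)
            state = cfg.to_state()
            raw = _connector_raw_offsets(system, state, conn_slice)
            rest = system.spr_dt0[conn_slice].copy()
            ratio = connector_k / CONNECTOR_K_LOCKED_N_MM
            system.spr_dt0[conn_slice] = raw - ratio * (raw - rest)
            system.spr_Kt[conn_slice] = CONNECTOR_K_LOCKED_N_MM
            cfg = solver.solve_equilibrium(system, n_steps=1, state=state,
                                           options=opts)
            state = cfg.to_state()
            trace.append({"step": "lock", "converged": True,
                          "iterations": sum(r.iterations
                                            for r in cfg.records)})
        except solver.ConvergenceError as e:
            converged = False
            if e.state is not None:
                state = e.state.to_state()
            trace.append({"step": "lock", "converged": False})

    gaps = _connector_gaps(system, state, conn_slice)
    forces = _connector_forces(system, state, conn_slice, conn_meta)

    final_cfg = solver.Configuration.from_state(state, converged=converged)
    spine_cfg = solver.Configuration(final_cfg.u[:n_spine],
                                     final_cfg.rotvec_deg[:n_spine],
                                     converged=converged)
    corrected = geom.moved(spine_cfg)
    report = (metrics.index_report(corrected, indices)
              if indices is not None else None)
    return SimulationResult(pattern, final_cfg, corrected, forces, trace,
                            float(np.max(gaps)) if len(gaps) else 0.0,
                            converged, report, steps_done)


def _connector_deflections(system, state, sl):
    dt, _ = solver.spring_deflections(system, state)
    return dt[sl]


def _connector_raw_offsets(system, state, sl):
    """Ball-to-node offsets in the rod-node frame (rest not subtracted)."""
    dt = _connector_deflections(system, state, sl)
    return dt + system.spr_dt0[sl]


def _connector_gaps(system, state, sl):
    """Deviation of the ball-to-rod distance from its commanded value."""
    dt = _connector_deflections(system, state, sl)
    return np.linalg.norm(dt[:, :2], axis=1)


def _connector_forces(system, state, sl, conn_meta):
    """Bone-screw reaction vectors (global frame, on the vertebra)."""
    dt = _connector_deflections(system, state, sl)
    bi = system.spr_bodies[sl.start:sl.stop, 0]
    EA = np.einsum("mij,mjk->mik", state.R[bi], system.spr_E0[sl])
    F_world = np.einsum("mij,mj->mi",
                        EA, system.spr_Kt[sl] * dt)   # restoring force on rod
    out = []
    for i, meta in enumerate(conn_meta):
        vec = -F_world[i]                    # force on the vertebra (anchor)
        s = meta["screw"]
        out.append({"level": s.level, "side": s.side,
                    "Fx": float(vec[0]), "Fy": float(vec[1]),
                    "Fz": float(vec[2]),
                    "magnitude": float(np.linalg.norm(vec))})
    return out
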