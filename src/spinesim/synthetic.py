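"""Synthetic 3-D scoliotic spine geometry matching prescribed clinical indices.

Stands in for biplanar-radiograph 3-D reconstruction: given one case's
clinical indices, it produces per-vertebra frames and landmark sets whose
*measured* indices (module :mod:`spinesim.metrics`) reproduce the requested
regional coronal Cobb angles, kyphosis, lordosis (each to +/- 1 deg) and
apical vertebral rotations (+/- 2 deg).

Construction: vertebral centers follow a composite 3-D curve obtained by
integrating a coronal tilt profile (piecewise-monotone interpolation through
the end-vertebra tilt controls of the PT / MT / TL-L regional arcs, zero at
each apex) and an analogous sagittal tilt profile for kyphosis/lordosis;
axial rotation follows a cosine bump peaking at each curve apex with
amplitude equal to the apical vertebral rotation.  Because projection
couplings between planes slightly perturb the measured angles, the control
amplitudes are refined by a short deterministic fixed-point loop that
re-measures the generated geometry until all targets are met.

Convexity convention (the case table does not print it): the main thoracic
curve is convex right; proximal thoracic and thoracolumbar/lumbar curves are
convex to the opposite side.  Configurable per case via
``ClinicalIndices.mt_convexity``.

The seed perturbs only mirror-symmetric features (sagittal profile, vertebral
dimensions), so geometry is deterministic per (indices, seed) and negating
the coronal convexity yields an exact mirror image.
"""
from __future__ import annotations

import json
import zlib

import numpy as np
from scipy.interpolate import PchipInterpolator

from . import levels, metrics
from .geometry import SpineGeometry, VertebraGeometry, vertebra_landmarks
from .indices import ClinicalIndices

__all__ = ["vertebral_dimensions", "generate_spine", "cohort_from_table",
           "DEFAULT_DIMENSIONS_MM", "REFERENCE_HEIGHT_CM"]

REFERENCE_HEIGHT_CM = 165.0

#: shipped default vertebral body dimensions (width, depth, height) in mm at
#: the reference stature, monotonically nondecreasing from T1 to L5.
DEFAULT_DIMENSIONS_MM = {
    "T1": (26.0, 17.0, 14.5), "T2": (27.2, 18.0, 15.3),
    "T3": (28.4, 19.0, 16.1), "T4": (29.5, 19.9, 16.9),
    "T5": (30.7, 20.9, 17.6), "T6": (31.9, 21.8, 18.4),
    "T7": (33.1, 22.8, 19.2), "T8": (34.2, 23.7, 20.0),
    "T9": (35.4, 24.7, 20.7), "T10": (36.6, 25.6, 21.5),
    "T11": (37.8, 26.6, 22.3), "T12": (39.0, 27.5, 23.0),
    "L1": (41.2, 29.0, 24.0), "L2": (43.4, 30.5, 24.8),
    "L3": (45.6, 32.0, 25.5), "L4": (47.8, 33.5, 26.3),
    "L5": (50.0, 35.0, 27.0),
}

#: pelvis stand-in body (sacral plate) dimensions at reference stature
PELVIS_DIMENSIONS_MM = (52.0, 36.0, 30.0)

#: disc height as a fraction of the mean adjacent vertebral body height
DISC_HEIGHT_FRACTION = 0.25


def vertebral_dimensions(level: str, height: float) -> tuple:
    """Vertebral body (width, depth, height) in mm, scaled linearly with
    patient stature from the shipped default table."""
    if not (120.0 <= height <= 200.0):
        raise ValueError(f"height: expected 120-200 cm, got {height}")
    lab = level.upper()
    if lab == levels.PELVIS:
        base = PELVIS_DIMENSIONS_MM
    else:
        try:
            base = DEFAULT_DIMENSIONS_MM[lab]
        except KeyError:
            raise ValueError(f"unknown vertebral level label: {level!r}") from None
    s = height / REFERENCE_HEIGHT_CM
    return tuple(s * d for d in base)


def _dev_signs(indices: ClinicalIndices) -> dict:
    """Lateral deviation sign per region: +1 convex toward +Y (left)."""
    s_mt = -1.0 if indices.mt_convexity == "right" else 1.0
    return {"PT": -s_mt, "MT": s_mt, "TLL": -s_mt}


def _coronal_controls(indices, amp, signs):
    """(index, tilt-deg) control points of the coronal tilt profile."""
    i = levels.index_of
    pt, mt, tll = amp["PT"], amp["MT"], amp["TLL"]
    b = signs["MT"] * mt / 2.0                    # tilt at the MT superior end
    ctrl = {
        i(indices.mt_sup_end): b,
        i(indices.mt_apex): 0.0,
        i(indices.mt_inf_end): b - signs["MT"] * mt,
        i(indices.pt_apex): 0.0,
        i(indices.pt_sup_end): b + signs["PT"] * pt,
        i(indices.tll_apex): 0.0,
        i(indices.tll_inf_end): b - signs["MT"] * mt - signs["TLL"] * tll,
    }
    theta_end = ctrl[i(indices.tll_inf_end)]
    if i(indices.pt_sup_end) > 0:
        ctrl[0] = ctrl[i(indices.pt_sup_end)]
    i_l5 = levels.index_of("L5")
    if i(indices.tll_inf_end) < i_l5:
        ctrl[i_l5] = 0.6 * theta_end
    ctrl[i_l5 + 1] = 0.3 * theta_end              # pelvis
    return ctrl


def _sagittal_controls(indices, amp):
    i = levels.index_of
    k2, l2 = amp["K"] / 2.0, amp["L"] / 2.0
    ctrl = {
        0: -k2, i("T2"): -k2,
        (i("T2") + i("T12")) // 2: 0.0,
        i("T12"): k2,
        i("L1"): l2, i("L3"): 0.0,
        i("L5"): -0.6 * l2, i("L5") + 1: -l2,
    }
    return ctrl


def _profile(ctrl: dict, n: int) -> np.ndarray:
    idx = np.array(sorted(ctrl))
    val = np.array([ctrl[j] for j in idx], dtype=float)
    if len(idx) < 2 or np.allclose(val, 0.0):
        out = np.zeros(n)
        out[idx.astype(int)] = val
        return out
    f = PchipInterpolator(idx, val, extrapolate=True)
    return f(np.arange(n))


def _axial_profile(indices, amp, signs, n):
    phi = np.zeros(n)
    i = levels.index_of
    for region, (a_amp, apex) in {
            "MT": (amp["AVR_MT"], indices.mt_apex),
            "TLL": (amp["AVR_TLL"], indices.tll_apex)}.items():
        up, lo = indices.region_span(region)
        iu, ia, il = i(up), i(apex), i(lo)
        for j in range(iu, il + 1):
            bound = iu if j <= ia else il
            if bound == ia:
                w = 1.0
            else:
                w = np.cos(0.5 * np.pi * (j - ia) / (bound - ia))
            phi[j] += signs[region] * a_amp * w
    return phi


def _rx(a):
    c, s = np.cos(a), np.sin(a)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


def _ry(a):
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])


def _rz(a):
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


def _build(indices, amp, signs, dims, sag_jit, x_jit):
    """Assemble one SpineGeometry from profile amplitudes."""
    n = len(levels.ALL_BODIES)
    theta_c = np.radians(_profile(_coronal_controls(indices, amp, signs), n))
    theta_s = np.radians(_profile(_sagittal_controls(indices, amp), n)
                         + sag_jit)
    phi = np.radians(_axial_profile(indices, amp, signs, n))

    heights = np.array([d[2] for d in dims])
    pos = np.zeros((n, 3))
    for j in range(1, n):
        disc = DISC_HEIGHT_FRACTION * 0.5 * (heights[j - 1] + heights[j])
        step = 0.5 * heights[j - 1] + disc + 0.5 * heights[j]
        tc = 0.5 * (theta_c[j - 1] + theta_c[j])
        ts = 0.5 * (theta_s[j - 1] + theta_s[j])
        d = _ry(-ts) @ _rx(tc) @ np.array([0.0, 0.0, -1.0])
        pos[j] = pos[j - 1] + step * d
    pos[:, 0] += x_jit

    # global balance (compensated curve): rigidly rotate the assembly about
    # T1 so the pelvis sits on the T1 plumb line in both planes.  Cobb
    # angles are tilt differences and unchanged to first order; the
    # refinement loop absorbs the projection residue.
    d = pos[-1] - pos[0]
    alpha = float(np.arctan(d[1] / d[2]))       # coronal drift
    z2 = d[2] * np.cos(alpha) + d[1] * np.sin(alpha)
    beta = float(np.arctan(-d[0] / z2))         # sagittal drift
    R_bal = _ry(beta) @ _rx(alpha)
    pos = (R_bal @ (pos - pos[0]).T).T + pos[0]

    bodies = []
    for j, lab in enumerate(levels.ALL_BODIES):
        R = R_bal @ _ry(-theta_s[j]) @ _rx(theta_c[j]) @ _rz(phi[j])
        lm = vertebra_landmarks(*dims[j])
        bodies.append(VertebraGeometry(lab, pos[j], R, lm, dims[j]))
    return SpineGeometry(bodies[:-1], bodies[-1])


_TARGET_KEYS = ["PT", "MT", "TLL", "K", "L", "AVR_MT", "AVR_TLL"]


def generate_spine(indices: ClinicalIndices, seed: int = 0,
                   max_refine: int = 8) -> SpineGeometry:
    """Generate a scoliotic spine whose measured indices match ``indices``.

    Deterministic for identical (indices, seed).  Raises ``ValueError``
    naming the violated constraint for infeasible index combinations.
    """
    indices.validate()
    rng = np.random.default_rng(int(seed) % (2**32))
    n = len(levels.ALL_BODIES)
    # mirror-symmetric perturbations only (see module docstring)
    dim_jit = 1.0 + 0.015 * rng.standard_normal(n)
    sag_jit = 0.3 * rng.standard_normal(n)
    x_jit = 0.3 * rng.standard_normal(n)
    dims = [tuple(np.asarray(vertebral_dimensions(lab, indices.height))
                  * dim_jit[j])
            for j, lab in enumerate(levels.ALL_BODIES)]

    signs = _dev_signs(indices)
    target = {"PT": indices.pt_cobb, "MT": indices.mt_cobb,
              "TLL": indices.tll_cobb, "K": indices.kyphosis,
              "L": indices.lordosis, "AVR_MT": indices.mt_avr,
              "AVR_TLL": indices.tll_avr}
    amp = dict(target)

    geom = None
    for _ in range(max_refine):
        geom = _build(indices, amp, signs, dims, sag_jit, x_jit)
        rep = metrics.index_report(geom, indices)
        meas = {"PT": rep.pt_cobb, "MT": rep.mt_cobb, "TLL": rep.tll_cobb,
                "K": rep.kyphosis, "L": rep.lordosis,
                "AVR_MT": rep.mt_avr, "AVR_TLL": rep.tll_avr}
        err = {k: target[k] - meas[k] for k in _TARGET_KEYS}
        ang_ok = all(abs(err[k]) < 0.2 for k in ("PT", "MT", "TLL", "K", "L"))
        avr_ok = all(abs(err[k]) < 0.5 for k in ("AVR_MT", "AVR_TLL"))
        if ang_ok and avr_ok:
            break
        for k in _TARGET_KEYS:
            amp[k] = max(0.0, amp[k] + 0.9 * err[k])
    return geom.validate()


def _row_seed(indices: ClinicalIndices, base_seed: int) -> int:
    """Stable per-row seed: identical rows get identical geometry."""
    payload = json.dumps(indices.to_dict(), sort_keys=True, default=str)
    return (int(base_seed) * 1000003 + zlib.crc32(payload.encode())) % (2**31)


def cohort_from_table(cases, seed: int = 0) -> list:
    """Generate one geometry per case row; returns [(indices, geometry)].

    ``cases`` is a list of :class:`ClinicalIndices` (see
    :func:`spinesim.io.read_case_table` for CSV parsing).  Deterministic:
    per-row seeds derive from the row content and the base seed.
    """
    out = []
    for row, ind in enumerate(cases):
        try:
            ind.validate()
        except ValueError as e:
            raise ValueError(f"case table row {row} "
                             f"(case_id={getattr(ind, 'case_id', '?')}): {e}"
                             ) from e
        out.append((ind, generate_spine(ind, _row_seed(ind, seed))))
    return out
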