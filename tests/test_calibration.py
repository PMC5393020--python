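"""Calibration: FSU-level fitting, release partition behavior, side-bending
simulation properties and patient-level parameter recovery."""
import dataclasses
import math

import numpy as np
import pytest

from spinesim import calibration as cal
from spinesim import model as md
from spinesim.metrics import signed_cobb
from spinesim.synthetic import generate_spine


def test_calibrate_fsu_hits_every_mode_target(calibrated_params):
    targets = cal.default_fsu_targets()
    for fsu in ("T2", "T6", "L4"):
        for mode in ("flexion", "lateral_bending", "axial_rotation",
                     "axial_compression"):
            want = targets.scaled_target(mode, fsu, calibrated_params)
            got = md.fsu_stiffness(
                md.canonical_fsu_model(fsu, calibrated_params), fsu, mode)
            assert got == pytest.approx(want, rel=0.02)


def test_calibrate_fsu_idempotent(calibrated_params):
    """Re-calibrating already-calibrated parameters changes nothing."""
    again = cal.calibrate_fsu(calibrated_params, cal.default_fsu_targets(),
                              "T6")
    assert np.allclose(again.primary_diag["T6"],
                       calibrated_params.primary_diag["T6"], rtol=1e-6)


def test_doubled_targets_double_recovered_stiffness():
    targets = cal.default_fsu_targets()
    big = cal.FsuTargets(
        mode_targets={k: 2.0 * v for k, v in targets.mode_targets.items()})
    base = cal.calibrate_fsu(md.default_stiffness_params(), targets, "T6")
    double = cal.calibrate_fsu(md.default_stiffness_params(), big, "T6")
    for mode in ("flexion", "lateral_bending", "axial_compression"):
        a = md.fsu_stiffness(md.canonical_fsu_model("T6", base), "T6", mode)
        b = md.fsu_stiffness(md.canonical_fsu_model("T6", double), "T6",
                             mode)
        assert b / a == pytest.approx(2.0, rel=0.02)


def test_infeasible_fsu_targets_name_the_mode():
    weak = cal.FsuTargets(mode_targets={
        "flexion": 1.0, "lateral_bending": 1.0, "axial_rotation": 1.0,
        "axial_compression": 1.0, "shear_ap": 1.0, "shear_lat": 1.0})
    with pytest.raises(cal.CalibrationError, match="infeasible"):
        cal.calibrate_fsu(md.default_stiffness_params(), weak, "T6")


def test_zero_reduction_targets_make_release_a_stiffness_noop():
    targets = cal.FsuTargets(
        reductions={k: 0.0 for k in md.RELEASE_REDUCTIONS})
    params = cal.calibrate_release_partition(
        md.default_stiffness_params(), targets, fsus=["T6"])
    intact = md.canonical_fsu_model("T6", params)
    released = md.apply_surgical_release(intact, ["T6"])
    for mode in ("axial_rotation", "flexion", "lateral_bending",
                 "axial_compression"):
        s_i = md.fsu_stiffness(intact, "T6", mode)
        s_r = md.fsu_stiffness(released, "T6", mode)
        assert s_r == pytest.approx(s_i, rel=0.005)
    # the removable elements carry (almost) no stiffness
    assert np.allclose(params.facet_diag["T6"][3:], 0.0, atol=1e-6)
    assert params.cable_k["T6"]["ISL_SSL"] == pytest.approx(0.0, abs=1e-9)


def test_side_bending_zero_load_is_identity(case1_model):
    bent, cfg = cal.simulate_side_bending(
        case1_model, "right", load={"t1_moment": 0.0, "distributed": 0.0})
    assert np.abs(cfg.u).max() < 1e-9


def test_side_bending_mirror_symmetry(straight_geometry, calibrated_params):
    model = __import__("spinesim.model", fromlist=["assemble_model"]) \
        .assemble_model(straight_geometry, calibrated_params)
    left, _ = cal.simulate_side_bending(model, "left")
    right, _ = cal.simulate_side_bending(model, "right")
    for lab in ("T1", "T8", "L3"):
        assert left[lab].position[1] == pytest.approx(
            -right[lab].position[1], abs=1e-4)


def test_stiffer_region_deflects_less(case1_model, case1):
    """Doubling a region's scale factor reduces its bending deflection."""
    up, lo = case1.region_span("MT")
    pre = signed_cobb(case1_model.geometry, up, lo)
    fsus = cal.region_fsus(case1)["MT"]
    soft, _ = cal.simulate_side_bending(case1_model, "right")
    stiff_model = case1_model.scaled({f: 2.0 for f in fsus})
    stiff, _ = cal.simulate_side_bending(stiff_model, "right")
    d_soft = abs(signed_cobb(soft, up, lo) - pre)
    d_stiff = abs(signed_cobb(stiff, up, lo) - pre)
    assert d_stiff < d_soft


def test_near_linear_deflection_halves_with_double_stiffness(
        case1_model, case1):
    up, lo = case1.region_span("MT")
    pre = signed_cobb(case1_model.geometry, up, lo)
    small = {"t1_moment": 120.0, "distributed": 10.0}
    fsus = {f: 1.0 for r in cal.region_fsus(case1).values() for f in r}
    bent1, _ = cal.simulate_side_bending(case1_model, "right", small)
    stiff = case1_model.scaled({f: 2.0 for f in fsus})
    bent2, _ = cal.simulate_side_bending(stiff, "right", small)
    d1 = signed_cobb(bent1, up, lo) - pre
    d2 = signed_cobb(bent2, up, lo) - pre
    # cable contributions are not scaled, so the ratio is below 2 but the
    # deflection must drop by a large factor
    assert d1 / d2 == pytest.approx(2.0, rel=0.35)
    assert abs(d2) < abs(d1)


def test_patient_calibration_reaches_all_six_bending_targets(case1_model,
                                                             case1):
    pc = cal.calibrate_patient(case1_model, case1)
    assert pc.converged
    assert max(pc.achieved_errors.values()) <= 2.0
    for (region, direction), s in pc.factors.items():
        assert 0.1 <= s <= 10.0


def test_fixed_point_when_targets_equal_model_output(case1_model, case1):
    """If the bending targets are the uncalibrated model's own output, the
    recovered factors are 1."""
    targets = {}
    for direction in ("left", "right"):
        bent, _ = cal.simulate_side_bending(case1_model, direction)
        for region in ("PT", "MT", "TLL"):
            targets[(region, direction)] = abs(
                signed_cobb(bent, *case1.region_span(region)))
    pc = cal.calibrate_patient(case1_model, case1, targets_deg=targets)
    for s in pc.factors.values():
        assert s == pytest.approx(1.0, abs=0.05)


def test_parameter_recovery_on_synthetic_truth(cases, calibrated_params):
    """Bending targets produced with known regional factors are recovered
    within 10 percent median absolute relative error."""
    rng = np.random.default_rng(42)
    errors = []
    for trial in range(20):
        ind = cases[trial % len(cases)]
        geom = generate_spine(ind, seed=100 + trial)
        model = md.assemble_model(geom, calibrated_params)
        regions = cal.region_fsus(ind)
        truth = {}
        targets = {}
        for direction in ("left", "right"):
            s = {r: float(np.exp(rng.uniform(np.log(0.3), np.log(3.0))))
                 for r in regions}
            truth[direction] = s
            m = model.scaled({f: s[r] for r in regions for f in regions[r]})
            bent, _ = cal.simulate_side_bending(m, direction)
            for r in regions:
                targets[(r, direction)] = abs(
                    signed_cobb(bent, *ind.region_span(r)))
        pc = cal.calibrate_patient(model, ind, targets_deg=targets)
        for (r, d), s_hat in pc.factors.items():
            errors.append(abs(s_hat - truth[d][r]) / truth[d][r])
    assert float(np.median(errors)) < 0.10


def test_corrective_factors_select_convexity_direction(case1):
    pc = cal.PatientCalibration(
        factors={(r, d): {("MT", "right"): 0.2}.get((r, d), 1.0)
                 for r in ("PT", "MT", "TLL") for d in ("left", "right")},
        achieved_errors={}, load_params={}, iterations=0, converged=True)
    fac = cal.corrective_factors(pc, case1)
    # MT is convex right: its corrective direction is right bending
    assert fac["T8"] == pytest.approx(0.2)
    # PT (convex left) takes its left-bending factor
    assert fac["T3"] == pytest.approx(1.0)
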