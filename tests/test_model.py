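"""Multibody spine model: element laws, assembly counts, surgical release,
FSU stiffness probes, rib-cage weighting and stiffness-matrix properties."""
import numpy as np
import pytest

from spinesim import calibration as cal
from spinesim import model as md
from spinesim import solver as sv


def test_printed_reference_cable_stiffnesses():
    params = md.default_stiffness_params()
    t6 = params.cable_k["T6"]
    assert t6["ALL"] == pytest.approx(23.6)
    assert t6["PLL"] == pytest.approx(24.9)
    assert t6["LF"] == pytest.approx(32.6)
    assert t6["ITL_left"] == pytest.approx(12.9)
    assert t6["ITL_right"] == pytest.approx(12.9)
    assert t6["ISL_SSL"] == pytest.approx(32.1)
    assert params.ribcage_weights == {"ry": 1.40, "rx": 1.35, "rz": 1.31}
    assert params.release_reductions["axial_rotation"] == 0.17
    assert params.release_reductions["lateral_bending"] == 0.038


def test_cable_stiffness_scales_with_vertebral_depth():
    params = md.default_stiffness_params()
    assert params.cable_k["L3"]["ALL"] > params.cable_k["T3"]["ALL"]
    assert params.level_scale["T6"] == pytest.approx(1.0, abs=0.02)


def test_cable_force_law():
    e = md.CableElement("ALL", "T6", "T6", "T7", np.zeros(3), np.zeros(3),
                        23.6, 30.0)
    assert md.cable_force(e, 31.0) == pytest.approx(23.6)   # +1 mm
    assert md.cable_force(e, 28.0) == 0.0                   # compression
    assert md.cable_force(e, 30.0) == 0.0                   # at rest
    with pytest.raises(ValueError):
        md.cable_force(e, -1.0)


def test_assembled_element_counts(case1_model):
    model = case1_model
    from spinesim import levels
    fsus = md.fsu_labels()
    assert len(fsus) == 17                       # T1-T2 ... L5-pelvis
    for fsu in fsus:
        elems = model.elements_of(fsu)
        cables = [e for e in elems if isinstance(e, md.CableElement)]
        springs = [e for e in elems if isinstance(e, md.GeneralSpring6D)]
        assert sorted(c.name for c in cables) == sorted(md.CABLE_NAMES)
        assert sorted(s.role for s in springs) == sorted(
            ["facet_left", "facet_right", "primary_disc"])


def test_assembly_is_force_free(case1_model):
    system = case1_model.build_system()
    assert np.abs(sv.residual(system, sv.State.rest(system))).max() < 1e-9


def test_release_removes_exactly_the_named_elements(case1_model):
    released = md.apply_surgical_release(case1_model, ["T6-T7"])
    elems = released.elements_of("T6")
    names = sorted(e.name if isinstance(e, md.CableElement) else e.role
                   for e in elems)
    assert names == sorted(["ALL", "PLL", "LF", "ITL_left", "ITL_right",
                            "primary_disc"])
    # other FSUs untouched
    assert len(released.elements_of("T8")) == 9
    # empty release is a no-op
    same = md.apply_surgical_release(case1_model, [])
    assert len(same.cables) == len(case1_model.cables)
    with pytest.raises(ValueError, match="unknown FSU"):
        md.apply_surgical_release(case1_model, ["C7"])


def test_release_of_fused_levels_covers_all_instrumented_fsus(case1_model,
                                                             case1):
    fused = case1.fused_levels
    assert fused[0] == "T4" and fused[-1] == "L2" and len(fused) == 11
    released = md.apply_surgical_release(case1_model, fused[:-1])
    assert len(released.released) == 10


def test_fsu_stiffness_single_cable_matches_analytic():
    """A lone axial cable probed in axial tension gives its own stiffness."""
    params = md.default_stiffness_params()
    model = md.canonical_fsu_model("T6", params)
    k = 40.0
    upper, lower = model.geometry.bodies
    # long vertical cable spanning both bodies (sup plate to inf plate)
    a = upper.world("sup_center") - upper.position
    b = lower.world("inf_center") - lower.position
    L0 = float(np.linalg.norm((lower.position + b) - (upper.position + a)))
    model.cables = [md.CableElement("ALL", "T6", "T6", "T7", a, b, k, L0)]
    model.springs = []
    got = md.fsu_stiffness(model, "T6", "axial_compression")
    # compression probe on an at-rest cable: it slackens, stiffness 0
    assert got == pytest.approx(0.0, abs=1e-9)
    # stretching the cable axially by d produces the analytic tension
    # k * (d - delta/2) (the solver's smoothed law beyond its blend zone)
    system = model.build_system()
    state = sv.State.rest(system)
    d = 0.5
    state.u[0, 2] = d
    res = sv.residual(system, state)
    f_axial = -res[0, 2]                 # cable pulls the upper body down
    expect = k * (d - sv.CABLE_SMOOTHING_MM / 2)
    assert f_axial == pytest.approx(expect, rel=1e-9)


def test_released_fsu_reductions_match_targets(calibrated_params):
    """Removing facet capsules + interspinous elements reduces FSU
    stiffness by 17 / 15 / 3.8 / 14 percent in the four calibrated modes."""
    for fsu in ("T3", "T6", "T10", "L2"):
        intact = md.canonical_fsu_model(fsu, calibrated_params)
        released = md.apply_surgical_release(intact, [fsu])
        for mode, want in (("axial_rotation", 17.0), ("flexion", 15.0),
                           ("lateral_bending", 3.8),
                           ("axial_compression", 14.0)):
            s_i = md.fsu_stiffness(intact, fsu, mode)
            s_r = md.fsu_stiffness(released, fsu, mode)
            red = 100.0 * (1.0 - s_r / s_i)
            assert red == pytest.approx(want, abs=0.5)


def test_ribcage_weighting_stiffens_thoracic_fsu(calibrated_params):
    """Thoracic FSUs with rib-cage weighting are 40/35/31 percent stiffer
    in flexion-extension / lateral bending / axial rotation."""
    targets = cal.default_fsu_targets()
    with_rc = cal.calibrate_fsu(calibrated_params, targets, "T6",
                                ribcage=True)
    without = cal.calibrate_fsu(calibrated_params, targets, "T6",
                                ribcage=False)
    for mode, ratio in (("flexion", 1.40), ("lateral_bending", 1.35),
                        ("axial_rotation", 1.31)):
        a = md.fsu_stiffness(md.canonical_fsu_model("T6", with_rc),
                             "T6", mode)
        b = md.fsu_stiffness(md.canonical_fsu_model("T6", without),
                             "T6", mode)
        assert a / b == pytest.approx(ratio, abs=0.005 * ratio)


def test_lumbar_fsu_carries_no_ribcage_weighting(calibrated_params):
    """Lumbar calibration defaults have no rib-cage factor: the probed
    stiffness equals the unweighted level-scaled target."""
    targets = cal.default_fsu_targets()
    want = targets.scaled_target("lateral_bending", "L2", calibrated_params)
    got = md.fsu_stiffness(md.canonical_fsu_model("L2", calibrated_params),
                           "L2", "lateral_bending")
    assert got == pytest.approx(want, rel=0.02)


def test_stiffness_matrices_symmetric_psd(calibrated_params):
    for fsu in md.fsu_labels():
        for diag in (calibrated_params.primary_diag[fsu],
                     calibrated_params.facet_diag[fsu]):
            K = np.diag(diag)
            assert np.allclose(K, K.T)
            assert np.all(np.linalg.eigvalsh(K) >= -1e-12)


def test_params_flat_config_round_trip(calibrated_params, tmp_path):
    flat = calibrated_params.to_flat()
    assert flat["cable.T6.ALL.N_per_mm"] == pytest.approx(23.6)
    back = md.StiffnessParams.from_flat(flat)
    assert back.cable_k["T9"]["LF"] == pytest.approx(
        calibrated_params.cable_k["T9"]["LF"])
    assert np.allclose(back.primary_diag["L1"],
                       calibrated_params.primary_diag["L1"])


def test_model_summary_export(case1_model, tmp_path):
    import json
    path = tmp_path / "model.json"
    case1_model.to_json(path)
    doc = json.loads(path.read_text())
    assert len(doc["bodies"]) == 18
    assert len(doc["elements"]) == 17 * 9
    cable = next(e for e in doc["elements"]
                 if e["kind"] == "cable" and e["fsu"] == "T6"
                 and e["name"] == "ALL")
    assert cable["stiffness_N_per_mm"] == pytest.approx(23.6)


def test_region_scaling_multiplies_coronal_stiffness(case1_model):
    base = md.fsu_stiffness(case1_model, "T8", "lateral_bending")
    scaled = case1_model.scaled({"T8": 0.5})
    soft = md.fsu_stiffness(scaled, "T8", "lateral_bending")
    assert soft < base
    # translational disc stiffness is not patient-scaled
    assert md.fsu_stiffness(scaled, "T8", "axial_compression") == \
        pytest.approx(md.fsu_stiffness(case1_model, "T8",
                                       "axial_compression"), rel=1e-9)
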