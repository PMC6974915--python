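"""Geometric trait quantification: closed forms, invariances, recovery."""

import math

import numpy as np
import pytest

import corollamorph as cm
from corollamorph.errors import DegenerateGeometryError

from conftest import build_cylinder, random_rotation

R, L, LOBE = 2.0, 20.0, 4.0  # cylinder fixture parameters


# -- tube axis --------------------------------------------------------------

def test_tube_axis_of_cylinder_is_straight_with_exact_length(template, cylinder):
    axis = cm.tube_axis(cylinder, template)
    assert axis.points.shape == (25, 3)
    assert np.abs(axis.points[:, 1:]).max() < 1e-12   # on the x axis
    assert axis.length == pytest.approx(L, abs=1e-9)


def test_tube_axis_rigid_equivariance(template, cylinder):
    rng = np.random.default_rng(0)
    rot, shift = random_rotation(rng), rng.normal(size=3)
    moved = cm.tube_axis(cylinder @ rot + shift, template)
    base = cm.tube_axis(cylinder, template)
    assert moved.length == pytest.approx(base.length, rel=1e-12)
    assert np.allclose(moved.points, base.points @ rot + shift, atol=1e-9)


def test_axis_matches_generator_centerline(template):
    lm = cm.generate_corolla(cm.CorollaParams(curvature=0.0, dilation_bulge=0.0,
                                              noise_sd=0.0), template)
    axis = cm.tube_axis(lm.coords, template)
    # straight generator: centerline on the x axis, orders at k/26 of length
    assert np.abs(axis.points[:, 1:]).max() < 1e-9
    expect = 25.0 * np.arange(1, 26) / 26
    assert np.allclose(axis.points[:, 0], expect, atol=1e-9)


# -- sagittal frame / curvature ---------------------------------------------

def test_sagittal_frame_planar_c_shape(template, cylinder):
    # bend the cylinder's axis into the xz plane (chord-aligned so the frame
    # abscissa stays on x): frame must be (x, z) up to sign
    coords = cylinder.copy()
    coords[:, 2] += 0.05 * coords[:, 0] * (coords[:, 0] - L)
    axis = cm.tube_axis(coords, template)
    frame = cm.sagittal_frame(axis, coords, template)
    for v in (frame.abscissa, frame.ordinate, frame.normal):
        assert np.linalg.norm(v) == pytest.approx(1.0, abs=1e-10)
    assert abs(frame.normal @ np.array([0, 1, 0])) == pytest.approx(1.0, abs=1e-9)
    assert frame.ordinate @ np.array([0, 0, 1]) > 0.99  # toward dorsal (+z)


def test_straight_axis_uses_dorsal_fallback(template, cylinder):
    axis = cm.tube_axis(cylinder, template)
    frame = cm.sagittal_frame(axis, cylinder, template)
    assert abs(frame.abscissa @ np.array([1, 0, 0])) == pytest.approx(1.0, abs=1e-9)
    assert frame.ordinate @ np.array([0, 0, 1]) > 0.9


def test_curvature_zero_and_exact_quadratic(template, cylinder):
    assert cm.tube_curvature(cylinder, template) == pytest.approx(0.0, abs=1e-9)
    bent = cylinder.copy()
    bent[:, 2] += 0.05 * bent[:, 0] * (bent[:, 0] - L)  # chord-aligned parabola
    assert cm.tube_curvature(bent, template) == pytest.approx(0.05, abs=1e-6)


def test_curvature_generator_ground_truth(template):
    lm = cm.generate_corolla(cm.CorollaParams(curvature=0.03, noise_sd=0.0), template)
    assert cm.tube_curvature(lm.coords, template) == pytest.approx(0.03, rel=0.02)


def test_curvature_rigid_invariance_and_scaling(template):
    lm = cm.generate_corolla(cm.CorollaParams(curvature=0.025, noise_sd=0.0), template)
    rng = np.random.default_rng(1)
    moved = lm.coords @ random_rotation(rng) + rng.normal(size=3)
    base = cm.tube_curvature(lm.coords, template)
    assert cm.tube_curvature(moved, template) == pytest.approx(base, abs=1e-9)
    assert cm.tube_curvature(lm.coords * 3.0, template) == pytest.approx(base / 3.0, rel=1e-9)


# -- triangulation / areas ---------------------------------------------------

def test_triangulation_deterministic_and_covering(template, cylinder):
    s1 = cm.corolla_triangulation(cylinder, template)
    s2 = cm.corolla_triangulation(cylinder, template)
    assert np.array_equal(s1.triangles, s2.triangles)
    assert np.array_equal(s1.tags, s2.tags)
    lm = cm.generate_corolla(cm.CorollaParams(noise_sd=0.0), template)
    surf = cm.corolla_triangulation(lm.coords, template)
    assert set(surf.triangles.ravel().tolist()) == set(range(template.size))


def test_tube_area_matches_decagon_prism(template, cylinder):
    surf = cm.corolla_triangulation(cylinder, template)
    areas = surf.areas(cylinder)
    tube = areas[surf.tags == "tube"].sum()
    assert tube == pytest.approx(2 * L * 10 * R * math.sin(math.pi / 10), rel=1e-9)


def _flat_lobe_polygon_area():
    """Independent shoelace oracle for one flat lobe of the cylinder fixture
    (lobes lie in the opening plane), re-deriving the boundary analytically."""
    rim_ext = 0.3 * LOBE
    half_w = (R + rim_ext) * math.sin(math.radians(60) / 2)
    # 2D in-plane coordinates: radial (r) and lateral (w), origin at IV
    pts = [(0.0, 0.0)]
    for j in range(1, 8):  # right rim, radial at +36 deg azimuth offset
        rad = R + (j / 7) * rim_ext
        pts.append((rad * math.cos(math.radians(36)) - R, -rad * math.sin(math.radians(36))))
    for m in range(1, 16):  # contour from the right rim side to the left
        g = m * math.pi / 16
        pts.append((1.05 * LOBE * math.sin(g), -half_w * math.cos(g)))
    for j in range(7, 0, -1):  # left rim back to IV
        rad = R + (j / 7) * rim_ext
        pts.append((rad * math.cos(math.radians(36)) - R, rad * math.sin(math.radians(36))))
    area = 0.0
    for (x1, y1), (x2, y2) in zip(pts, pts[1:] + pts[:1]):
        area += x1 * y2 - x2 * y1
    return abs(area) / 2


def test_lobe_area_matches_shoelace_oracle(template, cylinder):
    surf = cm.corolla_triangulation(cylinder, template)
    areas = surf.areas(cylinder)
    lobe = areas[surf.tags == "lobe"].sum()
    assert lobe == pytest.approx(5 * _flat_lobe_polygon_area(), rel=0.03)


def test_lobe_area_ratio_closed_form_and_scale_invariance(template, cylinder):
    ratio = cm.lobe_area_ratio(cylinder, template)
    tube = 2 * L * 10 * R * math.sin(math.pi / 10)
    lobes = 5 * _flat_lobe_polygon_area()
    assert ratio == pytest.approx(lobes / (tube + lobes), rel=0.03)
    assert cm.lobe_area_ratio(cylinder * 5.0, template) == pytest.approx(ratio, rel=1e-9)
    assert 0 < ratio < 1


def test_collapsed_lobes_drive_ratio_to_zero(template, cylinder):
    collapsed = cylinder.copy()
    lobe_ids = template.table.loc[template.table["region"] == "lobe", "landmark_id"]
    collapsed[lobe_ids.to_numpy()] = np.array([L, 0.0, 0.0])
    with pytest.warns(UserWarning, match="zero-area"):
        ratio = cm.lobe_area_ratio(collapsed, template)
    assert ratio == 0.0


# -- dilation ----------------------------------------------------------------

def test_dilation_cylinder_closed_form(template, cylinder):
    expect = math.sqrt(10) * R / L
    assert cm.tube_dilation(cylinder, template) == pytest.approx(expect, abs=1e-9)
    assert cm.tube_dilation(cylinder * 7.0, template) == pytest.approx(expect, rel=1e-9)


def test_dilation_monotone_in_bulge(template):
    values = [
        cm.tube_dilation(
            cm.generate_corolla(cm.CorollaParams(dilation_bulge=b, noise_sd=0.0), template).coords,
            template,
        )
        for b in (0.0, 0.2, 0.4, 0.6, 0.8)
    ]
    assert np.all(np.diff(values) > 0)


# -- recurvation ---------------------------------------------------------------

def test_recurvation_flat_lobes_90(template, cylinder):
    assert cm.lobe_recurvation(cylinder, template) == pytest.approx(90.0, abs=1e-9)


@pytest.mark.parametrize("theta", [0.0, 30.0, 75.0])
def test_recurvation_recovers_bend_angle(template, theta):
    lm = cm.generate_corolla(cm.CorollaParams(lobe_bend_deg=theta, noise_sd=0.0), template)
    assert cm.lobe_recurvation(lm.coords, template) == pytest.approx(theta, abs=1.0)


# -- rigid/scale invariance across all traits ---------------------------------

def test_all_traits_rigid_invariant(template):
    lm = cm.generate_corolla(cm.CorollaParams(curvature=0.02, noise_sd=0.0), template)
    rng = np.random.default_rng(3)
    moved = lm.coords @ random_rotation(rng) + rng.normal(size=3)
    for fn in (cm.tube_curvature, cm.lobe_area_ratio, cm.tube_dilation, cm.lobe_recurvation):
        assert fn(moved, template) == pytest.approx(fn(lm.coords, template), abs=1e-9)


def test_monotone_parameter_recovery_sweeps(template):
    """Rank correlation 1.0 between each generator parameter and its measured
    trait over a 5-point sweep at zero noise."""
    sweeps = {
        "curvature": (cm.tube_curvature, [0.0, 0.01, 0.02, 0.03, 0.04]),
        "lobe_length": (cm.lobe_area_ratio, [4.0, 6.0, 8.0, 10.0, 12.0]),
        "dilation_bulge": (cm.tube_dilation, [0.0, 0.2, 0.4, 0.6, 0.8]),
        "lobe_bend_deg": (cm.lobe_recurvation, [0.0, 20.0, 40.0, 60.0, 80.0]),
    }
    for name, (fn, values) in sweeps.items():
        measured = [
            fn(cm.generate_corolla(
                cm.CorollaParams(**{name: v, "noise_sd": 0.0}), template).coords, template)
            for v in values
        ]
        assert np.all(np.diff(measured) > 0), name


def test_trait_table_complete_and_flags_failures(template):
    study = cm.generate_study(cm.StudyDesign(
        tree=cm.random_tree(3, seed=5), specimens_per_species=2, seed=6))
    table = cm.trait_table(study.collection)
    assert len(table) == 6
    assert table["error"].isna().all() or (table["error"] == None).all()  # noqa: E711
    assert table[["tube_curvature", "lobe_area_ratio", "tube_dilation",
                  "lobe_recurvation"]].notna().all().all()


def test_single_factor_trait_correlates_with_leading_pc(template):
    """A study varying only tube curvature yields a leading shape PC whose
    scores track the measured curvature almost perfectly."""
    rng = np.random.default_rng(12)
    specs = []
    for i, c in enumerate(np.linspace(-0.01, 0.05, 10)):
        lm = cm.generate_corolla(cm.CorollaParams(curvature=c, noise_sd=0.0), template)
        lm.specimen_id = f"v{i}"
        specs.append(lm)
    coll = cm.SpecimenCollection(template=template, specimens=specs)
    space = cm.build_morphospace(cm.full_gpa(coll))
    curv = [cm.tube_curvature(s.coords, template) for s in specs]
    r = cm.score_correlations(space.scores[:, 0], np.asarray(curv))
    assert abs(r) > 0.95
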