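"""Shared fixtures: the packaged template, analytic cylinder corollas, and
session-scoped synthetic studies (generated once, reused across modules)."""

import math

import numpy as np
import pytest

import corollamorph as cm


@pytest.fixture(scope="session")
def template():
    return cm.default_template()


def build_cylinder(template, radius=2.0, length=20.0, lobe_length=4.0):
    """A straight cylindrical corolla whose 25 tube orders span [0, length]
    exactly, with flat radial lobes in the opening plane (bend angle 90°).

    Closed forms: tube axis length = ``length``; mid-tube transection centroid
    size = sqrt(10) * radius; tube strip area = 2 * length * 10 * radius *
    sin(pi/10) (inscribed decagon prism); tube curvature = 0; recurvation 90°.
    """
    coords = np.zeros((template.size, 3))
    x_hat = np.array([1.0, 0.0, 0.0])
    y_hat = np.array([0.0, 1.0, 0.0])
    z_hat = np.array([0.0, 0.0, 1.0])
    cyc = template.petal_cycle
    azim = {p: math.radians(-90 + 72 * i) for i, p in enumerate(cyc)}

    def ring(x, az):
        return x * x_hat + radius * (math.cos(az) * y_hat + math.sin(az) * z_hat)

    rim_ext = 0.3 * lobe_length
    for i, petal in enumerate(cyc):
        a = azim[petal]
        radial = math.cos(a) * y_hat + math.sin(a) * z_hat
        lateral = -math.sin(a) * y_hat + math.cos(a) * z_hat
        coords[template.primary_index("primary-II", petal)] = ring(0.0, a)
        for k, lid in enumerate(template.series_indices("tube_midrib", petal), start=1):
            coords[lid] = ring((k - 1) / 24 * length, a)
        iv = ring(length, a)
        coords[template.primary_index("primary-IV", petal)] = iv
        spine = template.series_indices("lobe_midrib", petal)
        for j, lid in enumerate(spine, start=1):
            coords[lid] = iv + (j / (len(spine) + 1)) * lobe_length * radial
        coords[template.primary_index("primary-III", petal)] = iv + lobe_length * radial
        contour = template.series_indices("lobe_contour", petal)
        half_w = (radius + rim_ext) * math.sin(math.radians(60) / 2)
        for m, lid in enumerate(contour, start=1):
            g = m * math.pi / (len(contour) + 1)
            coords[lid] = iv + 1.05 * lobe_length * math.sin(g) * radial + half_w * math.cos(g) * lateral

        rim = f"{petal}|{cyc[(i + 1) % len(cyc)]}"
        b = a + math.radians(36)
        rim_radial = math.cos(b) * y_hat + math.sin(b) * z_hat
        coords[template.primary_index("primary-V", rim)] = ring(0.0, b)
        for k, lid in enumerate(template.series_indices("tube_tube_rim", rim), start=1):
            coords[lid] = ring((k - 1) / 24 * length, b)
        rim_ids = template.series_indices("lobe_lobe_rim", rim)
        for j, lid in enumerate(rim_ids, start=1):
            coords[lid] = length * x_hat + (radius + (j / len(rim_ids)) * rim_ext) * rim_radial
    return coords


@pytest.fixture(scope="session")
def cylinder(template):
    return build_cylinder(template)


def random_rotation(rng):
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


@pytest.fixture(scope="session")
def two_clade_study():
    return cm.make_fixture("two-clade-curvature")


@pytest.fixture(scope="session")
def null_study():
    return cm.make_fixture("null")


@pytest.fixture(scope="session")
def allometric_study():
    return cm.make_fixture("allometric")
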