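"""Parametric synthetic corollas with known ground truth.

The generator builds a 415-landmark corolla from interpretable geometric
parameters that map one-to-one onto the four measured traits:

* the tube is a surface of revolution swept along a planar quadratic
  centerline (quadratic coefficient = ``curvature``, the tube-curvature
  ground truth), arc-length parameterized so the tube has length
  ``tube_length``;
* the cross-section radius profile ``base_radius * (1 + dilation_bulge *
  sin(pi t))`` bulges mid-tube (``dilation_bulge`` drives tube dilation);
* five lobes leave the tube opening tilted ``lobe_bend_deg`` away from the
  opening normal (the lobe-recurvation ground truth), with semi-elliptic
  contours spanning ``lobe_width_deg`` of azimuth;
* ``scale`` rescales the whole corolla and ``noise_sd`` adds isotropic
  Gaussian landmark noise (digitization error).

Whole synthetic studies evolve these parameters over a phylogeny by Brownian
motion, add specimen-level jitter, and label species with pollination types
by thresholding the ground-truth parameters (a synthetic convention:
hummingbird = strongly up-curved tubes, moth = long narrow tubes, bee = the
rest).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .data import LandmarkSet, SpecimenCollection
from .errors import CorollaError
from .phylo import PhyloTree, random_tree, simulate_bm
from .template import LandmarkTemplate, default_template


@dataclass
class CorollaParams:
    """Ground-truth geometric parameters of one corolla (lengths in mm)."""

    tube_length: float = 25.0
    base_radius: float = 4.0
    dilation_bulge: float = 0.3
    curvature: float = 0.02        # mm^-1, positive bends dorsally
    lobe_length: float = 8.0
    lobe_width_deg: float = 60.0
    lobe_bend_deg: float = 35.0
    scale: float = 1.0
    noise_sd: float = 0.15         # mm, isotropic landmark noise

    def __post_init__(self):
        if min(self.tube_length, self.base_radius, self.lobe_length) <= 0:
            raise ValueError("tube_length, base_radius, lobe_length must be positive")
        if self.noise_sd < 0 or self.dilation_bulge < 0:
            raise ValueError("noise_sd and dilation_bulge must be non-negative")


# -- centerline helpers ------------------------------------------------------

def _arc_antideriv(w: float) -> float:
    return 0.5 * (w * math.sqrt(1 + w * w) + math.asinh(w))


def _solve_extent(kappa: float, length: float) -> float:
    """Abscissa extent U such that the curve z = k*u*(u-U) has arc length
    ``length`` over u in [0, U]."""
    if kappa == 0:
        return length

    def arc(u_max):
        a = kappa * u_max
        return (_arc_antideriv(a) - _arc_antideriv(-a)) / (2 * kappa)

    return brentq(lambda u: arc(u) - length, 1e-12, length, xtol=1e-12)


class _Centerline:
    """Planar quadratic tube centerline, chord-aligned: z(u) = k*u*(u-U)."""

    def __init__(self, kappa: float, length: float):
        self.kappa = kappa
        self.length = length
        self.extent = _solve_extent(kappa, length)

    def u_at(self, t: float) -> float:
        """Abscissa at arc-length fraction t in [0, 1]."""
        if self.kappa == 0:
            return t * self.extent
        k, u_max = self.kappa, self.extent

        def arc_to(u):
            return (_arc_antideriv(k * (2 * u - u_max)) - _arc_antideriv(-k * u_max)) / (2 * k)

        target = t * self.length
        if t <= 0:
            return 0.0
        if t >= 1:
            return u_max
        return brentq(lambda u: arc_to(u) - target, 0.0, u_max, xtol=1e-12)

    def frame(self, t: float):
        """(point, tangent, in-plane normal) at arc fraction t."""
        u = self.u_at(t)
        slope = self.kappa * (2 * u - self.extent)
        denom = math.sqrt(1 + slope * slope)
        point = np.array([u, 0.0, self.kappa * u * (u - self.extent)])
        tangent = np.array([1.0, 0.0, slope]) / denom
        normal = np.array([-slope, 0.0, 1.0]) / denom  # toward +z (dorsal side)
        return point, tangent, normal


def generate_corolla(params: CorollaParams, template: LandmarkTemplate | None = None,
                     seed=None) -> LandmarkSet:
    """One synthetic corolla landmark configuration conforming to the
    template.  With ``noise_sd = 0`` the trait module recovers ``curvature``
    and ``lobe_bend_deg`` exactly (up to float precision)."""
    template = template or default_template()
    rng = np.random.default_rng(seed)
    line = _Centerline(params.curvature, params.tube_length)
    y_hat = np.array([0.0, 1.0, 0.0])

    def radius(t):
        return params.base_radius * (1 + params.dilation_bulge * math.sin(math.pi * t))

    def surf(t, azimuth):
        point, _, normal = line.frame(t)
        return point + radius(t) * (math.cos(azimuth) * y_hat + math.sin(azimuth) * normal)

    coords = np.zeros((template.size, 3))
    cyc = template.petal_cycle
    azimuth = {p: math.radians(-90 + 72 * i) for i, p in enumerate(cyc)}

    n_tube = template.series_counts["tube_midrib"]
    for i, petal in enumerate(cyc):
        a = azimuth[petal]
        coords[template.primary_index("primary-II", petal)] = surf(0.0, a)
        for k, lid in enumerate(template.series_indices("tube_midrib", petal), start=1):
            coords[lid] = surf(k / (n_tube + 1), a)
        coords[template.primary_index("primary-IV", petal)] = surf(1.0, a)
        rim = f"{petal}|{cyc[(i + 1) % len(cyc)]}"
        b = a + math.radians(36)
        coords[template.primary_index("primary-V", rim)] = surf(0.0, b)
        for k, lid in enumerate(template.series_indices("tube_tube_rim", rim), start=1):
            coords[lid] = surf(k / (n_tube + 1), b)

    # lobes leave the tube opening
    c1, t1, n1 = line.frame(1.0)
    r1 = radius(1.0)
    theta = math.radians(params.lobe_bend_deg)
    rim_ext = 0.3 * params.lobe_length  # radial reach of the lobe-lobe rims
    for i, petal in enumerate(cyc):
        a = azimuth[petal]
        radial = math.cos(a) * y_hat + math.sin(a) * n1
        lateral = -math.sin(a) * y_hat + math.cos(a) * n1
        direction = math.cos(theta) * t1 + math.sin(theta) * radial
        iv = c1 + r1 * radial
        iii = iv + params.lobe_length * direction
        coords[template.primary_index("primary-III", petal)] = iii
        spine = template.series_indices("lobe_midrib", petal)
        for j, lid in enumerate(spine, start=1):
            coords[lid] = iv + (j / (len(spine) + 1)) * params.lobe_length * direction
        # contour: semi-ellipse drawn 5% beyond the midrib tip
        contour = template.series_indices("lobe_contour", petal)
        half_w = (r1 + rim_ext) * math.sin(math.radians(params.lobe_width_deg) / 2)
        for m, lid in enumerate(contour, start=1):
            g = m * math.pi / (len(contour) + 1)
            coords[lid] = (
                iv
                + 1.05 * params.lobe_length * math.sin(g) * direction
                + half_w * math.cos(g) * lateral
            )
        # lobe-lobe rim toward the next petal; its distal entry is primary-I
        rim = f"{petal}|{cyc[(i + 1) % len(cyc)]}"
        b = a + math.radians(36)
        rim_radial = math.cos(b) * y_hat + math.sin(b) * n1
        rim_ids = template.series_indices("lobe_lobe_rim", rim)
        for j, lid in enumerate(rim_ids, start=1):
            coords[lid] = c1 + (r1 + (j / len(rim_ids)) * rim_ext) * rim_radial
        coords[template.primary_index("primary-I", rim)] = c1 + (r1 + rim_ext) * rim_radial

    coords *= params.scale
    if params.noise_sd > 0:
        coords = coords + rng.normal(0.0, params.noise_sd, coords.shape)
    return LandmarkSet(specimen_id="synthetic", species="synthetic",
                       pollination="unknown", coords=coords)


# ---------------------------------------------------------------------------
# whole studies
# ---------------------------------------------------------------------------

#: BM rates per unit tree height for species-level parameter evolution
DEFAULT_BM_RATES = {
    "tube_length": 16.0,
    "base_radius": 1.0,
    "dilation_bulge": 0.04,
    "curvature": 4e-4,
    "lobe_length": 4.0,
    "lobe_width_deg": 64.0,
    "lobe_bend_deg": 100.0,
    "log_scale": 0.16,
}

#: biologically plausible ranges; BM excursions are reflected back inside
PARAM_BOUNDS = {
    "tube_length": (8.0, 60.0),
    "base_radius": (1.5, 10.0),
    "dilation_bulge": (0.0, 1.5),
    "curvature": (-0.06, 0.08),
    "lobe_length": (3.0, 20.0),
    "lobe_width_deg": (25.0, 110.0),
    "lobe_bend_deg": (0.0, 120.0),
}

#: specimen-level parameter jitter (multiplicative CV / additive SD)
JITTER_CV = {"tube_length": 0.04, "base_radius": 0.04, "lobe_length": 0.04, "scale": 0.04}
JITTER_SD = {"curvature": 0.002, "dilation_bulge": 0.02,
             "lobe_bend_deg": 2.0, "lobe_width_deg": 3.0}


def _reflect(value: float, lo: float, hi: float) -> float:
    span = hi - lo
    x = (value - lo) % (2 * span)
    return lo + (x if x <= span else 2 * span - x)


def default_pollination_rule(params: CorollaParams) -> str:
    """Synthetic labelling convention: strongly up-curved tubes read as
    hummingbird flowers, long narrow straight tubes as moth flowers,
    everything else as bee flowers."""
    if params.curvature >= 0.015:
        return "hummingbird"
    if params.tube_length / params.base_radius >= 8.0:
        return "moth"
    return "bee"


@dataclass
class StudyDesign:
    """Design of a synthetic comparative study."""

    tree: PhyloTree = None
    base_params: CorollaParams = field(default_factory=CorollaParams)
    species_params: dict[str, CorollaParams] | None = None  # overrides BM evolution
    bm_rates: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BM_RATES))
    specimens_per_species: int | dict | None = None  # None: 6-16, drawn per species
    pollination_rule: object = None
    seed: int = 0

    def __post_init__(self):
        if self.tree is None:
            self.tree = random_tree(15, seed=self.seed)
        if self.pollination_rule is None:
            self.pollination_rule = default_pollination_rule


@dataclass
class SyntheticStudy:
    collection: SpecimenCollection
    tree: PhyloTree
    species_truth: pd.DataFrame   # species-level ground-truth parameters
    specimen_truth: pd.DataFrame  # per-specimen parameters after jitter


def _evolve_species_params(design: StudyDesign, rng) -> dict[str, CorollaParams]:
    if design.species_params is not None:
        return dict(design.species_params)
    base = design.base_params
    tips = design.tree.tip_labels
    zero = pd.Series(0.0, index=tips)
    devs = {}
    for name in list(PARAM_BOUNDS) + ["log_scale"]:
        rate = design.bm_rates.get(name, 0.0)
        if rate > 0:
            seed = int(rng.integers(2**31))
            devs[name] = simulate_bm(design.tree, sigma2=rate, seed=seed)
        else:
            devs[name] = zero
    out = {}
    for sp in tips:
        fields = {}
        for name, (lo, hi) in PARAM_BOUNDS.items():
            fields[name] = _reflect(getattr(base, name) + float(devs[name][sp]), lo, hi)
        fields["scale"] = base.scale * math.exp(float(devs["log_scale"][sp]))
        fields["noise_sd"] = base.noise_sd
        out[sp] = CorollaParams(**fields)
    return out


def _jitter(params: CorollaParams, rng) -> CorollaParams:
    fields = {}
    for name, cv in JITTER_CV.items():
        fields[name] = getattr(params, name) * rng.normal(1.0, cv)
    for name, sd in JITTER_SD.items():
        fields[name] = getattr(params, name) + rng.normal(0.0, sd)
    for name, (lo, hi) in PARAM_BOUNDS.items():
        if name in fields:
            fields[name] = _reflect(fields[name], lo, hi)
    fields["tube_length"] = max(fields["tube_length"], 1.0)
    fields["base_radius"] = max(fields["base_radius"], 0.2)
    fields["lobe_length"] = max(fields["lobe_length"], 0.5)
    return replace(params, **fields)


def generate_study(design: StudyDesign, template: LandmarkTemplate | None = None) -> SyntheticStudy:
    """A whole synthetic study: species parameters evolved on the tree,
    per-specimen jitter and landmark noise, pollination labels from the
    design's rule, and full ground-truth tables."""
    template = template or default_template()
    rng = np.random.default_rng(design.seed)
    species_params = _evolve_species_params(design, rng)

    counts = {}
    for sp in design.tree.tip_labels:
        if design.specimens_per_species is None:
            counts[sp] = int(rng.integers(6, 17))
        elif isinstance(design.specimens_per_species, dict):
            counts[sp] = int(design.specimens_per_species[sp])
        else:
            counts[sp] = int(design.specimens_per_species)
        if counts[sp] < 1:
            raise CorollaError(f"species {sp!r} has an invalid specimen count")

    specimens, spec_rows, sp_rows = [], [], []
    for sp in design.tree.tip_labels:
        params = species_params[sp]
        label = design.pollination_rule(params)
        sp_rows.append({"species": sp, "pollination": label, **vars(params)})
        for idx in range(counts[sp]):
            jp = _jitter(params, rng)
            lm = generate_corolla(jp, template, seed=int(rng.integers(2**31)))
            lm.specimen_id = f"{sp}_{idx + 1:02d}"
            lm.species = sp
            lm.pollination = label
            specimens.append(lm)
            spec_rows.append({"specimen_id": lm.specimen_id, "species": sp,
                              "pollination": label, **vars(jp)})
    return SyntheticStudy(
        collection=SpecimenCollection(template=template, specimens=specimens),
        tree=design.tree,
        species_truth=pd.DataFrame(sp_rows),
        specimen_truth=pd.DataFrame(spec_rows),
    )


# ---------------------------------------------------------------------------
# named fixtures
# ---------------------------------------------------------------------------

def _two_clade_tree() -> PhyloTree:
    left = "(" + ",".join(f"spA{i}:0.25" for i in range(1, 8)) + "):0.75"
    right = "(" + ",".join(f"spB{i}:0.25" for i in range(1, 9)) + "):0.75"
    return PhyloTree.from_string(f"({left},{right});")


def make_fixture(name: str) -> SyntheticStudy:
    """Deterministic named studies used by the test suite and examples.

    ``"null"``       no species-level effects; pollination labels random, so
                     association and allometry tests are calibrated nulls.
    ``"allometric"`` curvature coupled to size across species, producing a
                     strong shape-size correlation.
    ``"two-clade-curvature"`` a two-regime tree: one up-curved (hummingbird)
                     clade, one straight (bee) clade.
    """
    if name == "null":
        tree = random_tree(15, seed=101)
        rng = np.random.default_rng(7)
        params = {sp: CorollaParams() for sp in tree.tip_labels}
        # labels independent of geometry: a calibrated null for association tests
        labels = {sp: ("hummingbird", "bee", "moth")[rng.integers(3)]
                  for sp in tree.tip_labels}
        study = generate_study(
            StudyDesign(tree=tree, species_params=params, seed=11,
                        pollination_rule=lambda p: "bee")
        )
        for s in study.collection:
            s.pollination = labels[s.species]
        study.collection = SpecimenCollection(
            template=study.collection.template, specimens=study.collection.specimens
        )
        study.species_truth["pollination"] = study.species_truth["species"].map(labels)
        study.specimen_truth["pollination"] = study.specimen_truth["species"].map(labels)
        return study
    if name == "allometric":
        tree = random_tree(15, seed=202)
        rng = np.random.default_rng(17)
        params = {}
        for sp in tree.tip_labels:
            z = rng.normal()
            params[sp] = CorollaParams(
                scale=math.exp(0.35 * z),
                curvature=_reflect(0.02 + 0.018 * z, *PARAM_BOUNDS["curvature"]),
            )
        return generate_study(StudyDesign(tree=tree, species_params=params, seed=23))
    if name == "two-clade-curvature":
        tree = _two_clade_tree()
        params = {}
        for sp in tree.tip_labels:
            high = sp.startswith("spA")
            params[sp] = CorollaParams(curvature=0.045 if high else -0.005)
        return generate_study(
            StudyDesign(tree=tree, species_params=params,
                        specimens_per_species=6, seed=31)
        )
    raise KeyError(f"unknown fixture {name!r}; choose from "
                   "'null', 'allometric', 'two-clade-curvature'")
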