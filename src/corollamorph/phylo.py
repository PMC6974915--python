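"""Phylogenetic comparative operations on corolla traits and landmarks.

Covers newick tree handling (via dendropy), the Brownian-motion (BM) trait
model, Blomberg's K statistic with its permutation test, weighted
squared-change parsimony reconstruction of ancestral states (scalars or whole
landmark configurations, solved exactly as a sparse linear system), k-nearest
neighbour labelling of ancestral pollination types, and a subsample-based
uncertainty summary for the reconstructions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .data import SpecimenCollection
from .errors import CoverageError, DegenerateGeometryError
from .procrustes import full_gpa, partial_gpa

__all__ = [
    "PhyloTree",
    "read_newick",
    "write_newick",
    "random_tree",
    "phylo_covariance",
    "blomberg_k",
    "k_permutation_test",
    "simulate_bm",
    "AncestralReconstruction",
    "squared_change_parsimony",
    "ancestral_corollas",
    "classify_ancestral_pollination",
    "reconstruction_uncertainty",
]


class PhyloTree:
    """A rooted tree with branch lengths and uniquely labelled tips.

    Wraps a dendropy tree; internal nodes are assigned ids ``node1`` (root),
    ``node2``, ... in preorder for reporting ancestral states.
    """

    def __init__(self, dendropy_tree: dendropy.Tree):
        self._tree = dendropy_tree
        # flatten to parent-pointer arrays in preorder
        nodes = list(dendropy_tree.preorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        self.parent = np.full(len(nodes), -1, dtype=int)
        self.length = np.zeros(len(nodes))
        self.is_tip = np.zeros(len(nodes), dtype=bool)
        self.labels: list[str] = []
        n_internal = 0
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                self.parent[i] = index[id(nd.parent_node)]
                self.length[i] = nd.edge.length if nd.edge.length is not None else 0.0
                if self.length[i] < 0:
                    raise ValueError("negative branch length")
            if nd.is_leaf():
                self.is_tip[i] = True
                if nd.taxon is None or not nd.taxon.label:
                    raise ValueError("unlabeled tip in tree")
                self.labels.append(nd.taxon.label)
            else:
                n_internal += 1
                self.labels.append(f"node{n_internal}")
        tips = [l for l, t in zip(self.labels, self.is_tip) if t]
        if len(set(tips)) != len(tips):
            raise ValueError("duplicate tip labels in tree")

    # -- accessors ---------------------------------------------------------
    @property
    def tip_labels(self) -> list[str]:
        return [l for l, t in zip(self.labels, self.is_tip) if t]

    @property
    def internal_labels(self) -> list[str]:
        return [l for l, t in zip(self.labels, self.is_tip) if not t]

    @property
    def n_tips(self) -> int:
        return int(self.is_tip.sum())

    def depths(self) -> np.ndarray:
        """Distance from the root to every node (preorder array)."""
        d = np.zeros(len(self.labels))
        for i in range(1, len(self.labels)):
            d[i] = d[self.parent[i]] + self.length[i]
        return d

    @property
    def height(self) -> float:
        return float(self.depths().max())

    def patristic_distance(self, a: str, b: str) -> float:
        ia, ib = self.labels.index(a), self.labels.index(b)
        depths = self.depths()
        anc_a = self._ancestor_path(ia)
        anc_b = set(self._ancestor_path(ib))
        mrca = next(n for n in anc_a if n in anc_b)
        return float(depths[ia] + depths[ib] - 2 * depths[mrca])

    def _ancestor_path(self, i: int) -> list[int]:
        path = [i]
        while self.parent[path[-1]] >= 0:
            path.append(self.parent[path[-1]])
        return path

    def to_newick(self) -> str:
        return self._tree.as_string(schema="newick", suppress_rooting=True).strip()

    @classmethod
    def from_string(cls, newick: str) -> "PhyloTree":
        try:
            tree = dendropy.Tree.get(data=newick, schema="newick")
        except Exception as exc:
            raise ValueError(f"could not parse newick: {exc}") from exc
        return cls(tree)


def read_newick(path) -> PhyloTree:
    with open(path, encoding="utf-8") as fh:
        return PhyloTree.from_string(fh.read())


def write_newick(tree: PhyloTree, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(tree.to_newick() + "\n")


def random_tree(n_tips: int, seed=None, labels=None, height: float = 1.0) -> PhyloTree:
    """Random ultrametric tree built by coalescent-style pair merging with
    exponential waiting times, rescaled to the given height."""
    rng = np.random.default_rng(seed)
    if labels is None:
        labels = [f"sp{i + 1:02d}" for i in range(n_tips)]
    clusters = [(lbl, 0.0) for lbl in labels]  # (newick fragment, height)
    t = 0.0
    while len(clusters) > 1:
        t += rng.exponential(1.0)
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        (na, ha), (nb, hb) = clusters[i], clusters[j]
        merged = (f"({na}:{t - ha:.10f},{nb}:{t - hb:.10f})", t)
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
    newick, total = clusters[0]
    tree = PhyloTree.from_string(newick + ";")
    # rescale to requested height
    for nd in tree._tree.preorder_node_iter():
        if nd.edge.length is not None:
            nd.edge.length *= height / total
    return PhyloTree(tree._tree)


# ---------------------------------------------------------------------------
# Brownian motion and Blomberg's K
# ---------------------------------------------------------------------------

def phylo_covariance(tree: PhyloTree) -> tuple[np.ndarray, list[str]]:
    """BM covariance matrix: C[i, j] is the root-to-MRCA distance of tips i
    and j; the diagonal holds root-to-tip distances."""
    depths = tree.depths()
    tip_idx = np.flatnonzero(tree.is_tip)
    paths = [set(tree._ancestor_path(i)) for i in tip_idx]
    n = len(tip_idx)
    c = np.zeros((n, n))
    for a in range(n):
        c[a, a] = depths[tip_idx[a]]
        for b in range(a + 1, n):
            mrca = max(paths[a] & paths[b], key=lambda k: depths[k])
            c[a, b] = c[b, a] = depths[mrca]
    return c, [tree.labels[i] for i in tip_idx]


def _trait_vector(trait, tip_order: list[str]) -> np.ndarray:
    if isinstance(trait, pd.Series):
        trait = trait.to_dict()
    if isinstance(trait, dict):
        missing = [t for t in tip_order if t not in trait]
        if missing:
            raise CoverageError(f"trait missing for tips {missing}")
        return np.array([float(trait[t]) for t in tip_order])
    x = np.asarray(trait, dtype=float)
    if x.shape != (len(tip_order),):
        raise ValueError("trait vector length must equal the number of tips")
    return x


class _KStatistic:
    """Blomberg K evaluator with the tree-dependent pieces precomputed, so a
    permutation test costs one quadratic form per shuffle."""

    def __init__(self, tree: PhyloTree):
        c, self.tips = phylo_covariance(tree)
        n = len(self.tips)
        if n < 4:
            raise ValueError("Blomberg K needs at least 4 tips")
        try:
            self.cinv = np.linalg.inv(c)
        except np.linalg.LinAlgError:
            self.cinv = np.linalg.inv(c + 1e-10 * np.trace(c) / n * np.eye(n))
        ones = np.ones(n)
        self.sum_cinv = float(ones @ self.cinv @ ones)
        self.cinv_ones = self.cinv @ ones
        self.expected = (np.trace(c) - n / self.sum_cinv) / (n - 1)

    def __call__(self, x: np.ndarray) -> float:
        if np.ptp(x) == 0:
            raise DegenerateGeometryError("constant trait: K undefined")
        a_hat = (self.cinv_ones @ x) / self.sum_cinv
        resid = x - a_hat
        num = resid @ resid
        den = resid @ self.cinv @ resid
        if den <= 0 or num == 0:
            raise DegenerateGeometryError("constant trait: K undefined")
        return float((num / den) / self.expected)


def blomberg_k(tree: PhyloTree, trait) -> float:
    """Blomberg's K: the observed ratio of trait variance to
    phylogenetically corrected variance, scaled by its BM expectation.
    K = 1 is the Brownian-motion benchmark; K near 0 means no signal.
    """
    stat = _KStatistic(tree)
    return stat(_trait_vector(trait, stat.tips))


def k_permutation_test(
    tree: PhyloTree,
    trait,
    n_permutations: int = 10_000,
    seed=None,
    estimator: str = "strict",
) -> dict:
    """Permutation test for phylogenetic signal: trait values reshuffled
    across tips; p is the proportion of permuted K above the observed K."""
    stat = _KStatistic(tree)
    x = _trait_vector(trait, stat.tips)
    observed = stat(x)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        if stat(rng.permutation(x)) > observed:
            exceed += 1
    p_min = 1.0 / (n_permutations + 1)
    if estimator == "strict":
        p = max(exceed / n_permutations, p_min)
    elif estimator == "plus_one":
        p = (exceed + 1) / (n_permutations + 1)
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    return {"K": observed, "p_value": float(p), "n_permutations": n_permutations, "seed": seed}


def simulate_bm(tree: PhyloTree, sigma2: float = 1.0, seed=None,
                root_value: float = 0.0, return_internal: bool = False):
    """Brownian-motion trait simulation: child = parent + N(0, sigma2 * branch
    length), preorder down the tree.  Returns a Series over tips (and a dict
    over internal node ids when requested)."""
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    rng = np.random.default_rng(seed)
    values = np.zeros(len(tree.labels))
    values[0] = root_value
    for i in range(1, len(tree.labels)):
        values[i] = values[tree.parent[i]] + rng.normal(0.0, np.sqrt(sigma2 * tree.length[i]))
    tips = pd.Series(
        {l: values[i] for i, l in enumerate(tree.labels) if tree.is_tip[i]},
        name="trait",
    )
    if return_internal:
        internal = {l: values[i] for i, l in enumerate(tree.labels) if not tree.is_tip[i]}
        return tips, internal
    return tips


# ---------------------------------------------------------------------------
# ancestral reconstruction
# ---------------------------------------------------------------------------

@dataclass
class AncestralReconstruction:
    """Values at every node of the tree; tips equal the supplied values."""

    node_values: dict[str, np.ndarray]
    internal_ids: list[str]
    mode: str = "trait"
    method: str = "weighted squared-change parsimony"
    per_node_sd: dict[str, np.ndarray] = field(default_factory=dict)

    def value(self, node: str):
        return self.node_values[node]


def squared_change_parsimony(tree: PhyloTree, tip_values: dict,
                             mode: str = "trait") -> AncestralReconstruction:
    """Internal-node values minimizing sum over branches of
    (change)^2 / branch length, solved exactly from the stationarity
    conditions (each internal value is the inverse-branch-length weighted
    mean of its neighbours).  Applied independently per coordinate for
    array-valued tips.  Zero branch lengths are replaced by
    1e-8 * tree height with a warning.
    """
    tips = tree.tip_labels
    missing = [t for t in tips if t not in tip_values]
    if missing:
        raise CoverageError(f"tip values missing for {missing}")
    shapes = {np.shape(tip_values[t]) for t in tips}
    if len(shapes) != 1:
        raise ValueError("all tip values must share one shape")
    shape = shapes.pop()
    tip_mat = np.stack([np.asarray(tip_values[t], dtype=float).ravel() for t in tips])

    lengths = tree.length.copy()
    eps = 1e-8 * max(tree.height, 1.0)
    zero = (lengths <= 0) & (tree.parent >= 0)
    if zero.any():
        warnings.warn(f"replacing {int(zero.sum())} zero branch lengths by {eps:g}")
        lengths[zero] = eps

    internal_idx = np.flatnonzero(~tree.is_tip)
    pos = {int(i): k for k, i in enumerate(internal_idx)}
    tip_pos = {tree.labels[i]: r for r, i in enumerate(np.flatnonzero(tree.is_tip))}
    m = len(internal_idx)
    a = np.zeros((m, m))
    b = np.zeros((m, tip_mat.shape[1]))
    for child in range(1, len(tree.labels)):
        par = tree.parent[child]
        w = 1.0 / lengths[child]
        pi = pos[int(par)]
        if tree.is_tip[child]:
            a[pi, pi] += w
            b[pi] += w * tip_mat[tip_pos[tree.labels[child]]]
        else:
            ci = pos[int(child)]
            a[pi, pi] += w
            a[ci, ci] += w
            a[pi, ci] -= w
            a[ci, pi] -= w
    solution = np.linalg.solve(a, b) if m else np.zeros((0, tip_mat.shape[1]))

    node_values: dict[str, np.ndarray] = {}
    for k, i in enumerate(internal_idx):
        node_values[tree.labels[i]] = solution[k].reshape(shape) if shape else solution[k].item()
    for t in tips:
        v = np.asarray(tip_values[t], dtype=float)
        node_values[t] = v.reshape(shape) if shape else float(v)
    return AncestralReconstruction(
        node_values=node_values,
        internal_ids=[tree.labels[i] for i in internal_idx],
        mode=mode,
    )


def _species_mean_configs(collection: SpecimenCollection, tree: PhyloTree, mode: str):
    missing = [t for t in tree.tip_labels if t not in set(collection.species)]
    if missing:
        raise CoverageError(f"tree tips without specimens: {missing}")
    align = full_gpa if mode == "shape" else partial_gpa
    ensemble = align(collection.species_subset(tree.tip_labels))
    return ensemble, ensemble.species_means()


def ancestral_corollas(collection: SpecimenCollection, tree: PhyloTree,
                       mode: str = "shape"):
    """Ancestral landmark configurations by squared-change parsimony applied
    coordinate-wise to species-mean aligned configurations (full GPA for
    shape, partial GPA for form).

    Returns ``(reconstruction, ensemble)`` so downstream steps can project
    ancestors into the extant morphospace or measure their traits.
    """
    if mode not in ("shape", "form"):
        raise ValueError("mode must be 'shape' or 'form'")
    ensemble, means = _species_mean_configs(collection, tree, mode)
    recon = squared_change_parsimony(tree, means, mode=mode)
    return recon, ensemble


def ancestral_trait_table(recon: AncestralReconstruction, template) -> pd.DataFrame:
    """Centroid size and the four morphological traits measured on
    reconstructed configurations (meaningful for form-mode reconstructions,
    where size is retained)."""
    from .procrustes import centroid_size
    from .traits import lobe_area_ratio, lobe_recurvation, tube_curvature, tube_dilation

    rows = []
    for node in recon.internal_ids + [
        n for n in recon.node_values if n not in recon.internal_ids
    ]:
        cfg = recon.node_values[node]
        rows.append(
            {
                "node": node,
                "centroid_size": centroid_size(cfg),
                "tube_curvature": tube_curvature(cfg, template),
                "lobe_area_ratio": lobe_area_ratio(cfg, template),
                "tube_dilation": tube_dilation(cfg, template),
                "lobe_recurvation": lobe_recurvation(cfg, template),
            }
        )
    return pd.DataFrame(rows)


def classify_ancestral_pollination(extant_scores: np.ndarray, extant_labels,
                                   ancestral_scores: np.ndarray, k: int = 5) -> list[str]:
    """Majority pollination label among the k Euclidean-nearest extant
    specimens of each ancestral point; ties broken by the single nearest
    neighbour's label."""
    extant_scores = np.atleast_2d(np.asarray(extant_scores, dtype=float))
    ancestral_scores = np.atleast_2d(np.asarray(ancestral_scores, dtype=float))
    labels = np.asarray(extant_labels)
    if not 1 <= k <= len(labels):
        raise ValueError(f"k must be in [1, {len(labels)}]")
    d = cdist(ancestral_scores, extant_scores)
    out = []
    for row in d:
        nearest = np.argsort(row, kind="stable")[:k]
        votes = pd.Series(labels[nearest]).value_counts()
        top = votes[votes == votes.max()].index
        out.append(labels[nearest[0]] if len(top) > 1 else top[0])
    return out


def reconstruction_uncertainty(
    collection: SpecimenCollection,
    tree: PhyloTree,
    mode: str = "shape",
    reps: int = 100,
    subsample: int = 3,
    seed=None,
) -> AncestralReconstruction:
    """Reconstruction variability from specimen subsampling: in each
    repetition ``subsample`` specimens per species are drawn without
    replacement, species means recomputed, and the reconstruction repeated;
    per-node coordinate-wise SD across repetitions is reported."""
    rng = np.random.default_rng(seed)
    species = np.asarray(collection.species)
    ids = np.asarray(collection.specimen_ids)
    for name in dict.fromkeys(collection.species):
        if (species == name).sum() < subsample:
            raise ValueError(f"species {name!r} has fewer than {subsample} specimens")

    per_node: dict[str, list[np.ndarray]] = {}
    base = None
    for _ in range(reps):
        chosen = []
        for name in dict.fromkeys(collection.species):
            pool = ids[species == name]
            chosen.extend(rng.choice(pool, size=subsample, replace=False))
        recon, _ = ancestral_corollas(collection.subset(chosen), tree, mode=mode)
        base = recon
        for node, val in recon.node_values.items():
            per_node.setdefault(node, []).append(np.asarray(val))
    assert base is not None
    base.per_node_sd = {
        node: np.std(np.stack(vals), axis=0, ddof=0) for node, vals in per_node.items()
    }
    base.node_values = {
        node: np.mean(np.stack(vals), axis=0) for node, vals in per_node.items()
    }
    return base
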