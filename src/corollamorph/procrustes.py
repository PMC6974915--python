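"""Generalized Procrustes analysis of landmark configurations.

Two alignment modes are provided.  *Shape* mode (full GPA) removes
translation, rotation and scale: every configuration is centred, rescaled to
unit centroid size and rotated onto the evolving consensus.  *Form* mode
(partial GPA) removes translation and rotation only, so centroid size — the
standard geometric-morphometric size measure — is retained in the aligned
coordinates.

Rotations are proper (det = +1): corollas are bilaterally organized, chiral
structures, and a reflection would map the dorsal side onto the ventral side.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import SpecimenCollection
from .errors import DegenerateGeometryError, InsufficientSampleError
from .template import LandmarkTemplate


def centroid_size(config: np.ndarray) -> float:
    """Centroid size: root summed squared distance of landmarks from their
    centroid.  Invariant to translation and rotation; scales linearly."""
    config = np.asarray(config, dtype=float)
    centred = config - config.mean(axis=0)
    return float(np.sqrt((centred**2).sum()))


def optimal_rotation(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Proper rotation R (3x3, det = +1) minimizing ||source @ R - target||.

    Kabsch solution via SVD of the cross-covariance, with the smallest
    singular direction sign-corrected so reflections are never returned.
    """
    h = source.T @ target
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    sign = np.ones(3)
    sign[-1] = d if d != 0 else 1.0
    return (u * sign) @ vt


@dataclass
class AlignedEnsemble:
    """Procrustes-aligned configurations with consensus and sizes.

    ``configs`` is (S, K, 3); ``centroid_sizes`` are the pre-alignment sizes;
    ``consensus`` is the arithmetic mean of the aligned configurations.
    ``objective_history`` records the summed squared distance to the consensus
    at each iteration (non-increasing).
    """

    mode: str
    configs: np.ndarray
    consensus: np.ndarray
    centroid_sizes: np.ndarray
    template: LandmarkTemplate | None
    iterations_used: int
    converged: bool
    specimen_ids: list[str] = field(default_factory=list)
    species: list[str] = field(default_factory=list)
    pollination: list[str] = field(default_factory=list)
    objective_history: np.ndarray = field(default=None)

    @property
    def n_specimens(self) -> int:
        return self.configs.shape[0]

    @property
    def n_landmarks(self) -> int:
        return self.configs.shape[1]

    def flattened(self) -> np.ndarray:
        """Aligned coordinates as an (S, 3K) matrix (landmark-major)."""
        s = self.configs.shape[0]
        return self.configs.reshape(s, -1)

    def species_means(self) -> dict[str, np.ndarray]:
        """Mean aligned configuration per species."""
        out: dict[str, np.ndarray] = {}
        sp = np.asarray(self.species)
        for name in dict.fromkeys(self.species):  # preserve order
            out[name] = self.configs[sp == name].mean(axis=0)
        return out


def _as_arrays(collection):
    if isinstance(collection, SpecimenCollection):
        return (
            collection.coords_array(),
            collection.template,
            collection.specimen_ids,
            collection.species,
            collection.pollination,
        )
    arr = np.asarray(collection, dtype=float)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError("expected a SpecimenCollection or an (S, K, 3) array")
    n = arr.shape[0]
    return arr, None, [f"spec{i}" for i in range(n)], [""] * n, [""] * n


def _gpa(collection, scale: bool, tol: float, max_iter: int, mode: str) -> AlignedEnsemble:
    coords, template, ids, species, pollination = _as_arrays(collection)
    s = coords.shape[0]
    if s < 2:
        raise InsufficientSampleError("GPA requires at least 2 specimens")

    centred = coords - coords.mean(axis=1, keepdims=True)
    sizes = np.sqrt((centred**2).sum(axis=(1, 2)))
    if np.any(sizes <= 0):
        bad = ids[int(np.argmin(sizes))]
        raise DegenerateGeometryError(f"specimen {bad!r} has zero centroid size")
    work = centred / sizes[:, None, None] if scale else centred.copy()

    consensus = work[0].copy()
    if scale:
        consensus /= np.linalg.norm(consensus)
    converged = False
    history = []
    iterations = 0
    for iterations in range(1, max_iter + 1):
        for i in range(s):
            work[i] = work[i] @ optimal_rotation(work[i], consensus)
        history.append(float(((work - consensus) ** 2).sum()))
        new_consensus = work.mean(axis=0)
        if scale:
            norm = np.linalg.norm(new_consensus)
            if norm == 0:
                raise DegenerateGeometryError("degenerate consensus (zero norm)")
            new_consensus = new_consensus / norm
        rms = np.sqrt(((new_consensus - consensus) ** 2).mean())
        consensus = new_consensus
        if rms < tol:
            converged = True
            break

    return AlignedEnsemble(
        mode=mode,
        configs=work,
        consensus=work.mean(axis=0),
        centroid_sizes=sizes,
        template=template,
        iterations_used=iterations,
        converged=converged,
        specimen_ids=list(ids),
        species=list(species),
        pollination=list(pollination),
        objective_history=np.asarray(history),
    )


def full_gpa(collection, tol: float = 1e-8, max_iter: int = 100) -> AlignedEnsemble:
    """Full GPA (shape mode): centre, scale to unit centroid size, and
    iteratively rotate onto the unit-size consensus."""
    return _gpa(collection, scale=True, tol=tol, max_iter=max_iter, mode="shape")


def partial_gpa(collection, tol: float = 1e-8, max_iter: int = 100) -> AlignedEnsemble:
    """Partial GPA (form mode): identical iteration without the scaling step,
    so each aligned configuration keeps its original centroid size."""
    return _gpa(collection, scale=False, tol=tol, max_iter=max_iter, mode="form")
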