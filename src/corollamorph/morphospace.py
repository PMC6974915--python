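"""Principal-component morphospaces of aligned landmark coordinates.

PCA is applied directly to the flattened aligned coordinates (covariance PCA:
all coordinates share units, so no per-coordinate standardization).  Axes from
shape-mode ensembles are shape PCs (sPCs); axes from form-mode ensembles are
form PCs (fPCs).  The inverse transform synthesizes *virtual flowers* —
configurations at chosen scores along an axis, e.g. the mean ± 2 SD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateGeometryError, InsufficientSampleError
from .procrustes import AlignedEnsemble
from .template import LandmarkTemplate


@dataclass
class Morphospace:
    """PCA decomposition of an aligned ensemble.

    ``axes`` are orthonormal rows (C x 3K); ``eigenvalues`` are the sample
    variances (divisor S-1) along each axis, descending; ``scores`` is S x C.
    Axis signs follow a fixed convention (largest-magnitude loading positive)
    so results are reproducible across runs and platforms.
    """

    mode: str
    mean_vector: np.ndarray
    axes: np.ndarray
    eigenvalues: np.ndarray
    scores: np.ndarray
    variance_fractions: np.ndarray
    template: LandmarkTemplate | None = None
    specimen_ids: list[str] = field(default_factory=list)
    species: list[str] = field(default_factory=list)
    pollination: list[str] = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return self.axes.shape[0]

    def project(self, configs: np.ndarray) -> np.ndarray:
        """Scores of new configurations ((N, K, 3) or (N, 3K)) in this space."""
        x = np.asarray(configs, dtype=float)
        if x.ndim == 3:
            x = x.reshape(x.shape[0], -1)
        return (x - self.mean_vector) @ self.axes.T

    def inverse(self, scores: np.ndarray) -> np.ndarray:
        """Configurations (N, K, 3) reconstructed from full score vectors."""
        scores = np.atleast_2d(np.asarray(scores, dtype=float))
        flat = self.mean_vector + scores @ self.axes
        return flat.reshape(scores.shape[0], -1, 3)


def build_morphospace(ensemble: AlignedEnsemble) -> Morphospace:
    """Eigendecomposition (via SVD) of the covariance of flattened aligned
    coordinates; retains C = min(S-1, 3K) components."""
    x = ensemble.flattened()
    s, p = x.shape
    if s < 3:
        raise InsufficientSampleError("PCA needs at least 3 specimens")
    mean = x.mean(axis=0)
    xc = x - mean
    u, sv, vt = np.linalg.svd(xc, full_matrices=False)
    eig = sv**2 / (s - 1)
    total = eig.sum()
    if total <= 0:
        raise DegenerateGeometryError("all configurations identical: no shape variance")
    c = min(s - 1, p)
    axes, eig = vt[:c], eig[:c]
    # deterministic sign: largest-|loading| entry of each axis made positive
    flip = np.sign(axes[np.arange(c), np.abs(axes).argmax(axis=1)])
    flip[flip == 0] = 1.0
    axes = axes * flip[:, None]
    scores = xc @ axes.T
    return Morphospace(
        mode=ensemble.mode,
        mean_vector=mean,
        axes=axes,
        eigenvalues=eig,
        scores=scores,
        variance_fractions=eig / eig.sum(),
        template=ensemble.template,
        specimen_ids=list(ensemble.specimen_ids),
        species=list(ensemble.species),
        pollination=list(ensemble.pollination),
    )


def standardize_scores(scores: np.ndarray | Morphospace) -> np.ndarray:
    """Columns rescaled to zero mean, unit sample SD (ddof = 1)."""
    if isinstance(scores, Morphospace):
        scores = scores.scores
    scores = np.asarray(scores, dtype=float)
    sd = scores.std(axis=0, ddof=1)
    if np.any(sd <= 0):
        raise DegenerateGeometryError(
            f"zero-variance score column {int(np.argmin(sd))}"
        )
    return (scores - scores.mean(axis=0)) / sd


def virtual_shape(space: Morphospace, component: int, magnitude_sd: float) -> np.ndarray:
    """Configuration (K, 3) at ``magnitude_sd`` standard deviations along one
    component: mean + m * sqrt(eigenvalue) * axis.  ``magnitude_sd = ±2``
    gives the conventional mean ± 2 SD virtual flowers."""
    if not 0 <= component < space.n_components:
        raise IndexError(f"component {component} not retained (C={space.n_components})")
    flat = space.mean_vector + magnitude_sd * np.sqrt(space.eigenvalues[component]) * space.axes[component]
    return flat.reshape(-1, 3)


def within_species_variance(scores: np.ndarray, species, standardize: bool = True) -> pd.DataFrame:
    """Per-species sample variance of (standardized) scores per component.

    Species with a single specimen are excluded with a warning.
    """
    scores = standardize_scores(scores) if standardize else np.asarray(scores, float)
    species = np.asarray(species)
    rows, names = [], []
    for name in dict.fromkeys(species.tolist()):
        sub = scores[species == name]
        if sub.shape[0] < 2:
            warnings.warn(f"species {name!r} has a single specimen; excluded")
            continue
        rows.append(sub.var(axis=0, ddof=1))
        names.append(name)
    return pd.DataFrame(
        rows, index=pd.Index(names, name="species"),
        columns=[f"PC{i + 1}" for i in range(scores.shape[1])],
    )


def score_correlations(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation between two score (or size) vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("inputs must be equal-length vectors of length >= 3")
    if a.std() == 0 or b.std() == 0:
        raise DegenerateGeometryError("zero-variance input to correlation")
    return float(stats.pearsonr(a, b).statistic)
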