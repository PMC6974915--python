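"""End-to-end orchestration of the corolla shape analysis.

``run_pipeline`` executes the stages in dependency order — alignment (shape
and form), morphospaces and virtual flowers, evolutionary allometry, trait
quantification, trait-pollination association, phylogenetic signal, and
ancestral reconstruction — writing plain-text result files plus a manifest
with seeds, stage status and file checksums, so a run is reproducible from
its configuration alone.  Stage failures are recorded and dependent stages
skipped; a missing tree simply skips the comparative stages.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .allometry import allometry_test, select_median_specimens
from .association import group_comparisons, lod_permutation_test
from .data import SpecimenCollection, read_landmarks
from .errors import InsufficientSampleError
from .morphospace import build_morphospace, virtual_shape
from .phylo import (
    PhyloTree,
    ancestral_corollas,
    ancestral_trait_table,
    classify_ancestral_pollination,
    k_permutation_test,
    read_newick,
    reconstruction_uncertainty,
)
from .procrustes import full_gpa, partial_gpa
from .traits import TRAIT_COLUMNS, trait_table


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Inputs may be paths (landmark CSV, newick tree) or in-memory objects.
    Defaults follow the standard analysis settings: 10,000 permutations,
    k = 5 for ancestral pollination labelling, 100 subsampling repetitions
    drawing 3 of the 5 median-score specimens per species.
    """

    landmarks: object = None           # path or SpecimenCollection
    tree: object = None                # path or PhyloTree, optional
    out_dir: object = "results"
    n_permutations: int = 10_000
    seed: int = 0
    n_components_report: int = 4
    knn_k: int = 5
    reps: int = 100
    subsample: int = 3
    median_subset_n: int = 5
    uncertainty: bool = False

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            return cls(**json.load(fh))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_configs_csv(path: Path, configs: dict[str, np.ndarray]) -> None:
    rows = []
    for name, cfg in configs.items():
        for lid, (x, y, z) in enumerate(np.asarray(cfg)):
            rows.append({"name": name, "landmark_id": lid, "x": x, "y": y, "z": z})
    pd.DataFrame(rows).to_csv(path, index=False)


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages; returns the manifest (also written to manifest.json)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "n_permutations": config.n_permutations,
        "stages": {},
        "files": {},
    }
    results: dict = {}

    def record(stage: str, status: str, note: str = "") -> None:
        manifest["stages"][stage] = {"status": status, **({"note": note} if note else {})}

    def save_df(name: str, df: pd.DataFrame) -> None:
        path = out / name
        df.to_csv(path, index=False)
        manifest["files"][name] = _sha256(path)

    def save_json(name: str, obj) -> None:
        path = out / name
        path.write_text(json.dumps(obj, indent=2, default=float) + "\n")
        manifest["files"][name] = _sha256(path)

    # -- load ---------------------------------------------------------------
    collection = config.landmarks
    if not isinstance(collection, SpecimenCollection):
        collection = read_landmarks(collection)
    tree = config.tree
    if tree is not None and not isinstance(tree, PhyloTree):
        tree = read_newick(tree)
    record("load", "ok")

    # -- alignment + morphospaces --------------------------------------------
    spaces = {}
    try:
        for mode, align in (("shape", full_gpa), ("form", partial_gpa)):
            ensemble = align(collection)
            space = build_morphospace(ensemble)
            spaces[mode] = (ensemble, space)
            scores = pd.DataFrame(
                space.scores,
                columns=[f"PC{i + 1}" for i in range(space.n_components)],
            )
            scores.insert(0, "specimen_id", space.specimen_ids)
            scores.insert(1, "species", space.species)
            scores.insert(2, "pollination", space.pollination)
            scores.insert(3, "centroid_size", ensemble.centroid_sizes)
            save_df(f"scores_{mode}.csv", scores)
            virtual = {}
            for pc in range(min(config.n_components_report, space.n_components)):
                for sd in (-2.0, 0.0, 2.0):
                    virtual[f"PC{pc + 1}_{sd:+.0f}sd"] = virtual_shape(space, pc, sd)
            _write_configs_csv(out / f"virtual_{mode}.csv", virtual)
            manifest["files"][f"virtual_{mode}.csv"] = _sha256(out / f"virtual_{mode}.csv")
            save_json(
                f"morphospace_{mode}.json",
                {
                    "variance_fractions": space.variance_fractions.tolist(),
                    "iterations_used": ensemble.iterations_used,
                    "converged": bool(ensemble.converged),
                },
            )
        record("morphospace", "ok")
    except Exception as exc:  # noqa: BLE001 - recorded, downstream skipped
        record("morphospace", "failed", str(exc))
        save_json("manifest.json", manifest)
        return manifest

    shape_ens, shape_space = spaces["shape"]
    form_ens, form_space = spaces["form"]

    # -- allometry ------------------------------------------------------------
    try:
        allo = allometry_test(
            shape_ens, n_permutations=config.n_permutations, seed=config.seed
        )
        save_json(
            "allometry.json",
            {
                "r": allo.r,
                "r_squared": allo.r_squared,
                "p_value": allo.p_value,
                "n_permutations": allo.n_permutations,
            },
        )
        record("allometry", "ok")
        results["allometry"] = allo
    except Exception as exc:  # noqa: BLE001
        allo = None
        record("allometry", "failed", str(exc))

    # -- traits + association -------------------------------------------------
    try:
        traits = trait_table(collection)
        save_df("traits.csv", traits)
        record("traits", "ok")
        results["traits"] = traits
    except Exception as exc:  # noqa: BLE001
        traits = None
        record("traits", "failed", str(exc))

    if traits is not None and traits["error"].isna().all() and len(set(collection.pollination)) >= 2:
        assoc = {}
        labels = traits["pollination"].to_numpy()
        for i, col in enumerate(["centroid_size", *TRAIT_COLUMNS]):
            res = lod_permutation_test(
                traits[col].to_numpy(), labels,
                n_permutations=config.n_permutations,
                seed=config.seed + 1 + i, trait_name=col,
            )
            gc = group_comparisons(traits[col].to_numpy(), labels)
            assoc[col] = {
                "lod": res.lod,
                "p_value": res.p_value,
                "kruskal_H": float(gc.loc[0, "statistic"]),
                "kruskal_p": float(gc.loc[0, "p_value"]),
            }
        save_json("association.json", assoc)
        record("association", "ok")
        results["association"] = assoc
    else:
        record("association", "skipped", "traits unavailable or <2 pollination groups")

    # -- comparative stages ----------------------------------------------------
    if tree is None:
        record("phylo_signal", "skipped", "no tree supplied")
        record("ancestral", "skipped", "no tree supplied")
        save_json("manifest.json", manifest)
        results["manifest"] = manifest
        return manifest

    try:
        subset = collection
        try:
            keep = select_median_specimens(shape_ens, n=config.median_subset_n)
            subset = collection.subset(keep)
        except InsufficientSampleError:
            pass  # keep every specimen when species are too small
        sub_traits = trait_table(subset)
        means = sub_traits.groupby("species")[["centroid_size", *TRAIT_COLUMNS]].mean()
        signal = {}
        for i, col in enumerate(means.columns):
            res = k_permutation_test(
                tree, means[col],
                n_permutations=config.n_permutations, seed=config.seed + 100 + i,
            )
            signal[col] = {"K": res["K"], "p_value": res["p_value"]}
        save_json("phylo_signal.json", signal)
        record("phylo_signal", "ok")
        results["phylo_signal"] = signal
    except Exception as exc:  # noqa: BLE001
        subset = collection
        record("phylo_signal", "failed", str(exc))

    try:
        ancestral: dict = {}
        for mode in ("shape", "form"):
            recon, ens = ancestral_corollas(subset, tree, mode=mode)
            _write_configs_csv(
                out / f"ancestral_landmarks_{mode}.csv",
                {n: recon.node_values[n] for n in recon.internal_ids},
            )
            manifest["files"][f"ancestral_landmarks_{mode}.csv"] = _sha256(
                out / f"ancestral_landmarks_{mode}.csv"
            )
            space = shape_space if mode == "shape" else form_space
            nc = min(config.n_components_report, space.n_components)
            extant = space.scores[:, :nc]
            mu, sd = extant.mean(axis=0), extant.std(axis=0, ddof=1)
            anc_configs = np.stack([recon.node_values[n] for n in recon.internal_ids])
            anc_scores = (space.project(anc_configs)[:, :nc] - mu) / sd
            labels = classify_ancestral_pollination(
                (extant - mu) / sd, space.pollination, anc_scores, k=config.knn_k
            )
            ancestral[mode] = dict(zip(recon.internal_ids, labels))
            if mode == "form":
                save_df("ancestral_traits.csv", ancestral_trait_table(recon, collection.template))
            if config.uncertainty:
                unc = reconstruction_uncertainty(
                    subset, tree, mode=mode, reps=config.reps,
                    subsample=config.subsample, seed=config.seed + 200,
                )
                ancestral[f"{mode}_mean_node_sd"] = {
                    n: float(np.mean(unc.per_node_sd[n])) for n in unc.internal_ids
                }
        save_json("ancestral_pollination.json", ancestral)
        record("ancestral", "ok")
        results["ancestral"] = ancestral
    except Exception as exc:  # noqa: BLE001
        record("ancestral", "failed", str(exc))

    save_json("manifest.json", manifest)
    results["manifest"] = manifest
    return manifest
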