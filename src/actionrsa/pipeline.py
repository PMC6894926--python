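"""End-to-end synthetic pipeline and input validation.

``run_pipeline`` chains the stages — simulate latent structure and
behavior, build the model set, plant brain patterns, run the surface
searchlight RSA, group permutation inference, and geometry
characterization — into a run directory of plain-text artifacts with a
manifest of seeds and content hashes, so a rerun with the same
configuration is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .arrangement import ArrangementSession, aggregate_session, simulate_arranger
from .characterize import classical_mds, roi_geometry, silhouette_select_k
from .config import PipelineConfig
from .design import generate_trial_sequence, read_events_tsv, write_events_tsv
from .ground_truth import make_ground_truth
from .hmax import hmax_rdm
from .images import make_synthetic_images, normalize_luminance
from .inference import cluster_permutation, group_t_map
from .models import ModelSet, binary_feature_rdm, rating_rdm, RatingSet
from .patterns import plant_brain_patterns
from .rdm import RDM, normalize_rdm
from .searchlight import BetaDataset, build_searchlights, standard_rsa_map
from .surface import make_toy_surface

__all__ = ["run_pipeline", "validate_inputs", "build_demo_model_set"]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def build_demo_model_set(cfg: PipelineConfig):
    """Model set for the synthetic pipeline, plus its ground truth.

    The semantic model is the group aggregate of simulated arrangement
    sessions over the planted ground truth; body/scene/movement/object
    come from independent latent configurations (simulating the other
    arrangement tasks); sociality/transitivity/distance from simulated
    Likert ratings; the people model from an alternating binary label;
    hmax_c1 from the synthetic image families. Returns
    ``(model_set, ground_truth)``.
    """
    gt = make_ground_truth(cfg.n_items, cfg.n_clusters, cfg.cluster_spread,
                           cfg.within_spread, cfg.latent_dim,
                           seed=cfg.seeds.ground_truth)
    items = gt.items
    rng = np.random.default_rng(cfg.seeds.arrangement)
    sessions = [
        simulate_arranger(gt.true_rdm, cfg.arranger_noise_sd,
                          time_budget_trials=cfg.arrangement_trials,
                          seed=int(rng.integers(2 ** 31)),
                          subject=f"sub{s + 1:02d}")
        for s in range(cfg.n_subjects)
    ]
    subj_rdms = [aggregate_session(s) for s in sessions]
    semantic = normalize_rdm(RDM(items,
                                 np.mean([r.values for r in subj_rdms], axis=0),
                                 {"model": "semantic", "level": "group"}))
    models: dict[str, RDM] = {"semantic": semantic}
    # other arrangement tasks: distinct latent structures (cluster count,
    # scatter, dimensionality) so the model set is not strongly collinear
    task_structure = {"body": (4, 3, 1.2), "scene": (5, 2, 0.9),
                      "movement": (3, 3, 1.5), "object": (7, 2, 0.8)}
    for i, (name, (k, dim, spread)) in enumerate(task_structure.items()):
        alt = make_ground_truth(cfg.n_items, k, cfg.cluster_spread,
                                spread, dim,
                                seed=cfg.seeds.ground_truth + 101 + i)
        models[name] = alt.true_rdm.copy(model=name)
    rat_rng = np.random.default_rng(cfg.seeds.ground_truth + 500)
    for name, (lo, hi) in (("sociality", (1, 7)), ("transitivity", (1, 7)),
                           ("distance", (1, 3))):
        base = rat_rng.integers(lo, hi + 1, size=cfg.n_items)
        scores = np.clip(base + rat_rng.integers(-1, 2, size=(10, cfg.n_items)),
                         lo, hi)
        rs = RatingSet(pd.DataFrame(scores, columns=list(items)),
                       scale=(lo, hi), name=name)
        models[name] = rating_rdm(rs)[1]
    people = {it: int(i % 2) for i, it in enumerate(items)}
    models["people"] = binary_feature_rdm(people)
    stack = make_synthetic_images(cfg.n_items, n_exemplars=2,
                                  seed=cfg.seeds.images)
    stack, _ = normalize_luminance(stack)
    hm = hmax_rdm(stack)
    models["hmax_c1"] = RDM(items, hm.values, hm.meta)
    return ModelSet(models), gt


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run every stage and write artifacts + manifest into ``out_dir``."""
    cfg = config
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # stage 1: events (the fMRI design the simulated session would use)
    session_events = generate_trial_sequence(cfg.design, seed=cfg.seeds.design)
    write_events_tsv(session_events, out / "events.tsv")

    # stage 2: models from simulated behavior, images and ratings
    models, gt = build_demo_model_set(cfg)
    models.save(out / "models")

    # stage 3: toy surface with one planted semantic region. The brain
    # carries the ground-truth geometry; the behavioral semantic model is
    # its (noisy) estimate, as in a real study.
    mesh = make_toy_surface(cfg.mesh_subdivisions, n_regions=1,
                            region_size=cfg.region_size,
                            seed=cfg.seeds.surface)
    mesh.to_obj(out / "surface.obj")
    np.savetxt(out / "region_map.tsv", mesh.region_map, fmt="%d")
    planted = ModelSet({"semantic": gt.true_rdm.copy(model="semantic")})
    datasets = plant_brain_patterns(mesh, planted, {1: {"semantic": 1.0}},
                                    n_subjects=cfg.n_subjects,
                                    n_runs=cfg.n_runs,
                                    noise_sd=cfg.pattern_noise_sd,
                                    seed=cfg.seeds.patterns)
    datasets = [BetaDataset(d.subject, d.betas, models.items, mesh)
                for d in datasets]

    # stage 4: searchlight standard RSA, semantic model
    sls = build_searchlights(mesh, cfg.searchlight_features)
    maps = [standard_rsa_map(ds, models["semantic"], sls) for ds in datasets]
    map_frame = pd.DataFrame({m.meta["subject"]: m.values for m in maps})
    map_frame.to_csv(out / "subject_maps.tsv", sep="\t", index_label="vertex")

    # stage 5: group inference
    result = cluster_permutation(maps, mesh, n_perm=cfg.n_perm,
                                 p0=cfg.initial_p,
                                 seed=cfg.seeds.permutation)
    result.cluster_table().to_csv(out / "clusters.tsv", sep="\t", index=False)
    pd.DataFrame({"t": result.t_map.values,
                  "z": result.z_map.values}).to_csv(
        out / "group_maps.tsv", sep="\t", index_label="vertex")

    # stage 6: characterization
    semantic = models["semantic"]
    emb = classical_mds(semantic, k=3)
    emb.to_frame().to_csv(out / "mds_coords.tsv", sep="\t")
    best_k, curve, solution = silhouette_select_k(
        emb.coords, cfg.k_range, cfg.kmeans_restarts, seed=cfg.seeds.clustering)
    curve.to_csv(out / "silhouette_curve.tsv", sep="\t",
                 index_label="k")
    roi = roi_geometry(datasets, mesh, result.t_map, models,
                       roi_size=cfg.searchlight_features)
    roi.mean_tau.to_csv(out / "roi_model_tau.tsv", sep="\t",
                        index_label="model")
    (out / "roi_dendrogram.newick").write_text(roi.newick)

    cfg.to_yaml(out / "config.yaml")
    artifacts = sorted(p.name for p in out.iterdir() if p.is_file())
    manifest = {
        "package_version": __version__,
        "config": "config.yaml",
        "best_k": int(best_k),
        "n_significant_clusters": len(result.significant_clusters),
        "hashes": {name: _sha256(out / name) for name in artifacts},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def validate_inputs(paths: list[str | Path]) -> list[dict]:
    """Check files against their format contracts; collect, don't abort.

    Returns one report entry per file: ``{"path", "kind", "ok", "errors"}``.
    """
    report = []
    for p in paths:
        p = Path(p)
        entry = {"path": str(p), "kind": "unknown", "ok": False, "errors": []}
        try:
            if not p.exists():
                entry["errors"].append("file not found")
            elif p.suffix == ".json":
                entry["kind"] = "arrangement_session"
                ArrangementSession.from_json(p)
                entry["ok"] = True
            elif p.suffix == ".obj":
                entry["kind"] = "surface_mesh"
                from .surface import SurfaceMesh
                SurfaceMesh.from_obj(p)
                entry["ok"] = True
            elif p.suffix == ".tsv":
                head = p.read_text().splitlines()[0] if p.stat().st_size else ""
                if "onset" in head:
                    entry["kind"] = "events"
                    read_events_tsv(p)
                else:
                    entry["kind"] = "rdm"
                    mat = pd.read_csv(p, sep="\t", index_col=0)
                    v = mat.to_numpy(dtype=float)
                    asym = np.argwhere(~np.isclose(v, v.T, rtol=1e-8))
                    if asym.size:
                        cells = [f"({mat.index[i]},{mat.columns[j]})"
                                 for i, j in asym[:5]]
                        raise ValueError(f"asymmetric cells {cells}")
                    RDM(tuple(mat.index), v)
                entry["ok"] = True
            else:
                entry["errors"].append(f"unrecognized extension {p.suffix!r}")
        except Exception as exc:  # noqa: BLE001 - report, don't abort
            entry["errors"].append(str(exc))
        report.append(entry)
    return report
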