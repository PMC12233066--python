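"""End-to-end orchestration: simulate → segment → measure → profile →
analyze (→ train/cv), with a JSON manifest tying every output to its
config hash and seeds.  Rerunning with an identical config reproduces all
tabular outputs bit-identically."""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

from ._model import config_hash, derive_seed
from .analyze import write_analysis_outputs
from .classify import build_training_sets, cross_validate, train_category_model
from .config import RunConfig
from .morphometry import CellTable, measure_image
from .profiling import pool_condition, profile_conditions
from .segment import segment
from .synth import simulate_image, write_outputs

logger = logging.getLogger(__name__)


def run_pipeline(cfg: RunConfig, out_dir: str | Path) -> dict:
    """Execute every configured stage; returns (and writes) the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": cfg.hash,
        "seed": cfg.seed,
        "stages": {},
        "outputs": {},
        "conditions": {},
    }

    tables_by_condition: dict[str, list[CellTable]] = {}
    t0 = time.perf_counter()
    img_dir = out / "images"
    seg_dir = out / "segmentation"
    cell_dir = out / "cells"
    cell_dir.mkdir(parents=True, exist_ok=True)
    for cond in cfg.conditions:
        tables_by_condition[cond.name] = []
        for rep in range(cond.replicates):
            well_id = f"{cond.name}-r{rep + 1}"
            seed = derive_seed(cfg.seed, f"synth:{cond.name}:{rep}")
            spec = cond.synth.model_copy(update={"seed": seed})
            image, gt = simulate_image(spec)
            paths = write_outputs(img_dir, well_id, image, gt)
            lm = segment(image, cfg.segmentation, source_id=well_id)
            seg_dir.mkdir(parents=True, exist_ok=True)
            lm.write_qc(seg_dir / f"{well_id}_qc.json")
            import tifffile

            tifffile.imwrite(
                seg_dir / f"{well_id}_labels.tif",
                lm.labels.astype("uint16"),
            )
            table = measure_image(
                lm.labels,
                cfg.calibration,
                well_id=well_id,
                condition=cond.name,
                metadata={"source_image": paths["image"]},
            )
            table.to_csv(cell_dir / f"{well_id}_cells.csv")
            tables_by_condition[cond.name].append(table)
            manifest["conditions"].setdefault(cond.name, {})[well_id] = {
                "n_cells_ground_truth": gt.n_cells,
                "n_regions": lm.n_regions,
                "synth_seed": seed,
            }
    manifest["stages"]["simulate_segment_measure"] = round(
        time.perf_counter() - t0, 3
    )

    t0 = time.perf_counter()
    prof_cfg = cfg.profiling.model_copy(
        update={"seed": derive_seed(cfg.seed, "profile")}
    )
    matrix = profile_conditions(tables_by_condition, prof_cfg)
    profiles_path = out / "profiles.csv"
    matrix.to_csv(profiles_path)
    matrix.write_sidecar(
        out / "profiles_meta.json",
        {"profiling_config_hash": config_hash(prof_cfg), "seed": prof_cfg.seed},
    )
    manifest["outputs"]["profiles"] = str(profiles_path)
    for cond in cfg.conditions:
        manifest["conditions"][cond.name]["n_profiles"] = int(
            (matrix.conditions == cond.name).sum()
        )
    manifest["stages"]["profile"] = round(time.perf_counter() - t0, 3)

    t0 = time.perf_counter()
    analysis_paths = write_analysis_outputs(
        matrix,
        out / "analysis",
        standardize_features=cfg.analysis.standardize,
        umap_seed=derive_seed(cfg.seed, "umap") if cfg.analysis.umap else None,
        umap_n_neighbors=cfg.analysis.umap_n_neighbors,
        make_figure=cfg.analysis.figure,
    )
    manifest["outputs"].update(analysis_paths)
    manifest["stages"]["analyze"] = round(time.perf_counter() - t0, 3)

    if cfg.classifier is not None and len(cfg.conditions) >= 2:
        t0 = time.perf_counter()
        clf_cfg = cfg.classifier.model_copy(
            update={
                "categories": tuple(c.name for c in cfg.conditions),
                "seed": derive_seed(cfg.seed, "classifier"),
            }
        )
        pools = {
            name: pool_condition(tables, prof_cfg)
            for name, tables in tables_by_condition.items()
        }
        training = build_training_sets(pools, clf_cfg)
        training.to_csv(out / "training_profiles.csv")
        model = train_category_model(training, cfg=clf_cfg)
        model_dir = out / "model"
        model_dir.mkdir(parents=True, exist_ok=True)
        model.save(model_dir / "category_model.pkl")
        import pandas as pd

        pd.DataFrame(
            {
                "feature": list(model.feature_names),
                "importance": model.importances,
            }
        ).to_csv(out / "feature_importances.csv", index=False)
        cv = cross_validate(training, cfg=clf_cfg)
        cv.confusion.to_csv(out / "cv_confusion.csv")
        manifest["outputs"]["training_profiles"] = str(out / "training_profiles.csv")
        manifest["outputs"]["cv_confusion"] = str(out / "cv_confusion.csv")
        manifest["classifier"] = {
            "cv_accuracy": cv.accuracy,
            "config_hash": config_hash(clf_cfg),
        }
        manifest["stages"]["classify"] = round(time.perf_counter() - t0, 3)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
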