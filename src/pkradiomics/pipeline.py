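"""End-to-end pipeline: simulate -> fit-pk -> segment -> extract -> reduce
-> model, as one reproducible run.

Every stochastic stage draws its seed from the master seed through a
spawned SeedSequence, so a run is bit-identical under a fixed config.  The
run directory holds the feature table (CSV), per-task reduced sets and
final models (JSON), the AUC-vs-order curves (CSV) and a manifest (JSON)
recording all parameter values and derived seeds.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .features import IMAGE_NAMES, extract_all
from .modeling import (LogisticModel, bonferroni_flags, build_models,
                       mann_whitney_u, reduce_features, select_final_model)
from .pk import compute_pk_maps
from .segment import TumorMask, resample_mask, segment_lesion
from .synthetic import CohortSpec, Phantom, PhantomSpec, generate_cohort
from .volume import write_series, write_volume

log = logging.getLogger("pkradiomics")

__all__ = ["RunConfig", "run_pipeline", "phantom_features",
           "lesion_bbox_from_truth"]


@dataclass(frozen=True)
class RunConfig:
    """Parameters of one full synthetic-cohort run."""

    cohort: CohortSpec = field(default_factory=CohortSpec)
    segmentation_threshold: float = 0.75
    n_reduced: int = 25
    max_order: int = 10
    n_boot: int = 1000
    delta: float = 0.5
    seed: int = 0
    write_volumes: bool = False

    def to_dict(self) -> dict:
        def plain(obj):
            if isinstance(obj, dict):
                return {k: plain(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple, np.ndarray)):
                return [plain(v) for v in obj]
            if isinstance(obj, np.generic):
                return obj.item()
            return obj

        return plain(dataclasses.asdict(self))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "cohort" in d:
            c = dict(d["cohort"])
            if "template" in c:
                t = dict(c["template"])
                for key in ("grid_shape", "spacing", "lesion_center",
                            "flip_angles"):
                    if key in t:
                        t[key] = tuple(t[key])
                c["template"] = PhantomSpec(**t)
            if "tasks" in c:
                c["tasks"] = tuple(c["tasks"])
            d["cohort"] = CohortSpec(**c)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def lesion_bbox_from_truth(phantom: Phantom, margin: int = 2):
    """Bounding box around the truth lesion, with a margin, clipped to the
    grid — the synthetic stand-in for the radiologist's rectangle."""
    pos = np.argwhere(phantom.mask.data > 0)
    lo = np.maximum(pos.min(axis=0) - margin, 0)
    hi = np.minimum(pos.max(axis=0) + 1 + margin, phantom.mask.shape)
    return (*lo.tolist(), *hi.tolist())


def phantom_features(phantom: Phantom, threshold: float = 0.75,
                     n_boot_unused=None) -> dict[str, float]:
    """Segment one phantom, fit its maps and extract the 163 features."""
    spec = phantom.spec
    bbox = lesion_bbox_from_truth(phantom)
    mask = segment_lesion(phantom.series, bbox, threshold=threshold)
    maps = compute_pk_maps(phantom.series, phantom.vfa,
                           aif_from_spec(spec), roi=bbox, TR=spec.TR,
                           r1_relaxivity=spec.r1_relaxivity,
                           onset_s=spec.onset_s,
                           dynamic_flip_angle=spec.dynamic_flip_angle)
    images = dict(maps.as_dict())
    images["tirm"] = phantom.tirm
    images["postc"] = phantom.postc
    masks = {name: mask for name in IMAGE_NAMES if name not in
             ("tirm", "postc")}
    masks["tirm"] = resample_mask(mask, phantom.tirm)
    masks["postc"] = resample_mask(mask, phantom.postc)
    return extract_all(images, masks, shape_mask=mask)


def aif_from_spec(spec: PhantomSpec):
    from .aif import AIFModel
    return AIFModel(onset_time=spec.onset_s)


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute all stages; returns a results dict and writes the run dir."""
    t0 = time.time()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": _pkg_version, "config": config.to_dict(),
                      "stages": {}}

    log.info("simulating cohort: %d lesions, tasks %s",
             config.cohort.n_lesions, list(config.cohort.tasks))
    cohort_spec = dataclasses.replace(config.cohort, seed=config.seed)
    phantoms, labels = generate_cohort(cohort_spec)
    labels.to_csv(out / "labels.csv", index=False)
    manifest["stages"]["simulate"] = {"n_lesions": len(phantoms),
                                      "seed": config.seed}
    if config.write_volumes:
        vol_dir = out / "volumes"
        vol_dir.mkdir(exist_ok=True)
        for i, ph in enumerate(phantoms):
            write_series(ph.series, vol_dir / f"lesion{i:03d}_dyn.nii.gz")
            write_volume(ph.mask, vol_dir / f"lesion{i:03d}_truthmask.nii.gz")

    log.info("segmenting, fitting and extracting features")
    rows = []
    for i, ph in enumerate(phantoms):
        feats = phantom_features(ph, threshold=config.segmentation_threshold)
        feats["lesion_id"] = i
        rows.append(feats)
    table = pd.DataFrame(rows).set_index("lesion_id").sort_index()
    table.to_csv(out / "features.csv")
    n_feat = table.shape[1]
    manifest["stages"]["extract"] = {"n_features": n_feat}
    log.info("feature table: %d lesions x %d features", len(table), n_feat)

    ss = np.random.SeedSequence(config.seed)
    results: dict = {"feature_table": table, "labels": labels, "tasks": {}}
    for task in config.cohort.tasks:
        task_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2 ** 31))
        y = labels[labels.task == task].sort_values("lesion_id")[
            "label"].to_numpy()
        log.info("task %s: reducing %d -> %d features", task, n_feat,
                 config.n_reduced)
        reduced = reduce_features(table, y, k=config.n_reduced,
                                  n_boot=config.n_boot, seed=task_seed,
                                  delta=config.delta)
        (out / f"reduced_{task}.json").write_text(reduced.to_json())

        log.info("task %s: stepwise 0.632+ models up to order %d", task,
                 config.max_order)
        per_order, curve = build_models(reduced, table, y,
                                        max_order=config.max_order,
                                        n_boot=config.n_boot, seed=task_seed)
        pd.DataFrame({"order": np.arange(1, len(curve) + 1),
                      "auc": curve}).to_csv(out / f"auc_curve_{task}.csv",
                                            index=False)
        model, perf = select_final_model(per_order, curve, table, y,
                                         n_boot=config.n_boot,
                                         seed=task_seed, outcome_name=task)
        (out / f"model_{task}.json").write_text(model.to_json())

        pvals = np.array([mann_whitney_u(table[f][y == 0],
                                         table[f][y == 1])["p"]
                          for f in reduced.features])
        flags = bonferroni_flags(pvals)
        univar = pd.DataFrame({"feature": reduced.features, "p": pvals,
                               "bonferroni_significant": flags})
        univar.to_csv(out / f"univariate_{task}.csv", index=False)

        results["tasks"][task] = {"reduced": reduced, "per_order": per_order,
                                  "curve": curve, "model": model,
                                  "performance": perf, "univariate": univar}
        manifest["stages"][f"task:{task}"] = {
            "seed": task_seed, "selected_order": model.order,
            "auc": perf.auc, "auc_se": perf.auc_se}

    manifest["runtime_s"] = round(time.time() - t0, 2)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    results["manifest"] = manifest
    return results
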