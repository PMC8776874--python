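"""End-to-end pipeline: extract -> train -> cluster -> label -> classify.

``run_pipeline`` ties the stages together on a phantom cohort (or volumes
loaded from disk), writes per-stage artifacts plus a provenance record, and
is bit-reproducible for a fixed configuration: every random choice flows
from the seeds recorded in the config.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import io as gio
from .classify import bootstrap_k_selection, composition, compositions_to_table, svm_loocv
from .clustering import DEFAULT_K, DEFAULT_K_GRID, TwoLevelHabitatClustering
from .features import normalize_stack, sample_features
from .stats import categorize_labels
from .synthetic import HabitatSpec, PhantomCohort, generate_cohort

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Serializable configuration for one pipeline run."""

    out_dir: str = "gliohab_run"
    cohort_csv: Optional[str] = None      # None -> simulate a phantom cohort
    volume_root: Optional[str] = None
    # simulation
    n_mutant: int = 30
    n_wildtype: int = 30
    volume_shape: tuple[int, int, int] = (48, 48, 48)
    raw_scale: bool = False
    # pipeline parameters
    stride: int = 4
    k_max: int = 20
    n_epochs: int = 50
    n_clusters: int = DEFAULT_K
    k_grid: tuple[int, ...] = DEFAULT_K_GRID
    n_bootstrap: int = 100
    alpha: float = 0.05
    include_age: bool = False
    svm_grid: str = "two-step"
    run_select_k: bool = False
    run_categorize: bool = True
    write_label_maps: bool = False
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**data)
        if isinstance(cfg.volume_shape, list):
            cfg.volume_shape = tuple(cfg.volume_shape)
        if isinstance(cfg.k_grid, list):
            cfg.k_grid = tuple(cfg.k_grid)
        return cfg

    def config_hash(self) -> str:
        """Hash of the scientific parameters (paths excluded, so the same
        analysis in two directories shares one hash)."""
        params = {k: v for k, v in self.to_dict().items()
                  if k not in ("out_dir", "cohort_csv", "volume_root")}
        return hashlib.sha256(
            json.dumps(params, sort_keys=True).encode()).hexdigest()[:12]


def _load_cohort_from_disk(config: PipelineConfig) -> list:
    table = gio.read_cohort_table(config.cohort_csv)
    root = Path(config.volume_root or ".")
    stacks = []
    for _, row in table.iterrows():
        stacks.append(gio.load_subject(
            root / str(row["subject_id"]), str(row["subject_id"]),
            idh_status=row["idh_status"],
            age=float(row["age"]) if "age" in table.columns and pd.notna(row.get("age")) else None))
    return stacks


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full habitat pipeline and write its artifacts.

    Stages: simulate/load -> normalize (raw-scale inputs) -> strided
    feature extraction -> SOM+K-means training -> tumor label maps ->
    compositions -> LOOCV SVM (-> optional bootstrap K selection,
    categorization).  Returns the report dict that is also written to
    ``metrics.json``; rerunning with the same config reproduces it
    bit-exactly.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config_hash": config.config_hash()}
    stage = "simulate/load"
    try:
        if config.cohort_csv is None:
            spec = HabitatSpec(shape=tuple(config.volume_shape),
                               raw_scale=config.raw_scale)
            cohort = generate_cohort(spec, config.n_mutant, config.n_wildtype,
                                     seed=config.seed)
            stacks = cohort.stacks
        else:
            cohort = None
            stacks = _load_cohort_from_disk(config)
        logger.info("stage %s: %d subjects", stage, len(stacks))

        stage = "normalize"
        if config.raw_scale or config.cohort_csv is not None:
            stacks = [normalize_stack(s) for s in stacks]

        stage = "extract"
        features = sample_features(stacks, stride=config.stride)
        report["n_feature_rows"] = int(len(features))
        logger.info("stage extract: %d rows", len(features))

        stage = "cluster"
        model = TwoLevelHabitatClustering(
            n_clusters=config.n_clusters, k_max=config.k_max,
            n_epochs=config.n_epochs, random_state=config.seed).fit(features.X)
        gio.save_model(model, out / "model.json")
        planes = model.som_.component_planes()
        np.savetxt(out / "component_planes.csv",
                   planes.reshape(planes.shape[0], -1).T, delimiter=",",
                   header=",".join(f"plane_{c}" for c in range(planes.shape[0])),
                   comments="")

        stage = "label"
        labeled = [model.label_volume(s) for s in stacks]
        if config.write_label_maps:
            for lv in labeled:
                gio.save_volume(lv.labels.astype(np.int16),
                                out / f"{lv.subject_id}_labels.nii.gz")

        stage = "compose"
        comps = [composition(lv, idh_status=s.idh_status, age=s.age)
                 for lv, s in zip(labeled, stacks)]
        comp_df = pd.DataFrame(
            [{"subject_id": c.subject_id, "idh_status": c.idh_status,
              **{f"p_{k + 1}": c.p[k] for k in range(config.n_clusters)}}
             for c in comps])
        comp_df.to_csv(out / "compositions.csv", index=False)

        stage = "classify"
        X, y, ids = compositions_to_table(comps)
        ages = [c.age for c in comps] if config.include_age else None
        cv = svm_loocv(X, y, subject_ids=ids, ages=ages, seed=config.seed,
                       grid=config.svm_grid)
        cv.folds.to_csv(out / "loocv_folds.csv", index=False)
        report["metrics"] = cv.metrics

        if config.run_select_k:
            stage = "select-k"
            feats = {}
            for k in config.k_grid:
                mk = TwoLevelHabitatClustering(
                    n_clusters=k, k_max=config.k_max, n_epochs=config.n_epochs,
                    random_state=config.seed)
                mk.som_ = model.som_  # level one is shared across K
                from .clustering import kmeans_protoclusters
                mk.labeling_ = kmeans_protoclusters(model.som_, k,
                                                    seed=config.seed)
                comps_k = [composition(mk.label_volume(s), idh_status=s.idh_status)
                           for s in stacks]
                feats[k], _, _ = compositions_to_table(comps_k)
            ksel = bootstrap_k_selection(feats, y, n_bootstrap=config.n_bootstrap,
                                         seed=config.seed, grid="none")
            ksel.replicates.to_csv(out / "k_selection_replicates.csv", index=False)
            ksel.summary.to_csv(out / "k_selection_summary.csv", index=False)
            report["k_selection"] = {
                str(k): float(ksel.summary.query("K == @k and metric == 'auc'")["mean"].iloc[0])
                for k in config.k_grid}

        if config.run_categorize:
            stage = "categorize"
            catmap = categorize_labels(comps, alpha=config.alpha)
            catmap.to_frame().to_csv(out / "label_categories.csv", index=False)
            report["categories"] = {str(k): v for k, v in sorted(catmap.categories.items())}

        stage = "provenance"
        provenance = {"config": config.to_dict(), "config_hash": config.config_hash(),
                      "n_subjects": len(stacks)}
        gio.write_json(provenance, out / "provenance.json")
        gio.write_json(report, out / "metrics.json")
    except Exception as exc:
        logger.error("pipeline failed at stage %r: %s", stage, exc)
        gio.write_json({"failed_stage": stage, "error": str(exc), **report},
                       out / "metrics.json")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    return report
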