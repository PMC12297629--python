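"""End-to-end pipeline: scores -> hot spots -> sTILCs -> model comparison.

Each stage reads and writes plain CSV/JSON/PNG artifacts so any stage can be
rerun from persisted intermediates, and a run is fully reproducible from its
config: every stochastic stage has an explicit seed and every output embeds
the config hash.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import clustering, encoder, hotspot, lattice, models, simulate

__all__ = ["RunConfig", "PipelineError", "run_full_pipeline",
           "stage_simulate", "stage_score", "stage_hotspot", "stage_cluster",
           "stage_model"]

REQUIRED_SEEDS = ("simulation", "encoder", "kmeans", "split", "model")


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage and offending id."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage {stage}] {message}")


@dataclass
class RunConfig:
    """All seeds, stage parameters and paths for one pipeline run."""

    seeds: dict = field(default_factory=dict)
    n_patients: int = 200
    weight_scheme: str = "queen"
    hot_threshold: float = hotspot.DEFAULT_HOT_THRESHOLD
    z_clip: float = 4.0
    block_px: int = 8
    resize_mode: str = "pad"
    pca_variance_target: float = 0.95
    pca_k_cap: int | None = None
    candidate_ks: tuple[int, ...] = clustering.DEFAULT_CANDIDATE_KS
    split_ratio: float = 0.2
    dca_grid: tuple[float, float, float] = (0.01, 0.99, 0.01)
    outdir: str = "results/run"
    patch_table: str | None = None  # read instead of simulating when set
    clinical_table: str | None = None

    def __post_init__(self) -> None:
        missing = [s for s in REQUIRED_SEEDS if s not in self.seeds]
        if missing:
            raise ValueError(f"config is missing seeds for {missing}; every "
                             "stochastic stage needs an explicit seed")
        self.candidate_ks = tuple(self.candidate_ks)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def config_hash(self) -> str:
        """Hash of the scientific settings (paths excluded): two runs with the
        same hash produce identical numbers wherever they are written."""
        payload = asdict(self)
        for key in ("outdir", "patch_table", "clinical_table"):
            payload.pop(key, None)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _write_csv(df: pd.DataFrame, path: Path, cfg_hash: str) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# config_hash={cfg_hash}\n")
        df.to_csv(fh, index=False)


def read_stage_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def stage_simulate(config: RunConfig, outdir: Path) -> simulate.SimulatedCohort:
    spec = simulate.CohortSpec(n_patients=config.n_patients,
                               seed=config.seeds["simulation"])
    cohort = simulate.generate_cohort(spec)
    simulate.write_cohort(cohort, outdir / "simulated")
    return cohort


def stage_score(grids: Sequence[lattice.PatchGrid], outdir: Path,
                cfg_hash: str) -> pd.DataFrame:
    try:
        scores = lattice.score_table(grids)
    except ValueError as exc:
        raise PipelineError("score", str(exc)) from exc
    _write_csv(scores, outdir / "til_scores.csv", cfg_hash)
    return scores


def stage_hotspot(grids: Sequence[lattice.PatchGrid], config: RunConfig,
                  outdir: Path, cfg_hash: str) -> list[hotspot.HotspotMap]:
    maps = []
    tables = []
    for g in grids:
        try:
            hmap = hotspot.compute_hotspot_map(
                g, scheme=config.weight_scheme,
                hot_threshold=config.hot_threshold)
        except ValueError as exc:
            raise PipelineError("hotspot", f"slide {g.slide_id}: {exc}") from exc
        maps.append(hmap)
        tables.append(hotspot.hotspot_table(hmap))
    _write_csv(pd.concat(tables, ignore_index=True),
               outdir / "gi_star.csv", cfg_hash)
    return maps


def stage_cluster(maps: Sequence[hotspot.HotspotMap], config: RunConfig,
                  outdir: Path, cfg_hash: str) -> clustering.SpatialFeatureSet:
    enc_cfg = encoder.EncoderConfig(weight_seed=config.seeds["encoder"])
    feats = []
    for hmap in maps:
        img = hotspot.render_hotspot_map(hmap, block_px=config.block_px,
                                         z_clip=config.z_clip)
        arr = encoder.preprocess_map_image(img, size=enc_cfg.input_size,
                                           resize_mode=config.resize_mode)
        feats.append(encoder.encode_hotspot_map(arr, enc_cfg))
    raw = np.vstack(feats)
    try:
        pca_model, reduced = clustering.fit_pca(
            raw, variance_target=config.pca_variance_target,
            k_cap=config.pca_k_cap)
        vote = clustering.consensus_k_selection(
            reduced, candidate_ks=config.candidate_ks,
            seed=config.seeds["kmeans"])
    except ValueError as exc:
        raise PipelineError("cluster", str(exc)) from exc
    labels = vote.selected_labels
    stilc = None
    if vote.selected_k == 2:
        stilc = clustering.assign_stilc_names(labels, maps)
    else:
        warnings.warn(f"consensus selected k={vote.selected_k}; "
                      "sTILC naming applies only to the two-cluster outcome")
    fs = clustering.SpatialFeatureSet(
        slide_ids=[m.slide_id for m in maps], raw_features=raw,
        pca_model=pca_model, pca_components=reduced, vote=vote,
        cluster_labels=labels, stilc_labels=stilc)
    _write_csv(clustering.cluster_assignment_table(fs),
               outdir / "stilc_assignments.csv", cfg_hash)
    return fs


def stage_model(clinical: pd.DataFrame, config: RunConfig, outdir: Path,
                cfg_hash: str) -> models.ModelComparisonReport:
    try:
        train, val = models.split_cohort(clinical, test_size=config.split_ratio,
                                         seed=config.seeds["split"])
        m1 = models.train_model(train, models.FEATURES_M1,
                                seed=config.seeds["model"])
        m2 = models.train_model(train, models.FEATURES_M2,
                                seed=config.seeds["model"])
        report = models.compare_models(
            m1, m2, {"training": train, "validation": val},
            max_shapley_records=200, seed=config.seeds["model"])
    except ValueError as exc:
        raise PipelineError("model", str(exc)) from exc
    payload = report.to_dict()
    payload["config_hash"] = cfg_hash
    payload["seeds"] = dict(config.seeds)
    payload["best_params"] = {"m1": m1.best_params, "m2": m2.best_params}
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "model_report.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
    _write_csv(report.shapley_values, outdir / "shapley_values.csv", cfg_hash)
    return report


def run_full_pipeline(config: RunConfig) -> models.ModelComparisonReport:
    """Execute score -> hotspot -> cluster -> model comparison in order.

    When ``config.patch_table`` is unset a synthetic cohort is simulated
    first. Re-running with an identical config reproduces identical outputs.
    """
    outdir = Path(config.outdir)
    cfg_hash = config.config_hash()

    if config.patch_table is None:
        cohort = stage_simulate(config, outdir)
        grids, clinical = cohort.grids, cohort.clinical.copy()
    else:
        grids = lattice.read_patch_table(config.patch_table)
        if config.clinical_table is None:
            raise PipelineError("model", "clinical_table required with patch_table")
        clinical = read_stage_csv(config.clinical_table)

    scores = stage_score(grids, outdir, cfg_hash)
    maps = stage_hotspot(grids, config, outdir, cfg_hash)
    fs = stage_cluster(maps, config, outdir, cfg_hash)

    # patient-level TIL score (mean over slides) and recomputed sTILC coding
    per_patient = scores.groupby("patient_id")["til_score"].mean()
    slide_patient = {g.slide_id: g.patient_id for g in grids}
    clinical = clinical.set_index("patient_id")
    clinical["til_score"] = per_patient
    if fs.stilc_labels is not None:
        stilc_code = pd.Series(
            [1 if s == clustering.STILC_COLD else 2 for s in fs.stilc_labels],
            index=[slide_patient[sid] for sid in fs.slide_ids],
        )
        clinical["stilc"] = stilc_code.groupby(level=0).max()
    clinical = clinical.reset_index()

    return stage_model(clinical, config, outdir, cfg_hash)
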