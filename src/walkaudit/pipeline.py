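"""End-to-end pipeline driver: region -> truth -> calls -> summaries ->
macro index -> perceptions -> validity matrix.

Every stage consumes a seed derived deterministically from the global
seed, so re-running an identical configuration reproduces all outputs
byte-identically.  Each output CSV starts with a provenance comment line
naming the config hash and seed; a JSON-lines log records stage events.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml

from walkaudit import audit, geosim, macroscale, neighborhood
from walkaudit.classify import ClassifierConfig, train_classifier
from walkaudit.evalstats import metrics_table, validity_matrix
from walkaudit.features import PRIMITIVE_FEATURES, StreetFeature
from walkaudit.geosim import HEADINGS, RegionConfig
from walkaudit.scenes import SceneSpec, generate_scene_dataset, render_scene


@dataclasses.dataclass(frozen=True)
class PipelineConfig:
    """Full configuration of one audit-pipeline run.

    ``classifier_mode``: "oracle" wires ground truth straight into the
    audit stage (tests aggregation and scoring in isolation); "trained"
    renders directional scenes for every coordinate and classifies them
    with freshly trained per-feature models.
    """

    seed: int = 0
    grid_rows: int = 25
    grid_cols: int = 25
    edge_length: float = 100.0
    bg_rows: int = 5
    bg_cols: int = 5
    n_participants: int = 200
    buffer_radius: float = 500.0
    threshold: float = 0.50
    classifier_mode: str = "oracle"  # oracle | trained
    n_train_scenes: int = 400
    n_val_scenes: int = 200
    scene_distractor_rate: float = 0.0
    perception_noise_sd: float = 1.0
    buffer_denominator: str = "all"
    # optional override of the planted per-feature baseline rates (string
    # feature names); None keeps the study-region defaults
    baseline_rates: dict | None = None

    def __post_init__(self) -> None:
        if self.classifier_mode not in ("oracle", "trained"):
            raise ValueError("classifier_mode must be 'oracle' or 'trained'")

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]

    def stage_seed(self, stage: str) -> int:
        digest = hashlib.sha1(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(digest[:4], "big") % (2**31)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


def _write_csv(df: pd.DataFrame, path: Path, cfg: PipelineConfig) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={cfg.hash()} seed={cfg.seed}\n")
        df.to_csv(fh, index=False)


def read_output_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


class _StageLog:
    def __init__(self, path: Path):
        self.path = path
        self.path.write_text("")

    def event(self, stage: str, **fields) -> None:
        with open(self.path, "a") as fh:
            fh.write(json.dumps({"stage": stage, **fields}, sort_keys=True) + "\n")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, original: Exception):
        super().__init__(f"stage '{stage}' failed: {original}")
        self.stage = stage


def _trained_probs(cfg: PipelineConfig, region, truth) -> pd.DataFrame:
    """Train per-feature classifiers on synthetic scenes, render each
    coordinate's four directional scenes from planted truth, classify."""
    prevalence = {f: 0.5 for f in PRIMITIVE_FEATURES}
    train = generate_scene_dataset(cfg.n_train_scenes, prevalence, cfg.scene_distractor_rate, seed=cfg.stage_seed("scenes-train"))
    val = generate_scene_dataset(cfg.n_val_scenes, prevalence, cfg.scene_distractor_rate, seed=cfg.stage_seed("scenes-val"))
    images = {**train.images, **val.images}
    loader = lambda sid: images[sid].image  # noqa: E731
    cache: dict = {}
    clf_cfg = ClassifierConfig(seed=cfg.stage_seed("classifier"))
    classifiers = {}
    for f in PRIMITIVE_FEATURES:
        classifiers[f], _ = train_classifier(train.manifest, val.manifest, f, clf_cfg, loader, cache)

    directional = truth.directional
    rows = []
    scene_seed = cfg.stage_seed("coordinate-scenes")
    backbone = classifiers[PRIMITIVE_FEATURES[0]].backbone
    for i, cid in enumerate(truth.presence.index):
        for h in HEADINGS:
            flags = {f: bool(directional.at[(cid, f.value), f"h{h}"]) for f in PRIMITIVE_FEATURES}
            spec = SceneSpec(feature_flags=flags, layout_seed=i * 4 + HEADINGS.index(h))
            img = render_scene(spec, seed=scene_seed).image
            feats = backbone.extract(img)[None, :]  # shared across features
            for f in PRIMITIVE_FEATURES:
                prob = float(classifiers[f].predict_proba_features(feats)[0])
                rows.append({"coordinate_id": cid, "feature": f.value, "heading": h, "prob": prob})
    long = pd.DataFrame(rows)
    wide = long.pivot_table(index=["coordinate_id", "feature"], columns="heading", values="prob")
    wide.columns = [f"h{h}" for h in wide.columns]
    return wide.reset_index()


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path) -> Path:
    """Execute all stages, writing manifests, calls, summaries, metrics,
    the validity matrix, and a JSON-lines log into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = _StageLog(out / "pipeline.log.jsonl")
    cfg.to_yaml(out / "config.yaml")

    stage = "region"
    try:
        region_cfg = RegionConfig(
            grid_rows=cfg.grid_rows,
            grid_cols=cfg.grid_cols,
            edge_length=cfg.edge_length,
            bg_rows=cfg.bg_rows,
            bg_cols=cfg.bg_cols,
        )
        region = geosim.simulate_region(region_cfg, seed=cfg.stage_seed("region"))
        geosim.write_region(region, out / "region")
        log.event(stage, coordinates=len(region.coordinates), block_groups=len(region.block_groups))

        stage = "participants"
        participants = geosim.sample_participants(region, cfg.n_participants, seed=cfg.stage_seed("participants"))
        log.event(stage, n=len(participants))

        stage = "planted-truth"
        rates = None
        if cfg.baseline_rates is not None:
            rates = {StreetFeature(k): v for k, v in cfg.baseline_rates.items()}
        truth = geosim.plant_prevalences(region, baseline_rates=rates, seed=cfg.stage_seed("truth"))
        log.event(stage, coordinates=len(truth.presence))

        stage = "classify"
        if cfg.classifier_mode == "oracle":
            probs = geosim.oracle_directional_probs(truth)
        else:
            probs = _trained_probs(cfg, region, truth)
        log.event(stage, mode=cfg.classifier_mode, rows=len(probs))

        stage = "audit"
        ctypes = region.coordinates.set_index("coordinate_id")["type"]
        calls = audit.call_coordinates(probs, ctypes, threshold=cfg.threshold)
        _write_csv(calls, out / "calls.csv", cfg)
        log.event(stage, calls=len(calls))

        stage = "call-metrics"
        perf = metrics_table(truth.presence, calls)
        _write_csv(perf, out / "call_metrics.csv", cfg)

        stage = "buffers"
        buffers = {
            r.participant_id: geosim.network_buffer(region, r.home_node, cfg.buffer_radius)
            for r in participants.itertuples(index=False)
        }
        log.event(stage, mean_size=float(pd.Series([len(b) for b in buffers.values()]).mean()))

        stage = "summarize"
        summaries = neighborhood.summarize_neighborhoods(
            calls, buffers, ctypes, buffer_denominator=cfg.buffer_denominator
        )
        _write_csv(summaries, out / "summaries.csv", cfg)

        stage = "macro"
        macro = macroscale.macro_components_for_participants(region, participants, radius=cfg.buffer_radius)
        _write_csv(macro, out / "macro.csv", cfg)
        if len(region.block_groups) >= 10:
            bg_macro = macroscale.macro_components_for_block_groups(region)
            strata = macroscale.stratify(
                region.block_groups.set_index("block_group_id")["median_income"],
                bg_macro["walkability_index"],
            )
            _write_csv(strata.reset_index(), out / "strata.csv", cfg)
        else:
            log.event("strata", skipped="fewer than 10 block groups; deciles undefined")

        stage = "perceptions"
        perceived = geosim.simulate_perceptions(
            truth, region, participants, noise_sd=cfg.perception_noise_sd, seed=cfg.stage_seed("perceptions")
        )
        _write_csv(perceived, out / "perceived.csv", cfg)

        stage = "validity"
        matrix = validity_matrix(summaries, macro, perceived)
        _write_csv(matrix, out / "validity_matrix.csv", cfg)
        log.event(stage, cells=len(matrix))
    except Exception as exc:  # noqa: BLE001 - rewrap with stage context
        raise PipelineError(stage, exc) from exc

    log.event("done")
    return out
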