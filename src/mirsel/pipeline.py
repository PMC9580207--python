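"""End-to-end pipeline driver: simulate/load → screen → select → Cox filter.

Stage order follows the discovery procedure: (optional) preprocessing, seed
search for the screening split, bootstrap ensemble on the winning split,
frequency/participation feature selection, multivariate Cox fit, biomarker
filter — with every intermediate artifact written as TSV/JSON under a run
directory, plus a manifest recording the config hash, seeds and thresholds.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import data_io
from .cohort import ExpressionCohort
from .cox import fit_cox, filter_biomarkers
from .ensemble import seed_search, train_ensemble
from .feature_selection import (
    count_frequencies,
    select_features,
    select_per_subtype,
    subtype_participation_counts,
    write_panel,
)
from .penalized_mlr import PenaltyConfig
from .sampling import round_half_up, stratified_split
from .simulate import SimulationConfig, generate_cohort

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; partial artifacts are left in the run dir."""


@dataclass(frozen=True)
class PipelineConfig:
    """Everything the end-to-end run needs; see module docstring for stages."""

    out_dir: str = "runs/run"
    # either simulate…
    simulation: SimulationConfig | None = None
    # …or load from disk
    expression_path: str | None = None
    labels_path: str | None = None
    clinical_path: str | None = None
    raw_scale: bool = False  # apply the 1%-zeros filter + log2 when loading raw data
    max_nonexpressed_frac: float = 0.01

    penalty: PenaltyConfig = PenaltyConfig()
    M: int = 100
    n_repeats: int = 50
    train_frac: float = 0.8
    frequency_threshold: int | None = None  # default: round(M/2)
    min_subtypes: int = 3
    coef_thresh: float = 0.2
    p_thresh: float = 0.05
    cox_ridge: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.simulation is None and self.expression_path is None:
            raise ValueError("need either a simulation config or input paths")
        if not 1 <= self.min_subtypes <= 5:
            raise ValueError("min_subtypes must lie in 1..5")
        thr = self.resolved_frequency_threshold()
        if not 0 <= thr <= self.M:
            raise ValueError("frequency threshold must lie in [0, M]")
        if self.coef_thresh < 0 or not 0 < self.p_thresh <= 1:
            raise ValueError("invalid Cox thresholds")

    def resolved_frequency_threshold(self) -> int:
        if self.frequency_threshold is not None:
            return self.frequency_threshold
        return round_half_up(self.M / 2)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "simulation" in raw and raw["simulation"] is not None:
            sim = dict(raw["simulation"])
            if "n_per_subtype" in sim:
                sim["n_per_subtype"] = tuple(sim["n_per_subtype"])
            raw["simulation"] = SimulationConfig(**sim)
        if "penalty" in raw and raw["penalty"] is not None:
            pen = dict(raw["penalty"])
            if "alpha_grid" in pen:
                pen["alpha_grid"] = tuple(pen["alpha_grid"])
            raw["penalty"] = PenaltyConfig(**pen)
        return cls(**raw)


def _load_stage(config: PipelineConfig) -> ExpressionCohort:
    if config.simulation is not None:
        cohort, truth = generate_cohort(config.simulation)
        return cohort
    cohort = data_io.load_cohort(
        config.expression_path,
        config.labels_path,
        config.clinical_path,
        log_scale=not config.raw_scale,
    )
    return cohort


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages; returns the run directory.

    Re-running into a directory whose manifest records a different config
    hash is refused (no stale artifact mixing); the same hash overwrites
    deterministically.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    cfg_hash = config.config_hash()
    if manifest_path.exists():
        previous = json.loads(manifest_path.read_text())
        if previous.get("config_hash") != cfg_hash:
            raise StageError(
                f"run directory {out} holds artifacts from config "
                f"{previous.get('config_hash')}; refusing to mix with {cfg_hash}"
            )

    handler = logging.FileHandler(out / "pipeline.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    manifest: dict = {
        "config_hash": cfg_hash,
        "config": config.to_dict(),
        "stages": [],
    }

    def record(stage: str, **info) -> None:
        log.info("stage %s done: %s", stage, info)
        manifest["stages"].append({"stage": stage, **info})
        manifest_path.write_text(json.dumps(manifest, indent=2, default=str))

    try:
        stage = "load"
        cohort = _load_stage(config)
        if config.simulation is not None:
            _, truth = generate_cohort(config.simulation)
            truth.to_json(out / "ground_truth.json")
        if config.raw_scale and config.simulation is None:
            stage = "preprocess"
            cohort, removed = data_io.preprocess(
                cohort, config.max_nonexpressed_frac
            )
            (out / "removed_features.txt").write_text("\n".join(removed) + "\n")
            record(stage, removed=len(removed), retained=cohort.n_features)
        data_io.write_cohort(cohort, out / "cohort")
        record("load", n_samples=cohort.n_samples, n_features=cohort.n_features)

        stage = "seed_search"
        search = seed_search(
            cohort,
            n_repeats=config.n_repeats,
            M=config.M,
            config=config.penalty,
            train_frac=config.train_frac,
        )
        search.to_frame().to_csv(out / "seed_search.tsv", sep="\t", index=False)
        record(stage, best_seed=search.best_seed)

        stage = "train_ensemble"
        split = stratified_split(
            cohort.labels, train_frac=config.train_frac, seed=search.best_seed
        )
        ensemble = train_ensemble(
            cohort, split, M=config.M, config=config.penalty, seed=search.best_seed
        )
        record(stage, M=config.M, n_train=split.n_train, n_test=split.n_test)

        stage = "select_features"
        freq = count_frequencies(ensemble, feature_ids=cohort.feature_ids)
        d_sets = select_per_subtype(freq, config.resolved_frequency_threshold())
        panel = select_features(d_sets, config.min_subtypes)
        write_panel(panel, out / "feature_panel.tsv", freq)
        record(
            stage,
            threshold=config.resolved_frequency_threshold(),
            per_subtype=subtype_participation_counts(panel),
            selected=len(panel.selected),
        )

        if not panel.selected:
            log.warning("empty feature panel; skipping Cox stage")
            record("cox", skipped=True, reason="empty feature panel")
            return out

        stage = "cox"
        report = fit_cox(cohort, panel, ridge=config.cox_ridge)
        flagged = filter_biomarkers(report, config.coef_thresh, config.p_thresh)
        flagged.write(out / "biomarkers.tsv")
        record(stage, n_biomarkers=len(flagged.biomarkers))
        return out
    except StageError:
        raise
    except Exception as exc:
        raise StageError(f"stage {stage!r} failed: {exc}") from exc
    finally:
        log.removeHandler(handler)
        handler.close()
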