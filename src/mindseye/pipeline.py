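"""Config-driven orchestration of the full analysis.

A run reads (or synthesizes) fixation reports, filters them, computes the
per-trial measures — RQA, imagery-vs-encoding scanpath similarity,
quadrant-AOI looking-at-nothing association — then condition contrasts
and behavioural summaries, and archives everything with a manifest so the
run is reproducible from its config and seed.

Gaze cells are labelled by condition and phase: encoding cells keep the
display condition name (FP, GCW, AS) while imagery cells are prefixed
MI- (MI-FP, MI-GCW, MI-AS), matching how imagery-versus-encoding
contrasts are usually reported.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import aoi, rqa, similarity, stats, synthetic
from .errors import InputError, MindseyeError
from .io import ScreenGeometry, read_fixation_report, write_fixation_report
from .preprocess import filter_cohort, qc_summary

log = logging.getLogger("mindseye")

DEFAULT_CONTRASTS = [
    {"measure": "recurrence_rate", "a": "MI-FP", "b": "FP"},
    {"measure": "determinism", "a": "MI-FP", "b": "FP"},
    {"measure": "determinism", "a": "GCW", "b": "FP"},
    {"measure": "determinism", "a": "AS", "b": "FP"},
    {"measure": "laminarity", "a": "MI-FP", "b": "FP"},
    {"measure": "laminarity", "a": "AS", "b": "FP"},
    {"measure": "determinism", "a": "MI-GCW", "b": "MI-FP"},
    {"measure": "determinism", "a": "MI-AS", "b": "MI-FP"},
]


@dataclass
class RunConfig:
    """Everything needed to reproduce a run."""

    output_dir: str = "mindseye_out"
    seed: int = 0
    input_files: list = field(default_factory=list)  # fixation reports; empty -> synthetic
    synthetic: dict = field(default_factory=dict)    # SyntheticCohortConfig overrides
    geometry: dict = field(default_factory=dict)     # ScreenGeometry overrides
    min_duration_ms: float = 100.0
    max_duration_ms: float = 5000.0
    rqa: dict = field(default_factory=dict)          # RQAConfig overrides
    similarity: dict = field(default_factory=dict)   # SimilarityConfig overrides
    contrasts: list = field(default_factory=lambda: [dict(c) for c in DEFAULT_CONTRASTS])
    n_boot: int = 2000
    overwrite: bool = False
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def build_geometry(self) -> ScreenGeometry:
        return ScreenGeometry(**self.geometry)

    def build_synthetic(self) -> synthetic.SyntheticCohortConfig:
        kwargs = dict(self.synthetic)
        kwargs.setdefault("seed", self.seed)
        kwargs["geometry"] = self.build_geometry()
        return synthetic.SyntheticCohortConfig(**kwargs)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _cell(sp) -> str:
    return sp.condition if sp.phase == "encoding" else f"MI-{sp.condition}"


def load_or_simulate(config: RunConfig):
    """Returns (scanpaths, truth table or None)."""
    if config.input_files:
        geometry = config.build_geometry()
        scanpaths = []
        for path in config.input_files:
            if not Path(path).exists():
                raise InputError(f"input file not found: {path}")
            scanpaths.extend(read_fixation_report(path, geometry=geometry))
        return scanpaths, None
    cohort_cfg = config.build_synthetic()
    return generate_with_truth(cohort_cfg)


def generate_with_truth(cohort_cfg):
    return synthetic.generate_cohort(cohort_cfg)


def rqa_table(scanpaths, rqa_config: rqa.RQAConfig) -> pd.DataFrame:
    """Per-trial RQA measures for every scanpath with >= 2 fixations."""
    rows = []
    for sp in scanpaths:
        if len(sp) < 2:
            log.warning("skipping %s: fewer than 2 fixations", sp.key)
            continue
        res = rqa.analyze(sp, rqa_config)
        rows.append({
            "participant": sp.participant_id, "trial": sp.trial_id,
            "phase": sp.phase, "condition": sp.condition, "cell": _cell(sp),
            "category": sp.category, "n": res.n, "rec_count": res.rec_count,
            "recurrence_rate": res.recurrence_rate, "determinism": res.determinism,
            "laminarity": res.laminarity, "fixation_spread": res.fixation_spread,
        })
    return pd.DataFrame(rows)


def similarity_table(scanpaths, sim_config: similarity.SimilarityConfig) -> pd.DataFrame:
    """Imagery-vs-encoding similarity profile per trial, long format."""
    by_key = {}
    for sp in scanpaths:
        by_key.setdefault((sp.participant_id, sp.trial_id), {})[sp.phase] = sp
    rows = []
    for (pid, tid), phases in sorted(by_key.items()):
        enc, img = phases.get("encoding"), phases.get("imagery")
        if enc is None or img is None or len(enc) < 2 or len(img) < 2:
            continue
        profile = similarity.similarity_profile(img, enc, sim_config)
        for dim, value in profile.as_dict().items():
            rows.append({
                "participant": pid, "trial": tid,
                "comparison": f"MI-{enc.condition}", "dimension": dim,
                "similarity": value,
            })
    return pd.DataFrame(rows)


def lan_table(scanpaths) -> tuple[float, float, pd.DataFrame]:
    """Looking-at-nothing association over all encoding/imagery trial pairs."""
    by_key = {}
    for sp in scanpaths:
        by_key.setdefault((sp.participant_id, sp.trial_id), {})[sp.phase] = sp
    pairs = []
    for _, phases in sorted(by_key.items()):
        enc, img = phases.get("encoding"), phases.get("imagery")
        if enc is None or img is None:
            continue
        pairs.append((aoi.aoi_profile(enc), aoi.aoi_profile(img)))
    return aoi.lan_association(pairs)


def contrast_table(measures: pd.DataFrame, specs, n_boot: int, seed: int) -> pd.DataFrame:
    rows = []
    for i, spec in enumerate(specs):
        res = stats.condition_contrast(
            measures, spec["measure"], spec["a"], spec["b"],
            n_boot=n_boot, seed=seed + i, condition_col="cell",
        )
        rows.append(res.as_dict())
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage; returns the artifact directory.

    Raises on the first failing stage, leaving earlier stages' outputs in
    place; re-running over an existing directory requires ``overwrite``.
    """
    outdir = Path(config.output_dir)
    if outdir.exists() and any(outdir.iterdir()) and not config.overwrite:
        raise InputError(f"{outdir} exists and is not empty; set overwrite: true")
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level,
                        format="%(asctime)s %(name)s %(levelname)s %(message)s")

    stage = "load"
    try:
        scanpaths, truth = load_or_simulate(config)
        if truth is not None:
            write_fixation_report(scanpaths, outdir / "fixations.tsv")
            truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
        log.info("loaded %d scanpaths", len(scanpaths))

        stage = "preprocess"
        scanpaths, report = filter_cohort(
            scanpaths, config.min_duration_ms, config.max_duration_ms)
        (outdir / "preprocess_report.json").write_text(
            json.dumps(report.to_dict(), indent=2))
        qc_summary(scanpaths).to_csv(outdir / "qc_summary.tsv", sep="\t", index=False)

        stage = "rqa"
        rqa_cfg = rqa.RQAConfig(**config.rqa)
        measures = rqa_table(scanpaths, rqa_cfg)
        measures.to_csv(outdir / "rqa.tsv", sep="\t", index=False)

        stage = "similarity"
        sim_cfg = similarity.SimilarityConfig(**config.similarity)
        sims = similarity_table(scanpaths, sim_cfg)
        sims.to_csv(outdir / "similarity.tsv", sep="\t", index=False)

        stage = "lan"
        slope, intercept, lan_scatter = lan_table(scanpaths)
        lan_scatter.to_csv(outdir / "lan_scatter.tsv", sep="\t", index=False)
        (outdir / "lan.json").write_text(
            json.dumps({"slope": slope, "intercept": intercept}, indent=2))

        stage = "contrast"
        contrasts = contrast_table(measures, config.contrasts, config.n_boot, config.seed)
        contrasts.to_csv(outdir / "contrasts.tsv", sep="\t", index=False)

        stage = "behavioural"
        if truth is not None:
            stats.behavioural_summary(truth).to_csv(
                outdir / "behavioural.tsv", sep="\t", index=False)

        stage = "manifest"
        manifest = {
            "config": asdict(config),
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "n_scanpaths": len(scanpaths),
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    except MindseyeError:
        log.error("stage %r failed", stage)
        raise
    log.info("pipeline complete: %s", outdir)
    return outdir
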