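"""Config-driven orchestration of the five pipeline stages.

Stage order: dataset loading (or simulation), feature extraction, z-score
normalization, Fisher-score selection, cross-validated classification.
A run writes a CV report (JSON + TSV), the feature ranking, a fitted
model archive and a manifest (config hash, seed, versions) sufficient to
reproduce the run bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import joblib
import numpy as np
import pandas as pd
import yaml

import malosite
from malosite.featurize import EncoderConfig, FeatureExtractor, NAMED_COMBINATIONS
from malosite.model_eval import ClassifierSpec, CVReport, build_classifier, tenfold_cv
from malosite.preprocess_select import (
    fscore,
    select_top_fraction,
    zscore_fit,
    zscore_transform,
)
from malosite.sequence_io import SiteDataset, load_labeled_windows, load_window_fasta
from malosite.synthetic_data import EnrichmentProfile, generate

ARCHIVE_VERSION = 1


class PipelineError(RuntimeError):
    """A stage-tagged pipeline failure."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage: {stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Everything needed to reproduce one pipeline run."""

    # input: either pre-cut window FASTAs, a protein FASTA + site TSV,
    # or a synthetic simulation block
    pos_fasta: str | None = None
    neg_fasta: str | None = None
    dialect: str = "windows"
    site_table: str | None = None
    simulate: dict[str, Any] | None = None

    window_length: int = 25
    encoders: list[Any] = field(default_factory=lambda: ["EAAC", "EGAAC", "TFIDF"])
    selection_fraction: float | None = 0.8
    classifier: dict[str, Any] = field(
        default_factory=lambda: {"family": "gradient_boosted_trees"}
    )
    n_folds: int = 10
    n_perm: int | None = None
    seed: int = 0
    outdir: str = "malosite_run"

    def __post_init__(self) -> None:
        if isinstance(self.encoders, str):
            if self.encoders not in NAMED_COMBINATIONS:
                raise ValueError(
                    f"unknown combination {self.encoders!r}; "
                    f"known: {sorted(NAMED_COMBINATIONS)}"
                )
            self.encoders = list(NAMED_COMBINATIONS[self.encoders])
        if self.selection_fraction is not None and not (
            0.0 < self.selection_fraction <= 1.0
        ):
            raise ValueError("selection_fraction must be in (0, 1]")

    def encoder_configs(self) -> list[EncoderConfig]:
        out = []
        for e in self.encoders:
            if isinstance(e, str):
                out.append(EncoderConfig(e))
            elif isinstance(e, EncoderConfig):
                out.append(e)
            else:
                out.append(EncoderConfig(e["name"], dict(e.get("params", {}))))
        return out

    def classifier_spec(self) -> ClassifierSpec:
        d = dict(self.classifier)
        family = d.pop("family", "gradient_boosted_trees")
        return ClassifierSpec(family=family, hyperparameters=d)

    def canonical_json(self) -> str:
        d = asdict(self)
        d["encoders"] = [
            {"name": c.name, "params": c.params} for c in self.encoder_configs()
        ]
        return json.dumps(d, sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**d)


def _load_dataset(cfg: PipelineConfig) -> SiteDataset:
    if cfg.simulate is not None:
        sim = dict(cfg.simulate)
        prof = sim.get("profile")
        if isinstance(prof, str):
            profile = EnrichmentProfile.from_file(prof)
        elif isinstance(prof, dict):
            profile = EnrichmentProfile(
                background_freqs=prof.get(
                    "background_freqs", EnrichmentProfile().background_freqs
                ),
                enriched=tuple(
                    (int(e["offset"]), str(e["residue"]), float(e["shift"]))
                    for e in prof.get("enriched", [])
                ),
                label_gap=float(prof.get("label_gap", 1.0)),
            )
        else:
            profile = prof  # already an EnrichmentProfile, or None
        return generate(
            n_pos=int(sim.get("n_pos", 500)),
            n_neg=int(sim.get("n_neg", 500)),
            profile=profile,
            window_length=cfg.window_length,
            seed=int(sim.get("seed", cfg.seed)),
        )
    if cfg.pos_fasta is None:
        raise PipelineError("dataset", "no input configured (pos_fasta or simulate)")
    return load_labeled_windows(
        cfg.pos_fasta,
        cfg.neg_fasta or cfg.pos_fasta,
        window_length=cfg.window_length,
        dialect=cfg.dialect,  # type: ignore[arg-type]
        site_table=cfg.site_table,
    )


def _write_manifest(cfg: PipelineConfig, outdir: Path) -> None:
    manifest = {
        "archive_version": ARCHIVE_VERSION,
        "config": json.loads(cfg.canonical_json()),
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "versions": {
            "malosite": malosite.__version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
        },
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )


def run(config: PipelineConfig) -> CVReport:
    """Execute the full pipeline and write all artifacts to ``config.outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    try:
        data = _load_dataset(config)
    except PipelineError:
        raise
    except Exception as e:  # noqa: BLE001
        raise PipelineError("dataset", str(e)) from e

    try:
        report = tenfold_cv(
            data,
            encoders=config.encoder_configs(),
            selection_fraction=config.selection_fraction,
            spec=config.classifier_spec(),
            n_folds=config.n_folds,
            seed=config.seed,
            n_perm=config.n_perm,
        )
    except Exception as e:  # noqa: BLE001
        raise PipelineError("cross-validation", str(e)) from e

    try:
        artifact = fit_full(data, config)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("final-fit", str(e)) from e

    report.to_json(outdir / "cv_report.json")
    report.to_tsv(outdir / "cv_report.tsv")
    artifact["ranking"].to_tsv(outdir / "ranking.tsv")
    save_archive(artifact, outdir / "model")
    _write_manifest(config, outdir)
    return report


def fit_full(data: SiteDataset, config: PipelineConfig) -> dict[str, Any]:
    """Fit encoders, scaler, selection and classifier on the whole dataset."""
    fx = FeatureExtractor(config.encoder_configs()).fit(data)
    x = fx.transform(data)
    scaler = zscore_fit(x)
    x = zscore_transform(x, scaler)
    ranking = fscore(x)
    ranking = select_top_fraction(ranking, config.selection_fraction or 1.0)
    keep = ranking.selected_names()
    x_sel = x.select_columns(keep)
    model = build_classifier(config.classifier_spec(), config.seed)
    model.fit(x_sel.values, np.asarray([1 if l == "positive" else 0 for l in x_sel.labels]))
    return {
        "extractor": fx,
        "scaler": scaler,
        "ranking": ranking,
        "selected": keep,
        "classifier": model,
        "window_length": data.window_length,
    }


def save_archive(artifact: dict[str, Any], path: str | Path) -> None:
    """Serialize fitted state: one joblib bundle plus open-format exports."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    fx: FeatureExtractor = artifact["extractor"]
    bundle = {"version": ARCHIVE_VERSION, **artifact}
    joblib.dump(bundle, path / "artifact.joblib")
    artifact["scaler"].to_json(path / "scaler.json")
    if fx.idf_ is not None:
        fx.idf_.to_json(path / "idf.json")
    if fx.crf_ is not None:
        fx.crf_.to_json(path / "crf.json")
    if fx.pssm_ is not None:
        fx.pssm_.to_tsv(path / "pssm.tsv")
    (path / "archive.json").write_text(
        json.dumps(
            {
                "version": ARCHIVE_VERSION,
                "window_length": artifact["window_length"],
                "encoders": fx.encoder_names,
                "n_selected": len(artifact["selected"]),
            },
            indent=2, sort_keys=True,
        ) + "\n"
    )


def load_archive(path: str | Path) -> dict[str, Any]:
    path = Path(path)
    bundle = joblib.load(path / "artifact.joblib")
    if bundle.get("version") != ARCHIVE_VERSION:
        raise PipelineError(
            "predict", f"archive version {bundle.get('version')} unsupported"
        )
    return bundle


def predict(model_archive: str | Path, windows_fasta: str | Path) -> pd.DataFrame:
    """Score windows from a FASTA with a saved pipeline; (id, score, label)."""
    bundle = load_archive(model_archive)
    L = bundle["window_length"]
    from malosite.sequence_io import FastaFormatError

    try:
        windows = load_window_fasta(windows_fasta, "unknown", L)
    except FastaFormatError:
        # empty input is not an error: emit the header only
        return pd.DataFrame(columns=["id", "score", "label"])
    except ValueError as e:
        raise PipelineError("predict", str(e)) from e
    ds = SiteDataset(windows)
    x = bundle["extractor"].transform(ds)
    x = zscore_transform(x, bundle["scaler"])
    x = x.select_columns(bundle["selected"])
    scores = bundle["classifier"].predict_proba(x.values)[:, 1]
    return pd.DataFrame(
        {
            "id": [w.protein_id for w in windows],
            "score": scores,
            "label": np.where(scores >= 0.5, "positive", "negative"),
        }
    )
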