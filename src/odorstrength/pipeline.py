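"""End-to-end experiment orchestration from one declarative config.

Stages: simulate/ingest -> curate -> featurize -> split -> train (direct
models + optional hierarchical + ensemble) -> evaluate -> explain. Every
stage's outputs land in the run directory and are listed, with content
hashes, in ``manifest.json``; a run is reproducible from its config and
global seed. The global seed fans out to per-stage seeds through
``numpy.random.SeedSequence`` so stages are independently reproducible.

Protocol defaults match the study design: 80/20 grouped stratified holdout,
similarity threshold 0.8, 10-fold CV with 10 repeats (``paper_protocol``
preset); reduced-fold presets exist for smoke runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import chem_space, curation, evaluate, explain, featurize, models, split, synthetic


@dataclass
class ExperimentConfig:
    """Declarative description of one run."""

    outdir: str = "runs/default"
    seed: int = 0
    # input: either a records CSV or the synthetic generator
    records_csv: str | None = None
    generator: dict = field(default_factory=dict)
    # curation
    merge_precedence: str = "A"
    # featurization
    encoder: str = "descriptors"
    encoder_params: dict = field(default_factory=dict)
    # splitting — defaults are the study protocol constants
    test_fraction: float = 0.2
    similarity_threshold: float = 0.8
    n_folds: int = 10
    n_repeats: int = 10
    # models
    direct_specs: list = field(default_factory=lambda: [
        {"algorithm": "random_forest"},
        {"algorithm": "xgb"},
        {"algorithm": "mlp"},
    ])
    hierarchical: bool = False
    explain_enabled: bool = True
    n_noise_features: int = 0  # appended seeded noise columns (signal-recovery studies)

    @classmethod
    def paper_protocol(cls, **overrides) -> "ExperimentConfig":
        return cls(**overrides)

    @classmethod
    def smoke(cls, **overrides) -> "ExperimentConfig":
        defaults = dict(n_folds=3, n_repeats=2, generator={"n_molecules": 300})
        defaults.update(overrides)
        return cls(**defaults)

    @classmethod
    def from_json(cls, path: str | Path) -> "ExperimentConfig":
        with open(path) as fh:
            payload = json.load(fh)
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - valid
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**payload)


def _stage_seeds(seed: int, n: int = 8) -> list[int]:
    return [int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(seed).spawn(n)]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class StageError(RuntimeError):
    def __init__(self, stage: str, error: Exception):
        super().__init__(f"stage {stage!r} failed: {error}")
        self.record = {"stage": stage, "error": str(error), "type": type(error).__name__}


def run(config: ExperimentConfig) -> dict:
    """Execute the full pipeline; returns the artifact manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    artifacts: dict[str, str] = {}

    def emit(name: str, path: Path) -> None:
        artifacts[name] = str(path.relative_to(outdir))

    stage = "simulate"
    try:
        if config.records_csv is not None:
            records = curation.frame_to_records(pd.read_csv(config.records_csv))
            truth = None
        else:
            gen_cfg = synthetic.GeneratorConfig(**{"seed": seeds[0], **config.generator})
            records, dataset = synthetic.generate_dataset(gen_cfg)
            truth = dataset
            synthetic.write_dataset(str(outdir / "synthetic"), records, dataset)
            emit("records_csv", outdir / "synthetic_records.csv")
            emit("truth_csv", outdir / "synthetic_truth.csv")

        stage = "curate"
        merged, audit, agreement_report = curation.curate(records, precedence=config.merge_precedence)
        curation.write_outputs(str(outdir / "curation"), merged, audit, agreement_report)
        emit("curated_csv", outdir / "curation_curated.csv")
        emit("audit_json", outdir / "curation_audit.json")
        if agreement_report is not None:
            emit("agreement_json", outdir / "curation_agreement.json")

        smiles = [r.smiles_canonical for r in merged]
        y = np.asarray([r.strength for r in merged], dtype=int)

        stage = "featurize"
        if config.encoder == "descriptors":
            fm = featurize.descriptors(smiles)
        else:
            fm = featurize.fingerprint(smiles, kind=config.encoder, **config.encoder_params)
        X = fm.values
        names = list(fm.feature_names)
        if config.n_noise_features > 0:
            rng = np.random.Generator(np.random.PCG64(seeds[1]))
            X = np.hstack([X, rng.normal(size=(len(X), config.n_noise_features))])
            names += [f"noise_{i}" for i in range(config.n_noise_features)]
        fm.to_frame().to_csv(outdir / "features.csv")
        emit("features_csv", outdir / "features.csv")

        stage = "split"
        plan = split.make_split_plan(
            smiles, y,
            test_fraction=config.test_fraction,
            similarity_threshold=config.similarity_threshold,
            n_folds=config.n_folds, n_repeats=config.n_repeats, seed=seeds[2],
        )
        plan.to_frame(smiles).to_csv(outdir / "split_plan.csv", index=False)
        emit("split_plan_csv", outdir / "split_plan.csv")
        train_mask = ~plan.holdout
        X_train, y_train = X[train_mask], y[train_mask]
        X_test, y_test = X[plan.holdout], y[plan.holdout]

        stage = "train"
        specs = [models.ModelSpec(seed=seeds[3] + i, **s) for i, s in enumerate(config.direct_specs)]
        fitted = [models.train_direct(X_train, y_train, s) for s in specs]
        ensemble = models.OrdinalVoteEnsemble(fitted)
        hier = None
        if config.hierarchical:
            hier = models.HierarchicalOrdinalClassifier(
                models.ModelSpec(specs[0].algorithm, specs[0].hyperparameters, seed=seeds[4]),
                models.ModelSpec(specs[0].algorithm, specs[0].hyperparameters, seed=seeds[4] + 1),
            ).fit(X_train, y_train)

        stage = "evaluate"
        results = {}
        for s, m in zip(specs, fitted):
            pred = models.predict_ordinal(m, X_test)
            proba = m.predict_proba(X_test) if hasattr(m, "predict_proba") else None
            results[s.algorithm] = evaluate.report(y_test, pred, proba).to_dict()
        pred_ens = ensemble.predict(X_test)
        results["ensemble"] = evaluate.report(y_test, pred_ens).to_dict()
        if hier is not None:
            results["hierarchical"] = evaluate.report(y_test, hier.predict(X_test)).to_dict()
        with open(outdir / "evaluation.json", "w") as fh:
            json.dump(results, fh, indent=2)
        emit("evaluation_json", outdir / "evaluation.json")

        stage = "chem_space"
        if config.encoder == "descriptors":
            k = min(5, len(smiles) - 1, fm.values.shape[1])
            pres = chem_space.pca(fm, k=k)
            pd.DataFrame(pres.scores).to_csv(outdir / "pca_scores.csv", index=False)
            emit("pca_scores_csv", outdir / "pca_scores.csv")

        if config.explain_enabled:
            stage = "explain"
            xgb_member = next((m for s, m in zip(specs, fitted) if s.algorithm == "xgb"), fitted[0])
            attr = explain.attribute(xgb_member, X_test, X_train, seed=seeds[5])
            grouping = explain.correlation_grouping(X_train)
            importance = explain.group_importance(attr, grouping, names, y_true=y_test)
            payload = {
                "threshold": grouping.threshold,
                "n_groups": grouping.n_groups,
                "silhouette_curve": grouping.silhouette_curve,
                "ranking": importance["ranking"],
                "groups": importance["groups"],
            }
            with open(outdir / "explain.json", "w") as fh:
                json.dump(payload, fh, indent=2)
            emit("explain_json", outdir / "explain.json")
    except StageError:
        raise
    except Exception as err:
        raise StageError(stage, err) from err

    manifest = {
        "config": dataclasses.asdict(config),
        "seed": config.seed,
        "stage_seeds": seeds,
        "artifacts": {name: {"path": p, "sha256": _sha256(outdir / p)} for name, p in artifacts.items()},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
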