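"""End-to-end experiment orchestration.

One :class:`ExperimentConfig` drives generate → featurize → split (× repeat
seeds) → train (× models) → evaluate, with every artifact written under an
output directory and every stochastic stage seeded from the single global
seed plus a stage tag, so the run manifest alone reproduces a run
bit-identically.

The ``study_analog`` preset is the package's desk-scale mirror of the full
study protocol: 10,000 synthetic reports with ~4% boundary-localized labeller
disagreement and the class mix of the real corpus, two repeated stratified
splits (10% validation / 10% test), and the three models with their stated
training hyperparameters.  It uses a 50-dimensional synthetic embedding table
and 100 GP inducing points so a complete run takes minutes on one CPU.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import corpus as corpus_mod
from .baselines import (DeepEnsembleClassifier, EnsembleConfig, ForestConfig,
                        fit_forest)
from .corpus import (LABELS, LabelledCorpus, SeverityModel, generate_corpus,
                     corpus_stats)
from .features import EmbeddingTable, FeatureMatrix, featurize_corpus, synthetic_table
from .metrics import EvalReport, evaluate_run
from .splits import make_split, make_test_variants
from .svgp import SparseGPClassifier, SvgpConfig
from ._seeding import derive_seed

logger = logging.getLogger(__name__)


@dataclass
class ExperimentConfig:
    # corpus: synthetic parameters, or a path to an existing JSONL corpus
    corpus_path: str | None = None
    n_reports: int = 10_000
    boundary_width: float = 0.05
    target_disagreement: float = 0.04
    mean_doc_length: float = corpus_mod.DEFAULT_MEAN_DOC_LENGTH
    # embeddings: synthetic fixture, or a word2vec-text path
    embeddings_path: str | None = None
    embedding_dim: int = 50
    # splits
    val_fraction: float = 0.10
    test_fraction: float = 0.10
    n_repeats: int = 2
    # models
    models: tuple[str, ...] = ("gp", "rf", "ens")
    gp: dict = field(default_factory=dict)
    rf: dict = field(default_factory=dict)
    ens: dict = field(default_factory=dict)
    # global
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["models"] = list(self.models)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "models" in d:
            d["models"] = tuple(d["models"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def study_analog(seed: int = 0, models: tuple[str, ...] = ("gp", "rf", "ens"),
                 n_reports: int = 10_000) -> ExperimentConfig:
    """The desk-scale analog of the full study protocol (see module docstring)."""
    return ExperimentConfig(
        n_reports=n_reports, models=models, seed=seed,
        gp={"num_inducing": 100},
    )


# ---------------------------------------------------------------------------
# stage helpers
# ---------------------------------------------------------------------------

def _build_corpus(config: ExperimentConfig) -> LabelledCorpus:
    if config.corpus_path:
        return LabelledCorpus.from_jsonl(config.corpus_path)
    model = SeverityModel(
        boundary_width=config.boundary_width,
        target_disagreement=config.target_disagreement,
        mean_doc_length=config.mean_doc_length,
    )
    return generate_corpus(model=model, n=config.n_reports,
                           seed=derive_seed(config.seed, "corpus"))


def _build_table(config: ExperimentConfig) -> EmbeddingTable:
    if config.embeddings_path:
        return EmbeddingTable.from_word2vec(config.embeddings_path)
    return synthetic_table(dimension=config.embedding_dim,
                           seed=derive_seed(config.seed, "embeddings"))


def _label_indices(labels) -> np.ndarray:
    return np.array([LABELS.index(lab) for lab in labels])


def _train_model(name: str, config: ExperimentConfig, X_train, y_train,
                 X_val, y_val, repeat: int):
    seed = derive_seed(config.seed, f"{name}-repeat-{repeat}")
    if name == "gp":
        gp_cfg = SvgpConfig(**{"seed": seed, **config.gp})
        gp_cfg.seed = seed
        return SparseGPClassifier(X_train, y_train, gp_cfg).fit()
    if name == "rf":
        return fit_forest(X_train, y_train, ForestConfig(**config.rf),
                          X_val, y_val, seed=seed)
    if name == "ens":
        return DeepEnsembleClassifier(X_train, y_train, EnsembleConfig(**config.ens),
                                      seed=seed).fit()
    raise ValueError(f"unknown model {name!r} (expected gp | rf | ens)")


# ---------------------------------------------------------------------------
# run
# ---------------------------------------------------------------------------

def run_experiment(config: ExperimentConfig, outdir) -> dict[str, EvalReport]:
    """Execute the full pipeline; returns one :class:`EvalReport` per model.

    Writes, under ``outdir``: the resolved run manifest (before any
    computation), the corpus and its summary statistics, the split manifests,
    per-model JSON reports and the combined headline/group-wise CSV tables.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"config": config.to_dict(),
                "stage_seeds": {t: derive_seed(config.seed, t)
                                for t in ("corpus", "embeddings")}}
    _dump_json(manifest, outdir / "manifest.json")

    corpus = _build_corpus(config)
    corpus.to_jsonl(outdir / "corpus.jsonl")
    stats = corpus_stats(corpus)
    _dump_json(stats, outdir / "corpus_stats.json")
    logger.info("corpus: n=%d disagreement=%.3f mean length=%.1f", stats["n"],
                stats["disagreement_rate"], stats["mean_token_length"])

    table = _build_table(config)
    features = featurize_corpus(corpus, table)
    by_id = {r.report_id: r for r in corpus}

    collected: dict[str, list[dict]] = {m: [] for m in config.models}
    for repeat in range(config.n_repeats):
        split_seed = derive_seed(config.seed, f"split-{repeat}")
        split = make_split(corpus, config.val_fraction, config.test_fraction,
                           seed=split_seed)
        variants = make_test_variants(corpus, split,
                                      seed=derive_seed(config.seed, f"subsample-{repeat}"))
        _dump_json({"split": split.to_dict(),
                    "variants": {"cons_test": variants.cons_test,
                                 "incons_test": variants.incons_test,
                                 "cons_subsample": variants.cons_subsample}},
                   outdir / f"split_{repeat}.json")

        X_train = features.rows_for(split.train_ids)
        y_train = [by_id[i].primary_label for i in split.train_ids]
        X_val = features.rows_for(split.val_ids)
        y_val = [by_id[i].primary_label for i in split.val_ids]

        for name in config.models:
            logger.info("repeat %d: training %s", repeat, name)
            try:
                model = _train_model(name, config, X_train, y_train, X_val, y_val, repeat)
            except Exception:
                logger.error("stage 'train:%s' failed on repeat %d", name, repeat)
                raise
            rep_entry = {}
            for vname, ids, truth_map in variants.variant_items():
                if not ids:
                    rep_entry[vname] = (np.zeros((0, len(LABELS))), np.zeros(0, dtype=int))
                    continue
                probs = model.predict(features.rows_for(ids)).probs
                truth = _label_indices([truth_map[i] for i in ids])
                rep_entry[vname] = (probs, truth)
            collected[name].append(rep_entry)

    reports = {name: evaluate_run(name, reps) for name, reps in collected.items()}
    for name, report in reports.items():
        report.to_json(outdir / f"report_{name}.json")
    write_tables(reports.values(), outdir)
    return reports


def write_tables(reports, outdir) -> None:
    import pandas as pd

    outdir = Path(outdir)
    headline = pd.concat([r.headline_table() for r in reports], ignore_index=True)
    headline.to_csv(outdir / "table_headline.csv", index=False)
    groupwise = pd.concat([r.groupwise_table() for r in reports], ignore_index=True)
    groupwise.to_csv(outdir / "table_groupwise.csv", index=False)


def _dump_json(obj, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)


# simple lossless I/O wrappers (schema-validated on read by the constructors)
def read_corpus(path) -> LabelledCorpus:
    return LabelledCorpus.from_jsonl(path)


def write_corpus(corpus: LabelledCorpus, path) -> None:
    corpus.to_jsonl(path)


def read_features(path) -> FeatureMatrix:
    return FeatureMatrix.load(path)


def write_features(features: FeatureMatrix, path) -> None:
    features.save(path)


def read_report(path) -> EvalReport:
    return EvalReport.from_json(path)


def write_report(report: EvalReport, path) -> None:
    report.to_json(path)
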