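"""End-to-end semi-supervised pipeline and the model-comparison harness.

Three phases: (1) k-mer tokenization of labelled and unlabelled sequences,
(2) supervised training of the recurrent feature extractor on the labelled
split, (3) latent-space K-means prediction of the unlabelled split, with
clusters mapped to classes via the labelled-training latent means.  The
harness re-runs the pipeline over a grid of backbones, predictors, k values
and recurrent widths and tabulates accuracy and per-class
precision/recall/F1 for each cell.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .backbone import RecurrentNetClassifier
from .metrics import EvaluationReport, class_report
from .predictor import (
    ClusterLabelMap,
    LatentKMeans,
    make_comparator,
    map_clusters_to_labels,
    predict_labels,
)
from .preprocess import KmerVectorizer
from .seqdata import (
    DatasetSplit,
    SequenceRecord,
    SyntheticConfig,
    generate_synthetic,
    read_sequence_csv,
    split_dataset,
    write_sequence_csv,
)

logger = logging.getLogger("gruclust")


class SemiSupervisedSequenceClassifier(ClassifierMixin, BaseEstimator):
    """Semi-supervised DNA sequence classifier (tokenizer + GRU + K-means).

    ``fit`` consumes labelled sequences: it builds the k-mer vocabulary,
    trains the recurrent backbone, and stores the labelled latents for the
    cluster-to-class mapping.  ``predict`` consumes unlabelled sequences:
    it extracts their latents, clusters them into two groups, maps each
    cluster to the class with the nearest labelled-latent mean, and returns
    0/1 labels.  Test labels are never used.
    """

    def __init__(self, k: int = 2, stride: int = 1, ordering: str = "frequency_desc",
                 gru_units: int = 200, dense_units: tuple[int, ...] = (128, 64, 32, 16),
                 embedding_dim: int = 32, dropout_rate: float = 0.2,
                 latent_layer_index: int = 4, backbone_kind: str = "gru",
                 epochs: int = 50, batch_size: int = 32, learning_rate: float = 1e-3,
                 early_stopping_patience: int = 5, validation_fraction: float = 0.2,
                 predictor: str = "kmeans", n_clusters: int = 2, n_restarts: int = 10,
                 tol: float = 1e-4, max_iter: int = 300,
                 include_labelled_in_clustering: bool = False, random_state: int = 0):
        self.k = k
        self.stride = stride
        self.ordering = ordering
        self.gru_units = gru_units
        self.dense_units = dense_units
        self.embedding_dim = embedding_dim
        self.dropout_rate = dropout_rate
        self.latent_layer_index = latent_layer_index
        self.backbone_kind = backbone_kind
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.early_stopping_patience = early_stopping_patience
        self.validation_fraction = validation_fraction
        self.predictor = predictor
        self.n_clusters = n_clusters
        self.n_restarts = n_restarts
        self.tol = tol
        self.max_iter = max_iter
        self.include_labelled_in_clustering = include_labelled_in_clustering
        self.random_state = random_state

    @staticmethod
    def _records(X) -> list[SequenceRecord]:
        return [
            x if isinstance(x, SequenceRecord)
            else SequenceRecord(id=f"x{i}", sequence=str(x))
            for i, x in enumerate(X)
        ]

    def fit(self, X, y=None, validation_data=None) -> "SemiSupervisedSequenceClassifier":
        records = self._records(X)
        if y is not None:
            records = [
                SequenceRecord(id=r.id, sequence=r.sequence, label=int(lbl))
                for r, lbl in zip(records, y)
            ]
        if any(r.label is None for r in records):
            raise ValueError("fit requires labels for every sequence")
        self.vectorizer_ = KmerVectorizer(
            k=self.k, stride=self.stride, ordering=self.ordering, unknown="zero"
        ).fit([r.sequence for r in records])
        data = self.vectorizer_.encode(records)
        self.backbone_ = RecurrentNetClassifier(
            gru_units=self.gru_units,
            dense_units=tuple(self.dense_units),
            embedding_dim=self.embedding_dim,
            dropout_rate=self.dropout_rate,
            latent_layer_index=self.latent_layer_index,
            backbone_kind=self.backbone_kind,
            epochs=self.epochs,
            batch_size=self.batch_size,
            learning_rate=self.learning_rate,
            early_stopping_patience=self.early_stopping_patience,
            validation_fraction=self.validation_fraction,
            random_state=self.random_state,
        )
        if validation_data is not None:
            val_records = self._records(validation_data[0])
            val_records = [
                SequenceRecord(id=r.id, sequence=r.sequence, label=int(lbl))
                for r, lbl in zip(val_records, validation_data[1])
            ]
            val_ds = self.vectorizer_.encode(val_records)
            self.backbone_.fit(data, validation_data=val_ds)
        else:
            self.backbone_.fit(data)
        self.labelled_latents_ = self.backbone_.transform(data)
        self.labelled_labels_ = np.asarray([r.label for r in records], dtype=np.int64)
        self.classes_ = np.array([0, 1])
        if self.predictor != "kmeans":
            self.comparator_ = make_comparator(self.predictor, seed=self.random_state).fit(
                self.labelled_latents_, self.labelled_labels_
            )
        return self

    def transform(self, X) -> np.ndarray:
        """Latent representation of sequences under the trained backbone."""
        check_is_fitted(self, "backbone_")
        return self.backbone_.transform(self.vectorizer_.encode(self._records(X)))

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "backbone_")
        latents = self.transform(X)
        if self.predictor != "kmeans":
            return np.asarray(self.comparator_.predict(latents), dtype=np.int64)
        fit_X = latents
        if self.include_labelled_in_clustering:
            fit_X = np.vstack([latents, self.labelled_latents_])
        self.kmeans_ = LatentKMeans(
            n_clusters=self.n_clusters,
            n_restarts=self.n_restarts,
            max_iter=self.max_iter,
            tol=self.tol,
            random_state=self.random_state,
        ).fit(fit_X)
        self.label_map_ = map_clusters_to_labels(
            self.kmeans_, self.labelled_latents_, self.labelled_labels_
        )
        return predict_labels(self.kmeans_, self.label_map_, latents)

    def predict_detail(self, X) -> pd.DataFrame:
        """Per-sequence table: id, predicted_label, cluster, distance_to_centroid."""
        records = self._records(X)
        pred = self.predict(X)
        if self.predictor != "kmeans":
            return pd.DataFrame(
                {"id": [r.id for r in records], "predicted_label": pred,
                 "cluster": -1, "distance_to_centroid": np.nan}
            )
        latents = self.transform(X)
        clusters = self.kmeans_.predict(latents)
        dists = self.kmeans_.transform(latents)[np.arange(len(latents)), clusters]
        return pd.DataFrame(
            {
                "id": [r.id for r in records],
                "predicted_label": pred,
                "cluster": clusters,
                "distance_to_centroid": dists,
            }
        )


# ---------------------------------------------------------------------------
# File-level orchestration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Full configuration of one end-to-end run."""

    k: int = 2
    gru_units: int = 200
    dense_units: tuple[int, ...] = (128, 64, 32, 16)
    embedding_dim: int = 32
    dropout_rate: float = 0.2
    latent_layer_index: int = 4
    backbone_kind: str = "gru"
    predictor: str = "kmeans"
    epochs: int = 50
    batch_size: int = 32
    learning_rate: float = 1e-3
    early_stopping_patience: int = 5
    n_clusters: int = 2
    n_restarts: int = 10
    tol: float = 1e-4
    max_iter: int = 300
    learn_test_ratio: tuple[int, int] = (4, 1)
    train_val_ratio: tuple[int, int] = (4, 1)
    input_csv: Optional[str] = None
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    out_dir: str = "run_output"
    seed: int = 0

    def to_yaml(self, path: Union[str, Path]) -> None:
        payload = asdict(self)
        payload["synthetic"] = asdict(self.synthetic) if self.synthetic else None
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(payload)

    @classmethod
    def from_dict(cls, payload: dict) -> "PipelineConfig":
        payload = dict(payload)
        syn = payload.pop("synthetic", None)
        cfg = cls(**{k: v for k, v in payload.items() if k in
                     {f.name for f in dataclasses.fields(cls)}})
        if syn is not None:
            if isinstance(syn.get("insertion_prob"), list):
                syn["insertion_prob"] = tuple(syn["insertion_prob"])
            if isinstance(syn.get("background_composition"), list):
                syn["background_composition"] = tuple(syn["background_composition"])
            cfg.synthetic = SyntheticConfig(**syn)
        for name in ("dense_units", "learn_test_ratio", "train_val_ratio"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        return cfg


@dataclass
class RunArtifacts:
    """Paths and in-memory results of one pipeline run."""

    out_dir: Path
    vocabulary_file: Path
    checkpoint_dir: Path
    kmeans_file: Path
    predictions_file: Path
    report_file: Path
    history_file: Path
    log_file: Path
    report: EvaluationReport
    predictions: pd.DataFrame
    accuracy: float


def _load_records(config: PipelineConfig) -> list[SequenceRecord]:
    if config.input_csv:
        logger.info("loading labelled sequences from %s", config.input_csv)
        return read_sequence_csv(config.input_csv, has_labels=True)
    logger.info(
        "generating synthetic dataset: %d per class, length %d",
        config.synthetic.n_per_class, config.synthetic.seq_length,
    )
    synthetic = dataclasses.replace(config.synthetic, seed=config.seed)
    return generate_synthetic(synthetic)


def run_pipeline(config: PipelineConfig) -> RunArtifacts:
    """Execute preprocess -> train -> latent K-means -> evaluation; write artifacts."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_file = out / "run.log"
    handler = logging.FileHandler(log_file, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    stage = "load"
    try:
        records = _load_records(config)
        stage = "split"
        split = split_dataset(
            records, config.learn_test_ratio, config.train_val_ratio, seed=config.seed
        )
        logger.info(
            "split: %d train / %d validation / %d test",
            len(split.train), len(split.validation), len(split.test_unlabelled),
        )
        stage = "fit"
        model = SemiSupervisedSequenceClassifier(
            k=config.k,
            gru_units=config.gru_units,
            dense_units=config.dense_units,
            embedding_dim=config.embedding_dim,
            dropout_rate=config.dropout_rate,
            latent_layer_index=config.latent_layer_index,
            backbone_kind=config.backbone_kind,
            predictor=config.predictor,
            epochs=config.epochs,
            batch_size=config.batch_size,
            learning_rate=config.learning_rate,
            early_stopping_patience=config.early_stopping_patience,
            n_clusters=config.n_clusters,
            n_restarts=config.n_restarts,
            tol=config.tol,
            max_iter=config.max_iter,
            random_state=config.seed,
        )
        model.fit(
            split.train,
            validation_data=(
                split.validation, [r.label for r in split.validation]
            ),
        )
        stage = "predict"
        predictions = model.predict_detail(split.test_unlabelled)
        stage = "evaluate"
        report = class_report(split.test_labels, predictions["predicted_label"].to_numpy())
        logger.info("test accuracy %.4f", report.accuracy)

        stage = "write artifacts"
        vocabulary_file = out / "vocabulary.tsv"
        model.vectorizer_.vocabulary_.save(vocabulary_file)
        checkpoint_dir = out / "checkpoint"
        model.backbone_.save(checkpoint_dir)
        kmeans_file = out / "kmeans.json"
        if config.predictor == "kmeans":
            model.kmeans_.save(kmeans_file, label_map=model.label_map_)
        else:
            kmeans_file.write_text('{"predictor": "%s"}' % config.predictor)
        predictions_file = out / "predictions.csv"
        predictions.to_csv(predictions_file, index=False)
        report_file = out / "report.csv"
        report.write_csv(report_file)
        (out / "report.txt").write_text(report.to_text() + "\n")
        history_file = out / "history.csv"
        model.backbone_.history_.to_csv(history_file, index=False)
        return RunArtifacts(
            out_dir=out,
            vocabulary_file=vocabulary_file,
            checkpoint_dir=checkpoint_dir,
            kmeans_file=kmeans_file,
            predictions_file=predictions_file,
            report_file=report_file,
            history_file=history_file,
            log_file=log_file,
            report=report,
            predictions=predictions,
            accuracy=report.accuracy,
        )
    except Exception:
        logger.exception("pipeline failed during stage %r", stage)
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()


def compare_models(
    base: PipelineConfig,
    backbones: Sequence[str] = ("gru",),
    predictors: Sequence[str] = ("kmeans",),
    k_values: Sequence[int] = (2,),
    unit_counts: Sequence[int] = (200,),
) -> pd.DataFrame:
    """Grid harness: one row per (backbone, predictor, k, units) combination.

    Each cell is a full pipeline run under the shared seed; a failing cell
    is recorded with status ``failed`` instead of aborting the grid.  The
    default grid mirrors the operating-point comparison (units 100/200/300/
    400, k 2/3/4, four recurrent variants, four predictors).
    """
    rows = []
    for kind in backbones:
        for pred in predictors:
            for k in k_values:
                for units in unit_counts:
                    name = f"{kind}_{pred}_k{k}_u{units}"
                    cfg = dataclasses.replace(
                        base,
                        backbone_kind=kind,
                        predictor=pred,
                        k=k,
                        gru_units=units,
                        out_dir=str(Path(base.out_dir) / name),
                    )
                    row = {"backbone": kind, "predictor": pred, "k": k, "units": units}
                    try:
                        artifacts = run_pipeline(cfg)
                        row["status"] = "ok"
                        row["A"] = artifacts.report.accuracy
                        for r in artifacts.report.rows:
                            row[f"P_class{r.label}"] = r.precision
                            row[f"R_class{r.label}"] = r.recall
                            row[f"F1_class{r.label}"] = r.f1
                    except Exception as exc:  # a failing cell must not kill the grid
                        logger.warning("grid cell %s failed: %s", name, exc)
                        row["status"] = "failed"
                        row["error"] = str(exc)
                    rows.append(row)
    return pd.DataFrame(rows)
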