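"""End-to-end experiment orchestration.

The full discrimination pipeline, in the order the stages are fit:

1. stratified per-class train/test split (default 35 train / rest test);
2. pretreatment, fit on the training spectra only, applied to both sets;
3. PCA to ``n_pcs`` latent variables (default 7), fit on train only;
4. discriminant extraction on the training scores -- classical LDA,
   matrix-exponential iLDA, or fuzzy FiLDA (which first builds a fuzzy
   partition of the training scores);
5. projection of both sets onto the q = c-1 discriminant vectors;
6. KNN fit on the projected training set (K fixed or chosen by
   leave-one-out cross-validation) and evaluation on the projected test
   set.

Every stage with learnable state is fit on the training split alone, so
reported accuracies are leakage-free.  Given the same data, configuration
and seed, the whole run is bit-reproducible: the master seed expands into
per-stage sub-seeds through ``numpy.random.SeedSequence``.

:func:`run_grid` sweeps the pretreatment x method comparison grid and
averages each cell's test accuracy over seeds.
"""

from __future__ import annotations

import logging
import time
from contextlib import contextmanager
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .classification import (
    ConfusionResult,
    KNNModel,
    knn_fit,
    knn_predict,
    select_k,
)
from .datasets import GeneratorConfig, generate_spectra
from .discriminant import DiscriminantModel, fit_filda, fit_ilda, fit_lda, project
from .fuzzy import DEFAULT_ETA, FuzzyPartition, fuzzy_memberships
from .io import MODEL_SCHEMA_VERSION
from .pca import PCAModel, fit_pca, transform_pca
from .preprocessing import FittedPreprocessor, PreprocessConfig
from .spectra import SpectraSet, ValidationError

__all__ = [
    "ExperimentConfig",
    "ExperimentResult",
    "PipelineModel",
    "GridResult",
    "stratified_split",
    "run_experiment",
    "run_grid",
    "derive_seeds",
    "METHODS",
]

logger = logging.getLogger(__name__)

METHODS = ("lda", "ilda", "filda")


def derive_seeds(master_seed: int, n: int) -> list[int]:
    """Expand one master seed into ``n`` independent sub-seeds (< 2**31).

    Sub-seed ``i`` comes from the ``i``-th spawned child of
    ``SeedSequence(master_seed)``, so stages never share a stream.
    """
    children = np.random.SeedSequence(master_seed).spawn(n)
    return [int(c.generate_state(1)[0] % (2**31)) for c in children]


def stratified_split(
    s: SpectraSet, per_class_train: int, seed: int
) -> tuple[SpectraSet, SpectraSet]:
    """Per-class random split: exactly ``per_class_train`` samples of every
    class go to train, the remainder to test (each class must keep at
    least one test sample).  Seeded shuffling within each class makes the
    split reproducible; train/test are disjoint and exhaustive.
    """
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for c in s.classes:
        members = np.flatnonzero(s.labels == c)
        if members.size < per_class_train + 1:
            raise ValidationError(
                f"class {c} has {members.size} samples; needs at least "
                f"{per_class_train + 1} for a {per_class_train}-train split"
            )
        perm = rng.permutation(members)
        train_idx.extend(perm[:per_class_train].tolist())
        test_idx.extend(perm[per_class_train:].tolist())
    return s.subset(sorted(train_idx)), s.subset(sorted(test_idx))


@dataclass(frozen=True)
class ExperimentConfig:
    """Complete description of one pipeline run."""

    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    n_pcs: int = 7
    method: str = "filda"
    eta: float = DEFAULT_ETA
    membership_mode: str = "supervised_oneshot"
    k_neighbors: Union[str, int] = "auto"
    per_class_train: int = 35
    seed: int = 0
    class_weighted_sb: bool = False
    expm_overflow_guard: bool = True

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValidationError(f"method must be one of {METHODS}, got {self.method!r}")
        if self.n_pcs < 1:
            raise ValidationError(f"n_pcs must be >= 1, got {self.n_pcs}")
        if self.per_class_train < 1:
            raise ValidationError(f"per_class_train must be >= 1, got {self.per_class_train}")
        if isinstance(self.k_neighbors, str) and self.k_neighbors != "auto":
            raise ValidationError(
                f"k_neighbors must be 'auto' or a positive integer, got {self.k_neighbors!r}"
            )
        if isinstance(self.k_neighbors, int) and self.k_neighbors < 1:
            raise ValidationError(f"k_neighbors must be >= 1, got {self.k_neighbors}")


@dataclass
class PipelineModel:
    """All fitted stages of one run, applicable to new spectra."""

    preprocessor: FittedPreprocessor
    pca: PCAModel
    discriminant: DiscriminantModel
    knn: KNNModel
    partition: Optional[FuzzyPartition] = None

    def transform(self, s: SpectraSet) -> SpectraSet:
        """Raw spectra -> discriminant-vector space."""
        return project(self.discriminant, transform_pca(self.pca, self.preprocessor.transform(s)))

    def predict(self, s: SpectraSet) -> tuple[np.ndarray, ConfusionResult]:
        n_classes = self.discriminant.class_means_projected.shape[0]
        return knn_predict(self.knn, self.transform(s), n_classes=n_classes)

    # -- serialization -------------------------------------------------
    def to_document(self) -> dict:
        doc = {
            "schema_version": MODEL_SCHEMA_VERSION,
            "preprocess": {
                "method": self.preprocessor.config.method,
                "sg_order": self.preprocessor.config.sg_order,
                "sg_window": self.preprocessor.config.effective_sg_window,
                "snv_ddof": self.preprocessor.config.snv_ddof,
                "reference": self.preprocessor.reference,
            },
            "pca": {
                "mean": self.pca.mean,
                "loadings": self.pca.loadings,
                "eigenvalues": self.pca.eigenvalues,
                "k": self.pca.k,
            },
            "discriminant": {
                "method": self.discriminant.method,
                "W": self.discriminant.W,
                "eigenvalues": self.discriminant.eigenvalues,
                "class_means_projected": self.discriminant.class_means_projected,
                "q": self.discriminant.q,
            },
            "knn": {
                "reference_points": self.knn.reference_points,
                "reference_labels": self.knn.reference_labels,
                "reference_ids": list(self.knn.reference_ids),
                "k": self.knn.k,
            },
            "fuzzy": None,
        }
        if self.partition is not None:
            doc["fuzzy"] = {
                "eta": self.partition.eta,
                "c": self.partition.c,
                "centers": self.partition.centers,
            }
        return doc

    @classmethod
    def from_document(cls, doc: dict) -> "PipelineModel":
        pp = doc["preprocess"]
        config = PreprocessConfig(
            method=pp["method"],
            sg_order=pp["sg_order"],
            sg_window=pp["sg_window"],
            snv_ddof=pp.get("snv_ddof", 1),
        )
        ref = pp.get("reference")
        preprocessor = FittedPreprocessor(
            config=config, reference=None if ref is None else np.asarray(ref, dtype=float)
        )
        p = doc["pca"]
        pca = PCAModel(
            mean=p["mean"], loadings=p["loadings"], eigenvalues=p["eigenvalues"], k=p["k"]
        )
        d = doc["discriminant"]
        discriminant = DiscriminantModel(
            W=np.asarray(d["W"], dtype=float),
            method=d["method"],
            eigenvalues=np.asarray(d["eigenvalues"], dtype=float),
            class_means_projected=np.asarray(d["class_means_projected"], dtype=float),
            q=int(d["q"]),
        )
        k = doc["knn"]
        knn = KNNModel(
            reference_points=k["reference_points"],
            reference_labels=k["reference_labels"],
            reference_ids=k["reference_ids"],
            k=int(k["k"]),
        )
        partition = None
        fz = doc.get("fuzzy")
        if fz:
            # training memberships are not stored; keep the parameters
            c = int(fz["c"])
            partition = FuzzyPartition(
                U=np.full((1, c), 1.0 / c),
                centers=np.asarray(fz["centers"], dtype=float),
                eta=float(fz["eta"]),
                c=c,
            )
        return cls(
            preprocessor=preprocessor,
            pca=pca,
            discriminant=discriminant,
            knn=knn,
            partition=partition,
        )


@dataclass
class ExperimentResult:
    """Outcome of :func:`run_experiment`."""

    config: ExperimentConfig
    model: PipelineModel
    confusion: ConfusionResult
    predicted_labels: np.ndarray
    chosen_k: int
    train_ids: list[str]
    test_ids: list[str]

    @property
    def accuracy(self) -> float:
        return self.confusion.accuracy

    def report(self) -> dict:
        """Machine-readable run summary (JSON-safe via io.save_model_json)."""
        return {
            "schema_version": MODEL_SCHEMA_VERSION,
            "method": self.config.method,
            "preprocess": self.config.preprocess.method,
            "n_pcs": self.config.n_pcs,
            "eta": self.config.eta,
            "per_class_train": self.config.per_class_train,
            "seed": self.config.seed,
            "chosen_k": self.chosen_k,
            "accuracy": self.confusion.accuracy,
            "confusion_counts": self.confusion.counts,
            "per_class_errors": self.confusion.per_class_errors,
            "n_train": len(self.train_ids),
            "n_test": len(self.test_ids),
        }


@contextmanager
def _stage(name: str):
    t0 = time.perf_counter()
    try:
        yield
    except Exception as exc:
        exc.args = (f"[stage {name}] {exc}",) + exc.args[1:]
        raise
    finally:
        logger.info("stage %-12s %.3f s", name, time.perf_counter() - t0)


def run_experiment(config: ExperimentConfig, data: SpectraSet) -> ExperimentResult:
    """Run the full split/pretreat/PCA/discriminant/KNN pipeline once."""
    c = data.n_classes
    q = c - 1
    if c < 2:
        raise ValidationError(f"need >= 2 classes, got {c}")
    if config.n_pcs < q:
        raise ValidationError(
            f"n_pcs={config.n_pcs} is smaller than the number of discriminant "
            f"vectors q={q} for c={c} classes"
        )
    (split_seed,) = derive_seeds(config.seed, 1)

    with _stage("split"):
        train, test = stratified_split(data, config.per_class_train, split_seed)
    with _stage("preprocess"):
        preprocessor = FittedPreprocessor.fit(config.preprocess, train)
        train_p = preprocessor.transform(train)
        test_p = preprocessor.transform(test)
    with _stage("pca"):
        pca = fit_pca(train_p, k=config.n_pcs)
        train_scores = transform_pca(pca, train_p)
        test_scores = transform_pca(pca, test_p)
    partition = None
    with _stage("discriminant"):
        if config.method == "lda":
            disc = fit_lda(train_scores, class_weighted_sb=config.class_weighted_sb)
        elif config.method == "ilda":
            disc = fit_ilda(
                train_scores,
                class_weighted_sb=config.class_weighted_sb,
                overflow_guard=config.expm_overflow_guard,
            )
        else:
            partition = fuzzy_memberships(
                train_scores, eta=config.eta, mode=config.membership_mode
            )
            disc = fit_filda(
                train_scores, partition, overflow_guard=config.expm_overflow_guard
            )
        train_dv = project(disc, train_scores)
        test_dv = project(disc, test_scores)
    with _stage("knn"):
        if config.k_neighbors == "auto":
            chosen_k, _ = select_k(train_dv)
        else:
            chosen_k = int(config.k_neighbors)
        knn = knn_fit(train_dv, chosen_k)
        predicted, confusion = knn_predict(knn, test_dv, n_classes=c)

    model = PipelineModel(
        preprocessor=preprocessor, pca=pca, discriminant=disc, knn=knn, partition=partition
    )
    return ExperimentResult(
        config=config,
        model=model,
        confusion=confusion,
        predicted_labels=predicted,
        chosen_k=chosen_k,
        train_ids=list(train.sample_ids),
        test_ids=list(test.sample_ids),
    )


# ----------------------------------------------------------------------
# comparison grid
# ----------------------------------------------------------------------

@dataclass
class GridResult:
    """Mean accuracy for every (pretreatment, method) cell across seeds."""

    cells: dict
    preprocess_names: list[str]
    methods: list[str]
    seeds: list[int]

    def mean_accuracy(self, preprocess_name: str, method: str) -> float:
        return self.cells[(preprocess_name, method)]["mean_accuracy"]

    def to_frame(self) -> pd.DataFrame:
        """Methods as rows, pretreatments as columns (comparison-table layout)."""
        data = {
            pp: [self.cells[(pp, m)].get("mean_accuracy") for m in self.methods]
            for pp in self.preprocess_names
        }
        return pd.DataFrame(data, index=[f"PCA + {m.upper()}" for m in self.methods])

    def to_document(self) -> dict:
        return {
            "schema_version": MODEL_SCHEMA_VERSION,
            "seeds": self.seeds,
            "methods": self.methods,
            "preprocess": self.preprocess_names,
            "cells": [
                {
                    "preprocess": pp,
                    "method": m,
                    "mean_accuracy": cell.get("mean_accuracy"),
                    "accuracies": cell.get("accuracies"),
                    "confusion_total": cell.get("confusion_total"),
                    "error": cell.get("error"),
                }
                for (pp, m), cell in self.cells.items()
            ],
        }


def run_grid(
    preprocess_configs: Sequence[PreprocessConfig],
    methods: Sequence[str],
    seeds: Sequence[int],
    data: Optional[SpectraSet] = None,
    generator: Optional[GeneratorConfig] = None,
    base_config: Optional[ExperimentConfig] = None,
) -> GridResult:
    """Sweep the pretreatment x method grid, averaging accuracy over seeds.

    Exactly one of ``data`` (a fixed spectra set, re-split per seed) or
    ``generator`` (fresh synthetic spectra drawn per seed) must be given.
    A failure in one cell is recorded in that cell and the sweep continues.
    """
    if (data is None) == (generator is None):
        raise ValidationError("provide exactly one of data= or generator=")
    if not seeds:
        raise ValidationError("at least one seed is required")
    base = base_config if base_config is not None else ExperimentConfig()

    datasets: dict[int, SpectraSet] = {}
    for seed in seeds:
        if generator is not None:
            _, gen_seed = derive_seeds(seed, 2)  # child 0 is the split seed
            datasets[seed] = generate_spectra(replace(generator, seed=gen_seed))
        else:
            datasets[seed] = data

    cells: dict = {}
    for pp in preprocess_configs:
        for method in methods:
            accuracies = []
            confusion_total = None
            error = None
            for seed in seeds:
                config = replace(base, preprocess=pp, method=method, seed=seed)
                try:
                    result = run_experiment(config, datasets[seed])
                except Exception as exc:  # record and keep sweeping
                    error = f"{type(exc).__name__}: {exc}"
                    logger.warning("grid cell (%s, %s) failed: %s", pp.method, method, error)
                    break
                accuracies.append(result.accuracy)
                if confusion_total is None:
                    confusion_total = result.confusion.counts.copy()
                else:
                    confusion_total += result.confusion.counts
            cell = {"error": error}
            if accuracies and error is None:
                cell.update(
                    mean_accuracy=float(np.mean(accuracies)),
                    accuracies=[float(a) for a in accuracies],
                    confusion_total=confusion_total,
                )
            cells[(pp.method, method)] = cell

    return GridResult(
        cells=cells,
        preprocess_names=[pp.method for pp in preprocess_configs],
        methods=list(methods),
        seeds=list(seeds),
    )
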