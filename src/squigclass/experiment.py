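"""End-to-end simulated two-species experiments.

Mirrors the simulated-data control strategy: two species are generated
from distinct random 6-mer pore models (or from one shared genome and
pore model for the null control), the classifier is trained with k-fold
cross-validation on randomly segmented read bodies, the best fold is
selected by validation accuracy, and test reads are scored from their
first post-adaptor window only.

The default sizes here are the CPU-scale study conditions: 1000 training
and 500 test reads per class, 1000-sample segments, a 2-stage network,
and at most 20 epochs per fold with early stopping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .classifier import ModelConfig, build_classifier
from .evaluate import EvalReport, evaluate_reads
from .preprocess import PreprocessConfig, preprocess_dataset
from .simulate import SimConfig, make_genome, make_pore_model, simulate_species_reads
from .training import (
    FoldResult,
    SegmentData,
    TrainConfig,
    make_folds,
    select_best_model,
    train_fold,
)

__all__ = ["ExperimentConfig", "ExperimentResult", "run_species_experiment",
           "segments_from_reads"]


@dataclass
class ExperimentConfig:
    """Scaled two-species experiment parameters (CPU study conditions)."""

    n_train_reads_per_class: int = 1000
    n_test_reads_per_class: int = 500
    genome_length: int = 100_000
    read_length_bases: int = 400
    kmer: int = 6
    segment_length: int = 1000
    trim_samples: int = 1500
    mad_threshold: float = 5.0
    null_control: bool = False
    model: ModelConfig = field(default_factory=lambda: ModelConfig(
        input_length=1000, n_stages=2))
    train: TrainConfig = field(default_factory=lambda: TrainConfig(
        n_folds=5, batch_reads=64, max_epochs=20,
        lr_patience_epochs=2, early_stop_patience_epochs=3,
        initial_lr=3e-3))

    def preprocess_config(self, seed: int = 0) -> PreprocessConfig:
        return PreprocessConfig(
            trim_samples=self.trim_samples,
            segment_length=self.segment_length,
            min_read_samples=self.trim_samples + self.segment_length,
            mad_threshold=self.mad_threshold,
            rng_seed=seed,
        )


@dataclass
class ExperimentResult:
    fold_results: list[FoldResult]
    best: FoldResult
    report: EvalReport
    #: per fold: (train read ids, validation read ids)
    fold_memberships: list[tuple[frozenset, frozenset]] = field(default_factory=list)

    @property
    def fold_accuracies(self) -> list[float]:
        return [r.best_val_acc for r in self.fold_results]

    @property
    def fold_spread(self) -> float:
        """Max minus min best-validation accuracy across folds."""
        accs = self.fold_accuracies
        return max(accs) - min(accs)


def segments_from_reads(reads, pcfg: PreprocessConfig, mode: str) -> SegmentData:
    """Preprocess labelled reads into a SegmentData container."""
    X, y, provenance, _ = preprocess_dataset(reads, pcfg, mode=mode)
    return SegmentData(X, y, np.array([s.read_id for s in provenance]))


def run_species_experiment(
    cfg: ExperimentConfig | None = None, seed: int = 1
) -> ExperimentResult:
    """Simulate, train with CV, select the best fold, evaluate on test reads.

    With ``cfg.null_control`` both "species" share one genome and one pore
    model, so test accuracy should sit at chance; otherwise the two pore
    models are independently drawn and the species are separable.
    """
    cfg = cfg or ExperimentConfig()
    ss = np.random.SeedSequence(seed)
    (pm_seed_a, pm_seed_b, g_seed_a, g_seed_b,
     train_seed_a, train_seed_b, test_seed_a, test_seed_b,
     cv_seed, build_seed) = (int(s) % (2**31) for s in ss.generate_state(10))

    model_a = make_pore_model(cfg.kmer, pm_seed_a)
    genome_a = make_genome(cfg.genome_length, g_seed_a)
    if cfg.null_control:
        model_b, genome_b = model_a, genome_a
    else:
        model_b = make_pore_model(cfg.kmer, pm_seed_b)
        genome_b = make_genome(cfg.genome_length, g_seed_b)

    sim_train = SimConfig(
        genome_length=cfg.genome_length,
        n_reads=cfg.n_train_reads_per_class,
        read_length_bases=cfg.read_length_bases,
    )
    sim_test = SimConfig(
        genome_length=cfg.genome_length,
        n_reads=cfg.n_test_reads_per_class,
        read_length_bases=cfg.read_length_bases,
    )
    train_reads = simulate_species_reads(genome_a, model_a, sim_train, 1, "trA", train_seed_a)
    train_reads += simulate_species_reads(genome_b, model_b, sim_train, 0, "trB", train_seed_b)
    test_reads = simulate_species_reads(genome_a, model_a, sim_test, 1, "teA", test_seed_a)
    test_reads += simulate_species_reads(genome_b, model_b, sim_test, 0, "teB", test_seed_b)

    pcfg = cfg.preprocess_config(seed=cv_seed)
    data = segments_from_reads(train_reads, pcfg, mode="train")

    tcfg = TrainConfig(**{**vars(cfg.train), "rng_seed": cv_seed})
    folds = make_folds(data, tcfg.n_folds, tcfg.rng_seed)
    results, memberships = [], []
    for f, (train, val) in enumerate(folds):
        model = build_classifier(cfg.model, seed=build_seed + f)
        results.append(
            train_fold(model, train, val, tcfg,
                       segments_per_read=pcfg.segments_per_read_train, fold_index=f)
        )
        memberships.append(
            (frozenset(train.read_ids.tolist()), frozenset(val.read_ids.tolist()))
        )
    best = select_best_model(results)
    report = evaluate_reads(best.model, test_reads, pcfg, batch_reads=tcfg.batch_reads)
    return ExperimentResult(results, best, report, memberships)
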