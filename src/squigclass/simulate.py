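"""Pore-model squiggle simulator.

Generates synthetic nanopore reads from a k-mer pore model: each k-mer of
a random genome substring contributes ~9 consecutive signal samples (the
dwell) at that k-mer's expected current level plus Gaussian noise, preceded
by an adaptor-like block of broadband noise, and the whole pA trace is
digitized to 16-bit ADC counts by inverting the standard pA conversion.

The simulator is deliberately simple — no event warping, no long-range
drift — but exercises every stage of the pipeline and supports clean
positive controls (two distinct pore models => separable species) and null
controls (shared genome + pore model => chance-level separability).
"""

from __future__ import annotations

import itertools
import os
from dataclasses import dataclass

import numpy as np

from .signal_io import (
    INT16_MAX,
    INT16_MIN,
    RawRead,
    write_label_manifest,
    write_slow5,
)

__all__ = [
    "PoreModel",
    "SimConfig",
    "make_pore_model",
    "make_genome",
    "simulate_read",
    "simulate_dataset",
]

BASES = "ACGT"

#: pA band in which random pore-model levels are drawn
LEVEL_LOW, LEVEL_HIGH = 60.0, 130.0


@dataclass
class PoreModel:
    """k-mer -> expected current level table with noise/dwell parameters.

    ``dwell_mean`` defaults to 9 samples/base, consistent with DNA
    translocating at ~450 bases/s sampled at 4 kHz (~8-10 samples/base).
    """

    k: int
    level_mean: dict[str, float]
    level_sd: float = 1.5
    dwell_mean: float = 9.0
    dwell_sd: float = 1.0

    def __post_init__(self) -> None:
        expected = 4**self.k
        if len(self.level_mean) != expected:
            raise ValueError(
                f"pore model must cover all {expected} {self.k}-mers, "
                f"got {len(self.level_mean)}"
            )
        if self.level_sd < 0 or self.dwell_sd < 0:
            raise ValueError("level_sd and dwell_sd must be nonnegative")
        if self.dwell_mean <= 0:
            raise ValueError("dwell_mean must be positive")

    def levels_for(self, sequence: str) -> np.ndarray:
        """Expected level of each successive k-mer of ``sequence``."""
        k = self.k
        return np.array(
            [self.level_mean[sequence[i : i + k]] for i in range(len(sequence) - k + 1)]
        )


@dataclass
class SimConfig:
    """Dataset-level simulation parameters.

    Defaults give reads of ~1500 + 333*9 ≈ 4500 samples so that simulated
    reads qualify for training under the default preprocessing rule.
    Digitiser metadata mirrors a typical R9.4.1 MinION setup.
    """

    genome_length: int = 100_000
    n_reads: int = 100
    read_length_bases: int = 400
    adaptor_samples: int = 1500
    digitisation: float = 8192.0
    offset: float = 10.0
    range_pA: float = 1400.0
    sampling_rate: float = 4000.0
    rng_seed: int = 0
    #: adaptor block: broadband noise at a shifted mean, distinct from
    #: genomic signal so that trimming is meaningful
    adaptor_mean_pA: float = 70.0
    adaptor_sd_pA: float = 15.0

    def __post_init__(self) -> None:
        for name in ("genome_length", "n_reads", "read_length_bases"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.adaptor_samples < 0:
            raise ValueError("adaptor_samples must be nonnegative")


def make_pore_model(k: int, seed: int, **kwargs) -> PoreModel:
    """Random pore model with one expected level per k-mer, in [60, 130] pA.

    Levels follow a random position-weight construction, mirroring the
    approximately additive chemistry of real pores: each position in the
    k-mer contributes a base-specific random offset, plus a small k-mer-
    specific residual, and the table is affinely mapped onto the pA band.
    Because successive k-mers overlap in k-1 bases, this gives each model
    a characteristic level-transition texture — which is what
    distinguishes species after per-segment normalization removes
    absolute scale.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(seed)
    weights = rng.uniform(-1.0, 1.0, size=(k, 4))
    residual_sd = 0.1
    kmers = []
    raw = np.empty(4**k)
    base_index = {b: i for i, b in enumerate(BASES)}
    for i, p in enumerate(itertools.product(BASES, repeat=k)):
        kmers.append("".join(p))
        raw[i] = sum(weights[j, base_index[b]] for j, b in enumerate(p))
    raw += rng.normal(0.0, residual_sd, size=raw.size)
    lo, hi = raw.min(), raw.max()
    levels = LEVEL_LOW + (raw - lo) * (LEVEL_HIGH - LEVEL_LOW) / (hi - lo)
    return PoreModel(k=k, level_mean=dict(zip(kmers, levels)), **kwargs)


def make_genome(length: int, seed: int) -> str:
    """Random genome with uniform base composition."""
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    return "".join(np.array(list(BASES))[rng.integers(0, 4, size=length)])


def digitize(pa: np.ndarray, cfg: SimConfig) -> np.ndarray:
    """Invert the pA conversion: raw = round(pA * digitisation/range - offset)."""
    raw = np.rint(pa * cfg.digitisation / cfg.range_pA - cfg.offset)
    return np.clip(raw, INT16_MIN, INT16_MAX).astype(np.int16)


def simulate_read(
    genome: str,
    pore_model: PoreModel,
    cfg: SimConfig,
    seed: int,
    read_id: str = "read",
    label: int | None = None,
    truth: dict | None = None,
) -> RawRead:
    """Simulate one read from a uniformly chosen genome substring.

    Signal = adaptor noise block, then per k-mer round(dwell) samples at
    level_mean[kmer] + N(0, level_sd); digitized to int16 ADC counts.
    If a ``truth`` dict is supplied it is filled with the ground truth
    (genome start, fragment, per-k-mer levels and dwells) for validation.
    """
    k = pore_model.k
    span = cfg.read_length_bases + k
    if len(genome) < span:
        raise ValueError("genome shorter than read_length_bases + k")
    rng = np.random.default_rng(seed)
    start = int(rng.integers(0, len(genome) - span + 1))
    fragment = genome[start : start + span]
    levels = pore_model.levels_for(fragment)

    dwells = np.rint(
        rng.normal(pore_model.dwell_mean, pore_model.dwell_sd, size=levels.size)
    ).astype(np.int64)
    dwells = np.maximum(dwells, 1)
    body = np.repeat(levels, dwells)
    if pore_model.level_sd > 0:
        body = body + rng.normal(0.0, pore_model.level_sd, size=body.size)
    adaptor = rng.normal(cfg.adaptor_mean_pA, cfg.adaptor_sd_pA, cfg.adaptor_samples)
    pa = np.concatenate([adaptor, body])
    if truth is not None:
        truth.update(start=start, fragment=fragment, levels=levels, dwells=dwells)
    return RawRead(
        read_id=read_id,
        raw_signal=digitize(pa, cfg),
        digitisation=cfg.digitisation,
        offset=cfg.offset,
        range_pA=cfg.range_pA,
        sampling_rate=cfg.sampling_rate,
        label=label,
    )


def simulate_species_reads(
    genome: str,
    pore_model: PoreModel,
    cfg: SimConfig,
    label: int,
    prefix: str,
    seed: int,
) -> list[RawRead]:
    """Simulate ``cfg.n_reads`` labelled reads from one species."""
    seeds = np.random.SeedSequence(seed).generate_state(cfg.n_reads)
    return [
        simulate_read(
            genome, pore_model, cfg, int(s) % (2**31), f"{prefix}_{i:05d}", label
        )
        for i, s in enumerate(seeds)
    ]


def simulate_dataset(
    cfg: SimConfig,
    species_a_model: PoreModel,
    species_b_model: PoreModel,
    out_slow5: str | os.PathLike,
    out_manifest: str | os.PathLike,
    genome_a: str | None = None,
    genome_b: str | None = None,
) -> list[RawRead]:
    """Simulate a balanced two-species dataset and write SLOW5 + manifest.

    Species A reads get label 1 (target), species B label 0. Passing the
    same genome and pore model for both species yields the null control.
    Fully reproducible from ``cfg.rng_seed``.
    """
    root = np.random.SeedSequence(cfg.rng_seed)
    g_seed_a, g_seed_b, r_seed_a, r_seed_b = (int(s) % (2**31) for s in root.generate_state(4))
    if genome_a is None:
        genome_a = make_genome(cfg.genome_length, g_seed_a)
    if genome_b is None:
        genome_b = make_genome(cfg.genome_length, g_seed_b)
    reads = simulate_species_reads(genome_a, species_a_model, cfg, 1, "spA", r_seed_a)
    reads += simulate_species_reads(genome_b, species_b_model, cfg, 0, "spB", r_seed_b)
    write_slow5(reads, out_slow5)
    write_label_manifest([(r.read_id, r.label) for r in reads], out_manifest)
    return reads
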