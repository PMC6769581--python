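"""Synthetic genotype matrices with controllable linkage structure.

Two structural emulators cover the regimes in which reference-free
imputation is typically benchmarked:

* :func:`simulate_cross` — a two-parent haploid cross. Each offspring
  genome is a Markov mosaic of the two parental genotypes, so rows show
  long runs of identical class broken by rare crossover switches. Local
  correlation is near-perfect; marginal class frequencies are balanced,
  so column-wise (per-marker) imputation is near chance while any method
  exploiting neighbouring markers can do very well.

* :func:`simulate_population` — diploid population genotypes with
  haplotype-block linkage disequilibrium and a strongly skewed genotype
  distribution (the homozygous-reference class dominates, as in a short
  dense human region). Column-wise imputation is already strong here and
  the LD signal is weaker and blockwise.

Neither is a population-genetics simulator (no coalescent, recombination
map or mutation model); they are structural emulators with tunable
difficulty.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml

from .genotype_io import (
    GenotypeMatrix,
    SplitSpec,
    mask_random,
    split_indices,
    write_mask_tsv,
    write_matrix_tsv,
)

__all__ = [
    "CrossSimConfig",
    "PopSimConfig",
    "simulate_cross",
    "simulate_population",
    "make_benchmark",
]


@dataclass(frozen=True)
class CrossSimConfig:
    """Two-parent cross simulator parameters.

    ``switch_rate`` is the probability that adjacent markers derive from
    different parents; its reciprocal is the mean parental run length in
    markers.
    """

    n_samples: int = 1000
    n_markers: int = 1024
    switch_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2 or self.n_markers < 2:
            raise ValueError("need at least 2 samples and 2 markers")
        if not 0.0 <= self.switch_rate <= 0.5:
            raise ValueError("switch_rate must be in [0, 0.5]")


@dataclass(frozen=True)
class PopSimConfig:
    """Haplotype-block population simulator parameters.

    Markers are grouped into blocks of ``block_length``; each block has a
    shared pool of ``haplotypes_per_block`` binary haplotypes whose
    per-marker alternate-allele probability is ``1 - ref_allele_bias``.
    Every individual draws two haplotypes per block (with replacement,
    blocks independent), so markers within a block are in strong LD while
    blocks are independent.
    """

    n_samples: int = 1000
    n_markers: int = 1024
    block_length: int = 16
    haplotypes_per_block: int = 6
    ref_allele_bias: float = 0.97
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2 or self.n_markers < 2:
            raise ValueError("need at least 2 samples and 2 markers")
        if self.block_length < 1:
            raise ValueError("block_length must be >= 1")
        if self.haplotypes_per_block < 2:
            raise ValueError("haplotypes_per_block must be >= 2")
        if not 0.5 < self.ref_allele_bias < 1.0:
            raise ValueError("ref_allele_bias must be in (0.5, 1)")


def simulate_cross(cfg: CrossSimConfig) -> GenotypeMatrix:
    """Simulate a haploid two-parent cross as a Markov parental mosaic.

    The first marker of each sample is drawn uniformly from {1, 2}; each
    subsequent marker switches parent with probability ``switch_rate``.
    The result has ``n_classes = 2`` and no missing entries.
    """
    rng = np.random.default_rng(cfg.seed)
    n, m = cfg.n_samples, cfg.n_markers
    first = rng.integers(0, 2, size=(n, 1))
    switches = rng.random((n, m - 1)) < cfg.switch_rate
    # parent index = first XOR (cumulative number of switches mod 2)
    parity = np.cumsum(switches, axis=1) % 2
    parents = np.concatenate([first, (first + parity) % 2], axis=1)
    return GenotypeMatrix(parents.astype(np.int64) + 1, 2, ploidy_mode="cross")


def simulate_population(cfg: PopSimConfig) -> GenotypeMatrix:
    """Simulate diploid genotypes with haplotype-block LD.

    Per block, a pool of binary haplotypes is drawn once and shared by all
    individuals; each individual draws two pool members and the genotype
    class is 1/2/3 by allele sum. ``n_classes = 3``, no missing entries.
    """
    rng = np.random.default_rng(cfg.seed)
    n, m = cfg.n_samples, cfg.n_markers
    alt_p = 1.0 - cfg.ref_allele_bias
    values = np.empty((n, m), dtype=np.int64)
    start = 0
    while start < m:
        stop = min(start + cfg.block_length, m)
        pool = (rng.random((cfg.haplotypes_per_block, stop - start)) < alt_p).astype(
            np.int64
        )
        picks = rng.integers(0, cfg.haplotypes_per_block, size=(n, 2))
        values[:, start:stop] = 1 + pool[picks[:, 0]] + pool[picks[:, 1]]
        start = stop
    return GenotypeMatrix(values, 3, ploidy_mode="diploid")


def realized_class_frequencies(cfg: PopSimConfig) -> np.ndarray:
    """Expected class frequencies implied by the haplotype pools the given
    config actually draws (replays the pool RNG stream without sampling
    individuals; individual draws are uniform over the pool)."""
    rng = np.random.default_rng(cfg.seed)
    alt_p = 1.0 - cfg.ref_allele_bias
    m = cfg.n_markers
    h = cfg.haplotypes_per_block
    freqs = np.zeros(3)
    start = 0
    while start < m:
        stop = min(start + cfg.block_length, m)
        pool = (rng.random((h, stop - start)) < alt_p).astype(np.int64)
        rng.integers(0, h, size=(cfg.n_samples, 2))  # keep streams aligned
        # per marker: P(class) under two uniform pool draws
        p_alt = pool.mean(axis=0)  # per-marker pool alternate frequency
        freqs[0] += np.sum((1 - p_alt) ** 2)
        freqs[1] += np.sum(2 * p_alt * (1 - p_alt))
        freqs[2] += np.sum(p_alt**2)
        start = stop
    return freqs / m


def make_benchmark(
    dataset_kind: str,
    missing_levels: list[float],
    seed: int,
    out_dir: str | Path,
    cross_cfg: CrossSimConfig | None = None,
    pop_cfg: PopSimConfig | None = None,
    split: SplitSpec | None = None,
) -> dict:
    """Simulate, corrupt at each missing level, split 65/15/20 and serialize.

    One base matrix is simulated per benchmark and masked independently at
    each level. Writes, per level, the clean and corrupted train/val/test
    matrices plus the mask TSV, and a YAML manifest recording seeds,
    configs and file paths. Returns the manifest dict.
    """
    for level in missing_levels:
        if not 0.0 < level < 1.0:
            raise ValueError(f"missing level {level} outside (0,1)")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if dataset_kind == "cross":
        cfg = cross_cfg or CrossSimConfig(seed=seed)
        gm = simulate_cross(cfg)
    elif dataset_kind == "population":
        cfg = pop_cfg or PopSimConfig(seed=seed)
        gm = simulate_population(cfg)
    else:
        raise ValueError(f"unknown dataset_kind {dataset_kind!r}")
    split = split or SplitSpec(seed=seed + 1)

    manifest: dict = {
        "dataset_kind": dataset_kind,
        "seed": seed,
        "simulator_config": asdict(cfg),
        "split": asdict(split),
        "n_classes": gm.n_classes,
        "levels": [],
    }
    idx_train, idx_val, idx_test = split_indices(gm.n_samples, split)
    parts = {"train": idx_train, "val": idx_val, "test": idx_test}
    for level in missing_levels:
        mask_seed = seed + int(round(level * 10000))
        corrupted, mask = mask_random(gm, level, mask_seed)
        tag = f"{dataset_kind}_miss{int(round(level * 100)):02d}"
        entry = {
            "missing_level": level,
            "mask_seed": mask_seed,
            "n_masked": int(len(mask)),
            "mask_file": f"{tag}_mask.tsv",
            "files": {},
        }
        write_mask_tsv(mask, out_dir / entry["mask_file"])
        for part, idx in parts.items():
            clean_f = f"{tag}_{part}_clean.tsv"
            corr_f = f"{tag}_{part}_corrupted.tsv"
            write_matrix_tsv(gm.take_samples(idx), out_dir / clean_f)
            write_matrix_tsv(corrupted.take_samples(idx), out_dir / corr_f)
            entry["files"][part] = {"clean": clean_f, "corrupted": corr_f}
        manifest["levels"].append(entry)
    with open(out_dir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest
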