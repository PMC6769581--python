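"""Genotype matrices: containers, encodings, corruption, splitting and file I/O.

Genotype classes are small positive integers; ``0`` always means *missing*.
Two encodings are supported:

* ``cross`` — two-parent haploid cross data (e.g. a yeast BY×RM segregant
  panel): parent-1 alleles are class ``1``, parent-2 alleles class ``2``
  (raw ``-1`` calls are recoded to ``2`` so that all entries are
  non-negative), ``n_classes = 2``.
* ``diploid`` — biallelic diploid genotypes: ``0|0 → 1``, ``0|1``/``1|0``
  ``→ 2``, ``1|1 → 3``, ``n_classes = 3``.

Deliberate corruption ("masking to zeros") is recorded in a
:class:`MaskIndex` so the held-out truth can be restored and scored.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeMatrix",
    "MaskIndex",
    "SplitSpec",
    "ImputationResult",
    "read_vcf",
    "write_vcf",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_mask_tsv",
    "write_mask_tsv",
    "recode_cross",
    "mask_random",
    "unmask",
    "split_samples",
    "one_hot",
    "decode_argmax",
]


@dataclass
class GenotypeMatrix:
    """A samples × markers matrix of integer genotype classes (0 = missing).

    Parameters
    ----------
    values
        Integer array of shape ``(n_samples, n_markers)`` with entries in
        ``{0, 1, ..., n_classes}``.
    n_classes
        Number of valid (non-missing) genotype classes: 2 for cross data,
        3 for biallelic diploid data.
    sample_ids, marker_ids
        Row / column labels; autogenerated if omitted.
    ploidy_mode
        ``"cross"`` or ``"diploid"``.
    """

    values: np.ndarray
    n_classes: int
    sample_ids: list[str] = field(default_factory=list)
    marker_ids: list[str] = field(default_factory=list)
    ploidy_mode: str = "diploid"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D samples × markers array")
        if not np.issubdtype(self.values.dtype, np.integer):
            raise ValueError("genotype values must be integers")
        if self.ploidy_mode not in ("cross", "diploid"):
            raise ValueError(f"unknown ploidy_mode {self.ploidy_mode!r}")
        n, m = self.values.shape
        if not self.sample_ids:
            self.sample_ids = [f"S{i}" for i in range(n)]
        if not self.marker_ids:
            self.marker_ids = [f"M{j}" for j in range(m)]
        if len(self.sample_ids) != n or len(self.marker_ids) != m:
            raise ValueError("id list lengths do not match matrix shape")
        bad = (self.values < 0) | (self.values > self.n_classes)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"entry ({i},{j})={self.values[i, j]} outside "
                f"{{0,...,{self.n_classes}}}"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean array, True where the entry is missing."""
        return self.values == 0

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.values.copy(),
            self.n_classes,
            list(self.sample_ids),
            list(self.marker_ids),
            self.ploidy_mode,
        )

    def take_samples(self, idx: np.ndarray) -> "GenotypeMatrix":
        """Row subset preserving marker metadata."""
        idx = np.asarray(idx)
        return GenotypeMatrix(
            self.values[idx],
            self.n_classes,
            [self.sample_ids[i] for i in idx],
            list(self.marker_ids),
            self.ploidy_mode,
        )


@dataclass
class MaskIndex:
    """Coordinates deliberately masked to 0, with held-out original values."""

    coords: np.ndarray  # (n_masked, 2) int array of (sample, marker)
    original_values: np.ndarray  # (n_masked,) int array, valid classes
    fraction: float

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.int64).reshape(-1, 2)
        self.original_values = np.asarray(self.original_values, dtype=np.int64)
        if len(self.coords) != len(self.original_values):
            raise ValueError("coords and original_values lengths differ")
        if (self.original_values <= 0).any():
            raise ValueError("original values must be valid non-zero classes")

    def __len__(self) -> int:
        return len(self.coords)

    def restrict_rows(self, rows: np.ndarray) -> "MaskIndex":
        """Mask restricted to a sample subset, rows renumbered to the subset."""
        rows = np.asarray(rows)
        remap = {int(r): i for i, r in enumerate(rows)}
        keep = np.array([int(r) in remap for r in self.coords[:, 0]], dtype=bool)
        coords = self.coords[keep].copy()
        coords[:, 0] = np.array([remap[int(r)] for r in coords[:, 0]], dtype=np.int64)
        return MaskIndex(coords, self.original_values[keep], self.fraction)


@dataclass(frozen=True)
class SplitSpec:
    """Sample-wise train/validation/test partition fractions."""

    train_frac: float = 0.65
    val_frac: float = 0.15
    test_frac: float = 0.20
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = (self.train_frac, self.val_frac, self.test_frac)
        if any(f <= 0 for f in fracs):
            raise ValueError("split fractions must be positive")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


@dataclass
class ImputationResult:
    """A completed genotype matrix, optionally with class probabilities.

    ``completed`` preserves every observed entry of the corrupted input and
    fills each missing entry with a valid class. ``probabilities`` (where the
    method provides them) has shape ``(n_samples, n_markers, n_classes)`` with
    rows summing to 1.
    """

    completed: GenotypeMatrix
    probabilities: np.ndarray | None = None
    mask_used: MaskIndex | None = None
    info: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# VCF I/O (diploid 1/2/3 encoding)
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read biallelic diploid GT fields from a VCF into the 1/2/3 encoding.

    ``0|0 → 1``, ``0|1``/``1|0`` ``→ 2``, ``1|1 → 3``; missing calls
    (``./.``) → 0. Phased and unphased separators are treated identically.
    Multiallelic or non-diploid records are skipped with a warning.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    columns: list[np.ndarray] = []
    marker_ids: list[str] = []
    n_skipped = 0
    for variant in vcf:
        if len(variant.ALT) != 1:
            n_skipped += 1
            continue
        gts = variant.genotypes  # [[a0, a1, phased], ...]
        if any(len(g) != 3 for g in gts):
            n_skipped += 1
            continue
        col = np.empty(len(gts), dtype=np.int64)
        for i, (a0, a1, _phased) in enumerate(gts):
            if a0 < 0 or a1 < 0:
                col[i] = 0
            else:
                col[i] = 1 + a0 + a1
        columns.append(col)
        marker_ids.append(variant.ID or f"{variant.CHROM}:{variant.POS}")
    vcf.close()
    if n_skipped:
        logger.warning("skipped %d multiallelic/non-diploid records", n_skipped)
    if not columns:
        raise ValueError(f"no usable biallelic diploid records in {path}")
    values = np.stack(columns, axis=1)
    return GenotypeMatrix(values, 3, sample_ids, marker_ids, "diploid")


def write_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write a diploid 1/2/3-encoded matrix as a minimal VCF 4.2 file.

    Class 2 (heterozygote) is emitted as ``0|1``; positions are 1-based
    marker indices on a synthetic contig.
    """
    if gm.ploidy_mode != "diploid":
        raise ValueError("only diploid matrices can be written as VCF")
    gt_of = {0: "./.", 1: "0|0", 2: "0|1", 3: "1|1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID=1,length={gm.n_markers + 1}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.sample_ids)
            + "\n"
        )
        for j in range(gm.n_markers):
            gts = "\t".join(gt_of[int(v)] for v in gm.values[:, j])
            fh.write(f"1\t{j + 1}\t{gm.marker_ids[j]}\tA\tG\t.\tPASS\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# Delimited text I/O
# ---------------------------------------------------------------------------

def write_matrix_tsv(gm: GenotypeMatrix, path: str | Path) -> None:
    """Samples in rows, markers in columns, header of marker ids, first
    column the sample id."""
    df = pd.DataFrame(gm.values, index=gm.sample_ids, columns=gm.marker_ids)
    df.index.name = "sample"
    df.to_csv(path, sep="\t")


def read_matrix_tsv(
    path: str | Path, n_classes: int, ploidy_mode: str = "diploid"
) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return GenotypeMatrix(
        df.to_numpy(dtype=np.int64),
        n_classes,
        [str(s) for s in df.index],
        [str(m) for m in df.columns],
        ploidy_mode,
    )


def write_mask_tsv(mask: MaskIndex, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "sample_idx": mask.coords[:, 0],
            "marker_idx": mask.coords[:, 1],
            "original_class": mask.original_values,
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_mask_tsv(path: str | Path, fraction: float) -> MaskIndex:
    df = pd.read_csv(path, sep="\t")
    coords = df[["sample_idx", "marker_idx"]].to_numpy(dtype=np.int64)
    return MaskIndex(coords, df["original_class"].to_numpy(dtype=np.int64), fraction)


# ---------------------------------------------------------------------------
# Encoding and corruption
# ---------------------------------------------------------------------------

def recode_cross(raw: np.ndarray, missing_code: int | None = None) -> GenotypeMatrix:
    """Recode a two-parent cross matrix from {-1, 1} to classes {2, 1}.

    ``-1 → 2``, ``1 → 1``; an optional declared missing sentinel maps to 0.
    Any other entry raises a validation error naming the offending cell.
    """
    raw = np.asarray(raw)
    if raw.ndim != 2:
        raise ValueError("raw cross matrix must be 2-D")
    values = np.zeros(raw.shape, dtype=np.int64)
    ok = np.zeros(raw.shape, dtype=bool)
    values[raw == 1] = 1
    ok |= raw == 1
    values[raw == -1] = 2
    ok |= raw == -1
    if missing_code is not None:
        ok |= raw == missing_code
    if not ok.all():
        i, j = np.argwhere(~ok)[0]
        raise ValueError(f"invalid cross genotype {raw[i, j]} at cell ({i},{j})")
    return GenotypeMatrix(values, 2, ploidy_mode="cross")


def mask_random(
    gm: GenotypeMatrix, fraction: float, seed: int
) -> tuple[GenotypeMatrix, MaskIndex]:
    """Mask a random fraction of the *non-missing* entries to 0.

    Exactly ``round(fraction * n_nonmissing)`` entries are chosen uniformly
    without replacement among currently observed entries; the choice is
    reproducible from ``seed``.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must be in (0,1), got {fraction}")
    flat = gm.values.ravel()
    pool = np.flatnonzero(flat != 0)
    n_mask = int(round(fraction * pool.size))
    if n_mask > pool.size:
        raise ValueError("fewer non-missing entries than requested")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(pool, size=n_mask, replace=False)
    chosen.sort()
    coords = np.stack(np.unravel_index(chosen, gm.values.shape), axis=1)
    originals = flat[chosen].copy()
    corrupted = gm.copy()
    corrupted.values[coords[:, 0], coords[:, 1]] = 0
    return corrupted, MaskIndex(coords, originals, fraction)


def unmask(gm: GenotypeMatrix, mask: MaskIndex) -> GenotypeMatrix:
    """Restore masked entries from the held-out originals."""
    restored = gm.copy()
    restored.values[mask.coords[:, 0], mask.coords[:, 1]] = mask.original_values
    return restored


def split_samples(
    gm: GenotypeMatrix, spec: SplitSpec
) -> tuple[GenotypeMatrix, GenotypeMatrix, GenotypeMatrix]:
    """Disjoint sample-wise train/val/test partition.

    Validation and test sizes are ``floor(frac * n)`` (with a small float
    guard); the remainder goes to the training split. Reproducible from
    ``spec.seed``.
    """
    n = gm.n_samples
    if n < 3:
        raise ValueError("need at least 3 samples to split")
    n_val = int(spec.val_frac * n + 1e-9)
    n_test = int(spec.test_frac * n + 1e-9)
    n_train = n - n_val - n_test
    if min(n_train, n_val, n_test) < 1:
        raise ValueError(f"split of {n} samples leaves an empty part")
    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(n)
    idx_train = np.sort(perm[:n_train])
    idx_val = np.sort(perm[n_train : n_train + n_val])
    idx_test = np.sort(perm[n_train + n_val :])
    return (
        gm.take_samples(idx_train),
        gm.take_samples(idx_val),
        gm.take_samples(idx_test),
    )


def split_indices(n: int, spec: SplitSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Index triples underlying :func:`split_samples` (same rule and seed)."""
    n_val = int(spec.val_frac * n + 1e-9)
    n_test = int(spec.test_frac * n + 1e-9)
    n_train = n - n_val - n_test
    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(n)
    return (
        np.sort(perm[:n_train]),
        np.sort(perm[n_train : n_train + n_val]),
        np.sort(perm[n_train + n_val :]),
    )


# ---------------------------------------------------------------------------
# One-hot class channels
# ---------------------------------------------------------------------------

def one_hot(gm: GenotypeMatrix, dtype=np.float32) -> np.ndarray:
    """Encode classes as unit vectors over ``n_classes`` channels.

    Class ``c`` maps to the unit vector at channel ``c - 1``; missing (0)
    maps to the all-zero vector. Output shape is
    ``(n_samples, n_markers, n_classes)``.
    """
    n, m = gm.values.shape
    out = np.zeros((n, m, gm.n_classes), dtype=dtype)
    v = gm.values
    obs = v > 0
    i, j = np.nonzero(obs)
    out[i, j, v[i, j] - 1] = 1
    return out


def decode_argmax(tensor: np.ndarray, template: GenotypeMatrix) -> GenotypeMatrix:
    """Inverse of :func:`one_hot` for probability/one-hot tensors.

    Ties break toward the lowest class index (``argmax`` keeps the first
    maximum).
    """
    classes = np.argmax(tensor, axis=2).astype(np.int64) + 1
    return GenotypeMatrix(
        classes,
        template.n_classes,
        list(template.sample_ids),
        list(template.marker_ids),
        template.ploidy_mode,
    )
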