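"""Synthetic genotypes and phenotype record counts.

The rest of the package is exercised on simulated data: an n-individuals by
m-SNPs matrix of additive genotype codes drawn i.i.d. from {0 (AA), 1 (AB),
2 (BB)}, and a vector of per-individual phenotype record counts (the diagonal
of Z'Z in the no-fixed-effects animal model, where Z'Z is diagonal and Z is
never materialized).

Every operation takes an explicit integer seed and owns its own
``numpy.random.Generator``; there is no global random state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DimensionError, ValidationError

__all__ = [
    "GenotypeMatrix",
    "RecordCounts",
    "simulate_genotypes",
    "simulate_record_counts",
]


@dataclass
class GenotypeMatrix:
    """Genotypes for n individuals at m SNPs, coded 0/1/2 (AA/AB/BB).

    Parameters
    ----------
    ids
        Ordered, unique individual identifiers; length n.
    codes
        Integer matrix of shape (n, m) with entries in {0, 1, 2}.
    """

    ids: tuple[str, ...]
    codes: np.ndarray

    def __post_init__(self) -> None:
        self.ids = tuple(str(i) for i in self.ids)
        self.codes = np.asarray(self.codes)
        if self.codes.ndim != 2:
            raise DimensionError(
                f"codes must be 2-D (individuals x SNPs), got ndim={self.codes.ndim}"
            )
        n, m = self.codes.shape
        if n < 1 or m < 1:
            raise DimensionError(f"need n >= 1 individuals and m >= 1 SNPs, got {n}x{m}")
        if not np.issubdtype(self.codes.dtype, np.integer):
            if not np.all(self.codes == np.floor(self.codes)):
                raise ValidationError("genotype codes must be integers")
            self.codes = self.codes.astype(np.int64)
        if not np.isin(self.codes, (0, 1, 2)).all():
            bad = np.argwhere(~np.isin(self.codes, (0, 1, 2)))[0]
            raise ValidationError(
                f"genotype codes must be in {{0,1,2}}; offending entry at "
                f"row {bad[0]}, column {bad[1]}"
            )
        if len(self.ids) != n:
            raise DimensionError(f"{len(self.ids)} ids for {n} genotype rows")
        if len(set(self.ids)) != n:
            raise ValidationError("duplicate individual ids")

    @property
    def n_individuals(self) -> int:
        return self.codes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.codes.shape[1]


@dataclass
class RecordCounts:
    """Per-individual phenotype record counts: the diagonal of Z'Z."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 1:
            raise DimensionError("record counts must be a 1-D vector")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(self.counts == np.floor(self.counts)):
                raise ValidationError("record counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            raise ValidationError("record counts must be non-negative")

    def __len__(self) -> int:
        return self.counts.shape[0]


def simulate_genotypes(
    n: int,
    m: int,
    seed: int,
    code_probs: tuple[float, float, float] | None = None,
) -> GenotypeMatrix:
    """Draw an n x m matrix of i.i.d. genotype codes from {0, 1, 2}.

    ``code_probs`` defaults to the uniform distribution (1/3 each); passing
    e.g. Hardy-Weinberg proportions ``(q**2, 2*p*q, p**2)`` is supported.
    Identical arguments give bit-identical output.
    """
    if n < 1 or m < 1:
        raise DimensionError(f"need n >= 1 and m >= 1, got n={n}, m={m}")
    if code_probs is None:
        probs = np.full(3, 1.0 / 3.0)
    else:
        probs = np.asarray(code_probs, dtype=float)
        if probs.shape != (3,) or (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-9:
            raise ValidationError(
                "code_probs must be 3 non-negative probabilities summing to 1"
            )
    rng = np.random.default_rng(seed)
    codes = rng.choice(3, size=(n, m), p=probs).astype(np.int64)
    ids = tuple(f"ind{i + 1}" for i in range(n))
    return GenotypeMatrix(ids=ids, codes=codes)


def simulate_record_counts(
    n: int,
    n_phenotyped: int,
    records_per_animal: int = 1,
    seed: int = 0,
) -> RecordCounts:
    """Assign ``records_per_animal`` records to a random subset of individuals.

    Exactly ``n_phenotyped`` of the n individuals receive records; the subset
    is a seeded draw without replacement, everyone else gets 0.
    """
    if n < 1:
        raise DimensionError(f"need n >= 1, got {n}")
    if not 0 <= n_phenotyped <= n:
        raise ValidationError(f"n_phenotyped must be in [0, {n}], got {n_phenotyped}")
    if records_per_animal < 1:
        raise ValidationError("records_per_animal must be >= 1")
    rng = np.random.default_rng(seed)
    counts = np.zeros(n, dtype=np.int64)
    chosen = rng.choice(n, size=n_phenotyped, replace=False)
    counts[chosen] = records_per_animal
    return RecordCounts(counts=counts)
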