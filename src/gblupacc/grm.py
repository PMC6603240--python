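"""Genomic relationship matrix (VanRaden method 1).

G = WW' / (2 * sum_j p_j (1 - p_j)) with W the column-centered genotype
matrix, W_ij = x_ij - 2 p_j.  Allele frequencies p_j default to the
observed frequencies of the counted allele, which makes the unblended G
double-centered (zero row sums) and hence singular; the classic path, which
must invert G, therefore offers blending toward the identity,
G <- w G + (1 - w) I, the usual conditioning device.  The update path works
with any PSD G because it only ever inverts M = G + alpha (Z'Z)^-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import DegenerateInputError, DimensionError, ValidationError
from .simulate import GenotypeMatrix

__all__ = [
    "AlleleFrequencies",
    "GRM",
    "compute_allele_frequencies",
    "build_grm",
    "blend_grm",
    "cross_relationships",
]


@dataclass
class AlleleFrequencies:
    """Observed frequency of the counted allele at each SNP, p_j in [0, 1]."""

    freqs: np.ndarray

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.freqs.ndim != 1:
            raise DimensionError("allele frequencies must be a 1-D vector")
        if ((self.freqs < 0) | (self.freqs > 1)).any():
            raise ValidationError("allele frequencies must lie in [0, 1]")


@dataclass
class GRM:
    """A symmetric genomic relationship matrix with its scaling metadata.

    ``blend_weight`` is the weight on the genomic component (1.0 means
    unblended); ``denom`` is the VanRaden scaling constant
    2 * sum_j p_j (1 - p_j).
    """

    ids: tuple[str, ...]
    values: np.ndarray
    denom: float
    blend_weight: float = 1.0

    def __post_init__(self) -> None:
        self.ids = tuple(str(i) for i in self.ids)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise DimensionError(
                f"GRM values must be {n}x{n} to match ids, got {self.values.shape}"
            )
        # symmetrize to kill accumulation asymmetry from the matrix product
        self.values = (self.values + self.values.T) / 2.0

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    def diagonal(self) -> np.ndarray:
        return np.diag(self.values).copy()


def compute_allele_frequencies(g: GenotypeMatrix) -> AlleleFrequencies:
    """p_j = (column sum of 0/1/2 codes at SNP j) / (2 n)."""
    n = g.n_individuals
    freqs = g.codes.sum(axis=0) / (2.0 * n)
    return AlleleFrequencies(freqs=freqs)


def build_grm(
    g: GenotypeMatrix,
    freqs: AlleleFrequencies | str = "observed",
) -> GRM:
    """VanRaden method 1: G = WW'/denom with W = codes - 2P.

    ``freqs`` is either ``"observed"`` (computed from ``g``) or an
    :class:`AlleleFrequencies` for fixed base-population frequencies.

    Raises
    ------
    DegenerateInputError
        If every SNP is monomorphic at the given frequencies, so the
        scaling constant 2 * sum p(1-p) is zero.
    """
    if isinstance(freqs, str):
        if freqs != "observed":
            raise ValidationError(f"unknown freqs option {freqs!r}")
        freqs = compute_allele_frequencies(g)
    p = freqs.freqs
    if p.shape[0] != g.n_snps:
        raise DimensionError(
            f"{p.shape[0]} allele frequencies for {g.n_snps} SNPs"
        )
    denom = float(2.0 * np.sum(p * (1.0 - p)))
    if denom <= 0.0:
        raise DegenerateInputError(
            "all SNPs are monomorphic at the given allele frequencies: "
            "the VanRaden scaling constant 2*sum(p(1-p)) is zero"
        )
    w = g.codes.astype(float) - 2.0 * p
    values = w @ w.T / denom
    return GRM(ids=g.ids, values=values, denom=denom, blend_weight=1.0)


def blend_grm(grm: GRM, weight: float) -> GRM:
    """Shrink G toward the identity: w*G + (1-w)*I.

    Guarantees positive definiteness for any PSD G when weight < 1, which
    the classic full-inversion path requires (a G built from few SNPs is
    rank-deficient).  ``weight`` must lie in (0, 1]; weight 1 returns an
    unchanged copy.
    """
    if not 0.0 < weight <= 1.0:
        raise ValidationError(f"blend weight must be in (0, 1], got {weight}")
    n = grm.n_individuals
    values = weight * grm.values + (1.0 - weight) * np.eye(n)
    return GRM(ids=grm.ids, values=values, denom=grm.denom, blend_weight=weight)


def cross_relationships(
    core: GenotypeMatrix,
    new: GenotypeMatrix,
    freqs: AlleleFrequencies | None = None,
    blend_weight: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Relationships of new individuals to a fixed core population.

    Returns ``(g_pq, g_qq)`` where ``g_pq`` has shape (n_new, n_core) and
    ``g_qq`` the self-relationships of the new individuals.  Allele
    frequencies default to those observed in the core and stay frozen, so
    adding individuals never changes existing entries of G; blending scales
    cross terms by ``blend_weight`` and shifts self terms by
    ``1 - blend_weight``, consistent with :func:`blend_grm` applied to the
    joint matrix.
    """
    if new.n_snps != core.n_snps:
        raise DimensionError(
            f"new individuals have {new.n_snps} SNPs but the core has {core.n_snps}"
        )
    if not 0.0 < blend_weight <= 1.0:
        raise ValidationError(f"blend weight must be in (0, 1], got {blend_weight}")
    if freqs is None:
        freqs = compute_allele_frequencies(core)
    p = freqs.freqs
    denom = float(2.0 * np.sum(p * (1.0 - p)))
    if denom <= 0.0:
        raise DegenerateInputError(
            "all SNPs are monomorphic at the core allele frequencies"
        )
    w_core = core.codes.astype(float) - 2.0 * p
    w_new = new.codes.astype(float) - 2.0 * p
    g_pq = blend_weight * (w_new @ w_core.T) / denom
    g_qq = blend_weight * np.sum(w_new * w_new, axis=1) / denom + (1.0 - blend_weight)
    return g_pq, g_qq
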