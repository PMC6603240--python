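"""Classic full-inversion path for GBLUP accuracy.

Assembles the coefficient matrix of the no-fixed-effects animal model,
C = Z'Z + alpha G^-1, inverts it densely, and converts diagonal elements
c^ii to reliability and accuracy with Henderson's formula

    reliability_i = 1 - alpha * c^ii / g_ii,     accuracy_i = sqrt(reliability_i)

This is both the user-facing "classic approach" and the exact oracle the
incremental update path is tested against: no approximation anywhere, just
dense Cholesky factorizations at working precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .exceptions import (
    DegenerateInputError,
    DimensionError,
    InconsistentInputsError,
    NotPositiveDefiniteError,
)
from .grm import GRM
from .simulate import RecordCounts

__all__ = [
    "ModelParams",
    "CoefficientMatrix",
    "AccuracyResult",
    "build_coefficient_matrix",
    "cinverse_diagonal",
    "henderson_scores",
    "accuracy_table_classic",
]

#: half-width of the band around [0, 1] inside which reliabilities are
#: clipped; anything further out signals inconsistent inputs.
CLIP_BAND = 1e-10


@dataclass(frozen=True)
class ModelParams:
    """Variance ratio alpha = sigma_e^2 / sigma_u^2 of the animal model."""

    alpha: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.alpha) and self.alpha > 0):
            raise DegenerateInputError(
                f"alpha must be positive and finite, got {self.alpha}"
            )


@dataclass
class CoefficientMatrix:
    """The mixed-model-equations left-hand side C = Z'Z + alpha G^-1."""

    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.ids = tuple(str(i) for i in self.ids)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise DimensionError(
                f"coefficient matrix must be {n}x{n}, got {self.values.shape}"
            )
        self.values = (self.values + self.values.T) / 2.0


@dataclass(frozen=True)
class AccuracyResult:
    """Per-individual prediction-error diagonal and derived scores."""

    id: str
    cqq: float
    reliability: float
    accuracy: float
    phenotyped: bool


def _chol_inverse(a: np.ndarray, what: str) -> np.ndarray:
    """Symmetric positive-definite inverse via Cholesky; symmetrized."""
    try:
        c, low = linalg.cho_factor(a, lower=True, check_finite=False)
    except linalg.LinAlgError as exc:
        raise NotPositiveDefiniteError(
            f"{what} is not positive definite: {exc}"
        ) from None
    inv = linalg.cho_solve((c, low), np.eye(a.shape[0]), check_finite=False)
    return (inv + inv.T) / 2.0


def build_coefficient_matrix(
    grm: GRM, z: RecordCounts, params: ModelParams
) -> CoefficientMatrix:
    """C = diag(z) + alpha * G^-1 over all individuals, phenotyped or not.

    G must be invertible; a rank-deficient G (few SNPs, observed
    frequencies) should be blended first (:func:`gblupacc.grm.blend_grm`).
    """
    n = grm.n_individuals
    if len(z) != n:
        raise DimensionError(f"{len(z)} record counts for {n} individuals in G")
    try:
        ginv = _chol_inverse(grm.values, "G")
    except NotPositiveDefiniteError as exc:
        raise NotPositiveDefiniteError(
            f"{exc}; if G was built from few SNPs with observed allele "
            "frequencies it is singular by construction — blend it toward "
            "the identity first (blend_grm)"
        ) from None
    values = params.alpha * ginv
    values[np.diag_indices(n)] += z.counts
    return CoefficientMatrix(ids=grm.ids, values=values)


def cinverse_diagonal(c: CoefficientMatrix) -> np.ndarray:
    """Exact diagonal of C^-1 by dense Cholesky factorization.

    This is the oracle: the full inverse is formed, no approximation.
    """
    return np.diag(_chol_inverse(c.values, "C")).copy()


def henderson_scores(
    cqq: float,
    g_ii: float,
    params: ModelParams,
    phenotyped: bool,
    id: str = "",
) -> AccuracyResult:
    """Convert one diagonal element c^qq to reliability and accuracy.

    reliability = 1 - alpha*c^qq/g_ii, accuracy = sqrt(reliability).
    Values within CLIP_BAND of [0, 1] are clipped into the interval; larger
    excursions indicate a non-PSD G or mismatched alpha and raise.
    """
    if g_ii <= 0:
        raise DegenerateInputError(f"g_ii must be positive, got {g_ii}")
    if cqq <= 0:
        raise DegenerateInputError(f"c^qq must be positive, got {cqq}")
    reliability = 1.0 - params.alpha * cqq / g_ii
    if not -CLIP_BAND <= reliability <= 1.0 + CLIP_BAND:
        raise InconsistentInputsError(
            f"reliability {reliability} is outside [0, 1] beyond the "
            f"{CLIP_BAND} clip band; inputs are inconsistent (non-PSD G or "
            "wrong alpha?)"
        )
    reliability = float(min(max(reliability, 0.0), 1.0))
    return AccuracyResult(
        id=str(id),
        cqq=float(cqq),
        reliability=reliability,
        accuracy=float(np.sqrt(reliability)),
        phenotyped=bool(phenotyped),
    )


def accuracy_table_classic(
    grm: GRM, z: RecordCounts, params: ModelParams
) -> list[AccuracyResult]:
    """One AccuracyResult per individual by the full-inversion route."""
    c = build_coefficient_matrix(grm, z, params)
    diag = cinverse_diagonal(c)
    gdiag = grm.diagonal()
    return [
        henderson_scores(
            cqq=diag[i],
            g_ii=gdiag[i],
            params=params,
            phenotyped=z.counts[i] > 0,
            id=grm.ids[i],
        )
        for i in range(grm.n_individuals)
    ]
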