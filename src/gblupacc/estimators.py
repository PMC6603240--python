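"""scikit-learn style estimators over the functional core.

Two estimators cover the two evaluation routes:

``IncrementalGBLUPAccuracy``
    fit(X, record_counts) builds the reusable reference (allele frequencies
    frozen from the core, blended GRM block, M^-1); predict(X_new) answers
    per-individual accuracy in one matrix-vector product each;
    partial_fit(X_new, record_counts) grows the reference by the Schur
    block-inverse update.

``ClassicGBLUPAccuracy``
    fit(X, record_counts) runs the full build-and-invert route over all
    individuals at once and exposes the per-individual scores as fitted
    attributes.  It is the brute-force baseline the incremental route is
    validated against.

Both compose with sklearn model-selection utilities via
get_params/set_params; X is the raw 0/1/2 genotype matrix (individuals by
SNPs) unless ``relationships="precomputed"``.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from . import grm as grm_mod
from . import update as upd
from .classic import ModelParams, accuracy_table_classic
from .exceptions import DimensionError, ValidationError
from .simulate import GenotypeMatrix, RecordCounts

__all__ = ["IncrementalGBLUPAccuracy", "ClassicGBLUPAccuracy"]


def _as_counts(record_counts, n: int, default: int = 1) -> RecordCounts:
    if record_counts is None:
        return RecordCounts(counts=np.full(n, default, dtype=np.int64))
    if isinstance(record_counts, RecordCounts):
        counts = record_counts
    else:
        counts = RecordCounts(counts=np.asarray(record_counts))
    if len(counts) != n:
        raise DimensionError(f"{len(counts)} record counts for {n} individuals")
    return counts


def _as_genotypes(X, ids=None, offset: int = 0) -> GenotypeMatrix:
    X = np.asarray(X)
    if X.ndim != 2:
        raise DimensionError("X must be 2-D (individuals x SNPs)")
    if ids is None:
        ids = tuple(f"ind{offset + i + 1}" for i in range(X.shape[0]))
    return GenotypeMatrix(ids=tuple(ids), codes=X)


class IncrementalGBLUPAccuracy(BaseEstimator):
    """GBLUP accuracy for new genotyped individuals without re-inversion.

    Parameters
    ----------
    alpha : float, default=1.0
        Variance ratio sigma_e^2 / sigma_u^2.
    blend_weight : float, default=0.95
        Weight on the genomic component when shrinking G toward the
        identity; 1.0 disables blending (valid whenever G_pp is already
        positive definite, e.g. many SNPs).

    Attributes
    ----------
    state_ : ReferenceState
        Core ids, alpha, and M^-1 = (G_pp + alpha*(Z'Z)_pp^-1)^-1.
    allele_freqs_ : ndarray of shape (n_features_in_,)
        Core allele frequencies, frozen at fit time.
    denom_ : float
        VanRaden scaling constant from the core.
    n_features_in_ : int
        Number of SNPs.

    Examples
    --------
    >>> import numpy as np
    >>> from gblupacc.simulate import simulate_genotypes
    >>> X = simulate_genotypes(60, 200, seed=0).codes
    >>> model = IncrementalGBLUPAccuracy(alpha=2.0).fit(X[:50])
    >>> acc = model.predict(X[50:])        # unphenotyped by default
    >>> acc.shape
    (10,)
    """

    def __init__(self, alpha: float = 1.0, blend_weight: float = 0.95):
        self.alpha = alpha
        self.blend_weight = blend_weight

    def fit(self, X, y=None, record_counts=None, ids=None):
        """Build the reference from core genotypes and record counts.

        ``record_counts`` (alias ``y``) defaults to one record per core
        animal; every core count must be >= 1.
        """
        if record_counts is None:
            record_counts = y
        core = _as_genotypes(X, ids=ids)
        counts = _as_counts(record_counts, core.n_individuals, default=1)
        freqs = grm_mod.compute_allele_frequencies(core)
        g = grm_mod.build_grm(core, freqs=freqs)
        if self.blend_weight != 1.0:
            g = grm_mod.blend_grm(g, self.blend_weight)
        self.state_ = upd.build_reference(g, counts, ModelParams(alpha=self.alpha))
        self.allele_freqs_ = freqs.freqs.copy()
        self.denom_ = g.denom
        self._core_genotypes = core
        self.n_features_in_ = core.n_snps
        return self

    def _new_individuals(self, X, record_counts, ids):
        new = _as_genotypes(X, ids=ids, offset=self.state_.n_core)
        counts = _as_counts(record_counts, new.n_individuals, default=0)
        g_pq, g_qq = grm_mod.cross_relationships(
            self._core_genotypes,
            new,
            freqs=grm_mod.AlleleFrequencies(freqs=self.allele_freqs_),
            blend_weight=self.blend_weight,
        )
        return [
            upd.NewIndividual(
                id=new.ids[i], g_pq=g_pq[i], g_qq=g_qq[i], z_qq=counts.counts[i]
            )
            for i in range(new.n_individuals)
        ]

    def score_table(self, X, record_counts=None, ids=None):
        """Full per-individual results (c^qq, reliability, accuracy)."""
        check_is_fitted(self, "state_")
        return [
            upd.score_new_individual(self.state_, ind)
            for ind in self._new_individuals(X, record_counts, ids)
        ]

    def predict(self, X, record_counts=None, ids=None):
        """Prediction accuracy (sqrt reliability) of each new individual."""
        return np.array([r.accuracy for r in self.score_table(X, record_counts, ids)])

    def predict_reliability(self, X, record_counts=None, ids=None):
        """Reliability (squared accuracy) of each new individual."""
        return np.array(
            [r.reliability for r in self.score_table(X, record_counts, ids)]
        )

    def partial_fit(self, X, y=None, record_counts=None, ids=None):
        """Grow the reference by the given phenotyped individuals.

        Falls back to :meth:`fit` on the first call.  Each animal is added
        by the rank-one Schur update; its genotype row is appended to the
        frozen-frequency core so later relationship vectors include it.
        """
        if record_counts is None:
            record_counts = y
        if not hasattr(self, "state_"):
            return self.fit(X, record_counts=record_counts, ids=ids)
        new = _as_genotypes(X, ids=ids, offset=self.state_.n_core)
        counts = _as_counts(record_counts, new.n_individuals, default=1)
        if (counts.counts < 1).any():
            raise ValidationError(
                "every individual added to the core must have >= 1 record"
            )
        freqs = grm_mod.AlleleFrequencies(freqs=self.allele_freqs_)
        for i in range(new.n_individuals):
            # relationships against the *current* (grown) core, frequencies
            # still frozen at the original fit
            row = GenotypeMatrix(ids=(new.ids[i],), codes=new.codes[i:i + 1])
            g_pq, g_qq = grm_mod.cross_relationships(
                self._core_genotypes, row, freqs=freqs,
                blend_weight=self.blend_weight,
            )
            self.state_ = upd.update_reference(
                self.state_,
                upd.NewIndividual(
                    id=new.ids[i], g_pq=g_pq[0], g_qq=g_qq[0],
                    z_qq=counts.counts[i],
                ),
            )
            self._core_genotypes = GenotypeMatrix(
                ids=self._core_genotypes.ids + (new.ids[i],),
                codes=np.vstack([self._core_genotypes.codes, row.codes]),
            )
        return self


class ClassicGBLUPAccuracy(BaseEstimator):
    """Full build-and-invert GBLUP accuracy (the baseline route).

    Inverts G and then C = Z'Z + alpha*G^-1 densely and reads every
    individual's c^ii off the diagonal of C^-1.  Exact, and cubic in the
    number of individuals.

    Parameters
    ----------
    alpha : float, default=1.0
    blend_weight : float, default=0.95
        Applied to G before inversion (ignored for precomputed G when 1.0).
    relationships : {"genotypes", "precomputed"}, default="genotypes"
        With "precomputed", X passed to fit is the relationship matrix G
        itself rather than a genotype matrix.

    Attributes
    ----------
    results_ : list of AccuracyResult
    cqq_, reliability_, accuracy_ : ndarray of shape (n_individuals,)
    phenotyped_ : boolean ndarray
    """

    def __init__(
        self,
        alpha: float = 1.0,
        blend_weight: float = 0.95,
        relationships: str = "genotypes",
    ):
        self.alpha = alpha
        self.blend_weight = blend_weight
        self.relationships = relationships

    def fit(self, X, y=None, record_counts=None, ids=None):
        if record_counts is None:
            record_counts = y
        if self.relationships == "genotypes":
            geno = _as_genotypes(X, ids=ids)
            g = grm_mod.build_grm(geno)
            n = geno.n_individuals
        elif self.relationships == "precomputed":
            values = np.asarray(X, dtype=float)
            n = values.shape[0]
            if ids is None:
                ids = tuple(f"ind{i + 1}" for i in range(n))
            g = grm_mod.GRM(ids=tuple(ids), values=values, denom=np.nan)
        else:
            raise ValidationError(
                f"relationships must be 'genotypes' or 'precomputed', "
                f"got {self.relationships!r}"
            )
        if self.blend_weight != 1.0:
            g = grm_mod.blend_grm(g, self.blend_weight)
        counts = _as_counts(record_counts, n, default=1)
        self.results_ = accuracy_table_classic(g, counts, ModelParams(alpha=self.alpha))
        self.cqq_ = np.array([r.cqq for r in self.results_])
        self.reliability_ = np.array([r.reliability for r in self.results_])
        self.accuracy_ = np.array([r.accuracy for r in self.results_])
        self.phenotyped_ = np.array([r.phenotyped for r in self.results_])
        self.n_features_in_ = np.asarray(X).shape[1]
        return self
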