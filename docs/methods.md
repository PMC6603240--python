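# Methods

## Model

The package works in the simplest animal model without fixed effects,
y = Zu + e, with var(u) = G σ²u and var(e) = I σ²e. Because there are no
fixed-effect columns, Z'Z is diagonal: its i-th diagonal entry is the
number of phenotype records of individual i, and Z itself is never stored.
The mixed-model equations have left-hand side C = Z'Z + α G⁻¹ with
α = σ²e/σ²u, and the accuracy of each breeding value follows from the
diagonal of C⁻¹ (the prediction-error variance, up to σ²e):

    reliability_i = 1 − α c^ii / g_ii,   accuracy_i = √reliability_i.

Both reliability and accuracy are always reported so either convention can
be read off. Reliabilities within 1e-10 of the interval boundaries are
clipped into [0, 1]; larger excursions raise an error, since they can only
come from a non-PSD relationship matrix or a wrong α.

## The incremental route and why it is exact

The Woodbury identity turns C⁻¹ = (Z'Z + αG⁻¹)⁻¹ into
G (G + α(Z'Z)⁻¹)⁻¹ (Z'Z)⁻¹, so the only large inverse ever needed is
M⁻¹ with M = G_pp + α (Z'Z)_pp⁻¹ over the core (reference) animals, all of
whom must be phenotyped for (Z'Z)_pp to be invertible. For one new
individual q the partitioned algebra collapses to scalars: with
k = g_qq − g_pq' M⁻¹ g_pq,

    c^qq = k / (k z_qq + α)   if z_qq ≥ 1,
    c^qq = k / α              if z_qq = 0 (the z → 0 limit of the line above).

These are algebraic identities, not approximations: the test suite checks
agreement with the full dense inversion of C over core + q at 1e-12
absolute on c^qq across hundreds of random instances, and at machine
precision (≤ 8.88e-16 on accuracy) on a 100-core/20-newcomer instance.
The unphenotyped case is also verified numerically as the monotone limit
of the phenotyped expression as z_qq ↓ 0 through 1e-2, 1e-4, 1e-6.

Growing the core by a phenotyped animal uses the Schur block-inverse rule:
with v = M⁻¹ g_pq and s = g_qq + α/z_qq − g_pq' v,

    new M⁻¹ = [ M⁻¹ + v v'/s ,  −v/s ]
              [    −v'/s     ,   1/s ].

The update is rank-one; insertion order does not matter (verified at 1e-10
against from-scratch builds after 50 additions). Unphenotyped animals
cannot join the core: the α/z term of M is undefined at z = 0, and
admitting them would need a modeling choice (e.g. a pseudo-record weight)
the method does not make.

## Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| `alpha` | variance ratio σ²e/σ²u (unitless) | 1.0 | heritability 0.5; any positive finite value |
| `blend_weight` | weight on the genomic component of G | 0.95 | see below; 1.0 disables blending |
| `code_probs` | sampling distribution of genotype codes | uniform (1/3 each) | HWE-style vectors accepted |
| `records_per_animal` | records per phenotyped animal | 1 | makes (Z'Z)_pp the identity |

**Blending.** A VanRaden G built from m SNPs with observed allele
frequencies has rank ≤ min(n, m) − 1 (column-centering forces zero row
sums), so with few SNPs the classic route's G⁻¹ does not exist. Blending
G ← w G + (1 − w) I with w = 0.95 bounds the smallest eigenvalue away from
zero by 0.05 while perturbing relationships by at most 5%. The update
route does not need it (M is positive definite for any PSD G with
phenotyped core), but every comparison between the two routes uses the
same blended G — otherwise the equivalence being tested would be broken by
construction. Cross-relationships for new animals use allele frequencies
frozen at the core (reference-build) values, so scoring or adding
newcomers never changes existing entries of G.

## Synthetic data

The generator draws genotype codes i.i.d. from {0, 1, 2} (uniform by
default) and assigns phenotype records to a seeded random subset of
individuals. This reproduces the matrix shapes, conditioning and record
structure of an evaluation, which is all the linear algebra sees — c^qq
depends on the data only through G and Z'Z. It deliberately has no linkage
disequilibrium, minor-allele-frequency spectrum, pedigree structure or
trait values; passing tests therefore demonstrate numerical correctness
and scaling of the accuracy computation, not genetic realism of the
relationship estimates themselves on real panels.

## Numerical choices

* All symmetric inversions go through `scipy.linalg.cho_factor` /
  `cho_solve` (Cholesky); a factorization failure raises a
  not-positive-definite error, with a hint to blend when G is the culprit.
* Every constructed symmetric matrix is symmetrized as (A + A')/2 to stop
  accumulation asymmetry; M⁻¹ stays exactly symmetric through updates.
* M⁻¹ is stored explicitly rather than as a factor, so a query is one
  symmetric matrix–vector product and needs no triangular solves.
* k ≤ 0 (Schur residual) and s ≤ 0 (Schur complement) are rejected as
  inconsistent inputs: they mean the augmented relationship matrix is not
  positive definite.
* Degenerate inputs refused explicitly: all-monomorphic SNP panels (zero
  VanRaden denominator), g_ii ≤ 0, zero record counts in the core.
* Oracle-equivalence tolerances: 1e-12 absolute on c^qq, 1e-10 on
  elementwise M⁻¹ closure; these hold with large margin in practice.

## Persistence

The reference state (core ids, α, M⁻¹, optionally the core g_ii) is
written little-endian: magic `MINV`, u32 format version, one flags byte
(zlib compression, diagonal present), u64 core size, f64 α,
length-prefixed UTF-8 ids, u64 payload length, the row-major f64 payload,
and a CRC-32 of the payload. Round trips are bit-exact; wrong magic,
wrong version, truncation and checksum mismatch each raise a distinct
error.

## Benchmark design

`run_benchmark` simulates each core size with 7 SNPs (the number of SNPs
does not affect the timed linear algebra), builds one blended G, and times
(1) the classic build-and-invert of C including the inversion of G, (2)
building M⁻¹, (3) single c^qq queries with and without phenotype and one
rank-one reference update. Timings are medians of `time.perf_counter`
over a configurable number of repeats; the classic step is skipped above a
cap (default 5000) because its cubic cost dominates the run, and the
default sizes stop at 2000 for the same reason — correctness of the
method is size-independent, and absolute times depend on the machine and
the BLAS backend (thread count is left to the backend's configuration).
The qualitative content — queries orders of magnitude cheaper than the
classic rebuild, with a gap that widens with n — is asserted in the test
suite; absolute seconds are not reproducible claims.

## Known limitations

* No fixed effects and no dense Z'Z; the model is the plain animal model.
* The right-hand side of the mixed-model equations is never solved —
  the package computes accuracies, not breeding values.
* C^pp is not updated when existing core animals gain phenotypes; growing
  the core is the only supported state mutation.
* Core membership policy (which animals to add) is left to the user; the
  package provides the accuracy signal, not a selection heuristic.
* No APY/PICD-style approximate G inverses; exact algebra only.
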