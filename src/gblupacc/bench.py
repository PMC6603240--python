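"""Benchmark harness: classic rebuild vs incremental query/update.

For each population size n the harness simulates genotypes, builds one
blended G shared by both routes, and times three steps: (1) the classic
full build-and-invert of C (including the inversion of G), (2) building the
reusable M^-1, and (3) per-animal c^qq queries (with and without phenotype)
plus one reference update.  Timings are medians over ``repeats`` runs of
``time.perf_counter``; absolute numbers are hardware- and BLAS-dependent,
only the qualitative ordering is meaningful.
"""

from __future__ import annotations

import time
from dataclasses import asdict, dataclass

import numpy as np

from .classic import ModelParams, build_coefficient_matrix, cinverse_diagonal
from .exceptions import ValidationError
from .grm import blend_grm, build_grm
from .simulate import RecordCounts, simulate_genotypes
from .update import NewIndividual, build_reference, cqq_with_phenotype, \
    cqq_without_phenotype, update_reference

__all__ = ["BenchmarkRecord", "run_benchmark"]


@dataclass(frozen=True)
class BenchmarkRecord:
    """Median elapsed seconds for each step at one core-population size."""

    n: int
    t_classic: float
    t_build_m: float
    t_query_pheno: float
    t_query_nopheno: float
    t_update: float
    seed: int

    def as_dict(self) -> dict:
        return asdict(self)


def _median_time(fn, repeats: int) -> float:
    times = []
    for _ in range(repeats):
        t0 = time.perf_counter()
        fn()
        times.append(time.perf_counter() - t0)
    return float(np.median(times))


def run_benchmark(
    sizes: list[int],
    m_snps: int = 7,
    params: ModelParams | None = None,
    seed: int = 0,
    repeats: int = 3,
    blend_weight: float = 0.95,
    classic_cap: int = 5000,
) -> list[BenchmarkRecord]:
    """Time the classic and incremental routes at each core size.

    The classic full-inversion step is skipped (NaN) above ``classic_cap``
    individuals to keep runs tractable; pass a larger cap to extend.
    """
    if not sizes:
        raise ValidationError("sizes must be non-empty")
    if any(n < 2 for n in sizes):
        raise ValidationError("benchmark sizes must be >= 2")
    params = params or ModelParams(alpha=1.0)
    records = []
    for i, n in enumerate(sizes):
        sub_seed = (seed + 7919 * i) % (2**31)
        geno = simulate_genotypes(n + 1, m_snps, seed=sub_seed)
        g = blend_grm(build_grm(geno), blend_weight)
        core_vals = g.values[:n, :n]
        g_pq = g.values[:n, n]
        g_qq = float(g.values[n, n])
        z_core = RecordCounts(counts=np.ones(n, dtype=np.int64))
        z_all = RecordCounts(counts=np.ones(n + 1, dtype=np.int64))

        if n <= classic_cap:
            def classic() -> None:
                c = build_coefficient_matrix(g, z_all, params)
                cinverse_diagonal(c)

            t_classic = _median_time(classic, repeats)
        else:
            t_classic = float("nan")

        t_build_m = _median_time(
            lambda: build_reference(core_vals, z_core, params), repeats
        )
        state = build_reference(core_vals, z_core, params)
        ind_pheno = NewIndividual(id="new_p", g_pq=g_pq, g_qq=g_qq, z_qq=1)
        ind_nopheno = NewIndividual(id="new_u", g_pq=g_pq, g_qq=g_qq, z_qq=0)
        t_qp = _median_time(lambda: cqq_with_phenotype(state, ind_pheno), repeats)
        t_qn = _median_time(lambda: cqq_without_phenotype(state, ind_nopheno), repeats)
        t_up = _median_time(lambda: update_reference(state, ind_pheno), repeats)
        records.append(
            BenchmarkRecord(
                n=n,
                t_classic=t_classic,
                t_build_m=t_build_m,
                t_query_pheno=t_qp,
                t_query_nopheno=t_qn,
                t_update=t_up,
                seed=sub_seed,
            )
        )
    return records


def plot_benchmark(records: list[BenchmarkRecord], path) -> None:
    """Elapsed-time curves per step against population size."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ns = [r.n for r in records]
    fig, ax = plt.subplots(figsize=(7, 5))
    ax.plot(ns, [r.t_classic for r in records], "o-", label="classic (invert G and C)")
    ax.plot(ns, [r.t_build_m for r in records], "s-", label="build M$^{-1}$")
    ax.plot(ns, [r.t_update for r in records], "d-", label="update reference")
    ax.plot(ns, [r.t_query_pheno for r in records], "^-",
            label="c$^{qq}$ with phenotype")
    ax.plot(ns, [r.t_query_nopheno for r in records], "v--",
            label="c$^{qq}$ without phenotype")
    ax.set_xlabel("core population size")
    ax.set_ylabel("median elapsed time (s)")
    ax.set_yscale("log")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
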