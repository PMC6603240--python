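import numpy as np
import pytest

import gblupacc as ga


@pytest.fixture
def params():
    return ga.ModelParams(alpha=1.0)


@pytest.fixture
def grm_2x2():
    """The hand-checkable 2-individual system G = [[1, .5], [.5, 1]]."""
    return ga.GRM(
        ids=("a", "b"),
        values=np.array([[1.0, 0.5], [0.5, 1.0]]),
        denom=1.0,
    )


@pytest.fixture
def single_core_state(params):
    """Reference of one phenotyped core animal with g_11 = 1, alpha = 1."""
    return ga.build_reference(
        np.array([[1.0]]),
        ga.RecordCounts(np.array([1])),
        params,
        ids=("a",),
    )


def random_instance(seed, n_core, n_new=1, m=200, alpha=1.0, blend=0.95):
    """Simulate a blended-G instance shared by both evaluation routes.

    Returns (grm, core_state, new individual list) where the new
    individuals alternate phenotyped / unphenotyped.
    """
    n = n_core + n_new
    geno = ga.simulate_genotypes(n, m, seed=seed)
    g = ga.blend_grm(ga.build_grm(geno), blend)
    par = ga.ModelParams(alpha=alpha)
    core = ga.GRM(
        ids=geno.ids[:n_core],
        values=g.values[:n_core, :n_core],
        denom=g.denom,
        blend_weight=blend,
    )
    z_core = ga.RecordCounts(np.ones(n_core, dtype=np.int64))
    state = ga.build_reference(core, z_core, par)
    inds = [
        ga.NewIndividual(
            id=geno.ids[n_core + j],
            g_pq=g.values[:n_core, n_core + j],
            g_qq=g.values[n_core + j, n_core + j],
            z_qq=j % 2,
        )
        for j in range(n_new)
    ]
    return g, state, inds


def classic_cqq_for(g, n_core, q_index, z_qq, alpha=1.0):
    """Oracle: c^qq of the full coefficient matrix over core + one animal."""
    idx = list(range(n_core)) + [q_index]
    sub = ga.GRM(
        ids=tuple(g.ids[i] for i in idx),
        values=g.values[np.ix_(idx, idx)],
        denom=g.denom,
        blend_weight=g.blend_weight,
    )
    z = ga.RecordCounts(
        np.append(np.ones(n_core, dtype=np.int64), z_qq)
    )
    c = ga.build_coefficient_matrix(sub, z, ga.ModelParams(alpha=alpha))
    return ga.cinverse_diagonal(c)[-1]
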