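"""Shared fixtures: the mimic ground truth and the skeleton-recovery
experiment (5 replicate cohorts, bootstrap structure learning), computed
once per session because several tests interrogate the same runs."""

import numpy as np
import pytest

from irnet import bn_structure as bs
from irnet import synthetic_cohort as sc

RECOVERY_N = 20_000
RECOVERY_B = 200
RECOVERY_SEEDS = (1, 2, 3, 4, 5)
THRESHOLD = 0.75


@pytest.fixture(scope="session")
def mimic_spec():
    return sc.korean_cohort_spec()


@pytest.fixture(scope="session")
def mimic_cohort(mimic_spec):
    """One mid-sized sampled cohort with emitted continuous columns."""
    cohort = sc.sample_cohort(mimic_spec, 6000, seed=11)
    return sc.emit_continuous(cohort, mimic_spec, seed=12)


@pytest.fixture(scope="session")
def recovery_experiment(mimic_spec):
    """Bootstrap arc strengths + consensus DAG for 5 replicate cohorts."""
    nodes = list(mimic_spec.levels)
    runs = []
    for seed in RECOVERY_SEEDS:
        cohort = sc.sample_cohort(mimic_spec, RECOVERY_N, seed)
        data = bs.CategoricalData(cohort, columns=nodes)
        strengths = bs.bootstrap_arc_strength(data, B=RECOVERY_B, seed=100 + seed)
        consensus = bs.model_average(strengths, THRESHOLD, nodes=nodes)
        runs.append({"seed": seed, "strengths": strengths, "consensus": consensus})
    return runs


def random_dag(rng, n_nodes, arc_prob=0.3, prefix="v"):
    """A random labelled DAG via a random topological order."""
    nodes = [f"{prefix}{i}" for i in range(n_nodes)]
    order = rng.permutation(n_nodes)
    arcs = []
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < arc_prob:
                arcs.append((nodes[order[i]], nodes[order[j]]))
    return bs.DAG(nodes, arcs)


def random_fitted_bn(rng, n_nodes, arc_prob=0.35, max_levels=3):
    """A random fitted network with Dirichlet CPT rows."""
    from irnet import bn_inference as bi

    dag = random_dag(rng, n_nodes, arc_prob)
    levels = {n: [str(k) for k in range(rng.integers(2, max_levels + 1))]
              for n in dag.nodes}
    cpts, parent_order = {}, {}
    for n in dag.nodes:
        parents = sorted(dag.parents(n))
        parent_order[n] = parents
        q = int(np.prod([len(levels[p]) for p in parents])) if parents else 1
        r = len(levels[n])
        table = rng.dirichlet(np.ones(r) * 1.5, size=q)
        cpts[n] = table
    return bi.FittedBN(dag=dag, levels=levels, cpts=cpts,
                       parent_order=parent_order).validate(tol=1e-9)
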