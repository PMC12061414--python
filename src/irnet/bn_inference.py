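"""Parameter fitting and probabilistic inference on a discrete Bayesian network.

A fitted network pairs a DAG with one conditional probability table (CPT)
per node; the joint factorizes as ``P(V) = prod_i P(V_i | parents(V_i))``.
Queries of the form ``P(event | evidence)`` are answered either by exact
summation over the factorized joint (an enumeration oracle, feasible at
desk scale) or by Monte-Carlo estimation (likelihood weighting by default,
rejection sampling for parity with logic sampling).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bn_structure import DAG, CategoricalData

logger = logging.getLogger(__name__)

__all__ = [
    "FittedBN",
    "QueryResult",
    "fit_cpts",
    "markov_blanket",
    "d_separated",
    "exact_query",
    "sampled_query",
    "scenario_table",
]


class UndefinedConditionalError(ValueError):
    """Conditioning event has probability zero."""


class InsufficientSamplesError(RuntimeError):
    """No accepted samples / zero total weight; increase n_samples."""


# ---------------------------------------------------------------------------
# Fitted network
# ---------------------------------------------------------------------------

@dataclass
class FittedBN:
    """DAG + CPTs.

    ``cpts[node]`` is an array of shape ``(q, r)``: one row per parent
    configuration (mixed-radix index over ``parent_order[node]``, most
    significant parent first), one column per node level.  Every row sums
    to 1.
    """

    dag: DAG
    levels: dict
    cpts: dict
    parent_order: dict
    alpha: float = 0.0
    uniform_rows: list = field(default_factory=list)

    def level_index(self, node, level):
        try:
            return self.levels[node].index(level)
        except ValueError:
            raise KeyError(f"{level!r} is not a level of {node!r}") from None

    def row_index(self, node, parent_levels: dict) -> int:
        idx = 0
        for p in self.parent_order[node]:
            idx = idx * len(self.levels[p]) + self.level_index(p, parent_levels[p])
        return idx

    def validate(self, tol=1e-12):
        for node, table in self.cpts.items():
            if not np.allclose(table.sum(axis=1), 1.0, atol=tol):
                raise ValueError(f"CPT rows of {node!r} do not sum to 1")
            if (table < -tol).any() or (table > 1 + tol).any():
                raise ValueError(f"CPT of {node!r} outside [0, 1]")
        return self

    # -- serialization (structured text) -----------------------------------
    def to_dict(self):
        return {
            "nodes": list(self.dag.nodes),
            "arcs": [list(a) for a in self.dag.arcs],
            "levels": {n: list(v) for n, v in self.levels.items()},
            "alpha": self.alpha,
            "cpts": {
                n: {
                    "parents": list(self.parent_order[n]),
                    "table": self.cpts[n].tolist(),
                }
                for n in self.dag.nodes
            },
        }

    @classmethod
    def from_dict(cls, d):
        dag = DAG(d["nodes"], [tuple(a) for a in d["arcs"]])
        levels = {n: list(v) for n, v in d["levels"].items()}
        cpts = {n: np.asarray(spec["table"], dtype=float) for n, spec in d["cpts"].items()}
        parent_order = {n: list(spec["parents"]) for n, spec in d["cpts"].items()}
        return cls(dag=dag, levels=levels, cpts=cpts, parent_order=parent_order,
                   alpha=float(d.get("alpha", 0.0))).validate(tol=1e-9)


@dataclass
class QueryResult:
    estimate: float
    mc_standard_error: float
    n_effective: float
    method: str
    seed: int | None = None

    def __post_init__(self):
        if not (-1e-12 <= self.estimate <= 1 + 1e-12):
            raise ValueError("estimate outside [0, 1]")
        self.estimate = float(min(1.0, max(0.0, self.estimate)))


def fit_cpts(dag: DAG, data, alpha: float = 0.0) -> FittedBN:
    """Maximum-likelihood (``alpha=0``) or Laplace-smoothed CPT estimates.

    Entries are ``(N_jk + alpha) / (N_j + alpha * r)``.  With ``alpha=0`` an
    unseen parent configuration yields a uniform row, recorded in
    ``uniform_rows`` so downstream queries never meet undefined
    probabilities silently.
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    if not isinstance(data, CategoricalData):
        data = CategoricalData(data, columns=list(dag.nodes))
    idx = {c: i for i, c in enumerate(data.columns)}
    levels = {n: list(data.levels[n]) for n in dag.nodes}
    cpts, parent_order, uniform_rows = {}, {}, []
    for node in dag.nodes:
        parents = sorted(dag.parents(node))
        parent_order[node] = parents
        r = len(levels[node])
        q = int(np.prod([len(levels[p]) for p in parents])) if parents else 1
        key = np.zeros(data.n, dtype=np.int64)
        for p in parents:
            key = key * data.card[idx[p]] + data.codes[:, idx[p]]
        joint = key * r + data.codes[:, idx[node]]
        cnt = np.bincount(joint, minlength=q * r).reshape(q, r).astype(float)
        nj = cnt.sum(axis=1)
        table = np.empty_like(cnt)
        seen = nj + alpha * r > 0
        table[seen] = (cnt[seen] + alpha) / (nj[seen] + alpha * r)[:, None]
        if (~seen).any():
            table[~seen] = 1.0 / r
            for j in np.flatnonzero(~seen):
                uniform_rows.append((node, int(j)))
            logger.info("fit_cpts: %d unseen parent configurations of %r set uniform",
                        int((~seen).sum()), node)
        cpts[node] = table
    return FittedBN(dag=dag, levels=levels, cpts=cpts, parent_order=parent_order,
                    alpha=alpha, uniform_rows=uniform_rows).validate(tol=1e-9)


# ---------------------------------------------------------------------------
# Graphical queries
# ---------------------------------------------------------------------------

def markov_blanket(dag: DAG, node) -> frozenset:
    """Parents, children, and the children's other parents."""
    parents = dag.parents(node)
    children = dag.children(node)
    coparents = set()
    for c in children:
        coparents |= dag.parents(c)
    return frozenset((set(parents) | set(children) | coparents) - {node})


def d_separated(dag: DAG, x, y, z=()) -> bool:
    """d-separation of ``x`` and ``y`` given set ``z`` (Bayes-ball).

    Chains and forks are blocked when their middle node is in ``z``;
    colliders block unless the collider or one of its descendants is in
    ``z``.
    """
    z = frozenset(z)
    for n in (x, y):
        dag._check(n)
        if n in z:
            raise ValueError(f"query node {n!r} is in the conditioning set")
    ancestors_of_z = set(z)
    for s in z:
        ancestors_of_z |= dag.ancestors(s)
    # states: (node, direction); "up" = visited from a child, "down" = from a parent
    visited = set()
    stack = [(x, "up")]
    while stack:
        node, direction = stack.pop()
        if (node, direction) in visited:
            continue
        visited.add((node, direction))
        if node == y and node not in z:
            return False
        if direction == "up" and node not in z:
            for p in dag.parents(node):
                stack.append((p, "up"))
            for c in dag.children(node):
                stack.append((c, "down"))
        elif direction == "down":
            if node not in z:
                for c in dag.children(node):
                    stack.append((c, "down"))
            if node in ancestors_of_z:  # collider opened by z or a descendant in z
                for p in dag.parents(node):
                    stack.append((p, "up"))
    return True


# ---------------------------------------------------------------------------
# Exact enumeration oracle
# ---------------------------------------------------------------------------

def _joint_array(fbn: FittedBN, max_dims: float = 2.0**20):
    nodes = list(fbn.dag.nodes)
    shape = [len(fbn.levels[n]) for n in nodes]
    if float(np.prod([float(s) for s in shape])) > max_dims:
        raise ValueError("network too large for full enumeration")
    pos = {n: i for i, n in enumerate(nodes)}
    joint = np.ones([1] * len(nodes))
    for n in nodes:
        parents = fbn.parent_order[n]
        r = len(fbn.levels[n])
        dims = [pos[p] for p in parents] + [pos[n]]
        table = fbn.cpts[n].reshape([len(fbn.levels[p]) for p in parents] + [r])
        # permute factor axes into ascending joint-dimension order, then
        # reshape with singleton axes so it broadcasts against the joint
        perm = sorted(range(len(dims)), key=lambda i: dims[i])
        table = np.transpose(table, perm)
        full_shape = [1] * len(nodes)
        for axis, i in enumerate(perm):
            full_shape[dims[i]] = table.shape[axis]
        joint = joint * table.reshape(full_shape)
    return joint, nodes


def exact_query(fbn: FittedBN, event: dict, evidence: dict | None = None) -> QueryResult:
    """``P(event | evidence)`` by summing the factorized joint.

    Guarded to networks whose state space does not exceed 2^20 joint
    configurations.  The Monte-Carlo standard error is identically zero.
    """
    evidence = dict(evidence or {})
    conflict = any(event[k] != evidence[k] for k in set(event) & set(evidence))
    joint, nodes = _joint_array(fbn)

    def mask_sum(assign):
        sl = []
        for n in nodes:
            if n in assign:
                sl.append(slice(fbn.level_index(n, assign[n]), fbn.level_index(n, assign[n]) + 1))
            else:
                sl.append(slice(None))
        return float(joint[tuple(sl)].sum())

    p_evidence = mask_sum(evidence) if evidence else 1.0
    if p_evidence <= 0.0:
        raise UndefinedConditionalError("evidence has probability zero")
    if conflict:
        return QueryResult(0.0, 0.0, np.inf, "exact")
    both = dict(evidence)
    both.update(event)
    return QueryResult(mask_sum(both) / p_evidence, 0.0, np.inf, "exact")


# ---------------------------------------------------------------------------
# Sampling estimators
# ---------------------------------------------------------------------------

def _ancestral_sample(fbn: FittedBN, n_samples: int, rng, clamp: dict | None = None):
    """Vectorized ancestral sampling; optionally clamp evidence nodes.

    Returns (samples dict node -> int codes, log-weights for the clamped
    evidence under likelihood weighting).
    """
    clamp = clamp or {}
    samples: dict = {}
    weights = np.ones(n_samples)
    for node in fbn.dag.topological_order():
        parents = fbn.parent_order[node]
        r = len(fbn.levels[node])
        if parents:
            row = np.zeros(n_samples, dtype=np.int64)
            for p in parents:
                row = row * len(fbn.levels[p]) + samples[p]
            probs = fbn.cpts[node][row]  # (n_samples, r)
        else:
            probs = np.broadcast_to(fbn.cpts[node][0], (n_samples, r))
        if node in clamp:
            k = fbn.level_index(node, clamp[node])
            samples[node] = np.full(n_samples, k, dtype=np.int64)
            weights = weights * probs[:, k]
        else:
            u = rng.random(n_samples)
            cdf = np.cumsum(probs, axis=1)
            samples[node] = (u[:, None] > cdf[:, :-1]).sum(axis=1).astype(np.int64)
    return samples, weights


def _event_mask(fbn, samples, assign):
    mask = np.ones(len(next(iter(samples.values()))), dtype=bool)
    for n, lev in assign.items():
        mask &= samples[n] == fbn.level_index(n, lev)
    return mask


def sampled_query(
    fbn: FittedBN,
    event: dict,
    evidence: dict | None = None,
    n_samples: int = 100_000,
    method: str = "likelihood_weighting",
    seed: int = 0,
) -> QueryResult:
    """Monte-Carlo estimate of ``P(event | evidence)``.

    ``likelihood_weighting`` clamps evidence nodes and weights each sample
    by the product of the evidence CPT entries; ``rejection`` draws
    ancestral samples and keeps those matching the evidence.  Standard
    errors come from the ratio-estimator delta method (LW) or the binomial
    formula (rejection).
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    evidence = dict(evidence or {})
    rng = np.random.default_rng(seed)
    if method in ("likelihood_weighting", "lw"):
        samples, w = _ancestral_sample(fbn, n_samples, rng, clamp=evidence)
        wsum = w.sum()
        if wsum <= 0:
            raise InsufficientSamplesError(
                f"zero total weight with n_samples={n_samples}; increase n_samples")
        ind = _event_mask(fbn, samples, event).astype(float)
        est = float((w * ind).sum() / wsum)
        # delta-method SE of the ratio estimator
        se = float(np.sqrt(((w * (ind - est)) ** 2).sum()) / wsum)
        neff = float(wsum**2 / (w**2).sum())
        return QueryResult(est, se, neff, "likelihood_weighting", seed)
    if method == "rejection":
        samples, _ = _ancestral_sample(fbn, n_samples, rng)
        keep = _event_mask(fbn, samples, evidence) if evidence else np.ones(n_samples, bool)
        m = int(keep.sum())
        if m == 0:
            raise InsufficientSamplesError(
                f"no samples matched the evidence with n_samples={n_samples}; "
                "increase n_samples")
        ind = _event_mask(fbn, samples, event)[keep]
        est = float(ind.mean())
        se = float(np.sqrt(est * (1 - est) / m))
        return QueryResult(est, se, float(m), "rejection", seed)
    raise ValueError(f"unknown method {method!r}")


def scenario_table(
    fbn: FittedBN,
    index: str,
    outcome: str,
    extra: str | None = None,
    outcome_level: str = "yes",
    method: str = "likelihood_weighting",
    n_samples: int = 100_000,
    seed: int = 0,
    exact: bool = False,
) -> pd.DataFrame:
    """Conditional-probability scenario grid for one IR marker.

    Rows are ``P(outcome = outcome_level | index = Qk)`` for each quartile
    level, optionally stratified by each level of ``extra`` (the
    obesity / hypertension what-if scenarios).
    """
    rows = []
    qlevels = fbn.levels[index]
    extra_levels = fbn.levels[extra] if extra else [None]
    i = 0
    for q in qlevels:
        for e in extra_levels:
            evidence = {index: q}
            if extra:
                evidence[extra] = e
            if exact:
                res = exact_query(fbn, {outcome: outcome_level}, evidence)
            else:
                res = sampled_query(fbn, {outcome: outcome_level}, evidence,
                                    n_samples=n_samples, method=method, seed=seed + i)
            row = {"index": index, "quartile": q, "outcome": outcome,
                   "estimate": res.estimate, "se": res.mc_standard_error,
                   "n_effective": res.n_effective, "method": res.method,
                   "seed": res.seed}
            if extra:
                row[extra] = e
            rows.append(row)
            i += 1
    return pd.DataFrame(rows)
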