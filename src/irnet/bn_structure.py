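"""Discrete Bayesian-network structure learning.

Score-based learning for categorical data: decomposable log-likelihood /
AIC local scores, greedy hill-climbing over single-arc moves, an exhaustive
enumeration oracle for small node sets, nonparametric bootstrap arc
strengths, and threshold model averaging into a consensus DAG.

Conventions
-----------
* Scores are *maximized*.  ``aic = loglik - k_params`` with
  ``k_params = (r - 1) * q`` where ``r`` is the number of declared levels of
  the node and ``q`` the number of parent configurations.  (The classical
  ``-2*(loglik - k)`` scaling is a monotone transform and would select the
  same graphs.)
* Hill-climbing starts from the empty graph (plus any whitelist), scans
  moves in a fixed order (adds, then deletes, then reversals, each in
  lexicographic arc order) and accepts the first best strictly improving
  legal move, so runs are bit-reproducible.
"""

from __future__ import annotations

import hashlib
import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "DAG",
    "CategoricalData",
    "ScoreCache",
    "ArcStrengthTable",
    "local_score",
    "network_score",
    "hill_climb",
    "exhaustive_search",
    "enumerate_dags",
    "bootstrap_arc_strength",
    "model_average",
    "structural_hamming_distance",
    "read_arc_list",
    "write_arc_list",
]


class CyclicGraphError(ValueError):
    """Raised when an operation would create or received a cyclic graph."""


# ---------------------------------------------------------------------------
# DAG container
# ---------------------------------------------------------------------------

class DAG:
    """A labelled directed acyclic graph.

    Nodes are variable names; arcs are ordered ``(parent, child)`` pairs.
    Acyclicity is enforced on construction and on every mutation.
    """

    def __init__(self, nodes, arcs=()):
        self._nodes = tuple(nodes)
        if len(set(self._nodes)) != len(self._nodes):
            raise ValueError("duplicate node names")
        self._index = {n: i for i, n in enumerate(self._nodes)}
        self._parents = {n: set() for n in self._nodes}
        self.converged = True
        for u, v in arcs:
            self.add_arc(u, v)

    # -- accessors ---------------------------------------------------------
    @property
    def nodes(self):
        return self._nodes

    @property
    def arcs(self):
        """Sorted tuple of (parent, child) pairs."""
        return tuple(sorted((u, v) for v, ps in self._parents.items() for u in ps))

    def parents(self, node):
        return frozenset(self._parents[node])

    def children(self, node):
        self._check(node)
        return frozenset(v for v, ps in self._parents.items() if node in ps)

    def has_arc(self, u, v):
        return u in self._parents[v]

    def _check(self, node):
        if node not in self._index:
            raise KeyError(f"unknown node {node!r}")

    # -- mutation ----------------------------------------------------------
    def add_arc(self, u, v):
        self._check(u)
        self._check(v)
        if u == v:
            raise CyclicGraphError(f"self-arc {u!r}->{v!r}")
        if u in self._parents[v]:
            raise ValueError(f"duplicate arc {u!r}->{v!r}")
        if self._reachable(v, u):
            raise CyclicGraphError(f"arc {u!r}->{v!r} would create a cycle")
        self._parents[v].add(u)

    def remove_arc(self, u, v):
        self._parents[v].discard(u)

    def copy(self):
        g = DAG(self._nodes)
        for v, ps in self._parents.items():
            g._parents[v] = set(ps)
        return g

    # -- graph algorithms --------------------------------------------------
    def _reachable(self, src, dst):
        """True iff a directed path src -> ... -> dst exists (length >= 0)."""
        if src == dst:
            return True
        stack, seen = [src], {src}
        children = {n: [] for n in self._nodes}
        for v, ps in self._parents.items():
            for u in ps:
                children[u].append(v)
        while stack:
            x = stack.pop()
            for y in children[x]:
                if y == dst:
                    return True
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        return False

    def topological_order(self):
        indeg = {n: len(ps) for n, ps in self._parents.items()}
        children = {n: [] for n in self._nodes}
        for v, ps in self._parents.items():
            for u in ps:
                children[u].append(v)
        order = [n for n in self._nodes if indeg[n] == 0]
        out = []
        while order:
            n = order.pop(0)
            out.append(n)
            for c in sorted(children[n]):
                indeg[c] -= 1
                if indeg[c] == 0:
                    order.append(c)
        if len(out) != len(self._nodes):
            raise CyclicGraphError("graph is cyclic")
        return out

    def ancestors(self, node):
        self._check(node)
        out, stack = set(), [node]
        while stack:
            for p in self._parents[stack.pop()]:
                if p not in out:
                    out.add(p)
                    stack.append(p)
        return frozenset(out)

    def descendants(self, node):
        self._check(node)
        out, stack = set(), [node]
        children = {n: [] for n in self._nodes}
        for v, ps in self._parents.items():
            for u in ps:
                children[u].append(v)
        while stack:
            for c in children[stack.pop()]:
                if c not in out:
                    out.add(c)
                    stack.append(c)
        return frozenset(out)

    def skeleton(self):
        """Set of unordered adjacent pairs."""
        return {frozenset((u, v)) for u, v in self.arcs}

    # -- interchange -------------------------------------------------------
    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self._nodes)
        g.add_edges_from(self.arcs)
        return g

    def to_dot(self):
        lines = ["digraph bn {"]
        for n in self._nodes:
            lines.append(f'  "{n}";')
        for u, v in self.arcs:
            lines.append(f'  "{u}" -> "{v}";')
        lines.append("}")
        return "\n".join(lines) + "\n"

    def to_arc_frame(self):
        return pd.DataFrame(self.arcs, columns=["from", "to"])

    @classmethod
    def from_arc_frame(cls, nodes, frame):
        return cls(nodes, [(r["from"], r["to"]) for _, r in frame.iterrows()])

    def __eq__(self, other):
        return (
            isinstance(other, DAG)
            and set(self._nodes) == set(other._nodes)
            and self.arcs == other.arcs
        )

    def __hash__(self):
        return hash((self._nodes, self.arcs))

    def __repr__(self):
        return f"DAG({len(self._nodes)} nodes, {len(self.arcs)} arcs)"


def read_arc_list(path) -> list:
    """Read (from, to) arcs from a delimited file with a header row."""
    frame = pd.read_csv(path)
    return [(r["from"], r["to"]) for _, r in frame.iterrows()]


def write_arc_list(dag: DAG, path, strengths: "ArcStrengthTable | None" = None):
    """Write the DAG's arcs (optionally with bootstrap strengths) as CSV."""
    frame = dag.to_arc_frame()
    if strengths is not None:
        frame["strength"] = [strengths.strength(u, v) for u, v in dag.arcs]
        frame["direction_fraction"] = [
            strengths.direction_fraction(u, v) for u, v in dag.arcs]
    frame.to_csv(path, index=False)


def structural_hamming_distance(a: DAG, b: DAG, skeleton: bool = True) -> int:
    """Edge insertions/deletions (skeleton) or insertions/deletions/flips.

    With ``skeleton=True`` the count is the symmetric difference of the two
    undirected adjacency sets; with ``skeleton=False`` a directed arc present
    in both graphs with opposite orientation counts once.
    """
    if skeleton:
        return len(a.skeleton() ^ b.skeleton())
    sa, sb = set(a.arcs), set(b.arcs)
    flips = sum(1 for (u, v) in sa - sb if (v, u) in sb)
    return len(sa ^ sb) - flips


# ---------------------------------------------------------------------------
# Data container for fast counting
# ---------------------------------------------------------------------------

class CategoricalData:
    """Integer-coded categorical dataset with declared level sets.

    Declared levels (not just observed ones) determine the cardinality used
    in score penalties, so a variable whose sample collapses to one level
    keeps its nominal dimension.
    """

    def __init__(self, df: pd.DataFrame, columns=None, levels: dict | None = None):
        if columns is None:
            columns = list(df.columns)
        self.columns = tuple(columns)
        self.levels = {}
        codes = np.empty((len(df), len(columns)), dtype=np.int64)
        for j, c in enumerate(columns):
            col = df[c]
            if levels is not None and c in levels:
                cat = pd.Categorical(col, categories=list(levels[c]))
            elif isinstance(col.dtype, pd.CategoricalDtype):
                cat = pd.Categorical(col)
            else:
                cat = pd.Categorical(col.astype(str))
            if (cat.codes < 0).any():
                raise ValueError(f"column {c!r} has values outside declared levels")
            self.levels[c] = list(cat.categories)
            codes[:, j] = cat.codes
        self.codes = codes
        self.codes_t = np.ascontiguousarray(codes.T)
        self.card = np.array([len(self.levels[c]) for c in self.columns], dtype=np.int64)

    @property
    def n(self):
        return self.codes.shape[0]

    def fingerprint(self) -> str:
        h = hashlib.sha256()
        h.update(repr(self.columns).encode())
        h.update(repr({c: self.levels[c] for c in self.columns}).encode())
        h.update(np.ascontiguousarray(self.codes).tobytes())
        return h.hexdigest()

    def resample(self, rows: np.ndarray) -> "CategoricalData":
        out = object.__new__(CategoricalData)
        out.columns = self.columns
        out.levels = self.levels
        out.codes = self.codes[rows]
        out.codes_t = np.ascontiguousarray(out.codes.T)
        out.card = self.card
        return out

    @classmethod
    def from_frame(cls, df, columns=None, levels=None):
        return cls(df, columns=columns, levels=levels)


# ---------------------------------------------------------------------------
# Scores
# ---------------------------------------------------------------------------

def _local_score_codes(data: CategoricalData, v: int, parents, kind: str) -> float:
    codes_t, card = data.codes_t, data.card
    r = int(card[v])
    if parents:
        q = 1
        key = codes_t[parents[0]].copy()
        q = int(card[parents[0]])
        for pj in parents[1:]:
            key *= card[pj]
            key += codes_t[pj]
            q *= int(card[pj])
        key *= r
        key += codes_t[v]
        cnt = np.bincount(key, minlength=q * r).reshape(q, r)
    else:
        q = 1
        cnt = np.bincount(codes_t[v], minlength=r).reshape(1, r)
    nj = cnt.sum(axis=1)
    nz = cnt[cnt > 0]
    njnz = nj[nj > 0]
    loglik = float((nz * np.log(nz)).sum() - (njnz * np.log(njnz)).sum())
    if kind == "loglik":
        return loglik
    if kind == "aic":
        return loglik - (r - 1) * q
    raise ValueError(f"unknown score kind {kind!r}")


def local_score(node, parents, data, kind: str = "aic") -> float:
    """Decomposable local score of ``node`` given ``parents``.

    ``loglik`` is the maximized multinomial log-likelihood
    ``sum_jk N_jk * ln(N_jk / N_j)`` (``0 ln 0 = 0``); ``aic`` subtracts the
    free-parameter count ``(r - 1) * q``.
    """
    if node in parents:
        raise ValueError(f"node {node!r} cannot be its own parent")
    if not isinstance(data, CategoricalData):
        data = CategoricalData(data)
    if data.n == 0:
        raise ValueError("empty dataset")
    idx = {c: i for i, c in enumerate(data.columns)}
    return _local_score_codes(data, idx[node], sorted(idx[p] for p in parents), kind)


@dataclass
class ScoreCache:
    """Memoized local scores keyed by (node, parent set), tied to a dataset."""

    fingerprint: str
    kind: str = "aic"
    _table: dict = field(default_factory=dict)

    def key(self, node, parents):
        return (node, frozenset(parents))

    def get(self, node, parents):
        return self._table.get(self.key(node, parents))

    def put(self, node, parents, value):
        self._table[self.key(node, parents)] = value

    def __len__(self):
        return len(self._table)


def network_score(dag: DAG, data, kind: str = "aic", cache: ScoreCache | None = None) -> float:
    """Sum of local scores over the DAG's (node, parent-set) pairs."""
    if not isinstance(data, CategoricalData):
        data = CategoricalData(data, columns=list(dag.nodes))
    missing = set(dag.nodes) - set(data.columns)
    if missing:
        raise ValueError(f"dag nodes missing from data: {sorted(missing)}")
    dag.topological_order()  # raises CyclicGraphError on cycles
    total = 0.0
    for node in dag.nodes:
        ps = dag.parents(node)
        if cache is not None:
            val = cache.get(node, ps)
            if val is None:
                val = local_score(node, ps, data, kind)
                cache.put(node, ps, val)
        else:
            val = local_score(node, ps, data, kind)
        total += val
    return total


# ---------------------------------------------------------------------------
# Hill-climbing search
# ---------------------------------------------------------------------------

def _closure(adj: np.ndarray) -> np.ndarray:
    """Boolean reachability matrix (paths of length >= 1)."""
    reach = adj.copy()
    while True:
        new = reach | (reach @ adj)
        if (new == reach).all():
            return reach
        reach = new


def hill_climb(
    data,
    kind: str = "aic",
    whitelist=(),
    blacklist=(),
    max_iter: int = 10_000,
    eps: float = 1e-9,
) -> DAG:
    """Greedy structure search from the empty graph (plus whitelist).

    Each iteration evaluates every legal single-arc addition, deletion and
    reversal and applies the highest-scoring strictly improving move; the
    search stops at a single-move local optimum.  If ``max_iter`` is
    exhausted first, the returned DAG carries ``converged = False``.
    """
    if not isinstance(data, CategoricalData):
        data = CategoricalData(data)
    cols = data.columns
    p = len(cols)
    idx = {c: i for i, c in enumerate(cols)}
    bl = {(idx[u], idx[v]) for u, v in blacklist}
    wl = {(idx[u], idx[v]) for u, v in whitelist}

    parents = [set() for _ in range(p)]
    adj = np.zeros((p, p), dtype=bool)
    for u, v in wl:
        parents[v].add(u)
        adj[u, v] = True
    if _closure(adj).diagonal().any():
        raise CyclicGraphError("whitelist arcs are cyclic")

    cache: dict = {}

    def ls(v, ps):
        key = (v, ps)
        val = cache.get(key)
        if val is None:
            val = _local_score_codes(data, v, sorted(ps), kind)
            cache[key] = val
        return val

    cur = [ls(v, frozenset(parents[v])) for v in range(p)]
    converged = False
    for _ in range(max_iter):
        reach = _closure(adj)
        best_delta = eps
        best = None
        # additions, lexicographic (u, v)
        for u in range(p):
            row_adj = adj[u]
            col_adj = adj[:, u]
            for v in range(p):
                if u == v or row_adj[v] or col_adj[v] or (u, v) in bl or reach[v, u]:
                    continue
                d = ls(v, frozenset(parents[v] | {u})) - cur[v]
                if d > best_delta:
                    best_delta, best = d, ("add", u, v)
        arcs_sorted = sorted((u, v) for v in range(p) for u in parents[v])
        # deletions
        for u, v in arcs_sorted:
            if (u, v) in wl:
                continue
            d = ls(v, frozenset(parents[v] - {u})) - cur[v]
            if d > best_delta:
                best_delta, best = d, ("delete", u, v)
        # reversals
        for u, v in arcs_sorted:
            if (u, v) in wl or (v, u) in bl:
                continue
            # reversing u->v is illegal iff another directed path u ~> v exists
            if any(w != v and reach[w, v] for w in np.flatnonzero(adj[u])):
                continue
            d = (ls(u, frozenset(parents[u] | {v})) - cur[u]) + (
                ls(v, frozenset(parents[v] - {u})) - cur[v]
            )
            if d > best_delta:
                best_delta, best = d, ("reverse", u, v)

        if best is None:
            converged = True
            break
        op, u, v = best
        if op == "add":
            parents[v].add(u)
            adj[u, v] = True
            cur[v] = ls(v, frozenset(parents[v]))
        elif op == "delete":
            parents[v].discard(u)
            adj[u, v] = False
            cur[v] = ls(v, frozenset(parents[v]))
        else:
            parents[v].discard(u)
            parents[u].add(v)
            adj[u, v] = False
            adj[v, u] = True
            cur[v] = ls(v, frozenset(parents[v]))
            cur[u] = ls(u, frozenset(parents[u]))

    dag = DAG(cols)
    for v in range(p):
        for u in parents[v]:
            dag.add_arc(cols[u], cols[v])
    dag.converged = converged
    if not converged:
        logger.warning("hill_climb: max_iter=%d exhausted before convergence", max_iter)
    return dag


# ---------------------------------------------------------------------------
# Exhaustive oracle
# ---------------------------------------------------------------------------

def enumerate_dags(nodes):
    """Yield every labelled DAG over ``nodes`` (use only for <= 5 nodes)."""
    nodes = tuple(nodes)
    p = len(nodes)
    others = [tuple(j for j in range(p) if j != i) for i in range(p)]
    parent_choices = [
        [frozenset(c) for k in range(p) for c in itertools.combinations(others[i], k)]
        for i in range(p)
    ]

    def acyclic(assign):
        # Kahn's algorithm over the partial assignment
        indeg = {i: len(assign[i]) for i in range(len(assign))}
        ready = [i for i, d in indeg.items() if d == 0]
        seen = 0
        while ready:
            x = ready.pop()
            seen += 1
            for j in indeg:
                if x in assign[j]:
                    indeg[j] -= 1
                    if indeg[j] == 0:
                        ready.append(j)
        return seen == len(assign)

    for combo in itertools.product(*parent_choices):
        if acyclic(list(combo)):
            yield DAG(nodes, [(nodes[u], nodes[v]) for v in range(p) for u in combo[v]])


def exhaustive_search(data, kind: str = "aic", max_nodes: int = 5) -> DAG:
    """Globally optimal DAG by enumeration; ties break to the
    lexicographically smallest arc set."""
    if not isinstance(data, CategoricalData):
        data = CategoricalData(data)
    if len(data.columns) > max_nodes or len(data.columns) > 5:
        raise ValueError(f"exhaustive search limited to 5 nodes, got {len(data.columns)}")
    idx = {c: i for i, c in enumerate(data.columns)}
    cache: dict = {}

    def ls(node, ps):
        key = (node, ps)
        if key not in cache:
            cache[key] = _local_score_codes(data, idx[node], sorted(idx[x] for x in ps), kind)
        return cache[key]

    best_score, best_arcs, best_dag = -np.inf, None, None
    for dag in enumerate_dags(data.columns):
        s = sum(ls(n, dag.parents(n)) for n in dag.nodes)
        arcs = dag.arcs
        if s > best_score + 1e-12 or (
            abs(s - best_score) <= 1e-12 and (best_arcs is None or arcs < best_arcs)
        ):
            best_score, best_arcs, best_dag = s, arcs, dag
    return best_dag


# ---------------------------------------------------------------------------
# Bootstrap arc strengths and model averaging
# ---------------------------------------------------------------------------

@dataclass
class ArcStrengthTable:
    """Bootstrap adjacency and direction frequencies per unordered pair.

    ``table`` has one row per pair ``(x, y)`` with ``x < y``:
    ``adjacency`` = fraction of bootstrap networks containing the pair in
    either direction, ``dir_xy`` = fraction containing ``x -> y``.
    """

    table: pd.DataFrame
    B: int
    seed: int

    def strength(self, x, y):
        a, b = sorted((x, y))
        row = self.table[(self.table["x"] == a) & (self.table["y"] == b)]
        return float(row["adjacency"].iloc[0]) if len(row) else 0.0

    def direction_fraction(self, x, y):
        """Fraction of bootstrap networks containing exactly x -> y."""
        a, b = sorted((x, y))
        row = self.table[(self.table["x"] == a) & (self.table["y"] == b)]
        if not len(row):
            return 0.0
        d = float(row["dir_xy"].iloc[0])
        return d if (x, y) == (a, b) else float(row["adjacency"].iloc[0]) - d


def bootstrap_arc_strength(
    data,
    B: int,
    seed: int,
    kind: str = "aic",
    whitelist=(),
    blacklist=(),
    weights=None,
    max_redraws: int = 100,
) -> ArcStrengthTable:
    """Arc frequencies over ``B`` nonparametric bootstrap resamples.

    Rows are resampled with replacement at full size (unweighted by default;
    pass survey ``weights`` to resample proportional to weight for
    sensitivity analysis).  A resample in which any variable collapses to a
    single observed level is redrawn and the event logged.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if not isinstance(data, CategoricalData):
        data = CategoricalData(data)
    n = data.n
    rng = np.random.default_rng(seed)
    prob = None
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        prob = w / w.sum()
    cols = data.columns
    adj_counts: dict = {}
    dir_counts: dict = {}
    redraws = 0
    for _ in range(B):
        for _attempt in range(max_redraws):
            rows = rng.choice(n, size=n, replace=True, p=prob)
            sub = data.resample(rows)
            degenerate = any(
                np.unique(sub.codes[:, j]).size < 2 for j in range(len(cols))
            )
            if not degenerate:
                break
            redraws += 1
            logger.info("bootstrap_arc_strength: degenerate resample redrawn")
        else:
            raise RuntimeError("could not draw a non-degenerate bootstrap resample")
        g = hill_climb(sub, kind=kind, whitelist=whitelist, blacklist=blacklist)
        for u, v in g.arcs:
            a, b = sorted((u, v))
            adj_counts[(a, b)] = adj_counts.get((a, b), 0) + 1
            if (u, v) == (a, b):
                dir_counts[(a, b)] = dir_counts.get((a, b), 0) + 1
    rows_out = [
        {
            "x": a,
            "y": b,
            "adjacency": adj_counts[(a, b)] / B,
            "dir_xy": dir_counts.get((a, b), 0) / B,
        }
        for (a, b) in sorted(adj_counts)
    ]
    table = pd.DataFrame(rows_out, columns=["x", "y", "adjacency", "dir_xy"])
    if redraws:
        logger.info("bootstrap_arc_strength: %d degenerate resamples redrawn", redraws)
    return ArcStrengthTable(table=table, B=B, seed=seed)


def model_average(strengths: ArcStrengthTable, threshold: float = 0.75, nodes=None) -> DAG:
    """Consensus DAG keeping pairs with adjacency strength >= threshold.

    Each kept pair is oriented by its majority direction (exact ties go to
    the lexicographically smaller orientation, logged).  If the oriented
    graph is cyclic, the kept arc with the smallest adjacency strength is
    dropped repeatedly until acyclic; dropped arcs are recorded on the
    returned DAG as ``dropped_for_acyclicity``.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    tab = strengths.table
    kept = tab[tab["adjacency"] >= threshold].sort_values(["x", "y"])
    if nodes is None:
        nodes = sorted(set(tab["x"]) | set(tab["y"]))
    oriented = []
    for _, row in kept.iterrows():
        x, y, adjacency, dir_xy = row["x"], row["y"], row["adjacency"], row["dir_xy"]
        if dir_xy > adjacency - dir_xy:
            arc = (x, y)
        elif dir_xy < adjacency - dir_xy:
            arc = (y, x)
        else:
            arc = (x, y)  # exact tie: lexicographic orientation
            logger.info("model_average: direction tie for pair (%s, %s); using %s->%s",
                        x, y, x, y)
        oriented.append((arc, float(adjacency)))
    oriented.sort(key=lambda t: (-t[1], t[0]))
    dropped = []
    while True:
        try:
            dag = DAG(nodes, [a for a, _ in oriented])
            break
        except CyclicGraphError:
            arc, s = min(oriented, key=lambda t: (t[1], t[0]))
            oriented.remove((arc, s))
            dropped.append(arc)
            logger.warning("model_average: dropped %s->%s (strength %.3f) to break cycle",
                           arc[0], arc[1], s)
    dag.dropped_for_acyclicity = dropped  # type: ignore[attr-defined]
    return dag
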